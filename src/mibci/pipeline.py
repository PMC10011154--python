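"""Calibration and online decoding: the FBCSP + PSO + LDA pipeline.

Calibration (offline) learns, from one recorded session, everything the
testing (online) mode needs: per-band FIR coefficients, CSP spatial
filters, the PSO-selected feature mask and the LDA hyperplane.  The online
contract is strict causality — a 1-s window is notch- and band-filtered in
isolation, so the decision depends only on samples inside the window.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .csp import BandCSP, apply_csp, fit_csp
from .filters import (
    FilterBankSpec,
    bandpass_array,
    design_fir_notch,
    filter_bank,
)
from .pso import PSOConfig, PSOResult, pso_select
from .protocol import mi_windows, rest_windows
from .synth import EEGRecord

MI, REST = "mi", "rest"
LOGVAR_EPS = 1e-12
LDA_COND_MAX = 1e6


def fit_lda(features: np.ndarray, labels: np.ndarray):
    """Two-class LDA with equal priors; returns (weights, bias, estimator).

    Weights are proportional to pooled-covariance^-1 (mu_1 - mu_0) and the
    bias places the boundary midway between the projected class means.
    Ledoit-Wolf shrinkage is applied when the pooled covariance is
    ill-conditioned (condition number above 1e6).
    """
    features = np.asarray(features, float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("LDA requires exactly two classes")
    pooled = sum(
        np.cov(features[labels == c].T, ddof=1) * (np.sum(labels == c) - 1)
        for c in classes
    ) / (len(labels) - 2)
    pooled = np.atleast_2d(pooled)
    shrinkage = None
    if not np.all(np.isfinite(pooled)) or np.linalg.cond(pooled) > LDA_COND_MAX:
        shrinkage = "auto"
    clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=shrinkage,
                                     priors=[0.5, 0.5])
    clf.fit(features, labels)
    return clf.coef_.ravel().copy(), float(clf.intercept_[0]), clf


@dataclass
class PipelineModel:
    """Trained decoder bundle used by the online testing mode."""

    bank: FilterBankSpec
    fs: float
    n_channels: int
    m_pairs: int
    csp: list[BandCSP]
    mask: np.ndarray            # boolean, length n_bands * 2m
    lda_weights: np.ndarray     # over the selected features
    lda_bias: float
    threshold: float = 0.0
    labels: tuple[str, str] = (REST, MI)   # (negative side, positive side)
    pso_fitness: float | None = None

    @property
    def n_features(self) -> int:
        return self.bank.n_bands * 2 * self.m_pairs

    def to_json(self) -> str:
        return json.dumps(
            {
                "bands": list(self.bank.bands),
                "order": self.bank.order,
                "notch_freq": self.bank.notch_freq,
                "fs": self.fs,
                "n_channels": self.n_channels,
                "m_pairs": self.m_pairs,
                "csp_filters": [b.filters.tolist() for b in self.csp],
                "csp_eigenvalues": [b.eigenvalues.tolist() for b in self.csp],
                "mask": self.mask.astype(int).tolist(),
                "lda_weights": self.lda_weights.tolist(),
                "lda_bias": self.lda_bias,
                "threshold": self.threshold,
                "pso_fitness": self.pso_fitness,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "PipelineModel":
        o = json.loads(text)
        bank = FilterBankSpec(
            bands=tuple(tuple(b) for b in o["bands"]),
            order=o["order"], notch_freq=o["notch_freq"],
        )
        csp = [
            BandCSP(np.asarray(f, float), np.asarray(e, float))
            for f, e in zip(o["csp_filters"], o["csp_eigenvalues"])
        ]
        return cls(
            bank=bank, fs=o["fs"], n_channels=o["n_channels"],
            m_pairs=o["m_pairs"], csp=csp,
            mask=np.asarray(o["mask"], bool),
            lda_weights=np.asarray(o["lda_weights"], float),
            lda_bias=o["lda_bias"], threshold=o["threshold"],
            pso_fitness=o.get("pso_fitness"),
        )


def _window_bands(window: np.ndarray, notch_taps: np.ndarray,
                  band_taps: list[np.ndarray]) -> list[np.ndarray]:
    """Causally notch + band-filter one raw window, per filter-bank band."""
    notched = bandpass_array(window, notch_taps)
    return [bandpass_array(notched, taps) for taps in band_taps]


def logvar_features(band_windows: list[np.ndarray], csp: list[BandCSP],
                    eps: float = LOGVAR_EPS) -> np.ndarray:
    """Log-variance of every CSP projection, band-major / filter-minor."""
    feats = []
    for bw, bc in zip(band_windows, csp):
        proj = apply_csp(bw, bc)
        feats.append(np.log(np.maximum(proj.var(axis=1, ddof=0), eps)))
    return np.concatenate(feats)


def extract_features(record: EEGRecord, model: PipelineModel) -> np.ndarray:
    notch = design_fir_notch(model.bank.notch_freq, model.bank.order, model.fs)
    taps = filter_bank(model.bank, model.fs)
    return logvar_features(_window_bands(record.data, notch, taps), model.csp)


def calibrate(
    session: list[EEGRecord],
    bank: FilterBankSpec = FilterBankSpec(),
    m_pairs: int = 3,
    pso_config: PSOConfig = PSOConfig(),
    min_trials: int = 20,
) -> PipelineModel:
    """Train the full decoder from a calibration session.

    MI-period windows form the positive class, pre-cue rest windows the
    negative class (4 + 4 per trial — balanced by construction).
    """
    if len(session) < min_trials:
        raise ValueError(f"need at least {min_trials} trials, got {len(session)}")
    fs = session[0].fs
    n_channels = session[0].n_channels
    notch_taps = design_fir_notch(bank.notch_freq, bank.order, fs)
    band_taps = filter_bank(bank, fs)

    per_class: dict[str, list[list[np.ndarray]]] = {MI: [], REST: []}
    for rec in session:
        tl = rec.timeline
        if tl is None:
            raise ValueError("calibration records need trial timelines")
        for spec_list, label in ((mi_windows(tl), MI), (rest_windows(tl), REST)):
            for w in spec_list:
                raw = rec.slice_window(w.start, w.end).data
                per_class[label].append(_window_bands(raw, notch_taps, band_taps))

    csp_models = [
        fit_csp(
            [bw[b] for bw in per_class[MI]],
            [bw[b] for bw in per_class[REST]],
            m=m_pairs,
        )
        for b in range(bank.n_bands)
    ]

    feats, labels = [], []
    for label in (MI, REST):
        for bw in per_class[label]:
            feats.append(logvar_features(bw, csp_models))
            labels.append(1 if label == MI else 0)
    feats = np.asarray(feats)
    labels = np.asarray(labels)

    sel: PSOResult = pso_select(feats, labels, pso_config)
    w, b, _ = fit_lda(feats[:, sel.mask], labels)

    return PipelineModel(
        bank=bank, fs=fs, n_channels=n_channels, m_pairs=m_pairs,
        csp=csp_models, mask=sel.mask, lda_weights=w, lda_bias=b,
        pso_fitness=sel.fitness,
    )


def decision_value(window: EEGRecord, model: PipelineModel) -> float:
    if window.n_channels != model.n_channels:
        raise ValueError("window channel count does not match the model")
    if window.n_samples != int(round(model.fs)):
        raise ValueError("online windows must be exactly 1 s of samples")
    x = extract_features(window, model)[model.mask]
    return float(model.lda_weights @ x + model.lda_bias)


def classify_window(window: EEGRecord, model: PipelineModel) -> str:
    """Label a 1-s window as ``"mi"`` or ``"rest"`` (causal, deterministic)."""
    return MI if decision_value(window, model) > model.threshold else REST


def classify_trial(record: EEGRecord, model: PipelineModel) -> dict[str, list[str]]:
    """Labels for the scored windows of one trial, keyed by phase."""
    tl = record.timeline
    out = {"rest": [], "mi": []}
    for w in rest_windows(tl) + mi_windows(tl):
        lab = classify_window(record.slice_window(w.start, w.end), model)
        out[w.phase].append(lab)
    return out


def cross_validated_accuracy(
    session: list[EEGRecord],
    n_folds: int = 5,
    seed: int = 0,
    **calibrate_kwargs,
) -> float:
    """Trial-level k-fold accuracy of the full pipeline (refit per fold)."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(session))
    folds = np.array_split(order, n_folds)
    correct = total = 0
    for fold in folds:
        test_idx = set(int(i) for i in fold)
        train = [session[i] for i in range(len(session)) if i not in test_idx]
        model = calibrate(train, min_trials=2, **calibrate_kwargs)
        for i in sorted(test_idx):
            labels = classify_trial(session[i], model)
            correct += labels["mi"].count(MI) + labels["rest"].count(REST)
            total += len(labels["mi"]) + len(labels["rest"])
    return correct / total
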