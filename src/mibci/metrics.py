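"""Window-level decoder performance (Sens, CA) and the paired condition test.

Scoring is at the 1-s window level: the four MI-period windows of a trial
are positive ground truth, the four pre-cue rest windows negative.  Counts
are pooled over all trials of a participant's testing phase before the
percentages are computed, giving one Sens/CA value per participant and
condition.  The paired comparison across participants uses a
Lilliefors-corrected Kolmogorov-Smirnov normality check followed by a
two-sided Wilcoxon signed-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

from .pipeline import MI

WILCOXON_EXACT_MAX_N = 12


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.tn + other.tn,
                               self.fp + other.fp, self.fn + other.fn)

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def tally_confusion(predictions: list[str], phases: list[str]) -> ConfusionCounts:
    """Count TP/TN/FP/FN from per-window predictions and ground-truth phases."""
    if len(predictions) != len(phases):
        raise ValueError("one prediction per scored window required")
    tp = tn = fp = fn = 0
    for pred, phase in zip(predictions, phases):
        if phase == "mi":
            if pred == MI:
                tp += 1
            else:
                fn += 1
        elif phase == "rest":
            if pred == MI:
                fp += 1
            else:
                tn += 1
        else:
            raise ValueError(f"unknown phase {phase!r}")
    return ConfusionCounts(tp, tn, fp, fn)


def sensitivity(counts: ConfusionCounts) -> float:
    """Percent of MI-period windows recognized as MI: 100 * TP/(TP+FN)."""
    if counts.tp + counts.fn == 0:
        raise ValueError("sensitivity undefined: no MI-period windows scored")
    return 100.0 * counts.tp / (counts.tp + counts.fn)


def specificity(counts: ConfusionCounts) -> float:
    if counts.tn + counts.fp == 0:
        raise ValueError("specificity undefined: no rest-period windows scored")
    return 100.0 * counts.tn / (counts.tn + counts.fp)


def classification_accuracy(counts: ConfusionCounts) -> float:
    """Percent of all scored windows classified correctly."""
    if counts.total == 0:
        raise ValueError("accuracy undefined on zero windows")
    return 100.0 * (counts.tp + counts.tn) / counts.total


@dataclass(frozen=True)
class ParticipantPerformance:
    participant_id: str
    condition: str
    counts: ConfusionCounts

    @property
    def sens(self) -> float:
        return sensitivity(self.counts)

    @property
    def ca(self) -> float:
        return classification_accuracy(self.counts)


def performance_table(perfs: list[ParticipantPerformance]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "participant": p.participant_id, "condition": p.condition,
                "tp": p.counts.tp, "tn": p.counts.tn,
                "fp": p.counts.fp, "fn": p.counts.fn,
                "sens": p.sens, "ca": p.ca,
            }
            for p in perfs
        ]
    )


def _pratt_ranks(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Average ranks of |d| including zeros; returns (ranks, nonzero mask)."""
    ranks = stats.rankdata(np.abs(d))
    return ranks, d != 0


def wilcoxon_signed_rank(diffs: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are handled with the Pratt convention (ranked, then
    dropped from the statistic).  For n <= 12 the p-value comes from exact
    enumeration of all sign patterns; larger samples use the normal
    approximation with tie correction and continuity correction.
    Returns (W+, p).
    """
    d = np.asarray(diffs, float)
    if d.size < 2:
        raise ValueError("need at least two paired differences")
    ranks, nonzero = _pratt_ranks(d)
    if not nonzero.any():
        return 0.0, 1.0
    w_plus = float(ranks[nonzero & (d > 0)].sum())
    r = ranks[nonzero]
    k = r.size
    if k <= WILCOXON_EXACT_MAX_N:
        t_obs = float(np.sum(np.sign(d[nonzero]) * r))
        count = 0
        for signs in product((-1.0, 1.0), repeat=k):
            if abs(float(np.dot(signs, r))) >= abs(t_obs) - 1e-12:
                count += 1
        return w_plus, count / 2.0**k
    res = stats.wilcoxon(d, zero_method="pratt", correction=True,
                         method="approx")
    return w_plus, float(res.pvalue)


def lilliefors_normal(sample: np.ndarray, alpha: float = 0.05) -> tuple[bool, float]:
    """Lilliefors-corrected KS test; returns (is_gaussian_at_alpha, p)."""
    stat, p = lilliefors(np.asarray(sample, float), dist="norm")
    return bool(p >= alpha), float(p)


def compare_conditions(
    perf_a: np.ndarray, perf_b: np.ndarray, alpha: float = 0.05
) -> dict:
    """Paired comparison of per-participant metric values across conditions.

    Returns normality flags for both samples (Lilliefors-corrected KS),
    the two-sided Wilcoxon signed-rank p-value, medians, means and the
    per-participant differences (a - b).
    """
    a = np.asarray(perf_a, float)
    b = np.asarray(perf_b, float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if a.size < 6:
        raise ValueError("need at least 6 paired participants")
    diffs = a - b
    norm_a = lilliefors_normal(a, alpha)
    norm_b = lilliefors_normal(b, alpha)
    w_plus, p = wilcoxon_signed_rank(diffs)
    return {
        "normal_a": norm_a[0], "lilliefors_p_a": norm_a[1],
        "normal_b": norm_b[0], "lilliefors_p_b": norm_b[1],
        "w_plus": w_plus, "p_value": p,
        "median_a": float(np.median(a)), "median_b": float(np.median(b)),
        "mean_a": float(np.mean(a)), "mean_b": float(np.mean(b)),
        "differences": diffs,
        "significant": p < alpha,
    }
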