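"""Time-frequency ERD/ERS mapping with complex Morlet wavelets.

The offline chain: common-average re-referencing, zero-phase 8-30 Hz FIR
filtering, amplitude-threshold artifact rejection, then for every channel
the time-varying power

    P(t, f) = | w(t, f) * S(t) |^2

from the convolution with a complex Morlet wavelet family

    w(t, f0) = A exp(-t^2 / 2 sigma_t^2) exp(2 i pi f0 t),
    A = (1 / (sigma_t sqrt(pi)))^(1/2),   f0 / sigma_f = 6,
    sigma_t = 1 / (2 pi sigma_f),

on a 0-8 s x 8-30 Hz grid (0.1 s and 0.5 Hz resolution).  Power is
baseline-normalized into ERD/ERS = (P - P_R) / P_R, where P_R is the
average power over an interval of the pre-cue rest period; ERD (power
suppression) is negative.  Normalization is applied per (channel,
frequency) bin and band values are averaged afterwards, so the map values
keep the exact per-bin fractional-change semantics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sg

from .filters import design_fir_bandpass
from .synth import EEGRecord

#: Analysis grid defaults.
FREQS_DEFAULT = np.arange(8.0, 30.0 + 1e-9, 0.5)   # 45 frequencies
TIMES_DEFAULT = np.arange(0.0, 8.0 + 1e-9, 0.1)    # 81 time points
BANDS = {"alpha": (8.0, 13.0), "beta": (14.0, 30.0)}
BASELINE_DEFAULT = (1.0, 3.5)
ARTIFACT_THRESHOLD_UV = 100.0
WAVELET_RATIO = 6.0
SUPPORT_SIGMAS = 5.0


def car_filter(record: EEGRecord) -> EEGRecord:
    """Common average reference: subtract the instantaneous channel mean."""
    if record.n_channels < 2:
        raise ValueError("CAR needs at least two channels")
    data = record.data - record.data.mean(axis=0, keepdims=True)
    return EEGRecord(data, record.fs, record.labels, record.timeline,
                     record.condition, record.trial_index)


def broadband_filter(record: EEGRecord, low: float = 8.0, high: float = 30.0,
                     order: int = 30) -> EEGRecord:
    """Zero-phase (forward-backward) 8-30 Hz FIR filtering for offline maps."""
    taps = design_fir_bandpass(low, high, order, record.fs)
    data = sg.filtfilt(taps, 1.0, record.data, axis=1)
    return EEGRecord(data, record.fs, record.labels, record.timeline,
                     record.condition, record.trial_index)


def reject_artifacts(
    trials: list[EEGRecord],
    threshold_uv: float = ARTIFACT_THRESHOLD_UV,
    prefiltered: bool = False,
) -> tuple[list[EEGRecord], list[dict]]:
    """Drop trials whose 8-30 Hz-filtered amplitude exceeds the threshold.

    Automated stand-in for per-trial visual inspection: a trial is rejected
    iff any channel's absolute amplitude crosses ``threshold_uv`` after
    band-pass filtering (skipped when ``prefiltered``).  Returns
    (kept trials, per-trial report).
    """
    if threshold_uv <= 0:
        raise ValueError("threshold must be positive")
    kept, report = [], []
    for i, rec in enumerate(trials):
        checked = rec if prefiltered else broadband_filter(rec)
        peak = float(np.abs(checked.data).max())
        ok = peak <= threshold_uv
        report.append({"trial": i, "peak_uv": peak, "kept": ok})
        if ok:
            kept.append(rec)
    return kept, report


@dataclass(frozen=True)
class MorletParams:
    """Complex Morlet wavelet at center frequency ``f0`` with f0/sigma_f ratio."""

    f0: float
    ratio: float = WAVELET_RATIO

    def __post_init__(self) -> None:
        if self.f0 <= 0 or self.ratio <= 0:
            raise ValueError("f0 and ratio must be positive")

    @property
    def sigma_f(self) -> float:
        return self.f0 / self.ratio

    @property
    def sigma_t(self) -> float:
        return 1.0 / (2.0 * np.pi * self.sigma_f)

    @property
    def norm(self) -> float:
        return (1.0 / (self.sigma_t * np.sqrt(np.pi))) ** 0.5


def morlet_wavelet(params: MorletParams, fs: float,
                   support_sigmas: float = SUPPORT_SIGMAS) -> np.ndarray:
    """Sampled complex Morlet wavelet on [-k sigma_t, +k sigma_t]."""
    if fs <= 2 * params.f0:
        raise ValueError("sampling rate must exceed twice the center frequency")
    half = int(np.ceil(support_sigmas * params.sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    return params.norm * np.exp(-(t**2) / (2.0 * params.sigma_t**2)) * np.exp(
        2j * np.pi * params.f0 * t
    )


def tf_power(
    x: np.ndarray,
    fs: float,
    freqs: np.ndarray = FREQS_DEFAULT,
    times: np.ndarray = TIMES_DEFAULT,
    ratio: float = WAVELET_RATIO,
) -> np.ndarray:
    """Wavelet power of one channel on the (freqs x times) grid.

    The signal is reflection-padded by the wavelet support so grid points
    near the trial edges do not see zero-padding.  Raises if the grid
    extends past the signal.
    """
    x = np.asarray(x, float)
    idx = np.round(np.asarray(times) * fs).astype(int)
    if idx.min() < 0 or idx.max() >= x.size:
        raise ValueError("time grid extends past the signal")
    out = np.empty((len(freqs), len(times)))
    for i, f0 in enumerate(freqs):
        w = morlet_wavelet(MorletParams(f0, ratio), fs)
        half = (len(w) - 1) // 2
        pad = min(half, x.size - 1)
        xp = np.pad(x, pad, mode="reflect")
        conv = sg.fftconvolve(xp, w, mode="same")[pad : pad + x.size]
        out[i] = np.abs(conv[idx]) ** 2 / fs
    return out


@dataclass
class TFPower:
    """channel x frequency x time wavelet power, with its axes."""

    values: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.labels), len(self.freqs), len(self.times)):
            raise ValueError("values shape must match axes")
        if np.any(self.values < 0):
            raise ValueError("power must be non-negative")


def tf_power_record(
    record: EEGRecord,
    freqs: np.ndarray = FREQS_DEFAULT,
    times: np.ndarray = TIMES_DEFAULT,
    ratio: float = WAVELET_RATIO,
) -> TFPower:
    vals = np.stack(
        [tf_power(record.data[c], record.fs, freqs, times, ratio)
         for c in range(record.n_channels)]
    )
    return TFPower(vals, np.asarray(freqs, float), np.asarray(times, float),
                   record.labels)


@dataclass
class ERDSMap:
    """channel x frequency x time baseline-normalized power change."""

    values: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    labels: tuple[str, ...]
    baseline: tuple[float, float] = BASELINE_DEFAULT

    def same_grid(self, other: "ERDSMap") -> bool:
        return (
            self.values.shape == other.values.shape
            and np.allclose(self.freqs, other.freqs)
            and np.allclose(self.times, other.times)
        )


def erds_map(power: TFPower,
             baseline_interval: tuple[float, float] = BASELINE_DEFAULT) -> ERDSMap:
    """Normalize power to fractional change from the rest baseline.

    P_R is the per-(channel, frequency) time average of P over
    ``baseline_interval``; the map is (P - P_R) / P_R, so -0.4 means 40%
    power suppression (ERD) and +1 a doubling (ERS).
    """
    lo, hi = baseline_interval
    sel = (power.times >= lo) & (power.times <= hi)
    if not sel.any():
        raise ValueError("baseline interval outside the time grid")
    p_r = power.values[:, :, sel].mean(axis=2, keepdims=True)
    if np.any(p_r <= 0):
        raise ValueError("zero baseline power; cannot normalize")
    return ERDSMap((power.values - p_r) / p_r, power.freqs, power.times,
                   power.labels, baseline_interval)


def band_summary(
    emap: ERDSMap,
    band: str | tuple[float, float],
    interval: tuple[float, float],
) -> np.ndarray:
    """Mean map value per channel over a frequency band and a time interval."""
    lo, hi = BANDS[band] if isinstance(band, str) else band
    fsel = (emap.freqs >= lo) & (emap.freqs <= hi)
    tsel = (emap.times >= interval[0]) & (emap.times <= interval[1])
    if not fsel.any() or not tsel.any():
        raise ValueError("empty band or interval selection")
    return emap.values[:, fsel][:, :, tsel].mean(axis=(1, 2))


def topography_table(
    emap: ERDSMap,
    interval: tuple[float, float],
    bands: tuple[str, ...] = ("alpha", "beta"),
):
    """Long-form per-channel band summaries (for CSV export / topo plots)."""
    import pandas as pd

    rows = []
    for band in bands:
        vals = band_summary(emap, band, interval)
        for ch, v in zip(emap.labels, vals):
            rows.append((ch, band, interval[0], interval[1], float(v)))
    return pd.DataFrame(
        rows, columns=["channel", "band", "interval_start", "interval_end",
                       "value"])


def average_maps(maps: list[ERDSMap]) -> ERDSMap:
    """Element-wise mean of maps on identical grids (trial average)."""
    first = maps[0]
    for m in maps[1:]:
        if not first.same_grid(m):
            raise ValueError("maps must share an identical grid")
    vals = np.mean([m.values for m in maps], axis=0)
    return ERDSMap(vals, first.freqs, first.times, first.labels, first.baseline)


def grand_average(per_participant: list[ERDSMap | list[ERDSMap]]) -> ERDSMap:
    """Mean over participants of per-participant (trial-averaged) maps."""
    averaged = [
        average_maps(m) if isinstance(m, list) else m for m in per_participant
    ]
    return average_maps(averaged)


def session_erds(
    trials: list[EEGRecord],
    baseline_interval: tuple[float, float] = BASELINE_DEFAULT,
    freqs: np.ndarray = FREQS_DEFAULT,
    times: np.ndarray = TIMES_DEFAULT,
    threshold_uv: float = ARTIFACT_THRESHOLD_UV,
    ratio: float = WAVELET_RATIO,
) -> ERDSMap:
    """Full offline chain for one session: 8-30 Hz zero-phase filtering,
    CAR, artifact rejection, wavelet power averaged over trials, then
    baseline normalization of the average.

    Normalizing the trial-averaged power (rather than averaging per-trial
    ratios) is the standard ERD estimator: it avoids the upward ratio bias
    a noisy single-trial baseline induces.

    The band-pass step does not change the maps (the normalization in
    ``erds_map`` is a per-frequency ratio, invariant to linear filtering)
    but matches the offline processing order and keeps the rejection
    threshold referenced to in-band amplitude.
    """
    filtered = [car_filter(broadband_filter(t)) for t in trials]
    kept, _ = reject_artifacts(filtered, threshold_uv, prefiltered=True)
    if not kept:
        raise ValueError("all trials rejected")
    powers = [tf_power_record(t, freqs, times, ratio) for t in kept]
    avg = TFPower(
        np.mean([p.values for p in powers], axis=0),
        powers[0].freqs, powers[0].times, powers[0].labels,
    )
    return erds_map(avg, baseline_interval)
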