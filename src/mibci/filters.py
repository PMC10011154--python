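"""FIR filtering for the decoder: 30th-order band-pass filter bank and notch.

All online filtering is causal (forward-only ``lfilter``): the testing mode
classifies 1-s windows in real time and must not look at future samples.
The offline spectral analysis uses its own zero-phase chain (see
:mod:`mibci.erds`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .synth import EEGRecord

#: Filter bank of the decoder, Hz.
DEFAULT_BANDS: tuple[tuple[float, float], ...] = (
    (8, 12), (12, 16), (16, 20), (20, 24), (24, 28), (28, 32),
)
DEFAULT_ORDER = 30
DEFAULT_NOTCH = 60.0  # mains frequency at the recording site


@dataclass(frozen=True)
class FilterBankSpec:
    bands: tuple[tuple[float, float], ...] = DEFAULT_BANDS
    order: int = DEFAULT_ORDER
    notch_freq: float = DEFAULT_NOTCH

    def __post_init__(self) -> None:
        if self.order <= 0 or self.order % 2:
            raise ValueError("FIR order must be even and positive")
        for (lo, hi), (lo2, _) in zip(self.bands, self.bands[1:]):
            if not (lo < hi and hi == lo2):
                raise ValueError("bands must be contiguous and increasing")

    @property
    def n_bands(self) -> int:
        return len(self.bands)


def design_fir_bandpass(low: float, high: float, order: int, fs: float) -> np.ndarray:
    """Linear-phase band-pass FIR (Hamming window design), ``order + 1`` taps."""
    if not 0 < low < high < fs / 2:
        raise ValueError(f"invalid band edges ({low}, {high}) at fs={fs}")
    return signal.firwin(order + 1, [low, high], pass_zero=False, fs=fs)


def design_fir_notch(notch_freq: float, order: int, fs: float,
                     half_width: float = 2.0) -> np.ndarray:
    """Linear-phase FIR notch: identity minus a narrow band-pass.

    The construction places an exact spectral null at ``notch_freq`` while
    keeping the passband within a few percent of unity, which a plain
    window-design band-stop cannot achieve at order 30.
    """
    if not 0 < notch_freq < fs / 2:
        raise ValueError("notch frequency must lie in (0, fs/2)")
    bp = signal.firwin(
        order + 1, [notch_freq - half_width, notch_freq + half_width],
        pass_zero=False, fs=fs,
    )
    h = -bp
    h[order // 2] += 1.0
    return h


def filter_bank(spec: FilterBankSpec, fs: float) -> list[np.ndarray]:
    return [design_fir_bandpass(lo, hi, spec.order, fs) for lo, hi in spec.bands]


def apply_fir(record: EEGRecord, taps: np.ndarray) -> EEGRecord:
    """Causal FIR filtering along time, all channels."""
    out = signal.lfilter(taps, 1.0, record.data, axis=1)
    return EEGRecord(out, record.fs, record.labels, record.timeline,
                     record.condition, record.trial_index)


def apply_notch(record: EEGRecord, notch_freq: float = DEFAULT_NOTCH,
                order: int = DEFAULT_ORDER) -> EEGRecord:
    """Causal notch filtering; power at the notch frequency drops >= 10x."""
    return apply_fir(record, design_fir_notch(notch_freq, order, record.fs))


def bandpass_array(data: np.ndarray, taps: np.ndarray) -> np.ndarray:
    return signal.lfilter(taps, 1.0, data, axis=-1)
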