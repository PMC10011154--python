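"""Synthetic multi-channel EEG with planted sensorimotor ERD.

The generator emulates the statistical structure the downstream analysis
assumes, not the biophysics of the head: per channel the signal is

* Gaussian 1/f^alpha background noise (independent across channels), plus
* a mu-band (~10 Hz) and a beta-band (~20 Hz) rhythm, each produced by a
  lateralized cortical "source" whose gain over the electrodes is a
  Gaussian kernel in the head plane.

During the motor-imagery period the oscillator envelope of a source is
scaled by sqrt(1 + erd), so band *power* scales by (1 + erd) — exactly the
quantity the ERD/ERS normalization (P - P_R)/P_R estimates.  Envelope
transitions use a 250-ms raised-cosine ramp to avoid broadband splatter.
Right-hand MI puts the contralateral source over C3 and its mirror over C4,
each with its own ERD depth, so bilateral, contralateral-only and
ipsilateral-only effects can all be planted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .montage import Montage, DEFAULT_MONTAGE
from .protocol import (
    SessionSchedule,
    TrialTimeline,
)

FS_DEFAULT = 256.0
RAMP_SECONDS = 0.25


@dataclass
class EEGRecord:
    """channels x samples EEG matrix in microvolts."""

    data: np.ndarray
    fs: float
    labels: tuple[str, ...]
    timeline: TrialTimeline | None = None
    condition: str | None = None
    trial_index: int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if self.data.shape[0] != len(self.labels):
            raise ValueError("row count must match number of labels")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data must be finite")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def slice_window(self, start: float, end: float) -> "EEGRecord":
        i0 = int(round(start * self.fs))
        i1 = int(round(end * self.fs))
        if i1 > self.n_samples:
            raise ValueError("window extends past record end")
        return EEGRecord(self.data[:, i0:i1], self.fs, self.labels,
                         self.timeline, self.condition, self.trial_index)


@dataclass(frozen=True)
class BandEffect:
    """Planted fractional MI power change per hemisphere for one band.

    Values follow the ERD/ERS sign convention: negative = desynchronization.
    ``contra`` is the hemisphere contralateral to the imagined (right) hand,
    i.e. the left hemisphere source over C3.
    """

    contra: float = 0.0
    ipsi: float = 0.0

    def __post_init__(self) -> None:
        for v in (self.contra, self.ipsi):
            if not -1.0 <= v <= 1.0:
                raise ValueError("ERD values must lie in [-1, 1]")


@dataclass(frozen=True)
class ConditionEffects:
    alpha: BandEffect = BandEffect()
    beta: BandEffect = BandEffect()


def default_condition_effects() -> dict[str, ConditionEffects]:
    """Planted effects used for validation scenarios.

    Continuous feedback: bilateral alpha ERD (-0.5) plus ipsilateral beta
    ERD; discrete: contralateral-only alpha ERD (-0.3).  Mirrors the
    direction of the condition contrast the analysis is built to detect.
    """
    return {
        "continuous": ConditionEffects(
            alpha=BandEffect(contra=-0.5, ipsi=-0.5),
            beta=BandEffect(contra=0.0, ipsi=-0.3),
        ),
        "discrete": ConditionEffects(
            alpha=BandEffect(contra=-0.3, ipsi=0.0),
            beta=BandEffect(),
        ),
    }


@dataclass(frozen=True)
class ParticipantProfile:
    """Generative parameters of one synthetic participant."""

    participant_id: str = "P01"
    effects: Mapping[str, ConditionEffects] = field(
        default_factory=default_condition_effects
    )
    mu_freq: float = 10.0
    beta_freq: float = 20.0
    rhythm_amplitude: float = 20.0   # microvolt amplitude of each rhythm at the source
    noise_amplitude: float = 4.0     # microvolt RMS of the 1/f background per channel
    noise_exponent: float = 1.0
    source_center: str = "C3"        # contralateral source for right-hand MI
    spatial_sigma: float = 0.25      # head-plane units of the gain kernel
    seed: int = 0

    def __post_init__(self) -> None:
        for name, v in (
            ("rhythm_amplitude", self.rhythm_amplitude),
            ("noise_amplitude", self.noise_amplitude),
            ("spatial_sigma", self.spatial_sigma),
        ):
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be positive and finite")
        if not np.isfinite(self.noise_exponent):
            raise ValueError("noise_exponent must be finite")


def channel_gains(
    montage: Montage, source_center: str | tuple[float, float], spatial_sigma: float
) -> np.ndarray:
    """Gaussian source-to-electrode gain vector, in (0, 1], max near the source."""
    if spatial_sigma <= 0:
        raise ValueError("spatial_sigma must be positive")
    if isinstance(source_center, str):
        center = np.asarray(montage.positions[source_center], float)
    else:
        center = np.asarray(source_center, float)
    d2 = np.sum((montage.coords() - center) ** 2, axis=1)
    return np.exp(-d2 / (2.0 * spatial_sigma**2))


def pink_noise(
    rng: np.random.Generator, n_samples: int, fs: float, exponent: float = 1.0
) -> np.ndarray:
    """Gaussian noise with power spectrum 1/f^exponent, unit RMS.

    Spectral shaping in the Fourier domain: white Gaussian spectrum scaled
    by f^(-exponent/2); the DC bin is zeroed.
    """
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    spectrum = rng.normal(size=freqs.size) + 1j * rng.normal(size=freqs.size)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spectrum * scale, n=n_samples)
    return x / x.std()


def _mi_envelope(times: np.ndarray, timeline: TrialTimeline, erd: float,
                 fs: float) -> np.ndarray:
    """Amplitude envelope: 1 at rest, sqrt(1+erd) during MI, cosine ramps."""
    target = np.sqrt(max(1.0 + erd, 0.0))
    env = np.ones_like(times)
    ramp = RAMP_SECONDS

    def smooth_step(t, t0):  # 0 -> 1 raised cosine over [t0, t0+ramp]
        u = np.clip((t - t0) / ramp, 0.0, 1.0)
        return 0.5 * (1.0 - np.cos(np.pi * u))

    s_on = smooth_step(times, timeline.mi_onset)
    s_off = smooth_step(times, timeline.mi_end)
    env = 1.0 + (target - 1.0) * (s_on - s_off)
    return env


def _oscillation(rng: np.random.Generator, times: np.ndarray, freq: float) -> np.ndarray:
    """Unit-amplitude rhythm: sinusoid with random phase and slow AM jitter."""
    phase = rng.uniform(0.0, 2.0 * np.pi)
    carrier = np.sin(2.0 * np.pi * freq * times + phase)
    # mild multiplicative amplitude drift (~20%) so trials are not identical
    n_knots = max(int(times[-1] // 2) + 2, 2)
    knots = 1.0 + 0.2 * rng.standard_normal(n_knots)
    am = np.interp(times, np.linspace(times[0], times[-1], n_knots), knots)
    return carrier * np.clip(am, 0.1, None)


def generate_trial_eeg(
    profile: ParticipantProfile,
    timeline: TrialTimeline,
    condition: str,
    montage: Montage = DEFAULT_MONTAGE,
    fs: float = FS_DEFAULT,
    trial_index: int | None = None,
    rng: np.random.Generator | None = None,
    artifact_uv: float = 0.0,
) -> EEGRecord:
    """Generate one trial of 16-channel EEG with the planted condition effect.

    ``artifact_uv`` > 0 plants a square amplitude spike of that size on one
    channel during the MI period (for artifact-rejection tests).
    """
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence([profile.seed, trial_index or 0])
        )
    n = int(round(timeline.duration * fs))
    times = np.arange(n) / fs
    nch = montage.n_channels

    data = np.empty((nch, n))
    for ch in range(nch):
        data[ch] = profile.noise_amplitude * pink_noise(
            rng, n, fs, profile.noise_exponent
        )

    effects = profile.effects[condition]
    contra = profile.source_center
    ipsi = montage.mirrored(contra)
    for band_name, freq in (("alpha", profile.mu_freq), ("beta", profile.beta_freq)):
        eff: BandEffect = getattr(effects, band_name)
        for side, erd in ((contra, eff.contra), (ipsi, eff.ipsi)):
            gains = channel_gains(montage, side, profile.spatial_sigma)
            source = profile.rhythm_amplitude * _oscillation(rng, times, freq)
            env = _mi_envelope(times, timeline, erd, fs)
            data += gains[:, None] * (source * env)[None, :]

    if artifact_uv > 0.0:
        ch = int(rng.integers(nch))
        i0 = int(round(timeline.mi_onset * fs))
        data[ch, i0 : i0 + int(0.2 * fs)] += artifact_uv

    return EEGRecord(data, fs, montage.labels, timeline, condition, trial_index)


def generate_session(
    profile: ParticipantProfile,
    schedule: SessionSchedule,
    montage: Montage = DEFAULT_MONTAGE,
    fs: float = FS_DEFAULT,
) -> list[EEGRecord]:
    """One EEG record per scheduled trial; trial seeds derived from the
    profile seed and trial index, so regeneration is bit-identical."""
    records = []
    for trial in schedule.trials:
        rng = np.random.default_rng(
            np.random.SeedSequence(
                [profile.seed, schedule.seed, trial.trial_index,
                 0 if schedule.condition == "continuous" else 1,
                 0 if schedule.phase == "calibration" else 1]
            )
        )
        records.append(
            generate_trial_eeg(
                profile,
                trial.timeline(),
                schedule.condition,
                montage,
                fs,
                trial.trial_index,
                rng,
            )
        )
    return records


def cohort_profiles(
    n_participants: int,
    seed: int,
    base_effects: Mapping[str, ConditionEffects] | None = None,
    erd_sd: float = 0.1,
    **overrides,
) -> list[ParticipantProfile]:
    """Participant profiles with Gaussian variability in ERD depth.

    Per participant, every nonzero planted ERD is jittered by N(0, erd_sd)
    and clipped to [-0.95, 0.5]; zero effects stay exactly zero so that
    "no effect" conditions remain null.
    """
    base = base_effects if base_effects is not None else default_condition_effects()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    profiles = []
    for i in range(n_participants):
        effects = {}
        for cond, ce in base.items():
            bands = {}
            for band in ("alpha", "beta"):
                be: BandEffect = getattr(ce, band)
                vals = {}
                for side in ("contra", "ipsi"):
                    v = getattr(be, side)
                    if v != 0.0:
                        v = float(np.clip(v + rng.normal(0.0, erd_sd), -0.95, 0.5))
                    vals[side] = v
                bands[band] = BandEffect(**vals)
            effects[cond] = ConditionEffects(**bands)
        profiles.append(
            ParticipantProfile(
                participant_id=f"P{i + 1:02d}",
                effects=effects,
                seed=int(rng.integers(2**31 - 1)),
                **overrides,
            )
        )
    return profiles
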