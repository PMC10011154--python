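"""Morlet wavelet power and ERD/ERS normalization."""

import numpy as np
import pytest

from mibci.erds import (
    BANDS,
    ERDSMap,
    FREQS_DEFAULT,
    MorletParams,
    TFPower,
    TIMES_DEFAULT,
    band_summary,
    car_filter,
    erds_map,
    grand_average,
    average_maps,
    morlet_wavelet,
    reject_artifacts,
    tf_power,
    topography_table,
)
from mibci.montage import CHANNELS
from mibci.synth import EEGRecord, ParticipantProfile, generate_trial_eeg

FS = 256.0


def record(data):
    return EEGRecord(data, FS, CHANNELS[: data.shape[0]])


class TestCAR:
    def test_column_sums_zero(self):
        rng = np.random.default_rng(0)
        out = car_filter(record(rng.standard_normal((16, 512))))
        assert np.abs(out.data.sum(axis=0)).max() < 1e-10

    def test_common_mode_removed(self):
        x = np.tile(np.sin(np.arange(512) / 10), (16, 1))
        out = car_filter(record(x))
        assert np.abs(out.data).max() < 1e-12

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        rec = record(rng.standard_normal((16, 256)))
        once = car_filter(rec)
        twice = car_filter(once)
        assert np.allclose(once.data, twice.data)

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            car_filter(record(np.zeros((1, 100))))


class TestMorlet:
    def test_closed_form_sigmas_at_10hz(self):
        p = MorletParams(10.0, ratio=6.0)
        assert p.sigma_f == pytest.approx(10.0 / 6.0)
        assert p.sigma_t == pytest.approx(1.0 / (2 * np.pi * 10.0 / 6.0))
        assert p.sigma_t == pytest.approx(0.0955, abs=2e-4)

    def test_uncertainty_product_on_grid(self):
        for f0 in FREQS_DEFAULT:
            p = MorletParams(float(f0))
            assert p.sigma_t * p.sigma_f == pytest.approx(1 / (2 * np.pi),
                                                          abs=1e-12)

    def test_envelope_even_symmetry(self):
        w = morlet_wavelet(MorletParams(12.0), FS)
        assert np.allclose(np.abs(w), np.abs(w[::-1]), atol=1e-12)
        assert np.argmax(np.abs(w)) == (len(w) - 1) // 2

    def test_spectral_peak_at_center_frequency(self):
        for f0 in (8.0, 15.0, 30.0):
            w = morlet_wavelet(MorletParams(f0), FS)
            n = 8192
            spec = np.abs(np.fft.fft(w, n))
            freqs = np.fft.fftfreq(n, 1 / FS)
            peak = abs(freqs[np.argmax(spec)])
            assert peak == pytest.approx(f0, abs=FS / n + 1e-9)

    def test_nyquist_guard(self):
        with pytest.raises(ValueError):
            morlet_wavelet(MorletParams(200.0), FS)


class TestTFPower:
    def test_pure_tone_peak_frequency(self):
        t = np.arange(int(10 * FS)) / FS
        x = np.sin(2 * np.pi * 10.0 * t)
        p = tf_power(x, FS)
        avg = p.mean(axis=1)
        assert FREQS_DEFAULT[np.argmax(avg)] == pytest.approx(10.0, abs=0.5)

    def test_zero_signal_zero_power(self):
        p = tf_power(np.zeros(int(9 * FS)), FS)
        assert not p.any()

    def test_quadratic_scaling(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(int(9 * FS))
        p1 = tf_power(x, FS)
        p2 = tf_power(2 * x, FS)
        assert np.allclose(p2, 4 * p1, rtol=1e-10)

    def test_grid_shapes(self):
        x = np.zeros(int(9 * FS))
        p = tf_power(x, FS)
        assert p.shape == (45, 81)

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError):
            tf_power(np.zeros(100), FS)

    def test_matches_direct_summation_oracle(self):
        """FFT-based wavelet power equals a direct-summation convolution
        computed sample by sample (no fast transform)."""
        rng = np.random.default_rng(1)
        x = rng.standard_normal(int(1.0 * FS))
        freqs = np.array([10.0, 20.0])
        times = np.array([0.4, 0.5, 0.6])
        p = tf_power(x, FS, freqs, times)
        pad = None
        for i, f0 in enumerate(freqs):
            w = morlet_wavelet(MorletParams(f0), FS)
            half = (len(w) - 1) // 2
            pad = min(half, x.size - 1)
            xp = np.pad(x, pad, mode="reflect")
            for j, t0 in enumerate(times):
                k = int(round(t0 * FS)) + pad
                acc = 0.0 + 0.0j
                for m in range(len(w)):
                    idx = k + half - m
                    if 0 <= idx < xp.size:
                        acc += w[m] * xp[idx]
                expected = abs(acc) ** 2 / FS
                assert p[i, j] == pytest.approx(expected, rel=1e-6)


class TestERDSMap:
    def _power(self, values):
        return TFPower(values, FREQS_DEFAULT, TIMES_DEFAULT, CHANNELS)

    def test_constant_power_gives_zero_map(self):
        p = self._power(np.full((16, 45, 81), 3.0))
        m = erds_map(p)
        assert np.allclose(m.values, 0.0)

    def test_doubling_and_suppression_arithmetic(self):
        base = np.ones((16, 45, 81))
        mi = TIMES_DEFAULT >= 4.0
        base[:, :, mi] = 2.0
        assert erds_map(self._power(base)).values[:, :, mi] == pytest.approx(1.0)
        base[:, :, mi] = 0.6
        assert erds_map(self._power(base)).values[:, :, mi] == pytest.approx(-0.4)

    def test_lower_bound_minus_one(self):
        vals = np.random.default_rng(0).uniform(0, 5, (16, 45, 81))
        vals[:, :, :40] += 1.0
        m = erds_map(self._power(vals))
        assert m.values.min() >= -1.0

    def test_zero_baseline_rejected(self):
        vals = np.ones((16, 45, 81))
        vals[:, :, :40] = 0.0
        with pytest.raises(ValueError):
            erds_map(self._power(vals))

    def test_band_summary_constant_map(self):
        m = ERDSMap(np.full((16, 45, 81), -0.4), FREQS_DEFAULT, TIMES_DEFAULT,
                    CHANNELS)
        for band in ("alpha", "beta"):
            assert band_summary(m, band, (4, 8)) == pytest.approx(-0.4)

    def test_band_separation(self):
        vals = np.zeros((16, 45, 81))
        alpha_sel = (FREQS_DEFAULT >= 8) & (FREQS_DEFAULT <= 13)
        vals[:, alpha_sel, :] = -0.5
        m = ERDSMap(vals, FREQS_DEFAULT, TIMES_DEFAULT, CHANNELS)
        assert band_summary(m, "alpha", (4, 8)) == pytest.approx(-0.5)
        assert band_summary(m, "beta", (4, 8)) == pytest.approx(0.0)

    def test_topography_table_layout(self):
        m = ERDSMap(np.full((16, 45, 81), -0.25), FREQS_DEFAULT,
                    TIMES_DEFAULT, CHANNELS)
        table = topography_table(m, (4.0, 8.0))
        assert len(table) == 32  # 16 channels x 2 bands
        assert set(table.band) == {"alpha", "beta"}
        assert np.allclose(table.value, -0.25)

    def test_empty_band_rejected(self):
        m = ERDSMap(np.zeros((16, 45, 81)), FREQS_DEFAULT, TIMES_DEFAULT,
                    CHANNELS)
        with pytest.raises(ValueError):
            band_summary(m, (40.0, 50.0), (4, 8))


class TestAverages:
    def _map(self, c):
        return ERDSMap(np.full((16, 5, 9), c), np.arange(5.0), np.arange(9.0),
                       CHANNELS)

    def test_identical_maps_unchanged(self):
        g = grand_average([self._map(-0.3)] * 5)
        assert np.allclose(g.values, -0.3)

    def test_opposite_maps_cancel(self):
        g = grand_average([self._map(0.4), self._map(-0.4)])
        assert np.allclose(g.values, 0.0)

    def test_cohort_mean_recovers_planted_mean(self):
        rng = np.random.default_rng(0)
        maps = [self._map(-0.4 + rng.normal(0, 0.1)) for _ in range(18)]
        g = grand_average(maps)
        assert g.values.mean() == pytest.approx(-0.4, abs=3 * 0.1 / np.sqrt(18))

    def test_grid_mismatch_rejected(self):
        other = ERDSMap(np.zeros((16, 4, 9)), np.arange(4.0), np.arange(9.0),
                        CHANNELS)
        with pytest.raises(ValueError):
            average_maps([self._map(0.1), other])


class TestArtifactRejection:
    def test_clean_trials_kept_spiked_trial_dropped(self, timeline):
        profile = ParticipantProfile(seed=5)
        clean = [generate_trial_eeg(profile, timeline, "continuous",
                                    trial_index=i) for i in range(3)]
        spiked = generate_trial_eeg(profile, timeline, "continuous",
                                    trial_index=9, artifact_uv=500.0)
        kept, report = reject_artifacts(clean + [spiked], threshold_uv=100.0)
        assert len(kept) == 3
        assert [r["kept"] for r in report] == [True, True, True, False]

    def test_infinite_threshold_keeps_all(self, timeline):
        profile = ParticipantProfile(seed=5)
        trials = [generate_trial_eeg(profile, timeline, "continuous",
                                     trial_index=i, artifact_uv=500.0)
                  for i in range(2)]
        kept, _ = reject_artifacts(trials, threshold_uv=np.inf)
        assert len(kept) == 2

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            reject_artifacts([], threshold_uv=0.0)
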