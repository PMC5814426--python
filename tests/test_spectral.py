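"""Welch spectra, band powers, z-score maps, logistic baseline,
topographic interpolation."""

import numpy as np
import pandas as pd
import pytest

import eegsex as e
from eegsex.spectral import BANDS, SpectralTable, band_power, welch_psd

from conftest import tone_recording


class TestWelch:
    def test_tone_integrated_power(self):
        """Unit-amplitude sinusoid has total power 1/2 (Parseval)."""
        rec = tone_recording(10.0, fs=128.0, duration_s=120.0, n_channels=2)
        f, p = welch_psd(rec)
        total = p.sum(axis=1) * (f[1] - f[0])
        assert total == pytest.approx([0.5, 0.5], rel=0.02)

    def test_white_noise_variance(self):
        m = e.default_montage().subset(("Cz",))
        totals = []
        for seed in range(20):
            sig = np.random.default_rng(seed).normal(
                scale=2.0, size=(1, 128 * 60))
            rec = e.Recording("N", 0, 128.0, sig, m)
            f, p = welch_psd(rec)
            totals.append(p.sum() * (f[1] - f[0]))
        assert np.mean(totals) == pytest.approx(4.0, rel=0.05)

    def test_frequency_resolution(self):
        rec = tone_recording(10.0, fs=128.0, duration_s=120.0, n_channels=1)
        f, _ = welch_psd(rec, segment_seconds=10.0)
        assert f[1] - f[0] == pytest.approx(0.1)

    def test_too_short_raises(self):
        rec = tone_recording(10.0, fs=128.0, duration_s=5.0, n_channels=1)
        with pytest.raises(e.DataError):
            welch_psd(rec, segment_seconds=10.0)

    def test_agrees_with_single_periodogram_at_tone(self):
        from scipy.signal import periodogram

        rec = tone_recording(10.0, fs=128.0, duration_s=120.0, n_channels=1)
        f, p = welch_psd(rec)
        fp, pp = periodogram(rec.signal[0], fs=128.0, window="hann")
        # integrate both estimates over the tone's spectral neighbourhood
        tone_w = p[0][np.abs(f - 10.0) <= 0.3].sum() * (f[1] - f[0])
        tone_p = pp[np.abs(fp - 10.0) <= 0.3].sum() * (fp[1] - fp[0])
        assert tone_w == pytest.approx(tone_p, rel=0.05)


class TestBandPower:
    def test_tone_lands_in_beta(self):
        rec = tone_recording(20.0, fs=128.0, duration_s=120.0, n_channels=1)
        f, p = welch_psd(rec)
        beta = band_power(p, f, BANDS["beta"])[0]
        total = band_power(p, f, (f[0], f[-1]))[0]
        assert beta >= 0.99 * total

    def test_partition_additivity(self):
        rec = e.generate_recording(e.EffectSpec(), 0, 1, duration_s=20.0)
        f, p = welch_psd(rec)
        parts = [(0.5, 4.0), (4.0, 8.0), (8.0, 12.0), (12.0, 25.0),
                 (25.0, f[-1])]
        s = sum(band_power(p, f, b) for b in parts)
        total = band_power(p, f, (0.5, f[-1]))
        assert np.allclose(s, total, rtol=1e-6)

    def test_empty_band_is_zero(self):
        rec = tone_recording(10.0, fs=128.0, duration_s=20.0, n_channels=1)
        f, p = welch_psd(rec)
        assert band_power(p, f, (10.0, 10.0))[0] == 0.0

    def test_out_of_range_band(self):
        rec = tone_recording(10.0, fs=128.0, duration_s=20.0, n_channels=1)
        f, p = welch_psd(rec)
        with pytest.raises(e.ConfigurationError):
            band_power(p, f, (0.5, 200.0))


def _random_table(n_subjects, seed, shift_beta=0.0, n_ch=4):
    """Synthetic spectral table with lognormal PSDs (no recordings)."""
    rng = np.random.default_rng(seed)
    freqs = np.arange(0.5, 35.1, 0.1)
    psd = np.exp(rng.normal(size=(n_subjects, n_ch, freqs.size)))
    beta = (freqs >= 12.0) & (freqs < 25.0)
    psd[:, :, beta] *= np.exp(shift_beta)
    return SpectralTable(subject_ids=[f"S{i}" for i in range(n_subjects)],
                         labels=np.zeros(n_subjects, dtype=int),
                         channel_names=tuple("abcd"[:n_ch]),
                         freqs=freqs, psd=psd)


class TestGroupZscores:
    def test_identical_groups_near_zero(self):
        t = _random_table(800, seed=0)
        labels = np.r_[np.ones(400, int), np.zeros(400, int)]
        z = e.group_zscores(t, labels)
        assert z["z"].abs().max() <= 0.3
        assert z["z"].abs().mean() <= 0.1

    def test_planted_beta_effect_shows_in_beta(self):
        cohort = e.generate_cohort(e.CohortSpec(
            n_subjects=40, male_fraction=0.5, duration_s=20.0, seed=5))
        table = e.spectral_table(cohort)
        z = e.group_zscores(table)
        planted = [e.DEFAULT_CHANNELS[i] for i in range(4, 21)]
        zb = z[(z["band"] == "beta") & z["channel"].isin(planted)]
        zd = z[(z["band"] == "delta") & z["channel"].isin(planted)]
        assert zb["z"].abs().mean() > zd["z"].abs().mean()
        assert zb["z"].mean() > 0  # female minus male, females stronger

    def test_label_swap_flips_sign(self):
        t = _random_table(60, seed=1, shift_beta=0.5)
        labels = np.r_[np.ones(30, int), np.zeros(30, int)]
        z1 = e.group_zscores(t, labels)
        z2 = e.group_zscores(t, 1 - labels)
        assert np.allclose(z1["z"], -z2["z"])

    def test_small_group_rejected(self):
        t = _random_table(3, seed=2)
        with pytest.raises(e.DataError):
            e.group_zscores(t, np.array([1, 0, 0]))


class TestBetaLogistic:
    def test_planted_effect_beats_chance(self):
        """Log beta power separates the planted cohort well above the
        Monte-Carlo chance threshold for the test size."""
        spec = e.CohortSpec(n_subjects=150, male_fraction=0.5,
                            duration_s=30.0, seed=11)
        table = e.spectral_table(e.iter_cohort(spec))
        tr = _slice_table(table, slice(0, 100))
        te = _slice_table(table, slice(100, 150))
        acc = e.beta_logistic_baseline(tr, tr.labels, te, te.labels)
        null = e.simulate_null_threshold(50, float(te.labels.mean()), 0.47,
                                         n_sims=100_000, seed=0)
        assert acc > null.threshold_percent

    def test_uninformative_features_near_chance(self):
        tr = _random_table(200, seed=3)
        te = _random_table(100, seed=4)
        rng = np.random.default_rng(5)
        ytr = rng.permutation(np.r_[np.ones(100, int), np.zeros(100, int)])
        yte = rng.permutation(np.r_[np.ones(50, int), np.zeros(50, int)])
        acc = e.beta_logistic_baseline(tr, ytr, te, yte)
        assert 30.0 <= acc <= 70.0  # ~50% +/- 4 binomial SDs at n=100

    def test_zero_variance_feature_rejected(self):
        tr = _random_table(20, seed=6)
        tr.psd[:, 2, :] = 1.0
        te = _random_table(10, seed=7)
        ytr = np.r_[np.ones(10, int), np.zeros(10, int)]
        with pytest.raises(e.DataError, match="c"):
            e.beta_logistic_baseline(tr, ytr, te, np.zeros(10, int))


def _slice_table(t, sl):
    return SpectralTable(subject_ids=t.subject_ids[sl], labels=t.labels[sl],
                         channel_names=t.channel_names, freqs=t.freqs,
                         psd=t.psd[sl], bands=t.bands)


class TestLogAmplitude:
    def test_monotone_in_psd(self):
        t = _random_table(5, seed=8)
        la = t.log_amplitude()
        i, j = 2, 3
        order_psd = np.argsort(t.psd[:, i, j])
        order_log = np.argsort(la[:, i, j])
        assert np.array_equal(order_psd, order_log)


class TestTopographicGrid:
    def test_constant_field(self, montage):
        topo = e.topographic_grid(np.full(26, 3.14), montage)
        inside = np.isfinite(topo.values)
        assert np.allclose(topo.values[inside], 3.14)

    def test_electrode_values_exact(self, montage):
        vals = np.random.default_rng(0).normal(size=26)
        topo = e.topographic_grid(vals, montage)
        at = topo.at(montage.positions[:, 0], montage.positions[:, 1])
        assert np.allclose(at, vals, atol=1e-8)

    def test_single_hotspot_peaks_at_electrode(self, montage):
        vals = np.zeros(26)
        vals[12] = 1.0  # Cz
        topo = e.topographic_grid(vals, montage, resolution=101)
        k = np.nanargmax(topo.values)
        gx = topo.grid_x.ravel()[k]
        gy = topo.grid_y.ravel()[k]
        assert np.hypot(gx - montage.positions[12, 0],
                        gy - montage.positions[12, 1]) < 0.1

    def test_missing_value_rejected(self, montage):
        with pytest.raises(e.DataError):
            e.topographic_grid(np.zeros(25), montage)
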