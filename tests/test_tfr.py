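import numpy as np
import pytest
from scipy.signal import hilbert

import abrgap as ag
from conftest import make_epoch, tone_epoch

FS = 100_000.0


def _two_tone_epoch(f1=500.0, f2=900.0):
    t = np.arange(800) / FS
    return make_epoch(np.sin(2 * np.pi * f1 * t) + np.sin(2 * np.pi * f2 * t))


def _nearest_bin(freqs, f):
    return int(np.argmin(np.abs(freqs - f)))


class TestWignerVille:
    def test_tone_ridge_at_tone_frequency(self):
        W = ag.wigner_ville(tone_epoch(775.0))
        expected = _nearest_bin(W.freq_axis_hz, 775.0)
        interior = range(100, 700, 50)
        low = W.freq_axis_hz <= 5000  # ridge search below the filter band edge
        for i in interior:
            assert abs(int(np.argmax(W.power[i, low])) - expected) <= 1

    def test_energy_conservation_within_1pct(self):
        for epoch in (tone_epoch(775.0), _two_tone_epoch()):
            W = ag.wigner_ville(epoch)
            z = hilbert(epoch.samples_uv)
            energy = np.sum(np.abs(z) ** 2) / FS
            df = W.freq_axis_hz[1] - W.freq_axis_hz[0]
            tfr_energy = W.power.sum() * df / FS
            assert abs(tfr_energy - energy) / energy < 0.01

    def test_two_tone_cross_term_at_midpoint(self):
        """Quadratic TFRs of a two-tone signal show an oscillatory
        component midway between the tones (here 700 Hz)."""
        W = ag.wigner_ville(_two_tone_epoch(500.0, 900.0))
        mid = _nearest_bin(W.freq_axis_hz, 700.0)
        auto = _nearest_bin(W.freq_axis_hz, 500.0)
        cross_mag = np.abs(W.power[100:700, mid]).max()
        auto_mag = np.abs(W.power[100:700, auto]).max()
        assert cross_mag > 0.5 * auto_mag  # cross-term comparable to auto-terms

    def test_npoints_shorter_than_epoch_rejected(self):
        with pytest.raises(ValueError):
            ag.wigner_ville(tone_epoch(775.0), n_points=512)


class TestChoiWilliams:
    def test_cross_term_suppressed_at_least_half(self):
        epoch = _two_tone_epoch(500.0, 900.0)
        W = ag.wigner_ville(epoch)
        C = ag.choi_williams(epoch, sigma=1.0)
        mid = _nearest_bin(W.freq_axis_hz, 700.0)
        raw = np.abs(W.power[100:700, mid]).max()
        filt = np.abs(C.power[100:700, mid]).max()
        assert filt <= 0.5 * raw

    def test_large_sigma_recovers_raw_wvd(self):
        epoch = _two_tone_epoch()
        W = ag.wigner_ville(epoch)
        C = ag.choi_williams(epoch, sigma=1e6)
        assert np.max(np.abs(C.power - W.power)) < 0.01 * np.max(np.abs(W.power))

    def test_convergence_monotone_in_sigma(self):
        epoch = _two_tone_epoch()
        W = ag.wigner_ville(epoch)
        diffs = [
            np.max(np.abs(ag.choi_williams(epoch, sigma=s).power - W.power))
            for s in (0.1, 1.0, 10.0, 1e3, 1e6)
        ]
        assert all(b <= a * (1 + 1e-9) for a, b in zip(diffs, diffs[1:]))

    def test_single_tone_ridge_unchanged(self):
        epoch = tone_epoch(775.0)
        W = ag.wigner_ville(epoch)
        C = ag.choi_williams(epoch, sigma=1.0)
        low = W.freq_axis_hz <= 5000
        for i in (200, 400, 600):
            assert abs(
                int(np.argmax(C.power[i, low])) - int(np.argmax(W.power[i, low]))
            ) <= 1

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError):
            ag.choi_williams(tone_epoch(775.0), sigma=0.0)


def _toy_tfr(values, t=None, f=None):
    t = np.arange(0, 8, 0.1) if t is None else t
    f = np.arange(400.0, 1160.0, 20.0) if f is None else f
    power = np.broadcast_to(values, (len(t), len(f))).copy()
    return ag.TimeFrequencyRepresentation(power, t, f)


class TestDifferentialTfr:
    def test_identical_inputs_zero(self):
        a = _toy_tfr(1.5)
        assert not ag.differential_tfr(a, a).power.any()

    def test_antisymmetry_exact(self):
        rng = np.random.default_rng(0)
        t = np.arange(0, 8, 0.1)
        f = np.arange(400.0, 1160.0, 20.0)
        a = ag.TimeFrequencyRepresentation(rng.normal(size=(len(t), len(f))), t, f)
        b = ag.TimeFrequencyRepresentation(rng.normal(size=(len(t), len(f))), t, f)
        np.testing.assert_array_equal(
            ag.differential_tfr(a, b).power, -ag.differential_tfr(b, a).power
        )

    def test_axis_mismatch_rejected(self):
        a = _toy_tfr(1.0)
        b = _toy_tfr(1.0, f=np.arange(300.0, 1060.0, 20.0))
        with pytest.raises(ValueError):
            ag.differential_tfr(a, b)


class TestBandBinPowers:
    def test_zero_and_constant_inputs(self):
        zero = ag.band_bin_powers(_toy_tfr(0.0))
        assert zero.n_bins == 16
        assert all(not v.any() for v in zero.values.values())
        const = ag.band_bin_powers(_toy_tfr(3.25))
        for v in const.values.values():
            np.testing.assert_allclose(v, 3.25)

    def test_indicator_rectangle_hits_one_bin(self):
        t = np.arange(0, 8, 0.1)
        f = np.arange(400.0, 1160.0, 20.0)
        power = np.zeros((len(t), len(f)))
        sel_t = (t >= 3.0) & (t < 3.5)
        sel_f = (f >= 650.0) & (f < 900.0)
        power[np.ix_(sel_t, sel_f)] = 1.0
        binned = ag.band_bin_powers(ag.TimeFrequencyRepresentation(power, t, f))
        expected_bin = 6  # zero-based bin covering [3.0, 3.5) ms
        assert binned.values["mfb"][expected_bin] == 1.0
        mask = np.ones(16, bool)
        mask[expected_bin] = False
        assert not binned.values["mfb"][mask].any()
        assert not binned.values["lfb"].any()
        assert not binned.values["hfb"].any()

    def test_matches_brute_force_cell_averaging(self):
        rng = np.random.default_rng(42)
        t = np.arange(0, 8, 0.07)
        f = np.arange(390.0, 1210.0, 17.0)
        power = rng.normal(size=(len(t), len(f)))
        dtfr = ag.TimeFrequencyRepresentation(power, t, f)
        binned = ag.band_bin_powers(dtfr)
        for name, (lo, hi) in ag.DEFAULT_BANDS.items():
            for b in range(16):
                cells = [
                    power[i, j]
                    for i in range(len(t))
                    for j in range(len(f))
                    if 0.5 * b <= t[i] < 0.5 * (b + 1) and lo <= f[j] < hi
                ]
                assert binned.values[name][b] == pytest.approx(np.mean(cells))

    def test_empty_band_rejected(self):
        t = np.arange(0, 8, 0.1)
        f = np.array([400.0, 500.0, 600.0, 950.0, 1050.0, 1150.0])  # no MFB cells
        dtfr = ag.TimeFrequencyRepresentation(np.ones((len(t), len(f))), t, f)
        with pytest.raises(ValueError, match="mfb"):
            ag.band_bin_powers(dtfr)


class TestFeatureWindow:
    def test_window_averages_covered_bins(self):
        binned = ag.band_bin_powers(_toy_tfr(0.0))
        binned.values["mfb"][:] = np.arange(16.0)
        feats = ag.feature_window(binned, (3.0, 5.0))
        # bins covering [3, 5) ms are indices 6..9
        assert feats[1] == pytest.approx(np.mean([6.0, 7.0, 8.0, 9.0]))
        assert feats[0] == 0.0 and feats[2] == 0.0

    def test_indicator_feature_value(self):
        t = np.arange(0, 8, 0.1)
        f = np.arange(400.0, 1160.0, 20.0)
        power = np.zeros((len(t), len(f)))
        power[np.ix_((t >= 3.0) & (t < 3.5), (f >= 650.0) & (f < 900.0))] = 1.0
        binned = ag.band_bin_powers(ag.TimeFrequencyRepresentation(power, t, f))
        lfb, mfb, hfb = ag.feature_window(binned, (3.0, 5.0))
        assert mfb == pytest.approx(0.25)  # 1 of the 4 window bins is hot
        assert lfb == 0.0 and hfb == 0.0

    def test_misaligned_window_rejected(self):
        binned = ag.band_bin_powers(_toy_tfr(1.0))
        with pytest.raises(ValueError):
            ag.feature_window(binned, (3.25, 5.0))
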