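"""Time/frequency evaluation features and the contamination-distance metric."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy import signal as sps

from emgclean import (
    ContaminationMask,
    TimeSeries,
    ar_spectrum,
    band_features,
    feature_curve,
    median_frequency,
    normalized_distance,
    region_rms_median,
    time_features,
)

FS = 1000.0


def _mask_half(n, fs=FS):
    flags = np.zeros(n, dtype=bool)
    flags[: n // 2] = True
    return ContaminationMask(flags, fs)


class TestRegionRMS:
    def test_constant_signal(self):
        x = TimeSeries(np.full(4000, -2.5), FS)
        assert region_rms_median(x, _mask_half(4000), "noise") == pytest.approx(2.5)
        assert region_rms_median(x, _mask_half(4000), "emg") == pytest.approx(2.5)

    def test_long_sinusoid(self):
        t = np.arange(10000) / FS
        x = TimeSeries(np.sin(2 * np.pi * 50 * t), FS)
        assert region_rms_median(x, _mask_half(10000), "noise") == pytest.approx(
            1 / np.sqrt(2), rel=1e-3
        )

    def test_median_over_known_window_rms(self):
        # three 1 s windows with RMS 1, 2, 9 -> median 2
        vals = np.concatenate([np.full(1000, 1.0), np.full(1000, 2.0), np.full(1000, 9.0)])
        x = TimeSeries(vals, FS)
        mask = ContaminationMask(np.ones(3000, dtype=bool), FS)
        assert region_rms_median(x, mask, "emg") == pytest.approx(2.0)

    def test_short_region_rejected(self):
        x = TimeSeries(np.ones(1500), FS)
        flags = np.zeros(1500, dtype=bool)
        flags[:400] = True  # 0.4 s of EMG: less than one window
        with pytest.raises(ValueError):
            region_rms_median(x, ContaminationMask(flags, FS), "emg")


class TestTimeFeatures:
    def test_identity_filter_zero_gains(self, rng):
        x = TimeSeries(rng.standard_normal(8000), FS)
        tf = time_features(x, x, _mask_half(8000))
        assert tf.GL == pytest.approx(0.0, abs=1e-9)
        assert tf.GH == pytest.approx(0.0, abs=1e-9)

    def test_half_gain_filter(self, rng):
        x = TimeSeries(rng.standard_normal(8000), FS)
        half = x.with_samples(x.samples / 2)
        tf = time_features(x, half, _mask_half(8000))
        assert tf.GL == pytest.approx(20 * np.log10(0.5), abs=0.01)
        assert tf.GH == pytest.approx(20 * np.log10(0.5), abs=0.01)

    def test_gxin_from_known_region_amplitudes(self):
        burst = np.full(2000, 10.0)
        quiet = np.full(2000, 1.0)
        x = TimeSeries(np.concatenate([burst, quiet]), FS)
        tf = time_features(x, x, _mask_half(4000))
        assert tf.GXin == pytest.approx(20.0, abs=1e-9)
        assert tf.GXout == pytest.approx(20.0, abs=1e-9)

    def test_identities_recompute_from_medians(self, rng):
        x = TimeSeries(rng.standard_normal(8000), FS)
        y = x.with_samples(x.samples * 0.3 + 0.01 * rng.standard_normal(8000))
        tf = time_features(x, y, _mask_half(8000))
        m = tf.medians
        assert tf.GL == pytest.approx(20 * np.log10(m["Xout0"] / m["Xin0"]))
        assert tf.GH == pytest.approx(20 * np.log10(m["Xout1"] / m["Xin1"]))
        assert tf.GXin == pytest.approx(20 * np.log10(m["Xin1"] / m["Xin0"]))
        assert tf.GXout == pytest.approx(20 * np.log10(m["Xout1"] / m["Xout0"]))

    def test_scale_equivariance(self, rng):
        x = TimeSeries(rng.standard_normal(8000), FS)
        y = x.with_samples(x.samples * 0.5)
        g = 0.2
        tf1 = time_features(x, y, _mask_half(8000))
        tf2 = time_features(x, y.with_samples(y.samples * g), _mask_half(8000))
        shift = 20 * np.log10(g)
        assert tf2.GL - tf1.GL == pytest.approx(shift, abs=1e-9)
        assert tf2.GH - tf1.GH == pytest.approx(shift, abs=1e-9)


class TestFeatureCurve:
    def test_default_grid_length(self, muscle_block, contaminated_block):
        curve = feature_curve(
            contaminated_block, "ssa", muscle_block["mask"],
            params={"var_target": 1.0},
        )
        assert curve.k_grid.size == 20
        assert curve.GL_of_k.size == 20
        assert np.all(np.diff(curve.k_grid) > 0)

    def test_gl_non_increasing_in_k(self, muscle_block, contaminated_block):
        curve = feature_curve(
            contaminated_block, "ssa", muscle_block["mask"],
            params={"var_target": 1.0},
        )
        assert np.all(np.diff(curve.GL_of_k) <= 1e-9)

    def test_uncontaminated_channel_curves_coincide(self, muscle_block):
        curve = feature_curve(
            muscle_block["eeg"], "ssa", muscle_block["mask"],
            params={"var_target": 1.0},
        )
        d = normalized_distance(curve.GL_of_k, curve.GH_of_k)
        assert d < 0.15


class TestNormalizedDistance:
    def test_identical_vectors(self):
        u = np.array([1.0, 2.0, 3.0])
        assert normalized_distance(u, u) == 0.0

    def test_antipodal_vectors_boundary(self):
        u = np.array([1.0, -2.0])
        assert normalized_distance(u, -u) == pytest.approx(1.0)

    def test_hand_computed_example(self):
        assert normalized_distance([3.0, 0.0], [0.0, 4.0]) == pytest.approx(5 / 7)

    def test_both_zero_defined_as_zero(self):
        assert normalized_distance(np.zeros(3), np.zeros(3)) == 0.0

    def test_symmetric_and_bounded(self, rng):
        u, v = rng.standard_normal(20), rng.standard_normal(20)
        d = normalized_distance(u, v)
        assert d == normalized_distance(v, u)
        assert 0 <= d <= 1


class TestARSpectrum:
    def test_white_noise_flat(self, rng):
        x = TimeSeries(rng.standard_normal(50000), FS)
        sf = ar_spectrum(x, df=0.1)
        assert sf.pxx.std() / sf.pxx.mean() < 0.3

    def test_sinusoid_peak_location(self, rng):
        t = np.arange(20000) / FS
        x = TimeSeries(np.sin(2 * np.pi * 10 * t) + 0.05 * rng.standard_normal(20000), FS)
        sf = ar_spectrum(x, df=0.01)
        assert abs(sf.f[np.argmax(sf.pxx)] - 10.0) < 0.5

    def test_integral_approximates_variance(self, rng):
        x = TimeSeries(rng.standard_normal(50000), FS)
        sf = ar_spectrum(x, df=0.1)
        assert np.trapezoid(sf.pxx, sf.f) == pytest.approx(x.samples.var(), rel=0.1)

    def test_constant_signal_rejected(self):
        with pytest.raises(ValueError):
            ar_spectrum(TimeSeries(np.ones(1000), FS))


class TestMedianFrequency:
    def test_all_mass_at_one_point(self):
        f = np.arange(0, 10.0, 0.5)
        pxx = np.zeros_like(f)
        pxx[7] = 3.0
        fmed, p = median_frequency(f, pxx)
        assert fmed == f[7]
        assert p == 3.0

    def test_symmetric_two_peaks(self):
        f = np.arange(0, 30.0, 0.1)
        pxx = np.exp(-((f - 10) ** 2)) + np.exp(-((f - 20) ** 2))
        fmed, _ = median_frequency(f, pxx)
        assert 10 < fmed < 20

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(
        pxx=arrays(np.float64, st.integers(2, 200),
                   elements=st.floats(0, 1e3, allow_nan=False)).filter(
            lambda a: a.sum() > 0
        )
    )
    def test_matches_cumsum_brute_force(self, pxx):
        f = np.arange(pxx.size, dtype=float)
        fmed, p = median_frequency(f, pxx)
        # brute-force oracle: scan the cumulative sum
        cum = 0.0
        for i, v in enumerate(pxx):
            cum += v
            if cum >= pxx.sum() / 2:
                assert fmed == f[i]
                assert p == v
                break


class TestBandFeatures:
    def test_alpha_sinusoid_lands_in_alpha(self, rng):
        t = np.arange(20000) / FS
        x = TimeSeries(
            np.sin(2 * np.pi * 10 * t) + 0.1 * rng.standard_normal(20000), FS
        )
        bf = band_features(x, df=0.1)
        assert 7 <= bf["Alpha"].fmed <= 13
        assert abs(bf["full"].fmed - 10) < 1

    def test_alpha_noise_dwarfs_delta_band(self, rng):
        sos = sps.butter(8, [8, 12], btype="bandpass", fs=FS, output="sos")
        x = TimeSeries(sps.sosfiltfilt(sos, rng.standard_normal(30000)), FS)
        bf = band_features(x, df=0.1)
        p_alpha = np.trapezoid(bf["Alpha"].pxx, bf["Alpha"].f)
        p_delta = np.trapezoid(bf["Delta"].pxx, bf["Delta"].f)
        assert 10 * np.log10(p_delta / p_alpha) < -20

    def test_broadband_input_fmed_inside_each_band(self, rng):
        x = TimeSeries(rng.standard_normal(30000), FS)
        bf = band_features(x, df=0.1)
        from emgclean import EEG_BANDS

        for name, (lo, hi) in EEG_BANDS.items():
            assert lo <= bf[name].fmed <= hi
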