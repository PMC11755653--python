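"""Normalized cross spectrum, smoothing, band integration, record means."""

import numpy as np
import pytest

from wbsync import AnalysisConfig, build_frequency_grid, wavelet_coefficients
from wbsync.bicoherence import (band_integral, cross_spectrum, record_mean,
                                wb_series)
from wbsync.cwt import WaveletSpectrum
from wbsync.errors import AlignmentError, ConfigurationError
from wbsync.experiments import pair_analysis

from conftest import make_recording


def _spectrum_from(coeffs, freqs=None, times=None, valid=None, channel="a"):
    coeffs = np.asarray(coeffs, complex)
    nf, nt = coeffs.shape
    return WaveletSpectrum(
        coefficients=coeffs,
        freqs=np.asarray(freqs if freqs is not None else np.arange(1, nf + 1), float),
        times=np.asarray(times if times is not None else np.arange(nt) * 0.1, float),
        valid_mask=np.ones_like(coeffs, bool) if valid is None else valid,
        channel=channel,
    )


class TestCrossSpectrum:
    def test_identical_channels_give_unit_real_phasor(self, rng):
        c = rng.standard_normal((3, 50)) + 1j * rng.standard_normal((3, 50))
        wi = _spectrum_from(c)
        wj = _spectrum_from(c.copy(), channel="b")
        cs = cross_spectrum(wi, wj)
        assert np.allclose(cs.re[cs.valid], 1.0, atol=1e-12)
        assert np.allclose(cs.im[cs.valid], 0.0, atol=1e-12)

    def test_quarter_cycle_rotation_gives_minus_i(self, rng):
        c = rng.standard_normal((2, 40)) + 1j * rng.standard_normal((2, 40))
        cs = cross_spectrum(_spectrum_from(c), _spectrum_from(1j * c, channel="b"))
        assert np.allclose(cs.re[cs.valid], 0.0, atol=1e-12)
        assert np.allclose(cs.im[cs.valid], -1.0, atol=1e-12)

    def test_unit_modulus_identity(self, rng):
        ci = rng.standard_normal((4, 100)) + 1j * rng.standard_normal((4, 100))
        cj = rng.standard_normal((4, 100)) + 1j * rng.standard_normal((4, 100))
        cs = cross_spectrum(_spectrum_from(ci), _spectrum_from(cj, channel="b"))
        mod = cs.re[cs.valid] ** 2 + cs.im[cs.valid] ** 2
        assert np.allclose(mod, 1.0, atol=1e-12)

    def test_zero_coefficients_are_masked(self):
        ci = np.ones((1, 10), complex)
        cj = np.ones((1, 10), complex)
        cj[0, 3] = 0.0
        cs = cross_spectrum(_spectrum_from(ci), _spectrum_from(cj, channel="b"))
        assert not cs.valid[0, 3]
        assert cs.valid[0, :3].all()

    def test_grid_mismatch_raises(self, rng):
        c = rng.standard_normal((2, 10)) + 0j
        wi = _spectrum_from(c)
        wj = _spectrum_from(c, freqs=[2.0, 3.0], channel="b")
        with pytest.raises(AlignmentError):
            cross_spectrum(wi, wj)


class TestWbSeries:
    def test_constant_phase_lag_gives_unity(self):
        # constant unit phasor averages to itself
        nt = 200
        u = np.exp(1j * 0.7) * np.ones((1, nt))
        cs = cross_spectrum(_spectrum_from(u), _spectrum_from(np.ones((1, nt)),
                                                             channel="b"))
        wb, valid = wb_series(cs, smoothing_window=2.0, min_cycles=8.0)
        assert valid.any()
        assert np.allclose(wb[valid], 1.0, atol=1e-12)

    def test_unsmoothed_series_degenerates_to_one(self, rng):
        # single-sample window: the pointwise modulus identity makes WB = 1
        ci = rng.standard_normal((2, 100)) + 1j * rng.standard_normal((2, 100))
        cj = rng.standard_normal((2, 100)) + 1j * rng.standard_normal((2, 100))
        cs = cross_spectrum(_spectrum_from(ci), _spectrum_from(cj, channel="b"))
        wb, valid = wb_series(cs, smoothing_window=1e-6, min_cycles=0.0)
        assert valid.all()
        assert np.allclose(wb, 1.0, atol=1e-12)

    def test_window_floor_scales_with_frequency(self, rng):
        # at 1 Hz the window must span >= 8 s regardless of smoothing_window
        nt = 300
        ci = rng.standard_normal((1, nt)) + 1j * rng.standard_normal((1, nt))
        cj = rng.standard_normal((1, nt)) + 1j * rng.standard_normal((1, nt))
        wi = _spectrum_from(ci, freqs=[1.0])
        wj = _spectrum_from(cj, freqs=[1.0], channel="b")
        cs = cross_spectrum(wi, wj)
        wb, valid = wb_series(cs, smoothing_window=0.5, min_cycles=8.0)
        # 8 s window at 0.1 s steps -> 40 edge samples invalid on each side
        assert not valid[0, :40].any() and not valid[0, -40:].any()
        assert valid[0, 41:-41].all()

    def test_fully_masked_frequency_when_window_exceeds_record(self, rng):
        nt = 30  # 3 s of samples, 8 s window needed at 1 Hz
        ci = rng.standard_normal((1, nt)) + 1j * rng.standard_normal((1, nt))
        cs = cross_spectrum(_spectrum_from(ci, freqs=[1.0]),
                            _spectrum_from(ci * 1j, freqs=[1.0], channel="b"))
        wb, valid = wb_series(cs, smoothing_window=2.0)
        assert not valid.any()

    def test_amplitude_invariance(self, sinusoid_recording, small_config):
        rec = sinusoid_recording
        wb1, v1, s1 = pair_analysis(rec.signals[0], rec.signals[1], rec.fs,
                                    small_config)
        wb2, v2, s2 = pair_analysis(7.3 * rec.signals[0], 0.02 * rec.signals[1],
                                    rec.fs, small_config)
        assert np.array_equal(v1, v2)
        assert np.allclose(wb1[v1], wb2[v2], atol=1e-9)

    def test_prefactor_choice_cannot_affect_synchronization(self, rng):
        # the normalization cancels any real per-(f,t) scale, so the
        # transform's leading factor (sqrt(f) vs f) is irrelevant to WB
        from wbsync import AnalysisConfig
        from wbsync.experiments import single_band_config
        cfg_sqrt = single_band_config(AnalysisConfig(), "theta", points=5)
        cfg_lin = cfg_sqrt.replace(cwt_prefactor="linear")
        x, y = rng.standard_normal(3000), rng.standard_normal(3000)
        wb1, v1, _ = pair_analysis(x, y, 100.0, cfg_sqrt)
        wb2, v2, _ = pair_analysis(x, y, 100.0, cfg_lin)
        assert np.array_equal(v1, v2)
        assert np.allclose(wb1[v1], wb2[v2], atol=1e-12)

    def test_pair_symmetry(self, sinusoid_recording, small_config):
        rec = sinusoid_recording
        wb_ij, v_ij, _ = pair_analysis(rec.signals[0], rec.signals[1], rec.fs,
                                       small_config)
        wb_ji, v_ji, _ = pair_analysis(rec.signals[1], rec.signals[0], rec.fs,
                                       small_config)
        assert np.array_equal(v_ij, v_ji)
        assert np.allclose(wb_ij[v_ij], wb_ji[v_ji], atol=1e-12)

    def test_same_frequency_sinusoids_fully_synchronous(self, sinusoid_recording):
        cfg = AnalysisConfig(bands=(("theta", 4.0, 8.0),), freq_points_per_band=5)
        rec = sinusoid_recording
        _, _, series = pair_analysis(rec.signals[0], rec.signals[1], rec.fs, cfg)
        s = series["theta"]
        assert s.n_valid > 0
        assert s.mean_wb == pytest.approx(1.0, abs=1e-6)


class TestBandIntegral:
    freqs = np.linspace(4.0, 8.0, 9)

    def test_constant_field_integrates_to_constant(self):
        wb = np.full((9, 20), 0.37)
        valid = np.ones_like(wb, bool)
        series, vt = band_integral(wb, valid, self.freqs, (4.0, 8.0))
        assert vt.all()
        assert np.allclose(series, 0.37, atol=1e-12)

    def test_half_band_step_profile(self):
        wb = np.zeros((9, 5))
        wb[:5] = 1.0  # lower half of the band (plus midpoint)
        valid = np.ones_like(wb, bool)
        series, _ = band_integral(wb, valid, self.freqs, (4.0, 8.0))
        assert np.allclose(series, 0.5, atol=1.0 / 8.0)

    def test_matches_refined_grid_oracle(self):
        # smooth profile: trapezoid on 32 points vs 10x refinement
        def profile(f):
            return 0.5 + 0.4 * np.sin(f / 2.0) * np.exp(-((f - 6) ** 2) / 8)

        coarse = np.linspace(4.0, 8.0, 32)
        fine = np.linspace(4.0, 8.0, 320)
        wb = profile(coarse)[:, None] * np.ones((1, 3))
        series, _ = band_integral(wb, np.ones_like(wb, bool), coarse, (4.0, 8.0))
        oracle = np.trapezoid(profile(fine), fine) / 4.0
        assert np.abs(series - oracle).max() <= 1e-3

    def test_any_masked_frequency_masks_the_time_point(self):
        wb = np.ones((9, 4))
        valid = np.ones_like(wb, bool)
        valid[3, 2] = False
        _, vt = band_integral(wb, valid, self.freqs, (4.0, 8.0))
        assert list(vt) == [True, True, False, True]

    def test_uncovered_band_raises(self):
        wb = np.ones((9, 4))
        with pytest.raises(ConfigurationError):
            band_integral(wb, np.ones_like(wb, bool), self.freqs, (2.0, 8.0))


class TestRecordMean:
    def test_all_ones(self):
        assert record_mean(np.ones(10), np.ones(10, bool)) == 1.0

    def test_alternating_halves(self):
        wb = np.array([0.0, 1.0] * 50)
        assert record_mean(wb, np.ones(100, bool)) == pytest.approx(0.5)

    def test_masked_samples_excluded_like_explicit_loop(self, rng):
        wb = rng.uniform(size=200)
        valid = rng.uniform(size=200) > 0.3
        total, count = 0.0, 0
        for v, ok in zip(wb, valid):  # independent loop oracle
            if ok:
                total += v
                count += 1
        assert record_mean(wb, valid) == pytest.approx(total / count, rel=1e-12)

    def test_no_valid_points_gives_nan(self):
        assert np.isnan(record_mean(np.ones(5), np.zeros(5, bool)))
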