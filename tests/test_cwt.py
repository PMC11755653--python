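"""Morlet mother function and windowed-transform properties."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wbsync import AnalysisConfig, build_frequency_grid, morlet_mother, \
    wavelet_coefficients
from wbsync.config import TWO_PI
from wbsync.cwt import MorletCWT
from wbsync.errors import ConfigurationError, DomainError, MontageError

from conftest import make_recording


def quadrature_oracle(x, fs, f, t0_idx, w0=TWO_PI):
    """Direct windowed trapezoid evaluation of the wavelet integral."""
    n = x.size
    m = max(1, int(np.floor(4 * fs / f)))
    out = np.zeros(len(t0_idx), complex)
    valid = np.zeros(len(t0_idx), bool)
    for k, n0 in enumerate(t0_idx):
        if n0 - m < 0 or n0 + m > n - 1:
            continue
        idx = np.arange(n0 - m, n0 + m + 1)
        tau = (idx - n0) / fs
        integrand = x[idx] * np.conj(morlet_mother(f, tau, w0))
        out[k] = np.sqrt(f) * np.trapezoid(integrand, dx=1 / fs)
        valid[k] = True
    return out, valid


class TestMotherWavelet:
    def test_peak_modulus_and_phase(self):
        # (1/pi)^(1/4) at the envelope centre, zero phase
        v = morlet_mother(1.0, 0.0)
        assert abs(v) == pytest.approx((1 / np.pi) ** 0.25, abs=1e-12)
        assert np.angle(v) == pytest.approx(0.0, abs=1e-12)

    def test_window_edge_suppression(self):
        # at tau = 4/f the Gaussian factor is exp(-8) of the peak
        ratio = abs(morlet_mother(1.0, 4.0)) / abs(morlet_mother(1.0, 0.0))
        assert ratio == pytest.approx(np.exp(-8.0), rel=1e-12)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(f=st.floats(0.1, 40.0), tau=st.floats(-10.0, 10.0))
    def test_even_envelope(self, f, tau):
        assert abs(morlet_mother(f, tau)) == pytest.approx(
            abs(morlet_mother(f, -tau)), rel=1e-12)

    def test_rejects_nonpositive_frequency(self):
        with pytest.raises(DomainError):
            morlet_mother(0.0, 1.0)
        with pytest.raises(DomainError):
            morlet_mother(-2.0, 1.0)


class TestWaveletCoefficients:
    fs = 100.0

    def test_zero_signal_gives_zero_coefficients(self, small_config):
        rec = make_recording(np.zeros((1, 2000)), fs=self.fs)
        grid = build_frequency_grid(small_config, self.fs)
        spec = wavelet_coefficients(rec, "ch0", grid, np.arange(0, 20, 0.5))
        assert np.all(spec.coefficients[spec.valid_mask] == 0)
        assert spec.valid_mask.any()

    def test_matches_quadrature_oracle(self, rng):
        x = rng.standard_normal(1000)  # 10 s
        t0_idx = np.arange(0, 1000, 10)
        freqs = np.array([1.0, 3.3, 5.0, 13.7, 29.0])
        eng = MorletCWT(self.fs, freqs)
        coeffs, valid = eng.transform(x, t0_idx)
        for q, f in enumerate(freqs):
            ref, ref_valid = quadrature_oracle(x, self.fs, f, t0_idx)
            assert np.array_equal(valid[q], ref_valid)
            scale = np.abs(ref[ref_valid]).max()
            assert np.abs(coeffs[q][ref_valid] - ref[ref_valid]).max() <= 1e-6 * scale

    def test_sinusoid_peaks_at_its_frequency(self):
        t = np.arange(0, 60.0, 1 / self.fs)
        rec = make_recording(np.sin(2 * np.pi * 5.0 * t)[None, :], fs=self.fs)
        cfg = AnalysisConfig(bands=(("theta", 4.0, 8.0),),
                             freq_points_per_band=17)
        grid = build_frequency_grid(cfg, self.fs)
        spec = wavelet_coefficients(rec, "ch0", grid, np.array([30.0]))
        moduli = np.abs(spec.coefficients[:, 0])
        assert spec.valid_mask[:, 0].all()
        peak = grid.freqs[np.argmax(moduli)]
        assert peak == pytest.approx(5.0, abs=0.26)  # nearest grid point

    @settings(derandomize=True, max_examples=10, deadline=None)
    @given(alpha=st.floats(-3.0, 3.0), beta=st.floats(-3.0, 3.0))
    def test_linearity(self, alpha, beta):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(600)
        y = rng.standard_normal(600)
        t0_idx = np.arange(50, 550, 25)
        eng = MorletCWT(self.fs, [5.0, 12.0])
        cx, v = eng.transform(x, t0_idx)
        cy, _ = eng.transform(y, t0_idx)
        cz, _ = eng.transform(alpha * x + beta * y, t0_idx)
        assert np.allclose(cz[v], alpha * cx[v] + beta * cy[v],
                           atol=1e-10, rtol=1e-9)

    def test_time_shift_covariance(self):
        # periodic signal delayed by one grid step shifts the pattern
        t = np.arange(0, 40.0, 1 / self.fs)
        f0 = 5.0
        shift = 0.3  # seconds, multiple of the t0 step below
        x = np.sin(2 * np.pi * f0 * t)
        y = np.sin(2 * np.pi * f0 * (t - shift))
        t0_idx = np.arange(0, x.size, 10)
        eng = MorletCWT(self.fs, [f0])
        cx, vx = eng.transform(x, t0_idx)
        cy, vy = eng.transform(y, t0_idx)
        k = int(shift * self.fs / 10)
        inner = vx[0] & np.roll(vy[0], -k)
        inner[-k:] = False
        assert np.allclose(cy[0][np.where(inner)[0] + k], cx[0][inner],
                           atol=1e-6)

    def test_edge_windows_are_masked_not_padded(self, small_config):
        rec = make_recording(np.ones((1, 1000)), fs=self.fs)
        grid = build_frequency_grid(small_config, self.fs)
        spec = wavelet_coefficients(rec, "ch0", grid, np.arange(0, 10, 0.1))
        # 4/f at 4 Hz = 1 s: first/last second must be masked at that row
        row = np.argmin(np.abs(grid.freqs - 4.0))
        assert not spec.valid_mask[row, spec.times < 1.0].any()
        assert spec.valid_mask[row, (spec.times > 1.1) & (spec.times < 8.9)].all()

    def test_sample_mask_propagates_to_overlapping_windows(self, small_config):
        signals = np.ones((1, 2000))
        mask = np.ones_like(signals, dtype=bool)
        mask[0, 1000:1010] = False
        rec = make_recording(signals, fs=self.fs, mask=mask)
        grid = build_frequency_grid(small_config, self.fs)
        spec = wavelet_coefficients(rec, "ch0", grid, np.arange(0, 20, 0.1))
        row = np.argmin(np.abs(grid.freqs - 8.0))  # window +/-0.5 s
        t = spec.times
        hit = (t > 9.51) & (t < 10.59)
        assert not spec.valid_mask[row, hit].any()
        assert spec.valid_mask[row, (t > 1.1) & (t < 9.4)].all()

    def test_unknown_channel_raises_montage_error(self, small_config):
        rec = make_recording(np.zeros((1, 500)), fs=self.fs)
        grid = build_frequency_grid(small_config, self.fs)
        with pytest.raises(MontageError):
            wavelet_coefficients(rec, "Cz", grid, np.array([2.0]))

    def test_empty_t0_grid_rejected(self, small_config):
        rec = make_recording(np.zeros((1, 500)), fs=self.fs)
        grid = build_frequency_grid(small_config, self.fs)
        with pytest.raises(DomainError):
            wavelet_coefficients(rec, "ch0", grid, np.array([]))


def test_band_grid_includes_endpoints(default_config):
    grid = build_frequency_grid(default_config, 100.0)
    for name, lo, hi in default_config.bands:
        f = grid.freqs[grid.band_slices[name]]
        assert f[0] == lo and f[-1] == hi
        assert np.all(np.diff(f) > 0)


def test_band_above_nyquist_rejected():
    cfg = AnalysisConfig(bands=(("hf", 10.0, 30.0),))
    with pytest.raises(ConfigurationError):
        build_frequency_grid(cfg, 50.0)
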