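"""Pairwise phase-synchronization strength from wavelet spectra.

Given complex wavelet coefficients ``Wi = ai + j bi`` and ``Wj`` of two
channels on a common (f, t) grid, the normalized mutual wavelet spectrum
has real and imaginary parts

    Re = (ai aj + bi bj) / (|Wi| |Wj|),
    Im = (bi aj - ai bj) / (|Wi| |Wj|),

i.e. the unit phasor of the phase difference between the channels.  Its
pointwise modulus is identically one for any two nonzero signals, so the
pointwise modulus carries no information; the synchronization strength is
obtained by *time-averaging the phasor first*:

    WB(f, t) = | < Re + j Im >_window |,

a sliding-window phase-locking value in [0, 1].  The window is centered,
of length ``max(smoothing_window, min_cycles / f)`` seconds, so at least
``min_cycles`` oscillation cycles enter the average at every analysis
frequency.  WB = 1 signals a constant phase relation (complete
synchrony), WB -> 0 independent phases.

Band-integrated synchronization averages WB over a frequency band by the
trapezoidal rule, and the per-recording summary is the arithmetic mean of
the band series over all valid time points of the whole recording.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .config import AnalysisConfig
from .cwt import FrequencyGrid, MorletCWT, WaveletSpectrum, build_frequency_grid
from .errors import AlignmentError, ConfigurationError, DomainError

logger = logging.getLogger(__name__)

_warned: set = set()


def _warn_once(key, msg, *args):
    """Log a warning once per distinct condition (sweeps would repeat it)."""
    if key not in _warned:
        _warned.add(key)
        logger.warning(msg, *args)

__all__ = [
    "CrossSpectrumSeries",
    "BandSyncSeries",
    "cross_spectrum",
    "wb_series",
    "band_integral",
    "record_mean",
    "pair_band_sync",
    "sync_time_grid",
]

#: Relative floor below which a coefficient modulus is treated as zero
#: (the normalized cross spectrum is undefined there).
COEFF_FLOOR = 1e-12


@dataclass
class CrossSpectrumSeries:
    """Normalized mutual wavelet spectrum of one channel pair.

    ``unit`` holds ``Re + j Im`` -- a unit-modulus phasor wherever
    ``valid`` is true, zero elsewhere.
    """

    unit: np.ndarray  # complex [n_freqs, n_times]
    valid: np.ndarray  # bool
    freqs: np.ndarray
    times: np.ndarray

    @property
    def re(self) -> np.ndarray:
        return self.unit.real

    @property
    def im(self) -> np.ndarray:
        return self.unit.imag


@dataclass
class BandSyncSeries:
    """Band-integrated synchronization of one channel pair."""

    pair: tuple[str, str]
    band: str
    f_low: float
    f_high: float
    times: np.ndarray
    wb_t: np.ndarray
    valid: np.ndarray
    mean_wb: float  # NaN when no time point is valid

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


def cross_spectrum(wi: WaveletSpectrum, wj: WaveletSpectrum) -> CrossSpectrumSeries:
    """Normalized mutual wavelet spectrum of channels i and j.

    Entries where either coefficient modulus falls below
    ``COEFF_FLOOR`` times that channel's per-frequency RMS modulus are
    masked: the phase ratio is numerically undefined there (exact zeros
    occur e.g. for identically zero signals).
    """
    if wi.freqs.shape != wj.freqs.shape or not np.allclose(wi.freqs, wj.freqs):
        raise AlignmentError("frequency grids differ")
    if wi.times.shape != wj.times.shape or not np.allclose(wi.times, wj.times):
        raise AlignmentError("time grids differ")

    valid = wi.valid_mask & wj.valid_mask
    mi = np.abs(wi.coefficients)
    mj = np.abs(wj.coefficients)
    valid = valid & (mi > _row_floor(mi, valid)) & (mj > _row_floor(mj, valid))

    z = wi.coefficients * np.conj(wj.coefficients)
    mag = np.abs(z)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(valid & (mag > 0), z / np.where(mag > 0, mag, 1.0), 0.0)
    return CrossSpectrumSeries(unit=unit, valid=valid & (mag > 0),
                               freqs=wi.freqs.copy(), times=wi.times.copy())


def _row_floor(moduli: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Per-frequency absolute floor: COEFF_FLOOR x RMS modulus over valid entries."""
    counts = valid.sum(axis=1)
    sq = np.where(valid, moduli, 0.0) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        rms = np.sqrt(sq.sum(axis=1) / np.maximum(counts, 1))
    rms[counts == 0] = np.inf  # whole row invalid anyway
    return (COEFF_FLOOR * rms)[:, None]


def _centered_window_samples(win_sec: float, dt: float) -> int:
    """Odd window length (in grid samples) spanning at least ``win_sec``."""
    if win_sec <= dt:
        return 1
    half = int(np.ceil((win_sec / dt - 1.0) / 2.0 - 1e-9))
    return 2 * half + 1


def _moving_sum(a: np.ndarray, half: int) -> np.ndarray:
    """Centered moving sum over ``2*half + 1`` points; edges yield partial sums."""
    if half == 0:
        return a.copy()
    cs = np.concatenate(([0], np.cumsum(a)))
    n = a.size
    lo = np.clip(np.arange(n) - half, 0, n)
    hi = np.clip(np.arange(n) + half + 1, 0, n)
    return cs[hi] - cs[lo]


def wb_series(cs: CrossSpectrumSeries, smoothing_window: float,
              min_cycles: float = 8.0) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window synchronization strength WB(f, t).

    Returns ``(wb, valid)``.  A point is valid only when the full
    smoothing window around it is valid for both channels; the result is
    clipped to [0, 1] (the mathematical range; excursions are pure
    floating-point round-off, as with correlation coefficients).

    With ``smoothing_window`` at or below one time step and
    ``min_cycles = 0`` the window degenerates to a single sample and
    WB is identically 1 wherever defined -- the degenerate pointwise
    reading that motivates mandatory smoothing.
    """
    if smoothing_window <= 0:
        raise DomainError("smoothing_window must be positive")
    nt = cs.times.size
    dt = float(cs.times[1] - cs.times[0]) if nt > 1 else np.inf
    wb = np.zeros_like(cs.unit, dtype=float)
    out_valid = np.zeros_like(cs.valid)
    for q, f in enumerate(cs.freqs):
        win_sec = max(smoothing_window, (min_cycles / f) if min_cycles > 0 else 0.0)
        n_win = _centered_window_samples(win_sec, dt) if np.isfinite(dt) else 1
        half = n_win // 2
        v = cs.valid[q]
        count = _moving_sum(v.astype(np.int64), half)
        full = count == n_win
        if not full.any():
            _warn_once(("masked_freq", round(f, 6), round(win_sec, 3)),
                       "smoothing window (%.3g s) exceeds the valid span at "
                       "%.3g Hz; frequency fully masked", win_sec, f)
            continue
        s = _moving_sum(np.where(v, cs.unit[q], 0.0), half)
        with np.errstate(invalid="ignore"):
            row = np.abs(s) / n_win
        wb[q, full] = np.clip(row[full], 0.0, 1.0)
        out_valid[q] = full
    return wb, out_valid


def band_integral(wb: np.ndarray, valid: np.ndarray, freqs: np.ndarray,
                  band_edges: tuple[float, float],
                  band_slice: slice | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Frequency-average of WB over one band: trapezoid over f divided by the width.

    A time point is masked whenever any in-band frequency is masked there,
    so the quadrature is never taken over a ragged set of rows.
    """
    lo, hi = band_edges
    if band_slice is None:
        sel = (freqs >= lo - 1e-12) & (freqs <= hi + 1e-12)
        band_slice = slice(np.argmax(sel), freqs.size - np.argmax(sel[::-1]))
    f = freqs[band_slice]
    if f.size < 2 or abs(f[0] - lo) > 1e-9 or abs(f[-1] - hi) > 1e-9:
        raise ConfigurationError(
            f"band [{lo}, {hi}] Hz is not covered by the frequency grid")
    valid_t = valid[band_slice].all(axis=0)
    series = np.trapezoid(wb[band_slice], f, axis=0) / (hi - lo)
    series = np.where(valid_t, series, 0.0)
    return series, valid_t


def record_mean(wb_t: np.ndarray, valid: np.ndarray) -> float:
    """Whole-record mean over valid time points; NaN (with a warning) if none."""
    n = int(valid.sum())
    if n == 0:
        _warn_once(("empty_mean",),
                   "no valid time points; record mean is undefined")
        return float("nan")
    return float(wb_t[valid].mean())


def sync_time_grid(duration: float, fs: float, time_step: float) -> np.ndarray:
    """Sample indices of the synchronization time grid t0."""
    step = max(1, int(round(time_step * fs)))
    return np.arange(0, int(round(duration * fs)), step, dtype=np.int64)


def band_sync_from_wb(wb: np.ndarray, valid: np.ndarray, times: np.ndarray,
                      grid: FrequencyGrid, pair: tuple[str, str],
                      bands=None) -> dict[str, BandSyncSeries]:
    """Band series and whole-record means from a precomputed WB(f, t) matrix."""
    out: dict[str, BandSyncSeries] = {}
    for name in (bands or grid.band_slices.keys()):
        sl = grid.band_slices[name]
        edges = grid.band_edges[name]
        series, valid_t = band_integral(wb, valid, grid.freqs, edges, sl)
        out[name] = BandSyncSeries(
            pair=pair,
            band=name,
            f_low=edges[0],
            f_high=edges[1],
            times=times,
            wb_t=series,
            valid=valid_t,
            mean_wb=record_mean(series, valid_t),
        )
    return out


def pair_band_sync(wi: WaveletSpectrum, wj: WaveletSpectrum,
                   grid: FrequencyGrid, config: AnalysisConfig,
                   bands: tuple[str, ...] | None = None) -> dict[str, BandSyncSeries]:
    """Full per-pair chain: cross spectrum -> WB(f,t) -> band series -> means.

    The result is symmetric in (i, j): swapping the channels conjugates
    the phasor, which leaves its modulus -- and hence every WB value --
    unchanged.
    """
    cs = cross_spectrum(wi, wj)
    wb, valid = wb_series(cs, config.smoothing_window, config.min_cycles)
    return band_sync_from_wb(wb, valid, cs.times, grid,
                             (wi.channel, wj.channel), bands=bands)
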