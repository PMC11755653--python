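"""Reusable study routines built on the core estimator.

These functions back the validation studies the package ships: the
boundedness sweep over randomized coupled pairs, the coupling-recovery
sweep, and synthetic-cohort correlation recovery.  They are library code
(used by the test suite, the analysis scripts and the acceptance script
alike), with every source of randomness keyed by an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bicoherence import (band_sync_from_wb, cross_spectrum, sync_time_grid,
                          wb_series)
from .config import AnalysisConfig
from .cwt import MorletCWT, WaveletSpectrum, build_frequency_grid
from .stats import correlate_with_ahi
from .synthetic import (CouplingScheme, _band_params, generate_cohort,
                        generate_coupled_pair)

__all__ = [
    "pair_analysis",
    "randomized_pair_wb_extrema",
    "coupling_sweep",
    "cohort_correlation_replicates",
    "single_band_config",
]

_ENGINE_CACHE: dict = {}


def _engine(fs: float, freqs: np.ndarray, w0: float, prefactor: str) -> MorletCWT:
    key = (fs, freqs.tobytes(), w0, prefactor)
    if key not in _ENGINE_CACHE:
        _ENGINE_CACHE.clear()  # keep at most one configuration resident
        _ENGINE_CACHE[key] = MorletCWT(fs, freqs, w0=w0, prefactor=prefactor)
    return _ENGINE_CACHE[key]


def single_band_config(config: AnalysisConfig, band: str,
                       points: int | None = None) -> AnalysisConfig:
    """Restrict a configuration to one band (optionally coarser grid)."""
    edges = config.band_edges(band)
    kwargs = {"bands": ((band, *edges),)}
    if points is not None:
        kwargs["freq_points_per_band"] = points
    return config.replace(**kwargs)


def pair_analysis(x1: np.ndarray, x2: np.ndarray, fs: float,
                  config: AnalysisConfig):
    """Full WB analysis of one signal pair.

    Returns ``(wb, valid, band_series)``: the WB(f, t) matrix with its
    validity mask, and per-band :class:`~wbsync.bicoherence.BandSyncSeries`.
    """
    grid = build_frequency_grid(config, fs)
    n = x1.size
    t0_idx = sync_time_grid(n / fs, fs, config.wb_time_step)
    eng = _engine(fs, grid.freqs, config.w0, config.cwt_prefactor)
    spectra = []
    for x, name in ((x1, "ch1"), (x2, "ch2")):
        coeffs, valid = eng.transform(np.asarray(x, float), t0_idx)
        spectra.append(WaveletSpectrum(coefficients=coeffs, freqs=grid.freqs,
                                       times=t0_idx / fs, valid_mask=valid,
                                       channel=name, fs=fs))
    cs = cross_spectrum(*spectra)
    wb, valid = wb_series(cs, config.smoothing_window, config.min_cycles)
    series = band_sync_from_wb(wb, valid, cs.times, grid, ("ch1", "ch2"))
    return wb, valid, series


def randomized_pair_wb_extrema(n_pairs: int, seed: int, duration: float = 60.0,
                               fs: float = 100.0,
                               config: AnalysisConfig | None = None) -> dict:
    """Extrema of WB over randomized synthetic pairs.

    Each pair draws a coupling strength epsilon uniformly in [0, 1] and a
    carrier band uniformly among the configured bands, spanning the
    regimes from independent noise to full coupling.  Every WB(f, t)
    value on the full grid and every band mean enters the extrema.

    Returns ``{"max": ..., "min": ..., "n_pairs": ..., "n_values": ...}``.
    """
    config = config or AnalysisConfig()
    rng = np.random.default_rng([int(seed), 2024])
    vmax, vmin = -np.inf, np.inf
    n_values = 0
    for k in range(n_pairs):
        eps = float(rng.uniform(0.0, 1.0))
        name, lo, hi = config.bands[rng.integers(len(config.bands))]
        f_c, bw = _band_params(lo, hi)
        noise_sd = float(rng.uniform(0.0, 0.5))
        x1, x2 = generate_coupled_pair(f_c, bw, eps, duration, fs,
                                       seed=(int(seed), 3000 + k),
                                       noise_sd=noise_sd)
        wb, valid, series = pair_analysis(x1, x2, fs, config)
        if valid.any():
            vals = wb[valid]
            vmax = max(vmax, float(vals.max()))
            vmin = min(vmin, float(vals.min()))
            n_values += vals.size
        for s in series.values():
            if s.n_valid:
                vmax = max(vmax, float(s.wb_t[s.valid].max()), s.mean_wb)
                vmin = min(vmin, float(s.wb_t[s.valid].min()), s.mean_wb)
                n_values += s.n_valid + 1
    return {"max": vmax, "min": vmin, "n_pairs": n_pairs, "n_values": n_values}


def coupling_sweep(epsilons, n_seeds: int, seed: int, band: str = "theta",
                   duration: float = 600.0, fs: float = 100.0,
                   config: AnalysisConfig | None = None,
                   noise_sd: float = 0.0,
                   phase_diffusion: float | None = None) -> pd.DataFrame:
    """Mean synchronization versus programmed coupling strength.

    For each epsilon and seed, generates one coupled pair in ``band`` and
    records the whole-record band mean.  Returns a tidy frame
    (epsilon, seed, mean_wb).
    """
    from .synthetic import DEFAULT_PHASE_DIFFUSION

    base = config or AnalysisConfig()
    cfg = single_band_config(base, band, points=9)
    lo, hi = cfg.bands[0][1], cfg.bands[0][2]
    f_c, bw = _band_params(lo, hi)
    pd_rate = DEFAULT_PHASE_DIFFUSION if phase_diffusion is None else phase_diffusion
    rows = []
    for eps in epsilons:
        for s in range(n_seeds):
            x1, x2 = generate_coupled_pair(f_c, bw, float(eps), duration, fs,
                                           seed=(int(seed), 40, s),
                                           noise_sd=noise_sd,
                                           phase_diffusion=pd_rate)
            _, _, series = pair_analysis(x1, x2, fs, cfg)
            rows.append({"epsilon": float(eps), "seed": s,
                         "mean_wb": series[band].mean_wb})
    return pd.DataFrame(rows)


def cohort_correlation_replicates(n_replicates: int, seed: int,
                                  scheme: CouplingScheme,
                                  pair: tuple[str, str] = ("C3", "C4"),
                                  band: str = "delta",
                                  n_control: int = 33, n_main: int = 39,
                                  duration: float = 600.0, fs: float = 100.0,
                                  config: AnalysisConfig | None = None,
                                  method: str = "pearson") -> pd.DataFrame:
    """Replicate cohorts; per replicate, correlate one pair's band mean with AHI.

    Only the two channels of ``pair`` are synthesized and analyzed, which
    leaves the programmed ground truth untouched while keeping replicated
    cohorts tractable.  Returns (replicate, r, p, n).
    """
    base = config or AnalysisConfig()
    cfg = single_band_config(base, band, points=9)
    rows = []
    for rep in range(n_replicates):
        cohort = generate_cohort(n_control, n_main, scheme,
                                 seed=(int(seed), 50, rep), duration=duration,
                                 fs=fs, channels=pair)
        means, ahis = [], []
        for subj in cohort.subjects:
            rec = subj.recording
            i = rec.channel_labels.index(pair[0])
            j = rec.channel_labels.index(pair[1])
            _, _, series = pair_analysis(rec.signals[i], rec.signals[j],
                                         fs, cfg)
            means.append(series[band].mean_wb)
            ahis.append(subj.ahi)
        res = correlate_with_ahi(np.array(means), np.array(ahis),
                                 method=method, alpha=base.alpha_corr)
        rows.append({"replicate": rep, "r": res.r, "p": res.p, "n": res.n})
    return pd.DataFrame(rows)
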