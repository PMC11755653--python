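"""End-to-end orchestration: recording -> pair x band table -> cohort results."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bicoherence import pair_band_sync, sync_time_grid
from .config import AnalysisConfig
from .cwt import MorletCWT, WaveletSpectrum, build_frequency_grid
from .errors import MontageError, ValidationError
from .recordings import CANONICAL_CHANNELS, Recording
from .spatial import ConnectivityMatrix, all_pairs, build_subject_matrix, \
    difference_scheme, group_mean_matrix
from .stats import correlation_table, group_comparison_table

logger = logging.getLogger(__name__)

__all__ = ["subject_pair_table", "subject_matrices", "cohort_pair_table",
           "CohortResults", "cohort_results"]


def _channel_spectra(recording: Recording, config: AnalysisConfig,
                     channels) -> dict[str, WaveletSpectrum]:
    grid = build_frequency_grid(config, recording.fs)
    t0_idx = sync_time_grid(recording.duration, recording.fs, config.wb_time_step)
    engine = MorletCWT(recording.fs, grid.freqs, w0=config.w0,
                       prefactor=config.cwt_prefactor)
    label_index = {ch: i for i, ch in enumerate(recording.channel_labels)}
    spectra = {}
    for ch in channels:
        if ch not in label_index:
            raise MontageError([ch])
        i = label_index[ch]
        mask = None if recording.mask is None else recording.mask[i]
        coeffs, valid = engine.transform(recording.signals[i], t0_idx, mask)
        spectra[ch] = WaveletSpectrum(coefficients=coeffs, freqs=grid.freqs,
                                      times=t0_idx / recording.fs,
                                      valid_mask=valid, channel=ch,
                                      fs=recording.fs)
    return spectra, grid


def subject_pair_table(recording: Recording, config: AnalysisConfig,
                       pairs=None, bands=None) -> pd.DataFrame:
    """Whole-record mean synchronization for every channel pair and band.

    Returns a long table (ch_i, ch_j, band, mean_wb, n_valid); for the
    full 19-channel montage and six bands that is 171 x 6 = 1026 rows.
    """
    if pairs is None:
        pairs = all_pairs(recording.channel_labels)
    bands = tuple(bands) if bands is not None else config.band_names
    channels = sorted({ch for p in pairs for ch in p},
                      key=lambda ch: recording.channel_labels.index(ch))
    spectra, grid = _channel_spectra(recording, config, channels)
    rows = []
    for ch_i, ch_j in pairs:
        sync = pair_band_sync(spectra[ch_i], spectra[ch_j], grid, config,
                              bands=bands)
        for band in bands:
            s = sync[band]
            rows.append({"ch_i": ch_i, "ch_j": ch_j, "band": band,
                         "mean_wb": s.mean_wb, "n_valid": s.n_valid})
    return pd.DataFrame(rows)


def subject_matrices(table: pd.DataFrame, config: AnalysisConfig,
                     channels=CANONICAL_CHANNELS) -> dict[str, ConnectivityMatrix]:
    """Per-band connectivity matrices from one subject's pair table."""
    out = {}
    for band in config.band_names:
        sub = table[table["band"] == band]
        out[band] = build_subject_matrix(
            zip(sub["ch_i"], sub["ch_j"], sub["mean_wb"]), band=band,
            channels=channels)
    return out


def cohort_pair_table(subjects, config: AnalysisConfig, pairs=None,
                      bands=None) -> pd.DataFrame:
    """Long cohort table over (subject, pair, band).

    ``subjects`` yields objects with ``subject_id``, ``ahi``, ``group``
    and ``recording`` attributes (e.g. :class:`~wbsync.synthetic.SyntheticSubject`).
    """
    frames = []
    for s in subjects:
        t = subject_pair_table(s.recording, config, pairs=pairs, bands=bands)
        t.insert(0, "subject_id", s.subject_id)
        t["ahi"] = s.ahi
        t["group"] = s.group
        frames.append(t)
    return pd.concat(frames, ignore_index=True)


@dataclass
class CohortResults:
    """Bundle of cohort-level outputs."""

    pair_table: pd.DataFrame
    control_matrices: dict
    main_matrices: dict
    difference_matrices: dict
    correlation: pd.DataFrame
    group_comparison: pd.DataFrame


def cohort_results(cohort_table: pd.DataFrame, config: AnalysisConfig,
                   channels=CANONICAL_CHANNELS) -> CohortResults:
    """Group matrices, difference schemes, and statistics from a cohort table."""
    per_group = {"control": {}, "main": {}}
    for group in per_group:
        g = cohort_table[cohort_table["group"] == group]
        if g.empty:
            raise ValidationError(f"cohort has no {group} subjects")
        for band in config.band_names:
            mats = []
            for _, sub in g[g["band"] == band].groupby("subject_id", sort=True):
                mats.append(build_subject_matrix(
                    zip(sub["ch_i"], sub["ch_j"], sub["mean_wb"]),
                    band=band, channels=channels))
            per_group[group][band] = group_mean_matrix(mats)
    diffs = {band: difference_scheme(per_group["control"][band],
                                     per_group["main"][band])
             for band in config.band_names}
    corr = correlation_table(cohort_table, method=config.correlation_method,
                             alpha=config.alpha_corr)
    comp = group_comparison_table(cohort_table, alpha=config.alpha_mw)
    return CohortResults(pair_table=cohort_table,
                         control_matrices=per_group["control"],
                         main_matrices=per_group["main"],
                         difference_matrices=diffs,
                         correlation=corr,
                         group_comparison=comp)
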