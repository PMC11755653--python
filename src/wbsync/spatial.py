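"""Spatial connectivity matrices: subject, group average, and difference maps.

A connectivity matrix collects the whole-record mean synchronization of
every unordered channel pair for one band into a symmetric 19 x 19 array
in the canonical channel order.  The main diagonal is the maximal
self-connection (1) at subject and group level, and 0 in a difference
map.  Group maps are unweighted per-subject means -- each subject
contributes equally regardless of group size -- and the difference scheme
is ``control - main``, so positive cells mark connections that are
stronger in the control group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .recordings import CANONICAL_CHANNELS
from .errors import ValidationError

__all__ = [
    "ConnectivityMatrix",
    "build_subject_matrix",
    "group_mean_matrix",
    "difference_scheme",
    "all_pairs",
    "render_matrix",
]


def all_pairs(channels=CANONICAL_CHANNELS) -> list[tuple[str, str]]:
    """All unordered channel pairs in canonical order (171 for 19 channels)."""
    channels = tuple(channels)
    return [(channels[i], channels[j])
            for i in range(len(channels)) for j in range(i + 1, len(channels))]


@dataclass
class ConnectivityMatrix:
    """Symmetric per-band connectivity matrix with an explicit mask.

    Masked (unavailable) cells hold NaN.  ``cell_counts`` records, for
    group-level maps, how many subjects contributed to each cell.
    """

    band: str
    level: str  # "subject" | "group_mean" | "difference"
    values: np.ndarray
    channels: tuple[str, ...] = CANONICAL_CHANNELS
    n_subjects: int | None = None
    cell_counts: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.channels = tuple(self.channels)
        n = len(self.channels)
        if self.values.shape != (n, n):
            raise ValidationError(
                f"values shape {self.values.shape} does not match {n} channels")
        if self.level not in ("subject", "group_mean", "difference"):
            raise ValidationError(f"unknown level {self.level!r}")

    @property
    def mask(self) -> np.ndarray:
        """True where the cell is masked (unavailable)."""
        return np.isnan(self.values)

    def validate(self) -> None:
        v = self.values
        ok = ~np.isnan(v)
        if not np.array_equal(ok, ok.T) or not np.allclose(
                np.where(ok & ok.T, v, 0.0), np.where(ok & ok.T, v.T, 0.0),
                atol=1e-12, equal_nan=True):
            raise ValidationError("matrix is not symmetric")
        diag = np.diag(v)
        if self.level in ("subject", "group_mean"):
            if not np.allclose(diag, 1.0):
                raise ValidationError("diagonal must be 1 at subject/group level")
            off = v[~np.eye(len(self.channels), dtype=bool) & ok]
            if off.size and (off.min() < -1e-9 or off.max() > 1 + 1e-9):
                raise ValidationError("off-diagonal values must lie in [0, 1]")
        else:
            if not np.allclose(diag, 0.0):
                raise ValidationError("difference diagonal must be 0")


def build_subject_matrix(pair_means, band: str,
                         channels=CANONICAL_CHANNELS) -> ConnectivityMatrix:
    """Assemble one subject's matrix from ``(ch_i, ch_j, mean_wb)`` entries.

    Exactly one entry per unordered pair is allowed; absent pairs are
    masked (NaN), and masked means (NaN values) propagate.
    """
    channels = tuple(channels)
    index = {ch: k for k, ch in enumerate(channels)}
    n = len(channels)
    values = np.full((n, n), np.nan)
    np.fill_diagonal(values, 1.0)
    seen = set()
    for ch_i, ch_j, mean in pair_means:
        if ch_i not in index or ch_j not in index:
            raise ValidationError(f"unknown channel in pair ({ch_i}, {ch_j})")
        if ch_i == ch_j:
            raise ValidationError(f"self-pair ({ch_i}, {ch_j}) is not allowed")
        key = frozenset((ch_i, ch_j))
        if key in seen:
            raise ValidationError(f"duplicate entry for pair ({ch_i}, {ch_j})")
        seen.add(key)
        i, j = index[ch_i], index[ch_j]
        values[i, j] = values[j, i] = mean
    m = ConnectivityMatrix(band=band, level="subject", values=values,
                           channels=channels, n_subjects=1)
    return m


def group_mean_matrix(matrices) -> ConnectivityMatrix:
    """Elementwise unweighted mean over subjects, per cell over valid entries."""
    matrices = list(matrices)
    if not matrices:
        raise ValidationError("at least one subject matrix is required")
    band = matrices[0].band
    channels = matrices[0].channels
    for m in matrices:
        if m.band != band:
            raise ValidationError(f"band mismatch: {m.band!r} vs {band!r}")
        if m.channels != channels:
            raise ValidationError("channel order mismatch between subjects")
        if m.level != "subject":
            raise ValidationError("group mean expects subject-level matrices")
    stack = np.stack([m.values for m in matrices])
    valid = ~np.isnan(stack)
    counts = valid.sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, np.nansum(stack, axis=0) / np.maximum(counts, 1),
                        np.nan)
    return ConnectivityMatrix(band=band, level="group_mean", values=mean,
                              channels=channels, n_subjects=len(matrices),
                              cell_counts=counts)


def difference_scheme(control: ConnectivityMatrix,
                      main: ConnectivityMatrix) -> ConnectivityMatrix:
    """Control-minus-main difference map (positive = control prevails)."""
    if control.band != main.band:
        raise ValidationError("band mismatch between group matrices")
    if control.level != "group_mean" or main.level != "group_mean":
        raise ValidationError("difference expects two group_mean matrices")
    if control.channels != main.channels:
        raise ValidationError("channel order mismatch between group matrices")
    values = control.values - main.values
    np.fill_diagonal(values, 0.0)
    return ConnectivityMatrix(band=control.band, level="difference",
                              values=values, channels=control.channels)


def render_matrix(matrix: ConnectivityMatrix, path, cmap=None, title=None) -> None:
    """Convenience heatmap of a connectivity matrix (cosmetic only)."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    n = len(matrix.channels)
    if cmap is None:
        cmap = "RdBu" if matrix.level == "difference" else "viridis"
    fig, ax = plt.subplots(figsize=(7, 6))
    if matrix.level == "difference":
        vmax = np.nanmax(np.abs(matrix.values)) or 1.0
        im = ax.imshow(matrix.values, cmap=cmap, vmin=-vmax, vmax=vmax)
    else:
        im = ax.imshow(matrix.values, cmap=cmap, vmin=0.0, vmax=1.0)
    ax.set_xticks(range(n), matrix.channels, rotation=90, fontsize=7)
    ax.set_yticks(range(n), matrix.channels, fontsize=7)
    ax.set_title(title or f"{matrix.band} ({matrix.level})")
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=130)
    plt.close(fig)
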