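"""Cohort statistics: AHI correlation and Mann-Whitney group comparison.

Per channel pair and band, the whole-record mean synchronization of every
subject (both groups pooled) is correlated with the apnea-hypopnea index.
The correlation coefficient defaults to Pearson; significance comes from
the t statistic ``r * sqrt((n - 2) / (1 - r^2))`` with ``n - 2`` degrees
of freedom, two-sided.  Spearman (Pearson on midrank-transformed data) is
available for the heavily skewed AHI distribution.  Group differences per
cell use the two-sided Mann-Whitney U test, exact for small tie-free
samples, normal approximation with tie correction otherwise; no
correction for multiple comparisons is applied by default (an optional
Benjamini-Hochberg flag is provided for the full pair-by-band tables).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .errors import DomainError, ValidationError

__all__ = [
    "CorrelationResult",
    "GroupComparisonResult",
    "pearson_t_test",
    "correlate_with_ahi",
    "mann_whitney_cell",
    "correlation_table",
    "group_comparison_table",
    "TABLE_PAIRS",
]

#: The eight channel pairs highlighted in the reference correlation table.
TABLE_PAIRS: tuple[tuple[str, str], ...] = (
    ("C3", "C4"), ("C3", "Cz"), ("F3", "Cz"), ("F3", "F4"),
    ("F7", "Cz"), ("F7", "F8"), ("O1", "O2"), ("P3", "P4"),
)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int
    significant: bool
    defined: bool
    method: str = "pearson"


@dataclass(frozen=True)
class GroupComparisonResult:
    u_statistic: float
    p: float
    significant: bool
    median_control: float
    median_main: float
    n_control: int
    n_main: int
    method: str = "exact"


def pearson_t_test(x, y) -> tuple[float, float, int]:
    """Pearson r and its two-sided t-test p-value.

    Returns ``(r, p, n)``.  Raises :class:`DomainError` for n < 3 or zero
    variance in either variable (the correlation is undefined there).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 3:
        raise DomainError(f"correlation requires n >= 3 (got {n})")
    sx = x - x.mean()
    sy = y - y.mean()
    vx = np.dot(sx, sx)
    vy = np.dot(sy, sy)
    if vx == 0.0 or vy == 0.0:
        raise DomainError("zero variance: correlation undefined")
    r = float(np.clip(np.dot(sx, sy) / math.sqrt(vx * vy), -1.0, 1.0))
    if abs(r) == 1.0:
        return r, 0.0, n
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(sp_stats.t.sf(abs(t), n - 2))
    return r, min(p, 1.0), n


def correlate_with_ahi(values, ahi, method: str = "pearson",
                       alpha: float = 0.05) -> CorrelationResult:
    """Correlate per-subject synchronization means with AHI across the pooled cohort.

    Subjects with a masked (NaN) synchronization value are dropped.
    Degenerate inputs (n < 3 or zero variance) yield a flagged undefined
    result rather than a silent zero.
    """
    values = np.asarray(values, dtype=float)
    ahi = np.asarray(ahi, dtype=float)
    if values.shape != ahi.shape:
        raise DomainError("values and ahi must have equal length")
    keep = np.isfinite(values) & np.isfinite(ahi)
    v, a = values[keep], ahi[keep]
    if method == "spearman":
        if v.size:
            v = sp_stats.rankdata(v)  # midranks for ties
            a = sp_stats.rankdata(a)
    elif method != "pearson":
        raise DomainError(f"unknown correlation method {method!r}")
    try:
        r, p, n = pearson_t_test(v, a)
    except DomainError:
        return CorrelationResult(r=float("nan"), p=float("nan"), n=int(v.size),
                                 significant=False, defined=False, method=method)
    return CorrelationResult(r=r, p=p, n=n, significant=bool(p < alpha),
                             defined=True, method=method)


#: Exact Mann-Whitney null enumeration is used up to this product n1*n2.
_EXACT_LIMIT = 400


def mann_whitney_cell(control_values, main_values,
                      alpha: float = 0.001) -> GroupComparisonResult:
    """Two-sided Mann-Whitney U comparison of one (pair, band) cell.

    The U statistic reported is that of the control sample (range
    ``[0, n1*n2]``).  The exact null distribution is used when
    ``n1*n2 <= 400`` and the pooled sample is tie-free; otherwise the
    normal approximation with tie correction applies.
    """
    x = np.asarray(control_values, dtype=float)
    y = np.asarray(main_values, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if x.size == 0 or y.size == 0:
        raise DomainError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size * y.size <= _EXACT_LIMIT and not has_ties) \
        else "asymptotic"
    res = sp_stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    p = float(min(res.pvalue, 1.0))
    return GroupComparisonResult(
        u_statistic=float(res.statistic),
        p=p,
        significant=bool(p <= alpha),
        median_control=float(np.median(x)),
        median_main=float(np.median(y)),
        n_control=int(x.size),
        n_main=int(y.size),
        method=method,
    )


# ---------------------------------------------------------------------------
# Cohort-level tables
# ---------------------------------------------------------------------------

def _check_cohort_frame(df: pd.DataFrame) -> None:
    needed = {"subject_id", "ahi", "group", "ch_i", "ch_j", "band", "mean_wb"}
    if not needed.issubset(df.columns):
        raise ValidationError(
            f"cohort table needs columns {sorted(needed)}; got {list(df.columns)}")


def correlation_table(cohort: pd.DataFrame, method: str = "pearson",
                      alpha: float = 0.05, pairs=None,
                      fdr: bool = False) -> pd.DataFrame:
    """Per-(pair, band) correlation of mean synchronization with AHI.

    ``cohort`` is a long table with one row per (subject, pair, band).
    With ``fdr=True`` a Benjamini-Hochberg adjusted p-value column is
    added (off by default: per-test thresholds only).
    """
    _check_cohort_frame(cohort)
    if pairs is not None:
        keys = {frozenset(p) for p in pairs}
        cohort = cohort[[frozenset((i, j)) in keys
                         for i, j in zip(cohort["ch_i"], cohort["ch_j"])]]
    rows = []
    for (ch_i, ch_j, band), sub in cohort.groupby(["ch_i", "ch_j", "band"],
                                                  sort=False):
        res = correlate_with_ahi(sub["mean_wb"].to_numpy(),
                                 sub["ahi"].to_numpy(), method=method,
                                 alpha=alpha)
        rows.append({"ch_i": ch_i, "ch_j": ch_j, "band": band, "r": res.r,
                     "p": res.p, "n": res.n, "significant": res.significant,
                     "defined": res.defined})
    out = pd.DataFrame(rows)
    if fdr and len(out):
        from statsmodels.stats.multitest import multipletests

        ok = out["defined"] & np.isfinite(out["p"])
        adj = np.full(len(out), np.nan)
        if ok.any():
            adj[ok.to_numpy()] = multipletests(out.loc[ok, "p"],
                                               method="fdr_bh")[1]
        out["p_fdr"] = adj
        out["significant_fdr"] = out["p_fdr"] < alpha
    return out


def group_comparison_table(cohort: pd.DataFrame, alpha: float = 0.001,
                           pairs=None) -> pd.DataFrame:
    """Per-(pair, band) Mann-Whitney comparison of control vs main subjects."""
    _check_cohort_frame(cohort)
    if pairs is not None:
        keys = {frozenset(p) for p in pairs}
        cohort = cohort[[frozenset((i, j)) in keys
                         for i, j in zip(cohort["ch_i"], cohort["ch_j"])]]
    rows = []
    for (ch_i, ch_j, band), sub in cohort.groupby(["ch_i", "ch_j", "band"],
                                                  sort=False):
        ctrl = sub.loc[sub["group"] == "control", "mean_wb"].to_numpy()
        main = sub.loc[sub["group"] == "main", "mean_wb"].to_numpy()
        ctrl = ctrl[np.isfinite(ctrl)]
        main = main[np.isfinite(main)]
        if ctrl.size == 0 or main.size == 0:
            rows.append({"ch_i": ch_i, "ch_j": ch_j, "band": band,
                         "u_statistic": np.nan, "p": np.nan,
                         "significant": False, "median_control": np.nan,
                         "median_main": np.nan, "n_control": int(ctrl.size),
                         "n_main": int(main.size), "method": "undefined"})
            continue
        res = mann_whitney_cell(ctrl, main, alpha=alpha)
        rows.append({"ch_i": ch_i, "ch_j": ch_j, "band": band,
                     "u_statistic": res.u_statistic, "p": res.p,
                     "significant": res.significant,
                     "median_control": res.median_control,
                     "median_main": res.median_main,
                     "n_control": res.n_control, "n_main": res.n_main,
                     "method": res.method})
    return pd.DataFrame(rows)
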