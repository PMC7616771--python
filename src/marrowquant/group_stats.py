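"""Shared nonparametric testing and normalization primitives.

Covers the proteomics comparison chain — log2(x+1) variance stabilization,
per-feature min-max scaling to [0, 1], two-sided Wilcoxon rank-sum between
sample groups, Benjamini-Hochberg multiplicity adjustment — and serves as the
single Wilcoxon/BH backend for the score and positivity comparisons elsewhere
in the package.

The rank-sum test runs the exact permutation distribution when the combined
sample is small (total n <= 14) and tie-free, where the normal approximation
is weakest and enumeration is trivially cheap; otherwise the normal
approximation with tie and continuity corrections.  The result records which
path ran.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: Largest combined sample size for which the exact permutation path is used.
EXACT_MAX_TOTAL_N = 14


@dataclass
class AbundanceTable:
    """Features x samples abundance matrix with a group label per sample.

    ``data`` is a DataFrame (rows = features, columns = samples); missing
    values are allowed.  ``groups`` is a Series indexed by sample id.
    """

    data: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates or self.data.columns.has_duplicates:
            raise ValueError("feature and sample ids must be unique")
        missing = set(self.data.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"samples without a group label: {sorted(missing)[:5]}")
        self.groups = self.groups.loc[self.data.columns]

    @classmethod
    def from_csv(cls, table_csv, groups_csv) -> "AbundanceTable":
        data = pd.read_csv(table_csv, index_col=0)
        gdf = pd.read_csv(groups_csv)
        return cls(data, pd.Series(gdf["group"].values,
                                   index=gdf["sample_id"].astype(str)))


def log_normalize(table: AbundanceTable, base: float = 2.0) -> AbundanceTable:
    """Variance-stabilizing ``x -> log_base(x + 1)``; missing stays missing."""
    vals = table.data.to_numpy(dtype=float)
    if np.nanmin(vals) < 0:
        raise ValueError("log normalization requires non-negative abundances")
    out = np.log1p(vals) / np.log(base)
    return AbundanceTable(pd.DataFrame(out, index=table.data.index,
                                       columns=table.data.columns),
                          table.groups)


def min_max_scale(table: AbundanceTable) -> AbundanceTable:
    """Per-feature scaling to [0, 1]: ``x -> (x - min) / (max - min)``.

    Constant features map to 0 with a warning; a feature with no observed
    values is an error.
    """
    vals = table.data.to_numpy(dtype=float)
    out = np.empty_like(vals)
    for i, fid in enumerate(table.data.index):
        row = vals[i]
        obs = row[~np.isnan(row)]
        if obs.size == 0:
            raise ValueError(f"feature {fid!r} has no observed values")
        lo, hi = obs.min(), obs.max()
        if hi == lo:
            logger.warning("feature %r is constant; scaled to 0", fid)
            out[i] = np.where(np.isnan(row), np.nan, 0.0)
        else:
            out[i] = (row - lo) / (hi - lo)
    return AbundanceTable(pd.DataFrame(out, index=table.data.index,
                                       columns=table.data.columns),
                          table.groups)


@dataclass
class TestResult:
    """Two-sided rank-sum outcome; ``method`` records exact vs approximation."""

    statistic: float      # Mann-Whitney U for the first sample
    p: float
    method: str           # "exact" | "normal-approx"
    p_adjusted: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p outside [0, 1]")
        if self.p_adjusted is not None and not self.p <= self.p_adjusted <= 1.0:
            raise ValueError("p_adjusted must lie in [p, 1]")


def _has_ties(pooled: np.ndarray) -> bool:
    return np.unique(pooled).size < pooled.size


def wilcoxon_rank_sum(x, y) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact permutation null when ``len(x) + len(y) <= 14`` with no ties;
    otherwise the normal approximation with midrank tie correction and
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both groups must be non-empty")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("NaN values are not allowed; drop them first")
    pooled = np.concatenate([x, y])
    exact = (pooled.size <= EXACT_MAX_TOTAL_N) and not _has_ties(pooled)
    if exact:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        method = "exact"
    else:
        res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic", use_continuity=True)
        method = "normal-approx"
    return TestResult(float(res.statistic), float(min(res.pvalue, 1.0)), method)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    return adjust_pvalues(pvalues, method="bh")


def adjust_pvalues(pvalues, method: str = "bh") -> np.ndarray:
    """Multiplicity adjustment; ``method`` is "bh" or "bonferroni"."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    key = {"bh": "fdr_bh", "bonferroni": "bonferroni"}.get(method)
    if key is None:
        raise ValueError(f"unknown adjustment method {method!r}")
    return multipletests(p, method=key)[1]


def compare_groups(table: AbundanceTable, group_a: str, group_b: str,
                   adjust: str = "bh") -> pd.DataFrame:
    """Per-feature rank-sum comparison between two sample groups.

    Missing values are dropped per feature; features with fewer than one
    observation in either group get NaN p-values (excluded from adjustment).
    Returns a DataFrame indexed by feature with statistic, p, p_adjusted and
    the method tag.
    """
    for g in (group_a, group_b):
        if g not in set(table.groups):
            raise ValueError(f"group {g!r} not present in the table")
    a_cols = table.groups.index[table.groups == group_a]
    b_cols = table.groups.index[table.groups == group_b]
    rows = []
    for fid, row in table.data.iterrows():
        xa = row[a_cols].dropna().to_numpy(dtype=float)
        xb = row[b_cols].dropna().to_numpy(dtype=float)
        if xa.size < 1 or xb.size < 1:
            rows.append({"feature_id": fid, "statistic": np.nan, "p": np.nan,
                         "method": "insufficient-data",
                         "median_a": np.nan, "median_b": np.nan})
            continue
        res = wilcoxon_rank_sum(xa, xb)
        rows.append({"feature_id": fid, "statistic": res.statistic,
                     "p": res.p, "method": res.method,
                     "median_a": float(np.median(xa)),
                     "median_b": float(np.median(xb))})
    df = pd.DataFrame(rows).set_index("feature_id")
    ok = df["p"].notna()
    df["p_adjusted"] = np.nan
    if ok.any():
        df.loc[ok, "p_adjusted"] = adjust_pvalues(df.loc[ok, "p"].to_numpy(),
                                                  method=adjust)
    return df
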