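"""Group-comparison statistics.

Two-group comparisons use the unpaired two-sided Mann-Whitney U test —
the samples are small per-case values for which normality and
homoscedasticity cannot be assumed — and distribution comparisons (SAS
size frequency distributions) use the two-sample Kolmogorov-Smirnov
test.  The unit of analysis for the U test is the case (subject), never
the stack: stacks within a case are not independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["ComparisonResult", "mann_whitney", "ks_two_sample", "compare_study"]

ALPHA = 0.05


@dataclass
class ComparisonResult:
    variable: str
    test: str
    statistic: float
    pvalue: float
    group_a: str
    group_b: str
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int
    significant: bool | None  # None when not testable
    note: str = ""

    def as_row(self) -> dict:
        return dict(self.__dict__)


def _exact_applicable(a: np.ndarray, b: np.ndarray) -> bool:
    pooled = np.concatenate([a, b])
    return len(pooled) <= 12 and len(np.unique(pooled)) == len(pooled)


def mann_whitney(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U with midrank ties.

    Exact p by enumeration of arrangements when the pooled sample has
    ≤ 12 tie-free observations; otherwise the normal approximation with
    tie and continuity corrections.  Returns ``(U, p)`` with U the
    statistic of the first sample.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    method = "exact" if _exact_applicable(a, b) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def ks_two_sample(a, b) -> tuple[float, float]:
    """Two-sample KS: D = sup |ECDF_a − ECDF_b| with asymptotic p."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    res = sps.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)


def _mw_result(variable: str, a: np.ndarray, b: np.ndarray,
               names: tuple[str, str]) -> ComparisonResult:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    base = dict(
        variable=variable, group_a=names[0], group_b=names[1],
        mean_a=float(np.mean(a)) if len(a) else np.nan,
        mean_b=float(np.mean(b)) if len(b) else np.nan,
        sd_a=float(np.std(a, ddof=1)) if len(a) > 1 else np.nan,
        sd_b=float(np.std(b, ddof=1)) if len(b) > 1 else np.nan,
        n_a=len(a), n_b=len(b),
    )
    if len(a) < 2 or len(b) < 2:
        return ComparisonResult(test="mann-whitney", statistic=np.nan, pvalue=np.nan,
                                significant=None,
                                note="not testable: fewer than two cases in a group",
                                **base)
    u, p = mann_whitney(a, b)
    return ComparisonResult(test="mann-whitney", statistic=u, pvalue=p,
                            significant=bool(p < ALPHA), **base)


def compare_study(case_table: pd.DataFrame, pooled_distributions: dict | None = None,
                  group_col: str = "group") -> pd.DataFrame:
    """Study-level comparison table.

    ``case_table`` holds one row per case with a group column and numeric
    per-case variables (density, %AS, thickness, mean SAS area, curvature,
    nearest-neighbour distance, volume fractions, ...); each gets a
    Mann-Whitney comparison on case values.  ``pooled_distributions``
    optionally maps a variable name to ``(sample_a, sample_b)`` pooled
    per-synapse values compared by the KS test (SAS size distributions).
    Missing (NaN) values for any case make a variable not-testable and it
    is reported as such rather than dropped.
    """
    groups = list(dict.fromkeys(case_table[group_col]))
    if len(groups) != 2:
        raise ValueError(f"expected exactly two groups, got {groups}")
    ga = case_table[case_table[group_col] == groups[0]]
    gb = case_table[case_table[group_col] == groups[1]]
    results: list[ComparisonResult] = []
    for col in case_table.columns:
        if col == group_col or not pd.api.types.is_numeric_dtype(case_table[col]):
            continue
        a, b = ga[col].to_numpy(dtype=float), gb[col].to_numpy(dtype=float)
        if np.isnan(a).any() or np.isnan(b).any():
            results.append(ComparisonResult(
                variable=col, test="mann-whitney", statistic=np.nan, pvalue=np.nan,
                group_a=groups[0], group_b=groups[1],
                mean_a=float(np.nanmean(a)), mean_b=float(np.nanmean(b)),
                sd_a=np.nan, sd_b=np.nan, n_a=len(a), n_b=len(b),
                significant=None, note="not testable: missing case values"))
            continue
        results.append(_mw_result(col, a, b, (groups[0], groups[1])))
    for name, (da, db) in (pooled_distributions or {}).items():
        da = np.asarray(da, dtype=float)
        db = np.asarray(db, dtype=float)
        d, p = ks_two_sample(da, db)
        results.append(ComparisonResult(
            variable=name, test="kolmogorov-smirnov", statistic=d, pvalue=p,
            group_a=groups[0], group_b=groups[1],
            mean_a=float(da.mean()), mean_b=float(db.mean()),
            sd_a=float(da.std(ddof=1)), sd_b=float(db.std(ddof=1)),
            n_a=len(da), n_b=len(db), significant=bool(p < ALPHA)))
    return pd.DataFrame([r.as_row() for r in results])
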