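"""Temporal fold-change distributions and nonparametric group statistics.

Two kinds of downstream analysis are covered:

* Temporal analysis of gene lists (wild-type fold-changes 20→28 hpf and
  28→36 hpf for each pathway-regulated list, compared against the total
  arch-enriched list): per-list order-statistic summaries, a global
  Kruskal-Wallis test, and pairwise Mann-Whitney U tests against the total
  list with Bonferroni correction.
* Genotype × phenotype penetrance contingency tables: Pearson chi-square
  (no continuity correction) on r×2 count tables, with Fisher's exact test
  available for 2×2 tables whose expected counts are small.

The Mann-Whitney implementation enumerates the exact two-sided null when
the combined sample size is small (default ≤ 20) and uses midranks for
ties; otherwise it applies the tie-corrected normal approximation without
continuity correction, which makes the two-group Kruskal-Wallis identity
H = z² hold exactly.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
import warnings
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import ConfigurationError, ExpressionMatrix, SampleDesign

__all__ = [
    "ListSummary",
    "ComparisonReport",
    "ContingencyTable",
    "PenetranceResult",
    "temporal_fold_changes",
    "summarize_list",
    "mann_whitney_u",
    "kruskal_wallis",
    "bonferroni",
    "compare_lists",
    "chi_square_penetrance",
]

#: intervals of the wild-type time course, keyed by the column name used in
#: the temporal fold-change table
INTERVALS = {"20_28": (20, 28), "28_36": (28, 36)}


def temporal_fold_changes(
    matrix: ExpressionMatrix,
    design: SampleDesign,
    universe: Iterable[str] | None = None,
    zero_replacement: float = 0.01,
    condition: str = "wt",
) -> pd.DataFrame:
    """Wild-type double-positive fold-changes per interval for each gene.

    Returns a DataFrame with columns ``fc_20_28`` and ``fc_28_36``.  Zero
    RPKM values are replaced by ``zero_replacement`` before forming ratios,
    so six genes with zero 20 hpf expression (say) still get a finite,
    very large induction value rather than a division error.
    """
    cols = {}
    stage_values = {
        s: matrix.column(design.one("double_positive", s, condition))
        for s in (20, 28, 36)
    }
    if universe is not None:
        keep = stage_values[20].index.intersection(list(universe))
        stage_values = {s: v.loc[keep] for s, v in stage_values.items()}
    for name, (lo, hi) in INTERVALS.items():
        num = stage_values[hi]
        den = stage_values[lo]
        num = num.where(num > 0, zero_replacement)
        den = den.where(den > 0, zero_replacement)
        cols[f"fc_{name}"] = num / den
    return pd.DataFrame(cols)


@dataclasses.dataclass(frozen=True)
class ListSummary:
    """Order-statistic summary of one list's fold-changes."""

    name: str
    n: int
    median: float
    q1: float
    q3: float
    p5: float
    p95: float
    count_over_threshold: int
    threshold: float = 10.0


def summarize_list(
    fcs: Sequence[float], threshold: float = 10.0, name: str = ""
) -> ListSummary:
    """Median/quartiles/5th-95th percentiles plus a strict > threshold count.

    Quantiles use linear interpolation between order statistics (numpy's
    default convention).
    """
    values = np.asarray(list(fcs), dtype=float)
    if values.size == 0:
        raise ValueError("cannot summarize an empty list")
    p5, q1, med, q3, p95 = np.percentile(values, [5, 25, 50, 75, 95])
    return ListSummary(
        name=name,
        n=int(values.size),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        p5=float(p5),
        p95=float(p95),
        count_over_threshold=int((values > threshold).sum()),
        threshold=float(threshold),
    )


def _u_statistic(x: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """U statistic of x (rank-sum definition, midranks for ties)."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r_x = ranks[: len(x)].sum()
    u_x = r_x - len(x) * (len(x) + 1) / 2.0
    return float(u_x), ranks


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    mode: Literal["exact", "approximate", "auto"] = "auto",
    exact_limit: int = 20,
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of x, p).

    ``exact`` enumerates all C(n+m, n) assignments of the pooled midranks to
    the two groups and counts assignments whose U deviates from the null
    mean nm/2 at least as much as the observed U (ties handled exactly).
    ``approximate`` is the tie-corrected normal approximation without
    continuity correction.  ``auto`` switches at ``exact_limit`` combined
    observations.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n, m = len(x), len(y)
    u_obs, ranks = _u_statistic(x, y)
    mu = n * m / 2.0
    if mode == "auto":
        mode = "exact" if n + m <= exact_limit else "approximate"
    if mode == "exact":
        dev = abs(u_obs - mu)
        total = math.comb(n + m, n)
        offset = n * (n + 1) / 2.0
        count = 0
        for subset in itertools.combinations(range(n + m), n):
            u = ranks[list(subset)].sum() - offset
            if abs(u - mu) >= dev - 1e-12:
                count += 1
        return u_obs, count / total
    if mode != "approximate":
        raise ValueError(f"unknown mode {mode!r}")
    N = n + m
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum())
    sigma2 = n * m / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    if sigma2 <= 0:  # every pooled observation identical
        return u_obs, 1.0
    z = (u_obs - mu) / math.sqrt(sigma2)
    return u_obs, float(2.0 * sps.norm.sf(abs(z)))


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and chi-square p with df = k-1.

    Degenerate input where every pooled observation is identical yields
    H = 0, p = 1 (all rank distributions coincide).
    """
    arrays = [np.asarray(list(g), dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(a.size == 0 for a in arrays):
        raise ValueError("groups must be non-empty")
    pooled = np.concatenate(arrays)
    N = pooled.size
    ranks = sps.rankdata(pooled)
    h = 0.0
    start = 0
    for a in arrays:
        r = ranks[start : start + a.size]
        h += r.sum() ** 2 / a.size
        start += a.size
    h = 12.0 / (N * (N + 1)) * h - 3.0 * (N + 1)
    _, tie_counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - float((tie_counts**3 - tie_counts).sum()) / (N**3 - N)
    if correction <= 0:
        return 0.0, 1.0
    h /= correction
    h = max(h, 0.0)  # guard tiny negative rounding
    p = float(sps.chi2.sf(h, df=len(arrays) - 1))
    return float(h), p


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-adjusted p-value, capped at 1."""
    return min(1.0, p * m)


@dataclasses.dataclass
class ListComparison:
    summary: ListSummary
    u_statistic: float | None
    p_raw: float | None
    p_adjusted: float | None
    significant: bool | None


@dataclasses.dataclass
class ComparisonReport:
    interval: str
    alpha: float
    kruskal_h: float
    kruskal_wallis_p: float
    n_pairwise: int
    total: ListSummary
    lists: dict[str, ListComparison]

    def flagged(self) -> list[str]:
        return [k for k, v in self.lists.items() if v.significant]


def compare_lists(
    temporal: pd.DataFrame,
    lists: Mapping[str, Iterable[str]],
    interval: Literal["20_28", "28_36"],
    alpha: float = 0.05,
    total_name: str = "total",
    threshold: float = 10.0,
    mw_mode: Literal["exact", "approximate", "auto"] = "auto",
) -> ComparisonReport:
    """Compare each gene list's fold-changes against the total list.

    Kruskal-Wallis over all lists (total included), then each non-total list
    versus the total by Mann-Whitney, Bonferroni-adjusted over the number of
    pairwise tests actually performed.  Lists with fewer than two members are
    summarized but skipped from testing, with a warning.
    """
    if interval not in INTERVALS:
        raise ValueError(f"unknown interval {interval!r}")
    if total_name not in lists:
        raise ConfigurationError(f"lists must include the reference {total_name!r}")
    col = temporal[f"fc_{interval}"]

    def values(genes: Iterable[str]) -> np.ndarray:
        idx = col.index.intersection(list(genes))
        return col.loc[idx].to_numpy()

    total_values = values(lists[total_name])
    if total_values.size < 2:
        raise ValueError("total list must have at least two members")

    testable: dict[str, np.ndarray] = {}
    skipped: list[str] = []
    for name, genes in lists.items():
        if name == total_name:
            continue
        v = values(genes)
        if v.size < 2:
            warnings.warn(
                f"list {name!r} has fewer than 2 members; comparison skipped"
            )
            skipped.append(name)
        testable[name] = v

    kw_groups = [total_values] + [v for k, v in testable.items() if k not in skipped]
    if len(kw_groups) >= 2:
        kw_h, kw_p = kruskal_wallis(kw_groups)
    else:
        kw_h, kw_p = 0.0, 1.0

    m = sum(1 for k in testable if k not in skipped)
    comparisons: dict[str, ListComparison] = {}
    for name, v in testable.items():
        if name in skipped:
            summary = (
                summarize_list(v, threshold, name) if v.size else None
            )
            comparisons[name] = ListComparison(summary, None, None, None, None)
            continue
        u, p = mann_whitney_u(v, total_values, mode=mw_mode)
        p_adj = bonferroni(p, m)
        comparisons[name] = ListComparison(
            summary=summarize_list(v, threshold, name),
            u_statistic=u,
            p_raw=p,
            p_adjusted=p_adj,
            significant=bool(p_adj < alpha),
        )
    return ComparisonReport(
        interval=interval,
        alpha=alpha,
        kruskal_h=kw_h,
        kruskal_wallis_p=kw_p,
        n_pairwise=m,
        total=summarize_list(total_values, threshold, total_name),
        lists=comparisons,
    )


@dataclasses.dataclass(frozen=True)
class ContingencyTable:
    """Genotype × (affected, unaffected) counts for penetrance analysis."""

    groups: tuple[str, ...]
    affected: tuple[int, ...]
    unaffected: tuple[int, ...]

    def __post_init__(self):
        if len(self.groups) < 2:
            raise ValueError("need at least two genotype groups")
        if not (len(self.groups) == len(self.affected) == len(self.unaffected)):
            raise ValueError("groups, affected and unaffected must align")
        if any(a < 0 for a in self.affected) or any(u < 0 for u in self.unaffected):
            raise ValueError("counts must be non-negative")

    def to_array(self) -> np.ndarray:
        return np.column_stack([self.affected, self.unaffected]).astype(float)


@dataclasses.dataclass(frozen=True)
class PenetranceResult:
    method: str
    statistic: float  # chi-square statistic, or odds ratio for Fisher
    p_value: float
    dof: int
    min_expected: float
    low_expected_warning: bool


def chi_square_penetrance(
    table: ContingencyTable,
    mode: Literal["pearson", "fisher"] = "pearson",
) -> PenetranceResult:
    """Compare phenotype proportions across genotype groups.

    Pearson chi-square without continuity correction on the r×2 table
    (df = r−1); Fisher's exact test for 2×2 tables.  A warning flag is set
    when any expected count falls below 5.
    """
    arr = table.to_array()
    rows = arr.sum(axis=1)
    cols = arr.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("degenerate table: zero row or column margin")
    n = arr.sum()
    expected = np.outer(rows, cols) / n
    min_expected = float(expected.min())
    low = min_expected < 5
    if mode == "pearson":
        stat = float(((arr - expected) ** 2 / expected).sum())
        dof = arr.shape[0] - 1
        p = float(sps.chi2.sf(stat, df=dof))
        return PenetranceResult("pearson", stat, p, dof, min_expected, low)
    if mode == "fisher":
        if arr.shape != (2, 2):
            raise ValueError("Fisher's exact test requires a 2x2 table")
        odds, p = sps.fisher_exact(arr)
        return PenetranceResult("fisher", float(odds), float(p), 1, min_expected, low)
    raise ValueError(f"unknown mode {mode!r}")
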