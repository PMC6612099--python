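"""Candidate-validation numerics.

Covers the statistics used to confirm individual silenced genes:
bisulfite-pyrosequencing window averaging, 2^-ddCt relative expression
from qPCR cycle thresholds, rank-based two-group and k-group tests
(exact by enumeration at small sample sizes, normal/chi-square
approximations otherwise), and the demethylating-agent restoration
comparison.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n: tuple

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError(f"p-value outside [0, 1]: {self.p_value}")


def pyro_mean(per_cpg_pct) -> float:
    """Percent methylation of an assay window: mean over its CpGs.

    Pyrosequencing quantifies each CpG dinucleotide in the sequenced
    window separately; the assay-level value is their arithmetic mean.
    """
    vals = np.asarray(per_cpg_pct, dtype=float)
    if vals.size == 0:
        raise ValueError("need at least one CpG value")
    if np.any((vals < 0) | (vals > 100)):
        raise ValueError("percent methylation must lie in [0, 100]")
    return float(vals.mean())


def relative_expression(measurements: pd.DataFrame, calibrator_group: str) -> pd.Series:
    """Relative expression per group by the 2^-ddCt method.

    ``measurements`` needs columns ``group``, ``ct_target``,
    ``ct_reference`` (reference = endogenous-control gene, e.g. GAPDH).
    dCt = ct_target - ct_reference per measurement; ddCt contrasts
    group-mean dCt against the calibrator group; the calibrator itself
    is exactly 1 by construction.
    """
    required = {"group", "ct_target", "ct_reference"}
    if not required <= set(measurements.columns):
        raise ValueError(f"measurements need columns {sorted(required)}")
    ct = measurements[["ct_target", "ct_reference"]].astype(float)
    if ct.isna().any().any():
        raise ValueError("missing Ct value")
    if (ct <= 0).any().any() or not np.isfinite(ct.to_numpy()).all():
        raise ValueError("Ct values must be finite and positive")
    dct = ct["ct_target"] - ct["ct_reference"]
    mean_dct = dct.groupby(measurements["group"]).mean()
    if calibrator_group not in mean_dct.index:
        raise ValueError(f"calibrator group {calibrator_group!r} absent")
    ddct = mean_dct - mean_dct[calibrator_group]
    return np.power(2.0, -ddct).rename("relative_expression")


@lru_cache(maxsize=None)
def _u_counts(n1: int, n2: int) -> tuple:
    """Number of label arrangements per U value (no ties).

    Recurrence on whether the largest of the n1+n2 values belongs to
    the first sample: f(u; n1, n2) = f(u - n2; n1-1, n2) + f(u; n1, n2-1).
    """
    if n1 == 0 or n2 == 0:
        return (1,) + (0,) * (n1 * n2)
    counts = np.zeros(n1 * n2 + 1, dtype=float)
    a = np.asarray(_u_counts(n1 - 1, n2))
    counts[n2:n2 + a.size] += a
    b = np.asarray(_u_counts(n1, n2 - 1))
    counts[:b.size] += b
    return tuple(counts)


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U = #{(i,j): x_i > y_j} + 0.5 #{ties}, via midranks."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r1 = ranks[: len(x)].sum()
    return float(r1 - len(x) * (len(x) + 1) / 2)


def mann_whitney(x, y, mode: str = "auto", exact_max_n: int = 12) -> TestResult:
    """Two-sided Mann-Whitney U test.

    ``mode='auto'`` computes the exact null distribution by counting
    label arrangements when n1+n2 <= ``exact_max_n`` and the pooled
    data carry no ties; otherwise the normal approximation with tie and
    continuity corrections.  The exact two-sided p doubles the smaller
    tail (P(U <= u) vs P(U >= u)) and is capped at 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if mode not in ("auto", "exact", "approx"):
        raise ValueError(f"unknown mode {mode!r}")
    n1, n2 = len(x), len(y)
    u = _u_statistic(x, y)
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    use_exact = mode == "exact" or (
        mode == "auto" and n1 + n2 <= exact_max_n and not has_ties
    )
    if use_exact and has_ties:
        raise ValueError("exact mode requires tie-free data")
    if use_exact:
        counts = np.asarray(_u_counts(n1, n2))
        total = counts.sum()
        ui = int(round(u))
        cdf = counts[: ui + 1].sum() / total
        sf = counts[ui:].sum() / total
        p = min(1.0, 2.0 * min(cdf, sf))
        method = "mann-whitney-exact"
    else:
        mu = n1 * n2 / 2.0
        n = n1 + n2
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if var <= 0:
            p = 1.0
        else:
            # continuity correction of 0.5 toward the mean
            z = (u - mu - 0.5 * np.sign(u - mu)) / np.sqrt(var)
            p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
        method = "mann-whitney-normal"
    return TestResult(statistic=u, p_value=float(p), method=method, n=(n1, n2))


def _kruskal_h(pooled: np.ndarray, sizes: list[int]) -> float:
    """Kruskal-Wallis H with tie correction for groups laid out contiguously."""
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    h = 0.0
    start = 0
    for sz in sizes:
        rbar = ranks[start:start + sz].mean()
        h += sz * (rbar - (n + 1) / 2) ** 2
        start += sz
    h *= 12.0 / (n * (n + 1))
    _, tie_counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - (tie_counts**3 - tie_counts).sum() / (n**3 - n)
    if correction == 0:
        return 0.0  # all observations identical
    return h / correction


def _partitions(indices: tuple, sizes: list[int]):
    """All ways to split ``indices`` into ordered groups of given sizes."""
    if len(sizes) == 1:
        yield (indices,)
        return
    first, rest_sizes = sizes[0], sizes[1:]
    for combo in itertools.combinations(indices, first):
        remaining = tuple(i for i in indices if i not in combo)
        for rest in _partitions(remaining, rest_sizes):
            yield (combo,) + rest


def kruskal_wallis(groups, mode: str = "auto", exact_max_n: int = 10) -> TestResult:
    """Kruskal-Wallis rank test for >= 3 groups (2 groups fall back to U test).

    H carries the standard tie correction; the p-value is chi-square
    with k-1 df, or the exact permutation distribution of H when the
    pooled size is <= ``exact_max_n``.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size == 0 for g in groups):
        raise ValueError("all groups must be non-empty")
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if len(groups) == 2:
        return mann_whitney(groups[0], groups[1], mode=mode)
    sizes = [len(g) for g in groups]
    pooled = np.concatenate(groups)
    n = len(pooled)
    h = _kruskal_h(pooled, sizes)
    use_exact = mode == "exact" or (mode == "auto" and n <= exact_max_n)
    if use_exact:
        count_ge = 0
        total = 0
        for part in _partitions(tuple(range(n)), sizes):
            order = [i for grp in part for i in grp]
            h_perm = _kruskal_h(pooled[order], sizes)
            total += 1
            if h_perm >= h - 1e-12:
                count_ge += 1
        p = count_ge / total
        method = "kruskal-wallis-exact"
    else:
        p = float(sps.chi2.sf(h, df=len(groups) - 1))
        method = "kruskal-wallis-chi2"
    return TestResult(statistic=float(h), p_value=float(min(p, 1.0)),
                      method=method, n=tuple(sizes))


def restoration_test(untreated, dose_groups: dict, alpha: float = 0.05) -> pd.DataFrame:
    """Compare each demethylating-agent dose against untreated cells.

    For every dose group of relative-expression values, a two-sided
    Mann-Whitney test against the untreated group; restoration is
    declared when p < alpha and the dose median exceeds the untreated
    median (re-expression, not just any shift).
    """
    untreated = np.asarray(untreated, dtype=float)
    if untreated.size == 0 or not dose_groups:
        raise ValueError("need untreated values and at least one dose group")
    rows = []
    for dose, values in dose_groups.items():
        values = np.asarray(values, dtype=float)
        res = mann_whitney(values, untreated)
        increased = bool(np.median(values) > np.median(untreated))
        rows.append(
            {
                "dose": dose,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "method": res.method,
                "increased": increased,
                "restored": bool(res.p_value < alpha and increased),
            }
        )
    return pd.DataFrame(rows).set_index("dose")


def wilcoxon_signed_rank(pre, post) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired values."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.size == 0:
        raise ValueError("paired samples of equal non-zero length required")
    if np.all(pre == post):
        return TestResult(statistic=0.0, p_value=1.0,
                          method="wilcoxon-signed-rank", n=(len(pre),))
    stat, p = sps.wilcoxon(post, pre)
    return TestResult(statistic=float(stat), p_value=float(p),
                      method="wilcoxon-signed-rank", n=(len(pre),))
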