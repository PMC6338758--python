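"""The statistical battery of the courtship study.

Success rates (copulation, reproduction) are compared between two groups with
Fisher's exact test, two-sided by the point-probability rule (the convention
of R's ``fisher.test``: the p-value sums every hypergeometric table whose
probability does not exceed that of the observed table).  Courtship latency is
compared across k groups with the Kruskal–Wallis rank test and all-pairs
Steel–Dwass post-hoc comparisons; the courtship index with one-way ANOVA and
Tukey's HSD.  Significance is declared at α = 0.05 throughout.

Steel–Dwass is written out here: for each pair of groups the Wilcoxon
rank-sum statistic is computed on that pair alone, standardized with the
tie-corrected variance, and √2·|z| is referred to the studentized-range
distribution with k groups and infinite degrees of freedom.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import scipy.stats as sps

__all__ = [
    "ALPHA",
    "TestResult",
    "fisher_exact",
    "fisher_exact_from_counts",
    "kruskal_wallis",
    "steel_dwass",
    "anova_tukey",
    "results_frame",
]

ALPHA = 0.05


@dataclass(frozen=True)
class TestResult:
    """One hypothesis-test outcome with the α = 0.05 significance flag."""

    method: str
    statistic: float
    p_value: float
    groups: tuple[str, ...] = ()
    significant: bool = False

    @classmethod
    def make(
        cls, method: str, statistic: float, p_value: float, groups: Sequence[str] = ()
    ) -> "TestResult":
        p = float(min(max(p_value, 0.0), 1.0))
        return cls(
            method=method,
            statistic=float(statistic),
            p_value=p,
            groups=tuple(groups),
            significant=p < ALPHA,
        )


class DegenerateTableError(ValueError):
    """Raised for a 2×2 table with an empty margin."""


def fisher_exact(
    table: Sequence[Sequence[int]], convention: str = "point_probability"
) -> TestResult:
    """Two-sided Fisher's exact test on a 2×2 contingency table.

    ``convention='point_probability'`` (default) sums all tables at least as
    extreme in point probability as the observed one — what R's
    ``fisher.test`` reports.  ``convention='central'`` doubles the smaller
    one-sided tail instead (capped at 1).
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of non-negative counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise DegenerateTableError("a margin of the 2x2 table is zero")
    if convention == "point_probability":
        odds, p = sps.fisher_exact(t, alternative="two-sided")
    elif convention == "central":
        _, p_less = sps.fisher_exact(t, alternative="less")
        _, p_greater = sps.fisher_exact(t, alternative="greater")
        odds = sps.fisher_exact(t)[0]
        p = min(1.0, 2 * min(p_less, p_greater))
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return TestResult.make("fisher_exact", odds, p)


def fisher_exact_from_counts(
    successes_a: int, n_a: int, successes_b: int, n_b: int,
    groups: tuple[str, str] = ("A", "B"),
) -> TestResult:
    """Fisher's exact test comparing two success rates given as counts."""
    table = [[successes_a, n_a - successes_a], [successes_b, n_b - successes_b]]
    res = fisher_exact(table)
    return TestResult.make(res.method, res.statistic, res.p_value, groups)


def _as_groups(groups: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    out = {str(k): np.asarray(v, dtype=float) for k, v in groups.items()}
    for name, vals in out.items():
        if vals.size == 0:
            raise ValueError(f"group {name!r} is empty")
    return out


def kruskal_wallis(groups: Mapping[str, Sequence[float]]) -> TestResult:
    """Kruskal–Wallis H test (tie-corrected, chi-square reference, k−1 df)."""
    g = _as_groups(groups)
    if len(g) < 2:
        raise ValueError("need at least 2 groups")
    values = list(g.values())
    pooled = np.concatenate(values)
    if np.all(pooled == pooled[0]):
        warnings.warn("all observations identical: H = 0, p = 1", stacklevel=2)
        return TestResult.make("kruskal_wallis", 0.0, 1.0, tuple(g))
    h, p = sps.kruskal(*values)
    return TestResult.make("kruskal_wallis", h, p, tuple(g))


def steel_dwass(
    groups: Mapping[str, Sequence[float]], method: str = "asymptotic"
) -> list[TestResult]:
    """All-pairs Steel–Dwass nonparametric multiple comparisons.

    For every pair of the k groups, the two samples are ranked jointly
    (mid-ranks for ties), the rank sum of the first group is standardized by
    the tie-corrected null mean and variance, and √2·|z| is referred to the
    studentized-range distribution with parameters (k, ∞), which controls the
    family-wise error across the k(k−1)/2 comparisons.  ``method='exact'``
    replaces the normal standardization with the exact permutation
    distribution of the rank sum (small samples only).
    """
    g = _as_groups(groups)
    k = len(g)
    if k < 2:
        raise ValueError("need at least 2 groups")
    names = list(g)
    results: list[TestResult] = []
    for a, b in itertools.combinations(names, 2):
        x, y = g[a], g[b]
        if len(x) < 2 or len(y) < 2:
            warnings.warn(f"pair ({a}, {b}) skipped: a group has fewer than 2 observations",
                          stacklevel=2)
            continue
        n1, n2 = len(x), len(y)
        pooled = np.concatenate([x, y])
        ranks = sps.rankdata(pooled)
        w = ranks[:n1].sum()
        n = n1 + n2
        mean_w = n1 * (n + 1) / 2.0
        var_w = n1 * n2 / (n * (n - 1.0)) * (np.sum(ranks**2) - n * (n + 1.0) ** 2 / 4.0)
        if var_w <= 0:
            results.append(TestResult.make("steel_dwass", 0.0, 1.0, (a, b)))
            continue
        if method == "asymptotic":
            z = (w - mean_w) / math.sqrt(var_w)
            p = float(sps.studentized_range.sf(math.sqrt(2.0) * abs(z), k, np.inf))
            stat = z
        elif method == "exact":
            stat, p = _exact_ranksum(x, y)
        else:
            raise ValueError(f"unknown method {method!r}")
        results.append(TestResult.make("steel_dwass", stat, p, (a, b)))
    return results


def _exact_ranksum(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided rank-sum permutation p for one pair (small n only)."""
    n1 = len(x)
    pooled = np.concatenate([x, y])
    n = len(pooled)
    if math.comb(n, n1) > 2_000_000:
        raise ValueError("samples too large for exact enumeration")
    ranks = sps.rankdata(pooled)
    w_obs = ranks[:n1].sum()
    mean_w = n1 * (n + 1) / 2.0
    dev_obs = abs(w_obs - mean_w)
    count = 0
    total = 0
    for comb in itertools.combinations(range(n), n1):
        w = ranks[list(comb)].sum()
        total += 1
        if abs(w - mean_w) >= dev_obs - 1e-9:
            count += 1
    return w_obs - mean_w, count / total


def anova_tukey(
    groups: Mapping[str, Sequence[float]],
) -> tuple[TestResult, list[TestResult]]:
    """One-way ANOVA with Tukey HSD all-pairs comparisons.

    The omnibus F is the usual between/within mean-square ratio; pairwise
    p-values come from the studentized range with (k, N−k) parameters, with
    the Tukey–Kramer adjustment for unequal group sizes.
    """
    g = _as_groups(groups)
    if len(g) < 2:
        raise ValueError("need at least 2 groups")
    values = list(g.values())
    names = list(g)
    pooled = np.concatenate(values)
    grand = pooled.mean()
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in values)
    if ss_within == 0:
        raise ValueError("zero within-group variance everywhere: F undefined")
    f, p = sps.f_oneway(*values)
    omnibus = TestResult.make("anova", f, p, tuple(names))

    hsd = sps.tukey_hsd(*values)
    pairwise = [
        TestResult.make(
            "tukey_hsd", hsd.statistic[i, j], hsd.pvalue[i, j], (names[i], names[j])
        )
        for i, j in itertools.combinations(range(len(names)), 2)
    ]
    del grand
    return omnibus, pairwise


def results_frame(results: Sequence[TestResult]):
    """Tidy DataFrame of test results (method, groups, statistic, p, significant)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "method": r.method,
                "groups": "|".join(r.groups),
                "statistic": r.statistic,
                "p_value": r.p_value,
                "significant": r.significant,
            }
            for r in results
        ]
    )
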