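"""Occurrence-level VAF statistics by mutation category.

Trunk mutations arise before the most recent common ancestor of all cancer
cells, so their cancer-cell fraction is 1 in every region and their expected
VAF (0.5 x purity x CCF for heterozygous diploid loci) is the highest of the
three categories. This module groups occurrence VAFs by category and tests
trunk-vs-private and trunk-vs-branch differences with a two-sided Wilcoxon
rank-sum test, overall (pooled across regions) and per region.

The rank-sum test is implemented here: exact p-values by enumeration of the
null rank-sum distribution when the pooled sample is small (n1 + n2 <= 20) and
tie-free, otherwise a normal approximation with midranks, tie-corrected
variance and a continuity correction — the conventional defaults of R's
``wilcox.test``. A standard statistics library serves as an independent
cross-check in the test suite, never as the implementation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import ndtr
from scipy.stats import rankdata

from .classify import CategoryAssignment
from .model import CATEGORIES, CallSet


@dataclass
class VafGroup:
    """Occurrence VAFs of one category, with summary statistics."""

    category: str
    vafs: list[float]

    def __post_init__(self) -> None:
        for v in self.vafs:
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"VAF out of [0,1]: {v}")

    @property
    def n(self) -> int:
        return len(self.vafs)

    @property
    def mean(self) -> Optional[float]:
        return float(np.mean(self.vafs)) if self.vafs else None

    @property
    def min(self) -> Optional[float]:
        return min(self.vafs) if self.vafs else None

    @property
    def max(self) -> Optional[float]:
        return max(self.vafs) if self.vafs else None


def group_vafs(
    filtered: CallSet, a: CategoryAssignment, region: str = "ALL"
) -> list[VafGroup]:
    """One group per category, in (trunk, branch, private) order.

    For ``region="ALL"`` every occurrence contributes one VAF (a trunk site in
    R regions contributes up to R values); for a named region only that
    region's occurrences contribute. Records for sites without a category
    (e.g. functional classes outside the analysed matrix) are ignored.
    """
    vafs: dict[str, list[float]] = {c: [] for c in CATEGORIES}
    for site, obs in filtered.records:
        cat = a.categories.get(site.key)
        if cat is None:
            continue
        if region != "ALL" and obs.region != region:
            continue
        v = obs.tumor_vaf
        if v is not None:
            vafs[cat].append(v)
    return [VafGroup(category=c, vafs=vafs[c]) for c in CATEGORIES]


@dataclass(frozen=True)
class WilcoxonResult:
    """Two-sided rank-sum test result; ``statistic`` is the rank sum W of x."""

    statistic: float
    p_value: float
    method: str  # "exact" | "normal_approximation"
    n1: int
    n2: int
    degenerate: bool = False


def _exact_ranksum_sf_cdf(n1: int, n: int) -> np.ndarray:
    """Null distribution of the rank sum of n1 items out of ranks 1..n.

    Returns counts[s] = number of n1-subsets of {1..n} with rank sum s,
    computed by dynamic programming. Valid only for tie-free data.
    """
    max_sum = n * (n + 1) // 2
    # counts[k][s]
    counts = np.zeros((n1 + 1, max_sum + 1), dtype=np.float64)
    counts[0, 0] = 1.0
    for rank in range(1, n + 1):
        for k in range(min(n1, rank), 0, -1):
            counts[k, rank:] += counts[k - 1, : max_sum + 1 - rank]
    return counts[n1]


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> WilcoxonResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test of two samples."""
    x = list(map(float, x))
    y = list(map(float, y))
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be nonempty")
    n = n1 + n2
    pooled = np.asarray(x + y)
    ranks = rankdata(pooled)  # midranks for ties
    w = float(ranks[:n1].sum())
    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool((tie_counts > 1).any())

    if (tie_counts == n).all():  # every value identical across both groups
        return WilcoxonResult(
            statistic=w,
            p_value=1.0,
            method="normal_approximation",
            n1=n1,
            n2=n2,
            degenerate=True,
        )

    if n <= 20 and not has_ties:
        counts = _exact_ranksum_sf_cdf(n1, n)
        total = counts.sum()
        wi = int(round(w))
        p_le = counts[: wi + 1].sum() / total
        p_ge = counts[wi:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return WilcoxonResult(
            statistic=w, p_value=p, method="exact", n1=n1, n2=n2
        )

    mean = n1 * (n + 1) / 2.0
    tie_term = float(((tie_counts**3) - tie_counts).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return WilcoxonResult(
            statistic=w,
            p_value=1.0,
            method="normal_approximation",
            n1=n1,
            n2=n2,
            degenerate=True,
        )
    diff = w - mean
    # continuity correction toward the mean
    if diff > 0:
        diff -= 0.5
    elif diff < 0:
        diff += 0.5
    z = diff / math.sqrt(var)
    p = float(min(1.0, 2.0 * ndtr(-abs(z))))
    return WilcoxonResult(
        statistic=w, p_value=p, method="normal_approximation", n1=n1, n2=n2
    )


@dataclass
class RegionVafStats:
    """Group summaries and trunk-vs-other tests for one scope (region or ALL)."""

    scope: str
    groups: list[VafGroup]
    p_trunk_vs_private: Optional[WilcoxonResult]
    p_trunk_vs_branch: Optional[WilcoxonResult]
    ordering_ok: Optional[bool]  # trunk mean >= branch mean >= private mean

    def group(self, category: str) -> VafGroup:
        for g in self.groups:
            if g.category == category:
                return g
        raise KeyError(category)


@dataclass
class VafReport:
    overall: RegionVafStats
    per_region: dict[str, RegionVafStats] = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        rows = []
        for stats in [self.overall, *self.per_region.values()]:
            row = {"scope": stats.scope}
            for g in stats.groups:
                row[f"{g.category}_n"] = g.n
                row[f"{g.category}_mean_vaf"] = g.mean
            row["p_trunk_vs_private"] = (
                stats.p_trunk_vs_private.p_value if stats.p_trunk_vs_private else None
            )
            row["p_trunk_vs_branch"] = (
                stats.p_trunk_vs_branch.p_value if stats.p_trunk_vs_branch else None
            )
            row["ordering_trunk_ge_branch_ge_private"] = stats.ordering_ok
            rows.append(row)
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        def stats_dict(s: RegionVafStats) -> dict:
            return {
                "groups": {
                    g.category: {"n": g.n, "mean": g.mean, "min": g.min, "max": g.max}
                    for g in s.groups
                },
                "p_trunk_vs_private": (
                    s.p_trunk_vs_private.p_value if s.p_trunk_vs_private else None
                ),
                "p_trunk_vs_branch": (
                    s.p_trunk_vs_branch.p_value if s.p_trunk_vs_branch else None
                ),
                "ordering_trunk_ge_branch_ge_private": s.ordering_ok,
            }

        return {
            "overall": stats_dict(self.overall),
            "per_region": {r: stats_dict(s) for r, s in self.per_region.items()},
        }


def _stats_for(scope: str, groups: list[VafGroup]) -> RegionVafStats:
    by_cat = {g.category: g for g in groups}
    trunk, branch, private = by_cat["trunk"], by_cat["branch"], by_cat["private"]

    def test(other: VafGroup) -> Optional[WilcoxonResult]:
        if trunk.n == 0 or other.n == 0:
            return None
        return wilcoxon_rank_sum(trunk.vafs, other.vafs)

    means = [g.mean for g in (trunk, branch, private)]
    ordering = None
    if all(m is not None for m in means):
        ordering = means[0] >= means[1] >= means[2]
    return RegionVafStats(
        scope=scope,
        groups=groups,
        p_trunk_vs_private=test(private),
        p_trunk_vs_branch=test(branch),
        ordering_ok=ordering,
    )


def vaf_category_report(
    filtered: CallSet, a: CategoryAssignment, regions: Optional[list[str]] = None
) -> VafReport:
    """Overall and per-region VAF summaries with trunk-vs-other rank-sum tests.

    A region where trunk or the comparison category is empty gets ``None`` for
    that test (not applicable).
    """
    regions = regions if regions is not None else list(filtered.regions)
    overall = _stats_for("ALL", group_vafs(filtered, a, "ALL"))
    per_region = {
        r: _stats_for(r, group_vafs(filtered, a, r)) for r in regions
    }
    return VafReport(overall=overall, per_region=per_region)
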