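"""Biopsy-sufficiency statistic: trunk fraction of mutations shared by k regions.

For every subset of k regions, the *shared* sites are those present in every
member of the subset (column intersection of the presence matrix). The
statistic of interest is the fraction of those shared sites that are trunk
mutations: if it is high already at k = 2 or 3, a small number of biopsies
suffices to enrich for mutations carried by every cancer cell.

Two aggregates over the C(R, k) subsets are reported: the unweighted mean of
per-subset proportions (the headline, since subsets have unequal
denominators), and the pooled ratio sum(shared trunk) / sum(shared). Subsets
sharing zero sites are excluded from the mean and counted separately. Sharing
is site-level here: each shared site counts once per subset.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .classify import CategoryAssignment, PresenceMatrix
from .model import MutationSite


def shared_sites(m: PresenceMatrix, subset: Iterable[str]) -> list[MutationSite]:
    """Sites present in every region of ``subset`` (exact column intersection)."""
    subset = list(subset)
    if not subset:
        raise ValueError("subset must be nonempty")
    cols = [m.region_index(r) for r in subset]
    mask = m.values[:, cols].all(axis=1)
    return [s for s, keep in zip(m.sites, mask) if keep]


@dataclass(frozen=True)
class SubsetShare:
    members: tuple[str, ...]
    n_shared: int
    n_trunk: int

    @property
    def proportion(self) -> Optional[float]:
        return self.n_trunk / self.n_shared if self.n_shared else None


@dataclass
class SubsetSharingResult:
    """All size-k subsets with their shared/trunk counts and aggregates."""

    k: int
    per_subset: list[SubsetShare]
    mean_proportion: Optional[float]
    pooled_proportion: Optional[float]
    n_zero_shared: int
    sampled: bool = False  # True when Monte Carlo subsampling was used
    mean_std_error: Optional[float] = None


def _aggregate(k: int, shares: list[SubsetShare], sampled: bool) -> SubsetSharingResult:
    props = [s.proportion for s in shares if s.n_shared > 0]
    n_zero = sum(1 for s in shares if s.n_shared == 0)
    mean = sum(props) / len(props) if props else None
    tot_shared = sum(s.n_shared for s in shares)
    tot_trunk = sum(s.n_trunk for s in shares)
    pooled = tot_trunk / tot_shared if tot_shared else None
    se = None
    if sampled and len(props) > 1:
        se = float(np.std(props, ddof=1) / math.sqrt(len(props)))
    return SubsetSharingResult(
        k=k,
        per_subset=shares,
        mean_proportion=mean,
        pooled_proportion=pooled,
        n_zero_shared=n_zero,
        sampled=sampled,
        mean_std_error=se,
    )


def sharing_by_k(
    m: PresenceMatrix,
    a: CategoryAssignment,
    k: int,
    max_exact_regions: int = 20,
    n_samples: int = 2000,
    seed: int = 0,
) -> SubsetSharingResult:
    """Trunk fraction among sites shared by every size-k region subset.

    Enumerates all C(R, k) subsets exactly for R <= ``max_exact_regions``;
    beyond that, Monte Carlo subsampling with a fixed seed is used and a
    standard error reported. Exact enumeration is the default analysis mode.
    """
    R = m.n_regions
    if not 1 <= k <= R:
        raise ValueError(f"k must be in 1..{R}, got {k}")
    trunk = np.array([a[s.key] == "trunk" for s in m.sites], dtype=bool)

    def share_of(cols: tuple[int, ...]) -> SubsetShare:
        mask = m.values[:, list(cols)].all(axis=1)
        return SubsetShare(
            members=tuple(m.regions[c] for c in cols),
            n_shared=int(mask.sum()),
            n_trunk=int((mask & trunk).sum()),
        )

    if R <= max_exact_regions:
        shares = [share_of(c) for c in itertools.combinations(range(R), k)]
        return _aggregate(k, shares, sampled=False)
    rng = np.random.default_rng(seed)
    shares = []
    for _ in range(n_samples):
        cols = tuple(sorted(rng.choice(R, size=k, replace=False).tolist()))
        shares.append(share_of(cols))
    return _aggregate(k, shares, sampled=True)


def sufficiency_table(
    m: PresenceMatrix,
    a: CategoryAssignment,
    k_min: int = 1,
    k_max: Optional[int] = None,
    **kwargs,
) -> pd.DataFrame:
    """One row per subset size k with mean/pooled/min/max trunk proportions."""
    k_max = k_max if k_max is not None else m.n_regions
    if not 1 <= k_min <= k_max <= m.n_regions:
        raise ValueError(
            f"k range [{k_min}, {k_max}] not within 1..{m.n_regions}"
        )
    rows = []
    for k in range(k_min, k_max + 1):
        res = sharing_by_k(m, a, k, **kwargs)
        props = [s.proportion for s in res.per_subset if s.n_shared > 0]
        rows.append(
            {
                "k": k,
                "n_subsets": len(res.per_subset),
                "n_zero_shared": res.n_zero_shared,
                "mean_proportion": res.mean_proportion,
                "pooled_proportion": res.pooled_proportion,
                "min_proportion": min(props) if props else None,
                "max_proportion": max(props) if props else None,
            }
        )
    return pd.DataFrame(rows)
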