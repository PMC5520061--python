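"""Presence matrix construction and trunk/branch/private classification.

A site's *sharing level* is the number of regions in which it is present (the
row sum of the presence matrix). Classification is purely by sharing level:
present in all R regions -> trunk; in exactly one -> private; otherwise
branch. Both site-level and occurrence-level summaries are always produced,
because the two units answer different questions (an occurrence is one site in
one region, so a trunk site in six regions contributes six occurrences).

Presence means "a filtered call passed in that region"; there is no
cross-region rescue of borderline calls, so a true trunk mutation that fails
the filters in one region is observed as branch. Deep, uniform coverage is the
mitigation for this failure mode.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .model import CATEGORIES, NONSYNONYMOUS, CallSet, MutationSite

SiteKey = tuple[str, int, str, str]


@dataclass
class PresenceMatrix:
    """Boolean sites x regions matrix of filtered-call presence."""

    sites: list[MutationSite]
    regions: list[str]
    values: np.ndarray  # bool, shape (n_sites, n_regions)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.shape != (len(self.sites), len(self.regions)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.sites)} sites x {len(self.regions)} regions"
            )
        if len(self.regions) < 2:
            raise ValueError("presence matrix requires >= 2 regions")
        keys = [s.key for s in self.sites]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate sites in presence matrix")
        if len(self.sites) and not self.values.any(axis=1).all():
            raise ValueError("every site must be present in at least one region")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def row_sums(self) -> np.ndarray:
        """Sharing level per site."""
        return self.values.sum(axis=1)

    def region_index(self, region: str) -> int:
        try:
            return self.regions.index(region)
        except ValueError:
            raise KeyError(f"unknown region {region!r}; have {self.regions}") from None

    def site_keys(self) -> list[SiteKey]:
        return [s.key for s in self.sites]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.astype(int),
            index=[str(s) for s in self.sites],
            columns=self.regions,
        )


def build_presence_matrix(
    filtered: CallSet, func_classes: Iterable[str] = NONSYNONYMOUS
) -> PresenceMatrix:
    """One row per distinct site of the requested functional classes.

    Sites are ordered by site key; regions keep the callset's order. Raises if
    the callset covers fewer than two regions (classification is undefined).
    """
    if len(filtered.regions) < 2:
        raise ValueError(
            f"classification requires >= 2 regions, got {filtered.regions}"
        )
    wanted = frozenset(func_classes)
    by_key: dict[SiteKey, MutationSite] = {}
    present: dict[SiteKey, set[str]] = {}
    for site, obs in filtered.records:
        if site.func_class not in wanted:
            continue
        by_key.setdefault(site.key, site)
        present.setdefault(site.key, set()).add(obs.region)
    keys = sorted(by_key)
    values = np.zeros((len(keys), len(filtered.regions)), dtype=bool)
    col = {r: j for j, r in enumerate(filtered.regions)}
    for i, k in enumerate(keys):
        for r in present[k]:
            values[i, col[r]] = True
    return PresenceMatrix(
        sites=[by_key[k] for k in keys], regions=list(filtered.regions), values=values
    )


@dataclass
class CategoryAssignment:
    """Site key -> category ('trunk' | 'branch' | 'private')."""

    categories: dict[SiteKey, str]

    def __getitem__(self, key: SiteKey) -> str:
        return self.categories[key]

    def sites_in(self, category: str) -> list[SiteKey]:
        return [k for k, c in self.categories.items() if c == category]

    def to_frame(self, sites: Iterable[MutationSite] | None = None) -> pd.DataFrame:
        if sites is not None:
            rows = [
                {
                    "chrom": s.chrom,
                    "pos": s.pos,
                    "ref": s.ref,
                    "alt": s.alt,
                    "gene": s.gene or ".",
                    "category": self.categories[s.key],
                }
                for s in sorted(sites, key=lambda s: s.key)
            ]
            return pd.DataFrame(
                rows, columns=["chrom", "pos", "ref", "alt", "gene", "category"]
            )
        rows = [
            {"chrom": k[0], "pos": k[1], "ref": k[2], "alt": k[3], "category": c}
            for k, c in sorted(self.categories.items())
        ]
        return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "category"])


def classify_sites(m: PresenceMatrix) -> CategoryAssignment:
    """Trunk iff present in all regions, private iff in exactly one, else branch."""
    sums = m.row_sums()
    cats = {}
    for site, v in zip(m.sites, sums):
        if v == m.n_regions:
            cats[site.key] = "trunk"
        elif v == 1:
            cats[site.key] = "private"
        else:
            cats[site.key] = "branch"
    return CategoryAssignment(categories=cats)


@dataclass
class CompositionSummary:
    """Site- and occurrence-level category composition, overall and per region."""

    site_counts: dict[str, int]
    occurrence_counts: dict[str, int]
    occurrence_proportions: dict[str, float]
    per_region: dict[str, dict[str, dict[str, float]]]  # region -> cat -> {count, proportion}

    @property
    def n_sites(self) -> int:
        return sum(self.site_counts.values())

    @property
    def n_occurrences(self) -> int:
        return sum(self.occurrence_counts.values())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cat in CATEGORIES:
            rows.append(
                {
                    "scope": "overall",
                    "category": cat,
                    "site_count": self.site_counts[cat],
                    "occurrence_count": self.occurrence_counts[cat],
                    "occurrence_proportion": self.occurrence_proportions[cat],
                }
            )
        for region, cats in self.per_region.items():
            for cat in CATEGORIES:
                rows.append(
                    {
                        "scope": region,
                        "category": cat,
                        "site_count": cats[cat]["count"],
                        "occurrence_count": cats[cat]["count"],
                        "occurrence_proportion": cats[cat]["proportion"],
                    }
                )
        return pd.DataFrame(rows)


def summarize_composition(
    m: PresenceMatrix, a: CategoryAssignment
) -> CompositionSummary:
    """Count sites and occurrences by category; per-region proportions use the
    sites present in that region as the denominator."""
    sums = m.row_sums()
    site_counts = {c: 0 for c in CATEGORIES}
    occ_counts = {c: 0 for c in CATEGORIES}
    cats = np.array([a[s.key] for s in m.sites]) if m.n_sites else np.array([])
    for cat, v in zip(cats, sums):
        site_counts[cat] += 1
        occ_counts[cat] += int(v)
    total_occ = sum(occ_counts.values())
    occ_props = {
        c: (occ_counts[c] / total_occ if total_occ else float("nan"))
        for c in CATEGORIES
    }
    per_region: dict[str, dict[str, dict[str, float]]] = {}
    for j, region in enumerate(m.regions):
        mask = m.values[:, j]
        n_here = int(mask.sum())
        per_region[region] = {}
        for c in CATEGORIES:
            n_cat = int(((cats == c) & mask).sum()) if m.n_sites else 0
            per_region[region][c] = {
                "count": n_cat,
                "proportion": n_cat / n_here if n_here else float("nan"),
            }
    return CompositionSummary(
        site_counts=site_counts,
        occurrence_counts=occ_counts,
        occurrence_proportions=occ_props,
        per_region=per_region,
    )


@dataclass
class SharingSpectrum:
    """Per-region distribution over sharing levels 1..R.

    ``counts.loc[v, region]`` is the number of sites present in ``region``
    whose sharing level is ``v``; ``proportions`` normalizes each region's
    column to 1.
    """

    counts: pd.DataFrame
    proportions: pd.DataFrame


def sharing_spectrum(m: PresenceMatrix) -> SharingSpectrum:
    sums = m.row_sums()
    levels = range(1, m.n_regions + 1)
    counts = pd.DataFrame(0, index=list(levels), columns=m.regions)
    counts.index.name = "sharing_level"
    for j, region in enumerate(m.regions):
        here = sums[m.values[:, j]]
        for v in levels:
            counts.loc[v, region] = int((here == v).sum())
    totals = counts.sum(axis=0)
    proportions = counts / totals.replace(0, np.nan)
    return SharingSpectrum(counts=counts, proportions=proportions)


def gene_category_sets(
    a: CategoryAssignment, sites: Iterable[MutationSite]
) -> dict[str, list[str]]:
    """Sorted gene sets per category; a gene may appear in several categories.

    Sites with an empty gene symbol are excluded (a warning reports how many).
    """
    out: dict[str, set[str]] = {c: set() for c in CATEGORIES}
    n_empty = 0
    for site in sites:
        cat = a[site.key]
        if not site.gene:
            n_empty += 1
            continue
        out[cat].add(site.gene)
    if n_empty:
        warnings.warn(
            f"{n_empty} site(s) with empty gene symbol excluded from gene sets",
            stacklevel=2,
        )
    return {c: sorted(genes) for c, genes in out.items()}
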