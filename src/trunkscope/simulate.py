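"""Clonal-evolution simulator: ground-truth-labeled multiregion variant data.

The generative model is the standard clonal picture of a solid tumor: a
founding clone carries the trunk mutations; subclones arise on a tree, each
adding its own mutations; a biopsy region is a mixture of clones. A mutation's
cancer-cell fraction (CCF) in a region is the summed mixture fraction of the
clone it arose in plus all descendants, so CCF is monotone non-increasing down
the tree and trunk mutations have CCF 1 everywhere. Expected VAF for a
heterozygous diploid autosomal mutation is 0.5 x purity x CCF; copy-number
changes and LOH are deliberately out of scope (the main realism gap).

Read counts: tumor depth is rounded Normal(mean, sd) floored at 1 — Normal
rather than Poisson because real capture depth is overdispersed (sd 28 at mean
161 in the motivating six-region gastric case) — alt counts are Binomial at
the error-adjusted VAF, the matched normal is Poisson depth with
Binomial(error) alt reads. A record is emitted whenever at least one tumor alt
read exists; all realistic caller sensitivity behavior is delegated to the
downstream filters, which keeps the simulator analyzable.

Default parameters mirror the motivating case study's observed scale: 6
regions, 35 trunk sites, ~20 branch-clone sites, ~18 private sites per region,
161x mean depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .io import write_variant_tsv
from .model import CallSet, MutationSite, RegionObservation

_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class SimParams:
    """Simulation parameters; defaults mirror the six-region gastric WES case."""

    n_regions: int = 6
    n_trunk_sites: int = 35
    n_branch_clones: int = 4
    branch_mutations_per_clone: float = 5.0  # Poisson mean
    private_mutations_per_region: float = 18.0  # Poisson mean
    mean_depth: float = 161.0
    depth_dispersion: float = 28.0  # sd of the Normal depth model
    purity: Union[float, tuple] = 0.9
    normal_depth_mean: float = 100.0
    sequencing_error_rate: float = 0.0
    class_mixture: Mapping[str, float] = field(
        default_factory=lambda: {"nonsynonymous_snv": 1.0}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 1:
            raise ValueError("n_regions must be >= 1")
        for name in ("n_trunk_sites", "n_branch_clones"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for p in self.purities():
            if not 0.0 < p <= 1.0:
                raise ValueError("purity must be in (0, 1]")
        if not 0.0 <= self.sequencing_error_rate < 0.5:
            raise ValueError("sequencing_error_rate must be in [0, 0.5)")

    def purities(self) -> list[float]:
        if isinstance(self.purity, (int, float)):
            return [float(self.purity)] * self.n_regions
        p = list(self.purity)
        if len(p) != self.n_regions:
            raise ValueError("per-region purity length must equal n_regions")
        return [float(v) for v in p]


#: The defaults above as a named preset, for discoverability.
GASTRIC_WES_SCALE = SimParams()


@dataclass
class Clone:
    id: int
    parent: Optional[int]  # None for the founding clone
    regions: frozenset[str]
    mutations: list[MutationSite] = field(default_factory=list)
    private_region: Optional[str] = None


@dataclass
class CloneTree:
    """Clones with parent links, per-region mixture fractions, and mutations
    assigned to the edge above each clone (the root edge carries the trunk)."""

    clones: list[Clone]
    regions: list[str]
    fractions: dict[str, dict[int, float]]  # region -> clone id -> fraction

    def clone(self, cid: int) -> Clone:
        return self.clones[cid]

    def children(self, cid: int) -> list[int]:
        return [c.id for c in self.clones if c.parent == cid]

    def subtree_ids(self, cid: int) -> list[int]:
        out = [cid]
        for child in self.children(cid):
            out.extend(self.subtree_ids(child))
        return out

    def ccf(self, cid: int, region: str) -> float:
        """Fraction of cancer cells in ``region`` carrying clone ``cid``'s mutations."""
        fr = self.fractions[region]
        return sum(fr.get(k, 0.0) for k in self.subtree_ids(cid))

    def incidence_regions(self, cid: int) -> set[str]:
        return {r for r in self.regions if self.ccf(cid, r) > 0.0}

    def true_category(self, cid: int) -> str:
        inc = self.incidence_regions(cid)
        if len(inc) == len(self.regions):
            return "trunk"
        if len(inc) == 1:
            return "private"
        return "branch"

    def sites(self) -> list[tuple[MutationSite, int]]:
        """Every simulated site with its originating clone id."""
        return [(site, c.id) for c in self.clones for site in c.mutations]


def _draw_site(idx: int, rng: np.random.Generator, func_class: str) -> MutationSite:
    pos = (idx + 1) * 1000 + int(rng.integers(0, 1000))
    ref = _BASES[rng.integers(0, 4)]
    if func_class == "indel":
        alt = ref + _BASES[rng.integers(0, 4)]
    else:
        alt = _BASES[rng.integers(0, 4)]
        while alt == ref:
            alt = _BASES[rng.integers(0, 4)]
    return MutationSite(
        chrom="1",
        pos=pos,
        ref=ref,
        alt=alt,
        gene=f"GENE{idx + 1:04d}",
        func_class=func_class,
    )


def _draw_func_class(rng: np.random.Generator, mixture: Mapping[str, float]) -> str:
    classes = sorted(mixture)
    weights = np.array([mixture[c] for c in classes], dtype=float)
    weights = weights / weights.sum()
    return classes[rng.choice(len(classes), p=weights)]


def simulate_clone_tree(p: SimParams) -> CloneTree:
    """Sample the clone tree, region assignments, mutations and mixtures.

    Branch clones attach uniformly at random to an existing clone; their
    region sets (size 2..R-1, nested within a non-root parent's set) keep the
    incidence of every non-root mutation strictly below all-regions, so the
    "trunk iff founding-clone edge" labeling coincides with incidence. Each
    region also gets one region-confined leaf clone (its private mutations),
    attached to a random clone already present there. Mixture fractions per
    region are Dirichlet(1, ..., 1) over the clones present.
    """
    rng = np.random.default_rng(np.random.SeedSequence(p.seed).spawn(4)[0])
    regions = [f"R{i + 1}" for i in range(p.n_regions)]
    clones = [Clone(id=0, parent=None, regions=frozenset(regions))]
    site_idx = 0

    def add_mutations(clone: Clone, n: int) -> None:
        nonlocal site_idx
        for _ in range(n):
            fc = _draw_func_class(rng, p.class_mixture)
            clone.mutations.append(_draw_site(site_idx, rng, fc))
            site_idx += 1

    add_mutations(clones[0], p.n_trunk_sites)

    for _ in range(p.n_branch_clones):
        if p.n_regions < 3:
            break  # no region subset of size 2..R-1 exists
        parent = clones[int(rng.integers(0, len(clones)))]
        if parent.parent is None:
            pool = regions
        else:
            pool = sorted(parent.regions)
        max_size = min(len(pool), p.n_regions - 1)
        if max_size < 2:
            subset = frozenset(pool)
        else:
            size = int(rng.integers(2, max_size + 1))
            subset = frozenset(
                np.array(pool)[rng.choice(len(pool), size=size, replace=False)]
            )
        clone = Clone(id=len(clones), parent=parent.id, regions=subset)
        add_mutations(clone, int(rng.poisson(p.branch_mutations_per_clone)))
        clones.append(clone)

    for r in regions:
        eligible = [c for c in clones if r in c.regions]
        parent = eligible[int(rng.integers(0, len(eligible)))]
        clone = Clone(
            id=len(clones),
            parent=parent.id,
            regions=frozenset([r]),
            private_region=r,
        )
        add_mutations(clone, int(rng.poisson(p.private_mutations_per_region)))
        clones.append(clone)

    fractions: dict[str, dict[int, float]] = {}
    for r in regions:
        present = [c.id for c in clones if r in c.regions]
        fr = rng.dirichlet(np.ones(len(present)))
        fractions[r] = {cid: float(f) for cid, f in zip(present, fr)}
    return CloneTree(clones=clones, regions=regions, fractions=fractions)


@dataclass
class SyntheticDataset:
    """Simulated callset plus site-level truth and per-region CCF/VAF truth."""

    params: SimParams
    clone_tree: CloneTree
    callset: CallSet
    truth_sites: pd.DataFrame  # chrom pos ref alt gene func_class clone category
    truth_profiles: pd.DataFrame  # chrom pos ref alt region ccf true_vaf

    def true_categories(self) -> dict[tuple, str]:
        return {
            (r.chrom, r.pos, r.ref, r.alt): r.category
            for r in self.truth_sites.itertuples(index=False)
        }


def simulate_reads(tree: CloneTree, p: SimParams) -> SyntheticDataset:
    """Draw per-(site, region) read counts and emit the observed callset."""
    streams = np.random.SeedSequence(p.seed).spawn(4)
    rng = np.random.default_rng(streams[1])
    purities = dict(zip(tree.regions, p.purities()))
    e = p.sequencing_error_rate

    sites = tree.sites()
    truth_rows = []
    profile_rows = []
    records = []
    for site, cid in sites:
        category = tree.true_category(cid)
        truth_rows.append(
            {
                "chrom": site.chrom,
                "pos": site.pos,
                "ref": site.ref,
                "alt": site.alt,
                "gene": site.gene,
                "func_class": site.func_class,
                "clone": cid,
                "category": category,
            }
        )
        for region in tree.regions:
            ccf = tree.ccf(cid, region)
            vaf = 0.5 * purities[region] * ccf
            p_alt = vaf * (1.0 - e) + (1.0 - vaf) * e
            depth = max(1, int(round(rng.normal(p.mean_depth, p.depth_dispersion))))
            alt = int(rng.binomial(depth, p_alt))
            n_depth = int(rng.poisson(p.normal_depth_mean))
            n_alt = int(rng.binomial(n_depth, e)) if n_depth > 0 else 0
            profile_rows.append(
                {
                    "chrom": site.chrom,
                    "pos": site.pos,
                    "ref": site.ref,
                    "alt": site.alt,
                    "region": region,
                    "ccf": ccf,
                    "true_vaf": vaf,
                }
            )
            if alt >= 1:  # caller surrogate: any alt evidence yields a call
                records.append(
                    (
                        site,
                        RegionObservation(
                            region=region,
                            tumor_depth=depth,
                            tumor_alt=alt,
                            normal_depth=n_depth,
                            normal_alt=n_alt,
                        ),
                    )
                )
    callset = CallSet(regions=list(tree.regions), records=records)
    truth_sites = pd.DataFrame(
        truth_rows,
        columns=["chrom", "pos", "ref", "alt", "gene", "func_class", "clone", "category"],
    )
    truth_profiles = pd.DataFrame(
        profile_rows, columns=["chrom", "pos", "ref", "alt", "region", "ccf", "true_vaf"]
    )
    return SyntheticDataset(
        params=p,
        clone_tree=tree,
        callset=callset,
        truth_sites=truth_sites,
        truth_profiles=truth_profiles,
    )


def generate_dataset(
    p: SimParams, outdir: Optional[Union[str, Path]] = None
) -> SyntheticDataset:
    """Simulate tree + reads; optionally write variants/truth TSVs and params.

    Writing is deterministic: the same params (including seed) give
    byte-identical files.
    """
    tree = simulate_clone_tree(p)
    ds = simulate_reads(tree, p)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_variant_tsv(ds.callset, outdir / "variants.tsv")
        ds.truth_sites.to_csv(
            outdir / "truth_sites.tsv", sep="\t", index=False, lineterminator="\n"
        )
        ds.truth_profiles.to_csv(
            outdir / "truth_profiles.tsv", sep="\t", index=False, lineterminator="\n"
        )
        params = {
            k: (list(v) if isinstance(v, tuple) else dict(v) if isinstance(v, Mapping) else v)
            for k, v in vars(p).items()
        }
        with open(outdir / "params.yaml", "w") as fh:
            yaml.safe_dump(params, fh, sort_keys=True)
    return ds
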