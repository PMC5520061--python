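"""Core domain types for multiregion tumor-normal variant data.

A *site* is a unique somatic mutation identified by ``(chrom, pos, ref, alt)``;
an *occurrence* is a site observed in one tumor region. A site observed in all
six regions of a six-region tumor therefore contributes six occurrences. All
downstream statistics (classification, sharing, VAF grouping) are defined in
terms of these two units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

#: Recognised functional classes for a mutation site.
FUNC_CLASSES = frozenset(
    {"nonsynonymous_snv", "synonymous_snv", "stopgain", "indel", "other"}
)

#: Functional-class presets for building presence matrices.
NONSYNONYMOUS = frozenset({"nonsynonymous_snv"})
EXONIC = frozenset({"nonsynonymous_snv", "synonymous_snv", "stopgain", "indel"})
FUNC_CLASS_PRESETS = {"nonsynonymous": NONSYNONYMOUS, "exonic": EXONIC}

#: The three mutation categories, in the conventional reporting order.
CATEGORIES = ("trunk", "branch", "private")


@dataclass(frozen=True)
class MutationSite:
    """Identity and annotation of one somatic mutation.

    ``(chrom, pos, ref, alt)`` is the unique site key; ``gene`` may be empty
    and ``func_class`` must be one of :data:`FUNC_CLASSES`. Coordinates are
    1-based, VCF convention; indels are stored VCF-style (anchored ref/alt)
    and are never normalized here.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    func_class: str = "other"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt must differ at {self.chrom}:{self.pos}")
        if self.func_class not in FUNC_CLASSES:
            raise ValueError(
                f"unknown func_class {self.func_class!r}; expected one of "
                f"{sorted(FUNC_CLASSES)}"
            )
        length_change = len(self.ref) != len(self.alt)
        if length_change != (self.func_class == "indel"):
            raise ValueError(
                f"func_class {self.func_class!r} inconsistent with alleles "
                f"{self.ref}>{self.alt} at {self.chrom}:{self.pos}: "
                "length-changing variants must be 'indel' and vice versa"
            )

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass(frozen=True)
class RegionObservation:
    """Tumor and matched-normal read support for one site in one region.

    ``caller_filter`` is an optional pass-through of the upstream caller's
    FILTER value; ``None``, ``"PASS"`` and ``"."`` all mean "passed the
    caller". VAFs are always derived from the stored counts.
    """

    region: str
    tumor_depth: int
    tumor_alt: int
    normal_depth: int
    normal_alt: int
    caller_filter: Optional[str] = None

    def __post_init__(self) -> None:
        for name in ("tumor_depth", "tumor_alt", "normal_depth", "normal_alt"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool):
                raise ValueError(f"{name} must be an integer, got {v!r}")
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.tumor_alt > self.tumor_depth:
            raise ValueError(
                f"tumor_alt {self.tumor_alt} exceeds tumor_depth {self.tumor_depth}"
            )
        if self.normal_alt > self.normal_depth:
            raise ValueError(
                f"normal_alt {self.normal_alt} exceeds normal_depth {self.normal_depth}"
            )

    @property
    def tumor_vaf(self) -> Optional[float]:
        """Alt fraction in tumor reads; ``None`` when depth is zero."""
        if self.tumor_depth == 0:
            return None
        return self.tumor_alt / self.tumor_depth

    @property
    def normal_vaf(self) -> Optional[float]:
        if self.normal_depth == 0:
            return None
        return self.normal_alt / self.normal_depth

    @property
    def caller_passed(self) -> bool:
        return self.caller_filter in (None, "PASS", ".")


CallRecord = tuple[MutationSite, RegionObservation]


@dataclass
class CallSet:
    """A collection of per-region call records over an ordered region list.

    Region order is the order of first appearance and is preserved by every
    downstream stage (presence-matrix columns, reports). At most one record
    may exist per (site key, region) pair.
    """

    regions: list[str]
    records: list[CallRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.regions)) != len(self.regions):
            raise ValueError("duplicate region labels")
        region_set = set(self.regions)
        seen: set[tuple[tuple[str, int, str, str], str]] = set()
        for site, obs in self.records:
            if obs.region not in region_set:
                raise ValueError(
                    f"record region {obs.region!r} not in regions {self.regions}"
                )
            pair = (site.key, obs.region)
            if pair in seen:
                raise ValueError(f"duplicate record for site {site} in {obs.region}")
            seen.add(pair)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[CallRecord]:
        return iter(self.records)

    def sites(self) -> list[MutationSite]:
        """Distinct sites in site-key order (first annotation wins)."""
        by_key: dict[tuple, MutationSite] = {}
        for site, _ in self.records:
            by_key.setdefault(site.key, site)
        return [by_key[k] for k in sorted(by_key)]

    def sorted(self) -> "CallSet":
        """Canonical ordering: site key, then region in callset order."""
        order = {r: i for i, r in enumerate(self.regions)}
        recs = sorted(self.records, key=lambda t: (t[0].key, order[t[1].region]))
        return CallSet(regions=list(self.regions), records=recs)


def merge_callsets(callsets: list[CallSet]) -> CallSet:
    """Concatenate per-region callsets, preserving region first-appearance order."""
    regions: list[str] = []
    records: list[CallRecord] = []
    for cs in callsets:
        for r in cs.regions:
            if r not in regions:
                regions.append(r)
        records.extend(cs.records)
    return CallSet(regions=regions, records=records)
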