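"""Readers and writers for the package's external formats.

Supported formats: a minimal multi-sample VCF dialect (read-only, per-sample
AD/DP), the canonical tab-separated variant table (the exchange format every
stage and the simulator share), the 0/1 presence-matrix TSV, and Newick trees.

Conventions: tumor/normal depth is the sum of the AD entries rather than DP
(DP may include reads the caller discarded, and VAF denominators must match
the provenance of the alt counts); positions are 1-based throughout;
multi-allelic VCF lines are split into one record per alternate allele and
never re-merged.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import TYPE_CHECKING, Union

import pandas as pd
import pysam

from .model import FUNC_CLASSES, CallSet, MutationSite, RegionObservation

if TYPE_CHECKING:  # pragma: no cover
    from .classify import PresenceMatrix
    from .phylogeny import PhyloTree

PathLike = Union[str, Path]

#: Exact header of the canonical variant table.
VARIANT_TSV_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "func_class",
    "region",
    "tumor_depth",
    "tumor_alt",
    "normal_depth",
    "normal_alt",
]

_MATRIX_SITE_COLUMNS = ["chrom", "pos", "ref", "alt", "gene", "func_class"]


def _infer_func_class(ref: str, alt: str, annotated: str | None) -> str:
    if annotated:
        if annotated not in FUNC_CLASSES:
            raise ValueError(f"unknown func_class {annotated!r}")
        return annotated
    return "indel" if len(ref) != len(alt) else "other"


def read_vcf_minimal(
    path: PathLike,
    tumor_sample: str,
    normal_sample: str,
    region_label: str,
) -> CallSet:
    """Read one region's tumor-normal calls from a VCF with per-sample AD.

    One record is emitted per ALT allele per variant line; depth is the sum of
    the sample's AD entries. Optional ``GENE`` / ``FUNC_CLASS`` INFO fields
    populate the annotation; the FILTER column is carried through on
    ``caller_filter``.
    """
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    for name in (tumor_sample, normal_sample):
        if name not in samples:
            raise ValueError(
                f"sample {name!r} not found in {path}; available samples: {samples}"
            )
    if "AD" not in vf.header.formats:
        raise ValueError(f"{path} has no per-sample AD FORMAT field")

    records = []
    for line_no, rec in enumerate(vf, start=1):
        try:
            t_ad = rec.samples[tumor_sample].get("AD")
            n_ad = rec.samples[normal_sample].get("AD")
            if t_ad is None or n_ad is None or any(v is None for v in (*t_ad, *n_ad)):
                raise ValueError("missing AD values")
            alts = rec.alts or ()
            if len(t_ad) != len(alts) + 1 or len(n_ad) != len(alts) + 1:
                raise ValueError("AD length does not match allele count")
            filters = list(rec.filter.keys())
            caller_filter = ";".join(filters) if filters else None
            gene = rec.info.get("GENE", "") or ""
            annotated = rec.info.get("FUNC_CLASS", None)
            for i, alt in enumerate(alts):
                site = MutationSite(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=str(alt),
                    gene=str(gene),
                    func_class=_infer_func_class(rec.ref, str(alt), annotated),
                )
                obs = RegionObservation(
                    region=region_label,
                    tumor_depth=int(sum(t_ad)),
                    tumor_alt=int(t_ad[i + 1]),
                    normal_depth=int(sum(n_ad)),
                    normal_alt=int(n_ad[i + 1]),
                    caller_filter=caller_filter,
                )
                records.append((site, obs))
        except ValueError as exc:
            raise ValueError(f"{path}, variant record {line_no}: {exc}") from exc
    return CallSet(regions=[region_label], records=records)


def write_variant_tsv(callset: CallSet, path: PathLike) -> None:
    """Write the canonical variant table (rows sorted by site key then region)."""
    order = {r: i for i, r in enumerate(callset.regions)}
    recs = sorted(callset.records, key=lambda t: (t[0].key, order[t[1].region]))
    rows = [
        {
            "chrom": s.chrom,
            "pos": s.pos,
            "ref": s.ref,
            "alt": s.alt,
            "gene": s.gene or ".",
            "func_class": s.func_class,
            "region": o.region,
            "tumor_depth": o.tumor_depth,
            "tumor_alt": o.tumor_alt,
            "normal_depth": o.normal_depth,
            "normal_alt": o.normal_alt,
        }
        for s, o in recs
    ]
    df = pd.DataFrame(rows, columns=VARIANT_TSV_COLUMNS)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_variant_tsv(path: PathLike) -> CallSet:
    """Read the canonical variant table; strict header and integer counts."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns) != VARIANT_TSV_COLUMNS:
        raise ValueError(
            f"unexpected header in {path}: {list(df.columns)}; "
            f"expected {VARIANT_TSV_COLUMNS}"
        )
    regions: list[str] = []
    records = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        counts = {}
        for name in ("pos", "tumor_depth", "tumor_alt", "normal_depth", "normal_alt"):
            raw = getattr(row, name)
            try:
                counts[name] = int(raw)
            except ValueError as exc:
                raise ValueError(
                    f"{path} line {idx}: non-integer {name} value {raw!r}"
                ) from exc
        if row.func_class not in FUNC_CLASSES:
            raise ValueError(
                f"{path} line {idx}: unknown func_class {row.func_class!r}"
            )
        site = MutationSite(
            chrom=row.chrom,
            pos=counts["pos"],
            ref=row.ref,
            alt=row.alt,
            gene="" if row.gene == "." else row.gene,
            func_class=row.func_class,
        )
        obs = RegionObservation(
            region=row.region,
            tumor_depth=counts["tumor_depth"],
            tumor_alt=counts["tumor_alt"],
            normal_depth=counts["normal_depth"],
            normal_alt=counts["normal_alt"],
        )
        if row.region not in regions:
            regions.append(row.region)
        records.append((site, obs))
    return CallSet(regions=regions, records=records)


def write_presence_matrix_tsv(matrix: "PresenceMatrix", path: PathLike) -> None:
    """Serialize a presence matrix as 0/1 TSV, rows sorted by site key."""
    order = sorted(range(len(matrix.sites)), key=lambda i: matrix.sites[i].key)
    rows = []
    for i in order:
        s = matrix.sites[i]
        row = {
            "chrom": s.chrom,
            "pos": s.pos,
            "ref": s.ref,
            "alt": s.alt,
            "gene": s.gene or ".",
            "func_class": s.func_class,
        }
        for j, region in enumerate(matrix.regions):
            row[region] = int(matrix.values[i, j])
        rows.append(row)
    cols = _MATRIX_SITE_COLUMNS + list(matrix.regions)
    df = pd.DataFrame(rows, columns=cols)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_presence_matrix_tsv(path: PathLike) -> "PresenceMatrix":
    """Read a presence matrix TSV; any cell other than 0/1 is an error."""
    from .classify import PresenceMatrix  # local import to avoid a cycle

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns[: len(_MATRIX_SITE_COLUMNS)]) != _MATRIX_SITE_COLUMNS:
        raise ValueError(
            f"unexpected presence-matrix header in {path}: {list(df.columns)}"
        )
    regions = list(df.columns[len(_MATRIX_SITE_COLUMNS) :])
    sites = []
    values = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        sites.append(
            MutationSite(
                chrom=row.chrom,
                pos=int(row.pos),
                ref=row.ref,
                alt=row.alt,
                gene="" if row.gene == "." else row.gene,
                func_class=row.func_class,
            )
        )
        cells = []
        for region in regions:
            cell = getattr(row, region, None)
            if cell is None:  # pandas mangles non-identifier column names
                cell = df.iloc[idx - 2][region]
            if cell not in ("0", "1"):
                raise ValueError(
                    f"{path} line {idx}: presence cell must be 0 or 1, got {cell!r}"
                )
            cells.append(cell == "1")
        values.append(cells)
    import numpy as np

    arr = (
        np.asarray(values, dtype=bool)
        if values
        else np.zeros((0, len(regions)), dtype=bool)
    )
    return PresenceMatrix(sites=sites, regions=regions, values=arr)


def _format_branch_length(x: float) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        raise ValueError("branch length missing")
    return f"{x:.6g}"


def write_newick(tree: "PhyloTree") -> str:
    """Render a tree as a Newick string with 6-significant-digit lengths."""
    names = tree.leaf_names()
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate leaf labels in tree: {sorted(names)}")

    def render(node) -> str:
        if not node.children:
            label = node.name or ""
            if node.branch_length is None:
                return label
            return f"{label}:{_format_branch_length(node.branch_length)}"
        inner = ",".join(render(c) for c in node.children)
        label = node.name or ""
        if node.branch_length is None:
            return f"({inner}){label}"
        return f"({inner}){label}:{_format_branch_length(node.branch_length)}"

    root = tree.root
    if not root.children:
        return f"{root.name or ''};"
    return f"({','.join(render(c) for c in root.children)}){root.name or ''};"
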