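"""End-to-end analysis pipeline: filter -> classify -> share -> VAF -> tree.

``run_pipeline`` wires the stages over a config, writes every stage's table
plus a JSON summary of the headline statistics, and is deterministic given the
inputs and seed. Each stage's result is serialized exactly once, so the JSON
summary and the per-stage TSVs cannot disagree.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from . import io as tio
from .classify import (
    CategoryAssignment,
    CompositionSummary,
    PresenceMatrix,
    build_presence_matrix,
    classify_sites,
    sharing_spectrum,
    summarize_composition,
)
from .filters import FilterThresholds, RejectionReport, filter_callset
from .model import CATEGORIES, FUNC_CLASS_PRESETS, CallSet, merge_callsets
from .phylogeny import PhyloTree, region_tree
from .sharing import sufficiency_table
from .vaf_stats import VafReport, vaf_category_report

logger = logging.getLogger("trunkscope")


@dataclass
class VcfInput:
    path: str
    tumor_sample: str
    normal_sample: str
    region_label: str


@dataclass
class PipelineConfig:
    """Inputs, thresholds and options for one pipeline run."""

    variants_tsv: Optional[str] = None
    vcf_inputs: list[VcfInput] = field(default_factory=list)
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    func_class_preset: str = "nonsynonymous"  # matrix used for classification/VAF
    phylo_preset: str = "exonic"  # matrix used for the region tree
    k_min: int = 1
    k_max: Optional[int] = None  # default: number of regions
    distance_metric: str = "count"
    outdir: str = "trunkscope_out"
    seed: int = 0
    force: bool = False


def validate_config(cfg: PipelineConfig) -> list[str]:
    """Return a list of problems; empty iff the config is runnable."""
    problems = []
    if cfg.variants_tsv is None and not cfg.vcf_inputs:
        problems.append("no input: set variants_tsv or vcf_inputs")
    if cfg.variants_tsv is not None and not Path(cfg.variants_tsv).exists():
        problems.append(f"variants_tsv does not exist: {cfg.variants_tsv}")
    for v in cfg.vcf_inputs:
        if not Path(v.path).exists():
            problems.append(f"vcf input does not exist: {v.path}")
    for preset_field in ("func_class_preset", "phylo_preset"):
        preset = getattr(cfg, preset_field)
        if preset not in FUNC_CLASS_PRESETS:
            problems.append(
                f"{preset_field} must be one of {sorted(FUNC_CLASS_PRESETS)}, "
                f"got {preset!r}"
            )
    if cfg.k_min < 1:
        problems.append(f"k_min must be >= 1, got {cfg.k_min}")
    if cfg.k_max is not None and cfg.k_max < cfg.k_min:
        problems.append(f"k_max {cfg.k_max} is below k_min {cfg.k_min}")
    elif (
        cfg.k_max is not None
        and cfg.variants_tsv is not None
        and Path(cfg.variants_tsv).exists()
    ):
        try:  # cheap peek at the region count so k problems surface up front
            import pandas as pd

            n_regions = pd.read_csv(
                cfg.variants_tsv, sep="\t", usecols=["region"], dtype=str
            )["region"].nunique()
            if cfg.k_max > n_regions:
                problems.append(
                    f"k_max {cfg.k_max} exceeds the {n_regions} regions in "
                    f"{cfg.variants_tsv}"
                )
        except (ValueError, KeyError):
            pass  # header problems are reported by the reader at run time
    if cfg.distance_metric not in ("count", "pdist"):
        problems.append(f"distance_metric must be count|pdist, got {cfg.distance_metric!r}")
    return problems


@dataclass
class PipelineResult:
    callset: CallSet
    filtered: CallSet
    rejections: RejectionReport
    matrix: PresenceMatrix
    assignment: CategoryAssignment
    composition: CompositionSummary
    sufficiency: "object"
    vaf_report: VafReport
    tree: PhyloTree
    summary: dict


def _load_callset(cfg: PipelineConfig) -> CallSet:
    callsets = []
    if cfg.variants_tsv is not None:
        callsets.append(tio.read_variant_tsv(cfg.variants_tsv))
    for v in cfg.vcf_inputs:
        callsets.append(
            tio.read_vcf_minimal(
                v.path, v.tumor_sample, v.normal_sample, v.region_label
            )
        )
    return merge_callsets(callsets)


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Run every stage and write the report bundle to ``cfg.outdir``."""
    problems = validate_config(cfg)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    outdir = Path(cfg.outdir)
    if outdir.exists() and any(outdir.iterdir()) and not cfg.force:
        raise ValueError(
            f"output directory {outdir} is not empty; pass force=True to overwrite"
        )
    outdir.mkdir(parents=True, exist_ok=True)

    def stage(name):
        t0 = time.perf_counter()

        def done():
            logger.info("stage %s: %.2fs", name, time.perf_counter() - t0)

        return done

    done = stage("load")
    callset = _load_callset(cfg)
    if len(callset.regions) < 2:
        raise ValueError(
            f"pipeline requires >= 2 tumor regions, got {callset.regions}"
        )
    done()

    done = stage("filter")
    filtered, rejections = filter_callset(callset, cfg.thresholds)
    tio.write_variant_tsv(filtered, outdir / "filtered_variants.tsv")
    rejections.write_tsv(outdir / "rejections.tsv")
    done()

    done = stage("classify")
    matrix = build_presence_matrix(
        filtered, FUNC_CLASS_PRESETS[cfg.func_class_preset]
    )
    assignment = classify_sites(matrix)
    composition = summarize_composition(matrix, assignment)
    spectrum = sharing_spectrum(matrix)
    tio.write_presence_matrix_tsv(matrix, outdir / "presence_matrix.tsv")
    assignment.to_frame(matrix.sites).to_csv(
        outdir / "categories.tsv", sep="\t", index=False, lineterminator="\n"
    )
    composition.to_frame().to_csv(
        outdir / "composition.tsv", sep="\t", index=False, lineterminator="\n"
    )
    spectrum.proportions.to_csv(
        outdir / "sharing_spectrum.tsv", sep="\t", lineterminator="\n"
    )
    done()

    done = stage("subsets")
    k_max = cfg.k_max if cfg.k_max is not None else matrix.n_regions
    suff = sufficiency_table(matrix, assignment, cfg.k_min, k_max, seed=cfg.seed)
    suff.to_csv(outdir / "sufficiency.tsv", sep="\t", index=False, lineterminator="\n")
    done()

    done = stage("vafstats")
    vaf_report = vaf_category_report(filtered, assignment)
    vaf_report.to_frame().to_csv(
        outdir / "vaf_report.tsv", sep="\t", index=False, lineterminator="\n"
    )
    with open(outdir / "vaf_report.json", "w") as fh:
        json.dump(vaf_report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    done()

    done = stage("phylogeny")
    phylo_matrix = build_presence_matrix(
        filtered, FUNC_CLASS_PRESETS[cfg.phylo_preset]
    )
    tree = region_tree(phylo_matrix, metric=cfg.distance_metric)
    newick = tio.write_newick(tree)
    (outdir / "tree.nwk").write_text(newick + "\n")
    done()

    summary = {
        "n_regions": matrix.n_regions,
        "n_sites": matrix.n_sites,
        "n_occurrences": int(matrix.row_sums().sum()),
        "site_counts": {c: composition.site_counts[c] for c in CATEGORIES},
        "occurrence_counts": {
            c: composition.occurrence_counts[c] for c in CATEGORIES
        },
        "occurrence_proportions": {
            c: composition.occurrence_proportions[c] for c in CATEGORIES
        },
        "sufficiency": suff.to_dict(orient="records"),
        "vaf": vaf_report.to_dict(),
        "newick": newick,
        "seed": cfg.seed,
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return PipelineResult(
        callset=callset,
        filtered=filtered,
        rejections=rejections,
        matrix=matrix,
        assignment=assignment,
        composition=composition,
        sufficiency=suff,
        vaf_report=vaf_report,
        tree=tree,
        summary=summary,
    )
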