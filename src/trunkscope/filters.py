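"""Post-caller somatic filtering for SNVs and small indels.

Tumor-normal calls that survive the upstream caller's own filters are screened
with four depth/VAF rules per variant type. The defaults encode a stringent
screen for heterozygous somatic mutations at WES depths:

SNVs: (i) tumor depth >= 50, (ii) normal depth >= 30, (iii) tumor VAF >= 5%,
(iv) VAF in the matched normal exactly 0.

Indels: (i) tumor depth >= 10, (ii) normal depth >= 6, (iii) tumor VAF >= 5%
and at least 5 alt-supporting reads, (iv) normal VAF exactly 0.

Rule (iv) as an equality is implemented as ``normal_alt == 0`` when
``max_normal_vaf`` is 0 (the default); a nonzero ceiling is accepted for
sensitivity analyses. For indel rule (iii), "reads supporting a call" is read
as alt-supporting reads (not total depth). All failed rules are reported, not
just the first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .model import CallSet, RegionObservation


@dataclass(frozen=True)
class FilterThresholds:
    """Thresholds for the SNV and indel rule sets (defaults as in the module docstring)."""

    snv_min_tumor_depth: int = 50
    snv_min_normal_depth: int = 30
    min_tumor_vaf: float = 0.05
    max_normal_vaf: float = 0.0
    indel_min_tumor_depth: int = 10
    indel_min_normal_depth: int = 6
    indel_min_alt_reads: int = 5

    def __post_init__(self) -> None:
        for name in (
            "snv_min_tumor_depth",
            "snv_min_normal_depth",
            "indel_min_tumor_depth",
            "indel_min_normal_depth",
            "indel_min_alt_reads",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.min_tumor_vaf <= 1.0:
            raise ValueError("min_tumor_vaf must be in [0, 1]")
        if self.max_normal_vaf < 0:
            raise ValueError("max_normal_vaf must be >= 0")


SNV_RULES = ("snv_i", "snv_ii", "snv_iii", "snv_iv")
INDEL_RULES = ("indel_i", "indel_ii", "indel_iii", "indel_iv")
CALLER_RULE = "caller_filter"


@dataclass(frozen=True)
class FilterDecision:
    """Outcome of evaluating one observation; ``passed`` iff no rule failed."""

    passed: bool
    failed_rules: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.passed != (len(self.failed_rules) == 0):
            raise ValueError("passed must be True iff failed_rules is empty")


def _decide(failed: list[str]) -> FilterDecision:
    return FilterDecision(passed=not failed, failed_rules=tuple(failed))


def _normal_vaf_ok(obs: RegionObservation, max_normal_vaf: float) -> bool:
    # zero normal depth passes vacuously (alt must be 0); inadequate normal
    # coverage is rule (ii)'s job, and this keeps the rule monotone in the
    # ceiling. With the default ceiling of 0 this is exactly normal_alt == 0.
    if obs.normal_depth == 0:
        return obs.normal_alt == 0
    return obs.normal_alt / obs.normal_depth <= max_normal_vaf


def evaluate_snv(obs: RegionObservation, t: FilterThresholds) -> FilterDecision:
    """Apply SNV rules (i)-(iv); VAF rules are failures when not evaluable."""
    failed = []
    if obs.tumor_depth < t.snv_min_tumor_depth:
        failed.append("snv_i")
    if obs.normal_depth < t.snv_min_normal_depth:
        failed.append("snv_ii")
    vaf = obs.tumor_vaf
    if vaf is None or vaf < t.min_tumor_vaf:
        failed.append("snv_iii")
    if not _normal_vaf_ok(obs, t.max_normal_vaf):
        failed.append("snv_iv")
    return _decide(failed)


def evaluate_indel(obs: RegionObservation, t: FilterThresholds) -> FilterDecision:
    """Apply indel rules (i)-(iv)."""
    failed = []
    if obs.tumor_depth < t.indel_min_tumor_depth:
        failed.append("indel_i")
    if obs.normal_depth < t.indel_min_normal_depth:
        failed.append("indel_ii")
    vaf = obs.tumor_vaf
    if vaf is None or vaf < t.min_tumor_vaf or obs.tumor_alt < t.indel_min_alt_reads:
        failed.append("indel_iii")
    if not _normal_vaf_ok(obs, t.max_normal_vaf):
        failed.append("indel_iv")
    return _decide(failed)


@dataclass
class RejectionReport:
    """Per-region, per-rule rejection counts from :func:`filter_callset`."""

    counts: dict[str, dict[str, int]] = field(default_factory=dict)

    def add(self, region: str, rule: str) -> None:
        self.counts.setdefault(region, {})[rule] = (
            self.counts.get(region, {}).get(rule, 0) + 1
        )

    def total(self, rule: str | None = None) -> int:
        return sum(
            n
            for per_rule in self.counts.values()
            for r, n in per_rule.items()
            if rule is None or r == rule
        )

    def rule_totals(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for per_rule in self.counts.values():
            for rule, n in per_rule.items():
                out[rule] = out.get(rule, 0) + n
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"region": region, "rule": rule, "n_rejected": n}
            for region in sorted(self.counts)
            for rule, n in sorted(self.counts[region].items())
        ]
        return pd.DataFrame(rows, columns=["region", "rule", "n_rejected"])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, lineterminator="\n")


def filter_callset(
    calls: CallSet, t: FilterThresholds | None = None
) -> tuple[CallSet, RejectionReport]:
    """Keep passing records, preserving input order; count rejections per rule.

    Records whose ``caller_filter`` is set and not PASS are dropped before rule
    evaluation (counted under ``caller_filter``): the depth/VAF rules apply *in
    addition to* the upstream caller's own filters.
    """
    t = t or FilterThresholds()
    report = RejectionReport()
    kept = []
    for site, obs in calls.records:
        if not obs.caller_passed:
            report.add(obs.region, CALLER_RULE)
            continue
        decision = (
            evaluate_indel(obs, t) if site.is_indel else evaluate_snv(obs, t)
        )
        if decision.passed:
            kept.append((site, obs))
        else:
            for rule in decision.failed_rules:
                report.add(obs.region, rule)
    return CallSet(regions=list(calls.regions), records=kept), report
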