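# Methods

## Analysis model

The unit of identity is the mutation *site*, keyed by `(chrom, pos, ref,
alt)`; an *occurrence* is a site observed in one region, so a trunk site in a
six-region tumor contributes six occurrences. Both units are always reported:
per-region and headline percentages are occurrence-level (they weight a
mutation by how widely it is shared), while gene lists and recovery statistics
are site-level. Multi-allelic variants are distinct sites and are never
re-merged; indels stay in anchored VCF representation (no left-alignment or
normalization — annotation and normalization are upstream concerns).

### Somatic filtering

Calls that survived the upstream caller (a non-PASS `FILTER` value, when
present, drops a record before any rule runs) are screened per occurrence:

| rule | SNV | indel |
| --- | --- | --- |
| (i) tumor depth | ≥ 50 | ≥ 10 |
| (ii) normal depth | ≥ 30 | ≥ 6 |
| (iii) tumor VAF | ≥ 0.05 | ≥ 0.05 **and** alt reads ≥ 5 |
| (iv) normal VAF | = 0 | = 0 |

Depth is the sum of the sample's AD entries, not the DP field, so VAF
numerators and denominators share provenance. All thresholds are `≥`
(boundaries pass), and every failed rule is reported, not just the first.
Rule (iv) is the equality `normal_alt == 0` at the default ceiling of 0; a
positive ceiling is available for sensitivity analyses and is interpreted as
`normal_alt/normal_depth ≤ ceiling`, with zero normal depth passing vacuously
(insufficient normal coverage is rule (ii)'s job — this also keeps every rule
monotone in its threshold, which the property tests assert). For indel rule
(iii), "reads supporting the call" is taken to mean alt-supporting reads, not
total depth; total depth is already rule (i).

### Classification and presence

Presence of a site in a region means *a filtered call passed there*; there is
no cross-region rescue or force-calling. The documented consequence is a
censoring bias: a true trunk mutation that fails the filters in one region is
observed as branch, and a true branch mutation observed in one region becomes
private. Deep uniform coverage mitigates this, and the simulator quantifies it
(see below). Classification is by row sum of the presence matrix: R regions →
trunk, 1 → private, otherwise branch. The main analysis matrix uses
nonsynonymous SNVs only; the `exonic` preset (nonsynonymous + synonymous +
stopgain + indel) feeds the phylogeny and the exonic sharing pattern.

### Biopsy sufficiency (subset sharing)

For each of the C(R, k) subsets of k regions, the shared sites are the exact
intersection of the subset's presence columns, and the statistic is the trunk
fraction among them. Sharing is site-level: each shared site counts once per
subset. Two aggregates are computed, because subsets have unequal
denominators: the unweighted mean of per-subset proportions (headline) and the
pooled ratio Σtrunk/Σshared. Subsets sharing zero sites are excluded from the
mean and counted. Enumeration is exact up to 20 regions; beyond that a seeded
Monte Carlo mode with a reported standard error exists, but exact enumeration
is the only mode the tests and the acceptance script use.

### VAF statistics

Occurrence-level VAFs (`tumor_alt/tumor_depth`) are grouped by category,
pooled across regions for the overall test and restricted per region
otherwise. Group differences use a two-sided Wilcoxon rank-sum test
implemented in this package: when the pooled sample has ≤ 20 values and no
ties, the exact null distribution of the rank sum is built by dynamic
programming and the p-value is `min(1, 2·min(P(W≤w), P(W≥w)))`; otherwise a
normal approximation with midranks, tie-corrected variance and a continuity
correction is used — the conventional defaults of the standard R
implementation. Degenerate input (all values identical) returns p = 1 with a
flag. Two numerical caveats, both verified exhaustively and asserted in the
tests at the regime where they hold: the exact and approximate paths agree
within 0.01 absolute p at a pooled size of 20 only for near-balanced groups
(max gap 0.0086 at 10+10 but 0.114 at 1+19 — which is exactly why the exact
path exists), and on simulated data the full three-way mean ordering
trunk > branch > private holds in expectation but not in ~1 of 4 individual
replicates, because the branch mean averages over only a handful of subclones
(the tests assert trunk-mean dominance per replicate and the branch > private
ordering on across-replicate averages).

### Phylogeny

Each region's presence column is a binary profile; the matched germline is an
all-zero outgroup, valid because all characters are somatic. Distances are
absolute Hamming counts by default (integer-exact; the `pdist` option rescales
branch lengths but cannot change the topology). Neighbor joining is
implemented in-repo with the canonical Q criterion and branch-length formulas;
ties in Q break toward the lexicographically first pair under the current node
ordering, making output deterministic at the cost of matching any particular
external implementation's internal order. Negative pair branch lengths are
clamped to zero with the deficit moved to the sibling edge; the final 3-taxon
closed form clamps at zero. The root is placed at the midpoint of the
outgroup's pendant edge (placement on that edge is the only constraint the
outgroup argument provides; the midpoint is a symmetric convention). On
additive distances NJ recovers the generating topology and branch lengths
exactly; the test suite uses this consistency guarantee, plus an exhaustive
least-squares topology search at 4–5 taxa, as its oracle.

## The simulator

The generator encodes the standard clonal-evolution picture and the study
conditions the analysis assumes, with defaults at the motivating six-region
scale: a founding clone carrying 35 trunk mutations; 4 branch subclones, each
attached uniformly at random to an existing clone and carrying Poisson(5)
mutations; one region-confined leaf clone per region with Poisson(18) private
mutations; mean depth 161× with sd 28 (rounded Normal, floored at 1 — Normal
rather than Poisson because observed capture depth is overdispersed: sd 28 >
√161); purity 0.9; matched-normal depth Poisson(100).

Branch-clone region sets have size 2..R−1 and are nested inside a non-root
parent's set, so a clone's mutation incidence equals its own region set and
the label "trunk iff founding-clone edge" coincides with incidence-based
relabeling — an invariant the tests recompute from first principles. Region
mixtures are Dirichlet(1,…,1) over the clones present (the founding clone is
present everywhere); a mutation's CCF in a region is the summed fraction of
its clone's subtree, which makes CCF monotone non-increasing down the tree.

Reads: `tumor_alt ~ Binomial(depth, p)` with `p = vaf·(1−e) + (1−vaf)·e`,
`vaf = 0.5 · purity · CCF`, and `normal_alt ~ Binomial(Poisson(100), e)`;
`e = 0` by default. A record is emitted whenever at least one tumor alt read
exists — a deliberately permissive caller surrogate, so that *all* sensitivity
behavior is owned by the transparent filter rules rather than a simulated
caller. Randomness comes from substreams spawned off the master seed, so
generation is reproducible end to end and file output is byte-identical per
seed.

What the simulator does **not** model, hence what passing tests do not show
about real data: copy-number alterations and LOH (the 0.5 heterozygous-diploid
factor is fixed — the main realism gap), mutation signatures and positional
clustering, caller-specific artifacts, sample contamination, and FFPE/damage
noise. Sites are synthetic positions on one chromosome with one gene label per
site.

## Problem sizes and numerical choices

Test and acceptance workloads are sized for quick iteration: the brute-force
subset-sharing oracle runs on 200-site matrices at 4–8 regions; NJ consistency
uses random trees up to 8 taxa (1e−9 length tolerance); rank-sum enumeration
cross-checks pooled samples up to 12; parameter recovery uses 20 seeds at
500× (where every site whose minimum CCF over its carrying regions is ≥ 0.2
is classified identically to truth); null calibration uses 500 single-clone
replicates with permuted labels (KS uniformity at α = 0.01). The acceptance
script runs one default-scale simulation per invocation, fully determined by
`--seed`.

Degenerate inputs: zero tumor depth fails the depth rule and marks VAF rules
failed rather than raising; empty categories yield `n = 0` groups with missing
means and not-applicable tests; empty matrices serialize to header-only TSVs;
a single-leaf tree renders as `label;`. TSV and matrix writers are
deterministic (sorted rows, fixed line terminator), which the pipeline relies
on for byte-identical reruns.
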