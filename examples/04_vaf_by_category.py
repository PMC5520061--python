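"""VAF distributions by mutation category, with Wilcoxon rank-sum tests.

Trunk mutations are carried by every cancer cell (CCF = 1), so for
heterozygous diploid loci their expected VAF, 0.5 x purity x CCF, exceeds that
of branch and private mutations. The report pools occurrence-level VAFs and
tests trunk-vs-private (p1) and trunk-vs-branch (p2), overall and per region.
"""

import trunkscope as ts

ds = ts.generate_dataset(ts.SimParams(seed=7))
kept, _ = ts.filter_callset(ds.callset)
matrix = ts.build_presence_matrix(kept)
report = ts.vaf_category_report(kept, ts.classify_sites(matrix))

print("overall occurrence-level VAFs:")
for g in report.overall.groups:
    mean = f"{g.mean:.3f}" if g.mean is not None else "  NA "
    print(f"  {g.category:8s} n={g.n:4d} mean VAF {mean}")
p1 = report.overall.p_trunk_vs_private
p2 = report.overall.p_trunk_vs_branch
print(f"  trunk vs private: p = {p1.p_value:.3g} ({p1.method})")
print(f"  trunk vs branch:  p = {p2.p_value:.3g} ({p2.method})")

print("\nper region (trunk mean | private mean | p trunk-vs-private):")
for region, stats in report.per_region.items():
    t = stats.group("trunk").mean
    pr = stats.group("private").mean
    p = stats.p_trunk_vs_private
    p_str = f"{p.p_value:.2g}" if p else "NA"
    pr_str = f"{pr:.3f}" if pr is not None else "NA"
    print(f"  {region}: {t:.3f} | {pr_str} | {p_str}")
print("\nsmall p-values mean a single region's VAF spectrum already separates "
      "clonal from subclonal mutations at this depth and purity")
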