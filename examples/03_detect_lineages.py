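"""Detect faster- and slower-evolving lineages from root-to-tip rates.

Each order's rates are tested for unimodality (Hartigan dip, Monte-Carlo
p); orders that reject are split by 1-D DBSCAN, and the higher-rate
cluster is labelled the faster-evolving lineage (FEL).
"""

from orthodyn import (SimConfig, compute_coverage, filter_families,
                      root_to_tip_rates, simulate_all, split_lineages,
                      weighted_avg_size)

bundle = simulate_all(SimConfig(seed=1))
rates = root_to_tip_rates(bundle.tree)
coverage = compute_coverage(bundle.matrix, bundle.groups)
sizes = weighted_avg_size(bundle.matrix, "inv_max",
                          filter_families(coverage, 0.1))
split = split_lineages(rates, sizes, bundle.groups, alpha=0.05)

for order, g in sorted(split.groups.items()):
    tag = "SPLIT" if g.fel_tips else "     "
    print(f"{order}: dip p(rates) = {g.dip_p_rates:.4f}  {tag}"
          + (f"  fel={len(g.fel_tips)} sel={len(g.sel_tips)}"
             if g.fel_tips else ""))

truth = set(bundle.truth.fel_tips[bundle.config.fel_order])
found = set(split.groups[bundle.config.fel_order].fel_tips)
print(f"planted FEL tips recovered exactly: {found == truth}")
# Only the order carrying the planted rate shift rejects unimodality;
# its high-rate cluster coincides with the planted clade.
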