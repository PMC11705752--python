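"""Compare evolutionary conservation (phyloP-like scores) at C-of-CpG
positions against the surrounding region sequence.

phyloP is a signed -log10 p-value under neutral evolution: positive =
conserved, negative = accelerated.  dPhyloP subtracts each region's mean
score, removing between-region baselines before the group comparison.
"""

import promomethyl as pm
from promomethyl import fixtures
from promomethyl.simulate import simulate_conservation

sites = fixtures.study_site_table()
regions = fixtures.study_regions(sites)
cpgs = fixtures.cpg_positions_by_region(sites)

# simulated track with CpG scores depressed by 2 (score units ~ phyloP)
track = simulate_conservation(regions, cpgs, base_score_mean=0.5,
                              cpg_depression=2.0, seed=4)

comp = pm.conservation_compare(track, regions, cpgs)
print(f"raw scores:  W={comp['statistic_w']:.0f}, p={comp['p_value']:.3g} "
      f"({comp['n_cpg']} CpG vs {comp['n_other']} other positions)")

dp = pm.delta_phylop(track, regions, cpgs)
print(f"dPhyloP:     W={dp['statistic_w']:.0f}, p={dp['p_value']:.3g}")
print(f"mean dPhyloP at CpG positions: {dp['cpg_delta']['delta'].mean():.2f} "
      "(negative = CpGs less conserved than their regional context)")
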