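"""Correlate promoter CpG methylation with alternative first-exon
expression across the 19 cell-line samples.

Expression of each first exon is simulated with a negative coupling to the
mean methylation of its linked region, then the full site x target Spearman
family is tested with Benjamini-Hochberg FDR.
"""

import tempfile

import pandas as pd

import promomethyl as pm
from promomethyl import fixtures

with tempfile.TemporaryDirectory() as td:
    paths = fixtures.make_fixtures(td, seed=11, n_reads=60)
    sites = pm.read_site_table(paths["sites"])
    reads = pm.parse_read_calls(paths["reads"], sites)
    wide = pm.methylation_wide(pm.methylated_fraction(reads))
    expr = pd.read_csv(paths["expression"], sep="\t")

table = pm.methylation_expression_correlation(wide, expr, alpha=0.05)
print("strongest methylation-expression correlations (most negative rho):")
cols = ["site", "target", "rho", "n", "p_value", "fdr"]
print(table.sort_values("rho")[cols].head(8).to_string(index=False))
print(f"\nsites with p<0.05 for >=1 target: {table.attrs['n_sites_nominal']}")
print(f"sites significant after FDR:      {table.attrs['n_sites_fdr']}")
print("negative rho at linked regions reflects promoter silencing by "
      "methylation; the FDR column shows how much survives correction.")
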