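"""Simulate amplicon bisulfite reads from a subpopulation mixture and
recover per-site methylated fractions and epiallele pattern frequencies.

Each read reports the joint methylation state of every CpG in the region
(one DNA molecule = one epiallele), so pattern frequencies expose cellular
subpopulations that per-site averages cannot distinguish.
"""

import promomethyl as pm

# a region of 4 CpGs carried by three subpopulations: fully methylated
# (60%), fully unmethylated (30%) and an alternating mosaic (10%)
spec = pm.EpialleleMixtureSpec(
    region_id="region12",
    n_sites=4,
    patterns=[((1, 1, 1, 1), 0.6), ((0, 0, 0, 0), 0.3), ((1, 0, 1, 0), 0.1)],
    conversion_failure=0.02,  # unconverted C reads as methylated
    call_error=0.005,
    seed=1,
)
reads = pm.simulate_read_calls(spec, n_reads=5000, n_non_cpg=10_000)

fractions = pm.methylated_fraction(reads)
print("per-site methylated fractions (truth ~0.7 at odd sites, ~0.6 at even):")
print(fractions[["site_index", "fraction", "coverage"]].to_string(index=False))

patterns = pm.epiallele_patterns(reads, "region12", "S1")
print(f"\ntop epiallele patterns ({patterns.n_reads_used} reads used):")
print(patterns.table.head(5).to_string(index=False))

qc = pm.conversion_qc(reads)
print(f"\nbisulfite conversion QC: {qc['unconverted_pct'].iloc[0]:.2f}% "
      "unconverted non-CpG C (simulated truth 2%)")
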