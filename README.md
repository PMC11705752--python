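# promomethyl

Analysis of alternative-promoter CpG methylation and first-exon usage for
the oestrogen receptor gene *ESR1* in breast cancer models.

Endocrine-therapy resistance in ER-positive breast cancer is often
accompanied by changed ER expression, and *ESR1* transcription starts from
several alternative first exons (promA–promF) whose promoters can be
silenced by CpG methylation. `promomethyl` provides the computational
toolchain for studying this: it quantifies per-CpG methylation and
read-level epiallele patterns from amplicon bisulfite sequencing, relates
methylation to first-exon expression, compares CpG conservation against
expression-matched background regions, and stratifies tumour cohorts by
relative first-exon usage for survival analysis. A synthetic-data layer
generates inputs with the statistical structure each stage assumes, so the
whole pipeline is testable without access to patient data.

## What it computes

- **Methylation** — per-site methylated-read fraction
  m = #M / (#M + #U) with coverage, from native per-read call TSVs or
  bismark-style CpG-context output; bisulfite conversion QC from non-CpG
  cytosine tallies.
- **Epialleles** — per-read methylation patterns (one read = one DNA
  molecule), their frequencies per region and sample, and a
  parental-vs-derived classification of patterns as pre-existing or novel.
- **Correlation** — methylation deltas between sublines and parental
  lines; site × site and site × expression Spearman correlation (exact
  permutation p for n ≤ 9, t approximation otherwise) with
  Benjamini–Hochberg FDR over the full family.
- **Conservation** — Wilcoxon rank-sum comparison of phyloP scores at
  C-of-CpG positions vs surrounding region positions, raw and as ΔphyloP
  (score minus regional mean); construction of expression-matched
  background region sets (IQR gene selection, ±750 bp exon padding, CDS
  masking, >400 bp / ≥4 CpG filters).
- **Cohorts** — relative first-exon usage fractions (≥10-read filter),
  Ward clustering of usage profiles, low/high stratification,
  Kaplan–Meier curves, log-rank tests and Cox proportional-hazards
  regression (Efron ties).

See `docs/methods.md` for models, conventions and parameter defaults.

## Worked example

`examples/05_cohort_survival.py` simulates a 600-tumour cohort with five
first-exon usage clusters and cluster-dependent hazards, then runs the
cohort analysis end to end:

```text
600 tumours retained (0 below the 10-read filter)
cluster sizes: {1: 237, 2: 95, 3: 103, 4: 51, 5: 114}
silhouette: 0.60

log-rank (promA usage > 0.5 vs <= 0.5, OS): chi2=42.42, p=7.37e-11
Cox HR for high promA usage: 0.52 [0.42, 0.63], p=1.48e-10
```

The Ward clustering recovers the five simulated usage profiles; the
log-rank test and the Cox hazard ratio of 0.52 show that tumours dominated
by the main promoter (promA fraction > 0.5) have roughly half the event
hazard of the rest, matching the lower hazard assigned to the
promA-dominant cluster in the simulation.

The other examples cover epiallele pattern recovery and conversion QC
(`01`), methylation–expression correlation with FDR (`02`), differential
methylation between resistant sublines and parental lines (`03`), and the
conservation comparison (`04`). Each prints the numbers it computes and a
line on what they mean.

A command-line interface wraps the same functions for shell use:

```sh
promomethyl fixtures --out demo --seed 1     # synthetic study-scale dataset
promomethyl run --config demo/config.yaml    # full pipeline, manifest + sidecars
promomethyl tfbs --sites demo/sites.tsv --tfbs demo/tfbs.bed --out tfbs.tsv
```

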