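# Methods

`promomethyl` implements the computational core of an alternative-promoter
methylation study: quantifying CpG methylation from amplicon bisulfite
sequencing reads, relating it to alternative first-exon expression of the
oestrogen receptor gene *ESR1*, assessing evolutionary conservation of the
assayed CpGs, and stratifying tumour cohorts by relative first-exon usage.
This note records the models, conventions and parameter choices; every
number quoted here is computed by the test suite or `scripts/acceptance.py`.

## Methylation quantification

A CpG site is addressed by the 1-based genomic position of the C on the
forward strand. Calls observed on the bottom strand (the G position of the
symmetric CpG) are mapped back to the forward-strand C during parsing of
bismark-style CpG-context files (`Z` → methylated, `z` → unmethylated, site
absent from a read → `N`). The native call format is a four-column TSV of
(sample, region, read, call string), one character per region CpG in
coordinate order.

The per-site methylated fraction is m = #M / (#M + #U); `N` calls enter
neither numerator nor denominator. Sites below a coverage floor
(`min_coverage`, default 1) are reported as missing rather than zero.
Conversion QC is the percentage of unconverted cytosines among non-CpG
(CHG/CHH) contexts, where complete conversion is expected; a missing tally
raises an explicit "QC unavailable" error rather than reporting 0%.

## Epiallele pattern analysis

Each sequencing read derives from one DNA molecule, so the joint call
string over all CpGs of a region is an epiallele. Pattern frequencies are
computed over reads with no `N` call: amplicon reads should span the whole
region, and partial reads would inflate the pattern alphabet with
artefactual wildcards. Excluded reads are counted and reported. Reported
tables keep the union of the `top_k` (default 10) most frequent patterns
and all patterns at frequency ≥ `min_frequency` (default 0.01), with count
ties broken lexicographically; truncation is presentational only — all
downstream computation uses full counts, and a consistency check verifies
that per-site fractions recomputed from full pattern counts equal the
read-level estimator on `N`-free data.

Pattern sharing between a parental line and a derived subline classifies
each derived pattern as *pre-existing* (parental frequency ≥
`presence_threshold`, default 0.01) or *novel*, and reports the fraction of
derived reads carried by pre-existing patterns. Values near 1 are
consistent with selection on standing epigenetic subpopulations rather
than de novo (de)methylation.

## Correlation analyses

Spearman correlation is used throughout, with mid-ranks for ties. Two-sided
p-values are exact (full enumeration of rank permutations) for n ≤ 9 and
use the t approximation for larger n; with 19 samples the study-scale
analyses sit in the asymptotic regime. The t approximation is floored at
the smallest positive normal float so that degenerate |rho| = 1 pairs stay
inside the (0, 1] domain of the FDR step.

Methylation–expression testing runs every CpG site against every
expression target over shared samples with pairwise-complete deletion
(pairs with fewer than 4 complete samples, or a constant vector, are
skipped and logged). Benjamini–Hochberg adjustment is applied over the full
site × target family, not per target, because the study-level conclusion is
a single corrected statement across the family. The summary reports the
number of sites with p < α for at least one target and the number with
FDR < α for at least one target (α default 0.05).

Expression normalisation divides each target quantity by the sample's ACTB
quantity and multiplies by 10 000 for first exons (promA–promF) or 100 for
the 3′ UTR. The scales are plotting conveniences; a test confirms they
leave all rank statistics unchanged.

Differential methylation is the per-site difference in methylated fraction,
subline minus parental (positive = gain in the subline), missing whenever
either fraction is missing.

## Conservation analysis

Conservation uses phyloP-style scores: signed −log10 p-values under a
neutral-evolution null (positive = conserved, negative = accelerated).
Tracks are read from bedGraph (0-based half-open) or wig (1-based) and
held as 1-based per-position records. The core comparison is a two-sided
Wilcoxon rank-sum test of scores at C-of-CpG positions versus all other
positions of the assayed regions, pooled across regions by default (a
stratified per-region mode is provided). The test is exact for combined
n ≤ 10 without ties, and otherwise uses the normal approximation with tie
and continuity corrections. ΔphyloP subtracts each region's mean score
before the same comparison, removing between-region baselines; by
construction ΔphyloP averages to zero over each region's positions (tested
to 1e−9).

The expression-matched background builder selects protein-coding genes
whose mean expression falls inside the target gene's interquartile range
(quartiles by linear interpolation, range inclusive), pads their first
exons by ±750 bp, merges overlapping padded exons of the same gene,
subtracts all protein-coding (CDS) intervals, and keeps fragments strictly
longer than 400 bp containing at least four CpGs. "Longer than" is strict
and "at least" inclusive, taken verbatim from the procedure being
reproduced. Interval merge/subtract are implemented directly (ordinary 1-D
sweep) and property-tested against a per-base set-arithmetic oracle.

A 1-based position p lies in a 0-based half-open interval [s, e) iff
s < p ≤ e; the overlap annotator follows this conversion exactly and is
property-tested against a quadratic all-pairs scan.

## Cohort analysis

Relative first-exon usage is the fraction of a tumour's first-exon reads on
each annotated first exon; tumours with fewer than `min_reads` (default 10,
inclusive at the threshold) total first-exon reads are excluded. Fraction
profiles are clustered hierarchically (Ward linkage, Euclidean distance,
cut at k = 5 by default, matching the five-cluster structure of breast
tumour first-exon usage; method and k are configurable, and a seeded
k-means alternative exists). A silhouette score is attached as a cohesion
diagnostic.

Stratification labels a tumour *high* iff its fraction on the chosen exon
strictly exceeds the cutoff. Cutoffs are required inputs: reference strata
boundaries for this analysis exist only graphically, so a quantile helper
is provided for exploration but no default cutoff claims to reproduce any
particular grouping.

Survival uses lifelines: Kaplan–Meier product-limit curves per group, the
log-rank test across groups (verified against a hand-worked six-subject
example), and Cox proportional-hazards regression with Efron tie handling
(verified against direct grid maximisation of the partial likelihood to
1e−4). Tumour size enters Cox models dichotomised at 20 mm. Endpoint
columns (OS/RFI/DRFI) are taken as inputs; deriving endpoints from event
hierarchies is out of scope. All-censored inputs raise an explicit error.

## Synthetic data

The generators produce inputs with the statistical structure the analysis
assumes, not realistic sequence artefacts:

- **Reads**: each read draws an epiallele from a mixture of binary
  patterns; unmethylated sites flip to M with probability
  `conversion_failure` (bisulfite chemistry only fails in the U→M
  direction; incomplete methylation protection is folded into the
  symmetric `call_error`); then every call flips with probability
  `call_error`. Defaults used by the study-scale fixture set:
  conversion failure 0.02 (a realistic post-QC conversion rate),
  call error 0.005, 19 samples × 12 regions × 108 sites.
- **Expression**: log-expression = baseline + sign·strength·(mean linked
  methylation) + Gaussian noise; the fixture couplings are negative with
  strength 4 and noise SD 0.3 on the log scale, strong enough that the
  correlation structure is recoverable from 19 samples.
- **Conservation**: per-base scores Normal(mean, 1) with C-of-CpG
  positions shifted by −`cpg_depression` (fixture default 2, i.e. a
  2-SD depression).
- **Cohorts**: cluster labels by mixture weight; total first-exon depth
  Poisson (fixture mean 60); per-exon counts multinomial on the cluster
  profile; event and censoring times independent exponentials with
  cluster-specific event hazards, so proportional hazards hold exactly
  and Cox recovery is well-posed.

Each generator draws from a single `numpy.random.default_rng` stream seeded
from its spec, so fixed seeds reproduce outputs byte-identically.

What the generators do *not* emulate: PCR duplicates, read-quality decay,
alignment artefacts, fragment-length effects, correlated noise between
sites beyond the shared pattern structure, non-proportional hazards, and
informative censoring. Tests passing on synthetic data therefore establish
correctness of the estimators and procedures under their stated
assumptions, not robustness to those real-data complications.

## Synthetic summary-table stand-ins

The reference summary tables this analysis is usually run against cannot
be shipped, so the fixture layer fabricates *labelled synthetic* stand-ins
at the study scale: a
site table of 108 CpGs in 12 regions (including CpGs at chr6:151764484 and
chr6:151764506), a TFBS interval set constructed so exactly 41 sites have
at least one overlap, and a per-pair correlation table in which 58 sites
carry one nominally significant p-value (drawn strictly between 0.3·α and
0.9·α, far above the BH step-up line for a 756-test family, so none
survive FDR). These exercise the real parsing, overlap and counting code
paths; the constructed counts are design targets of the stand-ins, not
measurements.

## Numerical and design choices

- Spearman exact/approximate crossover at n = 9; Wilcoxon exact crossover
  at combined n = 10 without ties.
- BH adjustment delegates to `statsmodels.stats.multitest.multipletests`
  behind the package's validated surface (domain check: p ∈ (0, 1]).
- Pairwise-complete deletion everywhere correlations meet missing values;
  zero-variance vectors yield "undefined" (NaN), never 0.
- Problem sizes in tests and the acceptance script (10⁵ reads for mixture
  recovery, 2000 tumours for hazard-ratio recovery, 1000 seeds for type-I
  calibration, 150-tumour × 20-seed clustering sweeps) were chosen as the
  smallest sizes at which the binomial/asymptotic error bounds quoted in
  each check are meaningful.
- The pipeline writes a provenance sidecar (config hash, seed, package
  version) next to every output and a checksum manifest per run; reruns
  with identical config and inputs are byte-identical.

## Known limitations

- Exact Spearman enumeration is O(n!) and is intentionally capped at n = 9.
- The per-position conservation representation is a plain long table;
  whole-genome tracks would need a block representation (regions here span
  a few kilobases).
- Hemimethylation is invisible: bottom-strand calls are folded into the
  symmetric CpG.
- The cohort module takes endpoint columns and clinical covariates as
  given; no proportional-hazards diagnostics beyond convergence checks are
  run.
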