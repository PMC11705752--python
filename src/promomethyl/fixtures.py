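"""Study-scale synthetic fixtures (all data here is synthetic).

This module fabricates a complete, small input set mirroring the *shape* of
the ESR1 alternative-promoter study: 108 CpG sites in 12 amplicon regions
inside the ESR1 locus on chr6, 19 cell-line samples (six parental lines with
fulvestrant-resistant and withdrawal sublines), expression of first exons
promA-promF plus the 3' UTR, a TFBS interval set, per-base conservation
tracks, and a clustered tumour cohort with survival endpoints.

Nothing here is measured data: every table is generated from seeded
mixtures/couplings defined below, including the *synthetic stand-ins* for
study-style summary tables (site list with TFBS overlaps; per-pair
correlation p-values).  The stand-ins reproduce only the summary structure
— counts of sites, of TFBS-overlapping sites, and of nominally-significant
sites with none surviving FDR — so the package's counting rules can be
exercised end to end without controlled-access data.
"""

from __future__ import annotations

import itertools
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation, simulate
from .methylation import ReadCallSet, methylated_fraction, methylation_wide
from .sites import make_site_table, write_site_table

REGION_LENGTH = 400

# region start coordinates (0-based) inside the ESR1 locus span on chr6;
# region 6 is placed so that the CTCF-adjacent sites chr6:151764484 and
# chr6:151764506 fall on simulated CpGs
_REGION_STARTS = {
    "region01": 151_658_050,
    "region02": 151_658_900,
    "region03": 151_660_000,
    "region04": 151_692_000,
    "region05": 151_740_000,
    "region06": 151_764_300,
    "region07": 151_806_000,
    "region08": 151_842_000,
    "region09": 151_848_000,
    "region10": 151_871_000,
    "region11": 151_879_000,
    "region12": 151_883_000,
}

# CpG sites per region; sums to 108
_REGION_N_SITES = {
    "region01": 7, "region02": 9, "region03": 8, "region04": 10,
    "region05": 9, "region06": 12, "region07": 9, "region08": 8,
    "region09": 11, "region10": 9, "region11": 8, "region12": 8,
}

_REGION6_OFFSETS = [30, 60, 95, 130, 155, 184, 206, 240, 270, 300, 335, 365]

CELL_LINES = ["CAMA1", "EFM19", "HCC1428", "MCF7", "T47D", "ZR751"]

#: the 19 samples: P/FR/FR-F per line, plus a second CAMA-1 withdrawal point
SAMPLES = [
    "CAMA1_P", "CAMA1_FR", "CAMA1_FRF_w9", "CAMA1_FRF_w17",
    "EFM19_P", "EFM19_FR", "EFM19_FRF",
    "HCC1428_P", "HCC1428_FR", "HCC1428_FRF",
    "MCF7_P", "MCF7_FR", "MCF7_FRF",
    "T47D_P", "T47D_FR", "T47D_FRF",
    "ZR751_P", "ZR751_FR", "ZR751_FRF",
]

FR_PAIRS = [(f"{cl}_FR", f"{cl}_P") for cl in CELL_LINES]

EXONS = ["promA", "promB", "promC", "promD", "promE", "promF"]
TARGETS = EXONS + ["UTR3"]

#: which region's methylation drives each expression target (negative coupling)
TARGET_REGION = {
    "promA": "region10", "promB": "region10", "promC": "region09",
    "promD": "region07", "promE": "region02", "promF": "region05",
    "UTR3": "region06",
}

_TF_NAMES = ["GATA3", "CTCF", "TFAP2C", "ESR1", "JUND", "MYC", "RUNX1", "NR3C1"]


def study_site_table() -> pd.DataFrame:
    """The synthetic 108-site / 12-region CpG table."""
    records = []
    for region, start in _REGION_STARTS.items():
        n = _REGION_N_SITES[region]
        if region == "region06":
            offsets = _REGION6_OFFSETS
        else:
            offsets = np.round(np.linspace(30, 370, n)).astype(int)
        for off in offsets:
            records.append(("chr6", start + int(off), region))
    return make_site_table(records)


def study_regions(sites: pd.DataFrame) -> pd.DataFrame:
    """Amplicon region intervals (0-based half-open) for the site table."""
    rows = [
        (sites.loc[sites["region_id"] == rid, "chrom"].iloc[0], start,
         start + REGION_LENGTH, rid)
        for rid, start in _REGION_STARTS.items()
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "region_id"])


def cpg_positions_by_region(sites: pd.DataFrame) -> dict:
    return {
        rid: g["pos"].tolist() for rid, g in sites.groupby("region_id")
    }


def synthetic_tfbs(sites: pd.DataFrame, n_overlapping: int = 41, seed: int = 0) -> pd.DataFrame:
    """Synthetic TFBS interval set overlapping exactly ``n_overlapping`` sites.

    A stand-in for a UniBind-style robust TFBS collection: intervals of
    ~11 bp are centred on a seeded choice of CpG sites (site spacing in the
    synthetic table guarantees each interval covers exactly one site), with
    decoy intervals between regions that cover no site.
    """
    rng = np.random.default_rng(seed)
    chosen = np.sort(
        rng.choice(len(sites), size=n_overlapping, replace=False)
    )
    tf_cycle = itertools.cycle(_TF_NAMES)
    rows = []
    for i in chosen:
        s = sites.iloc[i]
        rows.append(
            (s["chrom"], s["pos"] - 6, s["pos"] + 5, next(tf_cycle), 0, "+",
             "breast")
        )
    # decoys in the gaps between regions
    for start in (151_659_600, 151_700_000, 151_820_000):
        rows.append(("chr6", start, start + 15, next(tf_cycle), 0, "+", "HepG2"))
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "name", "score", "strand", "cell_type"],
    )


def synthetic_correlation_pvalues(
    sites: pd.DataFrame,
    targets: list = TARGETS,
    n_significant_sites: int = 58,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic per-pair correlation table (site x target rho, p).

    Stand-in for a reference per-pair Spearman table: a seeded choice of
    ``n_significant_sites`` sites receives one target with p in
    (0.3*alpha, 0.9*alpha) — nominally significant but far above the BH
    step-up line for a family of this size, so nothing survives FDR — and
    every other pair draws p from (2*alpha, 1).
    """
    rng = np.random.default_rng(seed)
    sig_sites = set(rng.choice(len(sites), size=n_significant_sites, replace=False))
    rows = []
    for i, s in enumerate(sites.itertuples()):
        sig_target = rng.integers(len(targets)) if i in sig_sites else -1
        for j, t in enumerate(targets):
            if j == sig_target:
                p = rng.uniform(0.3 * alpha, 0.9 * alpha)
                rho = -rng.uniform(0.5, 0.8)
            else:
                p = rng.uniform(2 * alpha, 1.0)
                rho = rng.uniform(-0.4, 0.4)
            rows.append((s.chrom, s.pos, s.region_id, t, rho, p))
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "region_id", "target", "rho", "p_value"]
    )


def _dirichlet(rng, alpha):
    return rng.dirichlet(np.asarray(alpha, dtype=float))


def study_mixture_specs(
    sites: pd.DataFrame,
    conversion_failure: float = 0.02,
    call_error: float = 0.005,
    seed: int = 0,
) -> dict:
    """Per-(sample, region) epiallele mixture specs for the 19 samples.

    Each cell line gets a parental mixture over three patterns per region
    (all-U, all-M, one line-specific mosaic); FR and FR-F sublines reweight
    the *same* patterns (selection on standing subpopulations).  The
    stable-resistance signature is built in: ZR751 FR/FR-F and the late
    CAMA1 withdrawal sample shift regions 11-12 towards all-M.
    """
    rng = np.random.default_rng(seed)
    specs = {}
    for region, n in _REGION_N_SITES.items():
        all_u = tuple([0] * n)
        all_m = tuple([1] * n)
        for line in CELL_LINES:
            mosaic = tuple(int(b) for b in rng.integers(0, 2, size=n))
            if mosaic in (all_u, all_m):
                mosaic = tuple([1] + [0] * (n - 1))
            base_w = _dirichlet(rng, [8.0, 1.0, 3.0])  # mostly unmethylated
            shift = _dirichlet(rng, [4.0, 2.0, 4.0])
            line_samples = [s for s in SAMPLES if s.startswith(line + "_")]
            for sample in line_samples:
                state = sample.split("_", 1)[1]
                if state == "P":
                    w = base_w
                elif state == "FR":
                    w = 0.5 * base_w + 0.5 * shift
                else:  # FR-F variants
                    w = 0.75 * base_w + 0.25 * shift
                stable = (
                    line == "ZR751" and state in ("FR", "FRF")
                ) or sample == "CAMA1_FRF_w17"
                if stable and region in ("region11", "region12"):
                    w = np.array([0.05, 0.9, 0.05])
                w = w / w.sum()
                # seed derived per (sample, region) for stream independence
                sub_seed = int(
                    rng.integers(0, 2**31 - 1)
                )
                specs[(sample, region)] = simulate.EpialleleMixtureSpec(
                    region_id=region,
                    n_sites=n,
                    patterns=[(all_u, float(w[0])), (all_m, float(w[1])),
                              (mosaic, float(w[2]))],
                    conversion_failure=conversion_failure,
                    call_error=call_error,
                    seed=sub_seed,
                )
    return specs


def study_couplings(strength: float = 4.0, noise_sd: float = 0.3) -> list:
    """Negative methylation-expression couplings, one per target."""
    sites = study_site_table()
    by_region = cpg_positions_by_region(sites)
    return [
        simulate.CouplingSpec(
            exon_id=target,
            linked_sites=by_region[region][:4],
            direction="negative",
            strength=strength,
            noise_sd=noise_sd,
            baseline=1.0,
        )
        for target, region in TARGET_REGION.items()
    ]


def study_cohort_spec(n_tumours: int = 600, seed: int = 0) -> simulate.CohortSimSpec:
    """Five-cluster cohort spec with group-dependent hazards."""
    profiles = [
        ([0.70, 0.08, 0.08, 0.05, 0.04, 0.05], 0.40),  # promA-dominant
        ([0.25, 0.10, 0.45, 0.08, 0.06, 0.06], 0.20),  # promC-high
        ([0.20, 0.10, 0.10, 0.08, 0.07, 0.45], 0.15),  # promF-high
        ([0.40, 0.35, 0.10, 0.05, 0.05, 0.05], 0.15),  # promB-high
        ([0.30, 0.15, 0.20, 0.15, 0.12, 0.08], 0.10),  # mixed
    ]
    hazards = {1: 0.05, 2: 0.12, 3: 0.10, 4: 0.11, 5: 0.08}
    return simulate.CohortSimSpec(
        n_tumours=n_tumours,
        cluster_profiles=profiles,
        read_depth={"distribution": "poisson", "mean": 60},
        hazard_by_group=hazards,
        censoring_rate=0.03,
        exon_names=EXONS,
        seed=seed,
    )


def make_fixtures(out_dir, seed: int = 0, n_reads: int = 100) -> dict:
    """Write the full synthetic dataset and a demo pipeline config.

    Produces sites.tsv, reads.tsv (19 samples x 12 regions x ``n_reads``
    reads), non_cpg_tallies.tsv, expression.tsv, tfbs.bed, regions.bed,
    conservation.bedGraph, cohort.tsv, the two synthetic summary-table
    stand-ins, truth tables, and config.yaml wired to all of them.
    Returns a manifest dict of paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    sites = study_site_table()
    write_site_table(sites, out / "sites.tsv")

    specs = study_mixture_specs(sites, seed=int(rng.integers(2**31 - 1)))
    readset = simulate.simulate_mixture_readsets(specs, n_reads, sites)
    readset.to_tsv(out / "reads.tsv")

    tallies = pd.DataFrame(
        {
            "sample_id": SAMPLES,
            "converted_count": 0,
            "unconverted_count": 0,
        }
    )
    qc_rng = np.random.default_rng(int(rng.integers(2**31 - 1)))
    n_non_cpg = 5000
    unconv = qc_rng.binomial(n_non_cpg, 0.02, size=len(SAMPLES))
    tallies["unconverted_count"] = unconv
    tallies["converted_count"] = n_non_cpg - unconv
    tallies.to_csv(out / "non_cpg_tallies.tsv", sep="\t", index=False)

    wide = methylation_wide(methylated_fraction(readset))
    couplings = study_couplings()
    expr = simulate.simulate_expression(
        wide, couplings, seed=int(rng.integers(2**31 - 1))
    )
    expr.to_csv(out / "expression.tsv", sep="\t", index=False)

    tfbs = synthetic_tfbs(sites, seed=int(rng.integers(2**31 - 1)))
    tfbs.to_csv(out / "tfbs.bed", sep="\t", index=False, header=False)

    regions = study_regions(sites)
    regions.to_csv(out / "regions.bed", sep="\t", index=False, header=False)
    track = simulate.simulate_conservation(
        regions,
        cpg_positions_by_region(sites),
        base_score_mean=0.5,
        cpg_depression=2.0,
        seed=int(rng.integers(2**31 - 1)),
    )
    annotation.write_bedgraph(track, out / "conservation.bedGraph")

    cohort_spec = study_cohort_spec(seed=int(rng.integers(2**31 - 1)))
    cohort = simulate.simulate_cohort(cohort_spec)
    cohort.to_csv(out / "cohort.tsv", sep="\t", index=False)

    pvals = synthetic_correlation_pvalues(
        sites, seed=int(rng.integers(2**31 - 1))
    )
    pvals.to_csv(out / "synthetic_correlation_table.tsv", sep="\t", index=False)

    truth = {
        "mixture_weights": {
            f"{s}|{r}": [w for _, w in spec.patterns]
            for (s, r), spec in specs.items()
        },
        "conversion_failure": 0.02,
        "call_error": 0.005,
        "cpg_depression": 2.0,
        "cohort_hazards": {str(k): v for k, v in cohort_spec.hazard_by_group.items()},
    }
    with open(out / "truth.yaml", "w") as fh:
        yaml.safe_dump(truth, fh)

    config = {
        "schema_version": 1,
        "seed": seed,
        "out_dir": str(out / "results"),
        "inputs": {
            "sites": str(out / "sites.tsv"),
            "reads": str(out / "reads.tsv"),
            "non_cpg_tallies": str(out / "non_cpg_tallies.tsv"),
            "expression": str(out / "expression.tsv"),
            "tfbs": str(out / "tfbs.bed"),
            "regions": str(out / "regions.bed"),
            "conservation": str(out / "conservation.bedGraph"),
            "cohort": str(out / "cohort.tsv"),
        },
        "stages": [
            "methylation", "patterns", "delta", "site_correlation",
            "expression_correlation", "tfbs", "conservation", "cohort",
        ],
        "params": {
            "min_coverage": 1,
            "top_k": 10,
            "min_frequency": 0.01,
            "presence_threshold": 0.01,
            "alpha": 0.05,
            "min_reads": 10,
            "k_clusters": 5,
            "endpoint": "os",
            "pairs": [list(p) for p in FR_PAIRS],
            "exon_columns": EXONS,
            "cutoffs": {"promA": 0.5},
        },
    }
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)

    return {
        name: str(out / fname)
        for name, fname in [
            ("sites", "sites.tsv"), ("reads", "reads.tsv"),
            ("non_cpg_tallies", "non_cpg_tallies.tsv"),
            ("expression", "expression.tsv"), ("tfbs", "tfbs.bed"),
            ("regions", "regions.bed"),
            ("conservation", "conservation.bedGraph"),
            ("cohort", "cohort.tsv"),
            ("synthetic_correlation_table", "synthetic_correlation_table.tsv"),
            ("truth", "truth.yaml"), ("config", "config.yaml"),
        ]
    }
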