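"""Synthetic data with the statistical structure the analysis assumes.

Each generator emulates one class of study input:

* **Read calls** — amplicon bisulfite reads drawn from a mixture of epiallele
  patterns (cellular subpopulations), with bisulfite conversion failure
  (an unmethylated C surviving conversion and reading as methylated, U->M
  only) and a symmetric random call error.  Incomplete methylation
  protection is folded into the call error.
* **Expression** — log-scale first-exon expression coupled to the mean
  methylation of linked CpG sites, plus Gaussian noise; negative coupling
  reproduces the promoter-silencing signature.
* **Conservation** — per-base phyloP-like scores, Normal(mean, 1), with
  scores at C-of-CpG positions depressed by a fixed amount to emulate the
  reduced conservation of CpG sites relative to their surroundings.
* **Cohorts** — tumours with cluster-structured first-exon usage (multinomial
  read counts over cluster-specific fraction profiles), exponential survival
  times with cluster-dependent hazards and independent exponential censoring,
  so proportional hazards hold exactly and Cox recovery is well-posed.

Every generator takes its seed from the spec and draws from a single
``numpy.random.default_rng`` stream, so fixed seeds reproduce outputs
byte-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .methylation import ReadCallSet
from .sites import region_sizes

_WEIGHT_TOL = 1e-9


def _check_prob(name: str, p: float) -> None:
    if not (0.0 <= p <= 1.0):
        raise ValidationError(f"{name} must be in [0, 1], got {p}")


@dataclass
class EpialleleMixtureSpec:
    """Mixture of epiallele patterns for one amplicon region.

    ``patterns`` maps binary methylation vectors (1 = methylated) of length
    ``n_sites`` to mixture weights summing to 1.
    """

    region_id: str
    n_sites: int
    patterns: list  # [(tuple/array of 0/1 with len n_sites, weight), ...]
    conversion_failure: float = 0.0
    call_error: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_sites < 1:
            raise ValidationError("n_sites must be positive")
        if not self.patterns:
            raise ValidationError("at least one pattern required")
        total = 0.0
        for vec, w in self.patterns:
            if len(vec) != self.n_sites:
                raise ValidationError(
                    f"pattern {vec} has length {len(vec)}, expected {self.n_sites}"
                )
            if any(v not in (0, 1) for v in vec):
                raise ValidationError(f"pattern {vec} is not binary")
            if not (0.0 <= w <= 1.0):
                raise ValidationError(f"mixture weight {w} outside [0, 1]")
            total += w
        if abs(total - 1.0) > _WEIGHT_TOL:
            raise ValidationError(f"mixture weights sum to {total}, expected 1")
        _check_prob("conversion_failure", self.conversion_failure)
        _check_prob("call_error", self.call_error)


@dataclass
class CouplingSpec:
    """Link between one expression target and a set of CpG sites.

    ``strength`` is the change in log-expression per unit mean methylation;
    ``direction`` sets its sign (negative = methylation silences).
    """

    exon_id: str
    linked_sites: list  # site identifiers, matched against (chrom, pos) or pos
    direction: str = "negative"
    strength: float = 1.0
    noise_sd: float = 0.1
    baseline: float = 0.0

    def __post_init__(self):
        if not self.linked_sites:
            raise ValidationError("linked_sites must be non-empty")
        if self.direction not in ("negative", "positive"):
            raise ValidationError(f"direction {self.direction!r} invalid")
        if self.strength < 0:
            raise ValidationError("strength must be >= 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


@dataclass
class CohortSimSpec:
    """Tumour cohort with cluster-structured first-exon usage and survival.

    ``cluster_profiles`` is a list of (fraction vector over first exons,
    cluster weight); fraction vectors and cluster weights each sum to 1.
    ``read_depth`` parameterises total first-exon read counts, e.g.
    ``{"distribution": "poisson", "mean": 50}``.  ``hazard_by_group`` maps
    cluster labels (1-based ints) to exponential event rates.
    """

    n_tumours: int
    cluster_profiles: list
    read_depth: dict = field(default_factory=lambda: {"distribution": "poisson", "mean": 50})
    hazard_by_group: dict = field(default_factory=dict)
    censoring_rate: float = 0.05
    exon_names: list | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_tumours < 1:
            raise ValidationError("n_tumours must be positive")
        if not self.cluster_profiles:
            raise ValidationError("at least one cluster profile required")
        wsum = 0.0
        n_exons = len(self.cluster_profiles[0][0])
        for vec, w in self.cluster_profiles:
            vec = np.asarray(vec, dtype=float)
            if len(vec) != n_exons:
                raise ValidationError("fraction vectors differ in length")
            if (vec < 0).any():
                raise ValidationError("fraction vector has negative entries")
            if abs(vec.sum() - 1.0) > _WEIGHT_TOL:
                raise ValidationError(
                    f"fraction vector sums to {vec.sum()}, expected 1"
                )
            wsum += w
        if abs(wsum - 1.0) > _WEIGHT_TOL:
            raise ValidationError(f"cluster weights sum to {wsum}, expected 1")
        if self.censoring_rate < 0:
            raise ValidationError("censoring_rate must be >= 0")
        if self.exon_names is None:
            self.exon_names = [f"prom{chr(ord('A') + i)}" for i in range(n_exons)]
        if len(self.exon_names) != n_exons:
            raise ValidationError("exon_names length mismatch")


def simulate_read_calls(
    spec: EpialleleMixtureSpec,
    n_reads: int,
    sample_id: str = "S1",
    n_non_cpg: int = 0,
) -> ReadCallSet:
    """Draw bisulfite reads from an epiallele mixture.

    Each read picks a pattern by mixture weight; unmethylated sites flip to
    M with probability ``conversion_failure``; every call then flips with
    probability ``call_error``.  When ``n_non_cpg`` > 0, a matching
    Binomial(n_non_cpg, conversion_failure) tally of unconverted non-CpG
    cytosines is attached for conversion QC.
    """
    if n_reads < 1:
        raise ValidationError("n_reads must be >= 1")
    rng = np.random.default_rng(spec.seed)
    weights = np.array([w for _, w in spec.patterns])
    mats = np.array([list(map(int, vec)) for vec, _ in spec.patterns])
    choice = rng.choice(len(weights), size=n_reads, p=weights / weights.sum())
    calls = mats[choice].astype(bool)  # True = methylated
    if spec.conversion_failure > 0:
        fail = rng.random(calls.shape) < spec.conversion_failure
        calls = calls | (~calls & fail)
    if spec.call_error > 0:
        flip = rng.random(calls.shape) < spec.call_error
        calls = calls ^ flip
    strings = ["".join("M" if c else "U" for c in row) for row in calls]
    reads = pd.DataFrame(
        {
            "sample_id": sample_id,
            "region_id": spec.region_id,
            "read_id": [f"read{i}" for i in range(n_reads)],
            "calls": strings,
        }
    )
    sites = pd.DataFrame(
        {
            "chrom": "chrSim",
            "pos": np.arange(1, spec.n_sites + 1) * 10,
            "region_id": spec.region_id,
            "site_index": np.arange(spec.n_sites),
        }
    )
    tallies = None
    if n_non_cpg > 0:
        unconv = int(rng.binomial(n_non_cpg, spec.conversion_failure))
        tallies = pd.DataFrame(
            {
                "sample_id": [sample_id],
                "converted_count": [n_non_cpg - unconv],
                "unconverted_count": [unconv],
            }
        )
    return ReadCallSet(reads=reads, sites=sites, non_cpg_tallies=tallies)


def simulate_mixture_readsets(
    specs_by_sample: dict, n_reads: int, sites: pd.DataFrame
) -> ReadCallSet:
    """Combine per-(sample, region) mixture specs into one ReadCallSet.

    ``specs_by_sample`` maps (sample_id, region_id) -> EpialleleMixtureSpec;
    the shared ``sites`` table supplies coordinates for all regions.
    """
    sizes = region_sizes(sites)
    frames = []
    for (sample_id, region_id), spec in sorted(specs_by_sample.items()):
        if spec.n_sites != sizes.get(region_id):
            raise ValidationError(
                f"spec for region {region_id!r} has n_sites={spec.n_sites}, "
                f"site table has {sizes.get(region_id)}"
            )
        sub = simulate_read_calls(spec, n_reads, sample_id=sample_id)
        frames.append(sub.reads)
    reads = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["sample_id", "region_id", "read_id", "calls"]
    )
    return ReadCallSet(reads=reads, sites=sites)


def simulate_expression(
    methylation_wide: pd.DataFrame,
    couplings: list,
    seed: int = 0,
) -> pd.DataFrame:
    """Expression values per target and sample, coupled to methylation.

    ``methylation_wide`` is a (site x sample) fraction matrix whose row index
    includes a ``pos`` level (or is the position itself).  Per coupling,
    log-expression of the target in each sample is
    baseline + sign * strength * mean(linked-site methylation) + N(0, noise_sd),
    and the reported expression is exp(log-expression).  Returns a long
    DataFrame (target, sample, value).
    """
    rng = np.random.default_rng(seed)
    if isinstance(methylation_wide.index, pd.MultiIndex):
        pos_level = methylation_wide.index.get_level_values("pos")
    else:
        pos_level = methylation_wide.index
    rows = []
    for cp in couplings:
        mask = pos_level.isin(cp.linked_sites)
        found = set(pos_level[mask])
        missing = [s for s in cp.linked_sites if s not in found]
        if missing:
            raise ValidationError(
                f"coupling {cp.exon_id!r}: unknown site id {missing[0]!r}"
            )
        mean_meth = methylation_wide.loc[np.asarray(mask)].mean(axis=0)
        sign = -1.0 if cp.direction == "negative" else 1.0
        noise = (
            rng.normal(0.0, cp.noise_sd, size=len(mean_meth))
            if cp.noise_sd > 0
            else np.zeros(len(mean_meth))
        )
        logexpr = cp.baseline + sign * cp.strength * mean_meth.to_numpy() + noise
        for sample, le in zip(mean_meth.index, logexpr):
            rows.append((cp.exon_id, sample, float(np.exp(le))))
    return pd.DataFrame(rows, columns=["target", "sample", "value"])


def simulate_conservation(
    regions: pd.DataFrame,
    cpg_positions: dict,
    base_score_mean: float = 0.5,
    cpg_depression: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-base conservation scores over a region set.

    ``regions`` has columns chrom, start (0-based), end, region_id;
    ``cpg_positions`` maps region_id -> iterable of 1-based C positions,
    which must fall inside their region.  Scores are Normal(mean, 1) with
    C-of-CpG positions shifted down by ``cpg_depression``.  Returns a track
    DataFrame (chrom, pos, score) with 1-based positions.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for r in regions.itertuples():
        pos = np.arange(r.start + 1, r.end + 1)  # 1-based positions
        scores = rng.normal(base_score_mean, 1.0, size=len(pos))
        cpgs = np.asarray(sorted(cpg_positions.get(r.region_id, [])), dtype=int)
        if len(cpgs):
            if cpgs.min() <= r.start or cpgs.max() > r.end:
                raise ValidationError(
                    f"CpG position outside region {r.region_id!r}"
                )
            idx = cpgs - (r.start + 1)
            scores[idx] -= cpg_depression
        rows.append(
            pd.DataFrame({"chrom": r.chrom, "pos": pos, "score": scores})
        )
    return pd.concat(rows, ignore_index=True)


def simulate_cohort(spec: CohortSimSpec) -> pd.DataFrame:
    """Simulate a tumour cohort table.

    Per tumour: a cluster label drawn by cluster weight; a total first-exon
    read depth from the configured count distribution; per-exon counts
    multinomial on the cluster's fraction profile; and for each endpoint
    (os, rfi, drfi) an exponential event time at the cluster's hazard with
    independent exponential censoring.  Clusters without an entry in
    ``hazard_by_group`` default to rate 0.1.  Also attaches a binary
    ``size_gt_20mm`` covariate (independent of hazard) for regression
    exercises.
    """
    rng = np.random.default_rng(spec.seed)
    k = len(spec.cluster_profiles)
    weights = np.array([w for _, w in spec.cluster_profiles])
    profiles = np.array([np.asarray(v, float) for v, _ in spec.cluster_profiles])
    labels = rng.choice(k, size=spec.n_tumours, p=weights / weights.sum()) + 1

    dist = spec.read_depth.get("distribution", "poisson")
    if dist == "poisson":
        depth = rng.poisson(spec.read_depth["mean"], size=spec.n_tumours)
    elif dist == "negative_binomial":
        depth = rng.negative_binomial(
            spec.read_depth["n"], spec.read_depth["p"], size=spec.n_tumours
        )
    elif dist == "constant":
        depth = np.full(spec.n_tumours, int(spec.read_depth["value"]))
    else:
        raise ValidationError(f"unknown depth distribution {dist!r}")

    counts = np.vstack(
        [
            rng.multinomial(depth[i], profiles[labels[i] - 1])
            for i in range(spec.n_tumours)
        ]
    )
    out = pd.DataFrame(counts, columns=spec.exon_names)
    out.insert(0, "tumour_id", [f"T{i:05d}" for i in range(spec.n_tumours)])
    out["total_first_exon_reads"] = counts.sum(axis=1)
    out["cluster"] = labels
    hazards = np.array(
        [spec.hazard_by_group.get(g, 0.1) for g in labels], dtype=float
    )
    for endpoint in ("os", "rfi", "drfi"):
        event_t = rng.exponential(1.0 / hazards)
        if spec.censoring_rate > 0:
            cens_t = rng.exponential(1.0 / spec.censoring_rate, size=spec.n_tumours)
        else:
            cens_t = np.full(spec.n_tumours, np.inf)
        out[f"time_{endpoint}"] = np.minimum(event_t, cens_t)
        out[f"event_{endpoint}"] = (event_t <= cens_t).astype(int)
    out["size_gt_20mm"] = rng.integers(0, 2, size=spec.n_tumours)
    return out
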