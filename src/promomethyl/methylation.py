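"""Per-read CpG methylation calls: parsing, site fractions, epialleles.

Amplicon bisulfite sequencing yields one call per CpG site per read:
``M`` (methylated, bismark ``Z``), ``U`` (unmethylated, bismark ``z``) or
``N`` (no call at that site).  Because every read derives from a single DNA
molecule, the joint call string over all sites of a region is an epiallele —
the methylation pattern of one chromosome in one cell — and pattern
frequencies expose cellular subpopulations that per-site averages hide.

The module computes

* per-site methylated-read fractions m = #M / (#M + #U), with coverage;
* bisulfite-conversion QC from non-CpG (CHG/CHH) cytosine tallies, where
  residual unconverted C measures conversion failure;
* epiallele pattern frequency tables per region and sample, and a
  parental-vs-derived pattern-sharing classification that asks whether the
  patterns dominating a derived subline already existed in its parental line
  (selection on standing epigenetic variation) or are novel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParseError, QCUnavailableError, ValidationError
from .sites import region_sizes, site_lookup

logger = logging.getLogger(__name__)

CALL_ALPHABET = frozenset("MUN")

READ_COLUMNS = ["sample_id", "region_id", "read_id", "calls"]


@dataclass
class ReadCallSet:
    """Per-read CpG call strings grouped by sample and region.

    ``reads`` has columns sample_id, region_id, read_id, calls; ``calls`` is a
    string over {M, U, N} with one character per region CpG in site_index
    order.  ``non_cpg_tallies`` (optional) has columns sample_id,
    converted_count, unconverted_count and feeds conversion QC.
    """

    reads: pd.DataFrame
    sites: pd.DataFrame
    non_cpg_tallies: pd.DataFrame | None = None

    def __post_init__(self):
        self.reads = pd.DataFrame(self.reads, columns=READ_COLUMNS) if len(
            self.reads
        ) == 0 else self.reads[READ_COLUMNS].reset_index(drop=True)
        self._validate()

    def _validate(self) -> None:
        if self.reads.empty:
            return
        bad = ~self.reads["calls"].map(lambda s: set(s) <= CALL_ALPHABET)
        if bad.any():
            s = self.reads.loc[bad, "calls"].iloc[0]
            raise ValidationError(f"call string {s!r} has characters outside M/U/N")
        sizes = region_sizes(self.sites)
        lengths = self.reads["calls"].str.len()
        expected = self.reads["region_id"].map(sizes)
        if expected.isna().any():
            rid = self.reads.loc[expected.isna(), "region_id"].iloc[0]
            raise ValidationError(f"region {rid!r} absent from site table")
        mism = lengths != expected
        if mism.any():
            row = self.reads[mism].iloc[0]
            raise ValidationError(
                f"read {row['read_id']!r} in region {row['region_id']!r}: "
                f"{len(row['calls'])} calls for a {sizes[row['region_id']]}-site region"
            )
        if self.reads.duplicated(["sample_id", "region_id", "read_id"]).any():
            row = self.reads[
                self.reads.duplicated(["sample_id", "region_id", "read_id"])
            ].iloc[0]
            raise ValidationError(
                f"duplicate read id {row['read_id']!r} in "
                f"({row['sample_id']}, {row['region_id']})"
            )

    def to_tsv(self, path) -> None:
        self.reads.rename(
            columns={"sample_id": "sample", "calls": "call_string"}
        ).to_csv(path, sep="\t", index=False)

    def __len__(self) -> int:
        return len(self.reads)


def parse_read_calls(
    path, sites: pd.DataFrame, format: str = "native_tsv", sample_id: str | None = None
) -> ReadCallSet:
    """Parse per-read CpG calls from disk.

    ``native_tsv``: columns sample, region_id, read_id, call_string
    (header optional when exactly four tab-separated columns are present).
    ``bismark_cpg_context``: bismark methylation-extractor CpG-context lines
    ``read_id  strand  chrom  pos  call`` with Z -> M and z -> U; a site
    absent from a read becomes N; bottom-strand G positions (C position + 1)
    map to the forward-strand C of the symmetric CpG.  Reads whose positions
    match no configured site are dropped with a logged count.
    """
    if format == "native_tsv":
        return _parse_native(path, sites)
    if format == "bismark_cpg_context":
        if sample_id is None:
            raise ValidationError("bismark parsing requires sample_id")
        return _parse_bismark(path, sites, sample_id)
    raise ValidationError(f"unknown read-call format: {format!r}")


def _parse_native(path, sites: pd.DataFrame) -> ReadCallSet:
    rows = []
    sizes = region_sizes(sites)
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ParseError(
                    f"{path}:{lineno}: expected 4 tab-separated fields, "
                    f"got {len(fields)}"
                )
            if lineno == 1 and fields[0] in ("sample", "sample_id"):
                continue
            sample, region, read, calls = fields
            if region not in sizes:
                dropped += 1
                continue
            if not set(calls) <= CALL_ALPHABET:
                raise ParseError(
                    f"{path}:{lineno}: call string {calls!r} outside M/U/N"
                )
            rows.append((sample, region, read, calls))
    if dropped:
        logger.info("dropped %d reads mapping to no configured region", dropped)
    reads = pd.DataFrame(rows, columns=READ_COLUMNS)
    return ReadCallSet(reads=reads, sites=sites)


def _parse_bismark(path, sites: pd.DataFrame, sample_id: str) -> ReadCallSet:
    lookup = site_lookup(sites)
    sizes = region_sizes(sites)
    per_read: dict = {}
    dropped_calls = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("Bismark"):
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise ParseError(
                    f"{path}:{lineno}: expected 5 tab-separated fields, "
                    f"got {len(fields)}"
                )
            read_id, _strand, chrom, pos_s, call = fields
            try:
                pos = int(pos_s)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer position {pos_s!r}")
            if call not in ("Z", "z"):
                raise ParseError(
                    f"{path}:{lineno}: unexpected CpG-context call {call!r}"
                )
            key = lookup.get((chrom, pos))
            if key is None:
                # bottom-strand call at the G of a symmetric CpG
                key = lookup.get((chrom, pos - 1))
            if key is None:
                dropped_calls += 1
                continue
            region, idx = key
            per_read.setdefault((read_id, region), {})[idx] = (
                "M" if call == "Z" else "U"
            )
    if dropped_calls:
        logger.info(
            "dropped %d calls at positions outside configured regions",
            dropped_calls,
        )
    rows = []
    for (read_id, region), calls in sorted(per_read.items()):
        s = "".join(calls.get(i, "N") for i in range(sizes[region]))
        rows.append((sample_id, region, read_id, s))
    reads = pd.DataFrame(rows, columns=READ_COLUMNS)
    return ReadCallSet(reads=reads, sites=sites)


def _calls_matrix(calls: pd.Series, n_sites: int) -> np.ndarray:
    """View equal-length call strings as an (n_reads, n_sites) char array."""
    if len(calls) == 0:
        return np.empty((0, n_sites), dtype="U1")
    joined = "".join(calls)
    return np.array(list(joined), dtype="U1").reshape(len(calls), n_sites)


def methylated_fraction(
    readset: ReadCallSet, min_coverage: int = 1
) -> pd.DataFrame:
    """Per-site, per-sample methylated-read fraction with coverage.

    m = #M / (#M + #U); N calls enter neither numerator nor denominator.
    Sites with coverage below ``min_coverage`` get fraction NaN (missing),
    but their coverage is still reported.  Returns a long DataFrame with
    columns chrom, pos, region_id, site_index, sample, fraction, coverage.
    """
    if min_coverage < 0:
        raise ValidationError("min_coverage must be >= 0")
    sites = readset.sites
    sizes = region_sizes(sites)
    out = []
    grouped = readset.reads.groupby(["region_id", "sample_id"], sort=True)
    for (region, sample), grp in grouped:
        n = sizes[region]
        mat = _calls_matrix(grp["calls"], n)
        n_m = (mat == "M").sum(axis=0)
        n_u = (mat == "U").sum(axis=0)
        cov = n_m + n_u
        with np.errstate(invalid="ignore"):
            frac = np.where(cov > 0, n_m / np.maximum(cov, 1), np.nan)
        frac = np.where(cov >= max(min_coverage, 1), frac, np.nan)
        region_sites = sites[sites["region_id"] == region]
        for i, srow in enumerate(region_sites.itertuples()):
            out.append(
                (srow.chrom, srow.pos, region, srow.site_index, sample,
                 frac[i], int(cov[i]))
            )
    # samples x regions with no reads simply do not appear
    return pd.DataFrame(
        out,
        columns=["chrom", "pos", "region_id", "site_index", "sample",
                 "fraction", "coverage"],
    )


def methylation_wide(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long fraction table to a (site x sample) wide matrix.

    Rows are indexed by (chrom, pos, region_id, site_index) in coordinate
    order within region; columns are samples sorted lexicographically.
    """
    wide = matrix.pivot(
        index=["region_id", "site_index", "chrom", "pos"],
        columns="sample",
        values="fraction",
    )
    return wide.sort_index()


def conversion_qc(readset: ReadCallSet) -> pd.DataFrame:
    """Per-sample percentage of unconverted non-CpG cytosines.

    Unmethylated C outside CpG context should read fully converted; the
    residual unconverted percentage estimates bisulfite conversion failure.
    Raises :class:`QCUnavailableError` when tallies are absent — a missing
    tally is not 0% failure.
    """
    t = readset.non_cpg_tallies
    if t is None or len(t) == 0:
        raise QCUnavailableError(
            "non-CpG cytosine tallies absent: conversion QC unavailable"
        )
    t = t.copy()
    total = t["converted_count"] + t["unconverted_count"]
    if (total <= 0).any():
        raise ValidationError("sample with zero non-CpG cytosine observations")
    t["unconverted_pct"] = 100.0 * t["unconverted_count"] / total
    return t[["sample_id", "converted_count", "unconverted_count",
              "unconverted_pct"]].reset_index(drop=True)


@dataclass
class PatternFrequencyTable:
    """Epiallele pattern frequencies for one region and sample.

    ``table`` has columns pattern, count, frequency and is the *truncated*
    report (top_k / min_frequency union); ``full_counts`` keeps every
    observed N-free pattern so downstream consistency checks use exact
    counts.  Frequencies are always relative to ``n_reads_used``.
    """

    region_id: str
    sample_id: str
    table: pd.DataFrame
    full_counts: pd.Series = field(repr=False)
    n_reads_used: int = 0
    n_reads_excluded: int = 0


def epiallele_patterns(
    readset: ReadCallSet,
    region: str,
    sample: str,
    top_k: int = 10,
    min_frequency: float = 0.01,
) -> PatternFrequencyTable:
    """Frequencies of full-region methylation patterns for one sample.

    Reads containing any N are excluded (tallied in ``n_reads_excluded``):
    amplicon reads should span the whole region, and partial reads would
    inflate the pattern alphabet artificially.  The reported table keeps the
    union of the ``top_k`` most frequent patterns and all patterns at
    frequency >= ``min_frequency``; ties in count break lexicographically by
    pattern string.  Truncation is presentational: ``full_counts`` retains
    everything.
    """
    if region not in set(readset.sites["region_id"]):
        raise ValidationError(f"unknown region {region!r}")
    grp = readset.reads[
        (readset.reads["region_id"] == region)
        & (readset.reads["sample_id"] == sample)
    ]
    has_n = grp["calls"].str.contains("N")
    usable = grp.loc[~has_n, "calls"]
    n_used = len(usable)
    n_excluded = int(has_n.sum())
    counts = usable.value_counts()
    # deterministic order: descending count, then pattern string
    counts = counts.sort_index().sort_values(ascending=False, kind="mergesort")
    if n_used == 0:
        table = pd.DataFrame(columns=["pattern", "count", "frequency"])
        return PatternFrequencyTable(
            region, sample, table, counts, 0, n_excluded
        )
    freq = counts / n_used
    keep = counts.index[:top_k].union(freq.index[freq >= min_frequency])
    sel = counts.loc[counts.index.isin(keep)]
    table = pd.DataFrame(
        {
            "pattern": sel.index,
            "count": sel.values,
            "frequency": (sel / n_used).values,
        }
    ).reset_index(drop=True)
    return PatternFrequencyTable(region, sample, table, counts, n_used, n_excluded)


def fraction_from_patterns(pft: PatternFrequencyTable) -> np.ndarray:
    """Per-site methylated fraction implied by the full pattern counts.

    Consistency oracle: for N-free read sets this equals
    :func:`methylated_fraction` computed from the reads directly.
    """
    if pft.n_reads_used == 0:
        raise ValidationError("no usable reads")
    n_sites = len(pft.full_counts.index[0])
    acc = np.zeros(n_sites)
    for pattern, count in pft.full_counts.items():
        acc += count * (np.array(list(pattern)) == "M")
    return acc / pft.n_reads_used


def pattern_sharing(
    parental: PatternFrequencyTable,
    derived: PatternFrequencyTable,
    presence_threshold: float = 0.01,
) -> pd.DataFrame:
    """Classify derived-sample patterns as pre-existing or novel.

    A derived pattern is *pre-existing* iff its frequency in the parental
    sample is >= ``presence_threshold``; otherwise *novel*.  The returned
    frame carries one row per derived pattern (full counts, untruncated)
    plus the attrs key ``carried_fraction``: the fraction of derived reads
    whose pattern pre-existed.  High carried fractions are consistent with
    selection on standing subpopulations rather than de novo (de)methylation.
    """
    if parental.region_id != derived.region_id:
        raise ValidationError(
            f"region mismatch: parental {parental.region_id!r} "
            f"vs derived {derived.region_id!r}"
        )
    if derived.n_reads_used == 0:
        raise ValidationError("derived sample has no usable reads")
    par_freq = (
        parental.full_counts / parental.n_reads_used
        if parental.n_reads_used
        else parental.full_counts * 0.0
    )
    rows = []
    carried = 0
    for pattern, count in derived.full_counts.items():
        pf = float(par_freq.get(pattern, 0.0))
        pre = pf >= presence_threshold
        if pre:
            carried += count
        rows.append(
            (pattern, count, count / derived.n_reads_used, pf,
             "pre-existing" if pre else "novel")
        )
    out = pd.DataFrame(
        rows,
        columns=["pattern", "derived_count", "derived_frequency",
                 "parental_frequency", "classification"],
    )
    out.attrs["carried_fraction"] = carried / derived.n_reads_used
    return out
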