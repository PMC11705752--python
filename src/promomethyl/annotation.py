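"""TFBS overlap, background-region construction and conservation analysis.

Coordinate conventions.  Intervals are BED-style: 0-based, half-open
[start, end).  CpG sites and conservation-track positions are 1-based; a
1-based position ``pos`` lies inside [start, end) iff ``start < pos <= end``.
bedGraph input is 0-based half-open and wig (fixedStep/variableStep) is
1-based; both are converted to 1-based per-position records internally.

phyloP scores are signed -log10 p-values under a neutral-evolution null:
positive = conserved, negative = accelerated.  The central comparison asks
whether the C nucleotides of CpG sites are less conserved than the other
positions of their regions, via a two-sided Wilcoxon rank-sum test, either
on raw scores or on dPhyloP = score minus the mean score of the containing
region (which removes between-region baseline differences; per construction
dPhyloP averages to zero over each region's positions).

The expression-matched background builder reproduces the standard control:
take genes whose mean expression falls in the target gene's interquartile
range, pad their first exons, mask out protein-coding sequence, and keep
fragments longer than 400 bp (strict) with at least four CpGs (inclusive).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

INTERVAL_COLUMNS = ["chrom", "start", "end"]

WILCOXON_EXACT_N_MAX = 10


def validate_intervals(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    bad = df["end"] <= df["start"]
    if bad.any():
        row = df[bad].iloc[0]
        raise ValidationError(
            f"invalid interval {row['chrom']}:{row['start']}-{row['end']} (end <= start)"
        )
    return df


def read_bed(path, extra_names: tuple = ("name", "score", "strand", "cell_type")) -> pd.DataFrame:
    """Read BED3+ into an interval frame; extra columns named per BED6+1."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    names = INTERVAL_COLUMNS + list(extra_names)
    df.columns = names[: df.shape[1]]
    return validate_intervals(df)


def overlap_tfbs(sites: pd.DataFrame, tfbs: pd.DataFrame) -> pd.DataFrame:
    """Annotate CpG sites with overlapping TFBS intervals.

    A site (1-based ``pos``) overlaps a 0-based half-open interval iff
    ``start < pos <= end`` — the C base itself lies inside.  Returns one row
    per (site, overlapping TFBS) plus sites with no overlap (NaN TFBS
    fields); attrs carry ``n_sites_with_tfbs``, the number of sites with at
    least one overlap.
    """
    tfbs = validate_intervals(tfbs)
    rows = []
    hit_sites = set()
    by_chrom = {c: g.sort_values("start") for c, g in tfbs.groupby("chrom")}
    extra_cols = [c for c in tfbs.columns if c not in INTERVAL_COLUMNS]
    for s in sites.itertuples():
        g = by_chrom.get(s.chrom)
        matched = False
        if g is not None:
            hits = g[(g["start"] < s.pos) & (s.pos <= g["end"])]
            for h in hits.itertuples():
                rec = {
                    "chrom": s.chrom, "pos": s.pos,
                    "region_id": s.region_id, "site_index": s.site_index,
                    "tfbs_start": h.start, "tfbs_end": h.end,
                }
                for c in extra_cols:
                    rec[f"tfbs_{c}"] = getattr(h, c)
                rows.append(rec)
                matched = True
        if matched:
            hit_sites.add((s.chrom, s.pos))
        else:
            rows.append(
                {
                    "chrom": s.chrom, "pos": s.pos,
                    "region_id": s.region_id, "site_index": s.site_index,
                    "tfbs_start": np.nan, "tfbs_end": np.nan,
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["n_sites_with_tfbs"] = len(hit_sites)
    return out


# ---------------------------------------------------------------- intervals

def merge_intervals(intervals: pd.DataFrame) -> pd.DataFrame:
    """Union of possibly overlapping intervals, per chromosome."""
    out = []
    for chrom, g in validate_intervals(intervals).groupby("chrom"):
        g = g.sort_values(["start", "end"])
        cur_s = cur_e = None
        for r in g.itertuples():
            if cur_s is None:
                cur_s, cur_e = r.start, r.end
            elif r.start <= cur_e:
                cur_e = max(cur_e, r.end)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = r.start, r.end
        if cur_s is not None:
            out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=INTERVAL_COLUMNS)


def subtract_intervals(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Interval difference a \\ b; fragments inherit a's extra columns."""
    a = validate_intervals(a)
    b_merged = merge_intervals(b) if len(b) else b
    extra = [c for c in a.columns if c not in INTERVAL_COLUMNS]
    out = []
    for r in a.itertuples():
        cuts = (
            b_merged[
                (b_merged["chrom"] == r.chrom)
                & (b_merged["start"] < r.end)
                & (b_merged["end"] > r.start)
            ].sort_values("start")
            if len(b_merged)
            else b_merged
        )
        pos = r.start
        pieces = []
        for c in cuts.itertuples():
            if c.start > pos:
                pieces.append((pos, min(c.start, r.end)))
            pos = max(pos, c.end)
            if pos >= r.end:
                break
        if pos < r.end:
            pieces.append((pos, r.end))
        for s, e in pieces:
            rec = {"chrom": r.chrom, "start": s, "end": e}
            for c in extra:
                rec[c] = getattr(r, c)
            out.append(rec)
    return pd.DataFrame(out, columns=list(a.columns))


def build_background_regions(
    gene_expression: pd.DataFrame,
    target_gene: str,
    first_exons: pd.DataFrame,
    cds: pd.DataFrame,
    cpg_positions: pd.DataFrame,
    pad_bp: int = 750,
    min_len: int = 400,
    min_cpg: int = 4,
) -> pd.DataFrame:
    """Expression-matched background regions for the conservation control.

    ``gene_expression``: long frame (gene_id, sample, expression); the
    target gene's per-sample distribution defines [Q1, Q3] (linear
    interpolation) and genes whose *mean* expression falls inside that range
    (inclusive) are selected.  Their ``first_exons`` (chrom, start, end,
    gene_id) are padded by ``pad_bp`` on both sides, padded exons of the
    same gene merged, all ``cds`` intervals subtracted, and fragments kept
    only when strictly longer than ``min_len`` with at least ``min_cpg``
    CpGs (``cpg_positions``: chrom, pos 1-based).  Returns the fragment
    frame (chrom, start, end, gene_id, n_cpg) with attrs recording the IQR
    and selected-gene count.
    """
    expr_t = gene_expression.loc[
        gene_expression["gene_id"] == target_gene, "expression"
    ]
    if expr_t.empty:
        raise ValidationError(f"target gene {target_gene!r} absent from expression table")
    q1, q3 = np.percentile(expr_t.to_numpy(dtype=float), [25, 75])
    means = gene_expression.groupby("gene_id")["expression"].mean()
    selected = means[(means >= q1) & (means <= q3)].index
    selected = selected[selected != target_gene]
    if len(selected) == 0:
        logger.warning("no genes fall in the target IQR [%g, %g]", q1, q3)
        out = pd.DataFrame(columns=["chrom", "start", "end", "gene_id", "n_cpg"])
        out.attrs.update(iqr=(q1, q3), n_genes_selected=0)
        return out

    exons = first_exons[first_exons["gene_id"].isin(selected)].copy()
    exons = validate_intervals(exons)
    exons["start"] = np.maximum(exons["start"] - pad_bp, 0)
    exons["end"] = exons["end"] + pad_bp
    merged = []
    for gene, g in exons.groupby("gene_id"):
        m = merge_intervals(g[INTERVAL_COLUMNS])
        m["gene_id"] = gene
        merged.append(m)
    padded = pd.concat(merged, ignore_index=True)
    fragments = subtract_intervals(padded, cds[INTERVAL_COLUMNS]) if len(cds) else padded

    cpg_by_chrom = {
        c: np.sort(g["pos"].to_numpy(dtype=int))
        for c, g in cpg_positions.groupby("chrom")
    }
    n_cpg = []
    for r in fragments.itertuples():
        pos = cpg_by_chrom.get(r.chrom, np.empty(0, dtype=int))
        # 1-based pos inside [start, end): start < pos <= end
        n_cpg.append(int(np.sum((pos > r.start) & (pos <= r.end))))
    fragments = fragments.assign(n_cpg=n_cpg)
    keep = ((fragments["end"] - fragments["start"]) > min_len) & (
        fragments["n_cpg"] >= min_cpg
    )
    out = fragments[keep].reset_index(drop=True)
    out.attrs.update(iqr=(float(q1), float(q3)), n_genes_selected=int(len(selected)))
    return out


# ------------------------------------------------------------- conservation

def read_bedgraph(path) -> pd.DataFrame:
    """Per-position scores from bedGraph (0-based half-open) -> 1-based."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 bedGraph fields")
            chrom, start, end, score = fields[:4]
            try:
                start, end, score = int(start), int(end), float(score)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: malformed bedGraph record")
            for pos in range(start + 1, end + 1):
                rows.append((chrom, pos, score))
    return pd.DataFrame(rows, columns=["chrom", "pos", "score"])


def read_wig(path) -> pd.DataFrame:
    """Per-position scores from fixedStep/variableStep wig (1-based)."""
    rows = []
    chrom = None
    mode = None
    pos = step = span = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            if line.startswith(("fixedStep", "variableStep")):
                kv = dict(f.split("=") for f in line.split()[1:])
                chrom = kv["chrom"]
                mode = line.split()[0]
                span = int(kv.get("span", 1))
                if mode == "fixedStep":
                    pos = int(kv["start"])
                    step = int(kv.get("step", 1))
                continue
            if chrom is None:
                raise ParseError(f"{path}:{lineno}: data before wig header")
            if mode == "fixedStep":
                score = float(line)
                for k in range(span):
                    rows.append((chrom, pos + k, score))
                pos += step
            else:
                p_s, score_s = line.split()
                p, score = int(p_s), float(score_s)
                for k in range(span):
                    rows.append((chrom, p + k, score))
    return pd.DataFrame(rows, columns=["chrom", "pos", "score"])


def write_bedgraph(track: pd.DataFrame, path) -> None:
    """Write a per-position track as single-base bedGraph records."""
    with open(path, "w") as fh:
        for r in track.sort_values(["chrom", "pos"]).itertuples():
            fh.write(f"{r.chrom}\t{r.pos - 1}\t{r.pos}\t{r.score:g}\n")


def wilcoxon_rank_sum(a, b, exact_n_max: int = WILCOXON_EXACT_N_MAX):
    """Two-sided Wilcoxon rank-sum test.

    Exact when the combined sample size is <= ``exact_n_max`` and tie-free;
    otherwise the normal approximation with tie and continuity correction.
    Returns (rank-sum W of the first sample, p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("both groups must be non-empty")
    combined = np.concatenate([a, b])
    no_ties = len(np.unique(combined)) == len(combined)
    method = "exact" if (len(combined) <= exact_n_max and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    w = float(res.statistic + len(a) * (len(a) + 1) / 2.0)
    return w, float(res.pvalue)


def _split_scores(
    track: pd.DataFrame, regions: pd.DataFrame, cpg_positions: dict
):
    """Assign track positions to regions; return per-region score frames.

    ``regions``: chrom, start (0-based), end, region_id.  Positions without
    a score are dropped and counted.  Returns a frame (region_id, chrom,
    pos, score, is_cpg) and the number of region positions missing a score.
    """
    scored = {
        (r.chrom, r.pos): r.score for r in track.itertuples()
    }
    rows = []
    missing = 0
    for r in regions.itertuples():
        cpgs = set(cpg_positions.get(r.region_id, ()))
        for pos in range(r.start + 1, r.end + 1):
            score = scored.get((r.chrom, pos))
            if score is None:
                missing += 1
                continue
            rows.append((r.region_id, r.chrom, pos, score, pos in cpgs))
    df = pd.DataFrame(
        rows, columns=["region_id", "chrom", "pos", "score", "is_cpg"]
    )
    return df, missing


def conservation_compare(
    track: pd.DataFrame,
    regions: pd.DataFrame,
    cpg_positions: dict,
    mode: str = "pooled",
) -> dict:
    """Compare conservation at C-of-CpG positions vs other region positions.

    ``mode="pooled"`` (default) pools positions across regions into one
    two-sided Wilcoxon rank-sum test; ``mode="stratified"`` additionally
    runs the test per region.  Returns a dict with the pooled statistic and
    p, group sizes, per-region summaries, and the position-level frame.
    """
    df, missing = _split_scores(track, regions, cpg_positions)
    a = df.loc[df["is_cpg"], "score"].to_numpy()
    b = df.loc[~df["is_cpg"], "score"].to_numpy()
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("one of the comparison groups is empty")
    w, p = wilcoxon_rank_sum(a, b)
    per_region = (
        df.groupby(["region_id", "is_cpg"])["score"]
        .agg(["count", "mean", "median"])
        .reset_index()
    )
    out = {
        "statistic_w": w,
        "p_value": p,
        "n_cpg": int(len(a)),
        "n_other": int(len(b)),
        "n_missing_positions": int(missing),
        "per_region": per_region,
        "positions": df,
    }
    if mode == "stratified":
        strat = []
        for region, g in df.groupby("region_id"):
            ga = g.loc[g["is_cpg"], "score"].to_numpy()
            gb = g.loc[~g["is_cpg"], "score"].to_numpy()
            if len(ga) == 0 or len(gb) == 0:
                continue
            rw, rp = wilcoxon_rank_sum(ga, gb)
            strat.append((region, rw, rp, len(ga), len(gb)))
        out["stratified"] = pd.DataFrame(
            strat, columns=["region_id", "statistic_w", "p_value", "n_cpg", "n_other"]
        )
    return out


def delta_phylop(
    track: pd.DataFrame, regions: pd.DataFrame, cpg_positions: dict
) -> dict:
    """Conservation relative to the regional mean (dPhyloP) and its test.

    dPhyloP(pos) = score(pos) - mean(score over all scored positions of the
    containing region); by construction it averages to zero per region.
    Regions with zero scored positions are excluded with a warning.  The
    same Wilcoxon comparison then runs on dPhyloP at C-of-CpG vs other
    positions.
    """
    df, missing = _split_scores(track, regions, cpg_positions)
    if df.empty:
        raise ValidationError("no scored positions in any region")
    scored_regions = set(df["region_id"])
    for r in regions["region_id"]:
        if r not in scored_regions:
            logger.warning("region %r has no scored positions; excluded", r)
    df = df.assign(
        delta=df["score"] - df.groupby("region_id")["score"].transform("mean")
    )
    a = df.loc[df["is_cpg"], "delta"].to_numpy()
    b = df.loc[~df["is_cpg"], "delta"].to_numpy()
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("one of the comparison groups is empty")
    w, p = wilcoxon_rank_sum(a, b)
    return {
        "statistic_w": w,
        "p_value": p,
        "n_cpg": int(len(a)),
        "n_other": int(len(b)),
        "n_missing_positions": int(missing),
        "positions": df,
        "cpg_delta": df.loc[df["is_cpg"], ["region_id", "chrom", "pos", "delta"]],
    }
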