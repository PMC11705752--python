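"""CpG site tables: the coordinate scaffold for amplicon bisulfite data.

A site table lists every assayed CpG as the 1-based genomic position of the
C on the forward strand, grouped into amplicon regions.  Within a region,
sites carry a contiguous 0-based ``site_index`` in coordinate order; per-read
call strings are ordered by that index.  Calls observed on the bottom strand
(the G position of the symmetric CpG) are mapped back to the forward-strand C.

Tables are plain pandas DataFrames with columns
``chrom, pos, region_id, site_index``.
"""

from __future__ import annotations

import pandas as pd

from .errors import ValidationError

SITE_COLUMNS = ["chrom", "pos", "region_id", "site_index"]


def make_site_table(records) -> pd.DataFrame:
    """Build and validate a site table from (chrom, pos, region_id) records.

    ``site_index`` is assigned per region in coordinate order; any explicit
    index in the input is ignored.
    """
    df = pd.DataFrame(records, columns=["chrom", "pos", "region_id"])
    return _finalize(df)


def _finalize(df: pd.DataFrame) -> pd.DataFrame:
    if df.empty:
        return pd.DataFrame(columns=SITE_COLUMNS)
    df = df.copy()
    df["pos"] = df["pos"].astype(int)
    if (df["pos"] < 1).any():
        bad = df.loc[df["pos"] < 1, "pos"].iloc[0]
        raise ValidationError(f"CpG position must be >= 1, got {bad}")
    if df.duplicated(["chrom", "pos"]).any():
        dup = df[df.duplicated(["chrom", "pos"])].iloc[0]
        raise ValidationError(
            f"duplicate CpG site {dup['chrom']}:{dup['pos']}"
        )
    df = df.sort_values(["region_id", "chrom", "pos"], kind="mergesort")
    df["site_index"] = df.groupby("region_id", sort=False).cumcount()
    return df.reset_index(drop=True)[SITE_COLUMNS]


def read_site_table(path, format: str | None = None) -> pd.DataFrame:
    """Read a site table from TSV or BED.

    TSV needs columns chrom, pos (1-based C position), region_id.
    BED is 0-based half-open; each record is a single-C interval whose
    ``start`` converts to the 1-based position ``start + 1``, with the BED
    name field used as region id.
    """
    path = str(path)
    if format is None:
        format = "bed" if path.endswith(".bed") else "tsv"
    if format == "bed":
        bed = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "region_id"],
            usecols=[0, 1, 2, 3],
        )
        df = pd.DataFrame(
            {
                "chrom": bed["chrom"],
                "pos": bed["start"].astype(int) + 1,
                "region_id": bed["region_id"],
            }
        )
    elif format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        missing = {"chrom", "pos", "region_id"} - set(df.columns)
        if missing:
            raise ValidationError(
                f"site table {path} lacks columns: {sorted(missing)}"
            )
        df = df[["chrom", "pos", "region_id"]]
    else:
        raise ValidationError(f"unknown site-table format: {format!r}")
    return _finalize(df)


def write_site_table(sites: pd.DataFrame, path) -> None:
    sites[SITE_COLUMNS].to_csv(path, sep="\t", index=False)


def region_sizes(sites: pd.DataFrame) -> dict:
    """Number of CpG sites per region."""
    return sites.groupby("region_id")["pos"].size().to_dict()


def site_lookup(sites: pd.DataFrame) -> dict:
    """Map (chrom, pos) -> (region_id, site_index)."""
    return {
        (r.chrom, r.pos): (r.region_id, r.site_index)
        for r in sites.itertuples()
    }
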