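"""Differential methylation and methylation-expression correlation.

Four analyses sit here:

* per-site methylation deltas between a derived subline and its parental
  cell line (positive = methylation gained in the subline);
* the site x site Spearman correlation matrix of methylated fractions
  across samples, which exposes co-regulated CpG clusters;
* ACTB-normalised first-exon expression (target / ACTB, scaled by 1e4 for
  first exons and 1e2 for the 3' UTR — a plotting convenience that leaves
  every rank statistic untouched);
* Spearman correlation of each CpG site against each expression target
  with Benjamini-Hochberg FDR over the whole site x target family.

Spearman p-values are exact (full permutation enumeration) for n <= 9 and
use the t approximation otherwise; ties take mid-ranks throughout.
"""

from __future__ import annotations

import logging
import math
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

logger = logging.getLogger(__name__)

EXACT_N_MAX = 9

FIRST_EXON_SCALE = 10_000.0
UTR3_SCALE = 100.0


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Input p-values must lie in (0, 1]; output is monotone in the input
    ranks, elementwise >= the input, and capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def spearman(x, y, exact_n_max: int = EXACT_N_MAX):
    """Spearman rho with a two-sided p-value.

    For n <= ``exact_n_max`` the p-value enumerates all n! rank
    permutations (fraction with |rho| >= |observed|, within 1e-12);
    otherwise the usual t approximation.  Returns (rho, p, n).  Constant
    input yields (nan, nan, n).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = len(x)
    if n < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan, math.nan, n
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= exact_n_max:
        p = _exact_perm_p(rx, ry, rho)
    else:
        p = _t_approx_p(rho, n)
    return rho, p, n


def _t_approx_p(rho: float, n: int) -> float:
    tiny = float(np.finfo(float).tiny)  # keep p inside (0, 1] for BH
    if abs(rho) >= 1.0:
        return tiny
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    return max(float(2.0 * stats.t.sf(abs(t), df=n - 2)), tiny)


def _exact_perm_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    n = len(rx)
    perms = np.array(list(permutations(range(n))))
    permuted = ry[perms]  # (n!, n)
    rx_c = rx - rx.mean()
    ry_c = permuted - permuted.mean(axis=1, keepdims=True)
    num = ry_c @ rx_c
    den = math.sqrt((rx_c**2).sum()) * np.sqrt((ry_c**2).sum(axis=1))
    rhos = num / den
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def delta_methylation(
    wide: pd.DataFrame, pairs: list
) -> pd.DataFrame:
    """Per-site methylation deltas subline minus parental.

    ``wide`` is the (site x sample) fraction matrix; ``pairs`` is a list of
    (subline_id, parental_id).  Positive delta = methylation gained in the
    subline.  Missing whenever either fraction is missing.  Returns a long
    frame (site index columns, subline, parental, delta).
    """
    rows = []
    for subline, parental in pairs:
        for sample in (subline, parental):
            if sample not in wide.columns:
                raise ValidationError(f"unknown sample id {sample!r}")
        delta = wide[subline] - wide[parental]
        df = delta.rename("delta").reset_index()
        df["subline"] = subline
        df["parental"] = parental
        rows.append(df)
    out = pd.concat(rows, ignore_index=True)
    return out


def site_correlation_matrix(
    wide: pd.DataFrame, min_pairs: int = 3
) -> pd.DataFrame:
    """Site x site Spearman correlation of methylated fractions.

    Pairwise-complete across samples; a pair with fewer than ``min_pairs``
    complete observations, or a site with zero variance over the shared
    samples, yields NaN (undefined, never coerced to 0).  Symmetric with
    unit diagonal wherever defined.
    """
    sites = wide.index
    k = len(sites)
    vals = wide.to_numpy(dtype=float)
    out = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i, k):
            mask = np.isfinite(vals[i]) & np.isfinite(vals[j])
            if mask.sum() < min_pairs:
                continue
            xi, xj = vals[i, mask], vals[j, mask]
            if np.ptp(xi) == 0 or np.ptp(xj) == 0:
                if i == j and mask.sum() >= min_pairs and np.ptp(xi) == 0:
                    continue  # zero-variance site: diagonal undefined too
                continue
            rho = stats.spearmanr(xi, xj).statistic
            out[i, j] = out[j, i] = rho
    return pd.DataFrame(out, index=sites, columns=sites)


def normalize_expression(
    raw: pd.DataFrame, target_class: dict | None = None
) -> pd.DataFrame:
    """ACTB-normalised expression with class-specific plotting scale.

    ``raw`` needs columns sample, target, quantity, actb_quantity and an
    optional replicate column.  The normalised value is
    (quantity / actb_quantity) * scale with scale 10000 for first exons and
    100 for the 3' UTR; ``target_class`` maps target -> {"first_exon",
    "utr3"} (default: targets named "3UTR"/"UTR3" are UTR, all else first
    exons).  Replicate rows are preserved; per (target, sample) mean and SD
    are returned alongside in ``.attrs["summary"]``.
    """
    raw = raw.copy()
    if (raw["actb_quantity"] <= 0).any():
        bad = raw.loc[raw["actb_quantity"] <= 0, "sample"].iloc[0]
        raise ValidationError(
            f"non-positive ACTB quantity for sample {bad!r}"
        )

    def _class(t):
        if target_class is not None:
            return target_class[t]
        return "utr3" if str(t).upper() in ("3UTR", "UTR3", "3'UTR") else "first_exon"

    scale = raw["target"].map(
        lambda t: UTR3_SCALE if _class(t) == "utr3" else FIRST_EXON_SCALE
    )
    raw["value"] = raw["quantity"] / raw["actb_quantity"] * scale
    summary = (
        raw.groupby(["target", "sample"])["value"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    out = raw
    out.attrs["summary"] = summary
    return out


def methylation_expression_correlation(
    wide: pd.DataFrame,
    expression: pd.DataFrame,
    alpha: float = 0.05,
    min_shared: int = 4,
) -> pd.DataFrame:
    """Spearman correlation of every CpG site against every target.

    ``wide``: (site x sample) methylated fractions.  ``expression``: long
    frame (target, sample, value); replicate rows are averaged per
    (target, sample) first.  Per pair, correlation runs over shared samples
    with pairwise-complete deletion; pairs with fewer than ``min_shared``
    usable samples or a constant vector are skipped and logged.  BH FDR is
    applied over the full site x target family.  The returned frame has one
    row per tested pair (site index columns, target, rho, n, p_value, fdr)
    and attrs ``n_sites_nominal`` / ``n_sites_fdr``: the number of sites
    significant (p < alpha, resp. fdr < alpha) for at least one target.
    """
    expr = (
        expression.groupby(["target", "sample"])["value"].mean().unstack("sample")
    )
    rows = []
    skipped = 0
    for site_key, mrow in wide.iterrows():
        for target, erow in expr.iterrows():
            shared = mrow.index.intersection(erow.index)
            x = mrow[shared].to_numpy(dtype=float)
            y = erow[shared].to_numpy(dtype=float)
            mask = np.isfinite(x) & np.isfinite(y)
            if mask.sum() < min_shared:
                skipped += 1
                continue
            if np.ptp(x[mask]) == 0 or np.ptp(y[mask]) == 0:
                skipped += 1
                continue
            rho, p, n = spearman(x[mask], y[mask])
            rows.append((site_key, target, rho, n, p))
    if skipped:
        logger.info("skipped %d site-target pairs (too few samples or constant)", skipped)
    if not rows:
        out = pd.DataFrame(columns=["site", "target", "rho", "n", "p_value", "fdr"])
        out.attrs.update(n_sites_nominal=0, n_sites_fdr=0)
        return out
    out = pd.DataFrame(rows, columns=["site", "target", "rho", "n", "p_value"])
    out["fdr"] = bh_fdr(out["p_value"].to_numpy())
    summ = summarize_significance(out, alpha=alpha)
    out.attrs.update(summ)
    return out


def summarize_significance(
    table: pd.DataFrame, alpha: float = 0.05, site_col: str = "site"
) -> dict:
    """Count sites significant for >= 1 target, before and after FDR.

    ``table`` needs columns ``site_col``, ``p_value`` and optionally ``fdr``
    (recomputed over the whole family when absent).  Returns
    ``{"n_sites_nominal": ..., "n_sites_fdr": ...}``.
    """
    t = table.copy()
    if "fdr" not in t.columns:
        t["fdr"] = bh_fdr(t["p_value"].to_numpy())
    nominal = t.loc[t["p_value"] < alpha, site_col].nunique()
    fdr_sig = t.loc[t["fdr"] < alpha, site_col].nunique()
    return {"n_sites_nominal": int(nominal), "n_sites_fdr": int(fdr_sig)}
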