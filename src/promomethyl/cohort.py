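"""Relative first-exon usage, tumour clustering and survival analysis.

A tumour's promoter usage is summarised as the fraction of its first-exon
reads on each annotated alternative first exon (promA-promF for ESR1).
Tumours with fewer than 10 first-exon reads (configurable, inclusive at the
threshold) are excluded before fractions are formed.  Fraction profiles are
clustered (hierarchical Ward by default) and tumours are stratified into
low/high groups on a chosen exon's fraction for Kaplan-Meier curves,
log-rank tests, and univariable/multivariable Cox proportional-hazards
regression with Efron tie handling (via lifelines).  Stratification
cutoffs are required inputs: a quantile helper exists for exploration but
no externally defined cutoff is assumed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from sklearn.metrics import silhouette_score

from .errors import ValidationError


def first_exon_fractions(
    cohort: pd.DataFrame, exon_columns: list, min_reads: int = 10
) -> pd.DataFrame:
    """Per-tumour first-exon usage fractions.

    Tumours whose summed first-exon reads fall below ``min_reads`` are
    excluded (the threshold itself is retained: "at least ``min_reads``").
    Returns a frame indexed by tumour_id with one fraction column per exon;
    attrs record ``n_excluded``.
    """
    counts = cohort.set_index("tumour_id")[exon_columns]
    if (counts < 0).to_numpy().any():
        raise ValidationError("negative first-exon read counts")
    total = counts.sum(axis=1)
    keep = total >= min_reads
    fractions = counts[keep].div(total[keep], axis=0)
    fractions.attrs["n_excluded"] = int((~keep).sum())
    return fractions


def cluster_tumours(
    fractions: pd.DataFrame,
    k: int = 5,
    method: str = "ward",
    seed: int = 0,
) -> pd.DataFrame:
    """Cluster tumours on their fraction profiles.

    Default: hierarchical clustering with Ward linkage on Euclidean
    distances cut at ``k`` clusters (labels 1..k), matching the five-cluster
    structure seen in breast-tumour first-exon usage; ``method="kmeans"`` is
    available as a seeded alternative.  Returns a frame (cluster,
    heatmap_order) indexed like ``fractions``; attrs carry a silhouette
    cohesion diagnostic.
    """
    n = len(fractions)
    if k < 2:
        raise ValidationError("k must be >= 2")
    if k > n:
        raise ValidationError(f"k={k} exceeds number of tumours ({n})")
    if fractions.isna().to_numpy().any():
        raise ValidationError("fractions contain missing values")
    x = fractions.to_numpy(dtype=float)
    if method == "ward":
        z = linkage(x, method="ward")
        labels = fcluster(z, t=k, criterion="maxclust")
        order = leaves_list(z)
    elif method == "kmeans":
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(x)
        labels = km.labels_ + 1
        order = np.argsort(labels, kind="mergesort")
    else:
        raise ValidationError(f"unknown clustering method {method!r}")
    heat_rank = np.empty(n, dtype=int)
    heat_rank[order] = np.arange(n)
    out = pd.DataFrame(
        {"cluster": labels.astype(int), "heatmap_order": heat_rank},
        index=fractions.index,
    )
    if 1 < k < n:
        out.attrs["silhouette"] = float(silhouette_score(x, labels))
    return out


def stratify(fractions: pd.DataFrame, exon: str, cutoff: float) -> pd.Series:
    """Label tumours low/high on one exon's fraction.

    ``high`` iff fraction > cutoff (strict: a tumour exactly at the cutoff
    is ``low``).  ``cutoff`` must lie in (0, 1).
    """
    if exon not in fractions.columns:
        raise ValidationError(f"unknown exon {exon!r}")
    if not (0.0 < cutoff < 1.0):
        raise ValidationError(f"cutoff must be in (0, 1), got {cutoff}")
    return pd.Series(
        np.where(fractions[exon] > cutoff, "high", "low"),
        index=fractions.index,
        name=f"{exon}_group",
    )


def quantile_cutoff(fractions: pd.DataFrame, exon: str, q: float = 2 / 3) -> float:
    """Quantile-based cutoff helper for exploratory stratification.

    Provided for convenience only; it does not reproduce any externally defined
    stratification.
    """
    return float(fractions[exon].quantile(q))


@dataclass
class SurvivalResult:
    """Kaplan-Meier curves plus a log-rank test for one endpoint."""

    endpoint: str
    km_curves: pd.DataFrame  # group, time, at_risk, events, survival
    logrank_chi2: float
    logrank_p: float
    logrank_df: int


def km_logrank(
    cohort: pd.DataFrame,
    groups: pd.Series,
    endpoint: str = "os",
) -> SurvivalResult:
    """Kaplan-Meier estimates per group and a log-rank test across groups.

    ``cohort`` must carry ``time_<endpoint>`` and ``event_<endpoint>``
    columns and a ``tumour_id`` column aligning with ``groups``' index.
    Requires at least two non-empty groups and at least one event overall
    (an all-censored cohort leaves the test undefined and raises).
    """
    tcol, ecol = f"time_{endpoint}", f"event_{endpoint}"
    df = cohort.set_index("tumour_id").loc[groups.index, [tcol, ecol]]
    df["group"] = groups
    if df["group"].nunique() < 2:
        raise ValidationError("need at least two groups")
    counts = df.groupby("group").size()
    if (counts == 0).any():
        raise ValidationError("a group has zero subjects")
    if df[ecol].sum() == 0:
        raise ValidationError(
            "all observations censored: log-rank test undefined"
        )
    curves = []
    for g, sub in df.groupby("group"):
        kmf = KaplanMeierFitter()
        kmf.fit(sub[tcol], sub[ecol], label=str(g))
        ev = kmf.event_table
        surv = kmf.survival_function_.iloc[:, 0]
        curves.append(
            pd.DataFrame(
                {
                    "group": str(g),
                    "time": ev.index,
                    "at_risk": ev["at_risk"].to_numpy(),
                    "events": ev["observed"].to_numpy(),
                    "survival": surv.reindex(ev.index).to_numpy(),
                }
            )
        )
    res = multivariate_logrank_test(df[tcol], df["group"], df[ecol])
    return SurvivalResult(
        endpoint=endpoint,
        km_curves=pd.concat(curves, ignore_index=True),
        logrank_chi2=float(res.test_statistic),
        logrank_p=float(res.p_value),
        logrank_df=int(res.degrees_of_freedom),
    )


def dichotomize_size(size_mm: pd.Series, threshold: float = 20.0) -> pd.Series:
    """Tumour size coded 1 if > threshold mm else 0."""
    return (size_mm > threshold).astype(int)


def cox_fit(
    cohort: pd.DataFrame,
    covariates: list,
    endpoint: str = "os",
    mode: str = "multivariable",
) -> pd.DataFrame:
    """Cox proportional-hazards regression (Efron tie handling).

    ``mode="multivariable"`` fits all covariates jointly;
    ``mode="univariable"`` fits one model per covariate.  Covariates must
    already be numerically coded (e.g. tumour size dichotomised at 20 mm via
    :func:`dichotomize_size`).  Returns a tidy frame with hazard ratios,
    Wald 95% CIs and p-values.  Non-convergence or separation surfaces as a
    ValidationError with the underlying diagnostic.
    """
    tcol, ecol = f"time_{endpoint}", f"event_{endpoint}"
    missing = [c for c in covariates + [tcol, ecol] if c not in cohort.columns]
    if missing:
        raise ValidationError(f"missing columns: {missing}")
    n_events = int(cohort[ecol].sum())
    if mode == "multivariable" and n_events < len(covariates):
        raise ValidationError(
            f"{n_events} events for {len(covariates)} parameters"
        )
    if mode not in ("univariable", "multivariable"):
        raise ValidationError(f"unknown mode {mode!r}")
    covsets = [covariates] if mode == "multivariable" else [[c] for c in covariates]
    rows = []
    for covs in covsets:
        df = cohort[covs + [tcol, ecol]].dropna()
        cph = CoxPHFitter()
        try:
            cph.fit(df, duration_col=tcol, event_col=ecol)
        except Exception as exc:  # convergence / collinearity diagnostics
            raise ValidationError(f"Cox fit failed for {covs}: {exc}") from exc
        s = cph.summary
        for cov in covs:
            rows.append(
                {
                    "endpoint": endpoint,
                    "mode": mode,
                    "covariate": cov,
                    "coef": float(s.loc[cov, "coef"]),
                    "hr": float(s.loc[cov, "exp(coef)"]),
                    "hr_ci_low": float(s.loc[cov, "exp(coef) lower 95%"]),
                    "hr_ci_high": float(s.loc[cov, "exp(coef) upper 95%"]),
                    "p_value": float(s.loc[cov, "p"]),
                    "n": int(len(df)),
                    "n_events": int(df[ecol].sum()),
                }
            )
    return pd.DataFrame(rows)
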