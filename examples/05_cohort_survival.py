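"""Cluster a simulated tumour cohort by relative first-exon usage and
stratify survival on one exon's usage fraction.

Tumours with at least 10 first-exon reads contribute a fraction profile;
profiles are Ward-clustered, and a low/high split on promA usage feeds
Kaplan-Meier curves, a log-rank test and Cox regression.
"""

import promomethyl as pm
from promomethyl import fixtures

spec = fixtures.study_cohort_spec(n_tumours=600, seed=9)
cohort = pm.simulate_cohort(spec)

fractions = pm.first_exon_fractions(cohort, fixtures.EXONS, min_reads=10)
print(f"{len(fractions)} tumours retained "
      f"({fractions.attrs['n_excluded']} below the 10-read filter)")

clusters = pm.cluster_tumours(fractions, k=5)
print("cluster sizes:", clusters["cluster"].value_counts().sort_index().to_dict())
print(f"silhouette: {clusters.attrs['silhouette']:.2f}")

groups = pm.stratify(fractions, "promA", cutoff=0.5)
res = pm.km_logrank(cohort, groups, endpoint="os")
print(f"\nlog-rank (promA usage > 0.5 vs <= 0.5, OS): "
      f"chi2={res.logrank_chi2:.2f}, p={res.logrank_p:.3g}")

sub = cohort[cohort["tumour_id"].isin(fractions.index)].copy()
sub["promA_high"] = (groups.loc[sub["tumour_id"]].to_numpy() == "high").astype(int)
fit = pm.cox_fit(sub, ["promA_high"], endpoint="os", mode="univariable")
r = fit.iloc[0]
print(f"Cox HR for high promA usage: {r['hr']:.2f} "
      f"[{r['hr_ci_low']:.2f}, {r['hr_ci_high']:.2f}], p={r['p_value']:.3g}")
print("HR < 1 means dominant main-promoter usage tracks with lower hazard "
      "in this simulation.")
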