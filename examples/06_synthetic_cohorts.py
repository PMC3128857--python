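"""Synthetic cohort generation and its diagnostics.

The generator draws one latent multivariate-normal vector per subject and
maps it through bounded logistic-normal marginals calibrated to target
mean/sd pairs, giving skewed, strongly rank-correlated hourly retentions in
[0, 100] — the statistical signature of repeated gastric-emptying scans.
"""

from gesdx import GESCohortSpec, cohort_diagnostics, generate_cohort
from gesdx.cohort import write_cohort

spec = GESCohortSpec(seed=42)
cohort = generate_cohort(spec)
diag = cohort_diagnostics(cohort)

print(f"n = {diag['n']}, prevalence {100 * diag['prevalence']:.1f}%, "
      f"age {diag['age_mean']:.1f} +- {diag['age_sd']:.1f}, "
      f"{100 * diag['female_fraction']:.0f}% female")

print("\ncontrol-group retention by time point (mean, sd, skewness):")
print(diag["group_stats"]["control"].round(2).to_string())

print("\nSpearman rank correlations, diseased group:")
print(diag["spearman"]["diseased"].round(2).to_string())

write_cohort(cohort, "synthetic_cohort.csv")
print("\nwrote synthetic_cohort.csv (id,status,h1..h4,age,sex)")
print("Retentions decrease with time; adjacent scans correlate strongly;")
print("the 4-h control marginal is calibrated to mean 10.3, sd 16.9.")
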