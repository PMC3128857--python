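"""Best linear combination of the 3-h and 4-h retentions, two ways.

Fisher's LDA gives the closed-form optimum under a two-group normal model;
the distribution-free (DF) search maximises the empirical Mann-Whitney AUC
directly over a coefficient grid, so it cannot fall below the LDA point when
that point is in its grid.  Coefficients are scaled so the 3-h weight is 1;
the second entry is the 4-h weight relative to 3-h.
"""

from gesdx import (
    GESCohortSpec,
    GridSpec,
    df_objective,
    empirical_auc,
    fit_df,
    fit_lda,
    generate_cohort,
)
from gesdx.cohort import to_grouped_markers

cohort = generate_cohort(GESCohortSpec(seed=1))
data = to_grouped_markers(cohort, ("h3", "h4"))

for j, mk in enumerate(("h3", "h4")):
    auc = empirical_auc(data.diseased[:, j], data.control[:, j])
    print(f"single marker {mk}      : empirical AUC {auc:.3f}")

lda, params = fit_lda(data)
print(f"LDA combination       : alpha = (1, {lda.alpha[1]:.3f}), "
      f"binormal AUC {lda.train_auc:.3f}")
print(f"  same alpha, rank AUC: {df_objective(data, lda.alpha):.3f}")

df = fit_df(data, GridSpec(warm_start=lda.alpha))
print(f"DF combination        : alpha = (1, {df.alpha[1]:.3f}), "
      f"empirical AUC {df.train_auc:.3f}")
print("The DF optimum never falls below the rank AUC at the LDA coefficient")
print("and beats the better single time point; the moment-based LDA fit is")
print("handicapped by the skewed raw marginals (see the Box-Cox example).")
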