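"""Box-Cox normalisation of skewed retention marginals and its effect.

Late-hour retentions pile up near zero, which biases the group means and
variances that LDA uses.  A per-marker power transform (lambda fitted by
profile likelihood, 0.5-point shift so zeros stay in range) symmetrises the
marginals.  Rank-based quantities (single-marker AUCs) are untouched —
the transform is strictly increasing — but the LDA combination changes.
"""

import numpy as np
from scipy.stats import skew

from gesdx import (
    GESCohortSpec,
    GroupedMarkers,
    empirical_auc,
    fit_lda,
    fit_transform_spec,
    generate_cohort,
)
from gesdx.boxcox import apply_transform_spec
from gesdx.cohort import to_grouped_markers

cohort = generate_cohort(GESCohortSpec(seed=1))
data = to_grouped_markers(cohort, ("h3", "h4"))
pooled = np.vstack([data.diseased, data.control])

spec = fit_transform_spec(pooled, data.marker_names)
for mk, tr in zip(spec.markers, spec.transforms):
    col = pooled[:, spec.markers.index(mk)]
    before = skew(col)
    after = skew(apply_transform_spec(pooled, spec)[:, spec.markers.index(mk)])
    print(f"{mk}: lambda = {tr.lambda_:+.2f}  skewness {before:+.2f} -> {after:+.2f}")

transformed = GroupedMarkers(
    apply_transform_spec(data.diseased, spec),
    apply_transform_spec(data.control, spec),
    data.marker_names,
)
raw_auc = empirical_auc(data.diseased[:, 1], data.control[:, 1])
tr_auc = empirical_auc(transformed.diseased[:, 1], transformed.control[:, 1])
print(f"4-h rank AUC unchanged  : {raw_auc:.4f} -> {tr_auc:.4f}")

lda_raw, _ = fit_lda(data)
lda_tr, _ = fit_lda(transformed)
print(f"LDA binormal AUC        : raw {lda_raw.train_auc:.3f} "
      f"-> transformed {lda_tr.train_auc:.3f}")
print("Improving the normal fit is what lets the moment-based LDA catch up.")
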