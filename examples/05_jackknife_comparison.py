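"""Take-one-out comparison of LDA, DF and CART on one synthetic cohort.

Each subject is held out in turn; every method is refit on the rest and the
held-out subject is classified.  Linear methods classify at score cutoffs
anchored to preset sensitivities (0.7/0.8/0.9); the tree classifies at
terminal-node probability 0.5.  A 160-subject cohort keeps this quick; the
pipeline runs the same comparison at full size.
"""

from gesdx import (
    GESCohortSpec,
    compare_methods,
    generate_cohort,
    jackknife_cart,
    jackknife_linear,
)
from gesdx.cohort import feature_frame, to_grouped_markers

cohort = generate_cohort(GESCohortSpec(n_total=160, n_diseased=98, seed=4))
data = to_grouped_markers(cohort, ("h3", "h4"))

summaries = []
for method in ("LDA", "DF"):
    summary, stability = jackknife_linear(data, method=method)
    summaries.append(summary)
    auc = stability.quantities["auc"]
    print(f"{method}: across-fold AUC mean {auc.mean():.3f} "
          f"(range {auc.max() - auc.min():.4f})")

features, labels = feature_frame(cohort)
cart_summary, tree, cart_auc = jackknife_cart(features, labels, seed=4)
summaries.append(cart_summary)
print(f"CART: full-sample optimised tree AUC {cart_auc:.3f}, "
      f"{tree.n_leaves} leaves")

print("\nFalse classifications over the jackknife "
      "(fn/fp counts, % of each group):")
print(compare_methods(summaries).to_string(index=False))
print("\nFN rates of the linear rules sit near 1-level by construction;")
print("what separates methods is the false-positive cost of holding that "
      "sensitivity.")
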