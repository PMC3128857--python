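"""ROC primitives on a toy marker: AUC with ties, thresholds, confusion.

Six subjects with one marker each.  The Mann-Whitney AUC counts, over all
diseased-control pairs, how often the diseased subject scores higher (ties
count half): here 5.5 of 9 pairs, AUC 0.611.
"""

import numpy as np

from gesdx import (
    confusion_at_threshold,
    empirical_auc,
    empirical_roc_points,
    threshold_at_sensitivity,
)

diseased = [3.0, 5.0, 7.0]
control = [2.0, 5.0, 6.0]

auc = empirical_auc(diseased, control)
print(f"empirical AUC            : {auc:.4f}  (5.5 wins of 9 pairs, ties half)")

pts = empirical_roc_points(diseased, control)
print(f"ROC points (fpr, tpr)    : {[tuple(np.round(p, 2)) for p in pts]}")
print(f"trapezoidal area         : {np.trapezoid(pts[:, 1], pts[:, 0]):.4f}"
      "  (always equals the AUC)")

# a cutoff anchored so at least 2/3 of diseased score above it
c = threshold_at_sensitivity(diseased, level=0.66)
tp, fn, tn, fp = confusion_at_threshold(diseased, control, c)
print(f"cutoff at sensitivity 0.66: {c:.2f}")
print(f"confusion (TP,FN,TN,FP)  : {(tp, fn, tn, fp)}  "
      f"-> sensitivity {tp / 3:.2f}, specificity {tn / 3:.2f}")
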