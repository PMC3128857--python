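# Methods

## Problem setting

Gastric-emptying scintigraphy yields percent retention of a standardized
meal at 1, 2, 3 and 4 hours — four bounded, strongly rank-correlated, skewed
markers per subject — plus age and sex.  The package asks: what single score
or rule built from these best separates gastroparesis from other causes of
the same symptoms, and how well does that rule carry to subjects it was not
fitted on?  Throughout, higher score means more likely diseased (retention
is higher when emptying is delayed), and the classification rule is
"score strictly greater than cutoff ⇒ diseased"; ties with the cutoff go to
the non-diseased side, and half-weight ties appear only inside the
Mann–Whitney statistic itself.

## Empirical ROC machinery

`empirical_auc` computes the Mann–Whitney AUC through midranks
(`scipy.stats.rankdata`), algebraically identical to the explicit pair sum
(1/mn) Σ [I(w > v) + ½ I(w = v)]; the tests keep the O(mn) double loop as an
independent oracle.  Tie detection is exact equality on input values:
retentions are recorded discretely, and pre-rounding data can change the tie
term.  `empirical_roc_points` emits one (1−specificity, sensitivity) point
per distinct observed cutoff, (0,0)-anchored, and its trapezoidal area
equals the AUC exactly, ties contributing through diagonal segments.

**Sensitivity-anchored thresholds.**  The empirical cutoff for level L over
m diseased scores is the k-th ascending order statistic with
k = ⌊m(1−L)⌋ + 1, stepped down by half the smallest gap between distinct
scores.  This is the *largest* cutoff whose achieved sensitivity is ≥ L: at
integer m(1−L) the naive ⌈m(1−L)⌉ choice is conservative by one order
statistic, so the floor-plus-one form is used (e.g. m = 10, L = 0.9 gives
k = 2 — nine of ten above the cutoff — not k = 1).  If every diseased score
ties, sensitivity saturates at 1 below the minimum score and a warning is
emitted.  The binormal cutoff inverts the normal sensitivity curve in closed
form: c = α′μ_X + √(α′Σ_Xα)·Φ⁻¹(1−L).

One consequence worth stating plainly: a rule anchored at sensitivity L
misses ≈ (1−L) of the diseased *by design*, even on perfectly separated
data.  The jackknife false-negative rates near 1−L are the anchoring
working, not a defect; methods differ in the false-positive price of holding
the anchor.

## The linear combiners

**LDA.**  Group moments are unbiased per-group sample means and covariances
(group-specific, not pooled, because the sensitivity/specificity formulas
use group-specific variances).  The coefficient is
α ∝ (Σ_X + Σ_Y)⁻¹(μ_X − μ_Y); a numerically singular sum (collinear hourly
retentions are plausible) falls back to the Moore–Penrose pseudo-inverse
with a warning.  For one marker α = (1).

**DF.**  The empirical AUC is maximised over a deterministic grid.  For two
markers the free direction is the angle θ ∈ (−90°, 90°] with
α = (cos θ, sin θ), default step 0.25°, two refinement rounds each ten times
finer around the incumbent — the angular parameterisation bounds the search
and covers negative ratios and the pure-second-marker axis.  Beyond two
markers a full grid is computationally prohibitive; the search is
coordinate-wise on the free ratios around a warm start (the LDA estimate by
default), window ±2 at step 0.05, three passes, then the same tenfold
refinements.  Both α and −α are scored (max(AUC, 1−AUC)), so the half-grid
covers all directions.  The empirical AUC is piecewise constant in α, so
ties are common; they break deterministically toward the point nearest the
warm start in ratio space (else nearest (1, 0, …)), then the smallest value.
The warm-start point is inserted into the grid, which makes the training
dominance "DF ≥ AUC at the LDA point" structural.  All-tied scores return
the default direction with AUC 0.5 and a warning.

**Rescaling vs orientation.**  Coefficients are reported relative to marker
1 (first entry 1).  Orienting the score so the training AUC ≥ 0.5 takes
precedence: when the oriented first coefficient is negative or numerically
zero, the vector is divided by the *magnitude* of the largest-magnitude
entry instead (index recorded in `scale_index`), since dividing by a
negative entry would flip which group scores higher.  On GES-like data all
weights are positive and the first-entry-1 convention holds as stated.

## Box-Cox normalisation

Each marker is transformed as ((x + s)^λ − 1)/λ (log at λ = 0) with a fixed
shift s = 0.5 percentage points applied uniformly — retention can be exactly
0 (a fully emptied stomach), and a fixed shift keeps the transform
comparable across jackknife folds.  λ maximises the profile log-likelihood
over [−3, 3]: a 601-point grid evaluated by a vectorised closed form
(verified against `scipy.stats.boxcox_llf` to 1e-13), polished by bounded
scalar minimisation within one grid step.  λ is fitted per marker on the
fold's pooled diseased+control values — per fold, not once on the full
sample, so the held-out subject never influences its own transform; pooling
the groups avoids using the fold's labels twice.  Held-out values whose
shifted value is non-positive are clipped to the smallest shifted training
value with a warning.  Being strictly increasing, the transform leaves every
rank-based quantity unchanged; it matters only for the moment-based LDA fit
and the multi-marker geometry.

## Classification trees

Impurity is the binomial deviance −2 Σ n_k log(n_k/n) (Gini via config),
cutoffs are midpoints between adjacent distinct sorted values, children must
hold ≥ `min_node_size` subjects (default 10; the alternative convention of
10% of the learning sample is a caller choice).  Ties in gain go to the
smaller feature index, then the smaller cutoff.  Because cutoffs are
midpoints and routing compares raw values, strictly increasing per-feature
transforms leave structure and routing unchanged — the tree's answer to the
normality problem the other two methods must work around.  An unsplittable
sample (including fewer than 2·min_node_size subjects) yields the
single-node prior-probability tree rather than an error, so degenerate
validation settings classify by prevalence.

Pruning is weakest-link cost-complexity with training deviance as risk.
Candidate penalties lie between consecutive weakest-link α's of the grown
tree (geometric midpoints); each of 10 label-stratified, seeded CV folds
grows its own tree and is pruned incrementally over ascending candidates;
held-out deviance uses Laplace-smoothed leaf probabilities
(n₁ + 0.5)/(n + 1), so one held-out subject in a pure opposite-class leaf
cannot contribute an infinite deviance (reference tree software handles this
case by its own smoothing; the choice is documented rather than inherited).
The minimising penalty wins, ties toward the larger penalty (smaller tree) —
no 1-SE rule.  Missing split values raise by default; an optional policy
routes them to the larger child.  Sex enters as a 0/1 indicator split as
numeric (two levels only).

Tree AUC applies the empirical AUC to predicted probabilities, so subjects
sharing a leaf tie and get the half weight.

## Jackknife validation

Every subject is held out once; Box-Cox (if enabled), coefficients and
thresholds — or the grown-and-pruned tree — are refit on the remainder, and
the held-out subject is classified (linear rules at each preset level, trees
at probability ≥ 0.5, the "≥" making exact 0.5 diseased deterministically).
FN counts are over the m diseased, FP over the n controls; percentages are
rounded to one decimal, and the comparison table adds (a−b)/a percent
reductions against the first method listed.  Per-fold AUCs and free
coefficients aggregate into mean/sd/median/range stability tables.  The
threshold basis is deliberately per-method (LDA binormal inversion, DF
empirical quantiles): under skewed markers the moment-based inversion drifts
from the preset sensitivity while the empirical quantiles hold it, and the
harness is built to expose exactly that contrast.  CART pruning CV inside
fold i is seeded as master seed + i for bitwise reproducibility.

## Synthetic cohorts

One latent multivariate-normal draw per subject across the four time points
(correlation r_ij = product of adjacent correlations, default (0.75, 0.85,
0.92) — an AR-like structure, positive definite by construction), mapped
through per-timepoint logistic-normal marginals 100·expit(μ_t + σ_t z_t).
(μ_t, σ_t) are calibrated to target mean/sd pairs by nested 1-D root finding
with 80-node Gauss–Hermite moments; infeasible targets (sd beyond the
bounded-variance limit √(mean·(100−mean))) raise naming the time point.
Defaults: 320 subjects, 197 diseased; diseased means (80, 60, 45, 30) with
sds (15, 18, 20, 20); control means (70, 40, 20, 10.3) with sds (18, 20, 16,
16.9); age N(42.8, 14.3²) clamped to [16, 89]; 79% female.  The control 4-h
pair, age distribution, sex ratio and prevalence are published reference
anchors for mixed referral populations; the remaining marginal targets are
package defaults chosen once to respect the monotone decrease over time and
the observed 0.34–0.93 rank-correlation range — they are not measured
values.  The threshold-rule mode draws everyone from the control marginal
set and labels by "4-h > 10%" with flip-probability label noise, giving a
recoverable ground truth; the optional age interaction modifies disease
probability (0.85 under age 47.5, 0.44 over) only inside the discordant
"abnormal at 4 h, normal at 2 h" stratum, making an age split recoverable.

What passing tests on these cohorts do *not* show: real GES data have
measurement error structure, informative missingness, site effects and
meal-protocol variation the generator does not model, and the generator's
group separation is a package choice — absolute AUCs and misclassification
rates on synthetic cohorts characterise the methods' behaviour, not clinical
performance.

## Numerical choices and degenerate inputs

Tie tolerance inside grid searches and pruning is 1e-12; covariance
singularity is declared at condition number 1e12; empty groups,
non-finite values, non-positive shifted Box-Cox inputs, zero combined score
variance, and inconsistent threshold orderings raise `InvalidInputError`
(or `SchemaError`/`CalibrationError` in I/O and calibration).  Report files
are pure functions of (config, seed); wall-clock timings live only in
`run.log`, outside the byte-identical report set.

## Problem sizes

The default pipeline and the acceptance script run the full 320-subject
cohort.  Example scripts and the test suite use 80–320-subject cohorts and a
1,000-subject cohort for the sensitivity-anchoring check — sizes at which
every statistical assertion tested (calibration, dominance, recovery,
anchoring) is already stable across seeds.

## Known limitations

- The DF coordinate-wise search beyond two markers finds a local optimum of
  a piecewise-constant objective; only the two-marker angular grid is
  exhaustive at its resolution.
- No confidence intervals for AUC, no partial AUC, no smoothed ROC, no
  DeLong-style AUC comparisons (reporting is by cross-validated error
  counts), no surrogate splits or ensembles on the tree side.
- The binormal threshold basis assumes normality of the *combined* score in
  the diseased group; with heavy skew its achieved sensitivity drifts —
  by design it is contrasted with, not replaced by, the empirical basis.
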