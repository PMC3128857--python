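"""ROC/AUC primitives shared by every combiner.

Conventions used throughout the package:

* higher score means "more likely diseased" (gastric retention is higher in
  gastroparesis), and
* a subject is classified diseased when its score is *strictly* greater than
  the cutoff; ties with the cutoff go to the non-diseased side.  Half-weight
  ties appear only inside the Mann-Whitney AUC statistic itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm, rankdata


class InvalidInputError(ValueError):
    """Raised when an operation receives degenerate or malformed input."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupedMarkers:
    """Marker matrices for the diseased (m x p) and control (n x p) groups.

    ``diseased[j, i]`` is marker ``i`` of diseased subject ``j`` and
    ``control[k, i]`` marker ``i`` of control subject ``k``; for gastric
    emptying the markers are percent retentions at the hourly time points.
    """

    diseased: np.ndarray
    control: np.ndarray
    marker_names: tuple[str, ...] = ()

    def __post_init__(self):
        d = np.atleast_2d(np.asarray(self.diseased, dtype=float))
        c = np.atleast_2d(np.asarray(self.control, dtype=float))
        if d.shape[0] < 2 or c.shape[0] < 2:
            raise InvalidInputError("each group needs at least 2 subjects")
        if d.shape[1] != c.shape[1] or d.shape[1] < 1:
            raise InvalidInputError("groups must share p >= 1 markers")
        if not (np.isfinite(d).all() and np.isfinite(c).all()):
            raise InvalidInputError("marker values must be finite")
        object.__setattr__(self, "diseased", d)
        object.__setattr__(self, "control", c)
        names = tuple(self.marker_names) or tuple(
            f"m{i + 1}" for i in range(d.shape[1])
        )
        if len(names) != d.shape[1]:
            raise InvalidInputError("marker_names length must equal p")
        object.__setattr__(self, "marker_names", names)

    @property
    def m(self) -> int:
        return self.diseased.shape[0]

    @property
    def n(self) -> int:
        return self.control.shape[0]

    @property
    def p(self) -> int:
        return self.diseased.shape[1]

    def subset(self, markers) -> "GroupedMarkers":
        """Restrict to a subset of marker columns (by name)."""
        idx = [self.marker_names.index(m) for m in markers]
        return GroupedMarkers(
            self.diseased[:, idx], self.control[:, idx], tuple(markers)
        )


@dataclass(frozen=True)
class BinormalParams:
    """Group means and covariances of a multivariate-normal marker model."""

    mean_diseased: np.ndarray
    mean_control: np.ndarray
    cov_diseased: np.ndarray
    cov_control: np.ndarray

    def __post_init__(self):
        mu_x = np.atleast_1d(np.asarray(self.mean_diseased, dtype=float))
        mu_y = np.atleast_1d(np.asarray(self.mean_control, dtype=float))
        s_x = np.atleast_2d(np.asarray(self.cov_diseased, dtype=float))
        s_y = np.atleast_2d(np.asarray(self.cov_control, dtype=float))
        p = mu_x.size
        if mu_y.size != p or s_x.shape != (p, p) or s_y.shape != (p, p):
            raise InvalidInputError("inconsistent binormal dimensions")
        for s in (s_x, s_y):
            if not np.allclose(s, s.T, atol=1e-8 * (1 + np.abs(s).max())):
                raise InvalidInputError("covariance matrix not symmetric")
        object.__setattr__(self, "mean_diseased", mu_x)
        object.__setattr__(self, "mean_control", mu_y)
        object.__setattr__(self, "cov_diseased", s_x)
        object.__setattr__(self, "cov_control", s_y)

    @property
    def p(self) -> int:
        return self.mean_diseased.size


@dataclass(frozen=True)
class SensitivityThresholds:
    """Score cutoffs anchored at target sensitivity levels.

    Higher target sensitivity requires a lower cutoff (more subjects called
    diseased), so ``cutoffs`` is non-increasing when ``levels`` is increasing.
    """

    levels: tuple[float, ...]
    cutoffs: tuple[float, ...]
    basis: str  # "empirical" | "binormal"
    saturated: tuple[bool, ...] = field(default=())

    def __post_init__(self):
        if len(self.levels) != len(self.cutoffs):
            raise InvalidInputError("levels/cutoffs length mismatch")
        if any(not (0.0 < lv < 1.0) for lv in self.levels):
            raise InvalidInputError("sensitivity levels must lie in (0,1)")
        if self.basis not in ("empirical", "binormal"):
            raise InvalidInputError(f"unknown basis {self.basis!r}")
        order = np.argsort(self.levels)
        lv = np.asarray(self.levels)[order]
        ct = np.asarray(self.cutoffs)[order]
        if np.any(np.diff(lv) > 0) and np.any(np.diff(ct) > 1e-9):
            raise InvalidInputError(
                "cutoffs must be non-increasing in target sensitivity"
            )
        if not self.saturated:
            object.__setattr__(
                self, "saturated", tuple(False for _ in self.levels)
            )

    def cutoff_for(self, level: float) -> float:
        return self.cutoffs[self.levels.index(level)]


# ---------------------------------------------------------------------------
# empirical (rank based) ROC
# ---------------------------------------------------------------------------


def _as_scores(v, name: str) -> np.ndarray:
    a = np.asarray(v, dtype=float).ravel()
    if a.size == 0:
        raise InvalidInputError(f"{name} score vector is empty")
    if not np.isfinite(a).all():
        raise InvalidInputError(f"{name} scores must be finite")
    return a


def empirical_auc(scores_diseased, scores_control) -> float:
    """Mann-Whitney AUC with half-weight ties.

    Equals (1/mn) sum_j sum_k [ I(w_j > v_k) + 0.5 I(w_j = v_k) ], computed
    through midranks, so the tie term is exact for discretely recorded data.
    """
    w = _as_scores(scores_diseased, "diseased")
    v = _as_scores(scores_control, "control")
    m, n = w.size, v.size
    ranks = rankdata(np.concatenate([w, v]), method="average")
    return float((ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n))


def batched_empirical_auc(scores_diseased, scores_control) -> np.ndarray:
    """Column-wise Mann-Whitney AUC for (m x K) vs (n x K) score matrices."""
    w = np.atleast_2d(np.asarray(scores_diseased, dtype=float))
    v = np.atleast_2d(np.asarray(scores_control, dtype=float))
    m = w.shape[0]
    ranks = rankdata(np.vstack([w, v]), method="average", axis=0)
    return (ranks[:m].sum(axis=0) - m * (m + 1) / 2.0) / (m * v.shape[0])


def empirical_roc_points(scores_diseased, scores_control) -> np.ndarray:
    """Step-function ROC as (1-specificity, sensitivity) pairs.

    One point per distinct observed cutoff, beginning at (0,0) and ending at
    (1,1); the trapezoidal area over these points equals :func:`empirical_auc`
    (ties contribute through the diagonal segments).
    """
    w = _as_scores(scores_diseased, "diseased")
    v = _as_scores(scores_control, "control")
    cuts = np.unique(np.concatenate([w, v]))[::-1]
    fpr = [0.0]
    tpr = [0.0]
    for t in cuts:
        fpr.append(float(np.mean(v >= t)))
        tpr.append(float(np.mean(w >= t)))
    return np.column_stack([fpr, tpr])


def write_roc_points(points: np.ndarray, path) -> None:
    """Export ROC points as 2-column delimited text with a header row."""
    with open(path, "w") as fh:
        fh.write("fpr,tpr\n")
        for f, t in np.asarray(points):
            fh.write(f"{f:.10g},{t:.10g}\n")


# ---------------------------------------------------------------------------
# binormal model
# ---------------------------------------------------------------------------


def _score_moments(params: BinormalParams, alpha) -> tuple[float, float, float, float]:
    a = np.atleast_1d(np.asarray(alpha, dtype=float))
    if a.size != params.p:
        raise InvalidInputError("alpha length must equal p")
    mu_x = float(a @ params.mean_diseased)
    mu_y = float(a @ params.mean_control)
    var_x = float(a @ params.cov_diseased @ a)
    var_y = float(a @ params.cov_control @ a)
    return mu_x, mu_y, var_x, var_y


def binormal_auc(params: BinormalParams, alpha) -> float:
    """AUC of the linear score a'x under the two-group normal model:
    Phi( a'(mu_X - mu_Y) / sqrt(a' Sigma_X a + a' Sigma_Y a) ).
    """
    mu_x, mu_y, var_x, var_y = _score_moments(params, alpha)
    denom = var_x + var_y
    if denom <= 0:
        raise InvalidInputError("combined score variance is not positive")
    return float(norm.cdf((mu_x - mu_y) / np.sqrt(denom)))


def binormal_sens_spec(params: BinormalParams, alpha, cutoff: float):
    """(sensitivity, specificity) of the rule "a'x > cutoff" under the model."""
    mu_x, mu_y, var_x, var_y = _score_moments(params, alpha)
    if var_x <= 0 or var_y <= 0:
        raise InvalidInputError("degenerate score variance in a group")
    sens = float(1.0 - norm.cdf((cutoff - mu_x) / np.sqrt(var_x)))
    spec = float(norm.cdf((cutoff - mu_y) / np.sqrt(var_y)))
    return sens, spec


# ---------------------------------------------------------------------------
# thresholds and confusion counts
# ---------------------------------------------------------------------------


def threshold_at_sensitivity(
    scores_diseased=None,
    level: float = 0.9,
    basis: str = "empirical",
    params: BinormalParams | None = None,
    alpha=None,
) -> float:
    """Score cutoff whose sensitivity meets a preset level.

    empirical basis
        The largest cutoff c such that the fraction of diseased training
        scores strictly above c is >= ``level``: take the k-th ascending order
        statistic with k = floor((1-level)*m) + 1 and step half the smallest
        gap between distinct scores below it.  If all scores tie the level is
        met only by calling everyone diseased; the cutoff saturates below the
        minimum score and a warning is emitted.
    binormal basis
        Closed-form inversion of the normal sensitivity curve,
        c = mu_score + sigma_score * Phi^{-1}(1 - level).
    """
    if not (0.0 < level < 1.0):
        raise InvalidInputError("level must lie in (0,1)")
    if basis == "binormal":
        if params is None or alpha is None:
            raise InvalidInputError("binormal basis needs params and alpha")
        mu_x, _, var_x, _ = _score_moments(params, alpha)
        if var_x <= 0:
            raise InvalidInputError("degenerate diseased score variance")
        return float(mu_x + np.sqrt(var_x) * norm.ppf(1.0 - level))
    if basis != "empirical":
        raise InvalidInputError(f"unknown basis {basis!r}")

    w = np.sort(_as_scores(scores_diseased, "diseased"))
    m = w.size
    k = min(int(np.floor(m * (1.0 - level) + 1e-9)) + 1, m)
    distinct = np.unique(w)
    if distinct.size > 1:
        gap = float(np.diff(distinct).min())
    else:
        gap = max(1e-6, 1e-6 * abs(distinct[0]))
        warnings.warn(
            "all diseased scores tie; sensitivity saturates at 1 "
            "below the minimum score",
            RuntimeWarning,
            stacklevel=2,
        )
    return float(w[k - 1] - gap / 2.0)


def thresholds_at_levels(
    levels,
    scores_diseased=None,
    basis: str = "empirical",
    params: BinormalParams | None = None,
    alpha=None,
) -> SensitivityThresholds:
    """Vectorised :func:`threshold_at_sensitivity` packaged with its basis."""
    cutoffs = tuple(
        threshold_at_sensitivity(scores_diseased, lv, basis, params, alpha)
        for lv in levels
    )
    return SensitivityThresholds(tuple(levels), cutoffs, basis)


def confusion_at_threshold(scores_diseased, scores_control, cutoff: float):
    """(TP, FN, TN, FP) of the rule "score > cutoff => predicted diseased"."""
    w = _as_scores(scores_diseased, "diseased")
    v = _as_scores(scores_control, "control")
    tp = int(np.sum(w > cutoff))
    fp = int(np.sum(v > cutoff))
    return tp, w.size - tp, v.size - fp, fp
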