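"""Fisher's-LDA best linear combination under the binormal model.

With multivariate-normal markers in each group the coefficient vector
``alpha proportional to (Sigma_X + Sigma_Y)^{-1} (mu_X - mu_Y)`` maximises
the area under the ROC curve of the linear score ``alpha' x`` uniformly over
the specificity range.  Coefficients are reported rescaled so the first
marker's weight is 1 (weights are relative to marker 1), after orienting the
score so that higher means more likely diseased.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .roc import (
    BinormalParams,
    GroupedMarkers,
    InvalidInputError,
    SensitivityThresholds,
    binormal_auc,
    thresholds_at_levels,
)

_RESCALE_TOL = 1e-10


@dataclass(frozen=True)
class LinearCombination:
    """A fitted marker combination: coefficients, method and training AUC.

    ``alpha[scale_index]`` is +-1 after rescaling; ``scale_index`` is 0 (the
    first marker) unless that coefficient was numerically zero, in which case
    the largest-magnitude entry was used instead.
    """

    alpha: np.ndarray
    method: str  # "LDA" | "DF"
    train_auc: float
    basis: str = "raw"  # "raw" | "boxcox"
    scale_index: int = 0

    def __post_init__(self):
        a = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        object.__setattr__(self, "alpha", a)
        if not np.isfinite(a).all():
            raise InvalidInputError("non-finite coefficients")

    def scores(self, markers) -> np.ndarray:
        return np.atleast_2d(np.asarray(markers, dtype=float)) @ self.alpha


def rescale_coefficients(alpha) -> tuple[np.ndarray, int]:
    """Divide by the first coefficient (or, if it is numerically zero, by the
    magnitude of the largest entry) without changing the score's orientation.

    Dividing by a negative first coefficient would flip which group scores
    higher, so when ``alpha[0] < 0`` the magnitude is used and the first entry
    comes out as -1; orientation always wins over the alpha[0]=1 convention.
    """
    a = np.atleast_1d(np.asarray(alpha, dtype=float))
    norm_a = np.linalg.norm(a)
    if norm_a == 0:
        raise InvalidInputError("zero coefficient vector")
    idx = 0
    if abs(a[0]) < _RESCALE_TOL * norm_a:
        idx = int(np.argmax(np.abs(a)))
    return a / abs(a[idx]), idx


def estimate_binormal_params(data: GroupedMarkers) -> BinormalParams:
    """Per-group sample means and unbiased sample covariances."""
    if data.m < data.p + 1 or data.n < data.p + 1:
        warnings.warn(
            "fewer than p+1 subjects in a group; sample covariance may be "
            "singular",
            RuntimeWarning,
            stacklevel=2,
        )
    mu_x = data.diseased.mean(axis=0)
    mu_y = data.control.mean(axis=0)
    cov_x = np.atleast_2d(np.cov(data.diseased, rowvar=False, ddof=1))
    cov_y = np.atleast_2d(np.cov(data.control, rowvar=False, ddof=1))
    return BinormalParams(mu_x, mu_y, cov_x, cov_y)


def fit_lda(
    data: GroupedMarkers, basis: str = "raw"
) -> tuple[LinearCombination, BinormalParams]:
    """Closed-form best linear combination under the fitted binormal model.

    Returns the rescaled, orientation-corrected combination together with the
    group moment estimates (needed downstream for binormal thresholds).  A
    singular covariance sum falls back to the Moore-Penrose pseudo-inverse
    with a warning.
    """
    params = estimate_binormal_params(data)
    delta = params.mean_diseased - params.mean_control
    if data.p == 1:
        alpha = np.array([1.0])
    else:
        s = params.cov_diseased + params.cov_control
        if np.linalg.cond(s) > 1e12:
            warnings.warn(
                "singular covariance sum; using pseudo-inverse",
                RuntimeWarning,
                stacklevel=2,
            )
            alpha = np.linalg.pinv(s) @ delta
        else:
            alpha = np.linalg.solve(s, delta)
        if np.linalg.norm(alpha) == 0:
            # identical group means: no direction is informative
            alpha = np.zeros(data.p)
            alpha[0] = 1.0
    if binormal_auc(params, alpha) < 0.5:
        alpha = -alpha
    alpha, idx = rescale_coefficients(alpha)
    comb = LinearCombination(
        alpha,
        method="LDA",
        train_auc=binormal_auc(params, alpha),
        basis=basis,
        scale_index=idx,
    )
    return comb, params


def lda_thresholds(
    params: BinormalParams, comb: LinearCombination, levels=(0.7, 0.8, 0.9)
) -> SensitivityThresholds:
    """Cutoffs solving sensitivity(c) = level exactly under the binormal model."""
    return thresholds_at_levels(
        levels, basis="binormal", params=params, alpha=comb.alpha
    )
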