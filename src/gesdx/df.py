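"""Rank-based distribution-free best linear combination.

The coefficient vector is chosen to maximise the empirical Mann-Whitney AUC
of the linear score over a deterministic grid.  For two markers the single
free direction is parameterised by an angle theta in (-90, 90] degrees
(alpha = (cos theta, sin theta)), which bounds the search and covers
negative ratios and the pure second-marker axis; for more markers a
coordinate-wise grid around a warm start (normally the LDA estimate) is used,
since an exhaustive grid over several free ratios is computationally
prohibitive.  The empirical AUC is piecewise constant in alpha, so ties among
grid points are common; they are broken deterministically by proximity to the
warm start (else to the first-marker axis).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .lda import LinearCombination, fit_lda, rescale_coefficients
from .roc import (
    GroupedMarkers,
    InvalidInputError,
    SensitivityThresholds,
    batched_empirical_auc,
    empirical_auc,
    thresholds_at_levels,
)

_TIE_TOL = 1e-12


@dataclass(frozen=True)
class GridSpec:
    """Search-grid settings for the distribution-free combiner.

    For p=2 the grid is over the direction angle in degrees; ``step`` is the
    initial resolution and each refinement round shrinks it tenfold around
    the incumbent.  For p>2, ``coord_halfwidth``/``coord_step`` define the
    coordinate-wise window on each free ratio around the warm start.
    """

    low: float = -90.0
    high: float = 90.0
    step: float = 0.25
    n_points: int | None = None
    warm_start: np.ndarray | None = None
    refinement_rounds: int = 2
    coord_halfwidth: float = 2.0
    coord_step: float = 0.05
    coord_passes: int = 3

    def __post_init__(self):
        step = self.step
        if self.n_points is not None:
            if self.n_points < 2:
                raise InvalidInputError("n_points must be >= 2")
            step = (self.high - self.low) / self.n_points
        if not (np.isfinite(self.low) and np.isfinite(self.high)):
            raise InvalidInputError("grid range must be finite")
        if step <= 0 or self.high <= self.low:
            raise InvalidInputError("grid step must be positive, high > low")
        object.__setattr__(self, "step", float(step))
        if self.refinement_rounds < 0:
            raise InvalidInputError("refinement_rounds must be >= 0")
        if self.warm_start is not None:
            object.__setattr__(
                self,
                "warm_start",
                np.atleast_1d(np.asarray(self.warm_start, dtype=float)),
            )


def df_objective(data: GroupedMarkers, alpha) -> float:
    """Empirical Mann-Whitney AUC of the linear score alpha' x."""
    a = np.atleast_1d(np.asarray(alpha, dtype=float))
    if a.size != data.p:
        raise InvalidInputError("alpha length must equal p")
    return empirical_auc(data.diseased @ a, data.control @ a)


def _oriented_batch(data: GroupedMarkers, alphas: np.ndarray) -> np.ndarray:
    """max(AUC, 1-AUC) per candidate direction (columns of ``alphas``)."""
    auc = batched_empirical_auc(data.diseased @ alphas, data.control @ alphas)
    return np.maximum(auc, 1.0 - auc)


def _select(objs, candidates, ref) -> int:
    """Index of the best candidate; ties go to the point nearest ``ref``
    (Euclidean in the candidate parameter space), then to the smallest value."""
    best = objs.max()
    tie = np.flatnonzero(objs >= best - _TIE_TOL)
    if tie.size == 1:
        return int(tie[0])
    dist = np.abs(np.asarray(candidates)[tie] - ref)
    order = np.lexsort((np.asarray(candidates)[tie], dist))
    return int(tie[order[0]])


def _angle_of(alpha) -> float:
    """Map a 2-vector direction into the (-90, 90] degree half-plane."""
    a = np.asarray(alpha, dtype=float)
    if a[0] < 0 or (a[0] == 0 and a[1] < 0):
        a = -a
    theta = float(np.degrees(np.arctan2(a[1], a[0])))
    if theta <= -90.0:
        theta += 180.0
    return theta


def _ratio_of(theta_deg: float) -> float:
    r = np.tan(np.radians(theta_deg))
    return float(np.clip(r, -1e12, 1e12))


def _fit_df_2d(data: GroupedMarkers, grid: GridSpec) -> np.ndarray:
    ref_theta = 0.0
    if grid.warm_start is not None:
        ref_theta = _angle_of(grid.warm_start)
    ref_ratio = _ratio_of(ref_theta)

    thetas = np.arange(grid.low + grid.step, grid.high + 1e-9, grid.step)
    if grid.warm_start is not None:
        thetas = np.unique(np.append(thetas, ref_theta))
    step = grid.step
    incumbent = None
    for _ in range(grid.refinement_rounds + 1):
        if incumbent is not None:
            lo = max(grid.low, incumbent - step)
            hi = min(grid.high, incumbent + step)
            step /= 10.0
            thetas = np.unique(
                np.append(np.arange(lo, hi + 1e-12, step), incumbent)
            )
        rad = np.radians(thetas)
        alphas = np.vstack([np.cos(rad), np.sin(rad)])
        objs = _oriented_batch(data, alphas)
        ratios = np.array([_ratio_of(t) for t in thetas])
        incumbent = float(thetas[_select(objs, ratios, ref_ratio)])
    theta = np.radians(incumbent)
    return np.array([np.cos(theta), np.sin(theta)])


def _fit_df_coord(data: GroupedMarkers, grid: GridSpec) -> np.ndarray:
    warm = grid.warm_start
    if warm is None:
        warm, _ = fit_lda(data)
        warm = warm.alpha
    warm = np.asarray(warm, dtype=float)
    if abs(warm[0]) < 1e-12:
        warm = warm + np.eye(data.p)[0] * 1e-6
    ratios = warm[1:] / warm[0]
    ref = ratios.copy()
    hw, step = grid.coord_halfwidth, grid.coord_step
    for _ in range(grid.refinement_rounds + 1):
        for _ in range(grid.coord_passes):
            for i in range(ratios.size):
                cand = np.unique(
                    np.append(
                        np.arange(ratios[i] - hw, ratios[i] + hw + 1e-12, step),
                        [ratios[i], ref[i]],
                    )
                )
                alphas = np.ones((data.p, cand.size))
                for j in range(ratios.size):
                    alphas[j + 1] = cand if j == i else ratios[j]
                objs = _oriented_batch(data, alphas)
                ratios[i] = cand[_select(objs, cand, ref[i])]
        hw /= 10.0
        step /= 10.0
    return np.concatenate([[1.0], ratios])


def fit_df(
    data: GroupedMarkers, grid: GridSpec | None = None, basis: str = "raw"
) -> LinearCombination:
    """Grid-search the coefficient vector maximising the empirical AUC.

    Returns the combination oriented so the training AUC is >= 0.5 and
    rescaled so the first coefficient is 1 (weights relative to marker 1).
    For a single marker the combination is trivially (1,).
    """
    grid = grid or GridSpec()
    if data.p == 1:
        auc = empirical_auc(data.diseased[:, 0], data.control[:, 0])
        return LinearCombination(
            np.array([1.0]), method="DF", train_auc=auc, basis=basis
        )
    if data.p == 2:
        alpha = _fit_df_2d(data, grid)
    else:
        alpha = _fit_df_coord(data, grid)
    auc = df_objective(data, alpha)
    if auc < 0.5:
        alpha, auc = -alpha, 1.0 - auc
    if auc <= 0.5 + _TIE_TOL and np.ptp(data.diseased @ alpha) == 0:
        warnings.warn(
            "all combination scores tie; returning the default direction "
            "with AUC 0.5",
            RuntimeWarning,
            stacklevel=2,
        )
    alpha, idx = rescale_coefficients(alpha)
    return LinearCombination(
        alpha,
        method="DF",
        train_auc=df_objective(data, alpha),
        basis=basis,
        scale_index=idx,
    )


def df_thresholds(
    data: GroupedMarkers, comb: LinearCombination, levels=(0.7, 0.8, 0.9)
) -> SensitivityThresholds:
    """Empirical diseased-score quantile cutoffs at the target levels."""
    return thresholds_at_levels(
        levels, scores_diseased=data.diseased @ comb.alpha, basis="empirical"
    )
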