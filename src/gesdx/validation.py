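"""Take-one-out (jackknife) cross-validation and misclassification reporting.

Each of the m+n subjects is held out in turn; the combination (or tree) is
refit on the remaining subjects — including any Box-Cox normalisation, whose
power parameters are re-estimated inside the fold so the held-out subject
never influences its own classifier — and the held-out subject is classified.
False negatives (diseased called healthy) and false positives accumulate over
the folds into the misclassification summary; per-fold AUCs and coefficients
accumulate into parameter-stability statistics.

Threshold bases follow each method's own framework: the LDA combination uses
the closed-form binormal sensitivity inversion, the DF combination uses
empirical diseased-score quantiles.  This asymmetry is deliberate — when the
markers are skewed the moment-based inversion drifts from the preset
sensitivity while the empirical quantiles hold it, which is exactly the
contrast the harness is meant to expose.  Trees classify a held-out subject
as diseased when its terminal-node probability is >= 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .boxcox import DEFAULT_SHIFT, apply_transform_spec, fit_transform_spec
from .cart import grow_tree, predict_proba, prune_tree, tree_auc
from .df import GridSpec, df_thresholds, fit_df
from .lda import fit_lda, lda_thresholds
from .roc import GroupedMarkers, InvalidInputError

DEFAULT_LEVELS = (0.7, 0.8, 0.9)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


def summarize_misclassification(fn: int, fp: int, m: int, n: int) -> dict:
    """Counts and percentage rates (1 decimal) of a jackknife pass.

    FN rate is over the m diseased, FP rate over the n controls, the total
    over all m+n subjects.
    """
    if m <= 0 or n <= 0:
        raise InvalidInputError("group sizes must be positive")
    if fn > m or fp > n or fn < 0 or fp < 0:
        raise InvalidInputError("counts exceed group sizes")
    return {
        "fn": int(fn),
        "fp": int(fp),
        "total": int(fn + fp),
        "fn_pct": round(100.0 * fn / m, 1),
        "fp_pct": round(100.0 * fp / n, 1),
        "total_pct": round(100.0 * (fn + fp) / (m + n), 1),
    }


@dataclass(frozen=True)
class MisclassificationSummary:
    """Jackknife error counts per sensitivity level (or a single entry for
    probability-threshold classifiers such as trees, keyed ``0.5``)."""

    method: str
    m: int
    n: int
    per_level: dict = field(default_factory=dict)  # level -> (fn, fp)

    def rates(self) -> pd.DataFrame:
        rows = []
        for level, (fn, fp) in sorted(self.per_level.items()):
            rows.append(
                {"method": self.method, "level": level}
                | summarize_misclassification(fn, fp, self.m, self.n)
            )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class ParameterStability:
    """Across-fold mean/sd/median/range of the AUC and free coefficients."""

    method: str
    quantities: dict  # name -> 1-D array of per-fold values

    def table(self) -> pd.DataFrame:
        rows = []
        for name, vals in self.quantities.items():
            v = np.asarray(vals, dtype=float)
            rows.append(
                {
                    "method": self.method,
                    "quantity": name,
                    "mean": v.mean(),
                    "std": v.std(ddof=1) if v.size > 1 else 0.0,
                    "median": float(np.median(v)),
                    "range": float(np.ptp(v)),
                }
            )
        return pd.DataFrame(rows)


def compare_methods(summaries: list[MisclassificationSummary]) -> pd.DataFrame:
    """Side-by-side totals with percent-reduction columns (a-b)/a between the
    first summary and each later one, per shared level."""
    if not summaries:
        raise InvalidInputError("need at least one summary")
    tables = [s.rates() for s in summaries]
    out = pd.concat(tables, ignore_index=True)
    if len(summaries) > 1:
        base = tables[0].set_index("level")["total"]
        reductions = []
        for t in tables:
            cur = t.set_index("level")["total"]
            for level in t["level"]:
                a, b = base.get(level), cur.get(level)
                reductions.append(
                    100.0 * (a - b) / a if a not in (None, 0) else np.nan
                )
        out["reduction_vs_first_pct"] = np.round(reductions, 1)
    return out


# ---------------------------------------------------------------------------
# jackknife for the linear combiners
# ---------------------------------------------------------------------------


def _fit_linear_fold(
    fold_data: GroupedMarkers,
    heldout_markers: np.ndarray,
    method: str,
    levels,
    transform: bool,
    grid: GridSpec | None,
    boxcox_shift: float,
) -> dict:
    """Fit one jackknife fold and score the held-out subject.

    Everything — Box-Cox powers, coefficients, thresholds — is estimated from
    ``fold_data`` only; the held-out markers are merely pushed through.
    """
    if transform:
        pooled = np.vstack([fold_data.diseased, fold_data.control])
        spec = fit_transform_spec(
            pooled, fold_data.marker_names, shift=boxcox_shift
        )
        fold_data = GroupedMarkers(
            apply_transform_spec(fold_data.diseased, spec),
            apply_transform_spec(fold_data.control, spec),
            fold_data.marker_names,
        )
        heldout_markers = apply_transform_spec(
            np.atleast_2d(heldout_markers), spec
        )[0]
    basis = "boxcox" if transform else "raw"
    if method == "LDA":
        comb, params = fit_lda(fold_data, basis=basis)
        thr = lda_thresholds(params, comb, levels)
    elif method == "DF":
        comb = fit_df(fold_data, grid, basis=basis)
        thr = df_thresholds(fold_data, comb, levels)
    else:
        raise InvalidInputError(f"unknown method {method!r}")
    score = float(np.atleast_1d(heldout_markers) @ comb.alpha)
    return {
        "score": score,
        "auc": comb.train_auc,
        "alpha": comb.alpha,
        "cutoffs": dict(zip(thr.levels, thr.cutoffs)),
    }


def jackknife_linear(
    data: GroupedMarkers,
    method: str = "DF",
    levels=DEFAULT_LEVELS,
    transform: bool = False,
    grid: GridSpec | None = None,
    boxcox_shift: float = DEFAULT_SHIFT,
    return_folds: bool = False,
):
    """Leave-one-out validation of an LDA or DF linear combination.

    Returns ``(MisclassificationSummary, ParameterStability)`` and, when
    ``return_folds`` is set, the per-fold records as a third element.
    """
    if data.m + data.n < 20:
        raise InvalidInputError("jackknife needs at least 20 subjects")
    levels = tuple(levels)
    fn = {lv: 0 for lv in levels}
    fp = {lv: 0 for lv in levels}
    aucs, alphas, folds = [], [], []

    for label, group, other in (
        (1, data.diseased, data.control),
        (0, data.control, data.diseased),
    ):
        for j in range(group.shape[0]):
            rest = np.delete(group, j, axis=0)
            fold = GroupedMarkers(
                rest if label == 1 else other,
                other if label == 1 else rest,
                data.marker_names,
            )
            rec = _fit_linear_fold(
                fold, group[j], method, levels, transform, grid, boxcox_shift
            )
            rec["label"] = label
            for lv in levels:
                predicted = rec["score"] > rec["cutoffs"][lv]
                if label == 1 and not predicted:
                    fn[lv] += 1
                elif label == 0 and predicted:
                    fp[lv] += 1
            aucs.append(rec["auc"])
            alphas.append(rec["alpha"])
            if return_folds:
                folds.append(rec)

    summary = MisclassificationSummary(
        method=method,
        m=data.m,
        n=data.n,
        per_level={lv: (fn[lv], fp[lv]) for lv in levels},
    )
    quantities = {"auc": np.asarray(aucs)}
    alphas = np.asarray(alphas)
    for i in range(1, data.p):
        quantities[f"coef_{data.marker_names[i]}"] = alphas[:, i]
    stability = ParameterStability(method=method, quantities=quantities)
    if return_folds:
        return summary, stability, folds
    return summary, stability


# ---------------------------------------------------------------------------
# jackknife for trees
# ---------------------------------------------------------------------------


def jackknife_cart(
    features: pd.DataFrame,
    labels,
    min_node_size: int = 10,
    min_impurity_decrease: float = 0.0,
    criterion: str = "deviance",
    n_folds: int = 10,
    seed: int = 0,
    prune: bool = True,
    return_folds: bool = False,
):
    """Leave-one-out validation of a grown-and-pruned classification tree.

    Per fold the tree is grown (and cross-validation-pruned, with the fold's
    own pruning CV seeded from ``seed`` plus the fold index) on the remaining
    subjects; the held-out subject is called diseased when its terminal-node
    probability is >= 0.5.  Returns the misclassification summary together
    with the full-sample optimised tree and that tree's training AUC.
    """
    y = np.asarray(labels).astype(int).ravel()
    m, n = int(y.sum()), int((1 - y).sum())
    fn = fp = 0
    folds = []
    for i in range(y.size):
        keep = np.arange(y.size) != i
        sub = features.iloc[keep]
        tree = grow_tree(
            sub, y[keep], min_node_size, min_impurity_decrease, criterion
        )
        if prune:
            tree = prune_tree(
                tree,
                sub,
                y[keep],
                n_folds=n_folds,
                seed=seed + i,
                min_impurity_decrease=min_impurity_decrease,
            )
        prob = float(predict_proba(tree, features.iloc[[i]])[0])
        predicted = prob >= 0.5
        if y[i] == 1 and not predicted:
            fn += 1
        elif y[i] == 0 and predicted:
            fp += 1
        if return_folds:
            folds.append({"prob": prob, "label": int(y[i])})

    full = grow_tree(features, y, min_node_size, min_impurity_decrease, criterion)
    if prune:
        full = prune_tree(
            full,
            features,
            y,
            n_folds=n_folds,
            seed=seed,
            min_impurity_decrease=min_impurity_decrease,
        )
    summary = MisclassificationSummary(
        method="CART", m=m, n=n, per_level={0.5: (fn, fp)}
    )
    out = (summary, full, tree_auc(full, features, y))
    return out + (folds,) if return_folds else out
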