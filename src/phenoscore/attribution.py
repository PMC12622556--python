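"""Per-cell Shapley attributions and the Interpretable Score.

Attributions are exact Shapley values under the tree-conditional
(path-dependent) expectation convention, computed on probability outputs
for averaged forests so that a cell's score reads as a probability shift.
Per-repeat attribution matrices from the nested CV are averaged per cell,
multiclass outputs are collapsed to the cell's predicted class (binary
tasks use the positive-class slice uniformly so signs stay comparable),
and the Interpretable Score is the row sum across all design columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

from ._treeshap import forest_shap, tree_expectations
from .classify import DesignMatrix, FitResult

__all__ = [
    "AttributionTensor",
    "ScoreVector",
    "tree_shap",
    "compute_attributions",
    "average_over_repeats",
    "collapse_multiclass",
    "interpretable_score",
]


def _pack_trees(trees, n_classes: int, scales, values_fn):
    """Concatenate node arrays across trees for the numba kernel."""
    cls, crs, feats, thrs, covs, vals = [], [], [], [], [], []
    offsets = [0]
    max_depth = 0
    for tree in trees:
        t = tree.tree_
        cls.append(t.children_left.astype(np.int64))
        crs.append(t.children_right.astype(np.int64))
        feats.append(t.feature.astype(np.int64))
        thrs.append(t.threshold.astype(np.float64))
        covs.append(t.weighted_n_node_samples.astype(np.float64))
        vals.append(values_fn(t))
        offsets.append(offsets[-1] + t.node_count)
        max_depth = max(max_depth, t.max_depth)
    return (
        np.concatenate(cls), np.concatenate(crs), np.concatenate(feats),
        np.concatenate(thrs), np.concatenate(covs), np.concatenate(vals),
        np.asarray(offsets, dtype=np.int64), np.asarray(scales, dtype=np.float64),
        max_depth,
    )


def _classifier_leaf_values(t) -> np.ndarray:
    """Per-node class probabilities of a sklearn classification tree."""
    v = t.value[:, 0, :].astype(np.float64)
    totals = v.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return v / totals


def tree_shap(model, rows) -> tuple[np.ndarray, np.ndarray]:
    """Exact Shapley values for a fitted tree ensemble.

    Returns ``(phi, base)`` with ``phi`` of shape (cells, features,
    classes) and ``base`` of shape (classes,); ``base + phi.sum(axis=1)``
    reproduces the model output for every cell (local accuracy).  Averaged
    forests and single trees are explained on probability outputs;
    gradient boosting on its raw margin.
    """
    x = np.ascontiguousarray(np.asarray(rows, dtype=np.float64))
    if isinstance(model, (RandomForestClassifier, DecisionTreeClassifier)):
        trees = model.estimators_ if hasattr(model, "estimators_") else [model]
        n_classes = model.n_classes_
        scales = np.full(len(trees), 1.0 / len(trees))
        packed = _pack_trees(trees, n_classes, scales, _classifier_leaf_values)
        base = np.zeros(n_classes)
        for i, tree in enumerate(trees):
            t = tree.tree_
            ev = tree_expectations(
                t.children_left.astype(np.int64), t.children_right.astype(np.int64),
                t.weighted_n_node_samples.astype(np.float64),
                _classifier_leaf_values(t),
            )
            base += scales[i] * ev[0]
    elif isinstance(model, GradientBoostingClassifier):
        stages = model.estimators_  # (n_stages, K) regressors
        n_out = stages.shape[1]
        trees = [stages[s, k] for s in range(stages.shape[0]) for k in range(n_out)]
        # each regressor contributes to one output: expand into block values
        def values_fn_factory(k):
            def fn(t):
                v = np.zeros((t.node_count, n_out))
                v[:, k] = t.value[:, 0, 0]
                return v
            return fn
        cls, crs, feats, thrs, covs, vals_list = [], [], [], [], [], []
        offsets = [0]
        scales = []
        max_depth = 0
        for s in range(stages.shape[0]):
            for k in range(n_out):
                t = stages[s, k].tree_
                cls.append(t.children_left.astype(np.int64))
                crs.append(t.children_right.astype(np.int64))
                feats.append(t.feature.astype(np.int64))
                thrs.append(t.threshold.astype(np.float64))
                covs.append(t.weighted_n_node_samples.astype(np.float64))
                vals_list.append(values_fn_factory(k)(t))
                offsets.append(offsets[-1] + t.node_count)
                scales.append(model.learning_rate)
                max_depth = max(max_depth, t.max_depth)
        packed = (
            np.concatenate(cls), np.concatenate(crs), np.concatenate(feats),
            np.concatenate(thrs), np.concatenate(covs), np.concatenate(vals_list),
            np.asarray(offsets, dtype=np.int64), np.asarray(scales), max_depth,
        )
        raw0 = model._raw_predict_init(x[:1])[0]
        base = np.asarray(raw0, dtype=float)
        n_classes = n_out
    else:
        raise TypeError(
            f"unsupported model type {type(model).__name__}; "
            "tree attributions require a tree ensemble"
        )
    cl, cr, feat, thr, cov, vals, offsets, scales_arr, max_depth = packed
    phi = forest_shap(
        cl, cr, feat, thr, cov, vals, offsets, scales_arr, x,
        x.shape[1], max_depth,
    )
    return phi, base


@dataclass
class AttributionTensor:
    """Repeats x cells x features x classes Shapley values from nested CV."""

    values: np.ndarray  # (b, N, p, c); NaN where a cell was not attributed
    base_values: np.ndarray  # (b, c)
    feature_names: list[str]
    cell_ids: list | None = None

    @property
    def n_repeats(self) -> int:
        return self.values.shape[0]


def compute_attributions(fit: FitResult, design: DesignMatrix) -> AttributionTensor:
    """Shapley values for every cell in every CV repeat.

    Outer-test rows are attributed by their own fold's model (test rows
    only, never train rows); holdout rows — unseen by every outer model —
    are attributed by the repeat's first outer-fold model.
    """
    x = design.values
    n, p = x.shape
    c = len(fit.classes_)
    b = len(fit.models)
    values = np.full((b, n, p, c), np.nan)
    bases = np.zeros((b, c))
    for r in range(b):
        fold_of = fit.fold_assignment[r]
        base_accum = np.zeros(c)
        for f, model in enumerate(fit.models[r]):
            rows = np.flatnonzero(fold_of == f)
            if rows.size == 0:
                continue
            phi, base = tree_shap(model, x[rows])
            values[r, rows] = phi
            base_accum += base / len(fit.models[r])
        if fit.holdout_idx.size:
            phi, base = tree_shap(fit.models[r][0], x[fit.holdout_idx])
            values[r, fit.holdout_idx] = phi
        bases[r] = base_accum
    return AttributionTensor(
        values=values, base_values=bases,
        feature_names=list(fit.feature_names), cell_ids=design.cell_ids,
    )


def average_over_repeats(tensor: AttributionTensor) -> np.ndarray:
    """Elementwise mean over the repeats in which each cell was attributed;
    output keeps the (cells, features, classes) dimensions."""
    present = ~np.isnan(tensor.values[:, :, 0, 0])
    if (~present.any(axis=0)).any():
        missing = np.flatnonzero(~present.any(axis=0))
        raise ValueError(
            f"{missing.size} cells attributed in zero repeats (first: {missing[:5]})"
        )
    with np.errstate(invalid="ignore"):
        return np.nanmean(tensor.values, axis=0)


def collapse_multiclass(
    s_bar: np.ndarray,
    predicted_class: np.ndarray,
    mode: str = "auto",
    positive_class: int = 1,
) -> np.ndarray:
    """One Shapley value per cell per feature.

    ``literal`` takes each cell's predicted-class slice; ``positive`` takes
    a single class slice for all cells (sign-consistent scores for binary
    tasks); ``auto`` uses positive for 2 classes and literal otherwise.
    """
    n, p, c = s_bar.shape
    pred = np.asarray(predicted_class)
    if pred.shape[0] != n:
        raise ValueError("predicted_class length does not match cells")
    if np.isnan(s_bar).any():
        raise ValueError("non-finite attributions; average over repeats first")
    if mode == "auto":
        mode = "positive" if c == 2 else "literal"
    if mode == "positive":
        return s_bar[:, :, positive_class]
    if mode == "literal":
        if (pred < 0).any() or (pred >= c).any():
            raise ValueError("predicted class outside the class range")
        return s_bar[np.arange(n), :, pred]
    raise ValueError(f"unknown collapse mode {mode!r}")


@dataclass
class ScoreVector:
    """Per-cell Interpretable Score (row sum of collapsed attributions)."""

    scores: np.ndarray
    predicted_class: np.ndarray
    feature_ranking: pd.DataFrame  # feature, mean_abs_shap, sorted desc
    cell_ids: list | None = None


def interpretable_score(
    collapsed: np.ndarray,
    feature_names: list[str] | None = None,
    predicted_class: np.ndarray | None = None,
    roles: list[str] | None = None,
    columns: str = "all",
    cell_ids: list | None = None,
) -> ScoreVector:
    """Sum the collapsed attributions across design columns per cell.

    By default the sum runs over *all* columns (latent, covariate and
    interaction); ``columns="latent_only"`` restricts it to latent dims.
    Also returns the per-feature mean |SHAP| ranking.
    """
    mat = np.asarray(collapsed, dtype=float)
    if not np.isfinite(mat).all():
        raise ValueError("non-finite entries in collapsed attributions")
    n, p = mat.shape
    names = list(feature_names) if feature_names is not None else [
        f"f{i}" for i in range(p)
    ]
    if columns == "latent_only":
        if roles is None:
            raise ValueError("latent_only scoring requires column roles")
        keep = np.asarray([r == "latent" for r in roles])
    elif columns == "all":
        keep = np.ones(p, dtype=bool)
    else:
        raise ValueError(f"unknown columns selector {columns!r}")
    scores = mat[:, keep].sum(axis=1)
    ranking = (
        pd.DataFrame({
            "feature": names,
            "mean_abs_shap": np.abs(mat).mean(axis=0),
        })
        .sort_values("mean_abs_shap", ascending=False, kind="mergesort")
        .reset_index(drop=True)
    )
    if predicted_class is None:
        predicted_class = np.zeros(n, dtype=int)
    return ScoreVector(
        scores=scores, predicted_class=np.asarray(predicted_class),
        feature_ranking=ranking, cell_ids=cell_ids,
    )
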