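"""Design matrix assembly and nested cross-validated tree-ensemble fits.

The design matrix stacks latent abundance dimensions, encoded sample-level
covariates, and latent-by-covariate interaction products; the target is
each cell's sample-level clinical phenotype.  Models are tuned by
randomized search inside a nested, repeated cross-validation whose folds
group all cells of a sample together (blocking leakage between a sample's
cells) while stratifying on class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import (
    ParameterSampler,
    StratifiedGroupKFold,
    StratifiedKFold,
    train_test_split,
)

from .embedding import LatentEmbedding

__all__ = ["DesignMatrix", "ModelConfig", "FitResult", "build_design", "nested_cv_fit", "predict"]

ROLE_LATENT = "latent"
ROLE_COVARIATE = "covariate"
ROLE_INTERACTION = "interaction"


@dataclass
class DesignMatrix:
    values: np.ndarray  # cells x p
    columns: list[str]
    roles: list[str]  # latent | covariate | interaction per column
    y: np.ndarray  # encoded target per cell
    class_names: list
    groups: np.ndarray | None = None  # sample id per cell, for grouped folds
    cell_ids: list | None = None

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.columns)


def _encode(series: pd.Series, name: str) -> np.ndarray:
    if pd.api.types.is_numeric_dtype(series):
        return series.to_numpy(dtype=float)
    levels = series.nunique()
    if levels > 20:
        raise ValueError(
            f"covariate {name!r} has {levels} non-numeric levels; looks like an id column"
        )
    codes, _ = pd.factorize(series, sort=True)
    return codes.astype(float)


def build_design(
    embedding: LatentEmbedding,
    covariates: pd.DataFrame | None,
    interaction_vars: Sequence[str],
    y_raw: Sequence,
    groups: Sequence | None = None,
) -> DesignMatrix:
    """Assemble latent dims + encoded covariates + interaction products.

    Categorical targets/covariates are label encoded; continuous
    interaction variables are z-scored (binary ones 0/1 encoded) before the
    elementwise product with every latent dimension.  Constant covariates
    are dropped with a warning.
    """
    scores = embedding.scores
    n, d = scores.shape
    y_arr = np.asarray(y_raw)
    if y_arr.shape[0] != n:
        raise ValueError("y length does not match number of cells")
    class_names, y = np.unique(y_arr, return_inverse=True)
    if class_names.size < 2:
        raise ValueError("need at least two classes in y")

    cols = list(embedding.dim_names)
    roles = [ROLE_LATENT] * d
    blocks = [scores]

    cov = covariates if covariates is not None else pd.DataFrame(index=range(n))
    if len(cov) != n:
        raise ValueError("covariate table does not align with cells")
    missing = [v for v in interaction_vars if v not in cov.columns]
    if missing:
        raise ValueError(f"interaction variables not in covariates: {missing}")

    encoded: dict[str, np.ndarray] = {}
    for name in cov.columns:
        values = _encode(cov[name], name)
        if np.nanstd(values) == 0:
            warnings.warn(f"covariate {name!r} is constant; dropped", stacklevel=2)
            continue
        encoded[name] = values
        cols.append(name)
        roles.append(ROLE_COVARIATE)
        blocks.append(values[:, None])

    for var in interaction_vars:
        if var not in encoded:
            raise ValueError(f"interaction variable {var!r} was dropped or missing")
        z = encoded[var]
        uniq = np.unique(z)
        if uniq.size == 2:
            # 0/1 dummy complementary to the main-effect dummy: the level
            # absorbed as the main effect's reference carries the 1 here,
            # so the interaction column is live exactly where the main
            # effect is silent instead of duplicating it
            v = (z == uniq.min()).astype(float)
        else:
            v = (z - z.mean()) / z.std()  # continuous -> z-score
        prod = scores * v[:, None]
        blocks.append(prod)
        for j in range(d):
            cols.append(f"{embedding.dim_names[j]}:{var}")
            roles.append(ROLE_INTERACTION)

    values = np.column_stack(blocks) if blocks else np.empty((n, 0))
    grp = np.asarray(groups) if groups is not None else None
    if grp is not None and grp.shape[0] != n:
        raise ValueError("groups length does not match number of cells")
    return DesignMatrix(
        values=values, columns=cols, roles=roles, y=y,
        class_names=list(class_names), groups=grp, cell_ids=embedding.cell_ids,
    )


DEFAULT_FOREST_SPACE = {
    "n_estimators": [100, 200, 300, 400, 500],
    "max_depth": [None, 4, 6, 8, 10, 12, 14, 16],
    "min_samples_leaf": [1, 2, 3, 4, 5, 6, 7, 8, 9, 10],
    "max_features": ["sqrt", 0.3, 0.5, 0.7, 1.0],
}

DEFAULT_GBM_SPACE = {
    "n_estimators": [50, 100, 200],
    "max_depth": [2, 3, 4],
    "learning_rate": [0.03, 0.1, 0.3],
    "subsample": [0.7, 1.0],
}


@dataclass
class ModelConfig:
    family: str = "random_forest"  # random_forest | gradient_boosting
    search_space: dict | None = None
    n_outer_folds: int = 5
    n_inner_folds: int = 3
    n_repeats: int = 3
    search_budget: int = 20
    holdout_fraction: float = 0.2
    split_mode: str = "stratified_sample_grouped"  # or stratified_cell
    n_jobs: int = 1
    seed: int = 0

    def validate(self) -> None:
        if self.n_outer_folds < 2 or self.n_inner_folds < 2:
            raise ValueError("folds must be >= 2")
        if self.n_repeats < 1 or self.search_budget < 1:
            raise ValueError("repeats and search budget must be >= 1")
        if self.family not in ("random_forest", "gradient_boosting"):
            raise ValueError(f"unknown model family {self.family!r}")
        if self.split_mode not in ("stratified_sample_grouped", "stratified_cell"):
            raise ValueError(f"unknown split_mode {self.split_mode!r}")

    def space(self) -> dict:
        if self.search_space is not None:
            return self.search_space
        return DEFAULT_FOREST_SPACE if self.family == "random_forest" else DEFAULT_GBM_SPACE

    def make_estimator(self, params: dict, seed: int):
        if self.family == "random_forest":
            merged = {"n_estimators": 100, **params}
            return RandomForestClassifier(
                random_state=seed, n_jobs=self.n_jobs, **merged
            )
        return GradientBoostingClassifier(random_state=seed, **params)


@dataclass
class FitResult:
    models: list  # [repeat][outer_fold] fitted estimators
    chosen_params: list  # [repeat][outer_fold] dict
    classes_: list
    feature_names: list[str]
    fold_assignment: np.ndarray  # repeats x cells; outer test fold, -1 = holdout
    oof_proba: np.ndarray  # repeats x cells x classes (NaN on holdout rows)
    holdout_idx: np.ndarray
    holdout_proba: np.ndarray  # repeats x |holdout| x classes (mean over outer models)
    proba: np.ndarray  # cells x classes, combined across repeats
    y_pred: np.ndarray  # encoded predicted class per cell
    metrics: dict = field(default_factory=dict)
    config: ModelConfig | None = None


def _auroc(y_true: np.ndarray, proba: np.ndarray, n_classes: int) -> float:
    if len(np.unique(y_true)) < 2:
        return np.nan
    if n_classes == 2:
        return roc_auc_score(y_true, proba[:, 1])
    return roc_auc_score(
        y_true, proba, multi_class="ovr", average="macro", labels=np.arange(n_classes)
    )


def _auprc(y_true: np.ndarray, proba: np.ndarray, n_classes: int) -> dict:
    out = {}
    for c in range(n_classes):
        yc = (y_true == c).astype(int)
        out[c] = (
            float(average_precision_score(yc, proba[:, c])) if yc.min() != yc.max() else np.nan
        )
    return out


def _splitter(mode: str, n_splits: int, seed: int):
    if mode == "stratified_sample_grouped":
        return StratifiedGroupKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    return StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)


def _split(splitter, x, y, groups, mode):
    if mode == "stratified_sample_grouped":
        return list(splitter.split(x, y, groups))
    return list(splitter.split(x, y))


def nested_cv_fit(design: DesignMatrix, config: ModelConfig) -> FitResult:
    """Repeated nested CV with randomized hyperparameter search.

    A global grouped-stratified holdout (``holdout_fraction`` of samples)
    is carved out first and used only for final metrics.  Per repeat, the
    remaining cells get a stratified (sample-grouped) outer split; within
    each outer-train, a randomized search maximizes mean inner-fold AUROC;
    the best estimator is refit on outer-train and predicts the outer-test
    cells, so every CV cell receives an out-of-fold probability per repeat.
    """
    config.validate()
    x, y = design.values, design.y
    n = x.shape[0]
    n_classes = len(design.class_names)
    if n_classes < 2:
        raise ValueError("degenerate single-class target")
    grouped = config.split_mode == "stratified_sample_grouped"
    groups = design.groups
    if grouped and groups is None:
        raise ValueError("sample-grouped splitting requires design.groups")

    base = np.random.SeedSequence(config.seed).generate_state(8) % (2**31 - 1)

    # ----- global holdout ---------------------------------------------------
    if grouped:
        uniq, first = np.unique(groups, return_index=True)
        sample_class = y[first]
        counts = np.bincount(sample_class, minlength=n_classes)
        if (counts < 2).any():
            raise ValueError("every class needs >= 2 samples for stratified splits")
        tr_s, ho_s = train_test_split(
            uniq, test_size=config.holdout_fraction,
            stratify=sample_class, random_state=int(base[0]),
        )
        holdout_mask = np.isin(groups, ho_s)
    else:
        idx_all = np.arange(n)
        _, ho_i = train_test_split(
            idx_all, test_size=config.holdout_fraction,
            stratify=y, random_state=int(base[0]),
        )
        holdout_mask = np.zeros(n, dtype=bool)
        holdout_mask[ho_i] = True
    cv_idx = np.flatnonzero(~holdout_mask)
    ho_idx = np.flatnonzero(holdout_mask)
    if len(np.unique(y[cv_idx])) < 2 or len(np.unique(y[ho_idx])) < 2:
        raise ValueError("holdout split lost a class; reduce holdout_fraction")

    models, params_all = [], []
    fold_assign = np.full((config.n_repeats, n), -1, dtype=int)
    oof = np.full((config.n_repeats, n, n_classes), np.nan)
    ho_proba = np.zeros((config.n_repeats, ho_idx.size, n_classes))
    rep_metrics = []

    for r in range(config.n_repeats):
        rep_seed = int(base[1]) + 7919 * r
        outer = _splitter(config.split_mode, config.n_outer_folds, rep_seed)
        try:
            outer_folds = _split(
                outer, x[cv_idx], y[cv_idx],
                groups[cv_idx] if grouped else None, config.split_mode,
            )
        except ValueError as err:
            raise ValueError(
                f"outer split failed ({err}); try fewer folds"
            ) from err
        rep_models, rep_params = [], []
        ho_accum = np.zeros((ho_idx.size, n_classes))

        for f, (tr, te) in enumerate(outer_folds):
            tr_idx, te_idx = cv_idx[tr], cv_idx[te]
            if len(np.unique(y[te_idx])) < n_classes or len(np.unique(y[tr_idx])) < n_classes:
                raise ValueError(
                    f"outer fold {f} is missing a class; try fewer folds"
                )
            sampler = ParameterSampler(
                config.space(), n_iter=config.search_budget,
                random_state=rep_seed + 13 * f,
            )
            best_score, best_params = -np.inf, None
            for cand in sampler:
                inner = _splitter(config.split_mode, config.n_inner_folds, rep_seed + 1)
                try:
                    inner_folds = _split(
                        inner, x[tr_idx], y[tr_idx],
                        groups[tr_idx] if grouped else None, config.split_mode,
                    )
                except ValueError as err:
                    raise ValueError(
                        f"inner split failed ({err}); try fewer folds"
                    ) from err
                scores = []
                for itr, iva in inner_folds:
                    est = config.make_estimator(cand, seed=int(base[2]))
                    est.fit(x[tr_idx][itr], y[tr_idx][itr])
                    proba = est.predict_proba(x[tr_idx][iva])
                    auc = _auroc(y[tr_idx][iva], proba, n_classes)
                    if not np.isnan(auc):
                        scores.append(auc)
                score = float(np.mean(scores)) if scores else -np.inf
                if score > best_score:
                    best_score, best_params = score, cand
            est = config.make_estimator(best_params, seed=int(base[2]))
            est.fit(x[tr_idx], y[tr_idx])
            oof[r, te_idx] = est.predict_proba(x[te_idx])
            fold_assign[r, te_idx] = f
            ho_accum += est.predict_proba(x[ho_idx])
            rep_models.append(est)
            rep_params.append(dict(best_params))

        ho_proba[r] = ho_accum / len(outer_folds)
        models.append(rep_models)
        params_all.append(rep_params)
        rep_metrics.append(
            {
                "holdout_auroc": _auroc(y[ho_idx], ho_proba[r], n_classes),
                "holdout_auprc": _auprc(y[ho_idx], ho_proba[r], n_classes),
            }
        )

    with warnings.catch_warnings():
        # holdout rows are all-NaN across repeats and filled just below
        warnings.simplefilter("ignore", category=RuntimeWarning)
        proba = np.nanmean(oof, axis=0)
    proba[ho_idx] = ho_proba.mean(axis=0)
    y_pred = np.argmax(proba, axis=1)  # ties break toward the lower class index

    metrics = {
        "per_repeat": rep_metrics,
        "holdout_auroc": float(np.nanmean([m["holdout_auroc"] for m in rep_metrics])),
        "holdout_auprc": {
            c: float(np.nanmean([m["holdout_auprc"][c] for m in rep_metrics]))
            for c in range(n_classes)
        },
    }
    return FitResult(
        models=models, chosen_params=params_all, classes_=design.class_names,
        feature_names=list(design.columns), fold_assignment=fold_assign,
        oof_proba=oof, holdout_idx=ho_idx, holdout_proba=ho_proba,
        proba=proba, y_pred=y_pred, metrics=metrics, config=config,
    )


def predict(model, rows, feature_names: Sequence[str] | None = None):
    """Predicted class (argmax probability, ties toward the lower-indexed
    class) and per-class probabilities for new rows."""
    if isinstance(rows, pd.DataFrame):
        if feature_names is not None:
            missing = [c for c in feature_names if c not in rows.columns]
            if missing:
                raise ValueError(f"missing design columns: {missing}")
            rows = rows[list(feature_names)]
        x = rows.to_numpy(dtype=float)
    else:
        x = np.asarray(rows, dtype=float)
        if feature_names is not None and x.shape[1] != len(feature_names):
            raise ValueError(
                f"expected {len(feature_names)} columns, got {x.shape[1]}"
            )
    proba = model.predict_proba(x)
    return np.argmax(proba, axis=1), proba
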