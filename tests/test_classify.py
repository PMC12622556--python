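import numpy as np
import pandas as pd
import pytest

from phenoscore.classify import (
    ModelConfig,
    build_design,
    nested_cv_fit,
    predict,
)
from phenoscore.embedding import LatentEmbedding

from conftest import TINY_MODEL, make_blob_design


def embedding_of(scores):
    scores = np.asarray(scores, dtype=float)
    return LatentEmbedding(scores=scores, method="pca", d=scores.shape[1])


class TestBuildDesign:
    def test_no_covariates_reduces_to_plain_embedding(self):
        scores = np.random.default_rng(0).normal(size=(10, 3))
        d = build_design(embedding_of(scores), None, [], ["a", "b"] * 5)
        assert np.array_equal(d.values, scores)
        assert d.roles == ["latent"] * 3
        assert d.class_names == ["a", "b"]

    def test_interaction_columns_are_recomputable_products(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=(50, 3))
        age = rng.uniform(20, 80, size=50)
        cov = pd.DataFrame({"age": age})
        d = build_design(embedding_of(scores), cov, ["age"], ["x", "y"] * 25)
        assert len(d.columns) == 3 + 1 + 3
        z = (age - age.mean()) / age.std()
        for j in range(3):
            col = d.columns.index(f"LD{j + 1}:age")
            assert np.allclose(d.values[:, col], scores[:, j] * z)
        assert d.roles.count("interaction") == 3

    def test_covid_style_design_shape(self):
        # four covariates with age and sex as interaction variables
        rng = np.random.default_rng(2)
        n, dd = 40, 5
        cov = pd.DataFrame({
            "sex": rng.choice(["F", "M"], n),
            "age": rng.uniform(20, 80, n),
            "days_from_onset": rng.integers(0, 30, n).astype(float),
            "smoking": rng.choice(["no", "yes"], n),
        })
        d = build_design(
            embedding_of(rng.normal(size=(n, dd))), cov, ["age", "sex"],
            rng.choice(["healthy", "mild", "moderate"], n),
        )
        assert len(d.columns) == dd + 4 + 2 * dd
        assert len(d.class_names) == 3

    def test_binary_interaction_uses_complementary_dummy(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=(20, 2))
        cov = pd.DataFrame({"sex": ["F", "M"] * 10})
        d = build_design(embedding_of(scores), cov, ["sex"], ["a", "b"] * 10)
        sex_col = d.values[:, d.columns.index("sex")]
        inter = d.values[:, d.columns.index("LD1:sex")]
        # main effect codes M as 1; the interaction dummy is live for F
        assert np.allclose(sex_col, np.tile([0.0, 1.0], 10))
        assert np.allclose(inter, scores[:, 0] * np.tile([1.0, 0.0], 10))

    def test_suspect_id_column_rejected_and_constant_dropped(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=(30, 2))
        ids = pd.DataFrame({"cell": [f"c{i}" for i in range(30)]})
        with pytest.raises(ValueError, match="id column"):
            build_design(embedding_of(scores), ids, [], ["a", "b"] * 15)
        const = pd.DataFrame({"flat": [1.0] * 30})
        with pytest.warns(UserWarning, match="constant"):
            d = build_design(embedding_of(scores), const, [], ["a", "b"] * 15)
        assert "flat" not in d.columns


class TestNestedCv:
    def test_separable_blobs_reach_perfect_holdout_auroc(self, blob_fit):
        _, fit = blob_fit
        assert fit.metrics["holdout_auroc"] == pytest.approx(1.0, abs=1e-9)

    def test_every_cv_cell_in_exactly_one_outer_fold(self, blob_fit):
        design, fit = blob_fit
        n = design.n_cells
        cv_mask = ~np.isin(np.arange(n), fit.holdout_idx)
        for r in range(fit.fold_assignment.shape[0]):
            assert (fit.fold_assignment[r, cv_mask] >= 0).all()
            assert (fit.fold_assignment[r, ~cv_mask] == -1).all()

    def test_probabilities_sum_to_one_for_every_cell(self, blob_fit):
        _, fit = blob_fit
        assert np.allclose(fit.proba.sum(axis=1), 1.0, atol=1e-9)

    def test_groups_never_straddle_folds(self, blob_fit):
        design, fit = blob_fit
        df = pd.DataFrame({"g": design.groups, "f": fit.fold_assignment[0]})
        assert (df.groupby("g")["f"].nunique() == 1).all()

    def test_fold_class_shares_close_to_global(self):
        design = make_blob_design(n_per_sample=20, n_samples=60, seed=3)
        fit = nested_cv_fit(design, ModelConfig(seed=3, **TINY_MODEL))
        global_share = design.y.mean()
        for r in range(fit.fold_assignment.shape[0]):
            for f in np.unique(fit.fold_assignment[r]):
                if f < 0:
                    continue
                share = design.y[fit.fold_assignment[r] == f].mean()
                assert abs(share - global_share) <= 0.05

    def test_label_permutation_yields_chance_auroc(self):
        design = make_blob_design(
            n_per_sample=100, n_samples=20, seed=5, shuffle_y=True, separation=0.0
        )
        fit = nested_cv_fit(design, ModelConfig(seed=5, **TINY_MODEL))
        assert fit.metrics["holdout_auroc"] == pytest.approx(0.5, abs=0.25)

    def test_identical_seed_reproduces_everything(self):
        design = make_blob_design(seed=7)
        cfg = ModelConfig(seed=7, **TINY_MODEL)
        a = nested_cv_fit(design, cfg)
        b = nested_cv_fit(design, cfg)
        assert np.array_equal(a.fold_assignment, b.fold_assignment)
        assert a.chosen_params == b.chosen_params
        assert np.array_equal(a.proba, b.proba)

    def test_single_class_target_rejected(self):
        design = make_blob_design(seed=8)
        design.y = np.zeros_like(design.y)
        with pytest.raises(ValueError):
            nested_cv_fit(design, ModelConfig(seed=8, **TINY_MODEL))


class TestPredict:
    def test_majority_vote_matches_per_tree_hand_count(self):
        from sklearn.ensemble import RandomForestClassifier

        rng = np.random.default_rng(9)
        x = np.vstack([rng.normal(-3, 0.2, (30, 2)), rng.normal(3, 0.2, (30, 2))])
        y = np.array([0] * 30 + [1] * 30)
        m = RandomForestClassifier(n_estimators=3, random_state=0).fit(x, y)
        pred, proba = predict(m, x)
        votes = np.stack([t.predict(x) for t in m.estimators_])
        hand = (votes.mean(axis=0) > 0.5).astype(int)
        assert np.array_equal(pred, hand)
        assert np.allclose(proba.sum(axis=1), 1.0)

    def test_single_tree_forest_follows_its_tree(self):
        from sklearn.ensemble import RandomForestClassifier

        rng = np.random.default_rng(10)
        x = rng.normal(size=(40, 3))
        y = (x[:, 0] > 0).astype(int)
        m = RandomForestClassifier(n_estimators=1, bootstrap=False, random_state=0).fit(x, y)
        pred, _ = predict(m, x)
        assert np.array_equal(pred, m.estimators_[0].predict(x).astype(int))

    def test_missing_columns_reported(self, blob_fit):
        _, fit = blob_fit
        rows = pd.DataFrame({"LD1": [0.0], "LD2": [0.0]})
        with pytest.raises(ValueError, match="LD3"):
            predict(fit.models[0][0], rows, feature_names=fit.feature_names)


class TestInteractionBenefit:
    def test_interaction_columns_elevate_expanded_population_scores(self):
        """On a sex-by-disease abundance interaction, explicit latent-by-sex
        interaction columns should raise the scores of the female-expanded
        populations without materially degrading discriminative power."""
        from phenoscore import RunConfig, preset, run_analysis, simulate_dataset

        auroc_deltas = []
        for seed in (0, 1):
            ds = simulate_dataset(preset("interaction", cells_per_cluster=20, seed=seed))
            meta = ds.cell_meta
            expanded = (meta["sex"] == "F") & meta["cluster"].isin(["B", "J"])
            base_kw = dict(seed=seed, ve_threshold=None, covariates=("sex",))
            with_int = run_analysis(
                ds.expression, meta,
                RunConfig(model=ModelConfig(seed=seed, **TINY_MODEL),
                          interactions=("sex",), **base_kw),
            )
            without = run_analysis(
                ds.expression, meta,
                RunConfig(model=ModelConfig(seed=seed, **TINY_MODEL), **base_kw),
            )
            assert (
                with_int.score.scores[expanded].mean()
                > without.score.scores[expanded].mean()
            )
            auroc_deltas.append(
                with_int.fit.metrics["holdout_auroc"]
                - without.fit.metrics["holdout_auroc"]
            )
        assert np.mean(auroc_deltas) >= -0.05
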