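import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestClassifier

from phenoscore.attribution import (
    AttributionTensor,
    average_over_repeats,
    collapse_multiclass,
    compute_attributions,
    interpretable_score,
    tree_shap,
)

from _oracles import shap_bruteforce


def toy_forest(n_features=5, n_classes=2, depth=3, trees=3, seed=0, n=80):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, n_features))
    if n_classes == 2:
        y = (x[:, 0] + x[:, 1] * x[:, 2] > 0).astype(int)
    else:
        y = np.digitize(x[:, 0], [-0.5, 0.5])
    m = RandomForestClassifier(n_estimators=trees, max_depth=depth, random_state=seed)
    return m.fit(x, y), x


class TestTreeShap:
    @pytest.mark.parametrize("n_features", [5, 12])
    def test_matches_bruteforce_subset_enumeration(self, n_features):
        model, x = toy_forest(n_features=n_features, depth=3, trees=3, seed=1)
        rows = x[:2]
        phi, base = tree_shap(model, rows)
        for i in range(len(rows)):
            oracle = shap_bruteforce(model, rows[i], n_features)
            assert np.allclose(phi[i], oracle, atol=1e-8)

    def test_additivity_reproduces_probabilities(self):
        model, x = toy_forest(n_features=8, depth=None, trees=20, seed=2, n=300)
        phi, base = tree_shap(model, x[:50])
        proba = model.predict_proba(x[:50])
        assert np.allclose(base + phi.sum(axis=1), proba, atol=1e-6)

    def test_constant_model_attributes_nothing(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(50, 4))
        y = rng.integers(0, 2, size=50)
        # impurity bar high enough that no split is made: single-leaf trees
        m = RandomForestClassifier(
            n_estimators=5, min_impurity_decrease=10.0, random_state=0
        ).fit(x, y)
        phi, base = tree_shap(m, x[:10])
        assert np.allclose(phi, 0.0)
        assert np.allclose(base, m.predict_proba(x[:1])[0], atol=1e-12)

    def test_multiclass_output_shape(self):
        model, x = toy_forest(n_classes=3, seed=4)
        phi, base = tree_shap(model, x[:7])
        assert phi.shape == (7, 5, 3)
        assert base.shape == (3,)
        assert np.allclose(base.sum(), 1.0, atol=1e-9)

    def test_non_tree_model_rejected(self):
        from sklearn.linear_model import LogisticRegression

        rng = np.random.default_rng(5)
        x = rng.normal(size=(30, 3))
        m = LogisticRegression().fit(x, (x[:, 0] > 0).astype(int))
        with pytest.raises(TypeError, match="tree"):
            tree_shap(m, x)


class TestAveraging:
    def test_single_repeat_is_identity(self):
        vals = np.random.default_rng(0).normal(size=(1, 4, 3, 2))
        t = AttributionTensor(vals, np.zeros((1, 2)), [f"f{i}" for i in range(3)])
        assert np.array_equal(average_over_repeats(t), vals[0])

    def test_two_repeats_average_elementwise(self):
        vals = np.zeros((2, 1, 1, 1))
        vals[0, 0, 0, 0] = 0.2
        vals[1, 0, 0, 0] = 0.4
        t = AttributionTensor(vals, np.zeros((2, 1)), ["f0"])
        assert average_over_repeats(t)[0, 0, 0] == pytest.approx(0.3)

    def test_shape_preserved_and_missing_cells_rejected(self):
        vals = np.random.default_rng(1).normal(size=(3, 5, 4, 2))
        t = AttributionTensor(vals, np.zeros((3, 2)), [f"f{i}" for i in range(4)])
        assert average_over_repeats(t).shape == (5, 4, 2)
        vals[:, 2] = np.nan
        with pytest.raises(ValueError, match="zero repeats"):
            average_over_repeats(t)


class TestCollapse:
    def test_binary_uses_positive_class_slice(self):
        s = np.random.default_rng(0).normal(size=(6, 3, 2))
        s[:, :, 0] = -s[:, :, 1]  # anti-symmetric class slices
        out = collapse_multiclass(s, np.array([0, 1] * 3))
        assert np.array_equal(out, s[:, :, 1])

    def test_multiclass_literal_matches_direct_indexing(self):
        s = np.random.default_rng(1).normal(size=(5, 4, 3))
        pred = np.array([0, 2, 1, 2, 0])
        out = collapse_multiclass(s, pred, mode="literal")
        for i in range(5):
            assert np.array_equal(out[i], s[i, :, pred[i]])
        assert out.shape == (5, 4)  # one value per cell per feature

    def test_invalid_predictions_rejected(self):
        s = np.zeros((3, 2, 2))
        with pytest.raises(ValueError, match="class range"):
            collapse_multiclass(s, np.array([0, 1, 5]), mode="literal")


class TestInterpretableScore:
    def test_single_feature_score_is_that_attribution(self):
        sv = interpretable_score(np.array([[0.7], [-0.2]]))
        assert np.allclose(sv.scores, [0.7, -0.2])

    def test_row_sum_identity(self):
        collapsed = np.array([[0.1, -0.05, 0.2]])
        sv = interpretable_score(collapsed)
        assert sv.scores[0] == pytest.approx(0.25)

    def test_latent_only_restricts_columns(self):
        collapsed = np.array([[0.1, 0.5], [0.2, -0.5]])
        sv = interpretable_score(
            collapsed, feature_names=["LD1", "LD1:sex"],
            roles=["latent", "interaction"], columns="latent_only",
        )
        assert np.allclose(sv.scores, [0.1, 0.2])

    def test_ranking_orders_by_mean_abs_attribution(self):
        collapsed = np.array([[0.1, -0.9, 0.3], [0.2, 0.8, -0.3]])
        sv = interpretable_score(collapsed, feature_names=["a", "b", "c"])
        assert sv.feature_ranking["feature"].tolist() == ["b", "c", "a"]

    def test_cumulative_top_k_partial_scores_reconstruct_total(self):
        rng = np.random.default_rng(2)
        collapsed = rng.normal(size=(20, 5))
        sv = interpretable_score(collapsed, feature_names=[f"f{i}" for i in range(5)])
        ranked = sv.feature_ranking["feature"].tolist()
        names = [f"f{i}" for i in range(5)]
        partial = np.zeros(20)
        for k, feat in enumerate(ranked, start=1):
            partial += collapsed[:, names.index(feat)]
        assert np.allclose(partial, sv.scores, atol=1e-12)


class TestEndToEnd:
    def test_score_equals_probability_shift_in_binary_mode(self, blob_fit):
        design, fit = blob_fit
        tensor = compute_attributions(fit, design)
        s_bar = average_over_repeats(tensor)
        collapsed = collapse_multiclass(s_bar, fit.y_pred)
        sv = interpretable_score(collapsed, fit.feature_names, fit.y_pred)
        # per repeat, base + row-sum reproduces the attributing model's
        # positive-class probability; averaging preserves the identity
        for r in range(tensor.n_repeats):
            psi_r = tensor.values[r, :, :, 1].sum(axis=1)
            fold_of = fit.fold_assignment[r]
            for f, model in enumerate(fit.models[r]):
                rows = np.flatnonzero(fold_of == f)
                proba = model.predict_proba(design.values[rows])[:, 1]
                base_r = tree_shap(model, design.values[:1])[1][1]
                assert np.allclose(psi_r[rows], proba - base_r, atol=1e-6)
        assert np.allclose(sv.scores, collapsed.sum(axis=1), atol=1e-12)

    def test_every_cell_attributed_in_every_repeat(self, blob_fit):
        design, fit = blob_fit
        tensor = compute_attributions(fit, design)
        assert not np.isnan(tensor.values).any()
        assert tensor.values.shape == (
            len(fit.models), design.n_cells, len(fit.feature_names), 2,
        )
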