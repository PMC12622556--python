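import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import silhouette_score

from phenoscore.simulate import (
    SimulationConfig,
    compose_feature,
    plan_abundance,
    preset,
    sample_factor_signal,
    simulate_dataset,
    subject_table,
)


def realized_ratio(plan, cluster):
    pivot = plan.pivot_table(
        index=["subject_id", "condition"], columns="cluster",
        values="n_cells", aggfunc="sum",
    )
    prop = pivot.div(pivot.sum(axis=1), axis=0)
    grp = prop.groupby(level="condition").mean()
    return grp.loc["disease", cluster] / grp.loc["control", cluster]


class TestPlanAbundance:
    def test_unit_fold_change_leaves_counts_unchanged(self):
        cfg = SimulationConfig(fold_changes={"A": 1.0, "J": 1.0}, seed=0)
        plan = plan_abundance(cfg)
        wide = plan.pivot_table(index="condition", columns="cluster",
                                values="n_cells", aggfunc="mean")
        assert np.array_equal(wide.loc["disease"].to_numpy(),
                              wide.loc["control"].to_numpy())

    def test_single_expanded_cluster_realizes_exact_proportion_ratio(self):
        # one cluster at baseline share 0.1 expanded threefold: the
        # disease:control within-sample proportion ratio must equal 3
        cfg = SimulationConfig(fold_changes={"A": 3.0}, cells_per_cluster=100, seed=0)
        plan = plan_abundance(cfg)
        assert realized_ratio(plan, "A") == pytest.approx(3.0, abs=0.02)

    def test_dataset1_preset_ratio_stable_over_seeds(self):
        ratios = []
        for seed in range(10):
            plan = plan_abundance(preset("dataset1", cells_per_cluster=50, seed=seed))
            ratios.append(realized_ratio(plan, "A"))
            ratios.append(realized_ratio(plan, "J"))
        assert np.mean(ratios) == pytest.approx(3.0, abs=0.3)

    def test_interaction_stratum_restricts_shift_to_female_disease(self):
        cfg = preset("interaction", cells_per_cluster=40)
        subjects = subject_table(cfg)
        plan = plan_abundance(cfg, subjects).merge(subjects, on=["subject_id", "condition"])
        base_b = plan.query("condition == 'control' and cluster == 'B'")["n_cells"].iloc[0]
        male_b = plan.query("condition == 'disease' and sex == 'M' and cluster == 'B'")
        fem_b = plan.query("condition == 'disease' and sex == 'F' and cluster == 'B'")
        assert (male_b["n_cells"] == base_b).all()
        assert (fem_b["n_cells"] > 2 * base_b).all()

    def test_invalid_fold_changes_rejected(self):
        with pytest.raises(ValueError, match="> 0"):
            plan_abundance(SimulationConfig(fold_changes={"A": -1.0}))
        with pytest.raises(ValueError, match="zero baseline"):
            plan_abundance(
                SimulationConfig(
                    clusters=("A", "B"),
                    cluster_proportions=(0.0, 1.0),
                    fold_changes={"A": 2.0},
                )
            )
        with pytest.raises(ValueError, match="not in clusters"):
            SimulationConfig(fold_changes={"Z": 2.0}).validate()


class TestFactorSignal:
    def test_balanced_two_level_signal_standardizes_to_unit_levels(self):
        labels = ["lo"] * 500 + ["hi"] * 500
        s = sample_factor_signal(labels, {"lo": 0.0, "hi": 10.0}, 0.1, rng=0)
        assert s.mean() == pytest.approx(0.0, abs=1e-12)
        assert s.std() == pytest.approx(1.0, abs=1e-12)
        assert s[:500].mean() == pytest.approx(-1.0, abs=0.05)
        assert s[500:].mean() == pytest.approx(1.0, abs=0.05)

    def test_single_level_yields_standardized_noise(self):
        s = sample_factor_signal(["only"] * 1000, {"only": 5.0}, 1.0, rng=3)
        assert s.mean() == pytest.approx(0.0, abs=1e-12)
        assert s.var() == pytest.approx(1.0, abs=1e-12)

    def test_fixed_seed_reproduces_bytes(self):
        labels = ["a", "b"] * 50
        means = {"a": 0.0, "b": 1.0}
        s1 = sample_factor_signal(labels, means, 0.5, rng=11)
        s2 = sample_factor_signal(labels, means, 0.5, rng=11)
        assert s1.tobytes() == s2.tobytes()

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="two cells"):
            sample_factor_signal(["x"], {"x": 0.0}, 1.0, rng=0)
        with pytest.raises(ValueError, match="zero variance.*batch"):
            sample_factor_signal(["x"] * 10, {"x": 0.0}, 0.0, rng=0, name="batch")


class TestComposeFeature:
    def test_single_factor_identity_up_to_rescale(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=500)
        s = (s - s.mean()) / s.std()
        x = compose_feature({"f": s}, {"f": 1.0}, 0.0, rng=1)
        assert np.allclose(x, s, atol=1e-12)

    def test_variance_explained_matches_squared_weight(self):
        # weights (0.6, 0.8) normalize to unit sum of squares, so the
        # factor should explain 0.36 of the feature's variance
        rng = np.random.default_rng(5)
        n = 10_000
        s = rng.normal(size=n)
        s = (s - s.mean()) / s.std()
        x = compose_feature({"disease": s}, {"disease": 0.6}, 0.8, rng=rng)
        assert x.var() == pytest.approx(1.0, abs=1e-12)
        r2 = np.corrcoef(x, s)[0, 1] ** 2
        assert r2 == pytest.approx(0.36, abs=0.03)

    def test_interaction_term_uncorrelated_with_main_factors(self):
        rng = np.random.default_rng(6)
        n = 10_000
        a = np.where(rng.random(n) < 0.5, -1.0, 1.0)
        b = np.where(rng.random(n) < 0.5, -1.0, 1.0)
        a = (a - a.mean()) / a.std()
        b = (b - b.mean()) / b.std()
        x = compose_feature(
            {"disease": a, "sex": b},
            {"disease": 0.0, "sex": 0.0},
            0.3,
            interaction_weights=[("disease", "sex", 0.9)],
            rng=rng,
        )
        assert abs(np.corrcoef(x, a * b)[0, 1]) > 0.8
        assert abs(np.corrcoef(x, a)[0, 1]) < 0.05
        assert abs(np.corrcoef(x, b)[0, 1]) < 0.05

    def test_invalid_weights_and_lengths_rejected(self):
        s = np.linspace(-1, 1, 10)
        with pytest.raises(ValueError, match="negative"):
            compose_feature({"f": s}, {"f": -0.5}, 0.5, rng=0)
        with pytest.raises(ValueError, match="mismatched"):
            compose_feature({"f": s, "g": s[:5]}, {"f": 0.5, "g": 0.5}, 0.0, rng=0)


class TestSimulateDataset:
    def test_weight_normalization_is_exact(self):
        cfg = preset("dataset1")
        total = sum(w**2 for w in cfg.factor_weights.values()) + cfg.noise_weight**2
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_dataset1_preset_cohort_shape(self):
        cfg = preset("dataset1")
        assert cfg.n_subjects_per_group == 15
        assert cfg.clusters == tuple("ABCDEFGHIJ")
        plan = plan_abundance(cfg)
        control = plan.query("condition == 'control'")
        assert (control["n_cells"] == 100).all()
        assert plan["subject_id"].nunique() == 30

    def test_columns_standardized_and_cells_unique(self, small_dataset):
        x = small_dataset.expression
        assert np.allclose(x.mean(axis=0), 0.0, atol=0.05)
        assert np.allclose(x.var(axis=0), 1.0, atol=0.05)
        meta = small_dataset.cell_meta
        assert meta["cell_id"].is_unique
        assert (meta.groupby("subject_id")["condition"].nunique() == 1).all()

    def test_truth_flags_mark_expanded_disease_cells(self, small_dataset):
        meta = small_dataset.cell_meta
        flagged = meta[meta["truth_flag"]]
        assert set(flagged["cluster"]) == {"A", "J"}
        assert set(flagged["condition"]) == {"disease"}
        assert (meta.loc[~meta["truth_flag"], "truth_direction"] == 0).all()

    def test_interaction_preset_rare_clusters_at_five_percent(self):
        cfg = preset("interaction")
        assert cfg.proportions[-2:] == pytest.approx([0.05, 0.05])
        plan = plan_abundance(cfg)
        control = plan.query("condition == 'control'")
        shares = control.groupby("cluster")["n_cells"].sum()
        shares = shares / shares.sum()
        assert shares["I"] == pytest.approx(0.05, abs=0.005)
        assert shares["J"] == pytest.approx(0.05, abs=0.005)

    def test_pure_noise_features_carry_no_cluster_structure(self):
        cfg = SimulationConfig(
            n_subjects_per_group=4, cells_per_cluster=20,
            clusters=tuple("ABCD"), variance_fractions={}, n_features=10, seed=3,
        )
        ds = simulate_dataset(cfg)
        s = silhouette_score(ds.expression, ds.cell_meta["cluster"])
        assert abs(s) < 0.02

    def test_identical_config_reproduces_dataset(self):
        cfg = preset("dataset1", cells_per_cluster=5, n_subjects_per_group=3, seed=9)
        a = simulate_dataset(cfg)
        b = simulate_dataset(cfg)
        assert a.expression.tobytes() == b.expression.tobytes()
        assert a.cell_meta.equals(b.cell_meta)


class TestPresets:
    def test_dataset2_keeps_raw_weak_parameter(self):
        cfg = preset("dataset2")
        assert cfg.fold_changes["A"] == pytest.approx(0.1)
        assert cfg.realized_ratio("A") == pytest.approx(1.1)

    def test_unknown_preset_lists_valid_names(self):
        with pytest.raises(ValueError, match="dataset1, dataset2, interaction"):
            preset("nope")
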