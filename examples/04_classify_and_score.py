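"""Full run: classify disease status and compute per-cell scores.

Simulates a small disease-control cohort, runs the end-to-end pipeline,
and shows that only the disease-expanded clusters score positive.
"""

from phenoscore import ModelConfig, RunConfig, preset, run_analysis, simulate_dataset

ds = simulate_dataset(preset("dataset1", cells_per_cluster=20,
                             n_subjects_per_group=10, seed=4))
cfg = RunConfig(
    seed=4, ve_threshold=None,
    model=ModelConfig(
        seed=4, n_outer_folds=3, n_inner_folds=2, n_repeats=2, search_budget=2,
        search_space={"n_estimators": [50], "max_depth": [4, 6],
                      "min_samples_leaf": [2]},
    ),
)
res = run_analysis(ds.expression, ds.cell_meta, cfg)

print("holdout AUROC:", round(res.fit.metrics["holdout_auroc"], 3))
print("\nper-cluster mean Interpretable Score (A and J are expanded):")
print(res.detection.per_cluster_mean_score.round(3).to_string())
print("\nper-cluster detection accuracy vs simulated truth:")
print(res.detection.per_cluster.round(3).to_string())
print("median:", round(res.detection.median, 3))
print("\ntop features by mean |SHAP|:")
print(res.score.feature_ranking.head(5).to_string(index=False))
# positive scores mark cells whose neighborhoods push the classifier
# toward "disease"; the ranking shows which latent dims drive it
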