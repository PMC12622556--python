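"""Simulate a disease-control cohort with controlled differential abundance.

Generates the dataset1 scenario (15+15 subjects, 10 clusters, clusters A
and J expanded 3-fold in disease) and verifies the realized abundance.
"""

from phenoscore import plan_abundance, preset, simulate_dataset

cfg = preset("dataset1", seed=7)
ds = simulate_dataset(cfg)
print(f"{ds.n_cells} cells, {ds.expression.shape[1]} features")
print(ds.cell_meta.head())

plan = plan_abundance(cfg)
pivot = plan.pivot_table(index=["subject_id", "condition"], columns="cluster",
                         values="n_cells", aggfunc="sum")
prop = pivot.div(pivot.sum(axis=1), axis=0).groupby(level="condition").mean()
ratio = prop.loc["disease"] / prop.loc["control"]
print("\ndisease:control proportion ratio per cluster:")
print(ratio.round(2).to_string())
# A and J sit at 3.0 (the configured fold change); the untargeted
# clusters are diluted to 0.5 because proportions must sum to one.
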