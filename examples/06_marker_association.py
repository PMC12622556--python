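"""Correlate feature expression with the Interpretable Score.

Markers whose expression tracks the score (BH-adjusted p < 0.05) point
at the molecular programs of the condition-associated populations.
"""

import numpy as np

from phenoscore import (
    cluster_score_summary,
    marker_score_correlation,
    preset,
    simulate_dataset,
)

ds = simulate_dataset(preset("dataset1", cells_per_cluster=15,
                             n_subjects_per_group=6, seed=6))
# stand-in score: positive in the expanded clusters, as the pipeline produces
rng = np.random.default_rng(0)
psi = np.where(ds.cell_meta["cluster"].isin(["A", "J"]), 0.3, -0.2)
psi = psi + rng.normal(scale=0.1, size=len(psi))

table = marker_score_correlation(ds.expression, psi,
                                 feature_names=ds.feature_names)
sig = table[table["p_adj"] < 0.05]
print(f"{len(sig)} of {len(table)} features significant at adjusted p < 0.05")
print(sig.head(5).round(4).to_string(index=False))

summary, tests = cluster_score_summary(psi, ds.cell_meta["cluster"])
print(f"\ntop-scoring cluster: {tests['top_cluster']} "
      f"(vs rest, Wilcoxon p = {tests['top_cluster_p']:.2e})")
print(f"global {tests['global_test']} p = {tests['global_p']:.2e}")
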