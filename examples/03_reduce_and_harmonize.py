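"""Reduce the NAM to latent dimensions (PCA or NMF) and harmonize.

PCA keeps the top orthogonal variance directions; NMF learns
non-negative topics with a silhouette-selected rank; harmonization
removes sample-specific structure from the per-cell scores.
"""

from phenoscore import (
    build_knn_graph,
    build_nam,
    harmonize,
    preset,
    reduce_nmf,
    reduce_pca,
    select_nmf_rank,
    simulate_dataset,
)
from phenoscore.pipeline import embed_cells

ds = simulate_dataset(preset("dataset1", cells_per_cluster=15,
                             n_subjects_per_group=6, seed=2))
nam = build_nam(
    build_knn_graph(embed_cells(ds.expression, 30), k=20),
    ds.cell_meta["subject_id"].to_numpy(), s=3,
)

pca = reduce_pca(nam, n_init=100, n_keep=20, ve_threshold=None)
print(f"PCA: {pca.d} dims; variance explained by first 3:",
      pca.variance_explained[:3].round(3))

k = select_nmf_rank(nam, [2, 3, 4, 5], seed=0)
nmf = reduce_nmf(nam, k, seed=0)
print(f"NMF: silhouette-selected rank {k}; scores are non-negative:",
      bool((nmf.scores >= 0).all()))

adj = harmonize(pca, ds.cell_meta[["subject_id"]])
print("harmonized over:", adj.removed_covariates,
      "| shape unchanged:", adj.scores.shape == pca.scores.shape)
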