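# phenoscore

Explainable per-cell scoring of clinical phenotypes from single-cell
neighborhood abundance.

Multi-sample single-cell studies ask which cell populations shift with a
clinical outcome — disease vs control, inflamed vs non-inflamed,
responder vs non-responder.  Cluster-free differential-abundance tools
answer with statistical associations; `phenoscore` instead trains a
classifier to *predict* the outcome and uses exact Shapley attributions
to say, cell by cell, how much each cell's neighborhood contributes to
that prediction — including contributions from covariates and
condition-by-covariate interactions (e.g. sex- or age-dependent shifts)
that linear frameworks miss.

## Method in brief

1. **Neighborhood abundance.** Build a kNN graph on the cell embedding;
   with an s-step random walk, `Q[n, m]` is the row-normalized expected
   mass of sample *n*'s cells reaching the neighborhood anchored at cell
   *m*:  `R[n,m] = Σ_{m'∈C(n)} P(m'→m)`, `Q = row-normalize(R)`.
2. **Latent dims.** Reduce `Q` by PCA (top 20 of 100) or NMF (rank by
   silhouette); harmonize sample/batch structure out of the per-cell
   scores `X_i` (never age or sex).
3. **Classification.** Predictors `β = X_i + γ + X_i·δ` (latent dims,
   encoded covariates, latent-by-covariate products); nested, repeated,
   sample-grouped stratified cross-validation with randomized
   hyperparameter search over tree ensembles; metrics on a held-out
   sample set.
4. **Attribution.** Exact tree Shapley values `φ` on probability
   outputs (path-dependent conditional expectations), averaged over CV
   repeats, collapsed to one value per cell per feature.
5. **Interpretable Score.** `ψ_m = Σ_i φ_{m,i}` — each cell's summed
   contribution toward the predicted clinical class, plus a mean-|SHAP|
   feature ranking, marker–score correlations (BH-adjusted), per-cluster
   summaries and detection reports against simulated ground truth.

A Gaussian variance-partition simulator generates multi-sample cohorts
with controlled per-factor variance fractions (`VE_f = w_f²`,
`Σw² = 1`), fold-change-driven differential cluster abundance (realized
as proportion ratios), rare clusters, and sex-by-disease abundance
interactions — so the whole pipeline is testable offline.  See
`docs/methods.md` for models, defaults and limitations.

## Worked example

```python
import numpy as np
from phenoscore import preset, simulate_dataset, RunConfig, ModelConfig, run_analysis

ds = simulate_dataset(preset("dataset1", cells_per_cluster=25, seed=11))
cfg = RunConfig(
    seed=11, ve_threshold=None,
    model=ModelConfig(
        seed=11, n_outer_folds=3, n_inner_folds=2, n_repeats=2, search_budget=4,
        search_space={"n_estimators": [50], "max_depth": [4, 6],
                      "min_samples_leaf": [2, 5], "max_features": ["sqrt", 0.5]},
    ),
)
res = run_analysis(ds.expression, ds.cell_meta, cfg)
print("holdout AUROC:", round(res.fit.metrics["holdout_auroc"], 3))
print("median proportion correct:", round(res.detection.median, 3))
print(res.detection.per_cluster_mean_score.round(3).to_dict())
```

prints (single CPU, ~20 s):

```
holdout AUROC: 0.678
median proportion correct: 0.994
{'A': 0.141, 'B': -0.133, 'C': -0.126, 'D': -0.125, 'E': -0.126,
 'F': -0.128, 'G': -0.13, 'H': -0.125, 'I': -0.129, 'J': 0.141}
```

The two clusters simulated as disease-expanded (A and J, 3-fold
proportion ratio) are the only ones with positive mean Interpretable
Scores — their neighborhoods push the classifier toward "disease" —
while the relatively diluted clusters score negative; the per-cluster
detection accuracy against the simulator's truth flags has median 0.994.
Sample-level AUROC is moderate because only two of ten clusters carry
any condition signal.

`examples/` contains one short script per capability (simulation, NAM,
embedding choice, classification + attribution, interaction effects,
marker association).  A thin CLI mirrors the stages:

```bash
phenoscore simulate --preset dataset1 --seed 7 --out data/
phenoscore run --expression data/expression.mtx --metadata data/metadata.tsv --out out/
```

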