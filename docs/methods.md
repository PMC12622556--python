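# Methods

`phenoscore` scores every cell in a multi-sample single-cell study by how
much it contributes to a classifier's prediction of a sample-level
clinical phenotype.  The pipeline has five stages; this note records the
model behind each stage, the defaults and why, and what the bundled
simulator does and does not emulate.

## 1. Neighborhood abundance

Cells are embedded (top principal components of the normalized expression
matrix, default 30 dims) and connected in a k-nearest-neighbor graph
(default k = 30, union-symmetrized, binary edge weights, no self-loops).
Row-normalizing the adjacency gives a random-walk transition matrix
`A-hat`; the probability that an s-step walk from cell m' ends at cell m
is `(A-hat^s)[m', m]` (default s = 3).  For samples n = 1..N,

    R[n, m] = sum_{m' in C(n)} P(m' -> m),   Q[n, m] = R[n, m] / sum_m R[n, m]

where `C(n)` is sample n's cell set.  `R` is computed by propagating the
N x M sample-indicator matrix through s sparse products — the dense M x M
walk matrix is never formed — and conserves mass: row n of `R` sums to
|C(n)| exactly.  `Q` (the neighborhood abundance matrix, NAM) is
row-stochastic; neighborhoods are anchored at cells, one per cell.

k, s, the graph representation and edge weighting are configuration with
these documented defaults; none is canonical in the literature.

## 2. Latent embedding and harmonization

PCA: column-centered SVD of `Q`; per-cell scores are the neighborhood-axis
singular vectors scaled by singular values, signs flipped so each
dimension's largest-|loading| entry is positive.  Learning starts at 100
components (clipped to rank — a 30-sample NAM has rank 29) and keeps
`min(n_keep = 20, dims reaching a cumulative variance-explained threshold)`.
The threshold knob defaults to 0.90 in `reduce_pca` but the pipeline runs
with it disabled (keep the top 20): with few samples the NAM's variance
concentrates so aggressively that a 0.90 cutoff can keep ~5 dims and
discard the directions carrying weak abundance shifts.

NMF: multiplicative-update solver, non-negative double-SVD init,
tol 1e-5, max 500 iterations; per-cell scores are the neighborhood-side
factor matrix.  If no rank is given, candidate ranks are scored by the
mean silhouette of max-loading cell assignments in factor-score space and
the best (ties: smallest) is used.

Harmonization removes *technical* covariates (sample, batch) from the
latent scores and never biological ones (age, sex).  The default backend
is an iterative, clustering-localized residualization: k-means clusters
cells in the embedding, each covariate level's deviation from its
cluster's mean is removed with shrinkage n/(n + 10), repeated 3 times —
the within-cluster correction style that embedding-integration methods
use.  A one-pass global residualization is available as `backend="linear"`
but is deliberately not the default: subtracting global per-sample means
injects each sample's cluster *composition* — which tracks the clinical
outcome — into every cell's coordinates.  In development this raised the
"predict the anchor cell's sample condition from its latent coordinates"
AUROC from 0.57 (raw) to 0.96 (globally residualized), i.e. it converts a
neighborhood score into a disguised sample label.  Any per-cell NAM
pipeline faces this; the local backend keeps that leakage at chance while
still removing sample-specific clumping.  The backend interface (scores +
label table in, adjusted scores out) accepts any external implementation.

## 3. Classification

The design matrix per cell is `[latent dims | encoded covariates |
latent x interaction-variable products]`.  Categorical targets and
covariates are label encoded; continuous interaction variables are
z-scored before the product; binary ones are 0/1 dummies coded
*complementarily* to the main effect (the main-effect dummy codes the
lexicographically larger level as 1, the interaction dummy the smaller).
The complementary convention is deliberate: if the stratum carrying an
interaction effect happens to be the 0-level, the product column is
identically zero exactly where the effect lives and attribution credit
silently reroutes through the bare latent dimension.

Fitting is repeated nested cross-validation with randomized
hyperparameter search (random forest by default; gradient boosting
available).  Folds are stratified on class and grouped by sample — all
cells of a sample stay together, blocking within-sample leakage; a
cell-level stratified mode is retained for comparison.  A global
grouped-stratified holdout (20% of samples) is carved out first and used
only for final AUROC/AUPRC.  Per repeat: stratified-grouped outer folds
(default 5); in each, candidate hyperparameters (default budget 20 from
trees {100..500}, depth {None, 4..16}, min leaf {1..10}, feature fraction
{sqrt, 0.3..1.0}) are scored by mean inner-fold AUROC (default 3 inner
folds); the best is refit on the outer-train and predicts the outer-test,
so every CV cell gets an out-of-fold probability per repeat.  All
randomness derives from one seed; reruns are byte-identical.

## 4. Attribution and the Interpretable Score

Shapley values are computed exactly for tree ensembles under the
tree-path-dependent conditional-expectation convention (absent features
marginalized by training-cover weights), implemented natively with a
numba kernel; a brute-force subset-enumeration oracle in the test suite
checks it to 1e-8 on small trees, and local accuracy (base + sum of
attributions = model output) holds to 1e-6 everywhere.  Attributions are
computed on probability outputs for forests, so scores read as
probability shifts; only rows unseen by the attributing model are
explained (outer-test rows by their fold's model, holdout rows by the
repeat's first model).

Per-cell attributions are averaged elementwise across repeats, keeping
the cells x features x classes dimensions.  Multiclass tensors collapse
to one value per cell per feature by taking the cell's predicted-class
slice; binary tasks use the positive-class slice for all cells so signs
stay comparable (`collapse="literal"` restores the per-cell rule).  The
Interpretable Score is the row sum over *all* design columns — latent,
covariate and interaction (`score_columns="latent_only"` restricts it);
for binary probability attributions it equals `p-hat(positive) - base`
exactly.  Features are ranked by mean |attribution|.

## 5. Downstream interpretation

Marker-score association: per-feature Pearson correlation (Spearman via
flag) of expression with the score on a chosen cell subset, two-sided
p-values, Benjamini-Hochberg adjustment across all tested features;
zero-variance features are flagged and excluded from adjustment.
Cluster summaries: per-cluster mean/median/IQR, Wilcoxon rank-sum for two
groups or Kruskal-Wallis globally, top-scoring cluster tested against all
other cells; clusters under 3 cells are excluded.  Detection against
simulated truth: a cell is called condition-associated if its score
exceeds 0 (a quantile rule is available; for clusters whose injected
shift is a depletion the call is score < 0), and the report gives the
per-cluster proportion of calls matching the truth flags plus the median
across clusters.  Score-vs-probability separation: AUROC of
target-cluster membership against the score and against the classifier's
predicted probability on the same cells.

## The simulator

Each feature is a weighted sum of standardized per-factor Gaussian
signals plus noise, rescaled to mean 0 / sd 1.  Factor level means are
equally spaced integers, permuted independently per feature (without the
permutation all features would be collinear in the cluster direction and
ten clusters would collapse onto a line, which no real dataset
resembles); sigma defaults to 1.  Weights are stored as variance
fractions; amplitudes are their square roots, so squared amplitudes sum
to one exactly and the variance explained by factor f is w_f^2 (verified
by regression to ±0.03 at n = 10^4).  Interaction effects in expression
enter as standardized products of two factor signals (their own variance
fraction).  Age is uniform per subject then standardized; sex is a
balanced two-level factor.

Differential abundance is injected in metadata.  Control subjects get
`round(cells_per_cluster * p_j / max p)` cells of cluster j.  Disease
subjects' targeted-cluster counts are solved jointly so each targeted
cluster's expected within-sample *proportion* is f_j times its control
proportion; untargeted counts are left unchanged, so the disease total
grows (or shrinks) accordingly.  Because proportions sum to one, the
untargeted clusters are necessarily diluted — with two clusters of share
0.1 expanded 3-fold the untargeted proportion ratio is 0.5; no count
scheme can hold targeted ratios at 3.0 and untargeted at 1.0
simultaneously.  A fold parameter below 1 in `fold_mode="ratio"` is a
depletion; `fold_mode="fractional"` reads it as a fractional increase
(parameter 0.1 -> realized ratio 1.1), covering weak-shift scenarios.
Counts are deterministic rounded expectations; a Poisson-jitter flag
(default off) adds count noise.  An abundance stratum (e.g. sex = F)
restricts the shift to disease subjects in that stratum, creating
condition-by-covariate interactions.  Truth flags mark cells in a
targeted cluster AND the condition/stratum where the shift was injected,
with the shift direction recorded per cell.

Presets: `dataset1` (15+15 subjects, 10 equal clusters A-J, 100 cells per
cluster per control subject, A and J at ratio 3), `dataset2` (same with
the weak parameter 0.1, realized ratio 1.1) and `interaction` (A depleted
/ B expanded and rare I depleted / J expanded — I, J at 5% of cells —
only in female disease subjects, ratios 1/3 and 3).  Benchmark presets
put no variance on disease in expression (cell type 0.5, subject 0.05,
batch 0.05, noise 0.4): the condition signal lives purely in abundance,
as a differential-abundance benchmark requires — a direct disease
expression term would let the classifier bypass abundance entirely.

What the simulator does **not** emulate: count distributions (negative
binomial, dropout), library-size effects, doublets, continuous
trajectories, or overlapping clusters.  Gaussian clusters separated by
integer-spaced means are much cleaner than real data, so pipeline
accuracies here are upper bounds: passing tests demonstrate correctness
of the machinery, not expected performance on real tissue.

## Problem sizes and seeds

One global seed fans out to per-feature, per-stage child streams
(SeedSequence spawn keys), so adding features or stages never perturbs
earlier draws and identical configs reproduce byte-identical outputs.
Benchmark evaluations in the acceptance script and test suite run the
presets at 25-50 cells per cluster per subject with a reduced CV budget
(3 outer / 2 inner folds, 2 repeats, search budget 4, trees 50-100,
depth 4-8) — sizes chosen as the package's desk-scale defaults; the
simulation-only abundance checks run at the full 100-cell cohort.

## Known limitations

- The detection benchmark's per-cluster accuracy has structural ceilings:
  in an expanded cluster the truth-flag rule caps accuracy at the
  cluster's disease-cell fraction (0.857 for a 3-fold expansion with
  15+15 subjects), and a realized ratio of 1.1 carries almost no
  cell-level information, so the weak-shift benchmark hovers near chance
  by construction under this parameterization.
- When targeted expansions and depletions do not cancel in counts, the
  attribution base (the training disease fraction of cells) moves away
  from 0.5, shifting all scores additively; in the interaction preset
  this leaves unaffected (male) cells with a small negative mean score
  rather than exactly zero.
- The harmonization backend is a deliberately simple local residualizer;
  strong nonlinear batch structure calls for an external integration tool
  plugged into the same interface.
- Tree depth drives the exact-Shapley cost (O(leaves x depth^2) per cell
  per tree); unbounded-depth forests on tens of thousands of cells are
  expensive on one core, which is why the scaled benchmark search spaces
  bound depth.
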