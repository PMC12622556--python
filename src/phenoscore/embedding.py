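"""Latent embeddings of the neighborhood abundance matrix.

PCA (column-centered SVD of Q, per-cell scores on the neighborhood axis)
or NMF (topic-model-style non-negative factors, with silhouette-based rank
selection), followed by optional harmonization of technical covariates.
Harmonization removes sample/batch structure from the latent scores but is
never applied to biological covariates such as age or sex, whose variation
the classifier is meant to see.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import NMF
from sklearn.metrics import silhouette_score

from .neighborhood import NeighborhoodAbundanceMatrix

__all__ = [
    "LatentEmbedding",
    "reduce_pca",
    "reduce_nmf",
    "select_nmf_rank",
    "harmonize",
]


@dataclass
class LatentEmbedding:
    """Per-cell latent coordinates derived from the NAM."""

    scores: np.ndarray  # cells x d
    method: str  # "pca" | "nmf"
    d: int
    variance_explained: np.ndarray | None = None  # per dim (pca)
    nmf_rank: int | None = None
    harmonized: bool = False
    removed_covariates: tuple = ()
    sample_loadings: np.ndarray | None = None  # samples x d (pca: U)
    cell_ids: list | None = None

    @property
    def dim_names(self) -> list[str]:
        return [f"LD{i + 1}" for i in range(self.d)]


def reduce_pca(
    nam: NeighborhoodAbundanceMatrix,
    n_init: int = 100,
    n_keep: int = 20,
    ve_threshold: float | None = 0.90,
    center: bool = True,
) -> LatentEmbedding:
    """Column-centered SVD of Q; scores live on the neighborhood (cell) axis.

    Starts from ``n_init`` components (clipped to matrix rank with a
    warning) and keeps ``min(n_keep, dims reaching the cumulative
    variance-explained threshold)``.  Each dimension's sign is flipped so
    its largest-|loading| entry is positive, making output deterministic.
    """
    if n_keep > n_init:
        raise ValueError("n_keep must be <= n_init")
    q = nam.Q
    qc = q - q.mean(axis=0, keepdims=True) if center else q.copy()
    u, sv, vt = np.linalg.svd(qc, full_matrices=False)
    tol = max(qc.shape) * np.finfo(float).eps * (sv[0] if sv.size else 0.0)
    rank = int((sv > tol).sum())
    if rank == 0:
        raise ValueError("NAM has rank 0 after centering")
    if rank < n_keep:
        warnings.warn(
            f"rank {rank} below requested {n_keep} dims; keeping {rank}",
            stacklevel=2,
        )
    n_avail = min(n_init, rank)

    total_var = (sv**2).sum()
    ve = sv[:n_avail] ** 2 / total_var
    d = min(n_keep, n_avail)
    if ve_threshold is not None:
        cum = np.cumsum(ve)
        reached = int(np.searchsorted(cum, ve_threshold) + 1)
        d = min(d, max(1, reached))

    v = vt[:d].T  # M x d
    u = u[:, :d]
    # deterministic sign: largest-|loading| entry of each dim positive
    flip = np.sign(v[np.argmax(np.abs(v), axis=0), np.arange(d)])
    flip[flip == 0] = 1.0
    v = v * flip
    u = u * flip
    scores = v * sv[:d]
    return LatentEmbedding(
        scores=scores,
        method="pca",
        d=d,
        variance_explained=ve[:d],
        sample_loadings=u,
        cell_ids=nam.cell_ids,
    )


def reduce_nmf(
    nam: NeighborhoodAbundanceMatrix,
    k: int,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-5,
) -> LatentEmbedding:
    """Non-negative factorization Q ~ W H; per-cell scores are H^T.

    Multiplicative-update solver with non-negative double-SVD init, so the
    factorization is deterministic under a fixed seed.
    """
    q = nam.Q
    if (q < 0).any():
        raise ValueError("NAM contains negative entries; NMF requires Q >= 0")
    if k < 1 or k >= min(q.shape[0], q.shape[1]) + 1:
        raise ValueError(f"need 1 <= k <= min(N, M), got k={k}")
    model = NMF(
        n_components=k,
        init="nndsvda",
        solver="mu",
        beta_loss="frobenius",
        tol=tol,
        max_iter=max_iter,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence chatter on toy inputs
        w = model.fit_transform(q)
    scores = model.components_.T  # M x k
    return LatentEmbedding(
        scores=scores,
        method="nmf",
        d=k,
        nmf_rank=k,
        sample_loadings=w,
        cell_ids=nam.cell_ids,
    )


def select_nmf_rank(
    nam: NeighborhoodAbundanceMatrix,
    candidate_ks: Sequence[int],
    seed: int = 0,
) -> int:
    """Pick the NMF rank whose max-loading cell labeling has the highest
    mean silhouette in factor-score space (ties -> smallest k)."""
    ks = sorted(set(int(k) for k in candidate_ks))
    if not ks:
        raise ValueError("no candidate ranks")
    m = nam.n_neighborhoods
    for k in ks:
        if k < 2:
            raise ValueError("candidate ranks must be >= 2")
        if k >= m:
            raise ValueError(f"rank {k} >= number of neighborhoods {m}")
    best_k, best_score = None, -np.inf
    for k in ks:
        emb = reduce_nmf(nam, k, seed=seed)
        labels = np.argmax(emb.scores, axis=1)
        if len(np.unique(labels)) < 2:
            score = -1.0
        else:
            score = float(silhouette_score(emb.scores, labels))
        if score > best_score:
            best_k, best_score = k, score
    return int(best_k)


def _linear_residual_backend(
    scores: np.ndarray, labels: pd.DataFrame
) -> np.ndarray:
    """Remove per-level mean offsets of the covariates from each dimension.

    Ordinary least squares of each latent dimension on the one-hot encoded
    covariates; the adjusted embedding is the residual plus the grand mean,
    so between-level mean gaps vanish while within-level variation is kept.
    """
    dummies = pd.get_dummies(labels.astype(str), drop_first=True, dtype=float)
    x = np.column_stack([np.ones(len(labels)), dummies.to_numpy()])
    beta, *_ = np.linalg.lstsq(x, scores, rcond=None)
    resid = scores - x @ beta
    return resid + scores.mean(axis=0, keepdims=True)


def _clustered_residual_backend(
    scores: np.ndarray,
    labels: pd.DataFrame,
    n_iter: int = 3,
    n_clusters: int | None = None,
    ridge: float = 10.0,
) -> np.ndarray:
    """Iterative clustering-localized sample-effect removal.

    Per iteration, cells are k-means clustered in the current embedding
    and each covariate level's deviation from its cluster's mean is
    shrunk out (shrinkage ``n / (n + ridge)`` protects tiny groups).
    Local sample structure — e.g., a sample's cells clumping inside one
    cell state — is removed while between-state geometry is preserved;
    this is the correction style batch-integration methods apply to
    low-dimensional embeddings, here in its simplest deterministic form.

    Corrections are deliberately local: subtracting *global* per-sample
    means would inject each sample's cluster composition (which tracks the
    clinical outcome) into every cell's coordinates, defeating per-cell
    interpretation; the global variant remains available as the
    ``"linear"`` backend for covariates unrelated to composition.
    """
    from sklearn.cluster import KMeans

    z = scores.copy()
    n = z.shape[0]
    k = n_clusters or int(np.clip(round(np.sqrt(n / 10.0)), 5, 30))
    for it in range(n_iter):
        km = KMeans(n_clusters=min(k, n), n_init=3, random_state=100 + it)
        assign = km.fit_predict(z)
        for c in np.unique(assign):
            in_c = np.flatnonzero(assign == c)
            mu_c = z[in_c].mean(axis=0)
            for col in labels.columns:
                lv = labels[col].to_numpy()[in_c]
                for s in pd.unique(lv):
                    rows = in_c[lv == s]
                    shrink = rows.size / (rows.size + ridge)
                    z[rows] -= shrink * (z[rows].mean(axis=0) - mu_c)
    return z


def harmonize(
    embedding: LatentEmbedding,
    batch_labels: pd.DataFrame | pd.Series | Sequence,
    enabled: bool = True,
    backend: Callable[[np.ndarray, pd.DataFrame], np.ndarray] | str | None = None,
) -> LatentEmbedding:
    """Adjust latent scores for technical covariates (sample, batch).

    Narrow interface: the backend receives (scores, label table) and
    returns adjusted scores of identical shape, so an external
    harmonization implementation can be plugged in.  The default backend
    is the iterative clustering-localized residualization
    (``"clustered"``); ``"linear"`` selects the one-pass global
    residualization.  Disabled or single-level covariates pass through
    unchanged.
    """
    if not enabled:
        return embedding
    if isinstance(batch_labels, pd.Series):
        labels = batch_labels.to_frame()
    elif isinstance(batch_labels, pd.DataFrame):
        labels = batch_labels.copy()
    else:
        labels = pd.DataFrame({"batch": np.asarray(batch_labels)})
    if len(labels) != embedding.scores.shape[0]:
        raise ValueError("batch label length does not match number of cells")

    usable = []
    for col in labels.columns:
        if labels[col].nunique() < 2:
            warnings.warn(
                f"covariate {col!r} has a single level; nothing to remove",
                stacklevel=2,
            )
        else:
            usable.append(col)
    if not usable:
        return embedding

    if backend is None or backend == "clustered":
        fn = _clustered_residual_backend
    elif backend == "linear":
        fn = _linear_residual_backend
    elif callable(backend):
        fn = backend
    else:
        raise ValueError(f"unknown harmonization backend {backend!r}")
    adjusted = fn(embedding.scores, labels[usable])
    if adjusted.shape != embedding.scores.shape:
        raise ValueError("harmonization backend changed the embedding shape")
    return replace(
        embedding,
        scores=np.asarray(adjusted, dtype=float),
        harmonized=True,
        removed_covariates=tuple(usable),
    )
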