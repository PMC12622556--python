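"""Cell kNN graph, random-walk diffusion, and the sample x neighborhood
abundance matrix (NAM).

A neighborhood is the s-step random-walk footprint anchored at one cell, so
neighborhoods and cells are in one-to-one correspondence.  ``R[n, m]`` is
the expected number of cells from sample ``n`` ending a random walk at cell
``m``; the NAM ``Q`` row-normalizes ``R`` so each sample row sums to 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "NeighborGraph",
    "NeighborhoodAbundanceMatrix",
    "build_knn_graph",
    "random_walk_probability",
    "build_nam",
]


@dataclass
class NeighborGraph:
    """Weighted symmetric adjacency A and row-stochastic transition A-hat."""

    n_cells: int
    k: int
    adjacency: sp.csr_matrix
    transition: sp.csr_matrix
    feature_space: str = "expression"

    @classmethod
    def from_transition(cls, transition, feature_space: str = "custom") -> "NeighborGraph":
        """Wrap an explicit row-stochastic matrix (used by oracles/tests)."""
        t = sp.csr_matrix(np.asarray(transition) if not sp.issparse(transition) else transition)
        rows = np.asarray(t.sum(axis=1)).ravel()
        if not np.allclose(rows, 1.0, atol=1e-9):
            raise ValueError("transition rows must sum to 1")
        return cls(
            n_cells=t.shape[0], k=0, adjacency=t.maximum(t.T).tocsr(), transition=t,
            feature_space=feature_space,
        )


def build_knn_graph(
    cell_representation: np.ndarray,
    k: int = 30,
    weight: str = "binary",
    feature_space: str = "expression",
) -> NeighborGraph:
    """Union-symmetrized kNN graph with a row-normalized transition matrix.

    Edges are the union of directed kNN edges (self excluded); weights are
    binary by default or a Gaussian kernel of the distances (bandwidth =
    median neighbor distance) with ``weight="gaussian"``.  Row-wise
    normalization (random-walk convention) produces the transition matrix.
    """
    x = np.asarray(cell_representation, dtype=float)
    if x.ndim != 2:
        raise ValueError("cell_representation must be 2-D (cells x dims)")
    m = x.shape[0]
    if not np.isfinite(x).all():
        raise ValueError("non-finite values in cell representation")
    if k < 1 or k >= m:
        raise ValueError(f"need 1 <= k < n_cells, got k={k}, n_cells={m}")

    nn = NearestNeighbors(n_neighbors=k + 1).fit(x)
    dist, ind = nn.kneighbors(x)
    # drop self-neighbor (first column after sorting by distance)
    dist, ind = dist[:, 1:], ind[:, 1:]
    rows = np.repeat(np.arange(m), k)
    cols = ind.ravel()
    if weight == "binary":
        vals = np.ones(m * k)
    elif weight == "gaussian":
        bw = np.median(dist[dist > 0]) if (dist > 0).any() else 1.0
        vals = np.exp(-((dist.ravel() / bw) ** 2))
    else:
        raise ValueError(f"unknown weight scheme {weight!r}")
    a = sp.csr_matrix((vals, (rows, cols)), shape=(m, m))
    a = a.maximum(a.T)  # union symmetrization
    a.setdiag(0.0)
    a.eliminate_zeros()

    degree = np.asarray(a.sum(axis=1)).ravel()
    if (degree == 0).any():
        raise ValueError("isolated cell in kNN graph")
    t = sp.diags(1.0 / degree) @ a
    return NeighborGraph(
        n_cells=m, k=k, adjacency=a.tocsr(), transition=t.tocsr(),
        feature_space=feature_space,
    )


def random_walk_probability(graph: NeighborGraph, s: int) -> np.ndarray:
    """Dense M x M matrix of s-step walk probabilities P(m' -> m) = (A-hat^s).

    Materializes the full matrix; intended for small graphs and oracle
    checks.  :func:`build_nam` never forms this product explicitly.
    """
    if s < 0:
        raise ValueError("number of steps s must be >= 0")
    m = graph.n_cells
    p = np.eye(m)
    t = graph.transition.toarray()
    for _ in range(int(s)):
        p = p @ t
    return p


@dataclass
class NeighborhoodAbundanceMatrix:
    """Samples x neighborhoods abundance: raw counts R and row-stochastic Q."""

    Q: np.ndarray
    R: np.ndarray
    sample_ids: list
    sample_index: dict  # sample -> array of cell indices
    steps: int
    cell_ids: list | None = None

    @property
    def n_samples(self) -> int:
        return self.Q.shape[0]

    @property
    def n_neighborhoods(self) -> int:
        return self.Q.shape[1]


def build_nam(
    graph: NeighborGraph,
    sample_labels: Sequence,
    s: int = 3,
    cell_ids: Sequence | None = None,
) -> NeighborhoodAbundanceMatrix:
    """Propagate per-sample cell indicators through s transition steps.

    Computes ``R = C @ A-hat^s`` by repeated sparse products on the N x M
    indicator matrix ``C`` (row n marks sample n's cells), never forming
    the dense M x M walk matrix.  Row sums of R equal per-sample cell
    counts (random-walk mass conservation); Q row-normalizes R.
    """
    if s < 0:
        raise ValueError("number of steps s must be >= 0")
    labels = np.asarray(sample_labels)
    if labels.shape[0] != graph.n_cells:
        raise ValueError(
            f"sample_labels length {labels.shape[0]} != n_cells {graph.n_cells}"
        )
    samples = list(dict.fromkeys(labels.tolist()))  # first-appearance order
    index = {sid: np.flatnonzero(labels == sid) for sid in samples}
    for sid, idx in index.items():
        if idx.size == 0:
            raise ValueError(f"sample {sid!r} has no cells")

    r = np.zeros((len(samples), graph.n_cells))
    for i, sid in enumerate(samples):
        r[i, index[sid]] = 1.0
    tt = graph.transition.T.tocsr()
    for _ in range(int(s)):
        r = (tt @ r.T).T
    totals = r.sum(axis=1, keepdims=True)
    q = r / totals
    return NeighborhoodAbundanceMatrix(
        Q=q, R=r, sample_ids=samples, sample_index=index, steps=int(s),
        cell_ids=list(cell_ids) if cell_ids is not None else None,
    )
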