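"""Numba kernel for exact tree Shapley values.

Implements the polynomial-time path-dependent algorithm for trees: feature
subsets absent from the conditioning set are marginalized with the tree's
own training cover (weighted node sample counts), i.e. the
tree-conditional expectation convention.  The recursion keeps, per path,
the fraction of zero-paths and one-paths flowing down each split and the
permutation weights of each path length, exactly as in the exact-TreeSHAP
formulation; leaf contributions are unwound per path element.

Leaf values may be vectors (one entry per class), so a single traversal
yields attributions for every class.
"""

from __future__ import annotations

import numpy as np
from numba import njit, prange

__all__ = ["forest_shap", "tree_expectations"]


@njit(cache=True)
def _unwound_sum(z_buf, o_buf, w_buf, row, ud, i):
    one = o_buf[row, i]
    zero = z_buf[row, i]
    next_one = w_buf[row, ud]
    total = 0.0
    if one != 0.0:
        for j in range(ud - 1, -1, -1):
            tmp = next_one * (ud + 1.0) / ((j + 1.0) * one)
            total += tmp
            next_one = w_buf[row, j] - tmp * zero * (ud - j) / (ud + 1.0)
    else:
        for j in range(ud - 1, -1, -1):
            total += w_buf[row, j] * (ud + 1.0) / (zero * (ud - j))
    return total


@njit(cache=True)
def _unwind(d_buf, z_buf, o_buf, w_buf, row, ud, i):
    one = o_buf[row, i]
    zero = z_buf[row, i]
    next_one = w_buf[row, ud]
    for j in range(ud - 1, -1, -1):
        if one != 0.0:
            tmp = w_buf[row, j]
            w_buf[row, j] = next_one * (ud + 1.0) / ((j + 1.0) * one)
            next_one = tmp - w_buf[row, j] * zero * (ud - j) / (ud + 1.0)
        else:
            w_buf[row, j] = w_buf[row, j] * (ud + 1.0) / (zero * (ud - j))
    for j in range(i, ud):
        d_buf[row, j] = d_buf[row, j + 1]
        z_buf[row, j] = z_buf[row, j + 1]
        o_buf[row, j] = o_buf[row, j + 1]


@njit(cache=True)
def _walk(
    cl, cr, feat, thr, cov, vals, x, phi,
    d_buf, z_buf, o_buf, w_buf,
    s_node, s_ud, s_prow, s_pzero, s_pone, s_pfeat,
):
    """Iterative depth-first traversal of one tree.

    Each visited node copies its parent's path row into its own row
    (row = parent_row + 1), extends it with the incoming split, and either
    unwinds leaf contributions or pushes its hot/cold children.  Siblings
    reuse rows only after the first subtree is fully processed (LIFO), so
    parent rows are never clobbered.
    """
    top = 0
    s_node[0] = 0
    s_ud[0] = 0
    s_prow[0] = -1
    s_pzero[0] = 1.0
    s_pone[0] = 1.0
    s_pfeat[0] = -1
    while top >= 0:
        node = s_node[top]
        unique_depth = s_ud[top]
        parent_row = s_prow[top]
        parent_zero = s_pzero[top]
        parent_one = s_pone[top]
        parent_feat = s_pfeat[top]
        top -= 1

        row = parent_row + 1
        for i in range(unique_depth):
            d_buf[row, i] = d_buf[parent_row, i]
            z_buf[row, i] = z_buf[parent_row, i]
            o_buf[row, i] = o_buf[parent_row, i]
            w_buf[row, i] = w_buf[parent_row, i]
        # extend the path with the incoming split
        d_buf[row, unique_depth] = parent_feat
        z_buf[row, unique_depth] = parent_zero
        o_buf[row, unique_depth] = parent_one
        w_buf[row, unique_depth] = 1.0 if unique_depth == 0 else 0.0
        for i in range(unique_depth - 1, -1, -1):
            w_buf[row, i + 1] += (
                parent_one * w_buf[row, i] * (i + 1.0) / (unique_depth + 1.0)
            )
            w_buf[row, i] = (
                parent_zero * w_buf[row, i] * (unique_depth - i) / (unique_depth + 1.0)
            )

        if cl[node] < 0:  # leaf: unwind every path element into phi
            for i in range(1, unique_depth + 1):
                w = _unwound_sum(z_buf, o_buf, w_buf, row, unique_depth, i)
                scale = w * (o_buf[row, i] - z_buf[row, i])
                f = d_buf[row, i]
                for c in range(vals.shape[1]):
                    phi[f, c] += scale * vals[node, c]
            continue

        f = feat[node]
        if x[f] <= thr[node]:
            hot, cold = cl[node], cr[node]
        else:
            hot, cold = cr[node], cl[node]
        w_node = cov[node]
        hot_zero = cov[hot] / w_node
        cold_zero = cov[cold] / w_node
        inc_zero = 1.0
        inc_one = 1.0
        k = -1
        for i in range(1, unique_depth + 1):
            if d_buf[row, i] == f:
                k = i
                break
        ud = unique_depth
        if k >= 0:
            inc_zero = z_buf[row, k]
            inc_one = o_buf[row, k]
            _unwind(d_buf, z_buf, o_buf, w_buf, row, ud, k)
            ud -= 1
        # push cold first so the hot child is processed (and its rows
        # released) before the cold subtree re-copies the parent row
        top += 1
        s_node[top] = cold
        s_ud[top] = ud + 1
        s_prow[top] = row
        s_pzero[top] = cold_zero * inc_zero
        s_pone[top] = 0.0
        s_pfeat[top] = f
        top += 1
        s_node[top] = hot
        s_ud[top] = ud + 1
        s_prow[top] = row
        s_pzero[top] = hot_zero * inc_zero
        s_pone[top] = inc_one
        s_pfeat[top] = f


@njit(cache=True, parallel=True)
def forest_shap(cl, cr, feat, thr, cov, vals, offsets, scales, X, n_features, max_depth):
    """Shapley values for a forest over all rows of X.

    Tree ``t`` occupies slots ``offsets[t]:offsets[t+1]`` of the
    concatenated node arrays and its leaf contributions are multiplied by
    ``scales[t]`` (1/n_trees for averaged forests, the learning rate for
    boosted stages).  Returns (n_rows, n_features, n_outputs).
    """
    n = X.shape[0]
    n_out = vals.shape[1]
    n_trees = offsets.shape[0] - 1
    phi = np.zeros((n, n_features, n_out))
    size = max_depth + 3
    stack = 2 * size + 2
    for i in prange(n):
        d_buf = np.empty((size, size), dtype=np.int64)
        z_buf = np.empty((size, size))
        o_buf = np.empty((size, size))
        w_buf = np.empty((size, size))
        s_node = np.empty(stack, dtype=np.int64)
        s_ud = np.empty(stack, dtype=np.int64)
        s_prow = np.empty(stack, dtype=np.int64)
        s_pzero = np.empty(stack)
        s_pone = np.empty(stack)
        s_pfeat = np.empty(stack, dtype=np.int64)
        local = np.zeros((n_features, n_out))
        for t in range(n_trees):
            off = offsets[t]
            tmp = np.zeros((n_features, n_out))
            _walk(
                cl[off:offsets[t + 1]], cr[off:offsets[t + 1]],
                feat[off:offsets[t + 1]], thr[off:offsets[t + 1]],
                cov[off:offsets[t + 1]], vals[off:offsets[t + 1]],
                X[i], tmp, d_buf, z_buf, o_buf, w_buf,
                s_node, s_ud, s_prow, s_pzero, s_pone, s_pfeat,
            )
            for j in range(n_features):
                for c in range(n_out):
                    local[j, c] += scales[t] * tmp[j, c]
        phi[i] = local
    return phi


@njit(cache=True)
def tree_expectations(cl, cr, cov, vals):
    """Cover-weighted expected leaf value at every node (bottom-up)."""
    n_nodes, n_out = vals.shape
    ev = np.zeros((n_nodes, n_out))
    # nodes are stored parent-before-child, so iterate in reverse
    for node in range(n_nodes - 1, -1, -1):
        if cl[node] < 0:
            for c in range(n_out):
                ev[node, c] = vals[node, c]
        else:
            wl = cov[cl[node]]
            wr = cov[cr[node]]
            for c in range(n_out):
                ev[node, c] = (wl * ev[cl[node], c] + wr * ev[cr[node], c]) / (wl + wr)
    return ev
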