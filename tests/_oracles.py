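"""Independent reference implementations used to check the package.

These deliberately re-derive quantities from first principles (exhaustive
enumeration, direct formulas) and never call the code paths they verify.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def expvalue_path_dependent(tree, x, subset):
    """Conditional expectation of a sklearn tree's output for feature
    subset S, marginalizing absent features with training-cover weights."""
    t = tree.tree_

    def node_value(j):
        v = t.value[j, 0, :].astype(float)
        s = v.sum()
        return v / s if s else v

    def go(j):
        if t.children_left[j] < 0:
            return node_value(j)
        d = t.feature[j]
        if d in subset:
            nxt = t.children_left[j] if x[d] <= t.threshold[j] else t.children_right[j]
            return go(nxt)
        wl = t.weighted_n_node_samples[t.children_left[j]]
        wr = t.weighted_n_node_samples[t.children_right[j]]
        return (go(t.children_left[j]) * wl + go(t.children_right[j]) * wr) / (wl + wr)

    return go(0)


def shap_bruteforce(model, x, n_features):
    """Exhaustive Shapley values over all feature subsets (tree-conditional
    expectation convention), averaged over the forest's trees."""
    phi = np.zeros((n_features, model.n_classes_))
    feats = list(range(n_features))
    for tree in model.estimators_:
        for i in feats:
            others = [f for f in feats if f != i]
            for r in range(len(others) + 1):
                for subset in itertools.combinations(others, r):
                    w = (
                        math.factorial(len(subset))
                        * math.factorial(n_features - len(subset) - 1)
                        / math.factorial(n_features)
                    )
                    s = set(subset)
                    phi[i] += w * (
                        expvalue_path_dependent(tree, x, s | {i})
                        - expvalue_path_dependent(tree, x, s)
                    )
    return phi / len(model.estimators_)


def bh_stepup(pvals):
    """Benjamini-Hochberg adjusted p-values, direct step-up construction."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


def silhouette_direct(x, labels):
    """Mean silhouette coefficient from the pairwise-distance definition."""
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels)
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
    vals = []
    for i in range(len(x)):
        same = (labels == labels[i]) & (np.arange(len(x)) != i)
        if not same.any():
            vals.append(0.0)
            continue
        a = d[i, same].mean()
        b = min(
            d[i, labels == other].mean()
            for other in np.unique(labels)
            if other != labels[i]
        )
        vals.append((b - a) / max(a, b))
    return float(np.mean(vals))
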