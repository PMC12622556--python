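"""Downstream interpretation of the per-cell score.

Marker-score correlations with Benjamini-Hochberg control, per-cluster
score summaries with rank tests, detection accuracy against simulated
ground truth, and score-vs-probability separation comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from statsmodels.stats.multitest import multipletests

__all__ = [
    "MarkerCorrelationTable",
    "DetectionReport",
    "marker_score_correlation",
    "cluster_score_summary",
    "evaluate_detection",
    "separation_comparison",
]

MarkerCorrelationTable = pd.DataFrame  # feature, r, p, p_adj, n, direction


def _scores_of(scores) -> np.ndarray:
    return np.asarray(getattr(scores, "scores", scores), dtype=float)


def marker_score_correlation(
    expression,
    scores,
    cell_subset=None,
    method: str = "pearson",
    feature_names: Sequence[str] | None = None,
) -> MarkerCorrelationTable:
    """Per-feature correlation of expression with the Interpretable Score.

    Two-sided p-values, BH-adjusted across all tested features;
    zero-variance features are reported with missing r and excluded from
    the adjustment.  Rows sort by adjusted p then |r| descending.
    """
    if isinstance(expression, pd.DataFrame):
        feature_names = list(expression.columns)
        x = expression.to_numpy(dtype=float)
    else:
        x = np.asarray(expression, dtype=float)
        if feature_names is None:
            feature_names = [f"feature_{i + 1}" for i in range(x.shape[1])]
    psi = _scores_of(scores)
    if cell_subset is not None:
        mask = np.asarray(cell_subset)
        x, psi = x[mask], psi[mask]
    if x.shape[0] == 0:
        raise ValueError("empty cell subset")
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")

    rows = []
    for j, name in enumerate(feature_names):
        col = x[:, j]
        if np.std(col) == 0 or np.std(psi) == 0:
            rows.append((name, np.nan, np.nan, len(col), "flat", True))
            continue
        r, p = corr(col, psi)
        rows.append(
            (name, float(r), float(p), len(col), "pos" if r >= 0 else "neg", False)
        )
    table = pd.DataFrame(
        rows, columns=["feature", "r", "p", "n", "direction", "zero_variance"]
    )
    table["p_adj"] = np.nan
    tested = ~table["zero_variance"]
    if tested.any():
        table.loc[tested, "p_adj"] = multipletests(
            table.loc[tested, "p"], method="fdr_bh"
        )[1]
    table["abs_r"] = table["r"].abs()
    table = (
        table.sort_values(["p_adj", "abs_r"], ascending=[True, False], kind="mergesort")
        .drop(columns="abs_r")
        .reset_index(drop=True)
    )
    return table[["feature", "r", "p", "p_adj", "n", "direction", "zero_variance"]]


def cluster_score_summary(
    scores,
    cluster_labels: Sequence,
    pairwise: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Per-cluster score statistics plus rank tests.

    Wilcoxon rank-sum for two clusters, Kruskal-Wallis globally; the
    top-scoring cluster (by mean) is additionally tested against all other
    cells.  Clusters with fewer than 3 cells are flagged and excluded from
    the tests.
    """
    psi = _scores_of(scores)
    labels = np.asarray(cluster_labels)
    clusters = list(pd.unique(labels))
    if len(clusters) < 2:
        raise ValueError("need at least two clusters")
    rows = []
    for cl in clusters:
        vals = psi[labels == cl]
        q1, q3 = (np.percentile(vals, [25, 75]) if vals.size else (np.nan, np.nan))
        rows.append(
            {
                "cluster": cl,
                "n": int(vals.size),
                "mean": float(vals.mean()) if vals.size else np.nan,
                "median": float(np.median(vals)) if vals.size else np.nan,
                "iqr": float(q3 - q1),
                "excluded": vals.size < 3,
            }
        )
    summary = pd.DataFrame(rows)
    usable = [cl for cl, r in zip(clusters, summary["excluded"]) if not r]
    tests: dict = {"excluded_clusters": [c for c in clusters if c not in usable]}
    groups = [psi[labels == cl] for cl in usable]
    if len(groups) == 2:
        stat, p = stats.mannwhitneyu(groups[0], groups[1], alternative="two-sided")
        tests.update(global_test="wilcoxon_rank_sum", global_p=float(p))
    elif len(groups) > 2:
        stat, p = stats.kruskal(*groups)
        tests.update(global_test="kruskal_wallis", global_p=float(p))
    else:
        tests.update(global_test=None, global_p=np.nan)

    use = summary[~summary["excluded"]]
    if len(use):
        top = use.loc[use["mean"].idxmax(), "cluster"]
        rest = psi[labels != top]
        own = psi[labels == top]
        if rest.size >= 3:
            _, p_top = stats.mannwhitneyu(own, rest, alternative="two-sided")
        else:
            p_top = np.nan
        tests.update(top_cluster=top, top_cluster_p=float(p_top))
    if pairwise:
        pw = []
        for i, a in enumerate(usable):
            for b in usable[i + 1:]:
                _, p = stats.mannwhitneyu(
                    psi[labels == a], psi[labels == b], alternative="two-sided"
                )
                pw.append({"cluster_a": a, "cluster_b": b, "p": float(p)})
        tests["pairwise"] = pd.DataFrame(pw)
    return summary, tests


@dataclass
class DetectionReport:
    """Per-cluster proportion of cells whose thresholded call matches the
    simulated ground truth, and the median across clusters."""

    per_cluster: pd.Series
    median: float
    per_cluster_mean_score: pd.Series
    rule: str

    def to_dict(self) -> dict:
        return {
            "rule": self.rule,
            "median_proportion_correct": self.median,
            "per_cluster_proportion_correct": self.per_cluster.to_dict(),
            "per_cluster_mean_score": self.per_cluster_mean_score.to_dict(),
        }


def evaluate_detection(
    scores,
    truth_flags: Sequence,
    cluster_labels: Sequence,
    rule: str = "sign",
    threshold: float = 0.0,
    quantile: float | None = None,
    directions: Mapping | None = None,
) -> DetectionReport:
    """Call each cell condition-associated and grade the calls per cluster.

    Default rule: score > 0 flags a cell as condition-associated.  For
    clusters whose injected shift is a depletion (``directions[cluster] ==
    -1``), an associated cell is instead expected to score *below* the
    threshold.  ``rule="quantile"`` uses the given score quantile as the
    threshold instead of 0.
    """
    psi = _scores_of(scores)
    truth = np.asarray(truth_flags)
    if truth.shape[0] != psi.shape[0]:
        raise ValueError("truth flags do not align with scores")
    labels = np.asarray(cluster_labels)
    if rule == "quantile":
        if quantile is None:
            raise ValueError("quantile rule requires a quantile")
        threshold = float(np.quantile(psi, quantile))
        rule_desc = f"quantile({quantile})={threshold:.4f}"
    elif rule == "sign":
        rule_desc = f"score > {threshold:g}"
    else:
        raise ValueError(f"unknown detection rule {rule!r}")

    clusters = list(pd.unique(labels))
    prop, mean_score = {}, {}
    for cl in clusters:
        mask = labels == cl
        direction = directions.get(cl, 1) if directions else 1
        call = psi[mask] < -threshold if direction < 0 else psi[mask] > threshold
        prop[cl] = float((call == truth[mask].astype(bool)).mean())
        mean_score[cl] = float(psi[mask].mean())
    per_cluster = pd.Series(prop).sort_index()
    return DetectionReport(
        per_cluster=per_cluster,
        median=float(per_cluster.median()),
        per_cluster_mean_score=pd.Series(mean_score).sort_index(),
        rule=rule_desc,
    )


def separation_comparison(
    scores,
    probabilities: Sequence[float],
    cluster_labels: Sequence,
    target_clusters: Sequence,
) -> dict:
    """AUROC of target-cluster membership against the score and against the
    model's predicted probability, on the same cells."""
    psi = _scores_of(scores)
    labels = np.asarray(cluster_labels)
    proba = np.asarray(probabilities, dtype=float)
    member = np.isin(labels, list(target_clusters))
    if member.all() or not member.any():
        raise ValueError("target clusters cover all or none of the cells; AUROC undefined")
    return {
        "auroc_score": float(roc_auc_score(member, psi)),
        "auroc_probability": float(roc_auc_score(member, proba)),
        "n_target": int(member.sum()),
        "n_other": int((~member).sum()),
    }
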