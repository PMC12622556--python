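"""Gaussian variance-partition simulator for multi-sample single-cell cohorts.

Generates case/control cohorts in which every expression feature is a
weighted linear combination of standardized per-factor signals (cell type,
disease, subject, batch, age, sex), optional factor-by-factor interaction
products, and Gaussian noise.  Squared weights sum to one, so the fraction
of a feature's variance attributable to factor ``f`` is exactly ``w_f**2``.
Differential abundance is injected at the metadata level: targeted clusters
receive extra (or fewer) cells in disease subjects so that the realized
disease:control *proportion* ratio equals a per-cluster fold-change, either
globally or restricted to a covariate stratum (e.g., only female disease
subjects) to create condition-by-covariate interaction effects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "preset",
    "plan_abundance",
    "subject_table",
    "sample_factor_signal",
    "compose_feature",
    "simulate_dataset",
]

FACTORS = ("cell_type", "disease", "subject", "batch", "age", "sex")

#: default variance fractions; the remainder (0.2) is residual noise
DEFAULT_VARIANCE_FRACTIONS = {
    "cell_type": 0.4,
    "disease": 0.2,
    "subject": 0.1,
    "batch": 0.1,
}


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Independent child stream; adding streams never perturbs earlier ones."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


@dataclass(frozen=True)
class SimulationConfig:
    """Scenario description for :func:`simulate_dataset`.

    ``variance_fractions`` maps factor -> fraction of variance explained
    (``VE_f``); amplitudes are ``w_f = sqrt(VE_f)`` and the noise amplitude
    absorbs the remainder so that ``sum(w_f**2) + w_noise**2 == 1``.

    ``fold_changes`` maps cluster id -> fold parameter ``f``.  With
    ``fold_mode="ratio"`` the realized disease:control proportion ratio is
    ``f`` itself (``f < 1`` is a depletion); with ``fold_mode="fractional"``
    the parameter is a fractional increase and the realized ratio is
    ``1 + f`` (covers weak global shifts parameterized as, e.g., 0.1).

    ``abundance_stratum`` optionally restricts the injected shift to disease
    subjects matching the given subject-level attributes, e.g.
    ``{"sex": "F"}`` for a disease-by-sex interaction in abundance.
    """

    n_subjects_per_group: int = 15
    cells_per_cluster: int = 100
    clusters: tuple[str, ...] = tuple("ABCDEFGHIJ")
    cluster_proportions: tuple[float, ...] | None = None
    fold_changes: Mapping[str, float] = field(default_factory=dict)
    fold_mode: str = "ratio"
    abundance_stratum: Mapping[str, str] | None = None
    n_features: int = 30
    variance_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_VARIANCE_FRACTIONS)
    )
    interaction_specs: tuple[tuple[str, str, float], ...] = ()
    covariates: tuple[str, ...] = ("subject", "batch")
    n_batches: int = 2
    sigma: float = 1.0
    poisson_jitter: bool = False
    seed: int = 0

    # ---- derived quantities -------------------------------------------------

    @property
    def proportions(self) -> np.ndarray:
        if self.cluster_proportions is None:
            p = np.full(len(self.clusters), 1.0 / len(self.clusters))
        else:
            p = np.asarray(self.cluster_proportions, dtype=float)
        return p

    @property
    def factor_weights(self) -> dict[str, float]:
        """Normalized amplitudes w_f = sqrt(VE_f) (noise excluded)."""
        ve = dict(self.variance_fractions)
        total = sum(ve.values()) + sum(w for _, _, w in self.interaction_specs)
        if total > 1.0 + 1e-12:
            raise ValueError("variance fractions sum to more than 1")
        return {f: math.sqrt(v) for f, v in ve.items()}

    @property
    def interaction_weights(self) -> tuple[tuple[str, str, float], ...]:
        return tuple((a, b, math.sqrt(v)) for a, b, v in self.interaction_specs)

    @property
    def noise_weight(self) -> float:
        ve = sum(self.variance_fractions.values())
        ve += sum(w for _, _, w in self.interaction_specs)
        return math.sqrt(max(0.0, 1.0 - ve))

    def realized_ratio(self, cluster: str) -> float:
        """Targeted disease:control proportion ratio for ``cluster``."""
        f = self.fold_changes.get(cluster, None)
        if f is None:
            return 1.0
        if f <= 0:
            raise ValueError(f"fold change for cluster {cluster!r} must be > 0")
        if self.fold_mode == "fractional":
            return 1.0 + f
        if self.fold_mode != "ratio":
            raise ValueError(f"unknown fold_mode {self.fold_mode!r}")
        return float(f)

    def validate(self) -> None:
        p = self.proportions
        if len(p) != len(self.clusters):
            raise ValueError("cluster_proportions length mismatch")
        if (p < 0).any():
            raise ValueError("cluster proportions must be non-negative")
        if abs(p.sum() - 1.0) > 1e-8:
            raise ValueError("cluster proportions must sum to 1")
        unknown = set(self.fold_changes) - set(self.clusters)
        if unknown:
            raise ValueError(f"expanded clusters not in clusters: {sorted(unknown)}")
        for j, pj in zip(self.clusters, p):
            if j in self.fold_changes and pj == 0:
                raise ValueError(f"cluster {j!r} has zero baseline proportion")
            self.realized_ratio(j)
        for f, v in self.variance_fractions.items():
            if v < 0:
                raise ValueError(f"negative variance fraction for {f!r}")
            if f not in FACTORS:
                raise ValueError(f"unknown factor {f!r}")
        for a, b, v in self.interaction_specs:
            if v < 0:
                raise ValueError("negative interaction weight")
        self.factor_weights  # raises if fractions exceed 1
        if self.n_subjects_per_group < 1 or self.cells_per_cluster < 1:
            raise ValueError("subject and cell counts must be positive")


@dataclass
class SyntheticDataset:
    """Expression matrix plus aligned per-cell metadata and ground truth."""

    expression: np.ndarray  # cells x n_features, each column mean 0 / var 1
    cell_meta: pd.DataFrame  # cell_id, subject_id, condition, cluster, ...
    config: SimulationConfig

    @property
    def n_cells(self) -> int:
        return self.expression.shape[0]

    @property
    def feature_names(self) -> list[str]:
        return [f"feature_{i + 1}" for i in range(self.expression.shape[1])]


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

_BENCHMARK_VE = {"cell_type": 0.5, "subject": 0.05, "batch": 0.05}


def preset(name: str, **overrides) -> SimulationConfig:
    """Return one of the benchmark scenario configs.

    ``dataset1``: 15+15 subjects, 10 equally proportioned clusters A-J,
    ~100 cells per cluster per control subject, clusters A and J expanded
    at a proportion fold-change of 3.

    ``dataset2``: same cohort, but the weak expansion parameter 0.1
    (fractional mode, realized ratio 1.1) applied to A and J.

    ``interaction``: disease-by-sex abundance interaction; major clusters
    A (depleted) / B (expanded) and rare clusters I / J at 5% of cells,
    shifted only in female disease subjects (ratios 1/3 and 3).
    """
    if name == "dataset1":
        cfg = SimulationConfig(
            fold_changes={"A": 3.0, "J": 3.0},
            fold_mode="ratio",
            variance_fractions=dict(_BENCHMARK_VE),
        )
    elif name == "dataset2":
        cfg = SimulationConfig(
            fold_changes={"A": 0.1, "J": 0.1},
            fold_mode="fractional",
            variance_fractions=dict(_BENCHMARK_VE),
        )
    elif name == "interaction":
        rare = 0.05
        major = (1.0 - 2 * rare) / 8.0
        cfg = SimulationConfig(
            cluster_proportions=tuple([major] * 8 + [rare, rare]),
            fold_changes={"A": 1 / 3, "B": 3.0, "I": 1 / 3, "J": 3.0},
            fold_mode="ratio",
            abundance_stratum={"sex": "F"},
            covariates=("subject", "batch", "sex"),
            variance_fractions=dict(_BENCHMARK_VE),
        )
    else:
        raise ValueError(
            f"unknown preset {name!r}; valid presets: dataset1, dataset2, interaction"
        )
    if overrides:
        cfg = replace(cfg, **overrides)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# abundance planning
# ---------------------------------------------------------------------------

def subject_table(config: SimulationConfig) -> pd.DataFrame:
    """Subject-level metadata: id, condition, sex, batch, age.

    Sexes and batches alternate within each condition group (balanced up to
    parity); age is uniform on [20, 80] per subject, drawn from the
    metadata stream of the config seed.
    """
    rows = []
    rng = _rng(config.seed, 1)
    for cond in ("control", "disease"):
        for i in range(config.n_subjects_per_group):
            rows.append(
                {
                    "subject_id": f"{cond[0].upper()}{i + 1:02d}",
                    "condition": cond,
                    "sex": "F" if i % 2 == 0 else "M",
                    "batch": f"batch{i % config.n_batches + 1}",
                    "age": float(np.round(rng.uniform(20, 80), 1)),
                }
            )
    return pd.DataFrame(rows)


def _in_stratum(subject_row: pd.Series, stratum: Mapping[str, str] | None) -> bool:
    if not stratum:
        return True
    return all(subject_row[k] == v for k, v in stratum.items())


def plan_abundance(
    config: SimulationConfig, subjects: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-(subject, cluster) cell counts realizing the configured fold-changes.

    Control subjects get ``round(cells_per_cluster * p_j / max(p))`` cells of
    cluster ``j``.  For disease subjects (inside the abundance stratum, if
    any), targeted cluster counts ``x_j`` are solved jointly so that each
    targeted cluster's expected within-subject proportion is ``f_j`` times
    its control proportion, while untargeted counts are left unchanged:

        T_d = sum_untargeted c_j / (1 - sum_targeted f_j * c_j / T_c)
        x_j = f_j * (c_j / T_c) * T_d
    """
    config.validate()
    if subjects is None:
        subjects = subject_table(config)
    p = config.proportions
    base = np.round(config.cells_per_cluster * p / p.max()).astype(int)
    t_control = int(base.sum())
    if t_control == 0:
        raise ValueError("empty baseline plan")

    targeted = [j for j in config.clusters if config.realized_ratio(j) != 1.0]
    ratios = {j: config.realized_ratio(j) for j in config.clusters}
    frac = sum(
        ratios[j] * base[config.clusters.index(j)] / t_control for j in targeted
    )
    if frac >= 1.0:
        raise ValueError(
            "targeted fold changes are too large to realize as proportions "
            f"(sum f_j * p_j = {frac:.3f} >= 1)"
        )
    rest = sum(
        base[i] for i, j in enumerate(config.clusters) if j not in targeted
    )
    t_disease = rest / (1.0 - frac)

    shifted = {}
    for i, j in enumerate(config.clusters):
        if j in targeted:
            shifted[j] = int(round(ratios[j] * (base[i] / t_control) * t_disease))
        else:
            shifted[j] = int(base[i])

    jitter_rng = _rng(config.seed, 2) if config.poisson_jitter else None
    rows = []
    for _, subj in subjects.iterrows():
        shift = subj["condition"] == "disease" and _in_stratum(
            subj, config.abundance_stratum
        )
        for i, j in enumerate(config.clusters):
            n = shifted[j] if shift else int(base[i])
            if jitter_rng is not None:
                n = int(jitter_rng.poisson(n))
            rows.append(
                {
                    "subject_id": subj["subject_id"],
                    "condition": subj["condition"],
                    "cluster": j,
                    "n_cells": n,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# signal generation
# ---------------------------------------------------------------------------

def _standardize(x: np.ndarray, name: str = "signal") -> np.ndarray:
    mu = x.mean()
    sd = x.std()
    if sd == 0:
        raise ValueError(f"zero variance before standardization for factor {name!r}")
    return (x - mu) / sd


def sample_factor_signal(
    level_labels: Sequence,
    level_means: Mapping,
    sd: float,
    rng: np.random.Generator | int,
    name: str = "factor",
) -> np.ndarray:
    """Standardized pure signal for one factor.

    Each cell's value is drawn from N(mu_level, sd^2) where ``mu_level`` is
    the mean assigned to the cell's factor level; the vector is then
    standardized to zero mean / unit variance across cells.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    labels = np.asarray(level_labels)
    if labels.size < 2:
        raise ValueError("need at least two cells to standardize a signal")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    missing = set(pd.unique(labels)) - set(level_means)
    if missing:
        raise ValueError(f"levels without a mean for factor {name!r}: {sorted(missing)}")
    mu = np.array([level_means[l] for l in labels], dtype=float)
    x = mu + rng.normal(0.0, sd, size=labels.size)
    return _standardize(x, name)


def compose_feature(
    signals: Mapping[str, np.ndarray],
    factor_weights: Mapping[str, float],
    noise_weight: float | None = None,
    interaction_weights: Sequence[tuple[str, str, float]] = (),
    rng: np.random.Generator | int | None = None,
    noise_signal: np.ndarray | None = None,
) -> np.ndarray:
    """Weighted linear combination of standardized signals, rescaled to
    mean 0 / sd 1.

    Weights (factor amplitudes, interaction amplitudes and the noise
    amplitude) are renormalized so their squares sum to 1; the variance
    explained by factor ``f`` in the output is then ``w_f**2`` when signals
    are independent.  Interaction terms are elementwise products of two
    standardized signals, themselves standardized before weighting.
    """
    for f, w in list(factor_weights.items()) + [
        (f"{a}x{b}", w) for a, b, w in interaction_weights
    ]:
        if w < 0:
            raise ValueError(f"negative weight for {f!r}")
    lengths = {len(v) for v in signals.values()}
    if len(lengths) > 1:
        raise ValueError("signal vectors have mismatched lengths")
    if lengths:
        n = lengths.pop()
    elif noise_signal is not None:
        n = len(noise_signal)
    else:
        raise ValueError("no signals given; provide noise_signal to fix the length")

    if noise_signal is None:
        if isinstance(rng, (int, np.integer)):
            rng = np.random.default_rng(rng)
        if rng is None:
            raise ValueError("need rng or noise_signal")
        noise_signal = rng.normal(size=n)
    noise_signal = _standardize(np.asarray(noise_signal, dtype=float), "noise")

    weights = []
    parts = []
    for f, w in factor_weights.items():
        if w == 0:
            continue
        weights.append(w)
        parts.append(np.asarray(signals[f], dtype=float))
    for a, b, w in interaction_weights:
        if w == 0:
            continue
        weights.append(w)
        parts.append(_standardize(signals[a] * signals[b], f"{a}x{b}"))
    nw = 0.0 if noise_weight is None else float(noise_weight)
    norm = math.sqrt(sum(w * w for w in weights) + nw * nw)
    if norm == 0:
        raise ValueError("all weights are zero")
    x = np.zeros(n)
    for w, s in zip(weights, parts):
        x += (w / norm) * s
    x += (nw / norm) * noise_signal
    return _standardize(x, "feature")


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

def _level_means(levels: Sequence, rng: np.random.Generator) -> dict:
    """Equally spaced integer means, permuted per feature so that clusters
    occupy distinct positions along different features."""
    order = rng.permutation(len(levels))
    return {lvl: float(order[i]) for i, lvl in enumerate(levels)}


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate metadata (abundance plan) and expression features.

    Fully reproducible given ``config.seed``: feature ``k`` draws from an
    independent child stream keyed by ``k``, so adding features never
    perturbs earlier ones.
    """
    config.validate()
    subjects = subject_table(config)
    plan = plan_abundance(config, subjects)

    meta_rows = []
    idx = 0
    subj_attrs = subjects.set_index("subject_id")
    for _, row in plan.iterrows():
        subj = subj_attrs.loc[row["subject_id"]]
        for _ in range(int(row["n_cells"])):
            meta_rows.append(
                (
                    f"cell_{idx + 1:06d}",
                    row["subject_id"],
                    row["condition"],
                    row["cluster"],
                    subj["batch"],
                    subj["sex"],
                    subj["age"],
                )
            )
            idx += 1
    meta = pd.DataFrame(
        meta_rows,
        columns=["cell_id", "subject_id", "condition", "cluster", "batch", "sex", "age"],
    )

    # ground truth: targeted cluster AND the condition/stratum where the
    # shift was injected; direction records expansion (+1) vs depletion (-1)
    direction = np.zeros(len(meta), dtype=int)
    for j in config.clusters:
        r = config.realized_ratio(j)
        if r == 1.0:
            continue
        d = 1 if r > 1 else -1
        in_cluster = meta["cluster"].to_numpy() == j
        direction[in_cluster] = d
    in_stratum = np.ones(len(meta), dtype=bool)
    if config.abundance_stratum:
        for k, v in config.abundance_stratum.items():
            in_stratum &= meta[k].to_numpy() == v
    truth = (
        (direction != 0)
        & (meta["condition"].to_numpy() == "disease")
        & in_stratum
    )
    meta["truth_flag"] = truth
    meta["truth_direction"] = np.where(truth, direction, 0)

    n = len(meta)
    weights = config.factor_weights
    inter = config.interaction_weights
    active = [f for f, w in weights.items() if w > 0]
    for a, b, w in inter:
        for f in (a, b):
            if f not in active:
                active.append(f)

    labels = {
        "cell_type": meta["cluster"].to_numpy(),
        "disease": meta["condition"].to_numpy(),
        "subject": meta["subject_id"].to_numpy(),
        "batch": meta["batch"].to_numpy(),
        "sex": meta["sex"].to_numpy(),
    }
    levels = {f: list(pd.unique(labels[f])) for f in labels}
    ages = meta["age"].to_numpy()

    expr = np.empty((n, config.n_features))
    for k in range(config.n_features):
        rng = _rng(config.seed, 0, k)
        signals: dict[str, np.ndarray] = {}
        for f in active:
            if f == "age":
                signals[f] = _standardize(
                    ages + rng.normal(0.0, config.sigma, size=n), "age"
                )
            else:
                means = _level_means(levels[f], rng)
                signals[f] = sample_factor_signal(
                    labels[f], means, config.sigma, rng, name=f
                )
        expr[:, k] = compose_feature(
            signals,
            {f: weights.get(f, 0.0) for f in active},
            config.noise_weight,
            inter,
            noise_signal=rng.normal(size=n),
        )
    return SyntheticDataset(expression=expr, cell_meta=meta, config=config)
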