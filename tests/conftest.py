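import numpy as np
import pandas as pd
import pytest

from phenoscore import (
    DesignMatrix,
    ModelConfig,
    nested_cv_fit,
    preset,
    simulate_dataset,
)

# small, fast nested-CV settings shared by fixtures
TINY_MODEL = dict(
    n_outer_folds=3,
    n_inner_folds=2,
    n_repeats=2,
    search_budget=2,
    search_space={"n_estimators": [25], "max_depth": [4, 6], "min_samples_leaf": [2]},
)


def make_blob_design(n_per_sample=40, n_samples=12, separation=6.0, seed=0, shuffle_y=False):
    """Two-class Gaussian blob design with sample grouping."""
    rng = np.random.default_rng(seed)
    rows, y, groups = [], [], []
    for s in range(n_samples):
        label = s % 2
        center = np.array([separation * label, -separation * label, 0.0])
        rows.append(center + rng.normal(size=(n_per_sample, 3)))
        y += [label] * n_per_sample
        groups += [f"s{s:02d}"] * n_per_sample
    x = np.vstack(rows)
    y = np.asarray(y)
    if shuffle_y:
        # permute at the sample level so grouping stays meaningful
        perm = rng.permutation(n_samples)
        remap = {f"s{s:02d}": perm[s] % 2 for s in range(n_samples)}
        y = np.asarray([remap[g] for g in groups])
    return DesignMatrix(
        values=x,
        columns=["LD1", "LD2", "LD3"],
        roles=["latent"] * 3,
        y=y,
        class_names=["neg", "pos"],
        groups=np.asarray(groups),
        cell_ids=[f"c{i}" for i in range(len(y))],
    )


@pytest.fixture(scope="session")
def blob_fit():
    """Nested-CV fit on cleanly separable blobs (shared, expensive)."""
    design = make_blob_design(seed=1)
    fit = nested_cv_fit(design, ModelConfig(seed=1, **TINY_MODEL))
    return design, fit


@pytest.fixture(scope="session")
def small_dataset():
    """A small dataset1-preset cohort for structural checks."""
    cfg = preset("dataset1", cells_per_cluster=10, n_subjects_per_group=5, seed=7)
    return simulate_dataset(cfg)
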