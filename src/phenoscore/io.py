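"""Reading and writing the pipeline's file formats.

Expression travels as a Matrix Market triplet (cells as rows by default)
with features/barcodes TSVs, or as a single dense delimited table;
metadata as TSV keyed by cell_id.  Every derived artifact (NAM, embedding,
scores) is CSV/TSV with a small JSON sidecar recording its parameters.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .simulate import SyntheticDataset

__all__ = [
    "write_dataset",
    "read_inputs",
    "write_matrix_csv",
    "write_json",
    "read_json",
]

META_COLUMNS = ["cell_id", "subject_id", "condition", "cluster", "batch", "sex", "age"]


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=str) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


def write_dataset(dataset: SyntheticDataset, out_dir, fmt: str = "mtx") -> dict:
    """Write expression + metadata; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = dataset.cell_meta
    paths = {"metadata": out / "metadata.tsv"}
    meta.to_csv(paths["metadata"], sep="\t", index=False)
    if fmt == "mtx":
        paths["expression"] = out / "expression.mtx"
        mmwrite(str(paths["expression"]), sp.csr_matrix(dataset.expression))
        paths["features"] = out / "features.tsv"
        paths["barcodes"] = out / "barcodes.tsv"
        pd.Series(dataset.feature_names).to_csv(
            paths["features"], sep="\t", index=False, header=False
        )
        meta["cell_id"].to_csv(paths["barcodes"], sep="\t", index=False, header=False)
    elif fmt == "csv":
        paths["expression"] = out / "expression.csv"
        pd.DataFrame(
            dataset.expression, index=meta["cell_id"], columns=dataset.feature_names
        ).to_csv(paths["expression"])
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return {k: str(v) for k, v in paths.items()}


def _read_expression(path, features=None, barcodes=None, cells_as_rows=True):
    path = Path(path)
    if path.suffix == ".mtx":
        mat = mmread(str(path))
        x = np.asarray(mat.todense() if sp.issparse(mat) else mat, dtype=float)
        if not cells_as_rows:
            x = x.T
        feat = (
            pd.read_csv(features, sep="\t", header=None)[0].astype(str).tolist()
            if features
            else [f"feature_{i + 1}" for i in range(x.shape[1])]
        )
        cells = (
            pd.read_csv(barcodes, sep="\t", header=None)[0].astype(str).tolist()
            if barcodes
            else [f"cell_{i + 1}" for i in range(x.shape[0])]
        )
        return pd.DataFrame(x, index=cells, columns=feat)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    if not cells_as_rows:
        df = df.T
    bad = df.columns[~df.dtypes.map(pd.api.types.is_numeric_dtype)]
    if len(bad):
        raise ValueError(f"non-numeric matrix entries in columns: {list(bad[:5])}")
    return df


def read_inputs(
    expression_path,
    metadata_path,
    features=None,
    barcodes=None,
    cells_as_rows: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Load and align expression and metadata by cell id.

    Metadata rows are reordered to the matrix's cell order; mismatches
    raise with the first offending ids named.
    """
    expr = _read_expression(expression_path, features, barcodes, cells_as_rows)
    meta = pd.read_csv(metadata_path, sep="\t")
    if "cell_id" not in meta.columns:
        raise ValueError("metadata must contain a cell_id column")
    meta["cell_id"] = meta["cell_id"].astype(str)
    expr.index = expr.index.astype(str)

    dup = meta["cell_id"][meta["cell_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate cell ids in metadata: {dup.head(5).tolist()}")
    if expr.index.duplicated().any():
        dup = expr.index[expr.index.duplicated()]
        raise ValueError(f"duplicate cell ids in matrix: {list(dup[:5])}")

    matrix_ids = set(expr.index)
    meta_ids = set(meta["cell_id"])
    missing = sorted(matrix_ids - meta_ids)
    if missing:
        raise ValueError(f"metadata missing matrix cells: {missing[:5]}")
    extra = sorted(meta_ids - matrix_ids)
    if extra:
        raise ValueError(f"metadata has cells absent from matrix: {extra[:5]}")
    meta = (
        meta.set_index("cell_id")
        .loc[expr.index]
        .rename_axis("cell_id")
        .reset_index()
    )
    return expr, meta


def write_matrix_csv(matrix, path, index=None, columns=None) -> None:
    pd.DataFrame(np.asarray(matrix), index=index, columns=columns).to_csv(path)
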