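"""Readers and writers for the pipeline's plain-text formats.

Single-cell counts go to MatrixMarket (.mtx) plus gene/cell TSV indexes, or
to a dense TSV; bulk expression and clinical metadata to TSV; simulation
truth and reports to JSON; configuration to YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import io as scipy_io
from scipy import sparse

from .datatypes import META_COLUMNS, BulkCohort, SimTruth, SingleCellMatrix


def write_single_cell(matrix: SingleCellMatrix, out_dir, dense: bool = False) -> None:
    """Write counts as MTX + genes.tsv/cells.tsv, or as one dense TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cells = pd.DataFrame(
        {"cell_id": matrix.cell_ids, "cluster": matrix.cluster_labels}
    )
    if dense:
        df = pd.DataFrame(
            matrix.counts, index=matrix.gene_ids, columns=matrix.cell_ids
        )
        df.to_csv(out / "counts.tsv", sep="\t", index_label="gene_id")
        cells.to_csv(out / "cells.tsv", sep="\t", index=False)
    else:
        scipy_io.mmwrite(out / "counts.mtx", sparse.coo_matrix(matrix.counts))
        pd.Series(matrix.gene_ids, name="gene_id").to_csv(
            out / "genes.tsv", sep="\t", index=False
        )
        cells.to_csv(out / "cells.tsv", sep="\t", index=False)


def read_single_cell(in_dir) -> SingleCellMatrix:
    """Read counts written by :func:`write_single_cell` (either layout)."""
    src = Path(in_dir)
    cells = pd.read_csv(src / "cells.tsv", sep="\t")
    if (src / "counts.mtx").exists():
        counts = np.asarray(
            scipy_io.mmread(src / "counts.mtx").todense()
        ).astype(int)
        genes = pd.read_csv(src / "genes.tsv", sep="\t")["gene_id"].tolist()
    else:
        df = pd.read_csv(src / "counts.tsv", sep="\t", index_col="gene_id")
        counts = df.to_numpy().astype(int)
        genes = df.index.tolist()
    return SingleCellMatrix(
        counts=counts,
        gene_ids=genes,
        cell_ids=cells["cell_id"].tolist(),
        cluster_labels=cells["cluster"].to_numpy(),
    )


def write_bulk_cohort(cohort: BulkCohort, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.expr.to_csv(out / "expression.tsv", sep="\t", index_label="sample_id")
    cohort.meta.to_csv(out / "metadata.tsv", sep="\t", index_label="sample_id")


def read_bulk_cohort(expr_path, meta_path, require_survival: bool = False) -> BulkCohort:
    """Load a bulk cohort from TSV, validating the metadata schema up front."""
    expr = pd.read_csv(expr_path, sep="\t", index_col="sample_id")
    meta = pd.read_csv(meta_path, sep="\t", index_col="sample_id")
    required = list(META_COLUMNS) if require_survival else [
        c for c in META_COLUMNS if not c.startswith("pfs_")
    ]
    for col in required:
        if col not in meta.columns:
            raise ValueError(f"metadata is missing required column {col!r}")
    meta = meta.loc[expr.index]
    return BulkCohort(expr=expr, meta=meta)


def write_truth(truth: SimTruth, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=2, default=float)


def read_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def write_yaml(obj: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)
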