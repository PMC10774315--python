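"""Core data containers shared across the pipeline.

Two matrices drive the analysis: a single-cell count matrix with cluster
labels (the source of stromal markers) and one or more bulk expression
cohorts with clinical/survival metadata (the material the pair classifier
is trained and evaluated on).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Gleason grade categories, lowest ("<=6") is the reference level in Cox models.
GLEASON_LEVELS = ("<=6", "7", "8", "9", "10")

#: Clinical metadata columns every bulk cohort must carry.
META_COLUMNS = (
    "dataset",
    "met_event",
    "gleason",
    "age",
    "psa",
    "stage",
    "pfs_months",
    "pfs_event",
)


@dataclass
class SingleCellMatrix:
    """Genes x cells integer count matrix with per-cell cluster labels.

    Parameters
    ----------
    counts : ndarray of shape (n_genes, n_cells)
        Non-negative integer counts.
    gene_ids, cell_ids : sequences of unique strings.
    cluster_labels : one label per cell.
    """

    counts: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    cluster_labels: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.cluster_labels = np.asarray(self.cluster_labels)
        n_genes, n_cells = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError("gene_ids length does not match counts rows")
        if len(self.cell_ids) != n_cells:
            raise ValueError("cell_ids length does not match counts columns")
        if len(self.cluster_labels) != n_cells:
            raise ValueError("every cell needs a cluster label")
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("duplicate gene ids")
        if len(set(self.cell_ids)) != n_cells:
            raise ValueError("duplicate cell ids")
        if not np.isfinite(self.counts).all() or (self.counts < 0).any():
            raise ValueError("counts must be finite and non-negative")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def clusters(self) -> list[str]:
        """Cluster labels present, in order of first appearance."""
        return list(pd.unique(self.cluster_labels))


@dataclass
class BulkCohort:
    """Bulk expression cohort: samples x genes matrix plus clinical metadata.

    ``expr`` is log-scale expression indexed by sample id; ``meta`` is indexed
    identically and carries ``dataset``, the metastasis label ``met_event``,
    ``gleason`` (categorical <=6/7/8/9/10), ``age``, ``psa``, ``stage`` and —
    once survival has been attached — ``pfs_months``/``pfs_event``.
    """

    expr: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.expr.index.equals(self.meta.index):
            raise ValueError("expr and meta must share the same sample index")
        if self.expr.index.has_duplicates:
            raise ValueError("sample ids must be unique")
        if "dataset" not in self.meta.columns:
            raise ValueError("meta must carry a 'dataset' column")
        if self.expr.isna().any().any():
            raise ValueError("expression matrix contains missing values")

    @property
    def n_samples(self) -> int:
        return self.expr.shape[0]

    @property
    def genes(self) -> pd.Index:
        return self.expr.columns

    @property
    def sample_ids(self) -> pd.Index:
        return self.expr.index

    def subset(self, sample_ids) -> "BulkCohort":
        """Row-subset by sample id, preserving order of ``sample_ids``."""
        return BulkCohort(self.expr.loc[sample_ids], self.meta.loc[sample_ids])

    def split_by_dataset(self) -> list["BulkCohort"]:
        """One cohort per dataset id, in order of first appearance."""
        out = []
        for ds in pd.unique(self.meta["dataset"]):
            mask = self.meta["dataset"] == ds
            out.append(BulkCohort(self.expr.loc[mask], self.meta.loc[mask]))
        return out


@dataclass
class SimTruth:
    """Ground truth of a simulation run, for recovery tests.

    ``planted_markers`` rows: (cluster, gene, logfc_effect, base_mean) — the
    negative-binomial base mean lets tests compute the analytic detection/mean
    shift. ``planted_pairs`` rows: (up_gene, down_gene, delta_met, delta_nonmet)
    with the realized probit mean offsets per class.
    """

    planted_markers: pd.DataFrame = field(default_factory=pd.DataFrame)
    planted_pairs: pd.DataFrame = field(default_factory=pd.DataFrame)
    seed: int = 0

    def marker_genes(self, cluster: str) -> set[str]:
        if self.planted_markers.empty:
            return set()
        tab = self.planted_markers
        return set(tab.loc[tab["cluster"] == cluster, "gene"])

    def pair_set(self) -> set[tuple[str, str]]:
        if self.planted_pairs.empty:
            return set()
        return set(
            zip(self.planted_pairs["up_gene"], self.planted_pairs["down_gene"])
        )

    def to_dict(self) -> dict:
        return {
            "seed": int(self.seed),
            "planted_markers": self.planted_markers.to_dict(orient="records"),
            "planted_pairs": self.planted_pairs.to_dict(orient="records"),
        }
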