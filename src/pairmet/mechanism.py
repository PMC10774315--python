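"""Build the biological-constraint candidate pair set from cluster markers.

Each stromal cluster's marker table is split by the sign of avg logFC into
positive (up-regulated) and negative (down-regulated) markers; the top
``n_top`` of each side are crossed into oriented (up, down) candidate pairs.
The pooled, deduplicated union across clusters is the constraint the k-TSP
search is restricted to; the cluster-tagged multiset is kept for audit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .hurdle import FDR_MAX


@dataclass
class MechanismPairSet:
    """Cluster-tagged oriented candidate pairs plus the pooled training view."""

    entries: pd.DataFrame  # columns: cluster, up_gene, down_gene
    counts_per_cluster: dict[str, int] = field(default_factory=dict)

    @property
    def n_pairs(self) -> int:
        """Cluster-tagged total (pairs counted once per source cluster)."""
        return len(self.entries)

    @property
    def pooled(self) -> pd.DataFrame:
        """Deduplicated (up_gene, down_gene) pairs, for training."""
        if self.entries.empty:
            return pd.DataFrame(columns=["up_gene", "down_gene"])
        return (
            self.entries[["up_gene", "down_gene"]]
            .drop_duplicates()
            .reset_index(drop=True)
        )

    def genes(self) -> set[str]:
        if self.entries.empty:
            return set()
        return set(self.entries["up_gene"]) | set(self.entries["down_gene"])


def build_mechanism(
    marker_tables: Mapping[str, pd.DataFrame],
    n_top: int = 100,
    fdr_max: float = FDR_MAX,
) -> MechanismPairSet:
    """Cross each cluster's top positive and negative markers into pairs.

    Parameters
    ----------
    marker_tables : mapping cluster id -> marker table with columns
        gene, avg_logfc, fdr (as produced by :func:`pairmet.hurdle.rank_markers`).
    n_top : markers taken from each side of each cluster (paper default 100).
    fdr_max : significance gate applied before slicing.

    A cluster lacking positive or negative significant markers contributes
    no pairs (non-fatal warning). With three clusters each holding >= n_top
    markers per side, the cluster-tagged total is 3 * n_top^2.
    """
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    rows = []
    counts: dict[str, int] = {}
    for cluster, table in marker_tables.items():
        sig = table[table["fdr"] < fdr_max]
        pos = sig[sig["avg_logfc"] > 0].sort_values(
            ["avg_logfc", "gene"], ascending=[False, True], kind="stable"
        )["gene"].head(n_top)
        neg = sig[sig["avg_logfc"] < 0].sort_values(
            ["avg_logfc", "gene"], ascending=[True, True], kind="stable"
        )["gene"].head(n_top)
        if len(pos) == 0 or len(neg) == 0:
            warnings.warn(
                f"cluster {cluster!r} has no "
                f"{'positive' if len(pos) == 0 else 'negative'} markers; "
                "0 pairs contributed"
            )
            counts[cluster] = 0
            continue
        for up in pos:
            for down in neg:
                rows.append({"cluster": cluster, "up_gene": up, "down_gene": down})
        counts[cluster] = len(pos) * len(neg)
    entries = pd.DataFrame(rows, columns=["cluster", "up_gene", "down_gene"])
    return MechanismPairSet(entries=entries, counts_per_cluster=counts)
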