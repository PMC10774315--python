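"""Shared fixtures: tiny programmatically built cohorts and marker tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pairmet.datatypes import BulkCohort


def make_cohort(
    expr: np.ndarray,
    met: np.ndarray,
    genes: list[str] | None = None,
    dataset: str = "ds1",
    seed: int = 0,
) -> BulkCohort:
    """Wrap an expression array and labels into a minimal BulkCohort."""
    rng = np.random.default_rng(seed)
    n = expr.shape[0]
    genes = genes or [f"g{j}" for j in range(expr.shape[1])]
    idx = pd.Index([f"s{i}" for i in range(n)], name="sample_id")
    meta = pd.DataFrame(
        {
            "dataset": dataset,
            "met_event": np.asarray(met, dtype=int),
            "gleason": rng.choice(["<=6", "7", "8", "9", "10"], size=n),
            "age": rng.normal(66, 7, size=n).round(1),
            "psa": np.exp(rng.normal(2.2, 0.7, size=n)).round(2),
            "stage": rng.choice(["T1", "T2", "T3", "T4"], size=n),
            "pfs_months": np.nan,
            "pfs_event": np.nan,
        },
        index=idx,
    )
    return BulkCohort(expr=pd.DataFrame(np.asarray(expr, float), index=idx, columns=genes), meta=meta)


@pytest.fixture
def cohort_factory():
    return make_cohort


def make_marker_table(
    cluster: str, n_pos: int, n_neg: int, fdr: float = 1e-6
) -> pd.DataFrame:
    """A synthetic marker table with n_pos positive and n_neg negative markers."""
    rows = []
    for i in range(n_pos):
        rows.append(
            {"gene": f"{cluster}_up{i:03d}", "cluster": cluster,
             "avg_logfc": 2.0 - i * 1e-3, "fdr": fdr, "p_value": fdr}
        )
    for i in range(n_neg):
        rows.append(
            {"gene": f"{cluster}_dn{i:03d}", "cluster": cluster,
             "avg_logfc": -2.0 + i * 1e-3, "fdr": fdr, "p_value": fdr}
        )
    return pd.DataFrame(rows)


@pytest.fixture
def marker_table_factory():
    return make_marker_table
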