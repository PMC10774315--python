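"""Cross-cohort harmonization, stratified splitting and quantile normalization.

The harmonization recipe mirrors standard multi-cohort expression practice:
log2-scale each dataset (if linear), z-score each gene within its dataset
(which absorbs per-dataset location/scale batch effects), intersect gene
sets and concatenate. The train/test split stratifies jointly on dataset,
Gleason grade, age tertile, PSA tertile and stage with largest-remainder
allocation; quantile normalization is then applied to each partition
separately so no test-set information touches training.
"""

from __future__ import annotations

import math
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import BulkCohort

DEFAULT_STRATA = ("dataset", "gleason", "age", "psa", "stage")


def harmonize(
    datasets: Sequence[BulkCohort], linear: bool | Sequence[bool] = False
) -> BulkCohort:
    """Per-dataset gene-wise z-scoring, gene intersection, concatenation.

    ``linear`` flags datasets whose expression is on the linear scale and
    must be log2(x+1) transformed first. Genes constant within any dataset
    are dropped from every dataset (warning); an empty gene intersection is
    an error. Already-z-scored input passes through unchanged.
    """
    if len(datasets) == 0:
        raise ValueError("need at least one dataset")
    if isinstance(linear, bool):
        linear = [linear] * len(datasets)
    common: pd.Index | None = None
    for ds in datasets:
        common = ds.genes if common is None else common.intersection(ds.genes)
    if len(common) == 0:
        raise ValueError("empty gene intersection across datasets")

    transformed: list[pd.DataFrame] = []
    constant: set[str] = set()
    for ds, lin in zip(datasets, linear):
        if ds.n_samples < 2:
            raise ValueError("each dataset needs >= 2 samples")
        x = ds.expr[common]
        if lin:
            x = np.log2(x + 1.0)
        sd = x.std(axis=0, ddof=0)
        constant |= set(sd.index[sd == 0.0])
        transformed.append(x)
    if constant:
        warnings.warn(
            f"dropping {len(constant)} gene(s) constant within a dataset"
        )
        common = common.difference(pd.Index(sorted(constant)))
        if len(common) == 0:
            raise ValueError("no genes left after dropping constant genes")

    z_blocks, metas = [], []
    for ds, x in zip(datasets, transformed):
        x = x[common]
        z = (x - x.mean(axis=0)) / x.std(axis=0, ddof=0)
        z_blocks.append(z)
        metas.append(ds.meta)
    return BulkCohort(expr=pd.concat(z_blocks), meta=pd.concat(metas))


def _tertile_labels(values: pd.Series) -> pd.Series:
    """Tertile bins on the full cohort; missing values become 'unknown'."""
    out = pd.Series("unknown", index=values.index, dtype=object)
    ok = values.notna()
    if ok.sum() >= 3:
        out[ok] = pd.qcut(values[ok], 3, labels=False, duplicates="drop").astype(str)
    elif ok.any():
        out[ok] = "all"
    return out


def _strata_keys(cohort: BulkCohort, strata_vars: Sequence[str]) -> pd.Series:
    parts = []
    for var in strata_vars:
        if var not in cohort.meta.columns:
            raise ValueError(f"stratum variable {var!r} missing from metadata")
        col = cohort.meta[var]
        if var in ("age", "psa"):
            parts.append(_tertile_labels(pd.to_numeric(col, errors="coerce")))
        else:
            parts.append(col.astype(object).where(col.notna(), "unknown").astype(str))
    key = parts[0]
    for p in parts[1:]:
        key = key.str.cat(p, sep="|")
    return key


def stratified_split(
    cohort: BulkCohort,
    train_frac: float = 0.75,
    strata_vars: Sequence[str] = DEFAULT_STRATA,
    seed: int = 0,
) -> tuple[BulkCohort, BulkCohort]:
    """Stratified train/test partition with largest-remainder allocation.

    Strata are the cross of dataset x Gleason x age tertile x PSA tertile x
    stage. Each stratum contributes floor(n_s * train_frac) training samples
    plus at most one more, awarded by descending fractional remainder until
    the global training count reaches ceil(train_frac * n). Singleton strata
    go wholly to training (warning). The partition is disjoint and exhaustive.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must be in (0, 1)")
    n = cohort.n_samples
    target = math.ceil(train_frac * n)
    keys = _strata_keys(cohort, strata_vars)
    rng = np.random.default_rng(seed)

    strata = sorted(keys.unique())
    alloc: dict[str, int] = {}
    remainders = []
    singletons = 0
    for s in strata:
        n_s = int((keys == s).sum())
        if n_s == 1:
            alloc[s] = 1
            singletons += 1
            continue
        q = n_s * train_frac
        alloc[s] = int(math.floor(q))
        remainders.append((q - math.floor(q), s, n_s))
    if singletons:
        warnings.warn(f"{singletons} singleton stratum(s) assigned wholly to training")

    remaining = target - sum(alloc.values())
    # award the remainders; ties broken by stratum key for reproducibility
    for _, s, n_s in sorted(remainders, key=lambda t: (-t[0], t[1])):
        if remaining <= 0:
            break
        if alloc[s] < n_s:
            alloc[s] += 1
            remaining -= 1
    # if singleton strata overshot the target, pull back from smallest remainders
    if remaining < 0:
        for _, s, _ in sorted(remainders, key=lambda t: (t[0], t[1])):
            while remaining < 0 and alloc[s] > 0:
                alloc[s] -= 1
                remaining += 1

    train_ids: list = []
    for s in strata:
        members = cohort.sample_ids[(keys == s).to_numpy()]
        take = alloc[s]
        picked = rng.permutation(len(members))[:take]
        train_ids.extend(members[sorted(picked)])
    train_mask = cohort.sample_ids.isin(train_ids)
    return (
        cohort.subset(cohort.sample_ids[train_mask]),
        cohort.subset(cohort.sample_ids[~train_mask]),
    )


def quantile_normalize(expr: pd.DataFrame) -> pd.DataFrame:
    """Map every sample (row) onto the mean order-statistic profile.

    Each row's sorted values are replaced by the across-sample mean of the
    order statistics; ties within a row receive the average of their target
    quantiles. Afterwards all rows share one value multiset; the map is
    idempotent.
    """
    if expr.shape[0] < 2:
        warnings.warn("quantile normalization needs >= 2 samples; returning input")
        return expr.copy()
    values = expr.to_numpy(dtype=float)
    target = np.sort(values, axis=1).mean(axis=0)
    out = np.empty_like(values)
    for i, row in enumerate(values):
        order = np.argsort(row, kind="stable")
        assigned = np.empty_like(row)
        assigned[order] = target
        uniq, inv = np.unique(row, return_inverse=True)
        if len(uniq) < len(row):  # average target quantiles over ties
            sums = np.bincount(inv, weights=assigned)
            cnts = np.bincount(inv)
            assigned = (sums / cnts)[inv]
        out[i] = assigned
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)
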