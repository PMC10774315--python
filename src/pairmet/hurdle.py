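"""Two-part hurdle-model differential expression for single-cell data.

Single-cell expression is zero-inflated: a gene is either undetected in a
cell (a structural zero) or detected with a roughly log-normal positive
level. The hurdle model tests both parts jointly against a binary grouping:

* detection part — logistic model of the detection indicator on the group;
  with a single binary covariate the MLE is the 2x2 table of detection
  counts and the likelihood-ratio statistic has a closed form;
* continuous part — Gaussian model of log expression among detected cells,
  whose LRT is n * ln(RSS0 / RSS1) at the MLE variance.

The two statistics add to a chi-square(2) likelihood-ratio test (chi-square(1)
when a group has no detected cells and the continuous part is dropped).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import SingleCellMatrix

#: Minimum |avg logFC| (natural log) for a gene to be tested.
MIN_LOGFC = 0.25
#: Minimum detection fraction in either group for a gene to be tested.
MIN_PCT = 0.10
#: FDR gate for markers that feed the mechanism.
FDR_MAX = 0.05


@dataclass(frozen=True)
class HurdleFit:
    """One gene's two-part test result.

    ``detect_coef`` is the log-odds difference of detection between groups
    (+-inf on a boundary table); ``cont_coef`` the mean difference of log
    expression among detected cells (NaN when the continuous part is
    dropped); ``df`` is 2, or 1 when ``cont_dropped``.
    """

    detect_coef: float
    cont_coef: float
    lrt_stat: float
    p_value: float
    df: int
    cont_dropped: bool


def _binomial_ll(k: float, n: float) -> float:
    """Maximized Bernoulli log-likelihood of k successes in n (0*log0 = 0)."""
    if n == 0:
        return 0.0
    p = k / n
    ll = 0.0
    if k > 0:
        ll += k * np.log(p)
    if n - k > 0:
        ll += (n - k) * np.log(1.0 - p)
    return float(ll)


def fit_hurdle(expr: np.ndarray, group: np.ndarray) -> HurdleFit:
    """Fit the two-part hurdle model of ``expr`` on a binary ``group``.

    Parameters
    ----------
    expr : 1-d array of non-negative log expression; zero means undetected.
    group : boolean (or 0/1) array, same length; True is the in-group.
    """
    expr = np.asarray(expr, dtype=float)
    group = np.asarray(group, dtype=bool)
    if expr.shape != group.shape:
        raise ValueError("expr and group must have the same length")
    if group.all() or not group.any():
        raise ValueError("both groups must be non-empty")
    if (expr < 0).any():
        raise ValueError("expr must be non-negative (zeros = undetected)")

    det = expr > 0
    n1, n0 = int(group.sum()), int((~group).sum())
    k1, k0 = int(det[group].sum()), int(det[~group].sum())

    lrt_det = 2.0 * (
        _binomial_ll(k1, n1) + _binomial_ll(k0, n0) - _binomial_ll(k1 + k0, n1 + n0)
    )
    with np.errstate(divide="ignore"):
        l1 = np.log(k1) - np.log(n1 - k1)
        l0 = np.log(k0) - np.log(n0 - k0)
    # both groups on the same boundary (all or none detected): no difference
    detect_coef = 0.0 if l1 == l0 else float(l1 - l0)

    x1, x0 = expr[group & det], expr[~group & det]
    cont_dropped = len(x1) == 0 or len(x0) == 0
    if cont_dropped:
        lrt_cont, cont_coef = 0.0, float("nan")
    else:
        n_det = len(x1) + len(x0)
        rss1 = float(((x1 - x1.mean()) ** 2).sum() + ((x0 - x0.mean()) ** 2).sum())
        pooled = np.concatenate([x1, x0])
        rss0 = float(((pooled - pooled.mean()) ** 2).sum())
        if rss0 <= 0.0:
            lrt_cont = 0.0  # both groups constant at the same value
        elif rss1 <= 0.0:
            lrt_cont = float("inf")
        else:
            lrt_cont = n_det * float(np.log(rss0 / rss1))
        cont_coef = float(x1.mean() - x0.mean())

    df = 1 if cont_dropped else 2
    lrt = max(lrt_det + lrt_cont, 0.0)
    return HurdleFit(
        detect_coef=detect_coef,
        cont_coef=cont_coef,
        lrt_stat=lrt,
        p_value=float(stats.chi2.sf(lrt, df)),
        df=df,
        cont_dropped=cont_dropped,
    )


def log_normalize(counts: np.ndarray, scale: float = 1e4) -> np.ndarray:
    """Library-size normalize each cell to ``scale`` counts, then log1p."""
    counts = np.asarray(counts, dtype=float)
    libsize = counts.sum(axis=0)
    libsize[libsize == 0] = 1.0
    return np.log1p(counts / libsize[None, :] * scale)


def average_logfc(norm_in: np.ndarray, norm_out: np.ndarray) -> np.ndarray:
    """Natural-log fold change of group means on the de-logged scale.

    ln(mean(expm1(x_in)) + 1) - ln(mean(expm1(x_out)) + 1), per gene (rows).
    """
    mean_in = np.expm1(norm_in).mean(axis=1)
    mean_out = np.expm1(norm_out).mean(axis=1)
    return np.log(mean_in + 1.0) - np.log(mean_out + 1.0)


def rank_markers(
    matrix: SingleCellMatrix,
    cluster: str,
    *,
    min_logfc: float = MIN_LOGFC,
    min_pct: float = MIN_PCT,
    normalize: bool = True,
) -> pd.DataFrame:
    """Cluster-vs-rest hurdle DE with prefilters, BH FDR, sorted by avg logFC.

    Genes are prefiltered before any test: |avg logFC| >= ``min_logfc`` and
    detection in at least ``min_pct`` of cells in either group. The returned
    table has columns gene, cluster, avg_logfc, pct_in, pct_out, lrt_stat,
    p_value, fdr, cont_dropped, sorted by avg_logfc descending (positive
    markers first) so the mechanism can slice both ends.

    Set ``normalize=False`` when ``matrix.counts`` already holds log1p
    expression values.
    """
    labels = matrix.cluster_labels
    if cluster not in set(labels):
        raise KeyError(f"cluster {cluster!r} not present in labels")
    if len(set(labels)) < 2:
        raise ValueError("need at least 2 clusters")
    in_group = labels == cluster
    expr = log_normalize(matrix.counts) if normalize else np.asarray(
        matrix.counts, dtype=float
    )

    det = expr > 0
    pct_in = det[:, in_group].mean(axis=1)
    pct_out = det[:, ~in_group].mean(axis=1)
    logfc = average_logfc(expr[:, in_group], expr[:, ~in_group])
    keep = (np.abs(logfc) >= min_logfc) & (np.maximum(pct_in, pct_out) >= min_pct)

    rows = []
    for i in np.nonzero(keep)[0]:
        fit = fit_hurdle(expr[i], in_group)
        rows.append(
            {
                "gene": matrix.gene_ids[i],
                "cluster": cluster,
                "avg_logfc": float(logfc[i]),
                "pct_in": float(pct_in[i]),
                "pct_out": float(pct_out[i]),
                "lrt_stat": fit.lrt_stat,
                "p_value": fit.p_value,
                "cont_dropped": fit.cont_dropped,
            }
        )
    if not rows:
        warnings.warn(f"all genes filtered out for cluster {cluster!r}")
        return pd.DataFrame(
            columns=[
                "gene", "cluster", "avg_logfc", "pct_in", "pct_out",
                "lrt_stat", "p_value", "fdr", "cont_dropped",
            ]
        )
    table = pd.DataFrame(rows)
    table["fdr"] = multipletests(table["p_value"], method="fdr_bh")[1]
    table = table.sort_values("avg_logfc", ascending=False, kind="stable")
    cols = [
        "gene", "cluster", "avg_logfc", "pct_in", "pct_out",
        "lrt_stat", "p_value", "fdr", "cont_dropped",
    ]
    return table[cols].reset_index(drop=True)
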