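"""Mechanism-constrained k-top-scoring-pairs classifier.

A k-TSP model is an ordered list of k gene-disjoint (up, down) pairs. Each
pair votes for the metastatic class in a sample when the up gene's
expression exceeds the down gene's; the prediction is the majority vote.
Because votes depend only on within-sample orderings, the classifier is
invariant to any per-sample monotone transform of expression.

Pairs are scored by delta, the difference between classes in the empirical
probability of the inversion event expr(up) > expr(down), with the
within-sample rank-difference gap gamma as tie-breaker. The search is
restricted to the mechanism pair set derived from stromal cluster markers:
the constraint fixes each pair's orientation, so pairs are ranked by signed
delta and non-positive deltas are discarded.

The module follows the model/results convention: build a :class:`KTSP` from
a training cohort and mechanism, call :meth:`KTSP.fit`, and work with the
returned :class:`KTSPResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .datatypes import BulkCohort
from .mechanism import MechanismPairSet

#: Default CV grid of candidate signature sizes (odd so votes cannot deadlock).
DEFAULT_K_GRID = tuple(range(3, 26, 2))


@dataclass(frozen=True)
class ScoredPair:
    """An oriented candidate pair with its class-separation scores."""

    up_gene: str
    down_gene: str
    delta: float  # P(up>down | met) - P(up>down | non-met), in [-1, 1]
    gamma: float  # |rank-difference gap| between classes, >= 0

    @property
    def sort_key(self):
        return (-self.delta, -self.gamma, self.up_gene, self.down_gene)


def _met_labels(cohort: BulkCohort) -> np.ndarray:
    if "met_event" not in cohort.meta.columns:
        raise ValueError("cohort metadata lacks 'met_event'")
    y = cohort.meta["met_event"].to_numpy()
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("both outcome classes must be present in the cohort")
    return y.astype(int)


def _vote_matrix(expr: pd.DataFrame, up: np.ndarray, down: np.ndarray) -> np.ndarray:
    """Samples x pairs votes: 1 if up>down, 0 if <, 0.5 on an exact tie."""
    e = expr.to_numpy()
    cols = {g: i for i, g in enumerate(expr.columns)}
    iu = np.array([cols[g] for g in up])
    idn = np.array([cols[g] for g in down])
    diff = e[:, iu] - e[:, idn]
    return (diff > 0).astype(float) + 0.5 * (diff == 0)


def score_pairs(
    train: BulkCohort, mechanism: MechanismPairSet
) -> list[ScoredPair]:
    """Score every mechanism pair on the training cohort.

    delta is computed from within-class empirical inversion frequencies;
    gamma from within-sample ranks over the cohort's full gene panel.
    Mechanism genes absent from the cohort drop their pairs with a warning.
    Returns pairs sorted by (delta desc, gamma desc, gene ids).
    """
    y = _met_labels(train)
    pairs = mechanism.pooled
    present = set(train.genes)
    missing = mechanism.genes() - present
    if missing:
        warnings.warn(
            f"{len(missing)} mechanism gene(s) absent from cohort; "
            "their pairs are dropped"
        )
        pairs = pairs[
            pairs["up_gene"].isin(present) & pairs["down_gene"].isin(present)
        ]
    if pairs.empty:
        return []
    up = pairs["up_gene"].to_numpy()
    down = pairs["down_gene"].to_numpy()

    votes = _vote_matrix(train.expr, up, down)
    met, non = y == 1, y == 0
    delta = votes[met].mean(axis=0) - votes[non].mean(axis=0)

    ranks = rankdata(train.expr.to_numpy(), axis=1)
    cols = {g: i for i, g in enumerate(train.expr.columns)}
    iu = np.array([cols[g] for g in up])
    idn = np.array([cols[g] for g in down])
    rdiff = ranks[:, iu] - ranks[:, idn]
    gamma = np.abs(rdiff[met].mean(axis=0) - rdiff[non].mean(axis=0))

    scored = [
        ScoredPair(u, d, float(dl), float(g))
        for u, d, dl, g in zip(up, down, delta, gamma)
    ]
    return sorted(scored, key=lambda p: p.sort_key)


def select_pairs(scored: list[ScoredPair], k: int) -> list[ScoredPair]:
    """Greedy gene-disjoint selection of the k top pairs with delta > 0.

    Scans candidates in (delta desc, gamma desc, lexicographic) order,
    skipping any pair sharing a gene with an already selected one. Warns
    when fewer than k disjoint positive-delta pairs exist.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    used: set[str] = set()
    chosen: list[ScoredPair] = []
    for pair in sorted(scored, key=lambda p: p.sort_key):
        if pair.delta <= 0:
            break
        if pair.up_gene in used or pair.down_gene in used:
            continue
        chosen.append(pair)
        used.update((pair.up_gene, pair.down_gene))
        if len(chosen) == k:
            break
    if len(chosen) < k:
        warnings.warn(
            f"only {len(chosen)} disjoint positive-delta pairs available "
            f"(requested k={k})"
        )
    return chosen


def predict(
    pairs: list[ScoredPair], samples: BulkCohort, tie_class: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Majority-vote prediction: (vote_fraction in [0,1], class 0/1).

    A sample is called metastatic when vote_fraction >= 0.5 (the tie goes to
    the metastatic class by default — sensitivity-favoring, configurable via
    ``tie_class``). A model gene missing from ``samples`` is an error naming
    the gene.
    """
    if not pairs:
        raise ValueError("model has no pairs")
    present = set(samples.genes)
    for p in pairs:
        for g in (p.up_gene, p.down_gene):
            if g not in present:
                raise KeyError(f"model gene {g!r} missing from cohort")
    votes = _vote_matrix(
        samples.expr,
        np.array([p.up_gene for p in pairs]),
        np.array([p.down_gene for p in pairs]),
    )
    vote_fraction = votes.mean(axis=1)
    if tie_class == 1:
        classes = (vote_fraction >= 0.5).astype(int)
    else:
        classes = (vote_fraction > 0.5).astype(int)
    return vote_fraction, classes


def _auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    # local midrank Mann-Whitney to avoid importing the evaluation module
    r = rankdata(scores)
    n1 = labels.sum()
    n0 = len(labels) - n1
    return float((r[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def choose_k(
    train: BulkCohort,
    mechanism: MechanismPairSet,
    k_grid=DEFAULT_K_GRID,
    folds: int = 5,
    seed: int = 0,
) -> tuple[int, pd.DataFrame]:
    """Pick k by stratified cross-validation of the vote-fraction AUROC.

    For each fold, pairs are scored and greedily selected on the training
    folds up to max(k_grid); every k's model is a prefix of that selection,
    so one pass serves the whole grid. Returns the smallest k attaining the
    maximal mean held-fold AUROC, plus the CV table (k, mean_auroc).
    """
    k_grid = sorted(k_grid)
    if not k_grid:
        raise ValueError("k_grid must be non-empty")
    if any(k % 2 == 0 for k in k_grid):
        raise ValueError("all k in k_grid must be odd")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    y = _met_labels(train)
    k_max = k_grid[-1]

    for attempt in range(10):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + attempt)
        fold_aurocs: list[dict[int, float]] = []
        ok = True
        for tr_idx, te_idx in skf.split(np.zeros(len(y)), y):
            if len(np.unique(y[tr_idx])) < 2 or len(np.unique(y[te_idx])) < 2:
                ok = False
                break
            tr = train.subset(train.sample_ids[tr_idx])
            te = train.subset(train.sample_ids[te_idx])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                selected = select_pairs(score_pairs(tr, mechanism), k_max)
            if not selected:  # nothing separable in this fold: null model
                fold_aurocs.append({k: 0.5 for k in k_grid})
                continue
            votes = _vote_matrix(
                te.expr,
                np.array([p.up_gene for p in selected]),
                np.array([p.down_gene for p in selected]),
            )
            row = {}
            for k in k_grid:
                kk = min(k, votes.shape[1])
                row[k] = _auroc(votes[:, :kk].mean(axis=1), y[te_idx])
            fold_aurocs.append(row)
        if ok:
            break
    else:
        raise RuntimeError("could not form valid stratified folds in 10 attempts")

    table = pd.DataFrame(
        {
            "k": k_grid,
            "mean_auroc": [
                float(np.mean([f[k] for f in fold_aurocs])) for k in k_grid
            ],
        }
    )
    best = table["mean_auroc"].max()
    k_best = int(table.loc[table["mean_auroc"] >= best - 1e-12, "k"].iloc[0])
    return k_best, table


class KTSP:
    """Mechanism-constrained k-TSP model of metastasis.

    Parameters
    ----------
    cohort : training :class:`~pairmet.datatypes.BulkCohort` with both
        outcome classes.
    mechanism : candidate pair constraint from
        :func:`pairmet.mechanism.build_mechanism`.
    tie_class : predicted class at a 0.5 vote fraction (default metastatic).

    Examples
    --------
    >>> results = KTSP(train, mechanism).fit(k=13)
    >>> vote_fraction, classes = results.predict(test)
    """

    def __init__(
        self,
        cohort: BulkCohort,
        mechanism: MechanismPairSet,
        tie_class: int = 1,
    ) -> None:
        self.cohort = cohort
        self.mechanism = mechanism
        self.tie_class = tie_class

    @classmethod
    def from_dataframe(
        cls,
        expr: pd.DataFrame,
        met_event: pd.Series,
        pairs: pd.DataFrame,
        **kwargs,
    ) -> "KTSP":
        """Build from raw frames: expr (samples x genes), labels, pair list."""
        meta = pd.DataFrame({"dataset": "ds1", "met_event": met_event})
        mech = MechanismPairSet(entries=pairs.assign(cluster="pooled"))
        return cls(BulkCohort(expr=expr, meta=meta), mech, **kwargs)

    def fit(
        self,
        k: int | None = None,
        k_grid=DEFAULT_K_GRID,
        folds: int = 5,
        seed: int = 0,
    ) -> "KTSPResults":
        """Score, (optionally) cross-validate k, and select the signature."""
        cv_table = None
        if k is None:
            k, cv_table = choose_k(self.cohort, self.mechanism, k_grid, folds, seed)
        scored = score_pairs(self.cohort, self.mechanism)
        selected = select_pairs(scored, k)
        return KTSPResults(
            model=self, pairs=selected, k_requested=k, scored=scored,
            cv_table=cv_table,
        )


@dataclass
class KTSPResults:
    """Fitted k-TSP signature: ordered disjoint pairs and diagnostics."""

    model: KTSP
    pairs: list[ScoredPair]
    k_requested: int
    scored: list[ScoredPair] = field(repr=False, default_factory=list)
    cv_table: pd.DataFrame | None = None

    @property
    def k(self) -> int:
        return len(self.pairs)

    @property
    def genes(self) -> list[str]:
        out = []
        for p in self.pairs:
            out.extend((p.up_gene, p.down_gene))
        return out

    def predict(self, samples: BulkCohort) -> tuple[np.ndarray, np.ndarray]:
        return predict(self.pairs, samples, tie_class=self.model.tie_class)

    def signature_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "rank": i + 1,
                    "up_gene": p.up_gene,
                    "down_gene": p.down_gene,
                    "delta": p.delta,
                    "gamma": p.gamma,
                }
                for i, p in enumerate(self.pairs)
            ]
        )

    def summary(self) -> str:
        lines = [
            "k-TSP signature",
            f"  pairs selected: {self.k} (requested {self.k_requested})",
            f"  unique genes:   {len(set(self.genes))}",
            f"  candidates:     {len(self.scored)}",
            "",
            self.signature_table().to_string(index=False),
        ]
        if self.cv_table is not None:
            lines += ["", "cross-validated k:", self.cv_table.to_string(index=False)]
        return "\n".join(lines)
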