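"""k-TSP scoring, disjoint selection, k choice and voting — checked against
brute-force enumeration oracles and rank-invariance properties."""

import numpy as np
import pandas as pd
import pytest

from pairmet.datatypes import BulkCohort
from pairmet.ktsp import (
    KTSP,
    ScoredPair,
    choose_k,
    predict,
    score_pairs,
    select_pairs,
)
from pairmet.mechanism import MechanismPairSet
from pairmet.prep import harmonize
from pairmet.simulate import SimConfig, simulate_bulk_cohort
from tests.conftest import make_cohort


def mech_from_pairs(pairs: list[tuple[str, str]]) -> MechanismPairSet:
    return MechanismPairSet(
        entries=pd.DataFrame(
            [{"cluster": "c", "up_gene": u, "down_gene": d} for u, d in pairs]
        )
    )


# ---------------------------------------------------------------- oracles


def oracle_delta_gamma(expr: pd.DataFrame, y: np.ndarray, up: str, down: str):
    """Brute-force delta/gamma by looping over samples and midranking by hand."""
    votes, rdiffs = [], []
    for _, row in expr.iterrows():
        a, b = row[up], row[down]
        votes.append(1.0 if a > b else (0.5 if a == b else 0.0))
        vals = row.to_numpy()

        def midrank(v):
            return 1 + np.sum(vals < v) + (np.sum(vals == v) - 1) / 2.0

        rdiffs.append(midrank(a) - midrank(b))
    votes, rdiffs = np.array(votes), np.array(rdiffs)
    met = y == 1
    delta = votes[met].mean() - votes[~met].mean()
    gamma = abs(rdiffs[met].mean() - rdiffs[~met].mean())
    return delta, gamma


def oracle_select(scored: list[ScoredPair], k: int) -> list[ScoredPair]:
    """Exhaustive enumeration of gene-disjoint chains in sort-key order,
    returning the lexicographically best (prefix ties broken by length)."""
    positive = sorted([p for p in scored if p.delta > 0], key=lambda p: p.sort_key)

    best: list[list[ScoredPair]] = []

    def extend(chain, used, start):
        extended = False
        for i in range(start, len(positive)):
            p = positive[i]
            if p.up_gene in used or p.down_gene in used:
                continue
            if len(chain) + 1 <= k:
                extend(chain + [p], used | {p.up_gene, p.down_gene}, i + 1)
                extended = True
        if not extended or len(chain) == k:
            best.append(list(chain))

    extend([], set(), 0)
    if not best:
        return []
    return min(best, key=lambda c: ([p.sort_key for p in c], -len(c)))


# ---------------------------------------------------------------- scoring


def test_perfect_pair_has_delta_one():
    expr = np.array([[2.0, 1.0], [3.0, 0.5], [1.0, 2.0], [0.2, 0.9]])
    cohort = make_cohort(expr, [1, 1, 0, 0], genes=["u", "d"])
    scored = score_pairs(cohort, mech_from_pairs([("u", "d")]))
    assert scored[0].delta == pytest.approx(1.0)


def test_null_pair_has_delta_zero():
    expr = np.array([[2.0, 1.0], [1.0, 2.0], [2.0, 1.0], [1.0, 2.0]])
    cohort = make_cohort(expr, [1, 1, 0, 0], genes=["u", "d"])
    scored = score_pairs(cohort, mech_from_pairs([("u", "d")]))
    assert scored[0].delta == pytest.approx(0.0)


def test_delta_gamma_match_bruteforce_on_fixture():
    """5+5-sample fixture: scores equal brute-force counting to 1e-12."""
    rng = np.random.default_rng(13)
    expr = rng.normal(size=(10, 6)).round(1)  # rounding induces some ties
    genes = [f"g{j}" for j in range(6)]
    y = np.array([1] * 5 + [0] * 5)
    cohort = make_cohort(expr, y, genes=genes)
    pairs = [(a, b) for a in genes for b in genes if a != b][:30]
    scored = score_pairs(cohort, mech_from_pairs(pairs))
    by_name = {(p.up_gene, p.down_gene): p for p in scored}
    for u, d in pairs:
        delta, gamma = oracle_delta_gamma(cohort.expr, y, u, d)
        assert by_name[(u, d)].delta == pytest.approx(delta, abs=1e-12)
        assert by_name[(u, d)].gamma == pytest.approx(gamma, abs=1e-12)


def test_delta_negates_under_class_swap():
    rng = np.random.default_rng(14)
    expr = rng.normal(size=(12, 4))
    genes = ["a", "b", "c", "d"]
    y = np.array([1, 0] * 6)
    mech = mech_from_pairs([("a", "b"), ("c", "d")])
    s1 = score_pairs(make_cohort(expr, y, genes=genes), mech)
    s2 = score_pairs(make_cohort(expr, 1 - y, genes=genes), mech)
    m1 = {(p.up_gene, p.down_gene): p.delta for p in s1}
    m2 = {(p.up_gene, p.down_gene): p.delta for p in s2}
    for key in m1:
        assert m1[key] == pytest.approx(-m2[key], abs=1e-12)
        assert -1.0 <= m1[key] <= 1.0


def test_missing_mechanism_genes_dropped_with_warning():
    expr = np.random.default_rng(15).normal(size=(8, 2))
    cohort = make_cohort(expr, [1, 0] * 4, genes=["a", "b"])
    with pytest.warns(UserWarning, match="absent"):
        scored = score_pairs(cohort, mech_from_pairs([("a", "b"), ("a", "zz")]))
    assert len(scored) == 1


def test_single_class_cohort_errors():
    expr = np.zeros((4, 2))
    cohort = make_cohort(expr, [1, 1, 1, 1], genes=["a", "b"])
    with pytest.raises(ValueError, match="class"):
        score_pairs(cohort, mech_from_pairs([("a", "b")]))


# ---------------------------------------------------------------- selection


def test_greedy_equals_exhaustive_on_known_fixture():
    scored = [
        ScoredPair("a", "b", 0.9, 1.0),
        ScoredPair("a", "c", 0.8, 2.0),
        ScoredPair("d", "e", 0.8, 1.0),
        ScoredPair("f", "g", 0.7, 0.5),
        ScoredPair("b", "f", 0.6, 0.1),
        ScoredPair("h", "i", -0.2, 9.0),
    ]
    for k in (1, 3, 5):
        assert select_pairs(scored, k) == oracle_select(scored, k)


def test_greedy_equals_exhaustive_on_random_instances():
    """<=12-sample, <=30-pair instances: greedy matches the enumeration
    oracle and brute-force scoring end to end."""
    rng = np.random.default_rng(16)
    for trial in range(5):
        n = int(rng.integers(6, 13))
        g = 8
        genes = [f"g{j}" for j in range(g)]
        expr = rng.normal(size=(n, g)).round(1)
        y = np.array([1] * (n // 2) + [0] * (n - n // 2))
        cohort = make_cohort(expr, y, genes=genes, seed=trial)
        all_pairs = [(a, b) for a in genes for b in genes if a != b]
        sel = [all_pairs[i] for i in rng.choice(len(all_pairs), 30, replace=False)]
        scored = score_pairs(cohort, mech_from_pairs(sel))
        for k in (1, 3):
            with np.errstate(all="ignore"):
                assert select_pairs(scored, k) == oracle_select(scored, k)


def test_all_pairs_share_gene_gives_single_pair():
    scored = [
        ScoredPair("a", "b", 0.9, 1.0),
        ScoredPair("a", "c", 0.8, 1.0),
        ScoredPair("d", "a", 0.7, 1.0),
    ]
    with pytest.warns(UserWarning, match="disjoint"):
        model = select_pairs(scored, 3)
    assert len(model) == 1


def test_nonpositive_delta_discarded():
    scored = [ScoredPair("a", "b", 0.5, 1.0), ScoredPair("c", "d", -0.9, 9.0)]
    with pytest.warns(UserWarning):
        model = select_pairs(scored, 2)
    assert [(p.up_gene, p.down_gene) for p in model] == [("a", "b")]


def test_k_exceeding_supply_warns():
    scored = [ScoredPair("a", "b", 0.5, 1.0), ScoredPair("c", "d", 0.4, 1.0)]
    with pytest.warns(UserWarning, match="only 2"):
        model = select_pairs(scored, 7)
    assert len(model) == 2


# ---------------------------------------------------------------- prediction


def test_unanimous_votes():
    pairs = [ScoredPair("u1", "d1", 0.5, 1.0), ScoredPair("u2", "d2", 0.5, 1.0),
             ScoredPair("u3", "d3", 0.5, 1.0)]
    genes = ["u1", "d1", "u2", "d2", "u3", "d3"]
    expr = np.array([[2.0, 1.0, 2.0, 1.0, 2.0, 1.0]])
    cohort = make_cohort(expr, [1], genes=genes)
    vf, cls = predict(pairs, cohort)
    assert vf[0] == 1.0 and cls[0] == 1


def test_majority_and_tie_policy():
    pairs = [ScoredPair("u1", "d1", 0.5, 1.0), ScoredPair("u2", "d2", 0.5, 1.0),
             ScoredPair("u3", "d3", 0.5, 1.0)]
    genes = ["u1", "d1", "u2", "d2", "u3", "d3"]
    expr = np.array(
        [
            [2.0, 1.0, 1.0, 2.0, 1.0, 2.0],  # votes (1, 0, 0) -> 1/3
            [2.0, 1.0, 1.5, 1.5, 1.0, 2.0],  # votes (1, tie, 0) -> 0.5
        ]
    )
    cohort = make_cohort(expr, [1, 0], genes=genes)
    vf, cls = predict(pairs, cohort)
    assert vf[0] == pytest.approx(1 / 3)
    assert cls[0] == 0
    assert vf[1] == pytest.approx(0.5)
    assert cls[1] == 1  # >= rule sends the tie to the metastatic class
    vf2, cls2 = predict(pairs, cohort, tie_class=0)
    assert cls2[1] == 0


def test_missing_model_gene_named_in_error():
    pairs = [ScoredPair("u1", "zz", 0.5, 1.0)]
    cohort = make_cohort(np.zeros((2, 2)), [1, 0], genes=["u1", "d1"])
    with pytest.raises(KeyError, match="zz"):
        predict(pairs, cohort)


@pytest.mark.parametrize("seed", range(5))
def test_rank_invariance(seed):
    """Strictly increasing per-sample transforms leave delta, gamma, votes and
    predictions unchanged."""
    rng = np.random.default_rng(seed)
    n, g = 14, 6
    genes = [f"g{j}" for j in range(g)]
    # half-integer grid: values and their cubes are exactly representable,
    # so ties are exact and the monotone transform cannot collapse them
    expr = rng.integers(-6, 7, size=(n, g)).astype(float) / 2.0
    y = np.array([1, 0] * (n // 2))
    expr[y == 1, ::2] += 1.0  # informative pairs so selection is non-empty
    pairs = [("g0", "g1"), ("g2", "g3"), ("g4", "g5")]
    mech = mech_from_pairs(pairs)

    transformed = np.empty_like(expr)
    for i in range(n):
        a, b = rng.uniform(0.5, 3.0), rng.normal()
        transformed[i] = a * expr[i] ** 3 + b  # strictly increasing, per sample

    c1 = make_cohort(expr, y, genes=genes, seed=seed)
    c2 = make_cohort(transformed, y, genes=genes, seed=seed)
    s1, s2 = score_pairs(c1, mech), score_pairs(c2, mech)
    assert [(p.up_gene, p.down_gene, p.delta, p.gamma) for p in s1] == [
        (p.up_gene, p.down_gene, p.delta, p.gamma) for p in s2
    ]
    model = select_pairs(s1, 3)
    vf1, cl1 = predict(model, c1)
    vf2, cl2 = predict(model, c2)
    assert np.array_equal(vf1, vf2)
    assert np.array_equal(cl1, cl2)


# ---------------------------------------------------------------- choose_k


def test_single_candidate_forces_k_one():
    rng = np.random.default_rng(17)
    expr = rng.normal(size=(40, 4))
    expr[:20, 0] += 2.0  # make the pair informative
    y = np.array([1] * 20 + [0] * 20)
    cohort = make_cohort(expr, y, genes=["a", "b", "c", "d"])
    k, table = choose_k(cohort, mech_from_pairs([("a", "b")]), k_grid=[1, 3, 5])
    assert k == 1


def test_singleton_grid():
    rng = np.random.default_rng(18)
    expr = rng.normal(size=(30, 8))
    y = np.array([1, 0] * 15)
    expr[y == 1, ::2] += 1.0
    genes = [f"g{j}" for j in range(8)]
    cohort = make_cohort(expr, y, genes=genes)
    pairs = [("g0", "g1"), ("g2", "g3"), ("g4", "g5"), ("g6", "g7")]
    k, _ = choose_k(cohort, mech_from_pairs(pairs), k_grid=[3])
    assert k == 3


def test_even_k_rejected():
    cohort = make_cohort(np.zeros((10, 2)), [1, 0] * 5, genes=["a", "b"])
    with pytest.raises(ValueError, match="odd"):
        choose_k(cohort, mech_from_pairs([("a", "b")]), k_grid=[2, 3])


def test_choose_k_recovers_planted_signature_size():
    """With 13 strongly planted pairs (inversion 0.85/0.15, n=600) the
    cross-validated k lands in [9, 17] in at least 16 of 20 seeds."""
    hits = 0
    for seed in range(20):
        cfg = SimConfig.default_study(
            seed=seed, inversion_prob_met=0.85, inversion_prob_nonmet=0.15
        )
        bulk, truth = simulate_bulk_cohort(cfg)
        harm = harmonize(bulk.split_by_dataset())
        rng = np.random.default_rng(seed)
        genes = list(harm.genes)
        decoys = [
            (genes[i], genes[j])
            for i, j in zip(rng.integers(100, 1000, 40), rng.integers(1000, 2000, 40))
        ]
        mech = mech_from_pairs(list(truth.pair_set()) + decoys)
        k, _ = choose_k(harm, mech, seed=seed)
        if 9 <= k <= 17:
            hits += 1
    assert hits >= 16


# ---------------------------------------------------------------- model API


def test_model_results_roundtrip():
    rng = np.random.default_rng(19)
    expr = rng.normal(size=(60, 6))
    y = rng.integers(0, 2, 60)
    genes = [f"g{j}" for j in range(6)]
    expr[y == 1, 0] += 1.5
    cohort = make_cohort(expr, y, genes=genes)
    mech = mech_from_pairs([("g0", "g1"), ("g2", "g3"), ("g4", "g5")])
    results = KTSP(cohort, mech).fit(k=3)
    assert results.k <= 3
    assert len(set(results.genes)) == 2 * results.k
    vf, cls = results.predict(cohort)
    assert vf.shape == (60,)
    text = results.summary()
    assert "pairs selected" in text
    table = results.signature_table()
    assert list(table.columns) == ["rank", "up_gene", "down_gene", "delta", "gamma"]
    deltas = table["delta"].to_numpy()
    assert (np.diff(deltas) <= 1e-12).all()  # non-increasing
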