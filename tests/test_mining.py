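"""Combination mining: carrier semantics, scoring, search modes."""

import itertools

import numpy as np
import pytest

from combimine import (
    CohortSpec,
    FeatureState,
    MiningParams,
    evaluate_combination,
    generate_cohort,
    matches,
    mine_signatures,
)
from combimine.mining import carrier_vector
from tests.conftest import PLANTED_KEY, planted_spec


class TestMatches:
    def test_single_state_match(self):
        assert matches({"s1": 1, "s2": 2}, [FeatureState("s1", 1)])

    def test_state_mismatch(self):
        assert not matches(
            {"s1": 1, "s2": 2}, [FeatureState("s1", 1), FeatureState("s2", 0)]
        )

    def test_missing_genotype_is_noncarrier(self):
        assert not matches({"s1": -1}, [FeatureState("s1", 1)])
        assert not matches({"s1": None}, [FeatureState("s1", 0)])

    def test_unknown_snp_raises(self):
        with pytest.raises(KeyError, match="unknown SNP"):
            matches({"s1": 1}, [FeatureState("zzz", 1)])


class TestEvaluate:
    def test_cross_product_or(self, tiny_matrix):
        sig = evaluate_combination([FeatureState("a", 1), FeatureState("b", 2)], tiny_matrix)
        # carriers: s0, s1 (cases), s4 (control); s5 has missing 'a'
        assert sig.table.case_carriers == 2
        assert sig.table.control_carriers == 1
        assert sig.case_ids == {"s0", "s1"}
        assert sig.control_ids == {"s4"}
        # table (a=2, b=1, c=1, d=2): OR = (2*2)/(1*1)
        assert sig.odds_ratio == pytest.approx(4.0)

    def test_carrier_sets_match_naive_rescan(self, small_planted_cohort):
        gm = small_planted_cohort[0]
        rng = np.random.default_rng(0)
        snp_index = {s: j for j, s in enumerate(gm.snp_ids)}
        for _ in range(10):
            snps = rng.choice(gm.snp_ids, size=3, replace=False)
            states = [FeatureState(str(s), int(rng.integers(0, 3))) for s in snps]
            sig = evaluate_combination(states, gm)
            naive_cases, naive_ctrls = set(), set()
            for i, sid in enumerate(gm.sample_ids):
                if matches(gm.genotypes[i], states, snp_index=snp_index):
                    (naive_cases if gm.is_case[i] else naive_ctrls).add(sid)
            assert sig.case_ids == naive_cases
            assert sig.control_ids == naive_ctrls

    def test_empty_combination_prevalence_zero(self, tiny_matrix):
        sig = evaluate_combination(
            [FeatureState("a", 0), FeatureState("b", 0)], tiny_matrix
        )
        assert sig.table.case_carriers == 0
        assert sig.case_prevalence == 0.0


def _toy_planted_matrix():
    """20 cases / 20 controls over 6 SNPs; a 3-state combo carried by 12
    cases and 1 control."""
    rng = np.random.default_rng(5)
    geno = rng.integers(0, 3, size=(40, 6)).astype(np.int8)
    combo_cols, combo_states = [0, 2, 4], [1, 0, 2]
    # destroy accidental carriers, then plant
    geno[:, combo_cols[0]] = np.where(geno[:, combo_cols[0]] == 1, 0, geno[:, combo_cols[0]])
    carriers = list(range(12)) + [25]
    for col, st in zip(combo_cols, combo_states):
        geno[carriers, col] = st
    from combimine import GenotypeMatrix

    return (
        GenotypeMatrix(
            sample_ids=np.array([f"s{i}" for i in range(40)], dtype=object),
            snp_ids=np.array([f"m{j}" for j in range(6)], dtype=object),
            genotypes=geno,
            is_case=np.array([True] * 20 + [False] * 20),
        ),
        frozenset(
            FeatureState(f"m{c}", s) for c, s in zip(combo_cols, combo_states)
        ),
    )


class TestMineSignatures:
    def test_exhaustive_recovers_planted_combo_ranked_first(self):
        gm, key = _toy_planted_matrix()
        params = MiningParams(search_mode="exhaustive", max_order=3)
        sigs = mine_signatures(gm, params)
        assert sigs, "nothing mined"
        assert any(s.key() == key for s in sigs)
        # the planted combo (or a sub-combo sharing its carriers) tops the list
        assert key & sigs[0].key()

    def test_identical_rows_yield_empty(self):
        rng = np.random.default_rng(1)
        row = rng.integers(0, 3, size=30).astype(np.int8)
        from combimine import GenotypeMatrix

        gm = GenotypeMatrix(
            sample_ids=np.array([f"s{i}" for i in range(20)], dtype=object),
            snp_ids=np.array([f"v{j}" for j in range(30)], dtype=object),
            genotypes=np.tile(row, (20, 1)),
            is_case=np.array([True] * 10 + [False] * 10),
        )
        assert mine_signatures(gm, MiningParams(search_mode="exhaustive", max_order=2)) == []

    def test_no_signature_exceeds_max_order(self, small_planted_cohort):
        gm = small_planted_cohort[0]
        sigs = mine_signatures(gm, MiningParams(max_order=5, seed=0))
        assert sigs and all(s.order <= 5 for s in sigs)

    def test_greedy_results_subset_of_exhaustive_with_identical_stats(self):
        gm, _ = _toy_planted_matrix()
        ex = {
            s.key(): (s.table, s.p_value)
            for s in mine_signatures(gm, MiningParams(search_mode="exhaustive", max_order=3))
        }
        greedy = mine_signatures(
            gm, MiningParams(search_mode="greedy_stochastic", max_order=3, seed=4)
        )
        for s in greedy:
            assert s.key() in ex
            table, p = ex[s.key()]
            assert table == s.table
            assert p == pytest.approx(s.p_value, rel=1e-9)

    def test_adding_states_shrinks_carrier_sets(self, small_planted_cohort):
        gm = small_planted_cohort[0]
        rng = np.random.default_rng(3)
        for _ in range(8):
            snps = rng.choice(gm.snp_ids, size=3, replace=False)
            states = [FeatureState(str(s), int(rng.integers(0, 3))) for s in snps]
            prev = None
            for k in range(1, 4):
                sig = evaluate_combination(states[:k], gm)
                cur = sig.case_ids | sig.control_ids
                if prev is not None:
                    assert cur <= prev
                prev = cur

    def test_combination_budget_guard(self, small_planted_cohort):
        gm = small_planted_cohort[0]
        with pytest.raises(RuntimeError, match="budget"):
            mine_signatures(
                gm,
                MiningParams(
                    search_mode="exhaustive", max_order=5, combination_budget=1e4
                ),
            )

    def test_planted_signature_recovered_greedy(self, small_planted_cohort):
        gm = small_planted_cohort[0]
        sigs = mine_signatures(gm, MiningParams(seed=2, max_order=3))
        assert any(s.key() == PLANTED_KEY for s in sigs)

    def test_deterministic_replay(self, small_planted_cohort):
        gm = small_planted_cohort[0]
        p = MiningParams(seed=8)
        a = [(s.key(), s.p_value) for s in mine_signatures(gm, p)]
        b = [(s.key(), s.p_value) for s in mine_signatures(gm, p)]
        assert a == b

    def test_sorted_by_significance(self, small_planted_cohort):
        gm = small_planted_cohort[0]
        sigs = mine_signatures(gm, MiningParams(seed=0))
        ps = [s.p_value for s in sigs]
        assert ps == sorted(ps)
        assert all(s.odds_ratio > 1 for s in sigs)
        assert all(s.case_prevalence >= 0.05 for s in sigs)
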