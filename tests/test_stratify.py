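"""Stratification, forest data, GWAS baseline, restricted replication."""

import numpy as np
import pandas as pd
import pytest

from combimine import (
    CohortSpec,
    GenotypeMatrix,
    GwasParams,
    MiningParams,
    PlantedSignatureSpec,
    ValidationParams,
    bh_adjust,
    covariate_forest,
    generate_cohort,
    profile_subgroup,
    replicate_in_cohort,
    single_snp_gwas,
)
from combimine.stats import ContingencyTable2x2, fisher_exact_p
from tests.conftest import PLANTED_SNPS, planted_spec


class TestProfileSubgroup:
    def _covariates(self, n=400, seed=0, shift_first=0.0):
        rng = np.random.default_rng(seed)
        idx = [f"c{i}" for i in range(n)]
        bio = rng.normal(size=n)
        bio[: n // 4] += shift_first
        return pd.DataFrame(
            {"flag": rng.integers(0, 2, n), "bio": bio}, index=idx
        )

    def test_planted_shift_detected(self):
        detected = 0
        for seed in range(20):
            cov = self._covariates(n=1200, seed=seed, shift_first=1.0)
            sub = [f"c{i}" for i in range(300)]
            res = profile_subgroup(sub, cov.index, cov)
            p = {r.feature: r.raw_p for r in res}["bio"]
            detected += p < 0.05
        assert detected >= 18  # >= 90% of 20 seeds

    def test_null_covariate_p_uniformish(self):
        ps = []
        for seed in range(40):
            cov = self._covariates(n=200, seed=seed)
            sub = [f"c{i}" for i in range(50)]
            res = profile_subgroup(sub, cov.index, cov)
            ps.append({r.feature: r.raw_p for r in res}["bio"])
        assert 0.2 < np.mean(ps) < 0.8
        assert min(ps) < 0.5

    def test_q_values_equal_bh_of_raw(self):
        cov = self._covariates(n=300, seed=1, shift_first=0.5)
        sub = [f"c{i}" for i in range(75)]
        res = profile_subgroup(sub, cov.index, cov)
        q, _ = bh_adjust([r.raw_p for r in res])
        for r, qv in zip(res, q):
            assert r.q_value == pytest.approx(qv)
            assert r.q_value >= r.raw_p - 1e-12

    def test_subgroup_equals_cases_rejected(self):
        cov = self._covariates(n=50)
        with pytest.raises(ValueError, match="whole case population"):
            profile_subgroup(cov.index, cov.index, cov)

    def test_missing_values_excluded_pairwise(self):
        cov = self._covariates(n=100)
        cov.loc[cov.index[:10], "bio"] = np.nan
        res = profile_subgroup(cov.index[:30], cov.index, cov)
        assert any(r.feature == "bio" for r in res)


class TestForest:
    def _groups(self):
        rng = np.random.default_rng(2)
        mk = lambda n, p, pre: pd.DataFrame(
            {"cov": rng.random(n) < p}, index=[f"{pre}{i}" for i in range(n)]
        )
        return mk(500, 0.30, "a"), mk(500, 0.10, "b"), mk(2000, 0.10, "c")

    def test_point_estimates_are_group_proportions(self):
        cases, controls, rest = self._groups()
        out = covariate_forest(cases, controls, rest, ["cov"], n_boot=200, seed=0)
        by = {e.group: e for e in out}
        assert by["cases"].percentage == pytest.approx(100 * cases["cov"].mean())
        assert by["rest"].percentage == pytest.approx(100 * rest["cov"].mean())

    def test_all_ones_degenerate(self):
        ones = lambda pre: pd.DataFrame({"cov": [1] * 20}, index=[f"{pre}{i}" for i in range(20)])
        out = covariate_forest(ones("a"), ones("b"), ones("c"), ["cov"], seed=0)
        assert all((e.percentage, e.ci_low, e.ci_high) == (100.0, 100.0, 100.0) for e in out)

    def test_planted_enrichment_separates_cis(self):
        cases, controls, rest = self._groups()
        out = covariate_forest(cases, controls, rest, ["cov"], n_boot=500, seed=1)
        by = {e.group: e for e in out}
        assert by["cases"].ci_low > by["rest"].ci_high  # 30% vs 10% at n>=500

    def test_disjointness_enforced(self):
        cases, controls, _ = self._groups()
        with pytest.raises(ValueError, match="disjoint"):
            covariate_forest(cases, controls, cases, ["cov"])


class TestGwas:
    def test_null_cohort_nothing_genome_wide(self, null_cohort):
        res = single_snp_gwas(null_cohort[0])
        assert res["significant"].sum() == 0

    def test_identical_frequencies_p_one(self):
        geno = np.tile(np.array([0, 1, 2, 1], dtype=np.int8), (1, 1)).T
        geno = np.vstack([geno] * 10)  # 40 samples, identical case/control mix
        gm = GenotypeMatrix(
            sample_ids=np.array([f"s{i}" for i in range(40)], dtype=object),
            snp_ids=np.array(["v0"], dtype=object),
            genotypes=geno,
            is_case=np.array([True, False] * 20),
        )
        res = single_snp_gwas(gm)
        assert res.loc[0, "p"] == pytest.approx(1.0)

    def test_monomorphic_flagged(self):
        gm = GenotypeMatrix(
            sample_ids=np.array(["s0", "s1", "s2", "s3"], dtype=object),
            snp_ids=np.array(["v0"], dtype=object),
            genotypes=np.zeros((4, 1), dtype=np.int8),
            is_case=np.array([True, True, False, False]),
        )
        res = single_snp_gwas(gm)
        assert bool(res.loc[0, "monomorphic"]) and res.loc[0, "p"] == 1.0

    def test_single_snp_effect_detected_and_table_matches_recount(self):
        rng = np.random.default_rng(4)
        n_case, n_ctrl = 800, 1600
        case_g = rng.binomial(2, 0.35, n_case)
        ctrl_g = rng.binomial(2, 0.15, n_ctrl)
        noise = rng.binomial(2, 0.2, n_case + n_ctrl)
        gm = GenotypeMatrix(
            sample_ids=np.array([f"s{i}" for i in range(n_case + n_ctrl)], dtype=object),
            snp_ids=np.array(["hit", "noise"], dtype=object),
            genotypes=np.column_stack([np.concatenate([case_g, ctrl_g]), noise]).astype(np.int8),
            is_case=np.array([True] * n_case + [False] * n_ctrl),
        )
        res = single_snp_gwas(gm).set_index("snp_id")
        assert bool(res.loc["hit", "significant"])
        assert not bool(res.loc["noise", "significant"])
        # allele-count recount oracle
        assert res.loc["hit", "case_alt"] == int(case_g.sum())
        assert res.loc["hit", "control_ref"] == int(2 * n_ctrl - ctrl_g.sum())
        # fisher variant agrees in direction
        fisher_res = single_snp_gwas(gm, GwasParams(test="fisher")).set_index("snp_id")
        assert fisher_res.loc["hit", "p"] < 5e-8


class TestReplication:
    def test_restriction_property_and_replication(self):
        mp = MiningParams(seed=0, max_order=3)
        vp = ValidationParams(n_perm=30, seed=3, mining=mp)
        spec = CohortSpec(
            n_cases=400, n_controls=800, n_snps=40, seed=21,
            planted=(planted_spec(target_or=6.0, target_case_prevalence=0.15),),
        )
        gm2, *_ = generate_cohort(spec)
        refs = list(PLANTED_SNPS) + ["snp_00001", "absent_snp"]
        rep = replicate_in_cohort(refs, gm2, mp, vp)
        assert rep["untestable"] == ["absent_snp"]
        allowed = set(refs)
        for sig in rep["signatures"]:
            assert set(sig.snp_ids) <= allowed
        assert set(PLANTED_SNPS) <= set(rep["replicated"])

    def test_null_cohort_no_replication(self, null_cohort):
        gm = null_cohort[0]
        mp = MiningParams(seed=1, max_order=3)
        vp = ValidationParams(n_perm=20, seed=5, mining=mp)
        refs = list(gm.snp_ids[:8])
        rep = replicate_in_cohort(refs, gm, mp, vp)
        assert rep["replicated"] == []
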