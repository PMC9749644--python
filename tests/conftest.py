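import numpy as np
import pandas as pd
import pytest

from combimine import (
    CohortSpec,
    FeatureState,
    GenotypeMatrix,
    PlantedSignatureSpec,
    generate_cohort,
)

PLANTED_SNPS = ("rs1", "rs2", "rs3")
PLANTED_STATES = (1, 1, 0)
PLANTED_KEY = frozenset(
    FeatureState(s, g) for s, g in zip(PLANTED_SNPS, PLANTED_STATES)
)


def planted_spec(**kw) -> PlantedSignatureSpec:
    base = dict(
        snp_ids=PLANTED_SNPS,
        genotype_states=PLANTED_STATES,
        target_or=3.7,
        target_case_prevalence=0.10,
    )
    base.update(kw)
    return PlantedSignatureSpec(**base)


@pytest.fixture(scope="session")
def small_planted_cohort():
    """500/1000 cohort with one planted 3-SNP signature (OR 3.7, prev 0.10)."""
    spec = CohortSpec(
        n_cases=500, n_controls=1000, n_snps=60, seed=11, planted=(planted_spec(),)
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def null_cohort():
    """No planted structure: labels are independent of every genotype."""
    spec = CohortSpec(n_cases=200, n_controls=400, n_snps=50, seed=7)
    return generate_cohort(spec)


@pytest.fixture()
def tiny_matrix():
    """Hand-built 6-sample x 3-SNP matrix with known carriers."""
    geno = np.array(
        [
            [1, 2, 0],
            [1, 2, 0],
            [1, 0, 0],
            [0, 2, 0],
            [1, 2, 1],
            [-1, 2, 0],
        ],
        dtype=np.int8,
    )
    return GenotypeMatrix(
        sample_ids=np.array([f"s{i}" for i in range(6)], dtype=object),
        snp_ids=np.array(["a", "b", "c"], dtype=object),
        genotypes=geno,
        is_case=np.array([True, True, True, False, False, False]),
        snp_meta=pd.DataFrame(
            {
                "snp_id": ["a", "b", "c"],
                "chrom": ["1", "1", "2"],
                "pos": [100, 200, 300],
                "ref": ["A"] * 3,
                "alt": ["G"] * 3,
            }
        ).set_index("snp_id"),
    )
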