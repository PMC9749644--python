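"""Patient stratification, cohort covariate forests, GWAS baseline, and
restricted-SNP replication in disjoint cohorts.

Subgroup enrichment compares a community's (or gene's) case carriers
against the remaining cases: two-proportion z-test for categorical
covariates, Mann-Whitney U for continuous ones, with Benjamini-Hochberg
correction across the features tested per subgroup.  The single-SNP GWAS
baseline (allelic test, genome-wide alpha 5e-8) is what the combinatorial
search is contrasted against: planted marginal-free interactions are
invisible to it but recoverable by mining.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import GenotypeMatrix, MISSING
from .mining import MiningParams, Signature, mine_signatures
from .permutation import ValidationParams, compute_p1000, validate_signatures
from .stats import (
    ContingencyTable2x2,
    bh_adjust,
    bootstrap_proportion_ci,
    fisher_exact_p,
    mann_whitney_u,
    two_proportion_z,
)

__all__ = [
    "EnrichmentResult",
    "ForestEstimate",
    "GwasParams",
    "profile_subgroup",
    "covariate_forest",
    "single_snp_gwas",
    "replicate_in_cohort",
]


@dataclass(frozen=True)
class EnrichmentResult:
    subgroup_id: str
    feature: str
    feature_type: str  # "categorical" | "continuous"
    direction: str  # "enriched" | "depleted" | "none"
    raw_p: float
    q_value: float


@dataclass(frozen=True)
class ForestEstimate:
    group: str  # "cases" | "controls" | "rest"
    covariate: str
    percentage: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class GwasParams:
    test: str = "allelic_chisq"  # or "fisher"
    genome_wide_alpha: float = 5e-8

    def __post_init__(self) -> None:
        if not 0 < self.genome_wide_alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.test not in {"allelic_chisq", "fisher"}:
            raise ValueError(f"unknown GWAS test: {self.test}")


def profile_subgroup(
    subgroup_case_ids,
    all_case_ids,
    covariates: pd.DataFrame,
    subgroup_id: str = "subgroup",
    categorical: list[str] | None = None,
    continuous: list[str] | None = None,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Enrichment profile of a case subgroup against the remaining cases.

    Missing covariate values are excluded pairwise.  Feature lists default
    to dtype-based detection over the covariate columns.
    """
    sub = set(map(str, subgroup_case_ids))
    allc = set(map(str, all_case_ids))
    if not sub.issubset(allc):
        raise ValueError("subgroup must be a subset of the case population")
    rest = allc - sub
    if not rest:
        raise ValueError("subgroup equals the whole case population")
    idx = covariates.index.astype(str)
    in_sub = idx.isin(sub)
    in_rest = idx.isin(rest)
    if categorical is None or continuous is None:
        categorical = categorical or []
        continuous = continuous or []
        for col in covariates.columns:
            if col in categorical or col in continuous:
                continue
            vals = covariates[col].dropna()
            if vals.empty:
                continue
            if pd.api.types.is_numeric_dtype(vals) and vals.nunique() > 2:
                continuous.append(col)
            else:
                categorical.append(col)
    rows = []
    for col in categorical:
        series = covariates[col]
        # binary flags tested as-is; multi-level categoricals as one-vs-rest
        # on the most common level
        if pd.api.types.is_numeric_dtype(series):
            flag = series == 1
        else:
            top = series.dropna().mode().iloc[0]
            flag = series == top
        valid = series.notna().to_numpy()
        a = int((flag & in_sub & valid).sum())
        n1 = int((in_sub & valid).sum())
        c = int((flag & in_rest & valid).sum())
        n2 = int((in_rest & valid).sum())
        if n1 == 0 or n2 == 0:
            continue
        table = ContingencyTable2x2(a, n1 - a, c, n2 - c)
        _, p = two_proportion_z(table)
        direction = (
            "enriched" if a / n1 > c / n2 else "depleted" if a / n1 < c / n2 else "none"
        )
        rows.append((col, "categorical", direction, p))
    for col in continuous:
        series = covariates[col]
        valid = series.notna().to_numpy()
        x = series.to_numpy(dtype=float)[in_sub & valid]
        y = series.to_numpy(dtype=float)[in_rest & valid]
        if x.size == 0 or y.size == 0:
            continue
        _, p = mann_whitney_u(x, y)
        mx, my = np.median(x), np.median(y)
        direction = "enriched" if mx > my else "depleted" if mx < my else "none"
        rows.append((col, "continuous", direction, p))
    if not rows:
        return []
    q, _ = bh_adjust([r[3] for r in rows], alpha=alpha)
    return [
        EnrichmentResult(subgroup_id, col, ftype, direction, float(p), float(qv))
        for (col, ftype, direction, p), qv in zip(rows, q)
    ]


def covariate_forest(
    cases: pd.DataFrame,
    controls: pd.DataFrame,
    rest: pd.DataFrame,
    covariates: list[str],
    n_boot: int = 1000,
    seed: int = 0,
) -> list[ForestEstimate]:
    """Forest-plot data: per group x covariate percentage with a percentile
    bootstrap 95% CI (1000 iterations by default)."""
    groups = {"cases": cases, "controls": controls, "rest": rest}
    ids = [set(df.index) for df in groups.values()]
    if ids[0] & ids[1] or ids[0] & ids[2] or ids[1] & ids[2]:
        raise ValueError("groups must be disjoint")
    out = []
    for gi, (gname, df) in enumerate(groups.items()):
        if df.empty:
            raise ValueError(f"group {gname!r} is empty")
        for ci, cov in enumerate(covariates):
            flags = df[cov].dropna().to_numpy(dtype=float)
            point, lo, hi = bootstrap_proportion_ci(
                flags, n_boot=n_boot, seed=seed + 1000 * gi + ci
            )
            out.append(
                ForestEstimate(gname, cov, 100 * point, 100 * lo, 100 * hi)
            )
    return out


def single_snp_gwas(
    gm: GenotypeMatrix, params: GwasParams = GwasParams()
) -> pd.DataFrame:
    """Per-SNP allelic association test (2N allele counts, case vs control).

    Returns a table (snp_id, case/control alt allele counts, p, significant,
    monomorphic); monomorphic SNPs get p = 1 and a flag.
    """
    case_g = gm.genotypes[gm.is_case]
    ctrl_g = gm.genotypes[~gm.is_case]
    rows = []
    for j, snp in enumerate(gm.snp_ids):
        cg = case_g[:, j]
        kg = ctrl_g[:, j]
        cg = cg[cg != MISSING]
        kg = kg[kg != MISSING]
        a1 = int(cg.sum())  # alt alleles in cases
        a0 = int(2 * cg.size - a1)
        b1 = int(kg.sum())
        b0 = int(2 * kg.size - b1)
        mono = (a1 + b1 == 0) or (a0 + b0 == 0)
        if mono:
            p = 1.0
        elif params.test == "fisher":
            p = fisher_exact_p(ContingencyTable2x2(a1, a0, b1, b0))
        else:
            obs = np.array([[a1, a0], [b1, b0]])
            if obs.sum(axis=0).min() == 0 or obs.sum(axis=1).min() == 0:
                p = 1.0
            else:
                p = float(sps.chi2_contingency(obs, correction=False)[1])
        rows.append(
            {"snp_id": snp, "case_alt": a1, "case_ref": a0,
             "control_alt": b1, "control_ref": b0, "p": p, "monomorphic": mono}
        )
    df = pd.DataFrame(rows)
    df["significant"] = (df["p"] < params.genome_wide_alpha) & ~df["monomorphic"]
    return df


def replicate_in_cohort(
    reference_snps,
    gm2: GenotypeMatrix,
    mining_params: MiningParams = MiningParams(),
    validation_params: ValidationParams | None = None,
) -> dict:
    """Restricted-search replication: mine + validate a disjoint cohort over
    combinations drawn only from the reference SNP set.

    Returns a report with the validated signatures of the restricted run
    and which reference SNPs replicated (appear in >= 1 validated
    signature); reference SNPs absent from the cohort are listed as
    untestable.
    """
    reference_snps = list(dict.fromkeys(reference_snps))
    if not reference_snps:
        raise ValueError("reference SNP set is empty")
    present = [s for s in reference_snps if s in set(gm2.snp_ids)]
    untestable = [s for s in reference_snps if s not in set(gm2.snp_ids)]
    if not present:
        return {"replicated": [], "untestable": untestable, "signatures": []}
    restricted = gm2.subset_snps(present)
    sigs = mine_signatures(restricted, mining_params)
    if validation_params is None:
        validation_params = ValidationParams(mining=mining_params)
    report = compute_p1000(sigs, restricted, validation_params)
    validated = validate_signatures(sigs, report, validation_params)
    replicated = sorted({snp for s in validated for snp in s.snp_ids})
    return {
        "replicated": replicated,
        "untestable": untestable,
        "signatures": validated,
        "report": report,
    }
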