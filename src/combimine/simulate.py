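"""Synthetic case-control cohorts with planted combinatorial signatures.

The generator emulates the study conditions the pipeline is built for: a
2:1-matched case-control cohort with minor-allele-frequency-distributed
biallelic SNPs in Hardy-Weinberg proportions (independent across SNPs — no
LD by default), into which 3-5-SNP genotype-state signatures are planted at
target odds ratios, together with covariates, biomarkers and a synthetic
gene model.  A machine-readable truth set makes every downstream stage
testable by parameter recovery.

Disease status follows a liability model:

    log-odds(case) = baseline + sum_s beta_s * I(sample carries signature s)

Carrying a signature means an exact genotype-state match at every member
SNP.  Under this logistic model, each ``beta_s`` is solved numerically so
the *expected case-control sampled* odds ratio of the signature hits the
target; the member-SNP allele frequencies are solved so the expected
carrier fraction among sampled cases hits the target prevalence.  Samples
are then drawn retrospectively (cases and controls from their exact
conditional carrier-configuration distributions), which is what a
case-control design observes.

A separate *marginal-free* mode plants a pure interaction: the penetrance
of one exact multi-SNP genotype cell is elevated and the remaining cells
are compensated (a constrained least-squares projection) so that every
member SNP's single-locus case/control genotype distribution is identical
in expectation — detectable combinatorially, invisible to single-SNP GWAS.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .annotation import GeneModel
from .io import MISSING, GenotypeMatrix
from .mining import carrier_vector
from .stats import ContingencyTable2x2, odds_ratio

__all__ = [
    "PlantedSignatureSpec",
    "CovariateSpec",
    "CohortSpec",
    "TruthSet",
    "InfeasibleSignatureError",
    "generate_cohort",
]


class InfeasibleSignatureError(ValueError):
    """Raised when a planted signature's targets cannot be realised."""


@dataclass(frozen=True)
class PlantedSignatureSpec:
    """A 3-5-SNP genotype-state combination to plant at a target odds ratio."""

    snp_ids: tuple[str, ...]
    genotype_states: tuple[int, ...]
    target_or: float = 3.7
    target_case_prevalence: float = 0.15
    covariate_effects: dict = field(default_factory=dict)  # name -> log-odds in carriers
    biomarker_shifts: dict = field(default_factory=dict)  # name -> shift in SD units
    marginal_free: bool = False
    # marginal-free flatness: "single" (per-SNP genotype case rates flat) or
    # "pairwise" (all two-SNP joint case rates flat too: a pure XOR-style
    # interaction, invisible below its own order)
    purity: str = "single"

    def __post_init__(self) -> None:
        object.__setattr__(self, "snp_ids", tuple(self.snp_ids))
        object.__setattr__(self, "genotype_states", tuple(self.genotype_states))
        if not 3 <= len(self.snp_ids) <= 5:
            raise ValueError("planted signatures contain 3-5 SNPs")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("planted signature SNPs must be distinct")
        if len(self.genotype_states) != len(self.snp_ids):
            raise ValueError("one genotype state per SNP required")
        if any(g not in (0, 1, 2) for g in self.genotype_states):
            raise ValueError("genotype states must be in {0,1,2}")
        if self.purity not in {"single", "pairwise"}:
            raise ValueError("purity must be 'single' or 'pairwise'")
        if self.target_or <= 1:
            raise ValueError("target odds ratio must exceed 1")
        if not 0.05 < self.target_case_prevalence < 0.5:
            raise ValueError("target case prevalence must lie in (0.05, 0.5)")

    @property
    def order(self) -> int:
        return len(self.snp_ids)


@dataclass(frozen=True)
class CovariateSpec:
    name: str
    kind: str  # "binary" | "continuous"
    rate: float = 0.2  # binary: population rate
    mean: float = 0.0  # continuous
    sd: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in {"binary", "continuous"}:
            raise ValueError("covariate kind must be binary or continuous")


DEFAULT_COVARIATES = (
    CovariateSpec("sex_female", "binary", rate=0.544),
    CovariateSpec("stress_event", "binary", rate=0.20),
    CovariateSpec("autoimmune_comorbidity", "binary", rate=0.08),
    CovariateSpec("bmi", "continuous", mean=27.0, sd=4.5),
    CovariateSpec("biomarker", "continuous", mean=0.0, sd=1.0),
)


@dataclass(frozen=True)
class CohortSpec:
    """Cohort dimensions and planted structure.

    Defaults mirror the study conditions: 2382 cases with 2:1 matched
    controls and common biallelic SNPs (MAF 0.05-0.5).
    """

    n_cases: int = 2382
    control_ratio: int = 2
    n_controls: int | None = None  # defaults to control_ratio * n_cases
    n_snps: int = 200
    maf_range: tuple[float, float] = (0.05, 0.5)
    planted: tuple[PlantedSignatureSpec, ...] = ()
    baseline_case_logodds: float = -3.0
    covariate_schema: tuple[CovariateSpec, ...] = DEFAULT_COVARIATES
    seed: int = 0
    missing_rate: float = 0.0
    ld_rho: float = 0.0  # optional adjacent-SNP haplotype correlation, off by default
    allow_snp_overlap: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "planted", tuple(self.planted))
        object.__setattr__(self, "covariate_schema", tuple(self.covariate_schema))
        if self.n_cases < 1:
            raise ValueError("need at least one case")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        lo, hi = self.maf_range
        if not 0 < lo <= hi <= 0.5:
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if not self.allow_snp_overlap:
            seen: set[str] = set()
            for sig in self.planted:
                dup = seen.intersection(sig.snp_ids)
                if dup:
                    raise ValueError(
                        f"planted signatures share SNPs {sorted(dup)}; "
                        "set allow_snp_overlap to permit this"
                    )
                seen.update(sig.snp_ids)

    @property
    def resolved_n_controls(self) -> int:
        return self.n_controls if self.n_controls is not None else self.control_ratio * self.n_cases


@dataclass
class TruthSet:
    """Ground truth of a generated cohort, exactly recomputable from it."""

    planted: list[dict]  # one record per signature: spec fields + realised stats
    sample_communities: dict  # sample_id -> list of community labels carried

    def to_json(self, path) -> None:
        payload = {
            "planted": self.planted,
            "sample_communities": {k: v for k, v in self.sample_communities.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


# ---------------------------------------------------------------------------
# calibration: liability model
# ---------------------------------------------------------------------------

def _hwe_probs(p_alt: float) -> np.ndarray:
    return np.array([(1 - p_alt) ** 2, 2 * p_alt * (1 - p_alt), p_alt ** 2])


def _state_prob_to_alt_freq(state: int, t: float) -> float:
    """Invert the HWE genotype probability for one state; NaN if impossible."""
    if state == 0:
        return 1.0 - np.sqrt(t)
    if state == 2:
        return float(np.sqrt(t))
    if t > 0.5:
        return float("nan")
    return float((1.0 - np.sqrt(1.0 - 2.0 * t)) / 2.0)


def _config_weights(qs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All 2^K carrier configurations with their population probabilities."""
    K = qs.size
    configs = np.array(list(itertools.product([0, 1], repeat=K)), dtype=int)
    w = np.prod(np.where(configs == 1, qs, 1 - qs), axis=1)
    return configs, w


def _expected_table(qs, betas, baseline, s):
    """Expected carrier/non-carrier probabilities among sampled cases and
    controls for signature ``s`` under the joint liability model."""
    configs, w = _config_weights(qs)
    pcase = expit(baseline + configs @ betas)
    carrier = configs[:, s] == 1
    num_case = np.where(carrier, w * pcase, 0).sum()
    den_case = (w * pcase).sum()
    num_ctrl = np.where(carrier, w * (1 - pcase), 0).sum()
    den_ctrl = (w * (1 - pcase)).sum()
    return num_case / den_case, num_ctrl / den_ctrl


def _sampled_or(p_case: float, p_ctrl: float) -> float:
    return (p_case / (1 - p_case)) / (p_ctrl / (1 - p_ctrl))


def _calibrate_liability(planted, baseline, tol=1e-6, max_iter=200):
    """Solve (beta_s, q_s) per signature so the expected sampled OR and case
    prevalence hit their targets, by cyclic 1-D root finding."""
    K = len(planted)
    betas = np.array([np.log(s.target_or) for s in planted])
    qs = np.empty(K)
    for i, s in enumerate(planted):
        r = expit(baseline + betas[i]) / expit(baseline)
        prev = s.target_case_prevalence
        qs[i] = prev / (r * (1 - prev) + prev)
    for _ in range(max_iter):
        worst = 0.0
        for i, s in enumerate(planted):
            def or_gap(b):
                bb = betas.copy()
                bb[i] = b
                pc, pk = _expected_table(qs, bb, baseline, i)
                return _sampled_or(pc, pk) - s.target_or

            betas[i] = brentq(or_gap, 1e-9, 20.0, xtol=1e-12)

            def prev_gap(q):
                qq = qs.copy()
                qq[i] = q
                pc, _ = _expected_table(qq, betas, baseline, i)
                return pc - s.target_case_prevalence

            qs[i] = brentq(prev_gap, 1e-9, 1 - 1e-9, xtol=1e-14)
            pc, pk = _expected_table(qs, betas, baseline, i)
            worst = max(
                worst,
                abs(_sampled_or(pc, pk) - s.target_or),
                abs(pc - s.target_case_prevalence),
            )
        if worst < tol:
            break
    return betas, qs


# ---------------------------------------------------------------------------
# calibration: marginal-free interactions
# ---------------------------------------------------------------------------

def _marginal_free_penetrance(weights: np.ndarray, cells: np.ndarray, target_idx: int,
                              f0: float, f1: float, purity: str = "single") -> np.ndarray:
    """Penetrance vector over genotype cells: elevated at the target cell,
    compensated elsewhere so lower-order case rates are flat — per-SNP
    genotype rates ("single"), or additionally every two-SNP joint rate
    ("pairwise", a pure interaction).  Exact constrained least-squares
    projection."""
    n_cells, k = cells.shape
    free = [i for i in range(n_cells) if i != target_idx]
    rows = []
    rhs = []

    def flat_constraints(axes):
        # case rate of every genotype cell over `axes` equals the (0,..,0) one
        base = np.all(cells[:, axes] == 0, axis=1)
        pg0 = weights[base].sum()
        for combo in itertools.product((0, 1, 2), repeat=len(axes)):
            if all(g == 0 for g in combo):
                continue
            sel = np.all(cells[:, axes] == np.array(combo), axis=1)
            pg = weights[sel].sum()
            coeff = np.zeros(n_cells)
            coeff[base] += weights[base] / pg0
            coeff[sel] -= weights[sel] / pg
            rows.append(coeff[free])
            rhs.append(-coeff_target(coeff, target_idx) * f1)

    if purity == "pairwise":
        for i, j in itertools.combinations(range(k), 2):
            flat_constraints([i, j])
    else:
        for j in range(k):
            flat_constraints([j])
    C = np.array(rows)
    d = np.array(rhs)
    # probability-weighted projection: minimise sum_i w_i (x_i - f0)^2
    # s.t. Cx = d, so the compensation concentrates in rare genotype cells
    # (large deviations where carrier counts are small keeps every
    # non-target cell statistically quiet)  ->  x = f0 + W^-1 C^T lam
    w_free = np.maximum(weights[free], 1e-12)
    CW = C / w_free[None, :]
    lam, *_ = np.linalg.lstsq(C @ CW.T, d - C @ np.full(len(free), f0), rcond=None)
    x = np.full(len(free), f0) + CW.T @ lam
    f = np.empty(n_cells)
    f[free] = x
    f[target_idx] = f1
    return f


def coeff_target(coeff: np.ndarray, idx: int) -> float:
    return float(coeff[idx])


def _marginal_free_solution(sig: PlantedSignatureSpec, baseline: float, maf_range):
    """Solve (per-SNP alt freqs, penetrance table) for a marginal-free
    planted interaction at the target OR and case prevalence."""
    k = sig.order
    cells = np.array(list(itertools.product((0, 1, 2), repeat=k)), dtype=int)
    target_idx = int(np.flatnonzero((cells == np.array(sig.genotype_states)).all(axis=1))[0])
    f0 = float(expit(baseline))

    def build(q):
        t = q ** (1.0 / k)
        freqs = [_state_prob_to_alt_freq(g, t) for g in sig.genotype_states]
        if any(np.isnan(p) for p in freqs):
            raise InfeasibleSignatureError(
                f"signature {sig.snp_ids}: required genotype probability {t:.3f} "
                "is unreachable under Hardy-Weinberg"
            )
        w = np.ones(len(cells))
        for j, p in enumerate(freqs):
            w *= _hwe_probs(p)[cells[:, j]]
        return freqs, w

    def stats_for(q, f1):
        freqs, w = build(q)
        f = _marginal_free_penetrance(w, cells, target_idx, f0, f1, sig.purity)
        if f.min() < 1e-9 or f.max() > 1 - 1e-9:
            return freqs, f, np.nan, np.nan
        wt = w[target_idx]
        case_mass = float((w * f).sum())
        ctrl_mass = float((w * (1 - f)).sum())
        p_case = wt * f1 / case_mass
        p_ctrl = wt * (1 - f1) / ctrl_mass
        return freqs, f, _sampled_or(p_case, p_ctrl), p_case

    def solve_f1(q):
        def gap(f1):
            *_, or_, _ = stats_for(q, f1)
            if np.isnan(or_):
                return 1e9  # out-of-range penetrance: push away
            return or_ - sig.target_or

        return brentq(gap, f0 + 1e-9, 1 - 1e-6, xtol=1e-14)

    def prev_gap(q):
        f1 = solve_f1(q)
        *_, prev = stats_for(q, f1)
        return prev - sig.target_case_prevalence

    caps = {0: (1 - 1e-3) ** 2, 1: 0.5, 2: 0.25}
    q_hi = float(np.prod([caps[g] for g in sig.genotype_states])) * (1 - 1e-6)
    try:
        q = brentq(prev_gap, 1e-6, q_hi, xtol=1e-12)
        f1 = solve_f1(q)
    except ValueError as exc:
        raise InfeasibleSignatureError(
            f"signature {sig.snp_ids}: marginal-free targets unreachable ({exc})"
        ) from exc
    freqs, w = build(q)
    f = _marginal_free_penetrance(w, cells, target_idx, f0, f1, sig.purity)
    if f.min() < 0 or f.max() > 1:
        raise InfeasibleSignatureError(
            f"signature {sig.snp_ids}: compensated penetrance leaves [0,1]; "
            "lower target_or or target_case_prevalence"
        )
    # brentq can converge onto the penetrance-feasibility boundary instead
    # of the target; verify the achieved odds ratio honestly
    *_, achieved_or, achieved_prev = stats_for(q, f1)
    if not np.isfinite(achieved_or) or abs(achieved_or - sig.target_or) > 0.01 * sig.target_or:
        raise InfeasibleSignatureError(
            f"signature {sig.snp_ids}: a {sig.purity}-flat interaction at "
            f"prevalence {sig.target_case_prevalence} cannot reach OR "
            f"{sig.target_or} (achievable ~{achieved_or:.2f}); lower the "
            "target or raise the baseline risk"
        )
    _check_maf(freqs, maf_range, sig)
    return freqs, cells, w, f


def _check_maf(freqs, maf_range, sig) -> None:
    lo, hi = maf_range
    for snp, p in zip(sig.snp_ids, freqs):
        maf = min(p, 1 - p)
        if not lo <= maf <= hi + 1e-12:
            raise InfeasibleSignatureError(
                f"signature {sig.snp_ids}: member SNP {snp} needs MAF {maf:.4f} "
                f"outside the configured range {maf_range}; adjust targets"
            )


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _background_genotypes(rng, n, mafs, ld_rho):
    if ld_rho <= 0:
        return rng.binomial(2, mafs, size=(n, mafs.size)).astype(np.int8)
    # simple block-LD: each haplotype copies the previous SNP's allele with
    # probability ld_rho, else draws fresh at that SNP's frequency
    geno = np.zeros((n, mafs.size), dtype=np.int8)
    for hap in range(2):
        alleles = np.zeros((n, mafs.size), dtype=np.int8)
        alleles[:, 0] = rng.random(n) < mafs[0]
        for j in range(1, mafs.size):
            copy = rng.random(n) < ld_rho
            fresh = rng.random(n) < mafs[j]
            alleles[:, j] = np.where(copy, alleles[:, j - 1], fresh)
        geno += alleles
    return geno


def _sample_nonmatching(rng, n, freqs, states):
    """Genotype rows from independent HWE conditioned on NOT matching all
    required states (rejection sampling)."""
    k = len(freqs)
    out = np.empty((n, k), dtype=np.int8)
    need = np.arange(n)
    states = np.asarray(states)
    for _ in range(1000):
        if need.size == 0:
            break
        draw = np.column_stack(
            [rng.binomial(2, p, size=need.size) for p in freqs]
        ).astype(np.int8)
        out[need] = draw
        matched = (out[need] == states).all(axis=1)
        need = need[matched]
    if need.size:
        raise RuntimeError("rejection sampling failed to converge")
    return out


def _synthetic_gene_model(snp_meta: pd.DataFrame, planted) -> GeneModel:
    """Synthetic gene model placing each planted SNP inside a coding region,
    2 kb upstream, or 0.5 kb downstream of a named synthetic gene (cycled),
    plus one distant decoy gene per chromosome used."""
    rows, coding = [], {}
    i = 0
    for sig in planted:
        for snp in sig.snp_ids:
            chrom = str(snp_meta.loc[snp, "chrom"])
            pos = int(snp_meta.loc[snp, "pos"])
            cls = i % 3
            gid = f"GENE_{snp}"
            if cls == 0:  # SNP inside the coding interval
                start, end = pos - 500, pos + 500
                coding[gid] = [(pos - 100, pos + 100)]
            elif cls == 1:  # SNP 1.5 kb upstream of a + strand gene body
                start, end = pos + 1500, pos + 2500
                coding[gid] = [(start, end)]
            else:  # SNP 0.4 kb downstream of a + strand gene body
                start, end = pos - 1400, pos - 400
                coding[gid] = [(start, end)]
            rows.append(
                {"gene_id": gid, "chrom": chrom, "strand": "+",
                 "start": max(1, start), "end": end}
            )
            i += 1
    chroms = {str(c) for c in snp_meta["chrom"].unique()}
    for c in sorted(chroms):
        rows.append(
            {"gene_id": f"DECOY_{c}", "chrom": c, "strand": "-",
             "start": 900_000_000, "end": 900_001_000}
        )
    return GeneModel(genes=pd.DataFrame(rows), coding=coding)


def generate_cohort(spec: CohortSpec):
    """Generate (GenotypeMatrix, covariates, GeneModel, TruthSet).

    Bit-identical for identical spec + seed.
    """
    rng = np.random.default_rng(spec.seed)
    n_cases = spec.n_cases
    n_controls = spec.resolved_n_controls
    n = n_cases + n_controls
    is_case = np.zeros(n, dtype=bool)
    is_case[:n_cases] = True
    sample_ids = np.array(
        [f"case_{i + 1:05d}" for i in range(n_cases)]
        + [f"ctrl_{i + 1:05d}" for i in range(n_controls)],
        dtype=object,
    )

    # SNP universe: planted member SNPs keep their requested ids; background
    # SNPs fill the rest
    planted = list(spec.planted)
    member_ids = [s for sig in planted for s in sig.snp_ids]
    n_background = spec.n_snps - len(set(member_ids))
    if n_background < 0:
        raise ValueError("n_snps smaller than the number of planted SNPs")
    snp_ids = list(dict.fromkeys(member_ids)) + [
        f"snp_{i + 1:05d}" for i in range(n_background)
    ]
    col_of = {s: j for j, s in enumerate(snp_ids)}

    lo, hi = spec.maf_range
    mafs = rng.uniform(lo, hi, size=len(snp_ids))
    genotypes = _background_genotypes(rng, n, mafs, spec.ld_rho)

    liability = [s for s in planted if not s.marginal_free]
    marginal_free = [s for s in planted if s.marginal_free]
    if liability and marginal_free:
        raise ValueError(
            "mixing liability-model and marginal-free planted signatures in "
            "one cohort is not supported"
        )

    alt_freqs = mafs.copy()

    if liability:
        betas, qs = _calibrate_liability(liability, spec.baseline_case_logodds)
        # per-SNP allele frequencies realising each signature's carrier prob
        sig_freqs = []
        for sig, q in zip(liability, qs):
            t = q ** (1.0 / sig.order)
            freqs = [_state_prob_to_alt_freq(g, t) for g in sig.genotype_states]
            if any(np.isnan(p) for p in freqs):
                raise InfeasibleSignatureError(
                    f"signature {sig.snp_ids}: genotype probability {t:.3f} "
                    "unreachable under Hardy-Weinberg"
                )
            _check_maf(freqs, spec.maf_range, sig)
            sig_freqs.append(freqs)
        # retrospective sampling of the joint carrier configuration
        configs, w = _config_weights(qs)
        pcase = expit(spec.baseline_case_logodds + configs @ betas)
        p_cfg_case = w * pcase / (w * pcase).sum()
        p_cfg_ctrl = w * (1 - pcase) / (w * (1 - pcase)).sum()
        cfg = np.empty(n, dtype=int)
        cfg[is_case] = rng.choice(len(configs), size=n_cases, p=p_cfg_case)
        cfg[~is_case] = rng.choice(len(configs), size=n_controls, p=p_cfg_ctrl)
        carrier_flags = configs[cfg]  # n x K
        for i, (sig, freqs) in enumerate(zip(liability, sig_freqs)):
            cols = [col_of[s] for s in sig.snp_ids]
            carriers = carrier_flags[:, i] == 1
            genotypes[np.ix_(carriers, cols)] = np.array(sig.genotype_states, dtype=np.int8)
            non = np.flatnonzero(~carriers)
            genotypes[np.ix_(non, cols)] = _sample_nonmatching(
                rng, non.size, freqs, sig.genotype_states
            )
            for c, p in zip(cols, freqs):
                alt_freqs[c] = p
    elif marginal_free:
        carrier_flags = np.zeros((n, len(marginal_free)), dtype=int)
        for i, sig in enumerate(marginal_free):
            freqs, cells, w, f = _marginal_free_solution(
                sig, spec.baseline_case_logodds, spec.maf_range
            )
            p_cell_case = w * f / (w * f).sum()
            p_cell_ctrl = w * (1 - f) / (w * (1 - f)).sum()
            cell_idx = np.empty(n, dtype=int)
            cell_idx[is_case] = rng.choice(len(cells), size=n_cases, p=p_cell_case)
            cell_idx[~is_case] = rng.choice(len(cells), size=n_controls, p=p_cell_ctrl)
            cols = [col_of[s] for s in sig.snp_ids]
            genotypes[:, cols] = cells[cell_idx].astype(np.int8)
            target = np.array(sig.genotype_states)
            carrier_flags[:, i] = (cells[cell_idx] == target).all(axis=1)
            for c, p in zip(cols, freqs):
                alt_freqs[c] = p
    else:
        carrier_flags = np.zeros((n, 0), dtype=int)

    # missing-data injection (after planting; truth is rescanned afterwards)
    if spec.missing_rate > 0:
        mask = rng.random(genotypes.shape) < spec.missing_rate
        genotypes[mask] = MISSING

    # SNP metadata and gene model
    chroms = [str(1 + (j % 22)) for j in range(len(snp_ids))]
    positions = [100_000 * (j // 22 + 1) + 10_000 for j in range(len(snp_ids))]
    snp_meta = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": chroms,
            "pos": positions,
            "ref": "A",
            "alt": "G",
            "maf": np.minimum(alt_freqs, 1 - alt_freqs),
        }
    ).set_index("snp_id")

    gm = GenotypeMatrix(
        sample_ids=sample_ids,
        snp_ids=np.array(snp_ids, dtype=object),
        genotypes=genotypes,
        is_case=is_case,
        snp_meta=snp_meta,
    )
    gene_model = _synthetic_gene_model(snp_meta, planted)

    # covariates, with planted per-community effects applied to carriers
    cov = {}
    order = planted  # carrier_flags columns follow this order
    for cs in spec.covariate_schema:
        if cs.kind == "binary":
            lo_ = logit(np.clip(cs.rate, 1e-9, 1 - 1e-9))
            eta = np.full(n, lo_)
            for i, sig in enumerate(order):
                eff = sig.covariate_effects.get(cs.name, 0.0)
                eta += carrier_flags[:, i] * eff
            cov[cs.name] = (rng.random(n) < expit(eta)).astype(int)
        else:
            mu = np.full(n, float(cs.mean))
            for i, sig in enumerate(order):
                shift = sig.biomarker_shifts.get(cs.name, 0.0)
                mu += carrier_flags[:, i] * shift * cs.sd
            cov[cs.name] = mu + rng.normal(0.0, cs.sd, size=n)
    covariates = pd.DataFrame(cov, index=pd.Index(sample_ids, name="sample_id"))
    covariates["ancestry"] = "EUR"
    covariates["sex"] = np.where(
        covariates.get("sex_female", pd.Series(0, index=covariates.index)) == 1,
        "F",
        "M",
    )

    # truth: realised carrier stats by exact rescan of the emitted matrix
    truth_records = []
    sample_comms: dict[str, list[str]] = {str(s): [] for s in sample_ids}
    from .mining import FeatureState

    for i, sig in enumerate(planted):
        label = f"C{i + 1}"
        states = [FeatureState(s, g) for s, g in zip(sig.snp_ids, sig.genotype_states)]
        carrier = carrier_vector(gm, states)
        a = int((carrier & is_case).sum())
        c = int((carrier & ~is_case).sum())
        table = ContingencyTable2x2(a, n_cases - a, c, n_controls - c)
        for s in sample_ids[carrier]:
            sample_comms[str(s)].append(label)
        truth_records.append(
            {
                "community": label,
                "snp_ids": list(sig.snp_ids),
                "genotype_states": list(sig.genotype_states),
                "target_or": sig.target_or,
                "target_case_prevalence": sig.target_case_prevalence,
                "marginal_free": sig.marginal_free,
                "case_carriers": a,
                "control_carriers": c,
                "realized_or": odds_ratio(table),
                "realized_case_prevalence": a / n_cases,
            }
        )
    truth = TruthSet(planted=truth_records, sample_communities=sample_comms)
    return gm, covariates, gene_model, truth
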