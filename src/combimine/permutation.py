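"""Permutation-null validation of mined signatures (the P1000 score).

Case/control labels are shuffled (preserving the case:control ratio
exactly), mining is re-run with identical parameters on each shuffled
dataset, and each observed signature is checked against every permutation's
result set: a permutation scores a *hit* for a signature if it produced any
combination — of any order up to ``max_order`` — at least as strong on both
axes the score is defined over, odds ratio and case-carrier count.  The
per-signature hit count over ``n_perm`` permutations is the permutation
score (P1000 when ``n_perm`` = 1000); 0 means no random relabelling ever
produced a comparably strong combination.

Empirical p-values use the (hits+1)/(n_perm+1) correction so that BH on
them is well defined, and signatures are validated by BH at the configured
FDR plus the case-prevalence floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import GenotypeMatrix
from .mining import MiningParams, Signature, _raw_mine, _StateSpace
from .stats import bh_adjust

__all__ = [
    "ValidationParams",
    "PermutationReport",
    "permute_labels",
    "compute_p1000",
    "validate_signatures",
]


@dataclass(frozen=True)
class ValidationParams:
    n_perm: int = 1000
    fdr_alpha: float = 0.05
    p1000_significance_fraction: float = 0.05
    # hit criterion scaling (1.0 = combination must match the observed
    # signature on both odds ratio and case-carrier count)
    hit_or_scale: float = 1.0
    hit_count_scale: float = 1.0
    # "order_stratified": a hit must have the same combinatorial order as
    # the signature it is compared against; "any_order": order-agnostic
    hit_match: str = "order_stratified"
    seed: int = 0
    mining: MiningParams = field(default_factory=MiningParams)

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1 (empirical p undefined otherwise)")
        if not 0.0 < self.fdr_alpha < 1.0:
            raise ValueError("fdr_alpha must lie in (0, 1)")


@dataclass
class PermutationReport:
    """Per-signature permutation hit counts and validation flags."""

    signatures: list[Signature]
    p1000: np.ndarray  # int hit count per signature
    n_perm: int
    empirical_p: np.ndarray
    validated: np.ndarray | None = None
    p1000_significant: np.ndarray | None = None
    q_values: np.ndarray | None = None
    # audit trail: per permutation, the strongest combination found
    perm_log: list[dict] = field(default_factory=list)

    def to_records(self) -> list[dict]:
        recs = []
        for i, s in enumerate(self.signatures):
            recs.append(
                {
                    "states": ";".join(str(st) for st in s.states),
                    "p1000": int(self.p1000[i]),
                    "n_perm": self.n_perm,
                    "empirical_p": float(self.empirical_p[i]),
                    "q_value": None if self.q_values is None else float(self.q_values[i]),
                    "validated": None if self.validated is None else bool(self.validated[i]),
                    "p1000_significant": None
                    if self.p1000_significant is None
                    else bool(self.p1000_significant[i]),
                }
            )
        return recs

    def to_tsv(self, path) -> None:
        recs = self.to_records()
        with open(path, "w") as fh:
            cols = ["states", "p1000", "n_perm", "empirical_p", "q_value", "validated", "p1000_significant"]
            fh.write("\t".join(cols) + "\n")
            for r in recs:
                fh.write("\t".join("NA" if r[c] is None else str(r[c]) for c in cols) + "\n")


def permute_labels(gm: GenotypeMatrix, seed: int, iteration: int) -> np.ndarray:
    """Uniform random permutation of the existing case/control labels.

    Deterministic per (seed, iteration); the label multiset (and hence the
    case:control ratio) is preserved exactly.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(iteration,)))
    return rng.permutation(gm.is_case)


def compute_p1000(
    signatures: list[Signature],
    gm: GenotypeMatrix,
    params: ValidationParams = ValidationParams(),
) -> PermutationReport:
    """Permutation score for each mined signature.

    Mining is re-run on each label permutation with the same
    ``MiningParams`` used for the observed run (the stochastic search draws
    a per-iteration stream derived from the validation seed).  A signature
    scores a hit in a permutation iff the permuted result set contains any
    combination with odds ratio >= the signature's observed OR and
    case-carrier count >= its observed count — by default within the same
    combinatorial order, so each signature is compared against the
    permutation stratum searched under the same multiplicity (an
    order-agnostic variant is available via ``hit_match``).
    """
    if not signatures:
        return PermutationReport(
            signatures=[], p1000=np.array([], dtype=int), n_perm=params.n_perm,
            empirical_p=np.array([]),
        )
    space = _StateSpace(gm)
    obs_or = np.array([s.odds_ratio * params.hit_or_scale for s in signatures])
    obs_cnt = np.array([s.table.case_carriers * params.hit_count_scale for s in signatures])
    # combos weaker than the weakest signature on either axis can never
    # register a hit, so exhaustive re-mining may screen them out early
    screen_or = float(obs_or.min())
    screen_count = int(np.floor(obs_cnt.min()))
    hits = np.zeros(len(signatures), dtype=int)
    perm_log = []
    for it in range(params.n_perm):
        labels = permute_labels(gm, params.seed, it)
        iter_seed = int(
            np.random.SeedSequence(params.seed, spawn_key=(it, 1)).generate_state(1)[0]
            % (2**31)
        )
        raw = _raw_mine(
            space,
            labels,
            params.mining,
            seed=iter_seed,
            screen_or=screen_or,
            screen_count=screen_count,
        )
        if len(raw):
            ors = np.asarray(raw.ors)
            cnts = np.asarray(raw.case_carriers)
            hit_mask = (ors[None, :] >= obs_or[:, None]) & (
                cnts[None, :] >= obs_cnt[:, None]
            )
            if params.hit_match == "order_stratified":
                orders = np.array([len(c) for c in raw.combos])
                obs_order = np.array([s.order for s in signatures])
                hit_mask &= orders[None, :] == obs_order[:, None]
            hits += hit_mask.any(axis=1)
            perm_log.append(
                {"iteration": it, "n_combos": len(raw),
                 "max_or": float(ors.max()), "max_case_carriers": int(cnts.max())}
            )
        else:
            perm_log.append(
                {"iteration": it, "n_combos": 0, "max_or": None, "max_case_carriers": None}
            )
    empirical_p = (hits + 1.0) / (params.n_perm + 1.0)
    return PermutationReport(
        signatures=list(signatures),
        p1000=hits,
        n_perm=params.n_perm,
        empirical_p=empirical_p,
        perm_log=perm_log,
    )


def validate_signatures(
    signatures: list[Signature],
    report: PermutationReport,
    params: ValidationParams = ValidationParams(),
) -> list[Signature]:
    """BH-filter signatures on their permutation empirical p-values.

    Survivors must also satisfy the case-prevalence floor.  Signatures with
    a permutation hit fraction below ``p1000_significance_fraction`` are
    additionally flagged (not filtered) as permutation-significant.
    """
    if list(report.signatures) != list(signatures):
        raise ValueError("report does not cover the given signatures")
    if not signatures:
        report.validated = np.array([], dtype=bool)
        report.q_values = np.array([])
        report.p1000_significant = np.array([], dtype=bool)
        return []
    q, reject = bh_adjust(report.empirical_p, alpha=params.fdr_alpha)
    prev_ok = np.array(
        [s.case_prevalence >= params.mining.min_case_prevalence for s in signatures]
    )
    validated = reject & prev_ok
    report.q_values = q
    report.validated = validated
    report.p1000_significant = (report.p1000 / report.n_perm) < params.p1000_significance_fraction
    return [s for s, v in zip(signatures, validated) if v]
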