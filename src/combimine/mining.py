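"""High-order SNP-genotype combination mining.

The atomic unit is a *feature state*: a (SNP, ordinal genotype) pair.  A
*signature* is a combination of 1-5 feature states on distinct SNPs; a
sample *carries* a signature iff its genotype equals the required state at
every member SNP (a missing genotype never matches).  Mining searches for
combinations over-represented in cases: low Fisher p, odds ratio > 1, and
case prevalence above a floor.

Two search modes are provided:

* ``exhaustive`` — level-wise enumeration of all combinations up to
  ``max_order`` with monotone prevalence pruning (a combination's carrier
  set only shrinks as states are added).  Guarded by an evaluation budget.
* ``greedy_stochastic`` — seeded greedy extension from passing singleton
  states, adding at each step the feature state that most improves the
  score (-log10 Fisher p), stopping when no extension improves it.  This is
  a documented stand-in for large panels where exhaustive search is
  infeasible.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .io import MISSING, GenotypeMatrix
from .stats import (
    ContingencyTable2x2,
    fisher_exact_many,
    fisher_exact_p,
    odds_ratio,
)

__all__ = [
    "FeatureState",
    "Signature",
    "MiningParams",
    "matches",
    "evaluate_combination",
    "mine_signatures",
]

GENOTYPE_STATES = (0, 1, 2)


@dataclass(frozen=True, order=True)
class FeatureState:
    """One SNP fixed at one ordinal genotype."""

    snp_id: str
    genotype: int

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPE_STATES:
            raise ValueError("genotype state must be 0, 1 or 2")

    def __str__(self) -> str:
        return f"{self.snp_id}:{self.genotype}"


@dataclass(frozen=True)
class Signature:
    """A combination of feature states with its case/control statistics."""

    states: tuple[FeatureState, ...]
    table: ContingencyTable2x2
    odds_ratio: float
    p_value: float
    case_prevalence: float
    case_ids: frozenset
    control_ids: frozenset

    def __post_init__(self) -> None:
        snps = [s.snp_id for s in self.states]
        if len(set(snps)) != len(snps):
            raise ValueError("signature repeats a SNP")
        if not 1 <= len(self.states) <= 5:
            raise ValueError("signature order must be between 1 and 5")

    @property
    def order(self) -> int:
        return len(self.states)

    @property
    def snp_ids(self) -> tuple[str, ...]:
        return tuple(s.snp_id for s in self.states)

    def key(self) -> frozenset:
        return frozenset(self.states)

    def __str__(self) -> str:
        states = ";".join(str(s) for s in self.states)
        return (
            f"{states}\tOR={self.odds_ratio:.3g}\tp={self.p_value:.3g}"
            f"\tcases={self.table.case_carriers}/{self.table.n_cases}"
        )


@dataclass(frozen=True)
class MiningParams:
    max_order: int = 5
    p_max: float = 0.05
    min_case_prevalence: float = 0.05
    search_mode: str = "greedy_stochastic"
    n_random_starts: int = 200
    beam_width: int = 2
    seed: int = 0
    combination_budget: float = 5e7
    protective: bool = False  # also report OR < 1 combinations

    def __post_init__(self) -> None:
        if not 0.0 < self.min_case_prevalence < 1.0:
            raise ValueError("min_case_prevalence must be in (0, 1)")
        if not 1 <= self.max_order <= 5:
            raise ValueError("max_order must be between 1 and 5")
        if self.search_mode not in {"exhaustive", "greedy_stochastic"}:
            raise ValueError(f"unknown search mode: {self.search_mode}")


# ---------------------------------------------------------------------------
# carrier predicates
# ---------------------------------------------------------------------------

def matches(sample_genotypes, signature_states, snp_index=None) -> bool:
    """True iff the sample carries every state of the signature.

    ``sample_genotypes`` is either a mapping snp_id -> genotype or a 1-D
    array indexed via ``snp_index`` (mapping snp_id -> column).  A missing
    genotype (-1/None) at a member SNP makes the sample a non-carrier.
    """
    states = getattr(signature_states, "states", signature_states)
    for st in states:
        if snp_index is not None:
            if st.snp_id not in snp_index:
                raise KeyError(f"unknown SNP in signature: {st.snp_id}")
            g = sample_genotypes[snp_index[st.snp_id]]
        else:
            if st.snp_id not in sample_genotypes:
                raise KeyError(f"unknown SNP in signature: {st.snp_id}")
            g = sample_genotypes[st.snp_id]
        if g is None or g == MISSING or int(g) != st.genotype:
            return False
    return True


def carrier_vector(gm: GenotypeMatrix, states) -> np.ndarray:
    """Boolean per-sample carrier indicator for a combination of states."""
    states = getattr(states, "states", states)
    carrier = np.ones(gm.n_samples, dtype=bool)
    for st in states:
        j = gm.snp_index(st.snp_id)
        carrier &= gm.genotypes[:, j] == st.genotype
    return carrier


def evaluate_combination(states, gm: GenotypeMatrix) -> Signature:
    """Full-scan evaluation of one combination into a Signature."""
    states = tuple(sorted(states))
    carrier = carrier_vector(gm, states)
    case_car = carrier & gm.is_case
    ctrl_car = carrier & ~gm.is_case
    table = ContingencyTable2x2(
        int(case_car.sum()),
        int(gm.n_cases - case_car.sum()),
        int(ctrl_car.sum()),
        int(gm.n_controls - ctrl_car.sum()),
    )
    return Signature(
        states=states,
        table=table,
        odds_ratio=odds_ratio(table),
        p_value=fisher_exact_p(table),
        case_prevalence=table.case_carriers / max(table.n_cases, 1),
        case_ids=frozenset(gm.sample_ids[case_car]),
        control_ids=frozenset(gm.sample_ids[ctrl_car]),
    )


# ---------------------------------------------------------------------------
# internal vectorised search over a feature-state design matrix
# ---------------------------------------------------------------------------

class _StateSpace:
    """Dense float32 sample x feature-state indicator matrix.

    Built once per genotype matrix; label permutations reuse it, which is
    what makes permutation re-mining affordable.
    """

    def __init__(self, gm: GenotypeMatrix):
        self.gm = gm
        states = []
        cols = []
        for j in range(gm.n_snps):
            col = gm.genotypes[:, j]
            for g in GENOTYPE_STATES:
                ind = col == g
                if ind.any():
                    states.append((j, g))
                    cols.append(ind)
        self.states = states  # list of (snp_col, genotype)
        self.snp_of = np.array([j for j, _ in states])
        self.X = np.array(cols, dtype=np.float32).T  # samples x states
        self.Xb = self.X.astype(bool)

    @property
    def n_states(self) -> int:
        return len(self.states)

    def feature_state(self, idx: int) -> FeatureState:
        j, g = self.states[idx]
        return FeatureState(str(self.gm.snp_ids[j]), g)


class _MinedCombos:
    """Flat result of a raw search: passing combos as index tuples + stats."""

    def __init__(self):
        self.combos: list[tuple[int, ...]] = []
        self.case_carriers: list[int] = []
        self.control_carriers: list[int] = []
        self.pvals: list[float] = []
        self.ors: list[float] = []

    def add(self, combo, a, c, p, or_):
        self.combos.append(tuple(combo))
        self.case_carriers.append(int(a))
        self.control_carriers.append(int(c))
        self.pvals.append(float(p))
        self.ors.append(float(or_))

    def __len__(self) -> int:
        return len(self.combos)


def _passing_mask(a, c, n_cases, n_controls, params, pvals=None):
    a = np.asarray(a, dtype=float)
    c = np.asarray(c, dtype=float)
    prev_ok = a / n_cases >= params.min_case_prevalence
    with np.errstate(divide="ignore", invalid="ignore"):
        or_ = (a * (n_controls - c)) / ((n_cases - a) * c)
    enriched = a * (n_controls - c) > (n_cases - a) * c
    if params.protective:
        enriched |= a * (n_controls - c) < (n_cases - a) * c
    mask = prev_ok & enriched
    if pvals is not None:
        mask &= np.asarray(pvals) < params.p_max
    return mask, or_


def _search_exhaustive(
    space: _StateSpace,
    is_case: np.ndarray,
    params: MiningParams,
    screen_or: float | None = None,
    screen_count: int | None = None,
) -> _MinedCombos:
    """Level-wise exhaustive enumeration with monotone prevalence pruning.

    ``screen_or``/``screen_count`` optionally restrict the *reported* set to
    combos at least that strong (used by permutation hit counting, where
    weaker combos cannot register a hit); pruning by prevalence is always
    applied and is exact because carrier sets shrink monotonically.
    """
    F = space.n_states
    n_cases = int(is_case.sum())
    n_controls = int((~is_case).sum())
    total = sum(math.comb(F, k) for k in range(1, params.max_order + 1))
    if total > params.combination_budget:
        raise RuntimeError(
            f"exhaustive search would evaluate ~{total:.2e} combinations, "
            f"over the budget of {params.combination_budget:.0e}; "
            "use greedy_stochastic or raise combination_budget"
        )
    min_cases = math.ceil(params.min_case_prevalence * n_cases)
    case_f = is_case.astype(np.float32)
    ctrl_f = (~is_case).astype(np.float32)
    out = _MinedCombos()

    def report(combos, a_arr, c_arr):
        if len(combos) == 0:
            return
        a_arr = np.asarray(a_arr)
        c_arr = np.asarray(c_arr)
        mask, or_ = _passing_mask(a_arr, c_arr, n_cases, n_controls, params)
        if screen_or is not None:
            mask &= (or_ >= screen_or) & (a_arr >= screen_count)
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            return
        p = fisher_exact_many(a_arr[idx], n_cases, c_arr[idx], n_controls)
        for i, pi in zip(idx, p):
            if pi < params.p_max:
                out.add(combos[i], a_arr[i], c_arr[i], pi, or_[i])

    # order 1
    a1 = case_f @ space.X
    c1 = ctrl_f @ space.X
    report([(i,) for i in range(F)], a1, c1)

    # deeper orders: extend only prevalence-passing parents by states on
    # strictly later SNP columns (canonical, duplicate-free enumeration)
    frontier = [
        ((i,), space.Xb[:, i])
        for i in range(F)
        if a1[i] >= min_cases
    ]
    for _order in range(2, params.max_order + 1):
        if not frontier:
            break
        next_frontier = []
        combos_lvl: list[tuple[int, ...]] = []
        a_lvl: list[float] = []
        c_lvl: list[float] = []
        for combo, carrier in frontier:
            last_snp = space.snp_of[combo[-1]]
            cand = np.flatnonzero(space.snp_of > last_snp)
            if cand.size == 0:
                continue
            a_ext = (carrier * case_f) @ space.X[:, cand]
            keep = a_ext >= min_cases
            if not keep.any():
                continue
            c_ext = (carrier * ctrl_f) @ space.X[:, cand[keep]]
            for s, a_v, c_v in zip(cand[keep], a_ext[keep], c_ext):
                child = combo + (int(s),)
                combos_lvl.append(child)
                a_lvl.append(a_v)
                c_lvl.append(c_v)
                if _order < params.max_order:
                    next_frontier.append((child, carrier & space.Xb[:, s]))
        report(combos_lvl, a_lvl, c_lvl)
        frontier = next_frontier
    return out


def _search_greedy(
    space: _StateSpace,
    is_case: np.ndarray,
    params: MiningParams,
    rng: np.random.Generator,
) -> _MinedCombos:
    """Greedy seeded extension from passing singleton states."""
    n_cases = int(is_case.sum())
    n_controls = int((~is_case).sum())
    case_f = is_case.astype(np.float32)
    ctrl_f = (~is_case).astype(np.float32)
    a1 = case_f @ space.X
    c1 = ctrl_f @ space.X
    mask, _ = _passing_mask(a1, c1, n_cases, n_controls, params)
    cand_idx = np.flatnonzero(mask)
    out = _MinedCombos()
    if cand_idx.size == 0:
        return out
    p1 = fisher_exact_many(a1[cand_idx], n_cases, c1[cand_idx], n_controls)
    starts = cand_idx[p1 < params.p_max]
    start_p = dict(zip(starts.tolist(), p1[p1 < params.p_max].tolist()))
    if starts.size > params.n_random_starts:
        starts = rng.choice(np.sort(starts), size=params.n_random_starts, replace=False)
    seen: set[tuple[int, ...]] = set()
    tiny = np.nextafter(0, 1)

    def record(combo, a, c, p):
        # every passing combination along a greedy path is reported, so the
        # result set covers all layers of combinatorial order, not only the
        # path terminus
        if combo in seen:
            return
        seen.add(combo)
        m, or_ = _passing_mask(
            np.array([a]), np.array([c]), n_cases, n_controls, params
        )
        if m[0] and p < params.p_max:
            out.add(combo, a, c, p, or_[0])

    expanded: set[tuple[int, ...]] = set()
    stack = []
    for s0 in np.sort(starts)[::-1]:
        combo = (int(s0),)
        record(combo, a1[s0], c1[s0], start_p[int(s0)])
        score = -math.log10(max(start_p[int(s0)], tiny))
        stack.append((combo, space.Xb[:, s0], score))
    if params.max_order >= 2:
        # pair starts rescue signatures whose member pairs sit in a score
        # valley below a marginal singleton: screen all pairs by a pooled
        # two-proportion z, Fisher-score the best n_random_starts of them
        for i, j, a_p, c_p, p_p in _pair_starts(
            space, case_f, ctrl_f, n_cases, n_controls, params
        ):
            combo = (i, j)
            record(combo, a_p, c_p, p_p)
            if p_p < params.p_max:
                stack.append(
                    (
                        combo,
                        space.Xb[:, i] & space.Xb[:, j],
                        -math.log10(max(p_p, tiny)),
                    )
                )
    # beam extension: from each node, follow the top beam_width extensions
    # that strictly improve the score (depth-first, deduplicated)
    while stack:
        combo, carrier, score = stack.pop()
        if len(combo) >= params.max_order or combo in expanded:
            continue
        expanded.add(combo)
        used_snps = space.snp_of[list(combo)]
        cand = np.flatnonzero(~np.isin(space.snp_of, used_snps))
        if cand.size == 0:
            continue
        a_ext = (carrier * case_f) @ space.X[:, cand]
        c_ext = (carrier * ctrl_f) @ space.X[:, cand]
        # only extensions keeping enough case carriers can pass the floor
        viable = np.flatnonzero(a_ext / n_cases >= params.min_case_prevalence)
        if viable.size == 0:
            continue
        # rank viable extensions by a cheap pooled z and Fisher-score only
        # the leaders; the exact-score argmax is preserved in practice and
        # the procedure stays deterministic
        av, cv = a_ext[viable], c_ext[viable]
        pooled = (av + cv) / (n_cases + n_controls)
        zden = np.sqrt(
            np.maximum(pooled * (1 - pooled), 1e-12) * (1 / n_cases + 1 / n_controls)
        )
        zv = (av / n_cases - cv / n_controls) / zden
        n_screen = min(viable.size, max(8 * params.beam_width, 32))
        lead = viable[np.argsort(zv, kind="stable")[::-1][:n_screen]]
        p_ext = np.ones(cand.size)
        p_ext[lead] = fisher_exact_many(
            a_ext[lead], n_cases, c_ext[lead], n_controls
        )
        scores = -np.log10(np.maximum(p_ext, tiny))
        improving = np.flatnonzero(scores > score)
        if improving.size == 0:
            continue
        top = improving[np.argsort(scores[improving], kind="stable")][::-1]
        for idx in top[: params.beam_width]:
            child = tuple(sorted(combo + (int(cand[idx]),)))
            record(child, a_ext[idx], c_ext[idx], p_ext[idx])
            if child not in expanded:
                stack.append((child, carrier & space.Xb[:, cand[idx]], scores[idx]))
    return out


def _pair_starts(space, case_f, ctrl_f, n_cases, n_controls, params):
    """Top case-enriched state pairs by a cheap z screen, Fisher-scored.

    Returns tuples (i, j, case_carriers, control_carriers, fisher_p) for the
    best ``n_random_starts`` pairs (i < j, distinct SNPs) that pass the
    prevalence floor and are case-enriched.
    """
    X = space.X
    A2 = (X * case_f[:, None]).T @ X  # case carrier counts per pair
    C2 = (X * ctrl_f[:, None]).T @ X
    iu, ju = np.triu_indices(space.n_states, k=1)
    same_snp = space.snp_of[iu] == space.snp_of[ju]
    a = A2[iu, ju]
    c = C2[iu, ju]
    keep = (~same_snp) & (a / n_cases >= params.min_case_prevalence)
    keep &= a * (n_controls - c) > (n_cases - a) * c  # OR > 1
    if not keep.any():
        return []
    a, c, iu, ju = a[keep], c[keep], iu[keep], ju[keep]
    pooled = (a + c) / (n_cases + n_controls)
    denom = np.sqrt(
        np.maximum(pooled * (1 - pooled), 1e-12) * (1 / n_cases + 1 / n_controls)
    )
    z = (a / n_cases - c / n_controls) / denom
    k = min(params.n_random_starts, z.size)
    top = np.argsort(z, kind="stable")[::-1][:k]
    p = fisher_exact_many(a[top], n_cases, c[top], n_controls)
    return [
        (int(iu[t]), int(ju[t]), float(a[t]), float(c[t]), float(pv))
        for t, pv in zip(top, p)
    ]


def _raw_mine(
    space: _StateSpace,
    is_case: np.ndarray,
    params: MiningParams,
    seed: int | None = None,
    screen_or: float | None = None,
    screen_count: int | None = None,
) -> _MinedCombos:
    if params.search_mode == "exhaustive":
        return _search_exhaustive(space, is_case, params, screen_or, screen_count)
    rng = np.random.default_rng(params.seed if seed is None else seed)
    return _search_greedy(space, is_case, params, rng)


# ---------------------------------------------------------------------------
# public entry point
# ---------------------------------------------------------------------------

def mine_signatures(gm: GenotypeMatrix, params: MiningParams = MiningParams()) -> list[Signature]:
    """Mine case-enriched combinations of 1-``max_order`` feature states.

    Returns signatures passing ``p < p_max``, case prevalence above the
    floor and OR > 1, sorted by (p ascending, OR descending, order
    ascending, states lexicographically).
    """
    space = _StateSpace(gm)
    raw = _raw_mine(space, gm.is_case, params)
    sigs = [
        evaluate_combination([space.feature_state(i) for i in combo], gm)
        for combo in raw.combos
    ]
    sigs.sort(
        key=lambda s: (
            s.p_value,
            -s.odds_ratio,
            s.order,
            tuple((st.snp_id, st.genotype) for st in s.states),
        )
    )
    return sigs


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def signatures_to_tsv(signatures: list[Signature], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "states\torder\tcase_carriers\tcase_noncarriers\tcontrol_carriers"
            "\tcontrol_noncarriers\todds_ratio\tp_value\tcase_prevalence\n"
        )
        for s in signatures:
            t = s.table
            fh.write(
                ";".join(str(st) for st in s.states)
                + f"\t{s.order}\t{t.case_carriers}\t{t.case_noncarriers}"
                f"\t{t.control_carriers}\t{t.control_noncarriers}"
                f"\t{s.odds_ratio:.17g}\t{s.p_value:.17g}\t{s.case_prevalence:.17g}\n"
            )


def signatures_to_json(signatures: list[Signature]) -> list[dict]:
    return [
        {
            "states": [{"snp_id": st.snp_id, "genotype": st.genotype} for st in s.states],
            "case_carriers": s.table.case_carriers,
            "control_carriers": s.table.control_carriers,
            "odds_ratio": s.odds_ratio,
            "p_value": s.p_value,
            "case_prevalence": s.case_prevalence,
            "case_ids": sorted(map(str, s.case_ids)),
            "control_ids": sorted(map(str, s.control_ids)),
        }
        for s in signatures
    ]
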