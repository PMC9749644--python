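"""Disease architecture: clustering validated signatures into communities.

The architecture graph has one node per disease-associated feature state
(a SNP genotype); two states are connected when they co-occur in at least
one validated signature, so every signature induces a clique.  Edge weights
are the Jaccard similarity of the two states' case sets (union of the case
carriers of the validated signatures containing each state).  Seeded
modularity clustering of this graph yields *communities* — patient
subgroups with shared genetic drivers — whose pooled case sets give
per-community odds ratios, Fisher p-values and overlap statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .io import GenotypeMatrix
from .mining import FeatureState, Signature
from .stats import ContingencyTable2x2, fisher_exact_p, odds_ratio

__all__ = [
    "Community",
    "build_architecture",
    "detect_communities",
    "community_stats",
    "overlap_matrix",
    "cases_represented",
]


@dataclass
class Community:
    id: int
    states: tuple[FeatureState, ...]
    signatures: tuple[Signature, ...]
    case_set: frozenset = frozenset()
    control_set: frozenset = frozenset()
    odds_ratio: float = float("nan")
    p_value: float = float("nan")
    n_cases_represented: int = 0


def build_architecture(validated: list[Signature]) -> nx.Graph:
    """Feature-state co-occurrence graph over the validated signatures."""
    if not validated:
        raise ValueError("no validated signatures to build an architecture from")
    case_sets: dict[FeatureState, set] = {}
    for sig in validated:
        for st in sig.states:
            case_sets.setdefault(st, set()).update(sig.case_ids)
    g = nx.Graph()
    for st, cases in case_sets.items():
        g.add_node(st, case_set=frozenset(cases))
    for sig in validated:
        states = sorted(sig.states)
        for i in range(len(states)):
            for j in range(i + 1, len(states)):
                u, v = states[i], states[j]
                cu, cv = case_sets[u], case_sets[v]
                union = len(cu | cv)
                w = len(cu & cv) / union if union else 0.0
                g.add_edge(u, v, weight=w)
    g.graph["signatures"] = tuple(validated)
    return g


def detect_communities(
    graph: nx.Graph, method: str = "modularity", seed: int = 0
) -> list[Community]:
    """Partition the architecture graph into communities.

    ``modularity`` runs seeded Louvain modularity maximisation (resolution
    1.0); ``components`` uses connected components.  Communities are
    relabelled canonically by descending pooled case count (ties by state
    ids), so node insertion order cannot change the output ids.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty architecture graph")
    if method == "modularity":
        parts = nx.community.louvain_communities(
            graph, weight="weight", resolution=1.0, seed=seed
        )
    elif method == "components":
        parts = list(nx.connected_components(graph))
    else:
        raise ValueError(f"unknown community method: {method}")
    signatures: tuple[Signature, ...] = graph.graph.get("signatures", ())
    comms = []
    for nodes in parts:
        nodes = tuple(sorted(nodes))
        member_sigs = tuple(
            s for s in signatures if any(st in nodes for st in s.states)
        )
        case_set = frozenset().union(*(s.case_ids for s in member_sigs)) if member_sigs else frozenset()
        comms.append((nodes, member_sigs, case_set))
    comms.sort(key=lambda t: (-len(t[2]), t[0]))
    return [
        Community(id=i + 1, states=nodes, signatures=sigs, case_set=cases)
        for i, (nodes, sigs, cases) in enumerate(comms)
    ]


def community_stats(community: Community, gm: GenotypeMatrix) -> Community:
    """Fill carrier statistics: a sample is a community carrier iff it
    carries at least one member signature."""
    if not community.signatures:
        raise ValueError("community has no member signatures")
    case_set = frozenset().union(*(s.case_ids for s in community.signatures))
    control_set = frozenset().union(*(s.control_ids for s in community.signatures))
    a, c = len(case_set), len(control_set)
    table = ContingencyTable2x2(a, gm.n_cases - a, c, gm.n_controls - c)
    community.case_set = case_set
    community.control_set = control_set
    community.odds_ratio = odds_ratio(table)
    community.p_value = fisher_exact_p(table)
    community.n_cases_represented = a
    return community


def overlap_matrix(communities: list[Community]) -> np.ndarray:
    """Pairwise case-set overlap fractions, smaller community as the
    denominator; symmetric with unit diagonal."""
    if len(communities) < 2:
        raise ValueError("need at least two communities")
    k = len(communities)
    m = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            ci, cj = communities[i].case_set, communities[j].case_set
            denom = min(len(ci), len(cj))
            m[i, j] = m[j, i] = len(ci & cj) / denom if denom else 0.0
    return m


def cases_represented(validated: list[Signature], gm: GenotypeMatrix) -> float:
    """Fraction of all cases carrying at least one validated signature."""
    if not validated:
        return 0.0
    union = frozenset().union(*(s.case_ids for s in validated))
    return len(union) / gm.n_cases
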