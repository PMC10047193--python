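"""Hub-protein consensus from three local topological centralities.

The scored PPI edge list is first filtered to highest-confidence
interactions (score strictly greater than 0.9). On the filtered simple
graph three local centralities are computed per node v:

    Degree  — number of distinct neighbours.
    MNC     — maximum neighborhood component: the node count of the
              largest connected component of the subgraph induced by the
              open neighborhood N(v) (v itself excluded).
    MCC     — maximal clique centrality: the sum of (|C| - 1)! over the
              maximal cliques C of size >= 2 that contain v. When no two
              neighbours of v are adjacent this collapses to Degree(v).

Nodes scoring at or above the threshold (default 2) in a method form
that method's selected set; the consensus hubs are the intersection of
the three sets. Maximal cliques come from exact Bron-Kerbosch
enumeration with pivoting (networkx ``find_cliques``), guarded by a
configurable clique-count limit. A rank-based selection mode (top-k per
method) is available as an alternative to the raw-score threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import factorial

import networkx as nx

from .datamodel import PpiNetwork


@dataclass
class HubScoreTable:
    """Per-node centrality scores and the selected / consensus sets."""

    degree: dict[str, int]
    mnc: dict[str, int]
    mcc: dict[str, int]
    selected: dict[str, list[str]] = field(default_factory=dict)
    consensus: list[str] = field(default_factory=list)


def filter_edges(network: PpiNetwork, min_score: float = 0.9) -> PpiNetwork:
    """Keep edges with score strictly above ``min_score``; all nodes stay."""
    out = PpiNetwork()
    out.graph.add_nodes_from(network.graph.nodes)
    for a, b, score in network.edges:
        if score > min_score:
            out.add_edge(a, b, score)
    return out


def degree_centrality(network: PpiNetwork) -> dict[str, int]:
    """Number of distinct neighbours per node."""
    return {v: int(d) for v, d in network.graph.degree()}


def mnc_centrality(network: PpiNetwork) -> dict[str, int]:
    """Size of the largest connected component of each open neighborhood."""
    g = network.graph
    out: dict[str, int] = {}
    for v in g.nodes:
        nbrs = list(g.neighbors(v))
        if not nbrs:
            out[v] = 0
            continue
        sub = g.subgraph(nbrs)
        out[v] = max(len(c) for c in nx.connected_components(sub))
    return out


def mcc_centrality(network: PpiNetwork, max_cliques: int = 10**6) -> dict[str, int]:
    """Sum of (|C| - 1)! over maximal cliques C containing each node.

    Exact enumeration (Bron-Kerbosch with pivoting). Singleton cliques
    are excluded, so isolated nodes score 0. Aborts if the graph yields
    more than ``max_cliques`` maximal cliques.
    """
    g = network.graph
    out: dict[str, int] = {v: 0 for v in g.nodes}
    for n_seen, clique in enumerate(nx.find_cliques(g), start=1):
        if n_seen > max_cliques:
            raise RuntimeError(
                f"more than {max_cliques} maximal cliques; raise max_cliques "
                "to force enumeration"
            )
        if len(clique) < 2:
            continue
        w = factorial(len(clique) - 1)
        for v in clique:
            out[v] += w
    return out


def consensus_hubs(
    scores: HubScoreTable,
    threshold: float = 2,
    mode: str = "score",
    top_k: int = 10,
) -> HubScoreTable:
    """Select hubs per method and intersect.

    ``mode="score"`` (default): a node is selected by a method when its
    raw centrality score is >= ``threshold``. ``mode="rank"``: each
    method selects its ``top_k`` highest-scoring nodes (ties broken by
    node id). Selected sets are ordered by (score desc, node asc); the
    consensus is their intersection in the same order as the degree
    list.
    """
    if mode not in ("score", "rank"):
        raise ValueError(f"unknown mode {mode!r}")
    for method, m in (("degree", scores.degree), ("mnc", scores.mnc), ("mcc", scores.mcc)):
        if set(m) != set(scores.degree):
            raise ValueError(f"score map {method!r} covers a different node set")

    def select(m: dict[str, int]) -> list[str]:
        ordered = sorted(m, key=lambda v: (-m[v], v))
        if mode == "score":
            return [v for v in ordered if m[v] >= threshold]
        return ordered[:top_k]

    selected = {
        "degree": select(scores.degree),
        "mnc": select(scores.mnc),
        "mcc": select(scores.mcc),
    }
    common = set(selected["degree"]) & set(selected["mnc"]) & set(selected["mcc"])
    consensus = [v for v in selected["degree"] if v in common]
    return HubScoreTable(
        degree=scores.degree,
        mnc=scores.mnc,
        mcc=scores.mcc,
        selected=selected,
        consensus=consensus,
    )


def consensus_from_sets(
    degree_set: list[str], mcc_set: list[str], mnc_set: list[str]
) -> list[str]:
    """Intersection of three externally ranked hub lists, sorted by id.

    For consensus over per-method selections produced elsewhere (e.g.
    exported ranked tables) rather than recomputed centralities.
    """
    common = set(degree_set) & set(mcc_set) & set(mnc_set)
    return sorted(common)


def score_hubs(
    network: PpiNetwork,
    min_score: float = 0.9,
    threshold: float = 2,
    mode: str = "score",
    top_k: int = 10,
    max_cliques: int = 10**6,
) -> HubScoreTable:
    """Filter edges, compute the three centralities and take the consensus."""
    filtered = filter_edges(network, min_score=min_score)
    table = HubScoreTable(
        degree=degree_centrality(filtered),
        mnc=mnc_centrality(filtered),
        mcc=mcc_centrality(filtered, max_cliques=max_cliques),
    )
    return consensus_hubs(table, threshold=threshold, mode=mode, top_k=top_k)
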