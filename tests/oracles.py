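"""Independent brute-force oracles used by the tests.

Deliberately naive implementations — subset enumeration, BFS, direct
rule transcription — kept free of the package's own graph and
filtering code so they can stand as independent references.
"""

from __future__ import annotations

from itertools import combinations
from math import factorial


def brute_degree(nodes: list[str], edges: set[frozenset[str]]) -> dict[str, int]:
    return {v: sum(1 for e in edges if v in e) for v in nodes}


def _neighbors(v: str, edges: set[frozenset[str]]) -> set[str]:
    return {next(iter(e - {v})) for e in edges if v in e}


def brute_mnc(nodes: list[str], edges: set[frozenset[str]]) -> dict[str, int]:
    """Largest connected component of each open neighborhood, by BFS."""
    out = {}
    for v in nodes:
        nbrs = _neighbors(v, edges)
        best = 0
        unvisited = set(nbrs)
        while unvisited:
            comp = {unvisited.pop()}
            frontier = set(comp)
            while frontier:
                nxt = {
                    u
                    for w in frontier
                    for u in _neighbors(w, edges)
                    if u in unvisited
                }
                unvisited -= nxt
                comp |= nxt
                frontier = nxt
            best = max(best, len(comp))
        out[v] = best
    return out


def brute_mcc(nodes: list[str], edges: set[frozenset[str]]) -> dict[str, int]:
    """MCC by testing every node subset of size >= 2 for maximal cliqueness."""

    def is_clique(subset: tuple[str, ...]) -> bool:
        return all(frozenset(p) in edges for p in combinations(subset, 2))

    out = {v: 0 for v in nodes}
    node_list = sorted(nodes)
    for size in range(2, len(node_list) + 1):
        for subset in combinations(node_list, size):
            if not is_clique(subset):
                continue
            sset = set(subset)
            maximal = not any(
                is_clique(tuple(sset | {w})) for w in node_list if w not in sset
            )
            if maximal:
                for v in subset:
                    out[v] += factorial(size - 1)
    return out


def missingness_keep(
    na_control: int,
    na_case: int,
    group_size: int = 6,
    min_present_per_group: int = 4,
    max_total_na: int = 3,
) -> bool:
    """Direct transcription of the NA-filter rule for one protein."""
    present_control = group_size - na_control
    present_case = group_size - na_case
    return (
        present_control >= min_present_per_group
        and present_case >= min_present_per_group
        and na_control + na_case <= max_total_na
    )
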