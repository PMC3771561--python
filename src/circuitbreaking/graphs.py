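"""SCC condensation, elementary circuits and minimal circuit covers.

These are the purely topological steps of the circuit-breaking algorithm:
partition the interaction graph into strongly connected components ordered
hierarchically, enumerate each component's elementary circuits (Johnson's
algorithm via networkx, self-loops count as length-1 circuits), and find a
minimum-cardinality set of vertices hitting every circuit.  Removing all
in-edges of that set renders the component acyclic, which is what makes the
one-dimensional characteristic constructible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

from .errors import CBAError
from .model import InteractionGraph

Circuit = tuple[int, ...]


@dataclass(frozen=True)
class SCCDecomposition:
    """Strongly connected components in hierarchical (topological) order."""

    components: tuple[tuple[int, ...], ...]
    condensation_edges: tuple[tuple[int, int], ...]

    @property
    def order(self) -> tuple[int, ...]:
        return tuple(range(len(self.components)))

    def component_of(self, vertex: int) -> int:
        for k, comp in enumerate(self.components):
            if vertex in comp:
                return k
        raise KeyError(vertex)


@dataclass(frozen=True)
class CircuitCover:
    """Elementary circuit set and a minimal circuit-covering vertex set.

    ``cover`` is ordered ``(v_1, ..., v_m)``; circuits are re-closed starting
    from ``v_m`` (``release_order``) and ``v_1`` is the leading vertex whose
    axis carries the characteristic.  ``exact`` is False when the cover came
    from the greedy fallback and may be non-minimal; ``truncated`` marks a
    capped circuit enumeration.
    """

    circuits: tuple[Circuit, ...]
    cover: tuple[int, ...]
    complement: tuple[int, ...]
    truncated: bool = False
    exact: bool = True

    @property
    def release_order(self) -> tuple[int, ...]:
        return tuple(reversed(self.cover))

    @property
    def is_lvg(self) -> bool:
        return len(self.cover) == 1

    @property
    def leading_vertex(self) -> int | None:
        return self.cover[0] if self.cover else None

    def hits_all(self) -> bool:
        cs = set(self.cover)
        return all(cs & set(c) for c in self.circuits)


def scc_decompose(graph: InteractionGraph) -> SCCDecomposition:
    """CBA step 1: maximal SCCs, numbered along the condensation hierarchy.

    Ties in the topological order are broken by the smallest member vertex,
    so the numbering is deterministic.
    """
    g = graph.to_networkx()
    if g.number_of_nodes() == 0:
        raise CBAError("empty graph")
    cond = nx.condensation(g)
    members = {k: tuple(sorted(cond.nodes[k]["members"])) for k in cond.nodes}
    order = list(
        nx.lexicographical_topological_sort(cond, key=lambda k: min(members[k]))
    )
    relabel = {old: new for new, old in enumerate(order)}
    components = tuple(members[k] for k in order)
    cedges = tuple(sorted((relabel[a], relabel[b]) for a, b in cond.edges))
    return SCCDecomposition(components=components, condensation_edges=cedges)


def _canonical(cycle: Sequence[int]) -> Circuit:
    """Rotate a vertex-simple cycle so that its smallest vertex comes first."""
    cyc = list(cycle)
    k = cyc.index(min(cyc))
    return tuple(cyc[k:] + cyc[:k])


def enumerate_elementary_circuits(
    graph: InteractionGraph, cap: int = 10_000
) -> tuple[tuple[Circuit, ...], bool]:
    """CBA step 2(a): all elementary circuits, canonically rotated and sorted.

    Returns ``(circuits, truncated)``; when more than ``cap`` circuits exist
    only the first ``cap`` found are returned and ``truncated`` is True.
    """
    if cap < 1:
        raise CBAError("circuit cap must be >= 1")
    g = graph.to_networkx()
    out: list[Circuit] = []
    truncated = False
    for cyc in nx.simple_cycles(g):
        out.append(_canonical(cyc))
        if len(out) > cap:
            out.pop()
            truncated = True
            break
    out.sort(key=lambda c: (len(c), c))
    return tuple(out), truncated


def _exact_min_cover(circuits: Sequence[Circuit], candidates: Sequence[int]) -> list[int]:
    """Branch-and-bound minimum hitting set over the candidate vertices."""
    circ_sets = [frozenset(c) for c in circuits]
    best: list[list[int]] = [list(candidates)]  # trivial hitting set

    def rec(chosen: list[int], remaining: list[frozenset]) -> None:
        if len(chosen) >= len(best[0]):
            return
        if not remaining:
            best[0] = sorted(chosen)
            return
        # branch on the smallest uncovered circuit
        pivot = min(remaining, key=len)
        for v in sorted(pivot):
            nxt = [c for c in remaining if v not in c]
            rec(chosen + [v], nxt)

    rec([], circ_sets)
    return best[0]


def _greedy_cover(circuits: Sequence[Circuit]) -> list[int]:
    remaining = [set(c) for c in circuits]
    cover: list[int] = []
    while remaining:
        counts: dict[int, int] = {}
        for c in remaining:
            for v in c:
                counts[v] = counts.get(v, 0) + 1
        v = max(counts, key=lambda u: (counts[u], -u))
        cover.append(v)
        remaining = [c for c in remaining if v not in c]
    return cover


def minimal_circuit_cover(
    circuits: Sequence[Circuit],
    vertices: Iterable[int],
    exhaustive_cap: int = 20,
    truncated: bool = False,
) -> CircuitCover:
    """CBA step 2(b): minimum-cardinality circuit-covering vertex set.

    Exact branch-and-bound when at most ``exhaustive_cap`` distinct vertices
    appear in circuits, otherwise a greedy max-coverage fallback flagged via
    ``exact=False``.  Among equal-size covers, vertices contained in the most
    circuits are preferred, ties broken by smallest index; the same rule
    orders the cover, so ``v_1`` (the leading vertex) is the most-shared
    vertex.
    """
    verts = tuple(sorted(set(vertices)))
    circuits = tuple(circuits)
    if not circuits:
        return CircuitCover(circuits=(), cover=(), complement=verts, truncated=truncated)
    candidates = sorted({v for c in circuits for v in c})
    counts = {v: sum(v in c for c in circuits) for v in candidates}
    exact = len(candidates) <= exhaustive_cap
    if exact:
        base = _exact_min_cover(circuits, candidates)
        m = len(base)
        # pick the best minimum cover under the tie-break rule
        import itertools

        best = None
        best_key = None
        if len(candidates) <= 16:
            pool = itertools.combinations(candidates, m)
        else:
            pool = [tuple(base)]
        for combo in pool:
            cs = set(combo)
            if all(cs & set(c) for c in circuits):
                key = (sorted((-counts[v] for v in combo)), sorted(combo))
                if best_key is None or key < best_key:
                    best, best_key = combo, key
        cover = list(best)
    else:
        cover = _greedy_cover(circuits)
    cover.sort(key=lambda v: (-counts[v], v))
    complement = tuple(v for v in verts if v not in set(cover))
    return CircuitCover(
        circuits=circuits,
        cover=tuple(cover),
        complement=complement,
        truncated=truncated,
        exact=exact and not truncated,
    )


def cover_for_subgraph(
    graph: InteractionGraph,
    vertices: Iterable[int],
    circuit_cap: int = 10_000,
    exhaustive_cap: int = 20,
) -> CircuitCover:
    """Circuits and minimal cover of one SCC subgraph."""
    vs = tuple(sorted(vertices))
    sub = graph.subgraph(vs)
    circuits, truncated = enumerate_elementary_circuits(sub, cap=circuit_cap)
    return minimal_circuit_cover(circuits, vs, exhaustive_cap=exhaustive_cap, truncated=truncated)


def is_leading_vertex_graph(cover: CircuitCover) -> tuple[bool, int | None]:
    """True iff the minimal cover is a single vertex; returns it when so."""
    if cover.is_lvg:
        return True, cover.cover[0]
    return False, None
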