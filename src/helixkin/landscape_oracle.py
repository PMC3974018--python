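"""Exact reference computations on fully enumerated folding landscapes.

For sequences short enough to enumerate exhaustively, the landscape graph
(structures as nodes, the modified single-pair move set as edges) fits in
memory and exact saddle heights between any two structures can be computed
by a minimax best-first sweep.  These serve as the ground truth that the
heuristic pathway estimates are tested against.
"""

from __future__ import annotations

import heapq
from typing import Optional

import networkx as nx

from .energy_model import EnergyParameters, default_parameters
from .structures import (
    RnaSequence,
    SecondaryStructure,
    enumerate_structures,
    neighbors,
)

__all__ = ["UnreachableError", "build_landscape", "exact_barrier", "exact_saddle"]

DEFAULT_EXHAUSTIVE_LIMIT = 30


class UnreachableError(RuntimeError):
    """Raised when no path connects the two structures in the landscape."""


def build_landscape(
    seq: RnaSequence,
    params: Optional[EnergyParameters] = None,
    limit: int = DEFAULT_EXHAUSTIVE_LIMIT,
) -> nx.Graph:
    """The full landscape graph of ``seq``.

    Nodes are dot-bracket strings with ``energy`` and ``structure``
    attributes; edges are modified-neighbourhood moves.  The neighbourhood
    is symmetric, so the graph is undirected.
    """
    if params is None:
        params = default_parameters()
    graph = nx.Graph()
    space = enumerate_structures(seq, params, limit=limit)
    for s, energy in space:
        graph.add_node(s.dotbracket(), structure=s, energy=energy)
    for s, _ in space:
        db = s.dotbracket()
        for other in neighbors(seq, s):
            other_db = other.dotbracket()
            if other_db in graph:
                graph.add_edge(db, other_db)
    return graph


def exact_saddle(
    graph: nx.Graph, source: str, target: str
) -> tuple[float, list[str]]:
    """Minimal over all paths of the maximum node energy, with a witness.

    Ties between frontier states are broken by dot-bracket order so the
    witness path is deterministic.
    """
    if source not in graph or target not in graph:
        raise UnreachableError("source or target not in landscape")
    energy = {node: graph.nodes[node]["energy"] for node in graph}
    best: dict[str, float] = {source: energy[source]}
    parent: dict[str, Optional[str]] = {source: None}
    done: set[str] = set()
    heap = [(energy[source], source)]
    while heap:
        level, node = heapq.heappop(heap)
        if node in done:
            continue
        done.add(node)
        if node == target:
            path = [node]
            while parent[path[-1]] is not None:
                path.append(parent[path[-1]])
            return level, path[::-1]
        for other in sorted(graph.neighbors(node)):
            new_level = max(level, energy[other])
            if new_level < best.get(other, float("inf")):
                best[other] = new_level
                parent[other] = node
                heapq.heappush(heap, (new_level, other))
    raise UnreachableError(f"no landscape path from {source} to {target}")


def exact_barrier(
    seq: RnaSequence,
    start: SecondaryStructure,
    target: SecondaryStructure,
    params: Optional[EnergyParameters] = None,
    limit: int = DEFAULT_EXHAUSTIVE_LIMIT,
) -> float:
    """Exact energy barrier from ``start`` to ``target`` (kcal/mol).

    Defined as the minimal over all landscape paths of the maximum energy
    along the path, minus the energy of ``start``.  ``barrier(S, S) = 0``
    and ``barrier >= max(0, dG(T) - dG(S))`` always hold.
    """
    if params is None:
        params = default_parameters()
    graph = build_landscape(seq, params, limit=limit)
    source, sink = start.dotbracket(), target.dotbracket()
    saddle, _ = exact_saddle(graph, source, sink)
    return saddle - graph.nodes[source]["energy"]
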