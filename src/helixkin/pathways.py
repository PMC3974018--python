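"""Heuristic folding pathways and energy-barrier estimation.

Computing the globally optimal refolding path between two secondary
structures is NP-hard, so barriers are estimated in two stages:

1. *Direct paths*: a width-``k`` breadth-first beam search over paths whose
   intermediates only use base pairs present in the start or the target
   structure.  At each level the ``k`` lowest-saddle partial paths are
   kept.
2. *Anchored search*: the hairpin-level hishape classes that are "fuzzy
   related" to start and target (all their hairpin helix indices within a
   threshold ``theta`` of some start/target index) contribute their
   hishreps as anchor nodes.  Direct-path saddles between all node pairs
   fill a symmetric matrix, and a minimax variant of Dijkstra's algorithm
   (minimise the *maximum* edge weight instead of the sum) finds the route
   whose worst saddle is lowest.  The winning segments are stitched into a
   single folding path.

All saddles are absolute energies (kcal/mol); a path's *barrier* is its
saddle minus the start structure's energy.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass
from typing import Hashable, Iterable, Optional, Sequence

from .energy_model import EnergyParameters, default_parameters, structure_energy
from .hishape import (
    Hishape,
    HishapeClass,
    PI_H,
    classify,
    extract_hairpin_indices,
    map_structure,
)
from .landscape_oracle import UnreachableError, exact_saddle
from .structures import (
    RnaSequence,
    SecondaryStructure,
    neighbors,
)

import networkx as nx

__all__ = [
    "PathwayParameters",
    "FoldingPath",
    "auto_k",
    "fuzzy_related_hishapes",
    "direct_path_bfs",
    "minimax_dijkstra",
    "hipath2",
]


@dataclass(frozen=True)
class PathwayParameters:
    """Tunables of the pathway heuristics.

    ``candidate_count=None`` means auto-adjust via :func:`auto_k`.
    """

    bfs_width: int = 10
    fuzzy_threshold: float = 1.0
    candidate_count: Optional[int] = None
    strictly_negative: bool = False

    def __post_init__(self) -> None:
        if self.bfs_width < 1:
            raise ValueError("bfs_width must be >= 1")
        if self.fuzzy_threshold < 0:
            raise ValueError("fuzzy_threshold must be >= 0")
        if self.candidate_count is not None and self.candidate_count < 0:
            raise ValueError("candidate_count must be >= 0")


@dataclass(frozen=True)
class FoldingPath:
    """A chain of neighbouring structures from start to target."""

    steps: tuple[SecondaryStructure, ...]
    energies: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.steps) != len(self.energies) or not self.steps:
            raise ValueError("steps and energies must be non-empty and aligned")

    @property
    def saddle(self) -> float:
        """Maximum energy along the path (kcal/mol, absolute)."""
        return max(self.energies)

    @property
    def barrier(self) -> float:
        """Saddle height relative to the start structure's energy."""
        return self.saddle - self.energies[0]

    def reversed(self) -> "FoldingPath":
        return FoldingPath(self.steps[::-1], self.energies[::-1])

    def __len__(self) -> int:
        return len(self.steps)


def auto_k(n: int) -> int:
    """Auto-adjusted anchor count for sequence length ``n`` (nt).

    Evaluates ``124000 * n**(-3/2)``, rounded to the nearest integer with a
    floor of 1.  The constant reflects the exponential-growth prefactor of
    abstract-shape spaces; shorter sequences afford more anchors.
    """
    if n < 1:
        raise ValueError("sequence length must be >= 1")
    return max(1, round(124_000 * n ** (-1.5)))


def fuzzy_related_hishapes(
    alpha: Hishape,
    beta: Hishape,
    theta: float,
    universe: Iterable[Hishape],
) -> list[Hishape]:
    """Hishapes whose hairpin indices all lie within ``theta`` of start/target.

    A candidate ``gamma`` qualifies iff

        max over t in phi(gamma) of  min over z in phi(alpha) | phi(beta)
            of |t - z|   <=  theta

    where ``phi`` extracts hairpin helix indices.  The maximum over the
    empty set is treated as 0, so the open chain always qualifies.  With
    ``theta = 0`` this reduces to exact related hishapes (indices drawn
    from the start/target index pool only).
    """
    pool = extract_hairpin_indices(alpha) | extract_hairpin_indices(beta)
    selected = []
    for gamma in universe:
        values = extract_hairpin_indices(gamma)
        if not values:
            selected.append(gamma)
            continue
        if not pool:
            continue
        worst = max(min(abs(t - z) for z in pool) for t in values)
        if worst <= theta:
            selected.append(gamma)
    return selected


# ---------------------------------------------------------------------------
# direct-path beam search
# ---------------------------------------------------------------------------

def _restricted_moves(
    seq: RnaSequence,
    current: SecondaryStructure,
    allowed_pairs: frozenset,
    target_pairs: frozenset,
) -> list[SecondaryStructure]:
    """Neighbourhood moves that stay within ``allowed_pairs`` and strictly
    reduce the symmetric difference to the target."""
    delta = len(frozenset(current.pairs) ^ target_pairs)
    out = []
    for cand in neighbors(seq, current):
        cand_pairs = frozenset(cand.pairs)
        if not cand_pairs <= allowed_pairs:
            continue
        if len(cand_pairs ^ target_pairs) < delta:
            out.append(cand)
    return out


def _restricted_graph(
    seq: RnaSequence,
    start: SecondaryStructure,
    allowed_pairs: frozenset,
    params: EnergyParameters,
) -> nx.Graph:
    """All structures reachable from ``start`` using only allowed pairs."""
    graph = nx.Graph()
    stack = [start]
    graph.add_node(
        start.dotbracket(),
        structure=start,
        energy=structure_energy(seq, start, params),
    )
    while stack:
        node = stack.pop()
        db = node.dotbracket()
        for cand in neighbors(seq, node):
            if not frozenset(cand.pairs) <= allowed_pairs:
                continue
            cdb = cand.dotbracket()
            if cdb not in graph:
                graph.add_node(
                    cdb, structure=cand, energy=structure_energy(seq, cand, params)
                )
                stack.append(cand)
            graph.add_edge(db, cdb)
    return graph


def direct_path_bfs(
    seq: RnaSequence,
    start: SecondaryStructure,
    target: SecondaryStructure,
    k: int = 10,
    params: Optional[EnergyParameters] = None,
) -> FoldingPath:
    """Width-``k`` breadth-first direct-path search from start to target.

    Intermediates use only base pairs present in start or target.  At each
    level the ``k`` partial paths with the lowest running maximum energy
    are kept (ties broken by dot-bracket string), so the returned saddle is
    an upper bound on the exact one and is non-increasing in ``k``.  In the
    rare case the beam dead-ends, the search falls back to an exact minimax
    sweep of the (small) direct-path state space.
    """
    if params is None:
        params = default_parameters()
    start.is_compatible(seq)
    target.is_compatible(seq)
    e_start = structure_energy(seq, start, params)
    if start == target:
        return FoldingPath((start,), (e_start,))

    allowed = frozenset(start.pairs) | frozenset(target.pairs)
    target_pairs = frozenset(target.pairs)

    # beam items: (running_max, tiebreak, steps, energies)
    beam = [(e_start, (start.dotbracket(),), (start,), (e_start,))]
    completed: list[tuple[float, tuple, tuple, tuple]] = []
    max_levels = len(frozenset(start.pairs) ^ target_pairs) + 1
    for _ in range(max_levels):
        expansions = []
        seen: dict[str, float] = {}
        for running, _tb, steps, energies in beam:
            for cand in _restricted_moves(seq, steps[-1], allowed, target_pairs):
                energy = structure_energy(seq, cand, params)
                new_running = max(running, energy)
                db = cand.dotbracket()
                item = (
                    new_running,
                    tuple(s.dotbracket() for s in steps) + (db,),
                    steps + (cand,),
                    energies + (energy,),
                )
                if cand == target:
                    completed.append(item)
                elif db not in seen or new_running < seen[db]:
                    seen[db] = new_running
                    expansions.append(item)
        if not expansions:
            break
        # deduplicate by end state, keep best running max, then beam-prune
        best_by_state: dict[str, tuple] = {}
        for item in sorted(expansions, key=lambda it: (it[0], it[1])):
            db = item[1][-1]
            if db not in best_by_state:
                best_by_state[db] = item
        beam = sorted(best_by_state.values(), key=lambda it: (it[0], it[1]))[:k]

    if completed:
        _, _, steps, energies = min(completed, key=lambda it: (it[0], it[1]))
        return FoldingPath(steps, energies)

    # fallback: exact minimax over the direct-path state space
    graph = _restricted_graph(seq, start, allowed, params)
    try:
        _, node_path = exact_saddle(graph, start.dotbracket(), target.dotbracket())
    except UnreachableError:
        raise UnreachableError(
            "target not reachable through direct-path intermediates"
        ) from None
    steps = tuple(graph.nodes[node]["structure"] for node in node_path)
    energies = tuple(graph.nodes[node]["energy"] for node in node_path)
    return FoldingPath(steps, energies)


# ---------------------------------------------------------------------------
# minimax (bottleneck) Dijkstra
# ---------------------------------------------------------------------------

def minimax_dijkstra(
    nodes: Sequence[Hashable],
    weights: dict,
    source: Hashable,
    target: Hashable,
) -> tuple[list, float]:
    """Bottleneck shortest path: minimise the maximum edge weight.

    ``weights`` maps node pairs (either orientation) to edge weights;
    missing pairs are absent edges.  Weights may be negative (absolute
    saddle heights are energies).  Returns the witness path and its
    bottleneck; for ``source == target`` the trivial path with bottleneck
    0.  Ties are broken by node order in ``nodes``.
    """
    order = {node: pos for pos, node in enumerate(nodes)}
    if source not in order or target not in order:
        raise UnreachableError("source or target not among nodes")
    if source == target:
        return [source], 0.0

    def weight(u, v):
        if (u, v) in weights:
            return weights[(u, v)]
        return weights.get((v, u))

    best = {source: -math.inf}
    parent = {source: None}
    done = set()
    heap = [(-math.inf, order[source], source)]
    while heap:
        level, _, node = heapq.heappop(heap)
        if node in done:
            continue
        done.add(node)
        if node == target:
            path = [node]
            while parent[path[-1]] is not None:
                path.append(parent[path[-1]])
            return path[::-1], level
        for other in nodes:
            if other is node or other in done:
                continue
            w = weight(node, other)
            if w is None:
                continue
            new_level = max(level, w)
            if new_level < best.get(other, math.inf):
                best[other] = new_level
                parent[other] = node
                heapq.heappush(heap, (new_level, order[other], other))
    raise UnreachableError(f"no path from {source!r} to {target!r}")


# ---------------------------------------------------------------------------
# anchored two-level search
# ---------------------------------------------------------------------------

def _segment(
    seq: RnaSequence,
    a: SecondaryStructure,
    b: SecondaryStructure,
    k: int,
    params: EnergyParameters,
    cache: Optional[dict] = None,
) -> FoldingPath:
    """Best-of-both-directions direct path between two structures."""
    key = (a.dotbracket(), b.dotbracket(), k)
    if cache is not None:
        hit = cache.get(key) or cache.get((key[1], key[0], k))
        if hit is not None:
            return hit if hit.steps[0] == a else hit.reversed()
    forward = direct_path_bfs(seq, a, b, k, params)
    backward = direct_path_bfs(seq, b, a, k, params)
    best = backward.reversed() if backward.saddle < forward.saddle else forward
    if cache is not None:
        cache[key] = best
    return best


def select_anchors(
    seq: RnaSequence,
    start: SecondaryStructure,
    target: SecondaryStructure,
    pathway_params: PathwayParameters,
    params: EnergyParameters,
    universe: Optional[list[HishapeClass]] = None,
) -> list[SecondaryStructure]:
    """The N lowest-energy fuzzy-related hishreps used as path anchors.

    Anchoring always works at the hairpin level (``PI_H``), regardless of
    the abstraction used elsewhere.
    """
    n_anchors = (
        pathway_params.candidate_count
        if pathway_params.candidate_count is not None
        else auto_k(len(seq))
    )
    if n_anchors <= 0:
        return []
    if universe is None:
        universe = classify(
            seq,
            PI_H,
            strictly_negative=pathway_params.strictly_negative,
            params=params,
        )
    alpha = map_structure(seq, start, PI_H)
    beta = map_structure(seq, target, PI_H)
    related_texts = {
        h.text
        for h in fuzzy_related_hishapes(
            alpha,
            beta,
            pathway_params.fuzzy_threshold,
            [c.hishape for c in universe],
        )
    }
    by_energy = sorted(
        (c for c in universe if c.hishape.text in related_texts),
        key=lambda c: (c.hishrep_energy, c.hishape.text),
    )
    anchors: list[SecondaryStructure] = []
    seen = {start.dotbracket(), target.dotbracket()}
    for cls in by_energy:
        db = cls.hishrep.dotbracket()
        if db not in seen:
            anchors.append(cls.hishrep)
            seen.add(db)
        if len(anchors) >= n_anchors:
            break
    return anchors


def hipath2(
    seq: RnaSequence,
    start: SecondaryStructure,
    target: SecondaryStructure,
    pathway_params: Optional[PathwayParameters] = None,
    params: Optional[EnergyParameters] = None,
    universe: Optional[list[HishapeClass]] = None,
    segment_cache: Optional[dict] = None,
) -> FoldingPath:
    """Anchored heuristic folding path from ``start`` to ``target``.

    The hairpin-level (``PI_H``) hishape classes fuzzy related to start and
    target contribute their hishreps as anchors; the ``N`` lowest-energy
    ones are kept (``N`` from :func:`auto_k` unless fixed in
    ``pathway_params``).  Direct-path saddles between all pairs of
    {start, target, anchors} weight a complete graph, and the minimax
    Dijkstra route's segments are stitched into the returned path.  The
    direct start-target edge is always in the graph, so the result is never
    worse than the plain direct path.

    ``universe`` may supply precomputed ``PI_H`` classes (e.g. from
    :func:`~helixkin.hishape.classify`) to avoid re-enumeration.
    """
    if pathway_params is None:
        pathway_params = PathwayParameters()
    if params is None:
        params = default_parameters()
    e_start = structure_energy(seq, start, params)
    if start == target:
        return FoldingPath((start,), (e_start,))

    anchors = select_anchors(seq, start, target, pathway_params, params, universe)
    node_list = [start, target] + anchors
    labels = [s.dotbracket() for s in node_list]
    segments: dict[tuple[str, str], FoldingPath] = {}
    weights: dict[tuple[str, str], float] = {}
    for i in range(len(node_list)):
        for j in range(i + 1, len(node_list)):
            seg = _segment(
                seq,
                node_list[i],
                node_list[j],
                pathway_params.bfs_width,
                params,
                cache=segment_cache,
            )
            segments[(labels[i], labels[j])] = seg
            weights[(labels[i], labels[j])] = seg.saddle

    route, _bottleneck = minimax_dijkstra(labels, weights, labels[0], labels[1])

    steps: list[SecondaryStructure] = []
    energies: list[float] = []
    for a, b in zip(route, route[1:]):
        seg = segments.get((a, b))
        if seg is None:
            seg = segments[(b, a)].reversed()
        offset = 1 if steps else 0  # drop duplicated junction structure
        steps.extend(seg.steps[offset:])
        energies.extend(seg.energies[offset:])
    return FoldingPath(tuple(steps), tuple(energies))
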