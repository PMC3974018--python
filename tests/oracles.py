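"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive and shares no code path with the
package implementation: plain recursion over intervals, exhaustive path
search, and a second-opinion loop-energy recursion.
"""

from __future__ import annotations

import functools
import math

from helixkin.structures import MIN_HAIRPIN_UNPAIRED, RnaSequence


def naive_structure_sets(seq: RnaSequence) -> list[frozenset]:
    """All noLP pair sets by generate-everything-then-filter.

    Generates every nested pair set (lonely pairs allowed, hairpins >= 3)
    by interval recursion, then keeps the sets in which every pair stacks
    on a neighbour.
    """
    n = len(seq)

    @functools.lru_cache(maxsize=None)
    def region(i: int, j: int) -> tuple[frozenset, ...]:
        if j - i < MIN_HAIRPIN_UNPAIRED + 1:
            return (frozenset(),)
        out = list(region(i + 1, j))
        for k in range(i + MIN_HAIRPIN_UNPAIRED + 1, j + 1):
            if seq.can_pair(i, k):
                for inner in region(i + 1, k - 1):
                    for rest in region(k + 1, j):
                        out.append(inner | rest | {(i, k)})
        return tuple(out)

    everything = region(1, n)
    region.cache_clear()

    def nolp(pairs: frozenset) -> bool:
        return all(
            (i + 1, j - 1) in pairs or (i - 1, j + 1) in pairs for i, j in pairs
        )

    return [pairs for pairs in everything if nolp(pairs)]


def recount_decomposition(n: int, pairs: frozenset) -> tuple[int, int]:
    """(paired positions, unpaired positions) by direct counting."""
    paired = {p for pair in pairs for p in pair}
    return len(paired), n - len(paired)


def recursive_energy(seq: RnaSequence, pairs: frozenset, params) -> float:
    """Loop-sum free energy by an independent recursion over the pair tree."""
    table = {}
    for i, j in pairs:
        table[i] = j
        table[j] = i

    def scan(lo: int, hi: int):
        branches, unpaired = [], 0
        k = lo
        while k <= hi:
            if k in table and table[k] > k:
                branches.append((k, table[k]))
                k = table[k] + 1
            else:
                if k not in table:
                    unpaired += 1
                k += 1
        return branches, unpaired

    def pair_str(p):
        return seq.residues[p[0] - 1] + seq.residues[p[1] - 1]

    def penalty(p):
        return params.terminal_au_penalty if pair_str(p) in {"AU", "UA", "GU", "UG"} else 0.0

    def init(kind, size):
        return params.loop_initiation(kind, size)

    def closed(i: int, j: int) -> float:
        branches, unpaired = scan(i + 1, j - 1)
        if not branches:
            return init("hairpin", unpaired) + penalty((i, j))
        if len(branches) == 1:
            (c, d) = branches[0]
            inner = closed(c, d)
            if c == i + 1 and d == j - 1:
                return params.stacking[(pair_str((i, j)), pair_str((c, d)))] + inner
            kind = "bulge" if (c == i + 1 or d == j - 1) else "internal"
            return init(kind, unpaired) + penalty((i, j)) + penalty((c, d)) + inner
        total = (
            params.multiloop_offset
            + params.multiloop_branch * (len(branches) + 1)
            + params.multiloop_unpaired * unpaired
            + penalty((i, j))
        )
        for branch in branches:
            total += penalty(branch) + closed(*branch)
        return total

    top, _ = scan(1, len(seq))
    return sum(closed(i, j) for i, j in top)


def brute_minimax_edges(nodes, weights, source, target) -> float:
    """Minimum over all simple paths of the maximum edge weight."""

    def weight(u, v):
        if (u, v) in weights:
            return weights[(u, v)]
        return weights.get((v, u))

    best = math.inf
    n = len(nodes)

    def extend(path, level):
        nonlocal best
        node = path[-1]
        if node == target:
            best = min(best, level)
            return
        for other in nodes:
            if other in path:
                continue
            w = weight(node, other)
            if w is None:
                continue
            extend(path + [other], max(level, w))

    extend([source], -math.inf)
    return best


def brute_saddle_nodes(graph, source, target) -> float:
    """Minimum over all simple paths of the maximum node energy."""
    energy = {node: graph.nodes[node]["energy"] for node in graph}
    best = math.inf
    seen = {source}

    def extend(node, level):
        nonlocal best
        level = max(level, energy[node])
        if level >= best:
            return  # cannot improve
        if node == target:
            best = level
            return
        for other in graph.neighbors(node):
            if other not in seen:
                seen.add(other)
                extend(other, level)
                seen.remove(other)

    extend(source, -math.inf)
    return best
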