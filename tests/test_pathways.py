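import math
import random

import pytest

from helixkin.hishape import PI_H, Hishape, HelixIndex, classify, map_structure
from helixkin.landscape_oracle import UnreachableError, exact_barrier
from helixkin.pathways import (
    FoldingPath,
    PathwayParameters,
    auto_k,
    direct_path_bfs,
    fuzzy_related_hishapes,
    hipath2,
    minimax_dijkstra,
)
from helixkin.structures import neighbors, open_chain, parse_dotbracket
from helixkin.fixtures import random_sequences

from oracles import brute_minimax_edges


def make_shape(*values):
    return Hishape(
        PI_H,
        "[" + ",".join(str(v) for v in values) + "]",
        tuple(HelixIndex(float(v)) for v in values),
    )


OPEN = Hishape(PI_H, "[_]", ())


def assert_valid_path(seq, path: FoldingPath):
    """A folding path must be a neighbour chain whose max energy is its saddle."""
    from helixkin.energy_model import structure_energy

    for a, b in zip(path.steps, path.steps[1:]):
        assert b in neighbors(seq, a), f"{a} -> {b} is not a single move"
    for s, e in zip(path.steps, path.energies):
        assert structure_energy(seq, s) == pytest.approx(e)
    assert path.saddle == pytest.approx(max(path.energies))
    assert path.barrier == pytest.approx(path.saddle - path.energies[0])


class TestAutoK:
    def test_exact_power_of_ten(self):
        assert auto_k(100) == 124

    def test_short_sequence_limit(self):
        assert auto_k(1) == 124000

    def test_long_sequence_rounds_to_nearest(self):
        # 124000 * 500**-1.5 = 11.09... -> 11
        assert auto_k(500) == 11

    def test_floor_of_one(self):
        assert auto_k(10**6) == 1


class TestFuzzyRelated:
    def test_within_threshold_included(self):
        selected = fuzzy_related_hishapes(
            make_shape(10), make_shape(20), 1.0, [make_shape(11)]
        )
        assert [s.text for s in selected] == ["[11]"]

    def test_outside_threshold_excluded(self):
        selected = fuzzy_related_hishapes(
            make_shape(10), make_shape(20), 1.0, [make_shape(15)]
        )
        assert selected == []

    def test_open_chain_always_qualifies(self):
        selected = fuzzy_related_hishapes(make_shape(10), make_shape(20), 0.0, [OPEN])
        assert selected == [OPEN]

    def test_all_indices_must_be_close(self):
        # one helix close to the pool, one far away: excluded
        selected = fuzzy_related_hishapes(
            make_shape(10), make_shape(20), 1.0, [make_shape(10.5, 40)]
        )
        assert selected == []

    def test_theta_zero_reduces_to_exact_related(self, small_random_seqs, params, enumerated):
        for seq in small_random_seqs[:3]:
            classes = classify(seq, PI_H, params=params)
            shapes = [c.hishape for c in classes]
            alpha, beta = shapes[0], shapes[-1]
            pool = set()
            for shape in (alpha, beta):
                pool |= {idx.value for idx in shape.indices}
            exact = fuzzy_related_hishapes(alpha, beta, 0.0, shapes)
            for gamma in shapes:
                values = {idx.value for idx in gamma.indices if idx.marker is None}
                expected = values <= pool
                assert (gamma in exact) == expected


class TestMinimaxDijkstra:
    def test_single_edge(self):
        path, bottleneck = minimax_dijkstra(["a", "b"], {("a", "b"): 4.0}, "a", "b")
        assert path == ["a", "b"] and bottleneck == 4.0

    def test_three_node_detour(self):
        weights = {("s", "x"): 5.0, ("x", "t"): 3.0, ("s", "t"): 6.0}
        path, bottleneck = minimax_dijkstra(["s", "t", "x"], weights, "s", "t")
        assert path == ["s", "x", "t"] and bottleneck == 5.0

    def test_disconnected_raises(self):
        with pytest.raises(UnreachableError):
            minimax_dijkstra(["a", "b", "c"], {("a", "b"): 1.0}, "a", "c")

    def test_matches_brute_force_on_random_graphs(self):
        rng = random.Random(4711)
        for _ in range(60):
            n = rng.randint(2, 8)
            nodes = list(range(n))
            weights = {}
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.6:
                        weights[(i, j)] = round(rng.uniform(-5, 10), 3)
            try:
                _, bottleneck = minimax_dijkstra(nodes, weights, 0, n - 1)
            except UnreachableError:
                assert brute_minimax_edges(nodes, weights, 0, n - 1) == math.inf
                continue
            assert bottleneck == pytest.approx(
                brute_minimax_edges(nodes, weights, 0, n - 1)
            )


class TestDirectPath:
    def test_identity(self, toy_hairpin, params):
        s = parse_dotbracket("((...))")
        path = direct_path_bfs(toy_hairpin, s, s, 10, params)
        assert len(path) == 1 and path.barrier == 0.0

    def test_two_step_instance_matches_oracle(self, toy_hairpin, params):
        start = open_chain(7)
        target = parse_dotbracket("((...))")
        path = direct_path_bfs(toy_hairpin, start, target, 10, params)
        assert_valid_path(toy_hairpin, path)
        assert path.steps[-1] == target
        assert path.barrier == pytest.approx(
            exact_barrier(toy_hairpin, start, target, params)
        )

    def test_width_ordering_and_exact_lower_bound(self, params):
        for seq in random_sequences(6, 22, gc=0.5, seed=55):
            start = open_chain(len(seq))
            from helixkin.structures import enumerate_structures

            target = enumerate_structures(seq, params)[0][0]
            if start == target:
                continue
            wide = direct_path_bfs(seq, start, target, 10, params)
            narrow = direct_path_bfs(seq, start, target, 1, params)
            exact = exact_barrier(seq, start, target, params)
            assert_valid_path(seq, wide)
            assert_valid_path(seq, narrow)
            assert wide.barrier <= narrow.barrier + 1e-12
            assert exact <= wide.barrier + 1e-12


class TestHiPath2:
    def test_identity(self, toy_hairpin, params):
        s = parse_dotbracket("((...))")
        path = hipath2(toy_hairpin, s, s, params=params)
        assert len(path) == 1 and path.barrier == 0.0

    def test_never_worse_than_direct(self, params):
        for seq in random_sequences(4, 22, gc=0.5, seed=77):
            from helixkin.structures import enumerate_structures

            start = open_chain(len(seq))
            target = enumerate_structures(seq, params)[0][0]
            if start == target:
                continue
            pw = PathwayParameters(bfs_width=10)
            anchored = hipath2(seq, start, target, pw, params)
            direct = direct_path_bfs(seq, start, target, 10, params)
            assert_valid_path(seq, anchored)
            assert anchored.barrier <= direct.barrier + 1e-12

    def test_sandwich_against_exact(self, params):
        for seq in random_sequences(5, 20, gc=0.5, seed=88):
            from helixkin.structures import enumerate_structures

            start = open_chain(len(seq))
            target = enumerate_structures(seq, params)[0][0]
            if start == target:
                continue
            exact = exact_barrier(seq, start, target, params)
            anchored = hipath2(seq, start, target, params=params)
            narrow = direct_path_bfs(seq, start, target, 1, params)
            assert exact <= anchored.barrier + 1e-12
            assert anchored.barrier <= narrow.barrier + 1e-12

    def test_anchors_satisfy_fuzzy_relation(self, bistable, params):
        # every selected anchor must map to a hishape satisfying the fuzzy
        # relation for the given theta
        from helixkin.pathways import select_anchors
        from helixkin.structures import enumerate_structures

        start = open_chain(len(bistable))
        target = enumerate_structures(bistable, params)[0][0]
        theta = 1.0
        classes = classify(bistable, PI_H, params=params)
        related = {
            h.text
            for h in fuzzy_related_hishapes(
                map_structure(bistable, start, PI_H),
                map_structure(bistable, target, PI_H),
                theta,
                [c.hishape for c in classes],
            )
        }
        pw = PathwayParameters(fuzzy_threshold=theta, candidate_count=5)
        anchors = select_anchors(bistable, start, target, pw, params)
        assert anchors, "expected at least one anchor on the bistable fixture"
        for anchor in anchors:
            assert map_structure(bistable, anchor, PI_H).text in related

    def test_zero_candidates_falls_back_to_direct(self, toy_hairpin, params):
        start = open_chain(7)
        target = parse_dotbracket("((...))")
        pw = PathwayParameters(candidate_count=0)
        path = hipath2(toy_hairpin, start, target, pw, params)
        direct = direct_path_bfs(toy_hairpin, start, target, 10, params)
        assert path.barrier == pytest.approx(direct.barrier)
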