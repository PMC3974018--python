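import math

import pytest

from helixkin.hishape import (
    PI_A,
    PI_H,
    PI_HPLUS,
    PI_M,
    AbstractionLevel,
    HelixIndex,
    classify,
    extract_hairpin_indices,
    is_strictly_negative,
    map_structure,
)
from helixkin.structures import (
    RnaSequence,
    open_chain,
    parse_dotbracket,
)

LEVELS = [PI_H, PI_HPLUS, PI_M, PI_A]


class TestHelixIndex:
    def test_marker_validation(self):
        with pytest.raises(ValueError):
            HelixIndex(2.0, "x")
        with pytest.raises(ValueError):
            HelixIndex(-1.0)

    def test_rendering(self):
        assert str(HelixIndex(4.0)) == "4"
        assert str(HelixIndex(7.5, "m")) == "7.5m"


class TestMapStructure:
    def test_open_chain_at_every_level(self):
        seq = RnaSequence("x", "ACGUACGUAC")
        for level in LEVELS:
            assert map_structure(seq, open_chain(10), level).text == "[_]"

    def test_single_hairpin_index_is_loop_centre(self, toy_hairpin):
        # innermost pair (2,6) -> central position (2+6)/2 = 4
        s = parse_dotbracket("((...))")
        for level in LEVELS:
            assert map_structure(toy_hairpin, s, level).text == "[4]"

    def test_multiloop_markers_and_nesting(self):
        seq = RnaSequence("x", "GGAAGGGAAACCCGGGAAACCCACC")
        s = parse_dotbracket("((..(((...)))(((...))).))")
        assert map_structure(seq, s, PI_H).text == "[9,18]"
        assert map_structure(seq, s, PI_HPLUS).text == "[(9,18)]"
        assert map_structure(seq, s, PI_M).text == "[13m(9,18)]"
        assert map_structure(seq, s, PI_A).text == "[13m(9,18)]"

    def test_bulge_helix_retained_only_at_pi_a(self):
        seq = RnaSequence("x", "GGAGGAAACCCC")
        s = parse_dotbracket("((.((...))))")
        assert map_structure(seq, s, PI_A).text == "[6.5b,7]"
        for level in (PI_H, PI_HPLUS, PI_M):
            assert map_structure(seq, s, level).text == "[7]"

    def test_internal_helix_marker(self):
        seq = RnaSequence("x", "GGAGGAAACCACC")
        s = parse_dotbracket("((.((...)).))")
        assert map_structure(seq, s, PI_A).text == "[7i,7]"

    def test_pi_a_distinguishes_differing_helix_sets(self, small_random_seqs, enumerated):
        # two structures with different helix (inner-pair) sets must have
        # different pi_a hishapes whenever their decorated indices differ
        for seq in small_random_seqs[:2]:
            by_shape = {}
            for s, _ in enumerated(seq):
                shape = map_structure(seq, s, PI_A)
                by_shape.setdefault(shape.text, []).append(s)
            for text, members in by_shape.items():
                signatures = {
                    tuple(
                        sorted((idx.value, idx.marker or "") for idx in
                               map_structure(seq, m, PI_A).indices)
                    )
                    for m in members
                }
                assert len(signatures) == 1


class TestAbstractionLevels:
    def test_aliases(self):
        assert AbstractionLevel.from_string("1") is PI_H
        assert AbstractionLevel.from_string("h+") is PI_HPLUS
        assert AbstractionLevel.from_string("4") is PI_A
        with pytest.raises(ValueError):
            AbstractionLevel.from_string("z")

    def test_class_counts_monotone_under_refinement(self, small_random_seqs, params):
        for seq in small_random_seqs:
            counts = [len(classify(seq, level, params=params)) for level in LEVELS]
            assert counts == sorted(counts)


class TestPhi:
    def test_plain_and_empty(self, toy_hairpin):
        helix = map_structure(toy_hairpin, parse_dotbracket("((...))"), PI_H)
        assert extract_hairpin_indices(helix) == {4}
        empty = map_structure(toy_hairpin, open_chain(7), PI_H)
        assert extract_hairpin_indices(empty) == frozenset()

    def test_marked_indices_excluded(self):
        seq = RnaSequence("x", "GGAAGGGAAACCCGGGAAACCCACC")
        shape = map_structure(seq, parse_dotbracket("((..(((...)))(((...))).))"), PI_A)
        assert extract_hairpin_indices(shape) == {9, 18}


class TestStrictlyNegative:
    def test_open_chain_vacuously_negative(self, params):
        seq = RnaSequence("x", "ACGUACG")
        assert is_strictly_negative(seq, open_chain(7), params)

    def test_positive_energy_helix_rejected(self, toy_hairpin, params):
        # the toy helix costs +2.1 kcal/mol under the bundled table
        assert not is_strictly_negative(
            toy_hairpin, parse_dotbracket("((...))"), params
        )

    def test_stable_helix_accepted(self, stable_hairpin, params):
        assert is_strictly_negative(
            stable_hairpin, parse_dotbracket("(((...)))"), params
        )

    def test_sn_space_is_subset(self, small_random_seqs, enumerated, params):
        for seq in small_random_seqs:
            full = {s.dotbracket() for s, _ in enumerated(seq)}
            sn = {
                s.dotbracket()
                for s, _ in enumerated(seq)
                if is_strictly_negative(seq, s, params)
            }
            assert sn <= full and "." * len(seq) in sn

    def test_sn_class_counts_never_exceed_full(self, small_random_seqs, params):
        for seq in small_random_seqs:
            for level in LEVELS:
                full = classify(seq, level, params=params)
                sn = classify(seq, level, strictly_negative=True, params=params)
                assert len(sn) <= len(full)


class TestClassify:
    def test_unpairable_sequence_single_class(self, params):
        classes = classify(RnaSequence("x", "AAAA"), PI_H, params=params)
        assert len(classes) == 1
        assert classes[0].hishape.text == "[_]"
        assert classes[0].probability == pytest.approx(1.0)

    def test_two_class_probability_ratio(self, toy_hairpin, params):
        classes = {c.hishape.text: c for c in classify(toy_hairpin, PI_H, params=params)}
        kT = params.kT
        expected_ratio = math.exp(-classes["[_]"].hishrep_energy / kT) / math.exp(
            -classes["[4]"].hishrep_energy / kT
        )
        ratio = classes["[_]"].probability / classes["[4]"].probability
        assert ratio == pytest.approx(expected_ratio, rel=1e-12)

    def test_partition_and_conservation(self, small_random_seqs, enumerated, params):
        for seq in small_random_seqs:
            space = enumerated(seq)
            total = sum(math.exp(-e / params.kT) for _, e in space)
            for level in LEVELS:
                classes = classify(seq, level, params=params)
                assert sum(c.members for c in classes) == len(space)
                z_sum = sum(c.partition_function for c in classes)
                assert abs(z_sum - total) / total < 1e-9
                assert sum(c.probability for c in classes) == pytest.approx(1.0)

    def test_hishrep_is_minimum_member(self, small_random_seqs, enumerated, params):
        for seq in small_random_seqs[:3]:
            space = enumerated(seq)
            for level in LEVELS:
                best_by_shape = {}
                for s, e in space:
                    text = map_structure(seq, s, level).text
                    key = (e, s.dotbracket())
                    if text not in best_by_shape or key < best_by_shape[text]:
                        best_by_shape[text] = key
                for cls in classify(seq, level, params=params):
                    energy, db = best_by_shape[cls.hishape.text]
                    assert cls.hishrep_energy == pytest.approx(energy)
                    assert cls.hishrep.dotbracket() == db

    def test_ensemble_energy_identity(self, toy_hairpin, params):
        for cls in classify(toy_hairpin, PI_H, params=params):
            assert cls.ensemble_energy == pytest.approx(
                -params.kT * math.log(cls.partition_function)
            )

    def test_k_best_truncates_after_probabilities(self, small_random_seqs, params):
        seq = small_random_seqs[0]
        full = classify(seq, PI_H, params=params)
        top = classify(seq, PI_H, k_best=2, params=params)
        assert top == full[:2]
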