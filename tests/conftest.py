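import pytest

from helixkin.energy_model import default_parameters
from helixkin.fixtures import bistable_sequence, random_sequences
from helixkin.structures import RnaSequence, enumerate_structures


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def toy_hairpin():
    """Shortest sequence with a (positive-energy) noLP helix."""
    return RnaSequence("toy", "GGAAACC")


@pytest.fixture(scope="session")
def stable_hairpin():
    """A hairpin whose helix has negative energy under the bundled table."""
    return RnaSequence("stable", "GGGAAACCC")


@pytest.fixture(scope="session")
def small_random_seqs():
    """A handful of 22-nt random sequences with enumerable folding spaces."""
    return random_sequences(5, 22, gc=0.5, seed=101)


@pytest.fixture(scope="session")
def bistable(params):
    return bistable_sequence(5, seed=0, params=params)


@pytest.fixture(scope="session")
def enumerated(params):
    """Shared cache of enumerated spaces keyed by sequence residues."""
    cache = {}

    def get(seq):
        if seq.residues not in cache:
            cache[seq.residues] = enumerate_structures(seq, params)
        return cache[seq.residues]

    return get
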