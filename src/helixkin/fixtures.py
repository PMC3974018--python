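"""Deterministic synthetic inputs: random sequences, designed bistable
switches, and growth-curve fitting for folding-space sizes.

All generators are seeded (numpy PCG64) so every fixture is reproducible
bit-exactly from its parameters; no downloads are required anywhere in the
package.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np

from .energy_model import EnergyParameters, default_parameters
from .hishape import PI_H, classify
from .structures import RnaSequence

__all__ = [
    "random_sequences",
    "bistable_sequence",
    "growth_curve_fit",
    "GENERATOR_ID",
]

#: Recorded in output so fixtures survive platform changes.
GENERATOR_ID = "numpy-PCG64"

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


def random_sequences(
    n_seqs: int,
    length: int,
    gc: float = 0.5,
    seed: int = 0,
) -> list[RnaSequence]:
    """``n_seqs`` reproducible random sequences of the given length.

    ``gc`` is the expected G+C fraction; G/C and A/U are drawn with equal
    probability within their class.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0 <= gc <= 1:
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    probs = [gc / 2, gc / 2, (1 - gc) / 2, (1 - gc) / 2]
    alphabet = np.array(list("GCAU"))
    return [
        RnaSequence(
            f"random_{length}nt_gc{gc:g}_seed{seed}_{i}",
            "".join(rng.choice(alphabet, size=length, p=probs)),
        )
        for i in range(n_seqs)
    ]


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def bistable_sequence(
    arm_length: int = 5,
    seed: int = 0,
    params: Optional[EnergyParameters] = None,
    max_tries: int = 400,
    energy_window: float = 1.0,
) -> RnaSequence:
    """A designed sequence with two mutually exclusive helices of
    near-equal energy whose kinetic and thermodynamic preferences oppose.

    The layout is ``arm - linker - revcomp(arm) - linker - arm``: the
    central segment can pair with either flank but not both, giving two
    competing hairpin conformations.  Candidates are drawn from the seeded
    generator until exhaustive enumeration confirms the bistable-switch
    phenotype:

    * at least two non-open-chain hairpin-level hishape classes, the two
      best of which have hishrep energies within ``energy_window``
      kcal/mol of each other (and the best below zero);
    * the class with the *higher* equilibrium probability has a *higher*
      exact folding barrier from the open chain than the runner-up (by at
      least 0.05 kcal/mol, with an equilibrium-probability gap of at least
      0.05), so the metastable conformation folds first and is later
      overtaken — the hallmark occupancy crossing of bistable switches.
    """
    if arm_length < 4:
        raise ValueError("arm_length must be >= 4")
    if params is None:
        params = default_parameters()
    from .landscape_oracle import exact_barrier
    from .structures import open_chain

    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACGU"))
    linker = "AAAA"
    for attempt in range(max_tries):
        arm = "".join(rng.choice(alphabet, size=arm_length))
        if arm.count("G") + arm.count("C") < arm_length // 2:
            continue  # too weak to form stable helices
        residues = arm + linker + _revcomp(arm) + linker + arm
        seq = RnaSequence(f"bistable_arm{arm_length}_seed{seed}", residues)
        classes = classify(seq, PI_H, params=params)
        folded = [c for c in classes if not c.hishape.is_open_chain]
        if len(folded) < 2:
            continue
        folded.sort(key=lambda c: c.hishrep_energy)
        if not (
            folded[0].hishrep_energy < 0
            and folded[1].hishrep_energy - folded[0].hishrep_energy <= energy_window
        ):
            continue
        major, minor = sorted(folded[:2], key=lambda c: -c.probability)
        if major.probability - minor.probability < 0.05:
            continue
        unfolded = open_chain(len(seq))
        barrier_major = exact_barrier(seq, unfolded, major.hishrep, params)
        barrier_minor = exact_barrier(seq, unfolded, minor.hishrep, params)
        if barrier_major - barrier_minor >= 0.05:
            return seq
    raise RuntimeError(
        f"no bistable sequence found after {max_tries} tries; increase "
        "arm_length or widen energy_window"
    )


def growth_curve_fit(
    counts_per_length: Sequence[tuple[int, float]],
) -> tuple[float, float]:
    """Least-squares fit of folding-space sizes to ``a * b**n * n**(-3/2)``.

    Takes ``(length, count)`` points (at least three, counts positive) and
    fits ``log(count) = log(a) + n log(b) - 1.5 log(n)`` linearly.
    Returns ``(a, b)``.
    """
    points = list(counts_per_length)
    if len(points) < 3:
        raise ValueError("need at least three (length, count) points")
    if any(count <= 0 for _, count in points):
        raise ValueError("counts must be positive")
    lengths = np.array([n for n, _ in points], dtype=float)
    if len(set(lengths)) < 2:
        raise ValueError("need at least two distinct lengths")
    y = np.array([math.log(count) for _, count in points]) + 1.5 * np.log(lengths)
    design = np.column_stack([np.ones_like(lengths), lengths])
    (log_a, log_b), *_ = np.linalg.lstsq(design, y, rcond=None)
    return math.exp(log_a), math.exp(log_b)
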