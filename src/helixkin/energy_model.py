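"""Nearest-neighbor free-energy evaluation via loop decomposition.

Every pseudoknot-free secondary structure decomposes uniquely into loops:
hairpin loops, stacked pairs, bulge and internal loops, multiloops and one
exterior loop.  The free energy of a structure is the sum of its loop
energies; the exterior loop contributes exactly zero.

The bundled parameter table (``data/default_params.txt``) is a compact,
dangle-free nearest-neighbor model: stacking energies for all 36 canonical
pair combinations, tabulated hairpin/bulge/internal initiation energies up
to size 30 with logarithmic extrapolation beyond, an affine multiloop score
and a terminal AU/GU penalty.  All energies are kcal/mol.  The algorithms
in this package are agnostic to the parameter values; any file in the same
grammar can be plugged in via :func:`load_parameters`.

Penalty attribution (relevant for closed-substructure bookkeeping): the
terminal AU/GU penalty is charged to the loop a helix end faces — to the
hairpin/bulge/internal loop for its closing pair, and to a multiloop for
its closing pair and each branch.  Helix ends facing the exterior loop
carry no penalty, keeping the exterior contribution at zero.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass
from importlib import resources
from typing import Optional

from .structures import RnaSequence, SecondaryStructure, StructureError

__all__ = [
    "EnergyParameters",
    "Loop",
    "LoopDecomposition",
    "decompose",
    "structure_energy",
    "closed_substructure_energy",
    "load_parameters",
    "default_parameters",
]

_AU_LIKE = frozenset({"AU", "UA", "GU", "UG"})


@dataclass(frozen=True)
class EnergyParameters:
    """A nearest-neighbor parameter set (kcal/mol; temperatures in K)."""

    stacking: dict
    hairpin_initiation: dict
    bulge_initiation: dict
    internal_initiation: dict
    multiloop_offset: float
    multiloop_branch: float
    multiloop_unpaired: float
    terminal_au_penalty: float
    loop_extrapolation: float
    gas_constant: float = 0.0019872
    temperature: float = 310.15

    def __post_init__(self) -> None:
        if self.gas_constant <= 0 or self.temperature <= 0:
            raise ValueError("gas_constant and temperature must be positive")
        for name, table, floor in (
            ("hairpin_initiation", self.hairpin_initiation, 3),
            ("bulge_initiation", self.bulge_initiation, 1),
            ("internal_initiation", self.internal_initiation, 2),
        ):
            if any(size < floor for size in table):
                raise ValueError(f"{name} contains a loop size below {floor}")

    @property
    def kT(self) -> float:
        """Thermal energy k*T in kcal/mol."""
        return self.gas_constant * self.temperature

    def loop_initiation(self, kind: str, size: int) -> float:
        table = {
            "hairpin": self.hairpin_initiation,
            "bulge": self.bulge_initiation,
            "internal": self.internal_initiation,
        }[kind]
        if size in table:
            return table[size]
        largest = max(table)
        if size < largest:
            raise ValueError(f"no {kind} initiation energy for loop size {size}")
        return table[largest] + self.loop_extrapolation * math.log(size / largest)


@dataclass(frozen=True)
class Loop:
    """One loop of a decomposition.

    ``closing`` is the pair enclosing the loop (None for the exterior
    loop); ``branches`` are the closing pairs of the helices emanating into
    the loop; ``unpaired`` counts unpaired bases inside the loop.
    """

    kind: str  # hairpin | stack | bulge | internal | multiloop | exterior
    closing: Optional[tuple[int, int]]
    branches: tuple[tuple[int, int], ...]
    unpaired: int


@dataclass(frozen=True)
class LoopDecomposition:
    loops: tuple[Loop, ...]

    def __iter__(self):
        return iter(self.loops)


def _children(table, lo: int, hi: int) -> tuple[list[tuple[int, int]], int]:
    """Direct branch pairs and unpaired count strictly inside [lo, hi]."""
    branches: list[tuple[int, int]] = []
    unpaired = 0
    k = lo
    while k <= hi:
        partner = table[k]
        if partner > k:
            branches.append((k, partner))
            k = partner + 1
        else:
            unpaired += 1
            k += 1
    return branches, unpaired


def decompose(structure: SecondaryStructure) -> LoopDecomposition:
    """The unique loop decomposition of ``structure``.

    The exterior loop is always present exactly once; every base pair
    closes exactly one further loop and every unpaired base belongs to
    exactly one loop.
    """
    table = structure.pair_table
    loops: list[Loop] = []

    branches, unpaired = _children(table, 1, structure.length)
    loops.append(Loop("exterior", None, tuple(branches), unpaired))

    for i, j in structure.pairs:
        branches, unpaired = _children(table, i + 1, j - 1)
        if not branches:
            kind = "hairpin"
        elif len(branches) == 1:
            (c, d) = branches[0]
            if c == i + 1 and d == j - 1:
                kind = "stack"
            elif c == i + 1 or d == j - 1:
                kind = "bulge"
            else:
                kind = "internal"
        else:
            kind = "multiloop"
        loops.append(Loop(kind, (i, j), tuple(branches), unpaired))
    return LoopDecomposition(tuple(loops))


def _pair_string(seq: RnaSequence, pair: tuple[int, int]) -> str:
    i, j = pair
    return seq.residues[i - 1] + seq.residues[j - 1]


def _au_penalty(seq: RnaSequence, pair: tuple[int, int], params: EnergyParameters) -> float:
    return params.terminal_au_penalty if _pair_string(seq, pair) in _AU_LIKE else 0.0


def loop_energy(seq: RnaSequence, loop: Loop, params: EnergyParameters) -> float:
    """Free energy of a single loop under the parameter table."""
    if loop.kind == "exterior":
        return 0.0
    if loop.kind == "stack":
        outer = _pair_string(seq, loop.closing)
        inner = _pair_string(seq, loop.branches[0])
        return params.stacking[(outer, inner)]
    if loop.kind == "hairpin":
        return params.loop_initiation("hairpin", loop.unpaired) + _au_penalty(
            seq, loop.closing, params
        )
    if loop.kind in ("bulge", "internal"):
        energy = params.loop_initiation(loop.kind, loop.unpaired)
        energy += _au_penalty(seq, loop.closing, params)
        energy += _au_penalty(seq, loop.branches[0], params)
        return energy
    if loop.kind == "multiloop":
        energy = (
            params.multiloop_offset
            + params.multiloop_branch * (len(loop.branches) + 1)
            + params.multiloop_unpaired * loop.unpaired
        )
        energy += _au_penalty(seq, loop.closing, params)
        for branch in loop.branches:
            energy += _au_penalty(seq, branch, params)
        return energy
    raise ValueError(f"unknown loop kind {loop.kind!r}")


def structure_energy(
    seq: RnaSequence,
    structure: SecondaryStructure,
    params: Optional[EnergyParameters] = None,
) -> float:
    """Free energy of ``structure`` on ``seq`` in kcal/mol.

    The open chain has energy exactly 0.  Raises
    :class:`~helixkin.structures.StructureError` for non-canonical pairs.
    """
    if params is None:
        params = default_parameters()
    structure.is_compatible(seq)
    return sum(loop_energy(seq, loop, params) for loop in decompose(structure))


def closed_substructure_energy(
    seq: RnaSequence,
    structure: SecondaryStructure,
    closing_pair: tuple[int, int],
    params: Optional[EnergyParameters] = None,
) -> float:
    """Energy of the closed substructure rooted at ``closing_pair``.

    Sums the energies of all loops whose closing pair lies within
    ``closing_pair`` (inclusive).  The total structure energy equals the
    sum over all top-level closed substructures plus the multiloop and
    exterior contributions, because every loop is charged to exactly one
    closing pair.
    """
    if params is None:
        params = default_parameters()
    if closing_pair not in structure:
        raise StructureError(f"pair {closing_pair} not present in structure")
    structure.is_compatible(seq)
    lo, hi = closing_pair
    total = 0.0
    for loop in decompose(structure):
        if loop.closing is None:
            continue
        i, j = loop.closing
        if lo <= i and j <= hi:
            total += loop_energy(seq, loop, params)
    return total


# ---------------------------------------------------------------------------
# parameter file I/O
# ---------------------------------------------------------------------------

_SCALAR_KEYS = {
    "gas_constant",
    "temperature",
    "terminal_au_penalty",
    "multiloop_offset",
    "multiloop_branch",
    "multiloop_unpaired",
    "loop_extrapolation",
}
_TABLE_KEYS = {"stacking", "hairpin_initiation", "bulge_initiation", "internal_initiation"}


def parse_parameters(text: str) -> EnergyParameters:
    """Parse a parameter file in the documented whitespace grammar."""
    scalars: dict[str, float] = {}
    tables: dict[str, dict] = {key: {} for key in _TABLE_KEYS}
    section: Optional[str] = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) == 1:
            if fields[0] not in _TABLE_KEYS:
                raise ValueError(f"line {lineno}: unknown section {fields[0]!r}")
            section = fields[0]
        elif len(fields) == 2 and fields[0] in _SCALAR_KEYS:
            scalars[fields[0]] = float(fields[1])
            section = None
        elif section == "stacking" and len(fields) == 3:
            tables["stacking"][(fields[0], fields[1])] = float(fields[2])
        elif section in _TABLE_KEYS and len(fields) == 2:
            tables[section][int(fields[0])] = float(fields[1])
        else:
            raise ValueError(f"line {lineno}: cannot parse {raw!r}")
    missing = _SCALAR_KEYS - scalars.keys()
    if missing:
        raise ValueError(f"missing scalar parameters: {sorted(missing)}")
    return EnergyParameters(
        stacking=tables["stacking"],
        hairpin_initiation=tables["hairpin_initiation"],
        bulge_initiation=tables["bulge_initiation"],
        internal_initiation=tables["internal_initiation"],
        multiloop_offset=scalars["multiloop_offset"],
        multiloop_branch=scalars["multiloop_branch"],
        multiloop_unpaired=scalars["multiloop_unpaired"],
        terminal_au_penalty=scalars["terminal_au_penalty"],
        loop_extrapolation=scalars["loop_extrapolation"],
        gas_constant=scalars["gas_constant"],
        temperature=scalars["temperature"],
    )


def load_parameters(path) -> EnergyParameters:
    with open(path) as handle:
        return parse_parameters(handle.read())


@functools.lru_cache(maxsize=1)
def default_parameters() -> EnergyParameters:
    """The bundled compact parameter table."""
    text = resources.files("helixkin.data").joinpath("default_params.txt").read_text()
    return parse_parameters(text)
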