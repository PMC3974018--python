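"""Helix index shapes: a position-aware coarse-graining of folding spaces.

A helix is a maximal run of stacked base pairs.  Its *helix index* is
``(i + j) / 2`` for the innermost pair ``(i, j)`` — the central sequence
position of the loop-closing pair the helix ends in — and may be
half-integral.  Being a position, the index distinguishes alternative
helices of equal length, which is what makes the abstraction useful for
competing conformations.  The index is decorated ``m``, ``b`` or ``i``
when the terminating loop is a multiloop, bulge or internal loop; an
undecorated index denotes a hairpin helix.

Mapping a structure to the ordered list of its (decorated) helix indices
yields its *hishape*.  Four abstraction levels are provided, from coarse to
fine:

``PI_H``    hairpin helices only, as a flat list;
``PI_HPLUS``  additionally groups hairpin helices that sit inside the same
            multiloop in parentheses (nesting information);
``PI_M``    additionally keeps multiloop helices (``m``);
``PI_A``    additionally keeps bulge and internal helices (``b``/``i``).

Each hishape is an equivalence class of structures; the minimum-energy
member is the class representative (*hishrep*).  Classes carry a partition
function contribution ``Z = sum exp(-dG/kT)`` over their members, the
ensemble energy ``-kT ln Z`` and a Boltzmann probability.

The open chain maps to ``[_]`` at every level.

Text dialect: indices are comma-separated inside brackets, in 5' order of
each helix's outermost opening base; integral indices print without a
decimal point ("[2]"), half-integral with one decimal ("[7.5]").  At
``PI_HPLUS`` the contents of a multiloop appear as a parenthesised group;
at ``PI_M``/``PI_A`` the group is prefixed by the multiloop helix's own
index, e.g. ``[12m(4,8)]``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional, Sequence

from .energy_model import (
    EnergyParameters,
    closed_substructure_energy,
    decompose,
    default_parameters,
)
from .structures import (
    RnaSequence,
    SecondaryStructure,
    enumerate_structures,
)

__all__ = [
    "AbstractionLevel",
    "PI_H",
    "PI_HPLUS",
    "PI_M",
    "PI_A",
    "HelixIndex",
    "Hishape",
    "HishapeClass",
    "map_structure",
    "extract_hairpin_indices",
    "is_strictly_negative",
    "classify",
]


class AbstractionLevel(enum.Enum):
    """The four abstraction levels, in refinement order (coarse to fine)."""

    PI_H = "h"
    PI_HPLUS = "h+"
    PI_M = "m"
    PI_A = "a"

    @property
    def rank(self) -> int:
        return [PI_H, PI_HPLUS, PI_M, PI_A].index(self)

    @classmethod
    def from_string(cls, text: str) -> "AbstractionLevel":
        aliases = {
            "h": PI_H, "1": PI_H,
            "h+": PI_HPLUS, "hplus": PI_HPLUS, "2": PI_HPLUS,
            "m": PI_M, "3": PI_M,
            "a": PI_A, "4": PI_A,
        }
        try:
            return aliases[text.strip().lower()]
        except KeyError:
            raise ValueError(
                f"unknown abstraction level {text!r}; use one of h, h+, m, a "
                "(or the numeric aliases 1-4)"
            ) from None


PI_H = AbstractionLevel.PI_H
PI_HPLUS = AbstractionLevel.PI_HPLUS
PI_M = AbstractionLevel.PI_M
PI_A = AbstractionLevel.PI_A


@dataclass(frozen=True)
class HelixIndex:
    """A decorated helix index.  ``marker`` is None for hairpin helices."""

    value: float
    marker: Optional[str] = None  # None | "m" | "b" | "i"

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("helix index must be positive")
        if self.marker not in (None, "m", "b", "i"):
            raise ValueError(f"unknown helix marker {self.marker!r}")

    def __str__(self) -> str:
        return _format_value(self.value) + (self.marker or "")


def _format_value(value: float) -> str:
    return str(int(value)) if float(value).is_integer() else f"{value:.1f}"


@dataclass(frozen=True)
class Hishape:
    """A hishape: level, canonical text, and the flat index sequence."""

    level: AbstractionLevel
    text: str
    indices: tuple[HelixIndex, ...]

    def __str__(self) -> str:
        return self.text

    @property
    def is_open_chain(self) -> bool:
        return self.text == "[_]"


@dataclass(frozen=True)
class HishapeClass:
    """A hishape class over an enumerated (optionally filtered) space."""

    hishape: Hishape
    members: int
    hishrep: SecondaryStructure
    hishrep_energy: float
    partition_function: float
    ensemble_energy: float
    probability: float


# ---------------------------------------------------------------------------
# helix extraction and mapping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Helix:
    outer: tuple[int, int]
    inner: tuple[int, int]
    loop_kind: str  # kind of the loop the innermost pair closes
    children: tuple["_Helix", ...]

    @property
    def index(self) -> float:
        i, j = self.inner
        return (i + j) / 2


def _helix_tree(structure: SecondaryStructure) -> tuple[_Helix, ...]:
    """Top-level helices of ``structure``, each with nested children."""
    table = structure.pair_table
    loop_kind = {
        loop.closing: loop.kind for loop in decompose(structure) if loop.closing
    }

    def helix_from(outer: tuple[int, int]) -> _Helix:
        inner = outer
        while loop_kind[inner] == "stack":
            inner = (inner[0] + 1, inner[1] - 1)
        kind = loop_kind[inner]
        children = tuple(
            helix_from(branch) for branch in _branches(table, inner[0] + 1, inner[1] - 1)
        )
        return _Helix(outer, inner, kind, children)

    return tuple(helix_from(p) for p in _branches(table, 1, structure.length))


def _branches(table, lo: int, hi: int) -> list[tuple[int, int]]:
    out = []
    k = lo
    while k <= hi:
        if table[k] > k:
            out.append((k, table[k]))
            k = table[k] + 1
        else:
            k += 1
    return out


_MARKER = {"multiloop": "m", "bulge": "b", "internal": "i", "hairpin": None}


def _render(helices: Sequence[_Helix], level: AbstractionLevel):
    """Render helices to (text items, flat HelixIndex list) at ``level``."""
    items: list[str] = []
    flat: list[HelixIndex] = []
    for helix in helices:
        idx = HelixIndex(helix.index, _MARKER[helix.loop_kind])
        if helix.loop_kind == "hairpin":
            items.append(str(idx))
            flat.append(idx)
        elif helix.loop_kind == "multiloop":
            sub_items, sub_flat = _render(helix.children, level)
            if level is PI_H:
                items.extend(sub_items)
            elif level is PI_HPLUS:
                items.append("(" + ",".join(sub_items) + ")")
            else:  # PI_M, PI_A
                items.append(str(idx) + "(" + ",".join(sub_items) + ")")
                flat.append(idx)
            flat.extend(sub_flat)
        else:  # bulge / internal: a single child continues the chain
            sub_items, sub_flat = _render(helix.children, level)
            if level is PI_A:
                items.append(str(idx))
                flat.append(idx)
            items.extend(sub_items)
            flat.extend(sub_flat)
    return items, flat


def map_structure(
    seq: RnaSequence, structure: SecondaryStructure, level: AbstractionLevel
) -> Hishape:
    """Map a secondary structure to its hishape at the given level."""
    del seq  # the mapping is purely structural
    helices = _helix_tree(structure)
    items, flat = _render(helices, level)
    # drop indices not retained at this level from the flat list
    if level is PI_H or level is PI_HPLUS:
        flat = [idx for idx in flat if idx.marker is None]
    elif level is PI_M:
        flat = [idx for idx in flat if idx.marker in (None, "m")]
    text = "[" + (",".join(items) if items else "_") + "]"
    return Hishape(level, text, tuple(flat))


def extract_hairpin_indices(hishape: Hishape) -> frozenset[float]:
    """The hairpin-helix index values of a hishape (the function phi)."""
    return frozenset(idx.value for idx in hishape.indices if idx.marker is None)


# ---------------------------------------------------------------------------
# strictly negative filter
# ---------------------------------------------------------------------------

_SN_TOLERANCE = 1e-9


def is_strictly_negative(
    seq: RnaSequence,
    structure: SecondaryStructure,
    params: Optional[EnergyParameters] = None,
) -> bool:
    """True iff no closed substructure hanging off the exterior loop or a
    multiloop has positive free energy.

    "Not positive" is read literally: zero-energy substructures pass.  The
    open chain is strictly negative vacuously.
    """
    if params is None:
        params = default_parameters()
    for loop in decompose(structure):
        if loop.kind not in ("exterior", "multiloop"):
            continue
        for branch in loop.branches:
            if (
                closed_substructure_energy(seq, structure, branch, params)
                > _SN_TOLERANCE
            ):
                return False
    return True


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify(
    seq: RnaSequence,
    level: AbstractionLevel = PI_H,
    strictly_negative: bool = False,
    k_best: Optional[int] = None,
    params: Optional[EnergyParameters] = None,
    energy_band: Optional[float] = None,
    limit: int = 60,
) -> list[HishapeClass]:
    """Partition the enumerated folding space of ``seq`` into hishape classes.

    The space is the exhaustive noLP enumeration (optionally restricted to
    an energy band above the optimum and/or to strictly negative
    structures).  Each class carries its member count, hishrep (minimum
    energy member, ties broken by dot-bracket), partition function
    contribution, ensemble energy and Boltzmann probability over the same
    filtered space.  Classes are sorted by hishrep energy (ties by hishape
    text); ``k_best`` truncates the returned list after probabilities are
    computed over the full filtered space.
    """
    if params is None:
        params = default_parameters()
    space = enumerate_structures(seq, params, energy_band=energy_band, limit=limit)
    if strictly_negative:
        space = [(s, e) for s, e in space if is_strictly_negative(seq, s, params)]

    groups: dict[str, dict] = {}
    kT = params.kT
    for s, energy in space:
        shape = map_structure(seq, s, level)
        entry = groups.setdefault(
            shape.text,
            {"hishape": shape, "members": 0, "weight": 0.0, "best": None},
        )
        entry["members"] += 1
        entry["weight"] += math.exp(-energy / kT)
        key = (energy, s.dotbracket())
        if entry["best"] is None or key < entry["best"][0]:
            entry["best"] = (key, s, energy)

    total_weight = sum(entry["weight"] for entry in groups.values())
    classes = [
        HishapeClass(
            hishape=entry["hishape"],
            members=entry["members"],
            hishrep=entry["best"][1],
            hishrep_energy=entry["best"][2],
            partition_function=entry["weight"],
            ensemble_energy=-kT * math.log(entry["weight"]),
            probability=entry["weight"] / total_weight,
        )
        for entry in groups.values()
    ]
    classes.sort(key=lambda c: (c.hishrep_energy, c.hishape.text))
    if k_best is not None:
        classes = classes[:k_best]
    return classes
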