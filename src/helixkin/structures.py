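"""RNA sequences and pseudoknot-free, lonely-pair-free secondary structures.

A secondary structure is a set of base pairs ``(i, j)`` (1-based, ``i < j``)
that is nested (no pseudoknots), leaves at least three unpaired bases in
every hairpin loop, and contains no isolated ("lonely") base pairs: every
pair must stack on a neighbouring pair.  This is the ``noLP`` convention
commonly used when enumerating suboptimal structures.

The move set connecting structures ("neighbourhood") is the single
base-pair addition/removal move set with a lonely-pair repair rule: when a
removal leaves exactly one isolated pair, that pair is removed as well, and
when an addition would create an isolated pair an adjacent pair is closed
if possible.  The repaired moves change two adjacent pairs at once.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

__all__ = [
    "RnaSequence",
    "SecondaryStructure",
    "StructureError",
    "CANONICAL_PAIRS",
    "MIN_HAIRPIN_UNPAIRED",
    "parse_dotbracket",
    "write_dotbracket",
    "enumerate_structures",
    "neighbors",
    "is_locally_optimal",
]

#: Watson-Crick plus wobble pairs.
CANONICAL_PAIRS = frozenset({"AU", "UA", "GC", "CG", "GU", "UG"})

#: Minimum number of unpaired bases in a hairpin loop.
MIN_HAIRPIN_UNPAIRED = 3

#: Default hard limit (nt) for exhaustive enumeration.
DEFAULT_ENUMERATION_LIMIT = 60


class StructureError(ValueError):
    """Raised for malformed sequences or secondary structures."""


@dataclass(frozen=True)
class RnaSequence:
    """A single RNA sequence with 1-based positions.

    ``T`` is accepted on input and normalised to ``U``; lowercase is
    uppercased.  Only A/C/G/U survive normalisation.
    """

    identifier: str
    residues: str

    def __post_init__(self) -> None:
        normalised = self.residues.upper().replace("T", "U")
        if not normalised:
            raise StructureError("empty sequence")
        for pos, base in enumerate(normalised, start=1):
            if base not in "ACGU":
                raise StructureError(
                    f"illegal residue {base!r} at position {pos} in "
                    f"sequence {self.identifier!r}"
                )
        object.__setattr__(self, "residues", normalised)

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues

    def can_pair(self, i: int, j: int) -> bool:
        """True if positions i and j (1-based) form a canonical pair."""
        return self.residues[i - 1] + self.residues[j - 1] in CANONICAL_PAIRS


@dataclass(frozen=True)
class SecondaryStructure:
    """An immutable, validated pseudoknot-free noLP secondary structure.

    Parameters
    ----------
    length:
        Sequence length the structure lives on.
    pairs:
        Base pairs as ``(i, j)`` tuples, 1-based with ``i < j``.
    """

    length: int
    pairs: tuple[tuple[int, int], ...]
    _table: tuple[int, ...] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        pairs = tuple(sorted(tuple(p) for p in self.pairs))
        object.__setattr__(self, "pairs", pairs)
        table = _build_pair_table(self.length, pairs)
        object.__setattr__(self, "_table", table)
        _validate_nested(pairs)
        _validate_nolp(pairs)

    # -- accessors ---------------------------------------------------------

    @property
    def pair_table(self) -> tuple[int, ...]:
        """``table[i]`` is the partner of position i, or 0; index 0 unused."""
        return self._table

    def partner(self, i: int) -> int:
        return self._table[i]

    def __contains__(self, pair: tuple[int, int]) -> bool:
        i, j = pair
        return 1 <= i <= self.length and self._table[i] == j and i < j

    def __len__(self) -> int:
        return len(self.pairs)

    def dotbracket(self) -> str:
        return write_dotbracket(self)

    def __str__(self) -> str:
        return self.dotbracket()

    # -- helpers used across the package -----------------------------------

    def is_compatible(self, seq: RnaSequence) -> None:
        """Raise :class:`StructureError` unless all pairs are canonical."""
        if self.length != len(seq):
            raise StructureError(
                f"structure length {self.length} != sequence length {len(seq)}"
            )
        for i, j in self.pairs:
            if not seq.can_pair(i, j):
                raise StructureError(
                    f"non-canonical pair {seq.residues[i-1]}{seq.residues[j-1]} "
                    f"at positions ({i},{j})"
                )


def open_chain(length: int) -> SecondaryStructure:
    """The structure with no base pairs."""
    return SecondaryStructure(length, ())


def _build_pair_table(length: int, pairs: Sequence[tuple[int, int]]) -> tuple[int, ...]:
    table = [0] * (length + 1)
    for i, j in pairs:
        if not (1 <= i < j <= length):
            raise StructureError(f"pair ({i},{j}) out of range for length {length}")
        if j - i < MIN_HAIRPIN_UNPAIRED + 1:
            raise StructureError(
                f"pair ({i},{j}) closes a hairpin loop with fewer than "
                f"{MIN_HAIRPIN_UNPAIRED} unpaired bases"
            )
        for p in (i, j):
            if table[p]:
                raise StructureError(f"position {p} occurs in more than one pair")
        table[i], table[j] = j, i
    return tuple(table)


def _validate_nested(pairs: Sequence[tuple[int, int]]) -> None:
    # pairs sorted by i; a stack-based crossing check
    stack: list[tuple[int, int]] = []
    for i, j in pairs:
        while stack and stack[-1][1] < i:
            stack.pop()
        if stack and not (stack[-1][0] < i and j < stack[-1][1]):
            k, l = stack[-1]
            raise StructureError(f"pseudoknot: pairs ({k},{l}) and ({i},{j}) cross")
        stack.append((i, j))


def _validate_nolp(pairs: Sequence[tuple[int, int]]) -> None:
    pair_set = set(pairs)
    for i, j in pairs:
        if (i + 1, j - 1) not in pair_set and (i - 1, j + 1) not in pair_set:
            raise StructureError(f"lonely pair ({i},{j}) violates the noLP rule")


# ---------------------------------------------------------------------------
# dot-bracket I/O
# ---------------------------------------------------------------------------

def parse_dotbracket(text: str) -> SecondaryStructure:
    """Parse a dot-bracket string into a :class:`SecondaryStructure`.

    Only ``.``, ``(`` and ``)`` are accepted.  Errors report the first
    offending column (1-based).
    """
    pairs: list[tuple[int, int]] = []
    stack: list[int] = []
    for col, char in enumerate(text.strip(), start=1):
        if char == "(":
            stack.append(col)
        elif char == ")":
            if not stack:
                raise StructureError(f"unbalanced ')' at column {col}")
            pairs.append((stack.pop(), col))
        elif char != ".":
            raise StructureError(f"illegal character {char!r} at column {col}")
    if stack:
        raise StructureError(f"unbalanced '(' at column {stack[-1]}")
    return SecondaryStructure(len(text.strip()), tuple(pairs))


def write_dotbracket(structure: SecondaryStructure) -> str:
    chars = ["."] * structure.length
    for i, j in structure.pairs:
        chars[i - 1] = "("
        chars[j - 1] = ")"
    return "".join(chars)


# ---------------------------------------------------------------------------
# exhaustive enumeration
# ---------------------------------------------------------------------------

def _enumerate_pair_sets(seq: RnaSequence) -> list[frozenset[tuple[int, int]]]:
    """All noLP-valid pair sets for ``seq``.

    Structures are built helix-first: position ``i`` is either unpaired or
    opens a maximal helix of at least two stacked pairs.  Forcing helices to
    be maximal (the region inside a helix must not immediately extend it)
    makes the construction duplicate-free.
    """
    n = len(seq)
    can = seq.can_pair
    min_span = MIN_HAIRPIN_UNPAIRED + 1

    @functools.lru_cache(maxsize=None)
    def region(i: int, j: int) -> tuple[frozenset, ...]:
        """All pair sets on the closed interval [i, j]."""
        if j - i + 1 <= min_span:
            return (frozenset(),)
        out: list[frozenset] = list(region(i + 1, j))
        for k in range(i + min_span, j + 1):
            if not can(i, k):
                continue
            # grow a helix (i,k),(i+1,k-1),... of length h >= 2
            h = 1
            while (
                (k - h) - (i + h) >= min_span
                and can(i + h, k - h)
            ):
                h += 1
                helix = frozenset((i + d, k - d) for d in range(h))
                inner_lo, inner_hi = i + h, k - h
                forbidden = (inner_lo, inner_hi)
                for inner in region(inner_lo, inner_hi):
                    if forbidden in inner:
                        continue  # would extend the helix: counted at larger h
                    for rest in region(k + 1, j):
                        out.append(helix | inner | rest)
        return tuple(out)

    result = list(region(1, n))
    region.cache_clear()
    return result


def enumerate_structures(
    seq: RnaSequence,
    params: "EnergyParameters | None" = None,
    energy_band: Optional[float] = None,
    limit: int = DEFAULT_ENUMERATION_LIMIT,
) -> list[tuple[SecondaryStructure, float]]:
    """Exhaustively enumerate all noLP structures of ``seq`` with energies.

    Returns ``(structure, energy)`` pairs sorted by energy, ties broken by
    dot-bracket string.  With ``energy_band`` given, only structures within
    that many kcal/mol above the optimum are returned (the enumeration
    itself is exhaustive; the band is a filter, which keeps this routine at
    desk scale).

    Raises :class:`StructureError` if the sequence exceeds ``limit``.
    """
    from .energy_model import default_parameters, structure_energy

    if len(seq) > limit:
        raise StructureError(
            f"sequence length {len(seq)} exceeds the exhaustive enumeration "
            f"limit of {limit} nt; pass a larger limit= explicitly if you "
            "accept the cost, or analyse a shorter sequence"
        )
    if params is None:
        params = default_parameters()
    n = len(seq)
    scored: list[tuple[SecondaryStructure, float]] = []
    for pair_set in _enumerate_pair_sets(seq):
        s = SecondaryStructure(n, tuple(pair_set))
        scored.append((s, structure_energy(seq, s, params)))
    scored.sort(key=lambda se: (se[1], se[0].dotbracket()))
    if energy_band is not None:
        best = scored[0][1]
        scored = [(s, e) for s, e in scored if e <= best + energy_band]
    return scored


# ---------------------------------------------------------------------------
# modified neighbourhood (single-pair moves with lonely-pair repair)
# ---------------------------------------------------------------------------

def _try_structure(length: int, pairs: frozenset) -> Optional[SecondaryStructure]:
    try:
        return SecondaryStructure(length, tuple(pairs))
    except StructureError:
        return None


def _lonely_pairs(pairs: frozenset) -> list[tuple[int, int]]:
    return [
        (i, j)
        for i, j in pairs
        if (i + 1, j - 1) not in pairs and (i - 1, j + 1) not in pairs
    ]


def _addable_pairs(seq: RnaSequence, structure: SecondaryStructure) -> Iterator[tuple[int, int]]:
    n = len(seq)
    table = structure.pair_table
    pairs = structure.pairs
    for i in range(1, n + 1):
        if table[i]:
            continue
        for j in range(i + MIN_HAIRPIN_UNPAIRED + 1, n + 1):
            if table[j] or not seq.can_pair(i, j):
                continue
            if any(k < i < l < j or i < k < j < l for k, l in pairs):
                continue  # would cross an existing pair
            yield (i, j)


def _can_close(seq, pairs: frozenset, table_free, pair: tuple[int, int], n: int) -> bool:
    i, j = pair
    if not (1 <= i < j <= n) or j - i < MIN_HAIRPIN_UNPAIRED + 1:
        return False
    if not seq.can_pair(i, j):
        return False
    occupied = set()
    for a, b in pairs:
        occupied.add(a)
        occupied.add(b)
    if i in occupied or j in occupied:
        return False
    return not any(k < i < l < j or i < k < j < l for k, l in pairs)


def neighbors(
    seq: RnaSequence,
    structure: SecondaryStructure,
    params: "EnergyParameters | None" = None,
) -> set[SecondaryStructure]:
    """The modified single-pair neighbourhood of ``structure``.

    Removal of a pair that leaves exactly one lonely pair also removes that
    lonely pair.  Addition of a pair that would itself be lonely closes an
    adjacent pair when possible — each closable side, ``(i-1, j+1)`` and
    ``(i+1, j-1)``, yields a neighbour — and the move is discarded when
    neither closes.  Producing both closures (rather than preferring one
    side) is what keeps the relation symmetric: removing a mid-helix pair
    deletes a specific lonely end, and the reverse move must be able to
    rebuild exactly that end.  All returned structures are valid noLP
    structures distinct from the input; repaired moves differ by two
    adjacent pairs.
    """
    del params  # the move set is purely geometric
    n = structure.length
    result: set[SecondaryStructure] = set()
    pair_set = frozenset(structure.pairs)

    # removals
    for pair in structure.pairs:
        raw = pair_set - {pair}
        s = _try_structure(n, raw)
        if s is not None:
            result.add(s)
            continue
        lonely = _lonely_pairs(raw)
        if len(lonely) == 1:
            s = _try_structure(n, raw - {lonely[0]})
            if s is not None:
                result.add(s)

    # additions
    for pair in _addable_pairs(seq, structure):
        raw = pair_set | {pair}
        s = _try_structure(n, raw)
        if s is not None:
            result.add(s)
            continue
        if _lonely_pairs(raw) != [pair]:
            continue
        i, j = pair
        for closure in ((i - 1, j + 1), (i + 1, j - 1)):
            if closure in raw:
                continue
            if _can_close(seq, raw, None, closure, n):
                s = _try_structure(n, raw | {closure})
                if s is not None:
                    result.add(s)

    result.discard(structure)
    return result


def is_locally_optimal(
    seq: RnaSequence,
    structure: SecondaryStructure,
    params: "EnergyParameters | None" = None,
) -> bool:
    """True iff no neighbour has strictly lower free energy.

    Equal-energy neighbours do not disqualify a local optimum.
    """
    from .energy_model import default_parameters, structure_energy

    if params is None:
        params = default_parameters()
    own = structure_energy(seq, structure, params)
    return all(
        structure_energy(seq, other, params) >= own
        for other in neighbors(seq, structure)
    )
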