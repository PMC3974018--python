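# Methods

This note records the models implemented in `helixkin`, the choices made
where the design was genuinely open, and what the test suite does and
does not establish.

## Structure space

Structures are pseudoknot-free sets of canonical pairs (Watson–Crick plus
G·U wobble) with at least three unpaired hairpin bases and no lonely
pairs (noLP): every pair stacks on a neighbour. Coordinates are 1-based
closed intervals. The exhaustive enumerator builds structures helix-first
— a position is unpaired or opens a maximal helix of ≥ 2 stacked pairs —
which is duplicate-free by construction and is cross-checked in the tests
against a naive generate-everything-then-filter recursion. Exhaustive
enumeration is limited to 60 nt by default; an energy band, when given,
is applied as a filter on the exhaustive list (this keeps the enumerator
simple and testable at the expense of not extending the reachable length;
the package is deliberately desk-scale).

## Move set

The landscape neighbourhood is single base-pair addition/removal with
lonely-pair repair: a removal that leaves exactly one isolated pair also
removes it; an addition that would create an isolated pair closes an
adjacent pair instead, and is discarded if neither side closes. Both
closable sides yield neighbours. An earlier draft preferred one side
deterministically, but that provably breaks the symmetry of the relation
(removing a mid-helix pair from a four-stack deletes a specific lonely
end; the reverse addition must be able to rebuild exactly that end), and
symmetry is what makes the landscape graph undirected and the saddle
height well-defined in both directions. Symmetry is property-tested over
fully enumerated spaces.

Local optimality uses strict inequality: equal-energy neighbours do not
disqualify a local optimum. Note that under the bundled energy table
helix nucleation (one stack plus hairpin initiation) always costs more
than zero, so the open chain is always locally optimal.

## Energy model

A compact, dangle-free nearest-neighbor table is bundled as plain text:
stacking energies for all 36 canonical pair combinations, hairpin, bulge
and internal loop initiations tabulated to size 30 with logarithmic
extrapolation `ΔG(s) = ΔG(30) + c·ln(s/30)` beyond, an affine multiloop
score `a + b·branches + c·unpaired` (branches counted including the
closing pair), and a 0.5 kcal/mol terminal penalty for AU/GU helix ends.
Values are inspired by the standard nearest-neighbor literature but
deliberately compact; every algorithm in the package is agnostic to them
and accepts any table in the same grammar.

Penalty attribution is the one modelling convention with bookkeeping
consequences: the AU/GU penalty is charged to the loop the helix end
faces (hairpin/bulge/internal closing pairs to their own loop; multiloop
closing and branch pairs to the multiloop). Helix ends facing the
exterior loop carry no penalty, so the exterior loop contributes exactly
zero and the total energy decomposes exactly into closed-substructure
energies plus multiloop contributions — the decomposition the strictly
negative filter relies on.

Defaults: gas constant 0.0019872 kcal/(mol·K), temperature 310.15 K.

## Hishapes

The helix index is the central position (i+j)/2 of a helix's innermost
pair — a *position*, not a length, which is what lets the abstraction
separate alternative helices of identical size. Indices may be
half-integral and are decorated `m`/`b`/`i` by terminating loop type.

Text dialect (the nesting syntax is not standardised anywhere, so it is
fixed here): indices appear in 5' order of each helix's outermost opening
base, comma-separated in brackets; the open chain is `[_]`. At π_h+ the
hairpin helices inside a multiloop are parenthesised, `[(9,18)]`; at
π_m/π_a the group is prefixed with the multiloop helix's own index,
`[13m(9,18)]`. Bulge/internal helices at π_a are spliced inline
(`[6.5b,7]`) since they form a linear chain. This dialect makes the four
levels a strict refinement hierarchy, which is property-tested (class
counts are monotone along π_h → π_h+ → π_m → π_a).

Classification enumerates the (optionally banded, optionally
SN-filtered) space explicitly rather than using a grammar-based dynamic
program; this caps usable lengths but gives an oracle-testable
implementation. `Z_α` sums over all enumerated members of the class, and
probabilities are normalised over the same filtered space that produced
the classes.

"Must not have positive energy" in the SN filter is read literally as
≤ 0: zero-energy closed substructures are kept (a strict `< 0` would
drop neutral substructures with no textual justification), with a 1e-9
tolerance for float noise.

## Barrier estimation

Direct-path search: intermediates use only pairs of start ∪ target, and
every move must strictly reduce the symmetric difference to the target,
so paths terminate after at most |SΔT| moves. At each level the k
lowest-saddle partial paths survive (default k = 10; ties broken by
dot-bracket string, so runs are deterministic). If the beam dead-ends —
possible but never observed on test fixtures — the search falls back to
an exact minimax sweep of the (small) direct-path state space.

Anchored search: anchors are hishreps of the N lowest-energy fuzzy
related π_h hishapes; N defaults to the auto-adjusted count
`max(1, round(124000·n^(−3/2)))` (note the formula yields 11 at n = 500
under round-to-nearest; a floor convention would give 10 — the formula is
implemented literally). θ defaults to 1.0 helix-index units (no
established default exists; 1.0 admits single-position helix slippage,
which is the phenomenon the fuzzy relation was designed for). The open
chain (empty index set) always qualifies, treating the max over an empty
set as 0.

Edge weights in the anchor graph are absolute saddle heights, each
computed as the better of the two search directions; a path's barrier is
its bottleneck minus the start energy. Because the direct start–target
edge is always present, the anchored estimate is never worse than the
direct one, and because every segment is a true landscape path it is
never better than the exact saddle — the sandwich that the acceptance
tests verify against the enumerated oracle. Segment computations are
independent and cached, so pairwise barrier matrices reuse shared legs;
results are identical to sequential evaluation.

## Kinetics

States are hishape classes; rates follow the Arrhenius form
`r_βα = A·exp(−(ΔG[α,β] − ΔG(α))/kT)` applied literally (no capping when
the saddle lies below the ensemble energy). A = 1.0 µs⁻¹; times are
microseconds, default grid 10⁻²…10⁸ µs with 200 log-spaced points.
Saddles are stored once per unordered pair, which makes detailed balance
an algebraic identity and guarantees relaxation to the Boltzmann
distribution over ensemble energies — verified to 1e-6 on every fixture.

Propagation uses a symmetrised eigendecomposition
(`D^{-1/2} R D^{1/2}` is symmetric for reversible chains) when a
detailed-balance check on the computed stationary vector passes, and
scaling-and-squaring `expm` otherwise; the two agree to 1e-8 on test
problems. Occupancies are clipped at zero and renormalised per time
slice; conservation holds to 1e-9 before cleanup. States with no
finite-barrier connection are retained with zero rates and reported in a
warning.

The end-to-end simulation includes the `k_best` classes plus the open
chain and the user's initial hishape, computes all pairwise saddles
(dense; `k_best` is expected to stay small at desk scale), and starts
from the initial class's unit vector.

## Synthetic fixtures

`random_sequences` draws i.i.d. residues at a target GC fraction from a
seeded PCG64 generator (generator identity recorded in output).
`bistable_sequence` lays out `arm–linker–revcomp(arm)–linker–arm` so the
central segment can pair with either flank but not both, and accepts a
candidate only when enumeration confirms the bistable-switch phenotype:
two mutually exclusive folded classes within 1 kcal/mol of each other,
and the thermodynamically dominant class separated by a *higher* exact
folding barrier from the open chain (margins: 0.05 kcal/mol on the
barrier, 0.05 on the probability gap). The second condition is what
produces the characteristic occupancy crossing — the metastable hairpin
folds first and is overtaken later — and is part of the fixture's
definition, not a per-run adjustment.

What the fixtures do not emulate: natural sequence composition,
conserved structure, modified bases, tertiary interactions, and
co-transcriptional folding. Passing tests show the machinery is correct
on its own model; they do not validate the energy table against
experiment.

## Problem sizes

The test and acceptance runs use exhaustively enumerable instances:
random sequences of 18–30 nt, the 23-nt bistable switch, growth fits
over lengths 16–28 with three sequences per length. These sizes keep
every heuristic claim checkable against brute-force oracles (all-paths
minimax, generate-and-filter enumeration, exhaustive neighbour scans).

## Known limitations

* No pseudoknots, no lonely pairs, no dangling ends or coaxial stacking.
* Exhaustive-enumeration backend: lengths beyond ~60 nt are out of reach
  by design; the published asymptotic regimes (hundreds of nt) require a
  grammar-based dynamic program that is out of scope here.
* The bundled energy table is compact, not a full published parameter
  set; absolute energies should not be compared against experimental
  values.
* Barrier estimates are upper bounds; no indirect-path (tabu/evolutionary)
  refinement is implemented.
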