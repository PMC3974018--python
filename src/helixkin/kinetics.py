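"""Coarse-grained folding kinetics as a continuous-time Markov chain.

States are hishape classes.  The transition rate from class ``alpha`` to
class ``beta`` follows an Arrhenius law,

    r[beta <- alpha] = A * exp(-(dG[alpha,beta] - dG(alpha)) / kT)

where ``dG[alpha,beta]`` is the saddle height between the two hishreps
(estimated by the anchored pathway heuristic, stored once per unordered
pair so it is symmetric) and ``dG(alpha)`` is the class ensemble energy
``-kT ln Z_alpha``.  Using the ensemble energy weights transitions by
class size: leaving a large class is slow, entering it is fast.  Because
the saddles are symmetric, detailed balance holds exactly and the chain
relaxes to the Boltzmann distribution over ensemble energies.

The master equation ``dp/dt = R p`` with column sums zero is propagated as
``p(t) = exp(tR) p(0)``, via a symmetrised eigendecomposition when the
chain is reversible and scaling-and-squaring otherwise.

Times are microseconds; the default Arrhenius prefactor is A = 1.0 per
microsecond.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from .energy_model import EnergyParameters, default_parameters
from .hishape import AbstractionLevel, HishapeClass, PI_H, classify, map_structure
from .pathways import PathwayParameters, hipath2
from .structures import RnaSequence, open_chain

__all__ = [
    "KineticsParameters",
    "RateMatrix",
    "OccupancyTrajectory",
    "SimulationResult",
    "transition_rate",
    "build_rate_matrix",
    "propagate",
    "simulate",
    "default_time_grid",
]


def default_time_grid() -> np.ndarray:
    """200 log-spaced times from 1e-2 to 1e8 microseconds."""
    return np.logspace(-2, 8, 200)


@dataclass(frozen=True)
class KineticsParameters:
    """Arrhenius prefactor (1/us), output time grid (us), initial state."""

    prefactor: float = 1.0
    times: np.ndarray = field(default_factory=default_time_grid)
    initial_hishape: str = "[_]"

    def __post_init__(self) -> None:
        if self.prefactor <= 0:
            raise ValueError("prefactor must be positive")
        times = np.asarray(self.times, dtype=float)
        if times.ndim != 1 or len(times) == 0:
            raise ValueError("times must be a non-empty 1-D array")
        if np.any(times < 0) or np.any(np.diff(times) <= 0):
            raise ValueError("times must be non-negative and strictly increasing")
        object.__setattr__(self, "times", times)


def transition_rate(
    barrier: float,
    ensemble_energy: float,
    params: Optional[EnergyParameters] = None,
    prefactor: float = 1.0,
) -> float:
    """Arrhenius rate (1/us) out of a class with the given ensemble energy.

    ``barrier`` is the absolute saddle height dG[alpha,beta] (kcal/mol).
    The formula is applied literally; no capping at the prefactor.
    """
    if params is None:
        params = default_parameters()
    return prefactor * math.exp(-(barrier - ensemble_energy) / params.kT)


@dataclass(frozen=True)
class RateMatrix:
    """Rate matrix of the class-level chain.

    ``matrix[b, a]`` is the rate from state ``a`` to state ``b``; columns
    sum to zero.  ``states`` are hishape texts in matrix order.
    """

    states: tuple[str, ...]
    matrix: np.ndarray
    ensemble_energies: tuple[float, ...]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.states), len(self.states)):
            raise ValueError("matrix shape does not match state count")
        object.__setattr__(self, "matrix", m)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.states, columns=self.states)


def build_rate_matrix(
    classes: Sequence[HishapeClass],
    barriers: dict,
    params: Optional[EnergyParameters] = None,
    kinetics: Optional[KineticsParameters] = None,
) -> RateMatrix:
    """Assemble the CTMC rate matrix from classes and pairwise saddles.

    ``barriers`` maps unordered state-text pairs (``frozenset`` of two
    hishape texts, or tuples in either orientation) to absolute saddle
    heights dG[alpha,beta] in kcal/mol.  A missing barrier for any pair of
    states raises a :class:`KeyError` naming the pair.  States without a
    finite-barrier connection may be encoded with ``math.inf`` (rate 0); a
    warning lists them.
    """
    if params is None:
        params = default_parameters()
    if kinetics is None:
        kinetics = KineticsParameters()

    texts = [c.hishape.text for c in classes]
    energies = [c.ensemble_energy for c in classes]
    n = len(classes)

    def lookup(a: str, b: str) -> float:
        for key in ((a, b), (b, a)):
            if key in barriers:
                return barriers[key]
        key = frozenset((a, b))
        if key in barriers:
            return barriers[key]
        raise KeyError(f"missing barrier for state pair ({a!r}, {b!r})")

    matrix = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            saddle = lookup(texts[a], texts[b])
            if math.isinf(saddle):
                continue
            matrix[b, a] = transition_rate(
                saddle, energies[a], params, kinetics.prefactor
            )
            matrix[a, b] = transition_rate(
                saddle, energies[b], params, kinetics.prefactor
            )
    np.fill_diagonal(matrix, 0.0)
    np.fill_diagonal(matrix, -matrix.sum(axis=0))

    isolated = [texts[i] for i in range(n) if np.all(matrix[:, i] == 0)]
    if isolated and n > 1:
        warnings.warn(
            f"states with no finite-barrier connection retained with zero "
            f"rates: {isolated}",
            stacklevel=2,
        )
    return RateMatrix(tuple(texts), matrix, tuple(energies))


@dataclass(frozen=True)
class OccupancyTrajectory:
    """Occupancies ``p[state](t)`` on a time grid (times in us)."""

    times: np.ndarray
    occupancies: np.ndarray  # shape (n_times, n_states)
    states: tuple[str, ...]
    initial: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.occupancies, columns=self.states)
        frame.insert(0, "time", self.times)
        return frame

    def occupancy(self, state: str) -> np.ndarray:
        return self.occupancies[:, self.states.index(state)]


def _reversible_stationary(matrix: np.ndarray) -> Optional[np.ndarray]:
    """Stationary distribution if the chain satisfies detailed balance."""
    n = matrix.shape[0]
    eigvals, eigvecs = scipy.linalg.eig(matrix)
    idx = int(np.argmin(np.abs(eigvals)))
    pi = np.real(eigvecs[:, idx])
    if pi.sum() == 0:
        return None
    pi = pi / pi.sum()
    if np.any(pi <= 0):
        return None
    # detailed balance check r_ba * pi_a == r_ab * pi_b
    flux = matrix * pi[np.newaxis, :]
    scale = np.max(np.abs(flux)) or 1.0
    if np.max(np.abs(flux - flux.T)) > 1e-8 * scale:
        return None
    return pi


def propagate(
    rate_matrix: RateMatrix,
    p0: Sequence[float],
    times: Optional[np.ndarray] = None,
) -> OccupancyTrajectory:
    """Solve the master equation on the time grid.

    Uses a symmetrised eigendecomposition when the chain is reversible
    (detailed balance holds), which is numerically exact for long times;
    otherwise falls back to scaling-and-squaring matrix exponentials.
    Probability is conserved at every output time.
    """
    if times is None:
        times = default_time_grid()
    times = np.asarray(times, dtype=float)
    p0 = np.asarray(p0, dtype=float)
    n = len(rate_matrix.states)
    if p0.shape != (n,):
        raise ValueError(f"p0 must have length {n}")
    if np.any(p0 < 0) or abs(p0.sum() - 1.0) > 1e-9:
        raise ValueError("p0 must be a probability vector")

    R = rate_matrix.matrix
    pi = _reversible_stationary(R) if n > 1 else None
    if pi is not None:
        # S = D^-1/2 R D^1/2 is symmetric for reversible chains
        sqrt_pi = np.sqrt(pi)
        sym = R * (sqrt_pi[np.newaxis, :] / sqrt_pi[:, np.newaxis])
        sym = (sym + sym.T) / 2
        eigvals, eigvecs = np.linalg.eigh(sym)
        transformed = eigvecs.T @ (p0 / sqrt_pi)
        occupancies = np.empty((len(times), n))
        for row, t in enumerate(times):
            occupancies[row] = sqrt_pi * (eigvecs @ (np.exp(eigvals * t) * transformed))
    else:
        occupancies = np.empty((len(times), n))
        for row, t in enumerate(times):
            occupancies[row] = scipy.linalg.expm(R * t) @ p0

    # numerical cleanup: clip tiny negatives, renormalise
    occupancies = np.clip(occupancies, 0.0, None)
    occupancies /= occupancies.sum(axis=1, keepdims=True)
    return OccupancyTrajectory(times, occupancies, rate_matrix.states, p0)


@dataclass(frozen=True)
class SimulationResult:
    trajectory: OccupancyTrajectory
    rate_matrix: RateMatrix
    classes: tuple[HishapeClass, ...]
    barriers: dict


def simulate(
    seq: RnaSequence,
    level: AbstractionLevel = PI_H,
    strictly_negative: bool = False,
    k_best: Optional[int] = None,
    params: Optional[EnergyParameters] = None,
    pathway_params: Optional[PathwayParameters] = None,
    kinetics: Optional[KineticsParameters] = None,
) -> SimulationResult:
    """End-to-end kinetic simulation of a sequence's hishape classes.

    Classifies the folding space at ``level`` (optionally restricted to
    strictly negative structures), keeps the ``k_best`` classes by hishrep
    energy plus the open chain and the configured initial hishape,
    estimates all pairwise saddles with the anchored pathway heuristic,
    builds the Arrhenius rate matrix and propagates the master equation
    from the initial class's unit vector.
    """
    if params is None:
        params = default_parameters()
    if pathway_params is None:
        pathway_params = PathwayParameters()
    if kinetics is None:
        kinetics = KineticsParameters()

    all_classes = classify(
        seq, level, strictly_negative=strictly_negative, params=params
    )
    selected = list(all_classes if k_best is None else all_classes[:k_best])
    texts = {c.hishape.text for c in selected}
    open_text = map_structure(seq, open_chain(len(seq)), level).text
    for required in (open_text, kinetics.initial_hishape):
        if required not in texts:
            match = [c for c in all_classes if c.hishape.text == required]
            if not match:
                available = sorted(c.hishape.text for c in all_classes)
                raise ValueError(
                    f"hishape {required!r} not found in the classified space; "
                    f"available: {available}"
                )
            selected.append(match[0])
            texts.add(required)

    # anchor universe for the pathway heuristic, shared across pairs
    universe = (
        classify(seq, PI_H, strictly_negative=strictly_negative, params=params)
        if level is not PI_H
        else all_classes
    )

    barriers: dict[frozenset, float] = {}
    segment_cache: dict = {}  # direct-path segments shared across pairs
    for a in range(len(selected)):
        for b in range(a + 1, len(selected)):
            path = hipath2(
                seq,
                selected[a].hishrep,
                selected[b].hishrep,
                pathway_params,
                params,
                universe=universe,
                segment_cache=segment_cache,
            )
            key = frozenset(
                (selected[a].hishape.text, selected[b].hishape.text)
            )
            barriers[key] = path.saddle

    rate_matrix = build_rate_matrix(selected, barriers, params, kinetics)
    p0 = np.zeros(len(selected))
    p0[rate_matrix.states.index(kinetics.initial_hishape)] = 1.0
    trajectory = propagate(rate_matrix, p0, kinetics.times)
    return SimulationResult(trajectory, rate_matrix, tuple(selected), barriers)
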