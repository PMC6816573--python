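"""Mean-field Hopfield network with annealing for the traveling salesman problem.

Cities and tour positions are joined in an n x n grid of analog neurons;
``v[X, i]`` is the probability that city X occupies tour position i.  The
mean field felt by neuron (X, i) combines a position-occupancy penalty and
the distance cost of placing X adjacent (in tour time) to the other cities:

    E[X, i] = d_p * sum_{Y != X} v[Y, i]
            + sum_{Y != X} d[X, Y] * (v[Y, i+1] + v[Y, i-1])

Activities relax under a Boltzmann (softmax) rule at temperature T, each
city's row normalized to a probability distribution over positions.  Rows
are updated one city at a time (in seeded random order) because fully
synchronous updates of this coupling oscillate with period two instead of
converging.  The temperature starts above the ordering transition and is
cooled geometrically to a working value; once the largest activity change
in a sweep falls below tolerance, the tour is decoded by per-position
argmax and kept only if it visits every city exactly once.  Invalid
decodings are reported, not repaired.

Tour positions are an open chain by default (the first and last positions
have a single temporal neighbor).  With cyclic positions every direction-
reversal ("bitonic") rearrangement of a one-dimensional instance is exactly
degenerate with the sorted tour, so open-chain coupling is what makes
single-index optimization meaningful; set ``cyclic_positions=True`` for the
classical closed-tour formulation.

The solver is generic over any symmetric distance matrix, so tiny instances
can be checked against exhaustive search.  Distances are normalized to unit
maximum by default, which places the default penalty and temperature in
their working regime regardless of the scale of the supplied matrix.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class SolverParams:
    """Mean-field annealing parameters.

    ``d_p`` penalizes two cities sharing a tour position; ``temperature``
    is the working temperature at which the network settles.  Annealing
    starts at ``anneal_from`` (set equal to ``temperature`` for a purely
    fixed-temperature run) and multiplies the temperature by ``cooling``
    each sweep until the working value is reached.  Activities start
    uniformly in ``0.5 +/- init_half_width``.  ``scale_distances``
    normalizes the distance matrix to a maximum of ``distance_scale``
    before solving; the scale is calibrated so the default penalty and
    temperatures solve generic small instances to (near-)optimality.
    """

    d_p: float = 0.7
    temperature: float = 0.1
    anneal_from: float = 0.2
    cooling: float = 0.995
    init_half_width: float = 0.1
    max_sweeps: int = 5000
    tol: float = 1e-6
    cyclic_positions: bool = False
    scale_distances: bool = True
    distance_scale: float = 0.5

    def __post_init__(self):
        if self.d_p <= 0 or self.temperature <= 0:
            raise ValueError("d_p and temperature must be positive")
        if self.distance_scale <= 0:
            raise ValueError("distance_scale must be positive")
        if self.anneal_from < self.temperature:
            raise ValueError("anneal_from must be >= the working temperature")
        if not (0 < self.cooling <= 1):
            raise ValueError("cooling factor must be in (0, 1]")


def check_distance_matrix(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T) or np.any(np.diag(d) != 0) or np.any(d < 0):
        raise ValueError("distance matrix must be symmetric, nonnegative, zero-diagonal")
    return d


def _neighbor_sum(v: np.ndarray, cyclic: bool) -> np.ndarray:
    """v[:, i+1] + v[:, i-1] with wrap-around or open-chain boundaries."""
    if cyclic:
        return np.roll(v, -1, axis=1) + np.roll(v, 1, axis=1)
    s = np.zeros_like(v)
    s[:, :-1] += v[:, 1:]
    s[:, 1:] += v[:, :-1]
    return s


def mean_field(
    v: np.ndarray, d: np.ndarray, d_p: float, cyclic: bool = True
) -> np.ndarray:
    """Mean field E[X, i] for every neuron.

    Position indices i±1 wrap cyclically by default; with ``cyclic=False``
    the boundary positions have a single temporal neighbor.
    """
    v = np.asarray(v, dtype=float)
    d = check_distance_matrix(d)
    if v.ndim != 2 or v.shape[0] != d.shape[0]:
        raise ValueError("activity matrix rows must match distance matrix size")
    occupancy = d_p * (v.sum(axis=0, keepdims=True) - v)   # Y != X
    interaction = d @ _neighbor_sum(v, cyclic)             # diag(d) = 0 drops Y = X
    return occupancy + interaction


def boltzmann_update(E: np.ndarray, temperature: float) -> np.ndarray:
    """Row-wise softmax of -E/T: each city's position distribution sums to 1."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    logits = -np.asarray(E, dtype=float) / temperature
    logits -= logits.max(axis=1, keepdims=True)            # overflow guard
    ex = np.exp(logits)
    return ex / ex.sum(axis=1, keepdims=True)


def decode(v: np.ndarray) -> list[int]:
    """City with the highest activity at each tour position (ties: lowest index)."""
    return [int(np.argmax(v[:, i])) for i in range(v.shape[1])]


def validate_path(decoded: "list[int] | np.ndarray", n_cities: int) -> bool:
    """A decoding is a valid tour iff it is a permutation of all cities."""
    return sorted(decoded) == list(range(n_cities))


@dataclass(frozen=True)
class SolveResult:
    """Outcome of one annealing run; ``path`` is None for invalid decodings."""

    path: tuple[int, ...] | None
    valid: bool
    converged: bool
    sweeps: int
    activities: np.ndarray
    invalid_reason: str | None = None

    def tour_length(self, d: np.ndarray, cyclic: bool = False) -> float:
        if self.path is None:
            raise ValueError("no valid path to measure")
        return path_length(d, self.path, cyclic)


def path_length(
    d: np.ndarray, path: "tuple[int, ...] | list[int]", cyclic: bool = False
) -> float:
    d = np.asarray(d, dtype=float)
    total = sum(d[a, b] for a, b in zip(path, path[1:]))
    if cyclic:
        total += d[path[-1], path[0]]
    return float(total)


def solve(
    d: np.ndarray,
    params: SolverParams = SolverParams(),
    rng: np.random.Generator | int | None = None,
) -> SolveResult:
    """Anneal one randomly initialized network and decode its tour.

    City rows are updated sequentially in a freshly shuffled order each
    sweep; the sweep loop stops when the largest single-activity change
    drops below ``params.tol`` (with the temperature already at its working
    value) or after ``params.max_sweeps``.  Non-convergent or invalidly
    decoded runs yield ``valid=False`` with a diagnostic reason rather than
    an exception.
    """
    d = check_distance_matrix(d)
    n = d.shape[0]
    if params.scale_distances and d.max() > 0:
        d = d / d.max() * params.distance_scale
    rng = np.random.default_rng(rng)
    v = 0.5 + rng.uniform(-params.init_half_width, params.init_half_width, (n, n))
    T = params.anneal_from
    converged = False
    sweeps = 0
    for sweeps in range(1, params.max_sweeps + 1):
        change = 0.0
        for X in rng.permutation(n):
            S = _neighbor_sum(v, params.cyclic_positions)
            E = params.d_p * (v.sum(axis=0) - v[X]) + d[X] @ S
            logits = -E / T
            logits -= logits.max()
            row = np.exp(logits)
            row /= row.sum()
            change = max(change, float(np.abs(row - v[X]).max()))
            v[X] = row
        at_working_T = T <= params.temperature
        T = max(T * params.cooling, params.temperature)
        if change < params.tol and at_working_T:
            converged = True
            break
    decoded = decode(v)
    if not converged:
        return SolveResult(None, False, False, sweeps, v, "did not converge")
    if not validate_path(decoded, n):
        return SolveResult(None, False, True, sweeps, v, "decoding is not a permutation")
    return SolveResult(tuple(decoded), True, True, sweeps, v)


def brute_force_optimum(
    d: np.ndarray, cyclic: bool = False
) -> tuple[tuple[int, ...], float]:
    """Exhaustive-search shortest tour; tractable for n <= ~9.

    For cyclic tours the first city is fixed at 0 (rotations are
    equivalent); open-chain tours enumerate all orderings, relying on
    reversal symmetry only through the comparison order.
    """
    d = check_distance_matrix(d)
    n = d.shape[0]
    best_path, best_len = None, np.inf
    starts = (
        itertools.permutations(range(1, n)) if cyclic else itertools.permutations(range(n))
    )
    for perm in starts:
        p = (0, *perm) if cyclic else perm
        length = path_length(d, p, cyclic=cyclic)
        if length < best_len:
            best_path, best_len = p, length
    return best_path, float(best_len)
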