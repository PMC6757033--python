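"""Pluggable QUBO solvers for the neighbourhood subproblems.

``solve_exact`` enumerates the feasible one-hot product space directly
(Π|Θ_i| points rather than 2^n bitstrings) and plays the role of the
paper-style exact QUBO solver; ``solve_sa`` is a single-spin-flip simulated
annealer over the full binary space, the desk-scale stand-in for a quantum
annealing device.  ``brute_force_neighbourhood`` is the independent
direct-energy oracle that evaluates the molecular energy at every
neighbourhood grid point.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .neighbourhoods import NeighbourhoodSpec
from .qubo import QuboProblem

MAX_ENUMERATION = 10 ** 7


@dataclass
class SolverResult:
    x: np.ndarray
    objective: float
    samples: int
    feasible: bool


def solve_exact(qubo: QuboProblem) -> SolverResult:
    """Global optimum over all feasible one-hot assignments.

    Enumerates the S_k = Π|Θ_i| product space in lexicographic order of
    the angle-slot tuple; ties keep the lexicographically smallest tuple.
    Deterministic.
    """
    spec = qubo.spec
    sizes = [len(spec.angles[i]) for i in spec.torsions]
    s_k = int(np.prod(sizes))
    if s_k > MAX_ENUMERATION:
        raise ValueError(f"neighbourhood size {s_k} exceeds the exact "
                         f"solver's bound {MAX_ENUMERATION}")
    # flat variable index of (torsion rank, slot); raw coefficients, so no
    # penalty cancellation enters the optimum's value
    starts = np.concatenate(([0], np.cumsum(sizes)[:-1]))
    h = qubo.linear
    j = qubo.quadratic
    best_obj = np.inf
    best_combo = None
    for combo in product(*(range(sz) for sz in sizes)):
        idx = starts + np.array(combo)
        obj = h[idx].sum() + 0.5 * j[np.ix_(idx, idx)].sum()
        if obj < best_obj:
            best_obj = obj
            best_combo = combo
    x = np.zeros(qubo.n_variables, dtype=int)
    x[starts + np.array(best_combo)] = 1
    return SolverResult(x=x, objective=float(best_obj), samples=s_k,
                        feasible=True)


@dataclass
class SaSchedule:
    """Geometric inverse-temperature ramp for the simulated annealer."""

    beta_min: float = 0.1
    beta_max: float = 50.0
    n_sweeps: int = 2000

    def betas(self) -> np.ndarray:
        return np.geomspace(self.beta_min, self.beta_max, self.n_sweeps)


def _is_one_hot(x: np.ndarray, sizes) -> bool:
    pos = 0
    for sz in sizes:
        if x[pos:pos + sz].sum() != 1:
            return False
        pos += sz
    return True


def solve_sa(qubo: QuboProblem, schedule: SaSchedule | None = None,
             n_reads: int = 25,
             rng: np.random.Generator | None = None) -> SolverResult:
    """Best feasible sample over ``n_reads`` Metropolis anneals.

    Single-spin-flip dynamics over the full 2^n binary space with the
    one-hot constraints enforced only through the penalty; the best
    feasible (one-hot) state visited across all reads is returned.  With no
    feasible state found, ``feasible`` is False and the caller keeps its
    incumbent.  Deterministic for a fixed rng seed.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be at least 1")
    if schedule is None:
        schedule = SaSchedule()
    if rng is None:
        rng = np.random.default_rng()
    spec = qubo.spec
    sizes = [len(spec.angles[i]) for i in spec.torsions]
    n = qubo.n_variables
    h, jmat, _ = qubo.folded()
    betas = schedule.betas()

    best_obj = np.inf
    best_x = None
    samples = 0
    for _ in range(n_reads):
        x = rng.integers(0, 2, size=n).astype(float)
        obj = x @ h + 0.5 * x @ jmat @ x
        for beta in betas:
            order = rng.permutation(n)
            logu = np.log(rng.random(n))
            for a, lu in zip(order, logu):
                delta = (1.0 - 2.0 * x[a]) * (h[a] + jmat[a] @ x)
                if delta <= 0 or -beta * delta > lu:
                    x[a] = 1.0 - x[a]
                    obj += delta
            samples += 1
            if obj < best_obj and _is_one_hot(x, sizes):
                best_obj = obj
                best_x = x.copy()
    if best_x is None:
        return SolverResult(x=np.zeros(n, dtype=int), objective=np.inf,
                            samples=samples, feasible=False)
    xi = best_x.astype(int)
    # re-evaluate exactly (the incremental folded objective carries the
    # penalty's rounding; the penalty term is zero for a feasible state)
    return SolverResult(x=xi, objective=qubo.objective(xi),
                        samples=samples, feasible=True)


def brute_force_neighbourhood(spec: NeighbourhoodSpec, energy_fn,
                              t_incumbent: np.ndarray) -> tuple:
    """Direct-energy oracle: evaluate every neighbourhood grid point.

    ``energy_fn(t)`` must return the molecular energy of a full torsion
    vector (and do its own evaluation accounting).  Returns the minimising
    torsion vector and its energy; ties keep the lexicographically
    smallest slot tuple.
    """
    sizes = [len(spec.angles[i]) for i in spec.torsions]
    s_k = int(np.prod(sizes))
    if s_k > MAX_ENUMERATION:
        raise ValueError("neighbourhood too large for brute force")
    best_e = np.inf
    best_t = None
    t = np.array(t_incumbent, dtype=float)
    for combo in product(*(range(sz) for sz in sizes)):
        for i, k in zip(spec.torsions, combo):
            t[i] = spec.angles[i][k]
        e = energy_fn(t)
        if e < best_e:
            best_e = e
            best_t = t.copy()
    return best_t, float(best_e)


def exhaustive_minimum(energy_fn, grid_values: np.ndarray, m: int,
                       limit: int = 10 ** 6) -> tuple:
    """Global grid minimum by full d^M enumeration (small systems only)."""
    d = len(grid_values)
    if d ** m > limit:
        raise ValueError(f"search space d^M = {d ** m} exceeds {limit}")
    best_e = np.inf
    best_t = None
    for combo in product(range(d), repeat=m):
        t = grid_values[list(combo)]
        e = energy_fn(t)
        if e < best_e:
            best_e = e
            best_t = t
    return np.asarray(best_t, dtype=float), float(best_e)
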