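"""Conformational search drivers: VND, single-torsion LS, and LS–VND.

Variable neighbourhood descent iterates: sample a 2-torsion-dependent
neighbourhood of the incumbent, pre-evaluate its QUBO coefficients, solve
the QUBO, decode, and accept the decoded vector only on a strict energy
decrease.  The run stops after B iterations, after A consecutive
non-improving iterations, or as soon as the energy is within a tolerance
(default 0.1 kcal/mol) of a supplied reference target.

Local search (LS) is the degenerate single-torsion neighbourhood: steepest
descent over all M×d single-angle moves, terminating at a single-torsion
local optimum.  LS–VND runs LS first and hands its result to VND.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .energy import EnergyLedger, EnergyModel, qubo_coefficients, total_energy
from .molecule import AngleGrid, MolecularSystem, RigidBodyGraph
from .neighbourhoods import NeighbourhoodSampler
from .qubo import build_qubo, choose_penalty, decode_solution
from .solvers import SaSchedule, solve_exact, solve_sa


@dataclass
class RunConfig:
    """Tunable parameters of one search run.

    d : grid resolution (angles per torsion, 2π/d spacing).
    s : variable budget per QUBO, Σ|Θ_i| ≤ s.
    A : maximum consecutive non-improving iterations before stopping.
    B : maximum iterations.
    gamma, penalty_floor : one-hot penalty p = γ·(coefficient range),
        floored (kcal/mol).
    target_energy, target_tol : optional early stop when the best energy is
        within target_tol (kcal/mol) of the reference target.
    """

    d: int = 12
    s: int = 24
    A: int = 10
    B: int = 200
    gamma: float = 2.0
    penalty_floor: float = 1.0
    seed: int = 0
    solver: str = "exact"
    target_energy: float | None = None
    target_tol: float = 0.1
    sa_schedule: SaSchedule = field(default_factory=SaSchedule)
    sa_reads: int = 25

    def __post_init__(self):
        if self.d < 2 or self.s < 2 or self.A < 1 or self.B < 1:
            raise ValueError("require d ≥ 2, s ≥ 2, A ≥ 1, B ≥ 1")
        if self.solver not in ("exact", "sa"):
            raise ValueError(f"unknown solver {self.solver!r}")


@dataclass
class SearchResult:
    best_t: np.ndarray
    best_energy: float
    iterations: int
    energy_evaluations: int
    wall_time: float
    trace: list


def random_initial_solution(grid: AngleGrid, m: int,
                            rng: np.random.Generator) -> np.ndarray:
    """Uniform random torsion vector on the grid."""
    return grid.values[rng.integers(0, grid.d, size=m)]


def _target_reached(config: RunConfig, energy: float) -> bool:
    return (config.target_energy is not None
            and energy <= config.target_energy + config.target_tol)


def vnd(system: MolecularSystem, graph: RigidBodyGraph, config: RunConfig,
        t_init: np.ndarray | None = None,
        model: EnergyModel | None = None,
        ledger: EnergyLedger | None = None,
        rng: np.random.Generator | None = None) -> SearchResult:
    """Variable neighbourhood descent from ``t_init`` (random if omitted)."""
    start = time.perf_counter()
    if model is None:
        model = EnergyModel(system)
    if ledger is None:
        ledger = EnergyLedger()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    grid = AngleGrid.uniform(config.d)
    if t_init is None:
        t_init = random_initial_solution(grid, system.n_torsions, rng)
    t = np.array(t_init, dtype=float)

    base_count = ledger.count
    best_e = total_energy(system, graph, t, model, ledger)
    trace = [best_e]
    sampler = NeighbourhoodSampler(graph, grid, config.s, rng)
    no_improve = 0
    iterations = 0
    for _ in range(config.B):
        if _target_reached(config, best_e) or no_improve >= config.A:
            break
        iterations += 1
        spec = sampler.next_spec(t)
        coeffs = qubo_coefficients(system, graph, spec, t, model, ledger)
        p = choose_penalty(coeffs, gamma=config.gamma,
                           floor=config.penalty_floor)
        problem = build_qubo(coeffs, p)
        if config.solver == "exact":
            result = solve_exact(problem)
        else:
            result = solve_sa(problem, schedule=config.sa_schedule,
                              n_reads=config.sa_reads, rng=rng)
        improved = False
        if result.feasible:
            cand_t = decode_solution(result.x, spec, t)
            cand_e = problem.frozen_constant + result.objective
            if cand_e < best_e:
                t = cand_t
                best_e = cand_e
                improved = True
        no_improve = 0 if improved else no_improve + 1
        trace.append(best_e)
    return SearchResult(best_t=t, best_energy=best_e, iterations=iterations,
                        energy_evaluations=ledger.count - base_count,
                        wall_time=time.perf_counter() - start, trace=trace)


def local_search(system: MolecularSystem, graph: RigidBodyGraph,
                 config: RunConfig, t_init: np.ndarray | None = None,
                 model: EnergyModel | None = None,
                 ledger: EnergyLedger | None = None,
                 rng: np.random.Generator | None = None) -> SearchResult:
    """Steepest-descent single-torsion local search.

    Each sweep evaluates every alternative angle of every torsion (M·(d−1)
    energy evaluations) and takes the single best strictly improving move;
    the run ends when no neighbouring solution is lower, i.e. at a
    single-torsion local optimum.
    """
    start = time.perf_counter()
    if model is None:
        model = EnergyModel(system)
    if ledger is None:
        ledger = EnergyLedger()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    grid = AngleGrid.uniform(config.d)
    m = system.n_torsions
    if t_init is None:
        t_init = random_initial_solution(grid, m, rng)
    t = np.array(t_init, dtype=float)

    base_count = ledger.count
    best_e = total_energy(system, graph, t, model, ledger)
    trace = [best_e]
    sweeps = 0
    while not _target_reached(config, best_e):
        sweeps += 1
        move = None
        move_e = best_e
        for i in range(m):
            current = t[i]
            for theta in grid.values:
                if theta == current:
                    continue
                t[i] = theta
                e = total_energy(system, graph, t, model, ledger)
                if e < move_e:
                    move_e = e
                    move = (i, theta)
            t[i] = current
        if move is None:
            break
        t[move[0]] = move[1]
        best_e = move_e
        trace.append(best_e)
    return SearchResult(best_t=t, best_energy=best_e, iterations=sweeps,
                        energy_evaluations=ledger.count - base_count,
                        wall_time=time.perf_counter() - start, trace=trace)


def ls_vnd(system: MolecularSystem, graph: RigidBodyGraph, config: RunConfig,
           t_init: np.ndarray | None = None,
           model: EnergyModel | None = None,
           ledger: EnergyLedger | None = None,
           rng: np.random.Generator | None = None) -> SearchResult:
    """LS followed by VND from the LS optimum (shared ledger and rng)."""
    start = time.perf_counter()
    if model is None:
        model = EnergyModel(system)
    if ledger is None:
        ledger = EnergyLedger()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    ls = local_search(system, graph, config, t_init=t_init, model=model,
                      ledger=ledger, rng=rng)
    vn = vnd(system, graph, config, t_init=ls.best_t, model=model,
             ledger=ledger, rng=rng)
    return SearchResult(best_t=vn.best_t, best_energy=vn.best_energy,
                        iterations=ls.iterations + vn.iterations,
                        energy_evaluations=(ls.energy_evaluations
                                            + vn.energy_evaluations),
                        wall_time=time.perf_counter() - start,
                        trace=ls.trace + vn.trace[1:])
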