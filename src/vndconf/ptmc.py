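"""Parallel tempering Monte Carlo baseline and reference generator.

A ladder of replicas at geometrically spaced temperatures runs discrete
single-torsion Metropolis dynamics on the angle grid; adjacent replicas
periodically attempt configuration exchanges with the standard
replica-exchange acceptance rule.  The lowest energy ever visited by any
replica is the search result.  Long multi-seed runs supply the *reference*
energies against which success rates and residuals are measured.

The ladder defaults (8 replicas, kT from 0.2 to 5 kcal/mol, a swap attempt
every sweep) are documented reconstructions: the original ladder is not
available in machine-readable form.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .energy import EnergyLedger, EnergyModel, total_energy
from .molecule import AngleGrid, MolecularSystem, RigidBodyGraph
from .search import SearchResult, random_initial_solution


@dataclass
class PtmcConfig:
    d: int = 12
    n_replicas: int = 8
    kt_min: float = 0.2
    kt_max: float = 5.0
    sweeps: int = 500
    swap_interval: int = 1
    seed: int = 0
    target_energy: float | None = None
    target_tol: float = 0.1

    def __post_init__(self):
        if self.n_replicas < 1 or self.sweeps < 1:
            raise ValueError("need at least one replica and one sweep")
        if not 0 < self.kt_min <= self.kt_max:
            raise ValueError("require 0 < kt_min ≤ kt_max")

    def temperatures(self) -> np.ndarray:
        if self.n_replicas == 1:
            return np.array([self.kt_min])
        return np.geomspace(self.kt_min, self.kt_max, self.n_replicas)


@dataclass
class Replica:
    t: np.ndarray
    energy: float
    kt: float


@dataclass
class ReplicaLadder:
    replicas: list = field(default_factory=list)

    def __post_init__(self):
        kts = [r.kt for r in self.replicas]
        if any(b <= a for a, b in zip(kts, kts[1:])):
            raise ValueError("temperatures must be strictly increasing")


def mc_sweep(replica: Replica, system: MolecularSystem,
             graph: RigidBodyGraph, grid: AngleGrid, model: EnergyModel,
             rng: np.random.Generator,
             ledger: EnergyLedger | None = None) -> float:
    """One Metropolis sweep: M single-torsion proposals, in torsion order.

    Each proposal draws a uniformly random grid angle for the torsion and
    accepts with probability min(1, exp(−ΔU/kT)).  Returns the lowest
    energy seen during the sweep.
    """
    m = system.n_torsions
    lowest = replica.energy
    for i in range(m):
        old = replica.t[i]
        replica.t[i] = grid.values[rng.integers(0, grid.d)]
        e_new = total_energy(system, graph, replica.t, model, ledger)
        delta = e_new - replica.energy
        if delta <= 0 or rng.random() < np.exp(-delta / replica.kt):
            replica.energy = e_new
            lowest = min(lowest, e_new)
        else:
            replica.t[i] = old
    return lowest


def replica_swap(ladder: ReplicaLadder, rng: np.random.Generator) -> int:
    """Attempt adjacent-pair exchanges bottom-up; returns acceptances.

    The exchange of replicas at inverse temperatures β_i > β_j with
    energies U_i, U_j is accepted with probability
    min(1, exp((β_i − β_j)(U_i − U_j))), which preserves the joint
    extended-ensemble distribution.
    """
    reps = ladder.replicas
    accepted = 0
    for i in range(len(reps) - 1):
        lo, hi = reps[i], reps[i + 1]
        log_ratio = (1.0 / lo.kt - 1.0 / hi.kt) * (lo.energy - hi.energy)
        if log_ratio >= 0 or rng.random() < np.exp(log_ratio):
            lo.t, hi.t = hi.t, lo.t
            lo.energy, hi.energy = hi.energy, lo.energy
            accepted += 1
    return accepted


def ptmc_search(system: MolecularSystem, graph: RigidBodyGraph,
                config: PtmcConfig, model: EnergyModel | None = None,
                ledger: EnergyLedger | None = None,
                rng: np.random.Generator | None = None) -> SearchResult:
    """Run the ladder and return the lowest energy any replica visited."""
    start = time.perf_counter()
    if model is None:
        model = EnergyModel(system)
    if ledger is None:
        ledger = EnergyLedger()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    grid = AngleGrid.uniform(config.d)
    m = system.n_torsions
    base_count = ledger.count

    replicas = []
    for kt in config.temperatures():
        t = random_initial_solution(grid, m, rng)
        e = total_energy(system, graph, t, model, ledger)
        replicas.append(Replica(t=t, energy=e, kt=float(kt)))
    ladder = ReplicaLadder(replicas=replicas)

    best_t = min(replicas, key=lambda r: r.energy).t.copy()
    best_e = min(r.energy for r in replicas)
    trace = [best_e]
    sweeps_done = 0
    for sweep in range(config.sweeps):
        if (config.target_energy is not None
                and best_e <= config.target_energy + config.target_tol):
            break
        sweeps_done += 1
        for rep in ladder.replicas:
            low = mc_sweep(rep, system, graph, grid, model, rng, ledger)
            if rep.energy < best_e:
                best_e = rep.energy
                best_t = rep.t.copy()
        if (sweep + 1) % config.swap_interval == 0:
            replica_swap(ladder, rng)
        trace.append(best_e)
    return SearchResult(best_t=best_t, best_energy=best_e,
                        iterations=sweeps_done,
                        energy_evaluations=ledger.count - base_count,
                        wall_time=time.perf_counter() - start, trace=trace)


def generate_reference(system: MolecularSystem, graph: RigidBodyGraph,
                       config: PtmcConfig, n_seeds: int = 3,
                       model: EnergyModel | None = None) -> tuple:
    """Reference conformation: best of several independent long PTMC runs.

    The pooled minimum over ``n_seeds`` runs stands in for the absolute
    grid minimum; it uses the same potential energy model as the searches
    it calibrates.  Returns ``(torsion_vector, energy)``.
    """
    if model is None:
        model = EnergyModel(system)
    best = None
    for k in range(n_seeds):
        cfg = PtmcConfig(**{**config.__dict__,
                            "seed": config.seed + 7919 * k,
                            "target_energy": None})
        res = ptmc_search(system, graph, cfg, model=model)
        if best is None or res.best_energy < best[1]:
            best = (res.best_t, res.best_energy)
    return best
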