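"""Benchmark harness and performance metrics.

A run *succeeds* when its best energy is within 1 kcal/mol (roughly
chemical accuracy) of the reference conformation's energy; the *residual*
is the energy gap to the reference, optionally normalised by atom count.
Percentiles use the nearest-rank convention for determinism.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .energy import EnergyModel
from .molecule import AngleGrid, MolecularSystem, partition_rigid_bodies
from .ptmc import PtmcConfig, generate_reference, ptmc_search
from .search import RunConfig, local_search, ls_vnd, vnd
from .solvers import exhaustive_minimum

SUCCESS_THRESHOLD = 1.0  # kcal/mol, chemical accuracy

_METHODS = {"vnd": vnd, "ls": local_search, "lsvnd": ls_vnd}


def success_rate(run_energies, reference_energy: float,
                 threshold: float = SUCCESS_THRESHOLD) -> float:
    """Fraction of runs within ``threshold`` kcal/mol of the reference.

    The boundary counts as a success (≤ convention).
    """
    energies = np.asarray(run_energies, dtype=float)
    if energies.size == 0:
        raise ValueError("need at least one run")
    return float(np.mean(energies - reference_energy <= threshold))


def residuals(run_energy: float, reference_energy: float,
              n_atoms: int) -> tuple:
    """(residual, normalised residual) of one run, kcal/mol."""
    if n_atoms < 1:
        raise ValueError("n_atoms must be positive")
    r = run_energy - reference_energy
    return r, r / n_atoms


def nearest_rank(values, q: float) -> float:
    """q-th percentile by the nearest-rank method (q in (0, 100])."""
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("empty sample")
    rank = max(1, math.ceil(q / 100.0 * v.size))
    return float(v[rank - 1])


@dataclass
class BenchmarkTable:
    """Per method × molecule summary rows (one pandas DataFrame)."""

    frame: pd.DataFrame

    def __post_init__(self):
        for _, row in self.frame.iterrows():
            if not (row["residual_min"] <= row["residual_p50"]
                    <= row["residual_p75"]):
                raise ValueError("percentiles out of order")
            if not 0.0 <= row["success_rate"] <= 1.0:
                raise ValueError("success rate outside [0, 1]")


def reference_energy_for(system: MolecularSystem, config: RunConfig,
                         ptmc_config: PtmcConfig | None = None,
                         exhaustive_limit: int = 10 ** 5,
                         model: EnergyModel | None = None) -> float:
    """Reference energy: exhaustive d^M minimum when affordable, else PTMC."""
    graph = partition_rigid_bodies(system)
    if model is None:
        model = EnergyModel(system)
    grid = AngleGrid.uniform(config.d)
    m = system.n_torsions
    if config.d ** m <= exhaustive_limit:
        from .molecule import build_coordinates

        def efn(t):
            return model.total(build_coordinates(system, graph, t))

        _, e = exhaustive_minimum(efn, grid.values, m, limit=exhaustive_limit)
        return e
    if ptmc_config is None:
        ptmc_config = PtmcConfig(d=config.d, sweeps=1500,
                                 seed=config.seed + 101)
    _, e = generate_reference(system, graph, ptmc_config, model=model)
    return e


def run_benchmark(molecules: dict, methods, config: RunConfig,
                  n_runs: int, seeds=None, references: dict | None = None,
                  ptmc_config: PtmcConfig | None = None) -> BenchmarkTable:
    """Seeded multi-run comparison of search methods over molecules.

    ``molecules`` maps a label to a MolecularSystem.  ``references`` maps
    labels to reference energies; missing references are computed
    (exhaustive enumeration when the grid is small, long PTMC otherwise).
    Each run stops early once within ``config.target_tol`` of its
    reference.  The whole table is a pure function of (config, seeds).
    """
    if seeds is None:
        seeds = list(range(n_runs))
    if len(seeds) < n_runs:
        raise ValueError("need one seed per run")
    if ptmc_config is None:
        ptmc_config = PtmcConfig(d=config.d, seed=config.seed)
    rows = []
    for label, system in molecules.items():
        graph = partition_rigid_bodies(system)
        model = EnergyModel(system)
        if references is not None and label in references:
            ref = references[label]
        else:
            ref = reference_energy_for(system, config,
                                       ptmc_config=ptmc_config, model=model)
        for method in methods:
            energies, evals, times = [], [], []
            for r in range(n_runs):
                child = np.random.SeedSequence(
                    [seeds[r], zlib.crc32(label.encode()) % (2 ** 31),
                     zlib.crc32(method.encode()) % (2 ** 31)])
                rng = np.random.default_rng(child)
                if method == "ptmc":
                    pc = PtmcConfig(**{**ptmc_config.__dict__,
                                       "seed": seeds[r],
                                       "target_energy": ref,
                                       "target_tol": config.target_tol})
                    res = ptmc_search(system, graph, pc, model=model,
                                      rng=rng)
                else:
                    rc = RunConfig(**{**config.__dict__,
                                      "seed": seeds[r],
                                      "target_energy": ref})
                    res = _METHODS[method](system, graph, rc, model=model,
                                           rng=rng)
                energies.append(res.best_energy)
                evals.append(res.energy_evaluations)
                times.append(res.wall_time)
            res_vals = [e - ref for e in energies]
            norm_vals = [r_ / system.n_atoms for r_ in res_vals]
            rows.append({
                "molecule": label,
                "method": method,
                "n_runs": n_runs,
                "reference_energy": ref,
                "success_rate": success_rate(energies, ref),
                "mean_energy_evaluations": float(np.mean(evals)),
                "residual_min": min(res_vals),
                "residual_p50": nearest_rank(res_vals, 50),
                "residual_p75": nearest_rank(res_vals, 75),
                "norm_residual_min": min(norm_vals),
                "norm_residual_p50": nearest_rank(norm_vals, 50),
                "norm_residual_p75": nearest_rank(norm_vals, 75),
                "tts_min": min(times),
                "tts_p50": nearest_rank(times, 50),
                "tts_p75": nearest_rank(times, 75),
            })
    return BenchmarkTable(frame=pd.DataFrame(rows))
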