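"""File formats and run configuration.

Atom indices are 1-based in all user-facing files (XYZ/SDF convention) and
0-based internally; angles are degrees at the file/CLI boundary and
radians internally.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import yaml

from .molecule import MolecularSystem
from .ptmc import PtmcConfig
from .search import RunConfig
from .solvers import SaSchedule

log = logging.getLogger("vndconf")


class ParseError(ValueError):
    pass


def read_xyz(path) -> tuple:
    """Read a standard XYZ file; returns (elements, coords in Å)."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ParseError(f"{path}, line 1: expected an atom count")
    if len(lines) < n + 2:
        raise ParseError(f"{path}: header says {n} atoms but only "
                         f"{len(lines) - 2} record lines present")
    elements, coords = [], []
    for ln, line in enumerate(lines[2:2 + n], start=3):
        parts = line.split()
        if len(parts) < 4:
            raise ParseError(f"{path}, line {ln}: expected "
                             "'element x y z'")
        try:
            xyz = [float(p) for p in parts[1:4]]
        except ValueError:
            raise ParseError(f"{path}, line {ln}: bad coordinate")
        elements.append(parts[0])
        coords.append(xyz)
    return tuple(elements), np.array(coords)


def write_xyz(path, elements, coords, comment: str = "") -> None:
    coords = np.asarray(coords, dtype=float)
    with open(path, "w") as fh:
        fh.write(f"{len(elements)}\n{comment}\n")
        for el, (x, y, z) in zip(elements, coords):
            fh.write(f"{el} {x:.8f} {y:.8f} {z:.8f}\n")


def read_bonds(path) -> frozenset:
    """Bond list file: one `i j` pair per line, 1-based atom indices."""
    bonds = set()
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.split("#")[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ParseError(f"{path}, line {ln}: expected two indices")
            i, j = int(parts[0]) - 1, int(parts[1]) - 1
            bonds.add(frozenset((i, j)))
    return frozenset(bonds)


def read_torsions(path) -> tuple:
    """Torsion-spec file: ordered `i j` pairs, 1-based atom indices."""
    torsions = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.split("#")[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ParseError(f"{path}, line {ln}: expected two indices")
            torsions.append((int(parts[0]) - 1, int(parts[1]) - 1))
    return tuple(torsions)


def write_bonds(path, bonds) -> None:
    with open(path, "w") as fh:
        for b in sorted(tuple(sorted(x)) for x in bonds):
            fh.write(f"{b[0] + 1} {b[1] + 1}\n")


def read_sdf(path) -> tuple:
    """Read the first MOL (V2000) block of an SDF file.

    Returns (elements, coords, bonds); torsions are supplied separately
    through a torsion-spec file.  Charge/isotope fields are ignored with a
    warning.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 4:
        raise ParseError(f"{path}: truncated MOL block")
    counts = lines[3]
    try:
        n_atoms = int(counts[0:3])
        n_bonds = int(counts[3:6])
    except ValueError:
        raise ParseError(f"{path}, line 4: bad counts line {counts!r}")
    if len(lines) < 4 + n_atoms + n_bonds:
        raise ParseError(f"{path}: counts line promises {n_atoms} atoms / "
                         f"{n_bonds} bonds but the block is shorter")
    if n_atoms > 1 and n_bonds == 0:
        raise ParseError(f"{path}: multi-atom molecule with no bonds")
    elements, coords = [], []
    for ln, line in enumerate(lines[4:4 + n_atoms], start=5):
        try:
            x, y, z = float(line[0:10]), float(line[10:20]), float(line[20:30])
            el = line[31:34].strip()
        except (ValueError, IndexError):
            raise ParseError(f"{path}, line {ln}: bad atom line")
        charge = line[36:39].strip()
        if charge not in ("", "0"):
            warnings.warn(f"{path}, line {ln}: charge field {charge!r} "
                          "ignored (LJ-only energy model)")
        elements.append(el)
        coords.append((x, y, z))
    bonds = set()
    for ln, line in enumerate(lines[4 + n_atoms:4 + n_atoms + n_bonds],
                              start=5 + n_atoms):
        try:
            i, j = int(line[0:3]) - 1, int(line[3:6]) - 1
        except (ValueError, IndexError):
            raise ParseError(f"{path}, line {ln}: bad bond line")
        bonds.add(frozenset((i, j)))
    return tuple(elements), np.array(coords), frozenset(bonds)


def system_from_files(geometry_path, torsion_path,
                      bonds_path=None) -> MolecularSystem:
    """Assemble a MolecularSystem from XYZ+bonds or SDF, plus torsions."""
    path = str(geometry_path)
    if path.endswith((".sdf", ".mol")):
        elements, coords, bonds = read_sdf(path)
    else:
        elements, coords = read_xyz(path)
        if bonds_path is None:
            raise ValueError("XYZ input needs a bond-list file")
        bonds = read_bonds(bonds_path)
    torsions = read_torsions(torsion_path)
    return MolecularSystem(elements=elements, coords=coords, bonds=bonds,
                           torsion_bonds=torsions)


_RUN_KEYS = {"d", "s", "A", "B", "gamma", "penalty_floor", "seed", "solver",
             "target_energy", "target_tol", "sa_reads"}
_SA_KEYS = {"beta_min", "beta_max", "n_sweeps"}
_PTMC_KEYS = {"d", "n_replicas", "kt_min", "kt_max", "sweeps",
              "swap_interval", "seed"}


def load_config(path) -> tuple:
    """Load a YAML run configuration; returns (RunConfig, PtmcConfig).

    Unknown keys are an error (strict mode); an empty file yields full
    defaults.  All effective parameters are echoed to the log for
    provenance.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ParseError(f"{path}: top level must be a mapping")
    sa = raw.pop("sa", {}) or {}
    ptmc = raw.pop("ptmc", {}) or {}
    for name, given, allowed in (("run", raw, _RUN_KEYS),
                                 ("sa", sa, _SA_KEYS),
                                 ("ptmc", ptmc, _PTMC_KEYS)):
        unknown = set(given) - allowed
        if unknown:
            raise ParseError(f"{path}: unknown {name} keys {sorted(unknown)}")
    schedule = SaSchedule(**sa)
    run = RunConfig(sa_schedule=schedule, **raw)
    ptmc.setdefault("d", run.d)
    ptmc.setdefault("seed", run.seed)
    ptmc_cfg = PtmcConfig(**ptmc)
    log.info("run config: %s", run)
    log.info("ptmc config: %s", ptmc_cfg)
    return run, ptmc_cfg
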