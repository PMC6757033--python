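"""Synthetic molecule generator: chains, stars, and analytic toys.

Provides desk-scale systems with the two rigid-body-graph topologies that
matter for neighbourhood structure — paths (n-alkanes) and high-degree
hubs (star molecules) — plus a two-body toy whose exact torsion landscape
doubles as a test oracle.  Geometries are idealised (C–C 1.54 Å, C–H
1.09 Å, tetrahedral angles); bond lengths and angles never relax.
"""

from __future__ import annotations

import numpy as np

from .energy import EnergyModel
from .molecule import (AngleGrid, MolecularSystem, build_coordinates,
                       partition_rigid_bodies)

CC_BOND = 1.54
CH_BOND = 1.09
TETRAHEDRAL = np.deg2rad(109.47122063449069)


def _unit(v):
    return v / np.linalg.norm(v)


def make_alkane(n_carbons: int) -> MolecularSystem:
    """Idealised all-anti n-alkane C_nH_{2n+2}.

    Carbons come first (indices 0..n−1) in a zig-zag backbone, hydrogens
    after.  Rotatable bonds are the internal C–C bonds excluding the two
    terminal ones (the methyl rotors are discarded), so M = n − 3 and the
    rigid-body graph is a path of M edges.
    """
    n = n_carbons
    if n < 4:
        raise ValueError("need at least 4 carbons for one torsion")
    half = TETRAHEDRAL / 2.0
    sx, h = CC_BOND * np.sin(half), CC_BOND * np.cos(half)
    carbons = np.array([[i * sx, 0.0, (i % 2) * h] for i in range(n)])

    elements = ["C"] * n
    coords = [c for c in carbons]
    bonds = set()
    for i in range(n - 1):
        bonds.add((i, i + 1))

    def add_h(pos):
        elements.append("H")
        coords.append(pos)
        return len(coords) - 1

    half_hch = TETRAHEDRAL / 2.0
    for i in range(n):
        ci = carbons[i]
        if 0 < i < n - 1:
            a = _unit(carbons[i - 1] - ci)
            c = _unit(carbons[i + 1] - ci)
            n1 = _unit(-(a + c))
            n2 = _unit(np.cross(a, c))
            for sign in (+1, -1):
                d = n1 * np.cos(half_hch) + sign * n2 * np.sin(half_hch)
                bonds.add((i, add_h(ci + CH_BOND * d)))
        else:
            nb = carbons[1] if i == 0 else carbons[n - 2]
            a = _unit(nb - ci)
            p = _unit(np.cross(a, [0.0, 1.0, 0.0]))
            q = _unit(np.cross(a, p))
            for psi in np.deg2rad([60.0, 180.0, 300.0]):
                d = (np.cos(TETRAHEDRAL) * a
                     + np.sin(TETRAHEDRAL) * (np.cos(psi) * p
                                              + np.sin(psi) * q))
                bonds.add((i, add_h(ci + CH_BOND * d)))

    torsions = tuple((i, i + 1) for i in range(1, n - 2))
    return MolecularSystem(elements=tuple(elements),
                           coords=np.array(coords),
                           bonds=frozenset(frozenset(b) for b in bonds),
                           torsion_bonds=torsions)


def make_star_molecule(n_arms: int, arm_length: int = 1) -> MolecularSystem:
    """Star molecule: a hub body with ``n_arms`` straight carbon arms.

    Each arm is a chain of ``arm_length`` rigid units (a backbone carbon
    plus one off-axis hydrogen); every hub→arm and intra-arm backbone bond
    is a torsion, so the rigid-body graph has a degree-``n_arms`` hub and
    its incident edges form one maximal 2-torsion-dependent set of size
    ``n_arms``.  Pairwise arm–arm hydrogen contacts create the 2-torsion
    traps that defeat single-torsion local search.

    ``n_arms = 2`` is accepted and simply degenerates to a chain topology.
    """
    if n_arms < 2:
        raise ValueError("need at least 2 arms")
    if arm_length < 1:
        raise ValueError("arm_length must be at least 1")
    elements = ["C", "H"]
    coords = [np.zeros(3), np.array([0.0, 0.0, -CH_BOND])]
    bonds = {(0, 1)}
    torsions = []
    for k in range(n_arms):
        ang = 2 * np.pi * k / n_arms
        e = np.array([np.cos(ang), np.sin(ang), 0.0])
        w1 = np.array([0.0, 0.0, 1.0])
        w2 = _unit(np.cross(w1, e))
        prev = 0
        for j in range(1, arm_length + 1):
            c_idx = len(elements)
            elements.append("C")
            coords.append(j * CC_BOND * e)
            bonds.add((prev, c_idx))
            torsions.append((prev, c_idx))
            # off-axis hydrogen, tilt varies along the arm
            delta = np.deg2rad(35.0 * j)
            d = np.cos(delta) * w1 + np.sin(delta) * w2
            h_idx = len(elements)
            elements.append("H")
            coords.append(np.asarray(coords[c_idx]) + CH_BOND * d)
            bonds.add((c_idx, h_idx))
            prev = c_idx
    return MolecularSystem(elements=tuple(elements),
                           coords=np.array(coords),
                           bonds=frozenset(frozenset(b) for b in bonds),
                           torsion_bonds=tuple(torsions))


def make_two_body_toy(d: int) -> tuple:
    """Two rigid bodies joined by one torsion, plus its exact landscape.

    Returns ``(system, profile)`` where ``profile[k]`` is the molecular
    energy at the k-th angle of the uniform d-grid, computed by direct
    evaluation — an exhaustive oracle for any search method.
    """
    if d < 2:
        raise ValueError("need at least 2 grid points")
    half = TETRAHEDRAL / 2.0
    c0 = np.zeros(3)
    c1 = np.array([CC_BOND, 0.0, 0.0])
    off = np.array([-np.cos(half), 0.0, np.sin(half)])
    elements = ("C", "H", "H", "C", "H", "H")
    coords = np.array([
        c0,
        c0 + CH_BOND * off,
        c0 + CH_BOND * np.array([-np.cos(half), 0.4, -np.sin(half)]),
        c1,
        c1 + CH_BOND * np.array([np.cos(half), 0.0, np.sin(half)]),
        c1 + CH_BOND * np.array([np.cos(half), 0.35, -np.sin(half)]),
    ])
    bonds = {(0, 1), (0, 2), (0, 3), (3, 4), (3, 5)}
    system = MolecularSystem(elements=elements, coords=coords,
                             bonds=frozenset(frozenset(b) for b in bonds),
                             torsion_bonds=((0, 3),))
    graph = partition_rigid_bodies(system)
    model = EnergyModel(system)
    grid = AngleGrid.uniform(d)
    profile = np.array([
        model.total(build_coordinates(system, graph, np.array([theta])))
        for theta in grid.values])
    return system, profile
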