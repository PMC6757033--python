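"""Molecular graph, rigid-body partition, and torsion-driven coordinates.

A molecule is modelled as a fixed-geometry atom graph in which a designated
subset of bonds (the *torsions*) is free to rotate.  Removing the torsion
bonds partitions the atoms into rigid bodies; the bodies and torsions form a
tree, the *rigid-body graph*, whose edges carry the rotational degrees of
freedom.  A conformation is a torsion vector ``t`` of one angle per torsion,
applied as an offset to the reference geometry (``t = 0`` reproduces the
reference exactly).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial.transform import Rotation


class RingTorsionError(ValueError):
    """A designated torsion bond lies on a cycle of the bond graph."""


@dataclass(frozen=True)
class MolecularSystem:
    """Atoms, bonds and designated rotatable bonds of one molecule.

    Parameters
    ----------
    elements : tuple of str
        Element symbol per atom.
    coords : (n_atoms, 3) ndarray
        Reference Cartesian positions in Å.
    bonds : frozenset of frozenset pairs
        Unordered atom-index pairs (0-based).
    torsion_bonds : tuple of (int, int)
        Ordered list of the M rotatable bonds; each must be a bridge of the
        bond graph.
    """

    elements: tuple
    coords: np.ndarray
    bonds: frozenset
    torsion_bonds: tuple

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "elements", tuple(self.elements))
        bonds = frozenset(frozenset(b) for b in self.bonds)
        object.__setattr__(self, "bonds", bonds)
        tb = tuple(tuple(sorted(b)) for b in self.torsion_bonds)
        object.__setattr__(self, "torsion_bonds", tb)
        self._validate()

    def _validate(self):
        n = len(self.elements)
        if self.coords.shape != (n, 3):
            raise ValueError(
                f"coords shape {self.coords.shape} != ({n}, 3)")
        for b in self.bonds:
            if len(b) != 2:
                raise ValueError(f"bond {set(b)} is not an atom pair")
            for a in b:
                if not 0 <= a < n:
                    raise ValueError(f"bond atom index {a} out of range")
        if len(set(self.torsion_bonds)) != len(self.torsion_bonds):
            raise ValueError("torsion bonds must be distinct")
        for u, v in self.torsion_bonds:
            if frozenset((u, v)) not in self.bonds:
                raise ValueError(f"torsion bond ({u}, {v}) is not a bond")
        g = self.bond_graph()
        if n > 1 and not nx.is_connected(g):
            raise ValueError("bond graph is not connected")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def n_torsions(self) -> int:
        """M, the number of rotatable bonds."""
        return len(self.torsion_bonds)

    def bond_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_atoms))
        g.add_edges_from(tuple(b) for b in self.bonds)
        return g


@dataclass(frozen=True)
class RigidBody:
    """A maximal atom set whose internal geometry no torsion can change."""

    id: int
    atom_indices: frozenset


@dataclass
class RigidBodyGraph:
    """Tree of rigid bodies; edges are torsions.

    ``edges[i]`` is a ``(body_a, body_b, torsion_index)`` triple with
    ``body_a`` the root-side (proximal) body.  The root is the body holding
    atom 0, a deterministic convention.
    """

    bodies: list
    edges: list
    root: int
    system: MolecularSystem

    # caches populated lazily
    _tree: nx.Graph = field(default=None, repr=False, compare=False)
    _body_of_atom: np.ndarray = field(default=None, repr=False, compare=False)

    @property
    def n_bodies(self) -> int:
        return len(self.bodies)

    def tree(self) -> nx.Graph:
        if self._tree is None:
            g = nx.Graph()
            g.add_nodes_from(b.id for b in self.bodies)
            for a, b, ti in self.edges:
                g.add_edge(a, b, torsion=ti)
            self._tree = g
        return self._tree

    def body_of_atom(self, atom: int) -> int:
        if self._body_of_atom is None:
            lookup = np.empty(self.system.n_atoms, dtype=int)
            for body in self.bodies:
                for a in body.atom_indices:
                    lookup[a] = body.id
            self._body_of_atom = lookup
        return int(self._body_of_atom[atom])


@dataclass(frozen=True)
class AngleGrid:
    """Discretisation Θ of the torsion circle into d angles in [0, 2π)."""

    values: np.ndarray

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 1 or vals.size == 0:
            raise ValueError("grid must be a non-empty 1-D array")
        if np.any(np.diff(vals) <= 0):
            raise ValueError("grid values must be strictly increasing")
        if vals[0] < 0 or vals[-1] >= 2 * np.pi:
            raise ValueError("grid values must lie in [0, 2π)")

    @property
    def d(self) -> int:
        return self.values.size

    @classmethod
    def uniform(cls, d: int) -> "AngleGrid":
        """Evenly spaced grid θ_k = 2πk/d, k = 0..d−1 (includes 0)."""
        if d < 1:
            raise ValueError("d must be positive")
        return cls(2 * np.pi * np.arange(d) / d)


def partition_rigid_bodies(system: MolecularSystem) -> RigidBodyGraph:
    """Partition the molecule into M+1 rigid bodies joined by the torsions.

    Removing the M torsion bonds from the bond graph must leave exactly M+1
    connected components (each torsion a bridge); the components become the
    bodies and each torsion becomes a tree edge between the two bodies that
    hold its endpoint atoms.

    Raises
    ------
    RingTorsionError
        If any torsion bond lies on a cycle (is not a bridge).
    """
    g = system.bond_graph()
    torsion_set = {frozenset(b) for b in system.torsion_bonds}
    g.remove_edges_from(tuple(b) for b in torsion_set)

    comps = [frozenset(c) for c in nx.connected_components(g)]
    atom_to_comp = {}
    for ci, comp in enumerate(comps):
        for a in comp:
            atom_to_comp[a] = ci
    for u, v in system.torsion_bonds:
        if atom_to_comp[u] == atom_to_comp[v]:
            raise RingTorsionError(
                f"torsion bond ({u}, {v}) lies on a ring: removing it does "
                "not split the molecule, so it cannot rotate freely")
    m = system.n_torsions
    if len(comps) != m + 1:  # unreachable if all torsions are bridges
        raise RingTorsionError(
            f"expected {m + 1} rigid bodies, found {len(comps)}")

    bodies = [RigidBody(i, comp) for i, comp in enumerate(comps)]
    root = atom_to_comp[0]

    # orient each edge proximal→distal via BFS from the root
    tree = nx.Graph()
    tree.add_nodes_from(range(len(bodies)))
    for ti, (u, v) in enumerate(system.torsion_bonds):
        tree.add_edge(atom_to_comp[u], atom_to_comp[v], torsion=ti)
    edges = []
    for a, b in nx.bfs_edges(tree, root):
        edges.append((a, b, tree.edges[a, b]["torsion"]))
    edges.sort(key=lambda e: e[2])
    return RigidBodyGraph(bodies=bodies, edges=edges, root=root,
                          system=system)


def path_torsions(graph: RigidBodyGraph, a: int, b: int) -> list:
    """Torsion indices along the unique tree path from body ``a`` to ``b``.

    The returned list t_ab has m_ab entries in path order; the relative
    placement of the two bodies depends on exactly these torsions.
    """
    tree = graph.tree()
    if a not in tree or b not in tree:
        raise KeyError(f"unknown body id in ({a}, {b})")
    nodes = nx.shortest_path(tree, a, b)
    return [tree.edges[u, v]["torsion"] for u, v in zip(nodes, nodes[1:])]


def _rotation_about_line(point: np.ndarray, axis: np.ndarray,
                         angle: float) -> tuple:
    """Affine map (R, shift) for a right-handed rotation about a line."""
    rot = Rotation.from_rotvec(angle * axis).as_matrix()
    shift = point - rot @ point
    return rot, shift


def build_coordinates(system: MolecularSystem, graph: RigidBodyGraph,
                      t: np.ndarray) -> np.ndarray:
    """Cartesian coordinates (Å) of the conformation with torsion vector t.

    The root body stays at its reference position.  Each torsion rotates its
    distal subtree right-handedly about the bond axis (oriented from the
    proximal to the distal atom) by ``t_i`` relative to the reference, so
    ``t = 0`` reproduces the reference geometry and intra-body distances are
    exactly preserved.
    """
    t = np.asarray(t, dtype=float)
    if t.shape != (system.n_torsions,):
        raise ValueError(
            f"torsion vector length {t.shape} != M={system.n_torsions}")
    ref = system.coords
    out = ref.copy()

    # accumulated affine transform per body, composed root-outward
    transforms = {graph.root: (np.eye(3), np.zeros(3))}
    tree = graph.tree()
    order = list(nx.bfs_edges(tree, graph.root))
    edge_torsion = {(min(a, b), max(a, b)): ti for a, b, ti in graph.edges}
    for a, b in order:
        ti = edge_torsion[(min(a, b), max(a, b))]
        u, v = system.torsion_bonds[ti]
        # proximal atom sits in the parent body a
        if graph.body_of_atom(u) == a:
            prox, dist = u, v
        else:
            prox, dist = v, u
        axis = ref[dist] - ref[prox]
        axis = axis / np.linalg.norm(axis)
        r_loc, s_loc = _rotation_about_line(ref[dist], axis, t[ti])
        r_par, s_par = transforms[a]
        transforms[b] = (r_par @ r_loc, r_par @ s_loc + s_par)

    for body in graph.bodies:
        rot, shift = transforms[body.id]
        idx = sorted(body.atom_indices)
        out[idx] = ref[idx] @ rot.T + shift
    return out


def wrap_angle(theta):
    """Map angles to the canonical torus [0, 2π)."""
    return np.mod(theta, 2 * np.pi)


def random_torsion_vector(grid: AngleGrid, m: int,
                          rng: np.random.Generator) -> np.ndarray:
    """Uniform random torsion vector on the grid (one angle per torsion)."""
    return grid.values[rng.integers(0, grid.d, size=m)]
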