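"""Neighbourhood structures on the rigid-body graph.

A subset 𝒯' of torsion edges is *2-torsion dependent* when contracting all
other edges of the rigid-body tree yields a star graph: every pair of
contracted super-bodies is then separated by at most two of the selected
torsions, so the neighbourhood energy is a quadratic function of the
per-torsion one-hot variables and can be written as a QUBO.

A neighbourhood of the incumbent torsion vector t is given by such a subset
plus a per-torsion angle menu Θ_i ⊆ Θ with total budget s = Σ|Θ_i| (the
variable budget of the binary solver); it contains the S_k = Π|Θ_i|
vectors that differ from t only on the selected torsions, with each t'_i
drawn from Θ_i.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np

from .molecule import AngleGrid, RigidBodyGraph


class NotATreeError(ValueError):
    pass


class NotTwoTorsionDependentError(ValueError):
    pass


def contract_complement(graph: RigidBodyGraph, subset) -> nx.Graph:
    """Contract every tree edge NOT in ``subset``.

    Vertices of the result are frozensets of body ids (the connected
    components of the tree minus the subset edges); edges are the subset
    torsions, stored in the ``torsion`` edge attribute.  For a tree input
    the contraction is again a tree with |subset|+1 vertices.
    """
    subset = set(subset)
    tree = graph.tree()
    kept = nx.Graph()
    kept.add_nodes_from(tree.nodes)
    for u, v, data in tree.edges(data=True):
        if data["torsion"] not in subset:
            kept.add_edge(u, v)
    comp_of = {}
    comps = []
    for comp in nx.connected_components(kept):
        comp = frozenset(comp)
        comps.append(comp)
        for n in comp:
            comp_of[n] = comp
    out = nx.Graph()
    out.add_nodes_from(comps)
    for u, v, data in tree.edges(data=True):
        if data["torsion"] in subset:
            out.add_edge(comp_of[u], comp_of[v], torsion=data["torsion"])
    return out


def is_star(graph: nx.Graph) -> bool:
    """True iff the tree has at most one vertex of degree > 1."""
    n, m = graph.number_of_nodes(), graph.number_of_edges()
    if m != n - 1 or (n > 0 and not nx.is_connected(graph)):
        raise NotATreeError("is_star requires a tree")
    return sum(1 for _, deg in graph.degree if deg > 1) <= 1


def is_two_torsion_dependent(graph: RigidBodyGraph, subset) -> bool:
    """True iff contracting the complement of ``subset`` yields a star."""
    if not subset:
        return False
    return is_star(contract_complement(graph, subset))


def star_center(contracted: nx.Graph):
    """The vertex incident to every edge of a star contraction.

    For a single-edge star either endpoint qualifies; the one containing
    the smallest body id is returned for determinism.
    """
    if contracted.number_of_edges() == 1:
        u, v = next(iter(contracted.edges))
        return min(u, v, key=min)
    for node, deg in contracted.degree:
        if deg == contracted.number_of_edges():
            return node
    raise NotTwoTorsionDependentError("contraction is not a star")


def super_bodies(graph: RigidBodyGraph, subset) -> tuple:
    """Split the contraction into the centre and one leaf per torsion.

    Returns ``(center, leaves)`` where ``center`` is the frozenset of body
    ids of the star centre and ``leaves[i]`` the body ids of the super-body
    joined to the centre by torsion i.
    """
    contracted = contract_complement(graph, subset)
    if not is_star(contracted):
        raise NotTwoTorsionDependentError(
            f"torsion subset {sorted(subset)} is not 2-torsion dependent")
    center = star_center(contracted)
    leaves = {}
    for u, v, data in contracted.edges(data=True):
        leaves[data["torsion"]] = v if u == center else u
    return center, leaves


def _connected_vertex_sets(g: nx.Graph):
    """All non-empty connected vertex sets, each yielded exactly once.

    Sets are enumerated grouped by their minimum vertex (in node order):
    each candidate frontier vertex is either permanently excluded or added,
    so every connected set appears at exactly one recursion leaf.
    """
    order = {v: i for i, v in enumerate(g.nodes)}

    def rec(cur, frontier, forbidden, allowed):
        if not frontier:
            yield frozenset(cur)
            return
        u = min(frontier, key=order.get)
        rest = frontier - {u}
        yield from rec(cur, rest, forbidden | {u}, allowed)
        grown = cur | {u}
        newf = rest | {w for w in g[u]
                       if w in allowed and w not in grown
                       and w not in forbidden}
        yield from rec(grown, newf, forbidden, allowed)

    for v in g.nodes:
        allowed = {w for w in g.nodes if order[w] > order[v]}
        frontier = {w for w in g[v] if w in allowed}
        yield from rec({v}, frontier, set(), allowed)


def enumerate_maximal_subsets(graph: RigidBodyGraph) -> list:
    """All inclusion-maximal 2-torsion-dependent torsion subsets.

    Uses the boundary characterisation: a subset is 2-torsion dependent iff
    it is the edge boundary δ(C) of a connected vertex set C of the tree
    (C becomes the star centre).  Returned as sorted tuples of torsion
    indices, in lexicographic order.
    """
    tree = graph.tree()
    m = tree.number_of_edges()
    if m > 20:
        raise ValueError(
            f"exhaustive enumeration limited to 20 torsions (got {m}); "
            "use sample_neighbourhood for larger molecules")
    if m == 0:
        return []
    candidates = set()
    for c in _connected_vertex_sets(tree):
        boundary = frozenset(
            data["torsion"] for u, v, data in tree.edges(data=True)
            if (u in c) != (v in c))
        if boundary:
            candidates.add(boundary)
    maximal = [s for s in candidates
               if not any(s < o for o in candidates)]
    return sorted(tuple(sorted(s)) for s in maximal)


def are_neighbours(t, t_prime, subset, atol: float = 1e-9) -> bool:
    """True iff the two torsion vectors differ only on ``subset``.

    This is the neighbour relation N_k of the neighbourhood structure with
    torsion subset 𝒯_k (angle menus ignored).
    """
    t = np.asarray(t, float)
    tp = np.asarray(t_prime, float)
    if t.shape != tp.shape:
        raise ValueError("torsion vectors differ in length")
    outside = np.ones(t.size, dtype=bool)
    outside[list(subset)] = False
    diff = np.abs(np.angle(np.exp(1j * (t - tp))))
    return bool(np.all(diff[outside] <= atol))


@dataclass(frozen=True)
class NeighbourhoodSpec:
    """A sampled neighbourhood: torsion subset, angle menus, star centre.

    ``angles[i]`` is the sorted array Θ_i of candidate angles for torsion
    i (always containing the incumbent angle so descent can keep it).
    """

    torsions: tuple
    angles: dict
    center: frozenset

    def __post_init__(self):
        object.__setattr__(self, "torsions", tuple(sorted(self.torsions)))
        for i in self.torsions:
            if len(self.angles[i]) == 0:
                raise ValueError(f"empty angle menu for torsion {i}")

    @property
    def budget(self) -> int:
        """s = Σ|Θ_i|, the number of binary variables."""
        return sum(len(self.angles[i]) for i in self.torsions)

    @property
    def size(self) -> int:
        """S_k = Π|Θ_i|, the number of solutions in the neighbourhood."""
        out = 1
        for i in self.torsions:
            out *= len(self.angles[i])
        return out


def angle_menu_sizes(s: int, m: int, d: int) -> list:
    """Near-equal split of the budget s over m torsions, capped at d.

    The product Π sizes (the neighbourhood size S_k) is maximised by the
    equal split |Θ_i| = s/m; integer remainders go to the first torsions.
    """
    if m < 1:
        raise ValueError("need at least one torsion")
    base, rem = divmod(s, m)
    sizes = [min(d, base + (1 if r < rem else 0)) for r in range(m)]
    if any(sz < 1 for sz in sizes):
        raise ValueError(f"budget s={s} too small for {m} torsions")
    return sizes


def sample_neighbourhood(graph: RigidBodyGraph, phi, t, grid: AngleGrid,
                         s: int, rng: np.random.Generator,
                         start: int = 0) -> NeighbourhoodSpec:
    """Grow a 2-torsion-dependent subset in φ order and draw angle menus.

    Starting from the torsion ``phi[start]``, later torsions in the random
    ordering φ are added greedily while the subset stays 2-torsion
    dependent and has at most ⌊s/2⌋ members (every selected torsion must
    afford at least two angle values).  Each menu Θ_i keeps the incumbent
    angle t_i and fills up with distinct grid values drawn uniformly at
    random, sizes as equal as possible with Σ|Θ_i| ≤ s.
    """
    if s < 2:
        raise ValueError("budget s must be at least 2")
    t = np.asarray(t, float)
    lead = phi[start]
    subset = {lead}
    cap = max(1, s // 2)
    for nxt in list(phi[start + 1:]) + list(phi[:start]):
        if len(subset) >= cap:
            break
        if is_two_torsion_dependent(graph, subset | {nxt}):
            subset.add(nxt)
    torsions = sorted(subset)
    sizes = angle_menu_sizes(s, len(torsions), grid.d)

    angles = {}
    for i, size in zip(torsions, sizes):
        # locate the incumbent on the grid (it must be a grid angle)
        diff = np.abs(np.angle(np.exp(1j * (grid.values - t[i]))))
        inc = int(np.argmin(diff))
        if diff[inc] > 1e-9:
            raise ValueError(f"incumbent angle of torsion {i} not on grid")
        others = np.delete(np.arange(grid.d), inc)
        extra = rng.choice(others, size=size - 1, replace=False)
        idx = np.sort(np.concatenate(([inc], extra)))
        angles[i] = grid.values[idx]
    center, _ = super_bodies(graph, torsions)
    return NeighbourhoodSpec(torsions=tuple(torsions), angles=angles,
                             center=center)


class NeighbourhoodSampler:
    """Stateful φ-order neighbourhood selector used by the VND loop.

    Keeps a random permutation φ of the torsions and a cursor; each call
    grows a neighbourhood led by the cursor torsion, then advances.  When
    every torsion has led once, φ is reshuffled.
    """

    def __init__(self, graph: RigidBodyGraph, grid: AngleGrid, s: int,
                 rng: np.random.Generator):
        self.graph = graph
        self.grid = grid
        self.s = s
        self.rng = rng
        self._m = len(graph.edges)
        self.phi = list(rng.permutation(self._m))
        self.pos = 0

    def next_spec(self, t) -> NeighbourhoodSpec:
        spec = sample_neighbourhood(self.graph, self.phi, t, self.grid,
                                    self.s, self.rng, start=self.pos)
        self.pos += 1
        if self.pos >= self._m:
            self.phi = list(self.rng.permutation(self._m))
            self.pos = 0
        return spec


def brute_force_maximal_subsets(graph: RigidBodyGraph) -> list:
    """Independent oracle: 2^M sweep with the contract-and-star test.

    Exponential; intended for cross-checking ``enumerate_maximal_subsets``
    on small graphs only.
    """
    m = len(graph.edges)
    all_dep = []
    for r in range(1, m + 1):
        for subset in combinations(range(m), r):
            if is_two_torsion_dependent(graph, subset):
                all_dep.append(frozenset(subset))
    maximal = [s for s in all_dep if not any(s < o for o in all_dep)]
    return sorted(tuple(sorted(s)) for s in maximal)
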