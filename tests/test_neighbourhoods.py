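"""Star contraction, 2-torsion dependency, enumeration, and sampling."""

from itertools import product as iproduct
from math import comb, prod

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vndconf import (AngleGrid, are_neighbours, contract_complement,
                     enumerate_maximal_subsets, is_star,
                     is_two_torsion_dependent, make_alkane,
                     make_star_molecule, partition_rigid_bodies,
                     sample_neighbourhood)
from vndconf.molecule import RigidBody, RigidBodyGraph
from vndconf.neighbourhoods import (NeighbourhoodSampler, NotATreeError,
                                    angle_menu_sizes,
                                    brute_force_maximal_subsets)


def graph_from_tree(edges):
    """RigidBodyGraph stub from a list of tree edges (no molecule)."""
    nodes = sorted({v for e in edges for v in e})
    bodies = [RigidBody(i, frozenset()) for i in nodes]
    g = RigidBodyGraph(bodies=bodies,
                       edges=[(a, b, i) for i, (a, b) in enumerate(edges)],
                       root=nodes[0], system=None)
    return g


def path_graph(m):
    return graph_from_tree([(i, i + 1) for i in range(m)])


class TestContract:
    def test_full_subset_keeps_graph(self):
        g = path_graph(3)
        c = contract_complement(g, {0, 1, 2})
        assert c.number_of_nodes() == 4
        assert c.number_of_edges() == 3

    def test_empty_subset_single_vertex(self):
        g = path_graph(3)
        c = contract_complement(g, set())
        assert c.number_of_nodes() == 1
        assert c.number_of_edges() == 0

    def test_vertex_count_identity(self):
        g = path_graph(5)
        for subset in ({0}, {0, 2}, {1, 3, 4}):
            c = contract_complement(g, subset)
            assert c.number_of_nodes() == len(subset) + 1

    def test_boundary_subset_contracts_to_star(self):
        # picking the boundary edges of an inner segment yields a star
        g = path_graph(4)
        c = contract_complement(g, {1, 3})
        assert is_star(c)


class TestIsStar:
    def test_single_edge(self):
        g = nx.path_graph(2)
        assert is_star(g)

    def test_three_edge_path_is_not(self):
        assert not is_star(nx.path_graph(4))

    def test_k14(self):
        assert is_star(nx.star_graph(4))

    def test_non_tree_rejected(self):
        with pytest.raises(NotATreeError):
            is_star(nx.cycle_graph(4))


class TestTwoTorsionDependency:
    def test_worked_example_pairs(self):
        g = path_graph(3)
        assert is_two_torsion_dependent(g, {0, 2})
        assert is_two_torsion_dependent(g, {0, 1})
        assert is_two_torsion_dependent(g, {1, 2})
        assert not is_two_torsion_dependent(g, {0, 1, 2})

    def test_any_single_edge(self):
        g = path_graph(4)
        for i in range(4):
            assert is_two_torsion_dependent(g, {i})

    def test_empty_subset(self):
        assert not is_two_torsion_dependent(path_graph(3), set())


class TestEnumerateMaximal:
    def test_three_edge_path(self):
        assert enumerate_maximal_subsets(path_graph(3)) == [
            (0, 1), (0, 2), (1, 2)]

    @pytest.mark.parametrize("m", [2, 3, 4, 5, 6])
    def test_path_gives_all_pairs(self, m):
        subs = enumerate_maximal_subsets(path_graph(m))
        if m == 2:
            assert subs == [(0, 1)]
        else:
            assert len(subs) == comb(m, 2)
            assert subs == sorted(
                (i, j) for i in range(m) for j in range(i + 1, m))

    def test_star_molecule_single_maximal_hub_set(self):
        system = make_star_molecule(4, arm_length=1)
        graph = partition_rigid_bodies(system)
        subs = enumerate_maximal_subsets(graph)
        assert (0, 1, 2, 3) in subs  # all hub edges jointly optimizable

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(min_value=2, max_value=8), st.integers(0, 10 ** 6))
    def test_matches_brute_force_on_random_trees(self, m, seed):
        rng = np.random.default_rng(seed)
        # random labelled tree via random attachment
        edges = [(int(rng.integers(0, k)), k) for k in range(1, m + 1)]
        g = graph_from_tree(edges)
        assert enumerate_maximal_subsets(g) == brute_force_maximal_subsets(g)

    def test_size_limit(self):
        with pytest.raises(ValueError, match="20"):
            enumerate_maximal_subsets(path_graph(21))


class TestEqualSplit:
    @pytest.mark.parametrize("s", range(4, 31))
    def test_near_equal_split_maximizes_product(self, s):
        for m in (2, 3, 4):
            if s < 2 * m:
                continue
            sizes = angle_menu_sizes(s, m, d=10 ** 6)
            best = prod(sizes)
            # exhaust all compositions of s into m positive parts
            for combo in iproduct(range(1, s + 1), repeat=m - 1):
                if sum(combo) >= s:
                    continue
                parts = list(combo) + [s - sum(combo)]
                assert prod(parts) <= best

    def test_capped_at_grid(self):
        assert angle_menu_sizes(40, 2, d=12) == [12, 12]


class TestSampling:
    def test_spec_invariants(self, alkane6, grid12, rng):
        _, graph, _ = alkane6
        t = grid12.values[rng.integers(0, 12, size=3)]
        for start in range(3):
            phi = list(rng.permutation(3))
            spec = sample_neighbourhood(graph, phi, t, grid12, 8, rng,
                                        start=start)
            assert is_two_torsion_dependent(graph, spec.torsions)
            assert spec.budget <= 8
            assert spec.size == prod(
                len(spec.angles[i]) for i in spec.torsions)
            for i in spec.torsions:
                assert np.any(np.isclose(spec.angles[i], t[i]))

    def test_single_torsion_molecule(self, grid12, rng):
        system = make_alkane(4)
        graph = partition_rigid_bodies(system)
        spec = sample_neighbourhood(graph, [0], np.zeros(1), grid12, 8, rng)
        assert spec.torsions == (0,)
        assert len(spec.angles[0]) == 8
        spec = sample_neighbourhood(graph, [0], np.zeros(1), grid12, 40, rng)
        assert len(spec.angles[0]) == 12  # capped at d

    def test_equal_split_neighbourhood_size(self, alkane6, grid12, rng):
        _, graph, _ = alkane6
        t = np.zeros(3)
        spec = sample_neighbourhood(graph, [0, 2, 1], t, grid12, 8, rng)
        assert len(spec.torsions) == 2
        assert spec.size == 16  # (8/2)^2, the equal-split maximum

    def test_sampler_cycles_and_reshuffles(self, alkane6, grid12, rng):
        _, graph, _ = alkane6
        sampler = NeighbourhoodSampler(graph, grid12, 8, rng)
        t = np.zeros(3)
        leads = [sampler.next_spec(t) for _ in range(6)]
        for spec in leads:
            assert is_two_torsion_dependent(graph, spec.torsions)


class TestNeighbourRelation:
    def test_worked_example(self):
        t = np.deg2rad([5.0, 10.0, 20.0])
        t_yes = np.deg2rad([0.0, 10.0, 90.0])
        t_no = np.deg2rad([5.0, 15.0, 20.0])
        n1 = {0, 2}  # differ only on the first and third torsions
        assert are_neighbours(t, t_yes, n1)
        assert not are_neighbours(t, t_no, n1)

    def test_identical_vectors_always_neighbours(self):
        t = np.deg2rad([5.0, 10.0, 20.0])
        assert are_neighbours(t, t, {1})
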