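"""Lennard-Jones energy, rigid-body decomposition, coefficient counting."""

import networkx as nx
import numpy as np
import pytest

from vndconf import (AngleGrid, EnergyLedger, EnergyModel, ForceFieldParams,
                     body_pair_energy, build_coordinates, combine_params,
                     lj_pair, make_alkane, make_two_body_toy,
                     partition_rigid_bodies, qubo_coefficients,
                     sample_neighbourhood, total_energy)
from vndconf.energy import UnknownElementError
from vndconf.molecule import random_torsion_vector


class TestLjPair:
    def test_minimum_at_sigma(self):
        assert lj_pair(0.3, 3.5, 3.5) == pytest.approx(-0.3, abs=1e-14)

    def test_zero_crossing(self):
        r0 = 3.5 * 2 ** (-1 / 6)
        assert lj_pair(0.3, 3.5, r0) == pytest.approx(0.0, abs=1e-13)

    def test_decays_to_zero_from_below(self):
        rs = np.linspace(3.6, 40.0, 200)
        vals = np.array([lj_pair(0.3, 3.5, r) for r in rs])
        assert np.all(vals < 0)
        assert np.all(np.diff(vals) > 0)  # monotone toward 0 past the well

    def test_nonpositive_distance(self):
        with pytest.raises(ValueError):
            lj_pair(0.3, 3.5, 0.0)


class TestCombineParams:
    def test_same_element_identity(self):
        p = ForceFieldParams.uff()
        eps, sig = combine_params("C", "C", p)
        assert eps == pytest.approx(p.epsilon["C"])
        assert sig == pytest.approx(p.sigma["C"])

    def test_geometric_mean(self):
        p = ForceFieldParams(epsilon={"A": 0.1, "B": 0.4},
                             sigma={"A": 2.0, "B": 8.0})
        eps, sig = combine_params("A", "B", p)
        assert eps == pytest.approx(0.2)
        assert sig == pytest.approx(4.0)

    def test_unknown_element(self):
        with pytest.raises(UnknownElementError, match="Xx"):
            combine_params("Xx", "C", ForceFieldParams.uff())


def _brute_total(system, model, coords):
    """Independent double-loop oracle over included atom pairs."""
    g = system.bond_graph()
    paths = dict(nx.all_pairs_shortest_path_length(g))
    total = 0.0
    n = system.n_atoms
    for i in range(n):
        for j in range(i + 1, n):
            if paths[i].get(j, 99) < model.min_separation:
                continue
            eps, sig = combine_params(system.elements[i],
                                      system.elements[j], model.params)
            total += lj_pair(eps, sig, np.linalg.norm(coords[i] - coords[j]))
    return total


class TestTotalEnergy:
    def test_decomposition_equals_flat_sum(self, alkane6, rng):
        system, graph, model = alkane6
        grid = AngleGrid.uniform(8)
        for _ in range(5):
            t = random_torsion_vector(grid, 3, rng)
            coords = build_coordinates(system, graph, t)
            flat = _brute_total(system, model, coords)
            # regrouped: intra-body + cross-body terms
            regrouped = 0.0
            for body in graph.bodies:
                regrouped += model.intra(coords, body.atom_indices)
            for a in range(graph.n_bodies):
                for b in range(a + 1, graph.n_bodies):
                    regrouped += body_pair_energy(
                        coords, graph.bodies[a], graph.bodies[b], model)
            assert regrouped == pytest.approx(flat, abs=1e-10)
            assert model.total(coords) == pytest.approx(flat, abs=1e-10)

    def test_two_body_toy_matches_all_pairs(self):
        system, profile = make_two_body_toy(8)
        graph = partition_rigid_bodies(system)
        model = EnergyModel(system)
        grid = AngleGrid.uniform(8)
        for k, theta in enumerate(grid.values):
            coords = build_coordinates(system, graph, np.array([theta]))
            assert profile[k] == pytest.approx(
                _brute_total(system, model, coords), abs=1e-10)

    def test_leaf_rotation_locality(self, alkane6):
        system, graph, model = alkane6
        tree = graph.tree()
        # rotate the torsion attached to a leaf body only
        leaf = next(n for n, d in tree.degree if d == 1 and n != graph.root)
        torsion = [ti for a, b, ti in graph.edges if leaf in (a, b)][0]
        t = np.zeros(3)
        t2 = t.copy()
        t2[torsion] = 1.0
        c1 = build_coordinates(system, graph, t)
        c2 = build_coordinates(system, graph, t2)
        for a in range(graph.n_bodies):
            for b in range(a + 1, graph.n_bodies):
                e1 = body_pair_energy(c1, graph.bodies[a], graph.bodies[b],
                                      model)
                e2 = body_pair_energy(c2, graph.bodies[a], graph.bodies[b],
                                      model)
                if leaf in (a, b):
                    continue
                assert e1 == e2  # bit-identical: untouched bodies

    def test_rigid_motion_invariance(self, alkane6, rng):
        system, graph, model = alkane6
        coords = build_coordinates(system, graph, np.array([0.5, 1.0, 2.0]))
        from scipy.spatial.transform import Rotation
        rot = Rotation.from_rotvec([0.3, -0.2, 0.9]).as_matrix()
        moved = coords @ rot.T + np.array([5.0, -2.0, 1.0])
        assert model.total(moved) == pytest.approx(model.total(coords),
                                                   rel=1e-12)

    def test_ledger_counts_calls(self, alkane6):
        system, graph, model = alkane6
        ledger = EnergyLedger()
        total_energy(system, graph, np.zeros(3), model, ledger)
        total_energy(system, graph, np.zeros(3), model, ledger)
        assert ledger.count == 2
        with pytest.raises(ValueError):
            ledger.add(-1)

    def test_symmetric_body_pair(self, alkane6):
        system, graph, model = alkane6
        coords = system.coords
        a, b = graph.bodies[0], graph.bodies[1]
        assert body_pair_energy(coords, a, b, model) == body_pair_energy(
            coords, b, a, model)


class TestQuboCoefficients:
    def _spec(self, graph, grid, t, s, rng, phi=None):
        m = len(graph.edges)
        phi = list(range(m)) if phi is None else phi
        return sample_neighbourhood(graph, phi, t, grid, s, rng)

    def test_ledger_increment_formula(self, alkane6, grid12, rng):
        system, graph, model = alkane6
        t = np.zeros(3)
        spec = self._spec(graph, grid12, t, 7, rng)
        sizes = [len(spec.angles[i]) for i in spec.torsions]
        assert sorted(sizes) == [3, 4]
        ledger = EnergyLedger()
        qubo_coefficients(system, graph, spec, t, model, ledger)
        assert ledger.count == 3 * 4 + 7

    def test_single_torsion_increment_is_s(self):
        system = make_alkane(4)  # M = 1
        graph = partition_rigid_bodies(system)
        model = EnergyModel(system)
        grid = AngleGrid.uniform(12)
        rng = np.random.default_rng(0)
        spec = sample_neighbourhood(graph, [0], np.zeros(1), grid, 6, rng)
        ledger = EnergyLedger()
        qubo_coefficients(system, graph, spec, np.zeros(1), model, ledger)
        assert ledger.count == len(spec.angles[0]) == 6

    def test_randomized_count_identity(self, alkane6, grid12, rng):
        system, graph, model = alkane6
        for _ in range(10):
            t = random_torsion_vector(grid12, 3, rng)
            phi = list(rng.permutation(3))
            s = int(rng.integers(4, 20))
            spec = sample_neighbourhood(graph, phi, t, grid12, s, rng)
            sizes = [len(spec.angles[i]) for i in spec.torsions]
            expected = sum(sizes)
            for a in range(len(sizes)):
                for b in range(a + 1, len(sizes)):
                    expected += sizes[a] * sizes[b]
            ledger = EnergyLedger()
            qubo_coefficients(system, graph, spec, t, model, ledger)
            assert ledger.count == expected

    def test_reconstruction_matches_total_energy(self, alkane6, grid12, rng):
        system, graph, model = alkane6
        t = random_torsion_vector(grid12, 3, rng)
        spec = self._spec(graph, grid12, t, 8, rng)
        coeffs = qubo_coefficients(system, graph, spec, t, model)
        sizes = {i: len(spec.angles[i]) for i in spec.torsions}
        for combo in np.ndindex(*[sizes[i] for i in spec.torsions]):
            slots = dict(zip(spec.torsions, combo))
            w = t.copy()
            for i, k in slots.items():
                w[i] = spec.angles[i][k]
            direct = total_energy(system, graph, w, model)
            assert coeffs.point_energy(slots) == pytest.approx(
                direct, abs=max(1e-9, 1e-12 * abs(direct)))
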