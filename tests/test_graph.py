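"""Invasion-graph construction, cycles, verdicts and frondosity criteria."""

import dataclasses

import networkx as nx
import numpy as np
import pytest

import lvig as lv
from lvig.equilibria import CatalogEntry
from lvig.experiments import sample_with_ratio


class TestBuildIG:
    def test_rps3_singleton_cycle_edges(self, rps3_catalog):
        g = lv.build_ig(rps3_catalog)
        singles = [(1,), (2,), (3,)]
        single_edges = {(u, v) for u, v in g.edges if u in singles and v in singles}
        assert single_edges == {((1,), (2,)), ((2,), (3,)), ((3,), (1,))}

    def test_empty_community_edges(self, rps3_catalog):
        # r_i(empty) = b_i = 1 > 0 licenses the edge to every singleton
        g = lv.build_ig(rps3_catalog)
        for i in (1, 2, 3):
            assert g.has_edge((), (i,))

    def test_cycle4_mixed_dimension_cycle(self, cycle4_system):
        cat = lv.enumerate_admissible(*cycle4_system)
        g = lv.build_ig(cat)
        assert g.has_edge((1,), (2, 3))
        assert g.has_edge((2, 3), (4,))
        assert g.has_edge((4,), (1,))

    def test_no_self_edges_and_valid_endpoints(self, rpsls5_catalog):
        g = lv.build_ig(rpsls5_catalog)
        comms = set(rpsls5_catalog.communities())
        for u, v in g.edges:
            assert u != v
            assert u in comms and v in comms

    def test_edge_annotations_store_licensing_rates(self, rps3_catalog):
        g = lv.build_ig(rps3_catalog)
        rates = g.edges[(1,), (2,)]["rates"]
        assert rates["r_2(I)"] == pytest.approx(3.0)
        assert rates["r_1(J)"] == pytest.approx(-1.0)

    def test_edge_rule_strict_at_tolerance(self, rps3_catalog):
        """Perturbing a licensing rate across zero toggles the edge."""
        entries = []
        for e in rps3_catalog.entries:
            rates = e.rates.copy()
            if e.community == (1,):
                rates[1] = -1e-6  # invader 2 can no longer grow on {1}
            entries.append(CatalogEntry(e.community, e.equilibrium, rates))
        tweaked = dataclasses.replace(rps3_catalog, entries=entries)
        g = lv.build_ig(tweaked)
        assert not g.has_edge((1,), (2,))
        assert lv.build_ig(rps3_catalog).has_edge((1,), (2,))


class TestFindCycles:
    def test_rps3_single_elementary_cycle(self, rps3_catalog):
        rep = lv.find_cycles(lv.build_ig(rps3_catalog))
        assert rep.has_cycle
        assert rep.elementary_cycles == (((1,), (2,), (3,)),)

    def test_rpsls5_two_length5_cycles(self, rpsls5_catalog):
        rep = lv.find_cycles(lv.build_ig(rpsls5_catalog))
        singleton5 = [
            c for c in rep.elementary_cycles if len(c) == 5 and all(len(n) == 1 for n in c)
        ]
        triple5 = [
            c for c in rep.elementary_cycles if len(c) == 5 and all(len(n) == 3 for n in c)
        ]
        # both +1-step and +3-step singleton tours are licensed, so at
        # least one cycle of each kind must be present
        assert singleton5 and triple5
        assert ((1,), (2,), (3,), (4,), (5,)) in singleton5

    def test_dag_has_no_cycles(self):
        g = nx.DiGraph([((), (1,)), ((), (2,)), ((1,), (1, 2))])
        rep = lv.find_cycles(g)
        assert not rep.has_cycle
        assert rep.sccs == () and rep.elementary_cycles == ()

    def test_cap_flag(self, rpsls5_catalog):
        rep = lv.find_cycles(lv.build_ig(rpsls5_catalog), max_cycles=2)
        assert rep.cap_hit and rep.has_cycle and len(rep.elementary_cycles) == 2


class TestStructureVerdict:
    def test_high_selfregulation_gradient(self):
        cat = lv.enumerate_admissible(*lv.rpsls5(-1.5))
        v = lv.structure_verdict(cat, lv.build_ig(cat))
        assert v.gradient_certified and v.hyperbolic and v.acyclic and v.frondosity

    def test_cyclic_regime_not_certified(self, rpsls5_catalog):
        v = lv.structure_verdict(rpsls5_catalog, lv.build_ig(rpsls5_catalog))
        assert not v.acyclic and not v.gradient_certified and v.hyperbolic

    def test_nonhyperbolic_at_bifurcation(self):
        cat = lv.enumerate_admissible(*lv.rpsls5(-1.0))
        v = lv.structure_verdict(cat, lv.build_ig(cat))
        assert not v.hyperbolic and not v.gradient_certified


class TestFrondosity:
    def test_rpsls5_high_selfregulation_fully_frondose(self):
        ok, failing, _ = lv.check_frondosity(*lv.rpsls5(-1.5))
        assert ok and failing is None

    def test_rps3_fails_on_two_species_wall(self, rps3_system):
        ok, failing, reason = lv.check_frondosity(*rps3_system)
        assert not ok and failing == (1, 2) and reason == "negative_coordinate"

    def test_decoupled_frondose(self):
        ok, _, _ = lv.check_frondosity(-np.eye(3), np.ones(3))
        assert ok

    def test_full_frondosity_edge_set_is_strict_inclusion(self):
        """With maximal frondosity and hyperbolicity, I->J iff I is a strict
        subset of J."""
        cat = lv.enumerate_admissible(*lv.rpsls5(-1.5))
        g = lv.build_ig(cat)
        expected = {
            (i, j) for i in g.nodes for j in g.nodes if i != j and set(i) < set(j)
        }
        assert set(g.edges) == expected


class TestFrondositySufficientConditions:
    def test_dd_condition_examples(self):
        a = np.array([[-1.0, 0.1], [0.1, -1.0]])
        ok, slack = lv.frondosity_sufficient_dd(a, np.ones(2))
        assert ok and slack == pytest.approx(0.4)
        ok2, slack2 = lv.frondosity_sufficient_dd(a, np.array([1.0, 3.0]))
        assert ok2 and slack2 == pytest.approx(0.15)

    def test_dd_condition_is_only_sufficient(self):
        a, b = lv.rpsls5(-1.5)
        ok, slack = lv.frondosity_sufficient_dd(a, b)
        assert not ok and slack < 0  # LHS 8/3 > RHS 1/2, yet frondose

    def test_dd_condition_validation(self):
        with pytest.raises(ValueError):
            lv.frondosity_sufficient_dd(-np.eye(2), np.array([1.0, -1.0]))
        with pytest.raises(ValueError):
            lv.frondosity_sufficient_dd(np.array([[0.0, 1.0], [1.0, -1.0]]), np.ones(2))

    def test_cooperative_criterion(self):
        a = np.array([[-2.0, 0.5], [0.5, -2.0]])
        assert lv.frondosity_sufficient_cooperative(a, np.ones(2))
        ok, _, _ = lv.check_frondosity(a, np.ones(2))
        assert ok
        eq = lv.solve_equilibrium(a, np.ones(2), (1, 2))
        np.testing.assert_allclose(eq.u, [2 / 3, 2 / 3])

    def test_cooperative_criterion_negatives(self):
        assert not lv.frondosity_sufficient_cooperative(
            np.array([[-2.0, -0.5], [0.5, -2.0]]), np.ones(2)
        )
        assert not lv.frondosity_sufficient_cooperative(
            np.array([[-2.0, 0.5], [0.5, -2.0]]), np.array([1.0, 0.0])
        )


class TestSingleSpeciesCycles:
    def test_rps3_product_condition(self, rps3_system, rps3_catalog):
        a, b = rps3_system
        rep = lv.single_species_cycle_test(a, b, lv.build_ig(rps3_catalog))
        assert len(rep.cycles) == 1
        assert rep.product_condition == (True,)  # 1 >= 0.125
        assert not rep.contradiction

    def test_dd_samples_have_no_singleton_cycles(self, rng):
        from lvig.experiments import sample_dd_system

        for _ in range(50):
            a, b = sample_dd_system(4, rng)
            cat = lv.enumerate_admissible(a, b)
            rep = lv.single_species_cycle_test(a, b, lv.build_ig(cat))
            assert rep.cycles == ()

    def test_empty_report_without_singleton_sccs(self):
        g = nx.DiGraph([((1,), (2,)), ((2,), (1, 2))])
        rep = lv.single_species_cycle_test(-np.eye(2), np.ones(2), g)
        assert rep.cycles == ()


class TestSymmetricGradientProperty:
    def test_symmetric_stable_systems_acyclic(self, rng):
        """Symmetric stable interactions admit a Lyapunov function, so the
        invasion graph can never cycle."""
        for _ in range(30):
            n = int(rng.integers(3, 9))
            a = sample_with_ratio(n, 0.0, rng)
            cat = lv.enumerate_admissible(a, rng.standard_normal(n))
            assert not lv.find_cycles(lv.build_ig(cat)).has_cycle


class TestRigidity3D:
    def test_cyclic_3d_systems_have_may_leonard_structure(self, rng):
        """Every 3-species VL stable system with a cyclic IG has exactly 5
        admissible communities, no 2-species community, and an interior GASS."""
        found = 0
        for _ in range(300):
            a = sample_with_ratio(3, 4.0, rng, margin=0.2)
            cat = lv.enumerate_admissible(a, np.ones(3))
            if not lv.find_cycles(lv.build_ig(cat)).has_cycle:
                continue
            found += 1
            assert len(cat) == 5
            assert all(len(c) != 2 for c in cat.communities())
            assert lv.find_gass(cat).community == (1, 2, 3)
        assert found > 0  # the sweep must actually exercise cyclic systems


class TestExport:
    def test_dot_output(self, rps3_catalog):
        g = lv.build_ig(rps3_catalog)
        rep = lv.find_cycles(g)
        dot = lv.to_dot(g, cycles=rep.elementary_cycles)
        assert dot.startswith("digraph")
        assert '"(1)" -> "(2)" [color=red];' in dot
        assert '"()"' in dot
        assert '"()"' not in lv.to_dot(g, include_empty=False)

    def test_graphml_roundtrip(self, rps3_catalog, tmp_path):
        g = lv.build_ig(rps3_catalog)
        path = tmp_path / "ig.graphml"
        from lvig.graph import write_graphml

        write_graphml(g, path)
        back = nx.read_graphml(path)
        assert back.number_of_nodes() == g.number_of_nodes()
        assert back.number_of_edges() == g.number_of_edges()
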