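"""ILP network selection, time evolution, bootstrap consensus, controls."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from phosphonet import (
    EnsembleParams,
    bootstrap_ensemble,
    build_ilp,
    downstream_targets,
    evolve_time_course,
    randomized_control,
    solve_ilp,
)
from conftest import ilp_brute_force, random_ilp_instance


def _solve(graph, scores, epsilon=0.01, forced=frozenset()):
    problem = build_ilp(graph, scores, forced_edges=forced, epsilon=epsilon)
    return solve_ilp(problem)


class TestBuildAndSolve:
    def test_no_regulated_sites_gives_empty_network(self, chain_graph):
        edges, obj, optimal = _solve(chain_graph, {"K2_S5": 2.0})
        assert edges == [] and obj == 0.0 and optimal

    def test_chain_selected_for_regulated_site(self, chain_graph):
        edges, obj, _ = _solve(chain_graph, {"K2_S5": -2.0})
        assert edges == [("K", "K2_S5"), ("R", "K")]
        assert obj == pytest.approx(-2.0 + 0.02)

    def test_parsimony_prefers_short_route(self):
        g = nx.DiGraph()
        g.add_node("R", node_class="receptor", host_protein=None)
        for p in ("A", "B", "C"):
            g.add_node(p, node_class="protein", host_protein=None)
        g.add_node("T_S1", node_class="site", host_protein="T")
        for u, v, c in [("R", "A", "ppi"), ("A", "T_S1", "kinase_site"),
                        ("R", "B", "ppi"), ("B", "C", "ppi"),
                        ("C", "T_S1", "kinase_site")]:
            g.add_edge(u, v, interaction_class=c, sign=1, references=frozenset())
        edges, _, _ = _solve(g, {"T_S1": -3.0})
        assert edges == [("A", "T_S1"), ("R", "A")]

    def test_costly_intermediate_site_traded_off(self):
        # regulated site only reachable through a penalized site
        g = nx.DiGraph()
        g.add_node("R", node_class="receptor", host_protein=None)
        for p in ("K1", "K2"):
            g.add_node(p, node_class="protein", host_protein=None)
        g.add_node("K2_S1", node_class="site", host_protein="K2")
        g.add_node("T_S2", node_class="site", host_protein="T")
        for u, v, c in [("R", "K1", "ppi"), ("K1", "K2_S1", "kinase_site"),
                        ("K2_S1", "K2", "site_protein"), ("K2", "T_S2", "kinase_site")]:
            g.add_edge(u, v, interaction_class=c, sign=1, references=frozenset())
        # worth it: -5 + 1 + 4 eps < 0
        edges, obj, _ = _solve(g, {"T_S2": -5.0, "K2_S1": 1.0})
        assert len(edges) == 4
        assert obj == pytest.approx(-5.0 + 1.0 + 0.04)
        # not worth it: -0.5 + 1 + 4 eps > 0
        edges, obj, _ = _solve(g, {"T_S2": -0.5, "K2_S1": 1.0})
        assert edges == [] and obj == 0.0

    def test_forced_edge_absent_rejected(self, chain_graph):
        with pytest.raises(ValueError, match="forced"):
            build_ilp(chain_graph, {}, forced_edges={("R", "Z")})

    def test_epsilon_exceeding_weakest_target_rejected(self, chain_graph):
        with pytest.raises(ValueError, match="epsilon"):
            build_ilp(chain_graph, {"K2_S5": -0.005}, epsilon=0.01)

    def test_objective_never_above_empty_solution(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            g, scores = random_ilp_instance(rng)
            _, obj, _ = _solve(g, scores)
            assert obj <= 1e-9

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(123)
        for _ in range(30):
            g, scores = random_ilp_instance(rng)
            _, obj, optimal = _solve(g, scores)
            assert optimal
            assert obj == pytest.approx(ilp_brute_force(g, scores), abs=1e-6)


def _two_phase_graph():
    """R -> K1 -> s1, and K1 -> s2 via K2 (deeper branch)."""
    g = nx.DiGraph()
    g.add_node("R", node_class="receptor", host_protein=None)
    for p in ("K1", "K2"):
        g.add_node(p, node_class="protein", host_protein=None)
    g.add_node("A_S1", node_class="site", host_protein="A")
    g.add_node("K2_S9", node_class="site", host_protein="K2")
    g.add_node("B_S2", node_class="site", host_protein="B")
    for u, v, c in [("R", "K1", "ppi"), ("K1", "A_S1", "kinase_site"),
                    ("K1", "K2_S9", "kinase_site"), ("K2_S9", "K2", "site_protein"),
                    ("K2", "B_S2", "kinase_site")]:
        g.add_edge(u, v, interaction_class=c, sign=1, references=frozenset())
    return g


class TestEvolveTimeCourse:
    def test_identical_scores_identical_networks(self, chain_graph):
        scores = {t: {"K2_S5": -2.0} for t in (2.0, 10.0, 30.0)}
        sol = evolve_time_course(chain_graph, scores)
        nets = list(sol.edges_by_time.values())
        assert nets[0] == nets[1] == nets[2]

    def test_new_branch_extends_previous_network(self):
        g = _two_phase_graph()
        scores = {
            2.0: {"A_S1": -3.0, "K2_S9": 2.0, "B_S2": 2.0},
            10.0: {"A_S1": -3.0, "K2_S9": -2.0, "B_S2": -3.0},
        }
        sol = evolve_time_course(g, scores)
        t1, t2 = sol.edges_by_time[2.0], sol.edges_by_time[10.0]
        assert t1 == {("R", "K1"), ("K1", "A_S1")}
        assert t1 < t2
        assert ("K2", "B_S2") in t2

    def test_deregulated_branch_persists(self, chain_graph):
        scores = {2.0: {"K2_S5": -2.0}, 10.0: {"K2_S5": 3.0}}
        sol = evolve_time_course(chain_graph, scores)
        assert sol.edges_by_time[2.0] == sol.edges_by_time[10.0]

    def test_entry_times_match_first_appearance(self):
        g = _two_phase_graph()
        scores = {
            2.0: {"A_S1": -3.0, "B_S2": 2.0},
            10.0: {"A_S1": -3.0, "K2_S9": -2.0, "B_S2": -3.0},
        }
        sol = evolve_time_course(g, scores)
        assert sol.entry_time[("R", "K1")] == 2.0
        assert sol.entry_time[("K2", "B_S2")] == 10.0


class TestBootstrapEnsemble:
    def test_single_run_weights_binary(self, chain_graph):
        scores = {2.0: {"K2_S5": -2.0}}
        sol = bootstrap_ensemble(chain_graph, scores,
                                 EnsembleParams(n_runs=1, weight_threshold=1, seed=0))
        assert all(w in (0, 1) for wt in sol.weights.values() for w in wt.values())

    def test_unique_site_fraction_near_63_percent(self):
        g = _two_phase_graph()
        # many decoy scored sites so the resample pool is large
        for i in range(200):
            g.add_node(f"D{i}_S1", node_class="site", host_protein=f"D{i}")
            g.add_edge("K1", f"D{i}_S1", interaction_class="kinase_site", sign=1,
                       references=frozenset())
        scores = {2.0: {f"D{i}_S1": 1.0 for i in range(200)} | {"A_S1": -3.0}}
        sol = bootstrap_ensemble(g, scores, EnsembleParams(20, 5, seed=1))
        assert 0.55 <= np.mean(sol.unique_site_fractions) <= 0.72

    def test_weights_bounded_and_entry_threshold(self, small_differential, small_study):
        from phosphonet import attach_site_coupling, prune_to_reachable, scores_by_time

        truth, _, _ = small_study
        res, union = small_differential
        pruned, _ = prune_to_reachable(attach_site_coupling(truth.pkn),
                                       truth.receptor, union)
        params = EnsembleParams(n_runs=15, weight_threshold=5, seed=2)
        sol = bootstrap_ensemble(pruned, scores_by_time(res), params)
        for e, wt in sol.weights.items():
            assert max(wt.values()) <= 15
            crossing = [t for t in sol.time_points if wt[t] >= 5]
            if crossing:
                assert sol.entry_time[e] == crossing[0]
            else:
                assert e not in sol.entry_time
            # weights inherit nesting: non-decreasing across time
            seq = [wt[t] for t in sol.time_points]
            assert seq == sorted(seq)

    def test_weights_invariant_to_score_order(self, chain_graph):
        scores = {2.0: {"K2_S5": -2.0, "ZZ": 1.0, "AA": 0.5}}
        rev = {2.0: dict(reversed(list(scores[2.0].items())))}
        p = EnsembleParams(n_runs=10, weight_threshold=2, seed=7)
        w1 = bootstrap_ensemble(chain_graph, scores, p).weights
        w2 = bootstrap_ensemble(chain_graph, rev, p).weights
        assert w1 == w2


class TestRandomizedControl:
    def _table(self):
        rng = np.random.default_rng(0)
        idx = [f"S{i}_S1" for i in range(20)]
        return pd.DataFrame(rng.normal(size=(20, 4)), index=pd.Index(idx, name="site_id"))

    def test_deterministic_given_seed(self):
        t = self._table()
        reg, non = list(t.index[:5]), list(t.index[5:])
        a = randomized_control(t, reg, non, seed=3)
        b = randomized_control(t, reg, non, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_regulated_ids_absent_from_output(self):
        t = self._table()
        reg, non = list(t.index[:5]), list(t.index[5:])
        out = randomized_control(t, reg, non, seed=1)
        assert not set(reg) & set(out.index)

    def test_profiles_relocated_not_lost(self):
        t = self._table()
        reg, non = list(t.index[:3]), list(t.index[3:])
        out = randomized_control(t, reg, non, seed=2)
        for r in reg:
            match = (out.to_numpy() == t.loc[r].to_numpy()).all(axis=1)
            assert match.sum() == 1

    def test_small_pool_rejected(self):
        t = self._table()
        with pytest.raises(ValueError):
            randomized_control(t, list(t.index[:10]), list(t.index[10:15]), seed=0)


class TestDownstreamTargets:
    def test_chain_reachability(self):
        g = _two_phase_graph()
        scores = {2.0: {"A_S1": -3.0, "K2_S9": -2.0, "B_S2": -3.0}}
        sol = evolve_time_course(g, scores)
        assert downstream_targets(sol, "K1", 2.0) == {"A_S1", "K2_S9", "B_S2"}
        assert downstream_targets(sol, "K2", 2.0) == {"B_S2"}
        assert downstream_targets(sol, "B_S2", 2.0) == set()

    def test_absent_node_warns_empty(self, chain_graph):
        sol = evolve_time_course(chain_graph, {2.0: {"K2_S5": -2.0}})
        assert downstream_targets(sol, "NOPE", 2.0) == set()
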