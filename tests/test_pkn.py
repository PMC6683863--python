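"""PKN loading, isoform grouping, site coupling and path pruning."""

import networkx as nx
import numpy as np
import pytest

from phosphonet import (
    apply_grouping,
    attach_site_coupling,
    load_pkn,
    prune_to_reachable,
    set_receptor,
)
from phosphonet.pkn import add_edge, parse_site_id


def _write(tmp_path, name, lines):
    p = tmp_path / name
    p.write_text("\n".join(lines) + ("\n" if lines else ""))
    return p


class TestLoadPkn:
    def test_empty_files(self, tmp_path):
        ks = _write(tmp_path, "ks.tsv", [])
        ppi = _write(tmp_path, "ppi.tsv", [])
        g = load_pkn(ks, ppi)
        assert g.number_of_edges() == 0

    def test_duplicate_rows_merge_references(self, tmp_path):
        ks = _write(tmp_path, "ks.tsv", [
            "K1\tkinase_site\tAKT_S473\t+1\t11111",
            "K1\tkinase_site\tAKT_S473\t+1\t22222;33333",
        ])
        g = load_pkn(ks, None)
        assert g.number_of_edges() == 1
        assert g.edges["K1", "AKT_S473"]["references"] == {"11111", "22222", "33333"}

    def test_kinase_site_edge_must_target_site(self, tmp_path):
        ks = _write(tmp_path, "ks.tsv", ["K1\tkinase_site\tK2\t+1\t"])
        with pytest.raises(ValueError, match="malformed site id"):
            load_pkn(ks, None)

    def test_unknown_sign_reports_line(self, tmp_path):
        ks = _write(tmp_path, "ks.tsv", [
            "K1\tkinase_site\tA_S1\t+1\t",
            "K1\tkinase_site\tB_S2\t?\t",
        ])
        with pytest.raises(ValueError, match=":2"):
            load_pkn(ks, None)

    def test_malformed_row_reports_line(self, tmp_path):
        ks = _write(tmp_path, "ks.tsv", ["K1\tkinase_site"])
        with pytest.raises(ValueError, match=":1"):
            load_pkn(ks, None)

    @pytest.mark.parametrize(
        "site,expected",
        [("AKT_S473", ("AKT", "S", 473)), ("GSK3B_Y216", ("GSK3B", "Y", 216)),
         ("A_B_T5", ("A_B", "T", 5))],
    )
    def test_site_id_parsing(self, site, expected):
        assert parse_site_id(site) == expected


def _toy_graph():
    g = nx.DiGraph()
    set_receptor(g, "R")
    for p in ("K1", "K2"):
        g.add_node(p, node_class="protein", host_protein=None)
    g.add_node("K2_S10", node_class="site", host_protein="K2")
    g.add_node("X_S1", node_class="site", host_protein="X")
    add_edge(g, "R", "K1", "ppi", 1, frozenset({"a"}))
    add_edge(g, "K1", "K2_S10", "kinase_site", 1, frozenset({"b"}))
    add_edge(g, "K2_S10", "K2", "site_protein", 1)
    add_edge(g, "K2", "X_S1", "kinase_site", 1, frozenset({"c"}))
    return g


class TestApplyGrouping:
    def test_empty_grouping_is_identity(self):
        g = _toy_graph()
        out = apply_grouping(g, {})
        assert set(out.edges) == set(g.edges) and set(out.nodes) == set(g.nodes)

    def test_isoforms_merge_substrate_union(self):
        g = nx.DiGraph()
        set_receptor(g, "R")
        for k in ("AKT1", "AKT2"):
            g.add_node(k, node_class="protein", host_protein=None)
        g.add_node("A_S1", node_class="site", host_protein="A")
        g.add_node("B_S2", node_class="site", host_protein="B")
        add_edge(g, "AKT1", "A_S1", "kinase_site", 1)
        add_edge(g, "AKT2", "B_S2", "kinase_site", 1)
        out = apply_grouping(g, {"AKT1": "AKT", "AKT2": "AKT"})
        assert set(out.successors("AKT")) == {"A_S1", "B_S2"}

    def test_self_loop_dropped(self):
        g = nx.DiGraph()
        set_receptor(g, "R")
        g.add_node("K1", node_class="protein", host_protein=None)
        g.add_node("K2_S9", node_class="site", host_protein="K2")
        g.add_node("K2", node_class="protein", host_protein=None)
        add_edge(g, "K1", "K2_S9", "kinase_site", 1)
        add_edge(g, "K2_S9", "K2", "site_protein", 1)
        out = apply_grouping(g, {"K1": "K", "K2": "K"})
        # grouping turned K1 -> site-on-K2 into autophosphorylation: dropped
        assert not out.has_edge("K", "K2_S9")

    def test_receptor_merge_rejected(self):
        g = _toy_graph()
        with pytest.raises(ValueError, match="receptor"):
            apply_grouping(g, {"R": "K1"})

    def test_reference_count_preserved(self):
        g = _toy_graph()
        out = apply_grouping(g, {"K1": "G", "K2": "G2"})
        refs_in = sum(len(d["references"]) for *_e, d in g.edges(data=True))
        refs_out = sum(len(d["references"]) for *_e, d in out.edges(data=True))
        assert refs_in == refs_out


class TestAttachSiteCoupling:
    def test_terminal_host_gets_no_edge(self):
        g = _toy_graph()
        out = attach_site_coupling(g)
        assert not out.has_edge("X_S1", "X")  # X has no outgoing edges

    def test_inhibitory_annotation_flips_sign(self):
        g = _toy_graph()
        g.add_node("K1_S2", node_class="site", host_protein="K1")
        add_edge(g, "K2", "K1_S2", "kinase_site", 1)
        out = attach_site_coupling(g, inhibitory_sites={"K1_S2"})
        assert out.edges["K1_S2", "K1"]["sign"] == -1

    def test_graph_without_sites_unchanged(self):
        g = nx.DiGraph()
        set_receptor(g, "R")
        g.add_node("K1", node_class="protein", host_protein=None)
        add_edge(g, "R", "K1", "ppi", 1)
        out = attach_site_coupling(g)
        assert set(out.edges) == {("R", "K1")}


def _random_dag(rng, n_nodes=15):
    """Random typed DAG rooted at R; edges point from lower to higher index."""
    g = nx.DiGraph()
    set_receptor(g, "R")
    names = ["R"]
    for i in range(1, n_nodes):
        if rng.random() < 0.35:
            name = f"P{i}_S1"
            g.add_node(name, node_class="site", host_protein=f"P{i}")
        else:
            name = f"P{i}"
            g.add_node(name, node_class="protein", host_protein=None)
        names.append(name)
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < 0.2:
                u, v = names[i], names[j]
                if g.nodes[v]["node_class"] == "site":
                    if g.nodes[u]["node_class"] == "site":
                        continue
                    add_edge(g, u, v, "kinase_site", 1)
                elif g.nodes[u]["node_class"] == "site":
                    add_edge(g, u, v, "site_protein", 1)
                else:
                    add_edge(g, u, v, "ppi", 1)
    return g


class TestPruneToReachable:
    def test_isolated_node_removed(self):
        g = _toy_graph()
        g.add_node("LONER", node_class="protein", host_protein=None)
        pruned, _ = prune_to_reachable(g, "R", {"X_S1"})
        assert "LONER" not in pruned

    def test_single_chain_unchanged(self, chain_graph):
        pruned, unreachable = prune_to_reachable(chain_graph, "R", {"K2_S5"})
        assert set(pruned.edges) == set(chain_graph.edges)
        assert unreachable == []

    def test_unreachable_sites_reported(self):
        g = _toy_graph()
        g.add_node("FAR_S9", node_class="site", host_protein="FAR")
        pruned, unreachable = prune_to_reachable(g, "R", {"X_S1", "FAR_S9"})
        assert unreachable == ["FAR_S9"]
        assert "FAR_S9" not in pruned

    def test_missing_receptor_rejected(self):
        with pytest.raises(ValueError):
            prune_to_reachable(nx.DiGraph(), "R", set())

    def test_matches_path_enumeration_oracle_on_random_dags(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            g = _random_dag(rng)
            sites = [n for n, d in g.nodes(data=True) if d["node_class"] == "site"]
            if not sites:
                continue
            targets = set(rng.choice(sites, size=min(3, len(sites)), replace=False))
            pruned, _ = prune_to_reachable(g, "R", targets)
            expected = set()
            for t in targets:
                for path in nx.all_simple_paths(g, "R", t):
                    expected |= set(zip(path, path[1:]))
            assert set(pruned.edges) == expected

    def test_idempotent_and_doubly_reachable(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            g = _random_dag(rng)
            sites = [n for n, d in g.nodes(data=True) if d["node_class"] == "site"]
            if not sites:
                continue
            targets = set(rng.choice(sites, size=min(3, len(sites)), replace=False))
            pruned, _ = prune_to_reachable(g, "R", targets)
            again, _ = prune_to_reachable(pruned, "R", targets)
            assert set(again.edges) == set(pruned.edges)
            rev = pruned.reverse(copy=False)
            kept_targets = targets & set(pruned.nodes)
            back_from_targets = set(kept_targets)
            for t in kept_targets:
                back_from_targets |= nx.descendants(rev, t)
            forward = {"R"} | nx.descendants(pruned, "R")
            for u, v in pruned.edges:
                assert u in forward and v in back_from_targets
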