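"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately re-derive expected results by brute force
(exhaustive enumeration, closed-form combinatorics) so they stay independent
of the implementation paths they check.
"""

from __future__ import annotations

from math import comb

import networkx as nx
import numpy as np
import pytest

import phosphonet as pn


# ---------------------------------------------------------------------------
# Oracles


def bh_stepup_oracle(p: np.ndarray) -> np.ndarray:
    """Literal Benjamini-Hochberg step-up: q_(i) = min_{j>=i} m*p_(j)/j, capped."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running_min = np.inf
    for rank in range(m, 0, -1):
        running_min = min(running_min, m * p[order[rank - 1]] / rank)
        q_sorted[rank - 1] = min(running_min, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def hypergeom_tail_oracle(a: int, b: int, c: int, d: int) -> float:
    """P(X >= a) for X ~ Hypergeometric(N=a+b+c+d, K=a+c, n=a+b), via comb()."""
    N, K, n = a + b + c + d, a + c, a + b
    denom = comb(N, n)
    return sum(comb(K, x) * comb(N - K, n - x) for x in range(a, min(K, n) + 1)) / denom


def running_sum_oracle(metrics, hit_positions) -> float:
    """Plain-loop weighted KS running sum; es = value at max |deviation|."""
    hits = set(hit_positions)
    total_hit = sum(abs(metrics[i]) for i in hits)
    n_miss = len(metrics) - len(hits)
    run, best = 0.0, 0.0
    for i, m in enumerate(metrics):
        run += abs(m) / total_hit if i in hits else -1.0 / n_miss
        if abs(run) > abs(best):
            best = run
    return best


def ilp_brute_force(graph: nx.DiGraph, scores: dict[str, float],
                    epsilon: float = 0.01, forced=frozenset()) -> float:
    """Exhaustive optimum over all consistent edge subsets.

    A subset is consistent iff it is acyclic and every selected edge's source
    is reachable from the receptor through selected edges.  A site with a
    selected outgoing edge is forcibly included (paying its score); any other
    fed site is included only when its score helps.  Forced edges cost no
    epsilon.
    """
    edges = sorted(graph.edges)
    receptor = next(n for n, d in graph.nodes(data=True) if d["node_class"] == "receptor")
    sites = [n for n, d in graph.nodes(data=True) if d["node_class"] == "site"]
    forced = set(forced)
    best = np.inf
    for mask in range(2 ** len(edges)):
        S = {e for i, e in enumerate(edges) if mask >> i & 1}
        if not forced <= S:
            continue
        sub = nx.DiGraph(list(S))
        sub.add_node(receptor)
        if S and not nx.is_directed_acyclic_graph(sub):
            continue
        reach = {receptor} | nx.descendants(sub, receptor)
        if any(u not in reach for u, _ in S):
            continue
        obj = epsilon * len(S - forced)
        ok = True
        for s in sites:
            out_sel = any(u == s for u, _ in S)
            fed = any(
                v == s and graph.edges[u, v]["interaction_class"] == "kinase_site"
                for u, v in S
            )
            score = scores.get(s, 0.0)
            if out_sel:
                if not fed:
                    ok = False
                    break
                obj += score
            elif fed and score < 0:
                obj += score
        if ok:
            best = min(best, obj)
    return best


def random_ilp_instance(rng: np.random.Generator) -> tuple[nx.DiGraph, dict[str, float]]:
    """Random typed graph with <= 10 edges and <= 4 scored sites."""
    g = nx.DiGraph()
    g.add_node("R", node_class="receptor", host_protein=None)
    proteins = [f"P{i}" for i in range(int(rng.integers(2, 5)))]
    sites = [f"P{i}_S1" for i in range(int(rng.integers(1, 5)))]
    for p in proteins:
        g.add_node(p, node_class="protein", host_protein=None)
    for s in sites:
        g.add_node(s, node_class="site", host_protein=s.split("_")[0])
    n_edges = int(rng.integers(3, 11))
    attempts = 0
    while g.number_of_edges() < n_edges and attempts < 200:
        attempts += 1
        kind = rng.choice(["ppi", "kinase_site", "site_protein"])
        if kind == "ppi":
            u = rng.choice(["R", *proteins])
            v = rng.choice(proteins)
        elif kind == "kinase_site":
            u, v = rng.choice(proteins), rng.choice(sites)
        else:
            u, v = rng.choice(sites), rng.choice(proteins)
        if u == v or g.has_edge(u, v):
            continue
        g.add_edge(u, v, interaction_class=kind, sign=1, references=frozenset())
    scores = {s: float(np.round(rng.uniform(-5, 3), 2)) for s in sites}
    scores = {s: v for s, v in scores.items() if abs(v) > 0.05}
    return g, scores


# ---------------------------------------------------------------------------
# Fixtures


SMALL_PARAMS = pn.GeneratorParams(
    n_kinases=8, substrates_per_kinase=2, n_branches=4, n_background_sites=100, seed=11
)


@pytest.fixture(scope="session")
def small_study():
    """One deterministic small synthetic study shared across tests."""
    truth, records, ann = pn.generate_study(SMALL_PARAMS, n_modules=2)
    return truth, records, ann


@pytest.fixture(scope="session")
def small_site_table(small_study):
    truth, records, ann = small_study
    recs = pn.normalize_records(pn.filter_and_group_localization(records))
    table = pn.peptides_to_sites(recs)
    return table.drop(columns=["protein_id", "localized"]), ann


@pytest.fixture(scope="session")
def small_differential(small_site_table):
    table, ann = small_site_table
    res = pn.differential_analysis(table, ann)
    res, union = pn.call_targets(res)
    return res, union


@pytest.fixture(scope="session")
def chain_graph():
    """receptor -> kinase -> site chain."""
    g = nx.DiGraph()
    g.add_node("R", node_class="receptor", host_protein=None)
    g.add_node("K", node_class="protein", host_protein=None)
    g.add_node("K2_S5", node_class="site", host_protein="K2")
    g.add_edge("R", "K", interaction_class="ppi", sign=1, references=frozenset())
    g.add_edge("K", "K2_S5", interaction_class="kinase_site", sign=1, references=frozenset())
    return g
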