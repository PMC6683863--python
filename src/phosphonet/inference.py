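"""Boolean signalling-subnetwork selection by integer linear programming.

Given the pruned prior-knowledge graph and a per-site score
s = log2(q / qThresh) at each time point, the ILP selects a receptor-rooted
sub-DAG minimising the summed scores of included sites plus a small
per-edge cost.  Regulated sites (negative score) reward inclusion, while any
non-regulated site a path must traverse is penalized (positive score), and
the epsilon edge cost makes parsimonious routes strictly preferred.

Decision variables per time point:

* ``x_e``  in {0,1} — edge e selected;
* ``y_v``  in {0,1} — non-receptor protein v active;
* ``z_s``  in {0,1} — site s included;
* ``d_v``  in {0..|V|} — topological depth, eliminating cycles.

Constraints: the receptor is active at depth 0; an edge requires an active
source (y for proteins, z for sites); a protein is active only with a
selected incoming edge; a site is included only with a selected incoming
kinase->site edge; ``d_target >= d_source + 1 - |V|(1 - x_e)`` orders every
selected edge; forced edges (carried forward from earlier time points) are
fixed to 1 with their edge cost waived.

The time course is modelled by solving time points in order, forcing each
solution's edges into the next solve, so edge sets are nested.  A bootstrap
ensemble repeats the whole time course on data down-sampled with replacement
and reports, per edge and time point, the number of runs selecting it
(weight) and the first time point at which the weight reaches a consensus
threshold (entry time).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import LinearConstraint, milp
from scipy.optimize import Bounds

logger = logging.getLogger(__name__)

Edge = tuple[str, str]


@dataclass
class IlpProblem:
    """Compiled ILP for one time point on one graph."""

    graph: nx.DiGraph
    receptor: str
    edges: list[Edge]
    y_nodes: list[str]
    z_nodes: list[str]
    d_nodes: list[str]
    scores: dict[str, float]
    forced_edges: set[Edge]
    epsilon: float
    c: np.ndarray
    constraints: list[LinearConstraint]
    integrality: np.ndarray
    bounds: Bounds


@dataclass
class SolutionNetwork:
    """Selected edge sets per time point with ensemble weights.

    ``weights[e][t]`` counts the runs whose time-``t`` network contains edge
    ``e`` (0..n_runs); ``entry_time[e]`` is the first time point at which the
    weight reaches the consensus threshold.  For a single un-resampled pass
    ``n_runs`` is 1 and weights are 0/1.
    """

    graph: nx.DiGraph
    receptor: str
    time_points: list[float]
    edges_by_time: dict[float, set[Edge]]
    objective_by_time: dict[float, float]
    n_runs: int = 1
    weight_threshold: int = 1
    weights: dict[Edge, dict[float, int]] = field(default_factory=dict)
    entry_time: dict[Edge, float] = field(default_factory=dict)
    unique_site_fractions: list[float] = field(default_factory=list)
    n_failed_runs: int = 0

    def consensus_edges(self, weight_threshold: int | None = None) -> set[Edge]:
        """Edges whose weight at the last time point meets the threshold."""
        thr = self.weight_threshold if weight_threshold is None else weight_threshold
        t_last = self.time_points[-1]
        return {e for e, w in self.weights.items() if w.get(t_last, 0) >= thr}


@dataclass(frozen=True)
class EnsembleParams:
    """Bootstrap-consensus settings (resampling with replacement, full size)."""

    n_runs: int = 100
    weight_threshold: int = 20
    epsilon: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.weight_threshold <= self.n_runs):
            raise ValueError("0 < weight_threshold <= n_runs required")


def _find_receptor(g: nx.DiGraph) -> str:
    receptors = [n for n, d in g.nodes(data=True) if d.get("node_class") == "receptor"]
    if len(receptors) != 1:
        raise ValueError(f"expected exactly one receptor, found {receptors}")
    return receptors[0]


def build_ilp(
    graph: nx.DiGraph,
    scores: dict[str, float],
    forced_edges: set[Edge] = frozenset(),
    epsilon: float = 0.01,
) -> IlpProblem:
    """Compile the selection ILP for one time point.

    ``scores`` maps measured site ids to s = log2(q/qThresh); sites in the
    graph without a score contribute 0 (they still cost epsilon per edge to
    reach).  Scored sites missing from the graph are dropped with a report.
    Aborts if epsilon is not strictly below the smallest |score| among
    regulated (negative-score) sites, which would let parsimony override data.
    """
    receptor = _find_receptor(graph)
    forced_edges = set(forced_edges)
    missing_forced = forced_edges - set(graph.edges)
    if missing_forced:
        raise ValueError(f"forced edges absent from graph: {sorted(missing_forced)}")
    dropped = [s for s in scores if s not in graph]
    if dropped:
        logger.info("%d scored sites not in pruned graph", len(dropped))
    scores = {s: v for s, v in scores.items() if s in graph}
    neg = [-v for v in scores.values() if v < 0]
    if neg and epsilon >= min(neg):
        raise ValueError(
            f"epsilon={epsilon} >= smallest regulated-site |score| {min(neg):.4g}; "
            "edge parsimony would override the data"
        )

    edges = sorted(graph.edges)
    nodes = sorted(graph.nodes)
    node_class = {n: graph.nodes[n]["node_class"] for n in nodes}
    y_nodes = [n for n in nodes if node_class[n] == "protein"]
    z_nodes = [n for n in nodes if node_class[n] == "site"]
    d_nodes = nodes
    n_x, n_y, n_z, n_d = len(edges), len(y_nodes), len(z_nodes), len(d_nodes)
    n_var = n_x + n_y + n_z + n_d
    xi = {e: i for i, e in enumerate(edges)}
    yi = {v: n_x + i for i, v in enumerate(y_nodes)}
    zi = {s: n_x + n_y + i for i, s in enumerate(z_nodes)}
    di = {v: n_x + n_y + n_z + i for i, v in enumerate(d_nodes)}
    V = len(nodes)

    c = np.zeros(n_var)
    for s in z_nodes:
        c[zi[s]] = scores.get(s, 0.0)
    for e in edges:
        if e not in forced_edges:
            c[xi[e]] = epsilon

    rows, cols, vals, ub = [], [], [], []

    def _row(entries: list[tuple[int, float]], upper: float) -> None:
        r = len(ub)
        for j, a in entries:
            rows.append(r)
            cols.append(j)
            vals.append(a)
        ub.append(upper)

    for e in edges:
        u, v = e
        # (ii) edge requires active source (receptor always active)
        if node_class[u] == "protein":
            _row([(xi[e], 1.0), (yi[u], -1.0)], 0.0)
        elif node_class[u] == "site":
            _row([(xi[e], 1.0), (zi[u], -1.0)], 0.0)
        # (v) acyclicity: d_u - d_v + V*x_e <= V - 1
        _row([(di[u], 1.0), (di[v], -1.0), (xi[e], float(V))], float(V - 1))
    # (iii) protein active only with selected incoming edge
    for v in y_nodes:
        _row([(yi[v], 1.0)] + [(xi[e], -1.0) for e in graph.in_edges(v)], 0.0)
    # (iv) site included only with selected incoming kinase->site edge
    for s in z_nodes:
        inc = [
            e for e in graph.in_edges(s)
            if graph.edges[e]["interaction_class"] == "kinase_site"
        ]
        _row([(zi[s], 1.0)] + [(xi[e], -1.0) for e in inc], 0.0)

    from scipy.sparse import csr_matrix

    A = csr_matrix((vals, (rows, cols)), shape=(len(ub), n_var))
    constraints = [LinearConstraint(A, -np.inf, np.array(ub))]

    lb = np.zeros(n_var)
    hi = np.ones(n_var)
    hi[n_x + n_y + n_z :] = float(V)
    for e in forced_edges:
        lb[xi[e]] = 1.0
    lb[di[receptor]] = hi[di[receptor]] = 0.0  # receptor at depth 0
    integrality = np.ones(n_var)

    return IlpProblem(
        graph=graph, receptor=receptor, edges=edges, y_nodes=y_nodes,
        z_nodes=z_nodes, d_nodes=d_nodes, scores=scores,
        forced_edges=forced_edges, epsilon=epsilon, c=c,
        constraints=constraints, integrality=integrality,
        bounds=Bounds(lb, hi),
    )


def solve_ilp(
    problem: IlpProblem, time_limit: float | None = None
) -> tuple[list[Edge], float, bool]:
    """Solve to proven optimality (MILP gap 0) with the HiGHS backend.

    Returns (sorted selected edges, objective, optimal flag).  If the time
    limit is hit, the best incumbent is returned with ``optimal=False``.
    The objective counts included-site scores plus epsilon per selected
    non-forced edge (forced edges are cost-free).
    """
    if not problem.edges:
        return [], 0.0, True
    options = {"mip_rel_gap": 0.0, "presolve": True}
    if time_limit is not None:
        options["time_limit"] = float(time_limit)
    res = milp(
        c=problem.c,
        constraints=problem.constraints,
        integrality=problem.integrality,
        bounds=problem.bounds,
        options=options,
    )
    if res.x is None:
        raise RuntimeError(f"ILP solve failed: {res.message}")
    optimal = bool(res.status == 0)
    if not optimal:
        logger.warning("ILP not solved to optimality: %s", res.message)
    x = res.x[: len(problem.edges)]
    selected = sorted(e for e, v in zip(problem.edges, x) if v > 0.5)
    return selected, float(res.fun), optimal


def evolve_time_course(
    graph: nx.DiGraph,
    scores_by_time: dict[float, dict[str, float]],
    epsilon: float = 0.01,
    time_limit: float | None = None,
) -> SolutionNetwork:
    """Solve time points in ascending order, carrying edges forward.

    The first time point is solved unconstrained; each later solve forces the
    previous solution's edges (cost-free) and optimises only that time
    point's scores, so edge sets are nested across time by construction.
    """
    receptor = _find_receptor(graph)
    time_points = sorted(scores_by_time)
    forced: set[Edge] = set()
    edges_by_time: dict[float, set[Edge]] = {}
    objective_by_time: dict[float, float] = {}
    for t in time_points:
        problem = build_ilp(graph, scores_by_time[t], forced_edges=forced, epsilon=epsilon)
        selected, obj, _optimal = solve_ilp(problem, time_limit=time_limit)
        forced = set(selected)
        edges_by_time[t] = set(selected)
        objective_by_time[t] = obj
    weights = {
        e: {t: int(e in edges_by_time[t]) for t in time_points}
        for e in edges_by_time[time_points[-1]]
    }
    entry = {e: min(t for t in time_points if w[t]) for e, w in weights.items()}
    return SolutionNetwork(
        graph=graph, receptor=receptor, time_points=time_points,
        edges_by_time=edges_by_time, objective_by_time=objective_by_time,
        n_runs=1, weight_threshold=1, weights=weights, entry_time=entry,
    )


def bootstrap_ensemble(
    graph: nx.DiGraph,
    scores_by_time: dict[float, dict[str, float]],
    params: EnsembleParams = EnsembleParams(),
) -> SolutionNetwork:
    """Bootstrap consensus over repeated down-sampled time-course solves.

    Each run resamples the measured site identifiers with replacement to the
    original count, deduplicates to the unique subset (which retains about
    63% of sites), reruns the full time-course solve on the subset's scores,
    and contributes to per-edge, per-time-point selection counts (weights).
    An edge's entry time is the earliest time point at which its weight
    reaches ``params.weight_threshold``.  Individual failed runs are skipped
    and counted; more than 10% failures aborts.
    """
    receptor = _find_receptor(graph)
    measured = sorted(set().union(*(set(s) for s in scores_by_time.values())))
    if not measured:
        raise ValueError("no measured sites in scores")
    time_points = sorted(scores_by_time)
    root = np.random.SeedSequence(params.seed)
    weights: dict[Edge, dict[float, int]] = {}
    objective_sums = {t: 0.0 for t in time_points}
    unique_fracs: list[float] = []
    n_failed = 0
    for run, child in enumerate(root.spawn(params.n_runs)):
        rng = np.random.default_rng(child)
        draw = rng.integers(0, len(measured), size=len(measured))
        kept = {measured[i] for i in draw}
        unique_fracs.append(len(kept) / len(measured))
        sub_scores = {
            t: {s: v for s, v in sc.items() if s in kept}
            for t, sc in scores_by_time.items()
        }
        try:
            sol = evolve_time_course(graph, sub_scores, epsilon=params.epsilon)
        except Exception:
            n_failed += 1
            logger.exception("bootstrap run %d failed", run)
            if n_failed > 0.1 * params.n_runs:
                raise RuntimeError(f"{n_failed} bootstrap runs failed; aborting")
            continue
        for t in time_points:
            objective_sums[t] += sol.objective_by_time[t]
            for e in sol.edges_by_time[t]:
                weights.setdefault(e, {tt: 0 for tt in time_points})[t] += 1
    n_ok = params.n_runs - n_failed
    entry = {}
    for e, w in weights.items():
        hits = [t for t in time_points if w[t] >= params.weight_threshold]
        if hits:
            entry[e] = hits[0]
    edges_by_time = {
        t: {e for e, w in weights.items() if w[t] >= params.weight_threshold}
        for t in time_points
    }
    return SolutionNetwork(
        graph=graph, receptor=receptor, time_points=time_points,
        edges_by_time=edges_by_time,
        objective_by_time={t: objective_sums[t] / max(n_ok, 1) for t in time_points},
        n_runs=params.n_runs, weight_threshold=params.weight_threshold,
        weights=weights, entry_time=entry,
        unique_site_fractions=unique_fracs, n_failed_runs=n_failed,
    )


def resample_unique_fraction(
    n_sites: int, n_iterations: int = 500, seed: int = 0
) -> float:
    """Mean fraction of unique site identifiers kept by bootstrap resampling.

    Uses the same scheme as :func:`bootstrap_ensemble`: draw ``n_sites``
    identifiers with replacement from ``n_sites`` and deduplicate.  For large
    pools the expectation approaches 1 - 1/e (about 63.2%).
    """
    root = np.random.SeedSequence(seed)
    fracs = np.empty(n_iterations)
    for i, child in enumerate(root.spawn(n_iterations)):
        rng = np.random.default_rng(child)
        draw = rng.integers(0, n_sites, size=n_sites)
        fracs[i] = np.unique(draw).size / n_sites
    return float(fracs.mean())


def randomized_control(
    site_table: pd.DataFrame,
    regulated_ids: list[str],
    nonregulated_ids: list[str],
    seed: int = 0,
) -> pd.DataFrame:
    """Re-key regulated sites' profiles to random non-regulated identifiers.

    The control dataset keeps the regulated quantitative profiles but assigns
    them identifiers drawn without replacement from the non-regulated pool,
    scattering the signal to random graph positions; a network built from it
    should not reproduce the real structure.
    """
    regulated_ids = sorted(regulated_ids)
    nonregulated_ids = sorted(nonregulated_ids)
    if len(nonregulated_ids) < len(regulated_ids):
        raise ValueError("non-regulated pool smaller than regulated set")
    rng = np.random.default_rng(seed)
    chosen = list(rng.choice(nonregulated_ids, size=len(regulated_ids), replace=False))
    out = site_table.drop(index=[s for s in regulated_ids if s in site_table.index])
    for reg, new_id in zip(regulated_ids, chosen):
        out.loc[new_id] = site_table.loc[reg]
    return out.sort_index()


def downstream_targets(
    solution: SolutionNetwork, node_id: str, time_min: float
) -> set[str]:
    """Site nodes reachable from ``node_id`` via selected edges at a time point."""
    if node_id not in solution.graph:
        logger.warning("node %s not in solution graph", node_id)
        return set()
    sub = nx.DiGraph()
    sub.add_nodes_from(solution.graph.nodes)
    sub.add_edges_from(solution.edges_by_time[time_min])
    reachable = nx.descendants(sub, node_id)
    return {
        n for n in reachable if solution.graph.nodes[n]["node_class"] == "site"
    }


# ---------------------------------------------------------------------------
# Export


def export_solution(solution: SolutionNetwork, out_dir, prefix: str = "network") -> None:
    """Write SIF-like edges, per-time weights/entry times, and a JSON bundle."""
    import json
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    g = solution.graph
    t_last = solution.time_points[-1]
    with open(out / f"{prefix}_edges.sif.tsv", "w") as fh:
        for u, v in sorted(solution.edges_by_time[t_last]):
            d = g.edges[u, v]
            fh.write(f"{u}\t{d['interaction_class']}\t{v}\t{d['sign']:+d}\n")
    with open(out / f"{prefix}_edge_attributes.tsv", "w") as fh:
        cols = "\t".join(f"weight_t{t:g}" for t in solution.time_points)
        fh.write(f"source\ttarget\t{cols}\tentry_time\n")
        for e in sorted(solution.weights):
            w = solution.weights[e]
            ws = "\t".join(str(w[t]) for t in solution.time_points)
            et = solution.entry_time.get(e, "")
            fh.write(f"{e[0]}\t{e[1]}\t{ws}\t{et}\n")
    doc = {
        "receptor": solution.receptor,
        "time_points": solution.time_points,
        "n_runs": solution.n_runs,
        "weight_threshold": solution.weight_threshold,
        "objective_by_time": {str(t): v for t, v in solution.objective_by_time.items()},
        "nodes": [
            {"id": n, "class": g.nodes[n]["node_class"]} for n in sorted(g.nodes)
        ],
        "edges": [
            {
                "source": e[0],
                "target": e[1],
                "weights": {str(t): w[t] for t in solution.time_points},
                "entry_time": solution.entry_time.get(e),
            }
            for e, w in sorted(solution.weights.items())
        ],
        "unique_site_fractions": solution.unique_site_fractions,
        "n_failed_runs": solution.n_failed_runs,
    }
    with open(out / f"{prefix}.json", "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
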