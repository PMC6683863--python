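"""Prior-knowledge network (PKN) assembly.

The PKN is a typed, signed, directed graph over three node classes:

* ``receptor`` — the single stimulated receptor the model is rooted at;
* ``protein``  — kinases, G proteins and other signalling proteins;
* ``site``     — measured phosphosites, each hosted on a protein.

and three edge classes: ``kinase_site`` (kinase phosphorylates site),
``site_protein`` (a phosphosite couples to the activity of its host protein,
so a path can traverse an intermediary kinase through one of its sites) and
``ppi`` (signed directed protein-protein interaction).  Closely related
isoforms and G-protein subunits may be merged via a grouping map.  Before
inference the graph is pruned to nodes and edges lying on at least one
directed path from the receptor to a regulated site.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

NODE_CLASSES = {"receptor", "protein", "site"}
EDGE_CLASSES = {"kinase_site", "site_protein", "ppi"}


def _ensure_node(g: nx.DiGraph, node_id: str, node_class: str, host: str | None = None):
    if node_id in g:
        existing = g.nodes[node_id]["node_class"]
        if existing != node_class:
            raise ValueError(
                f"node {node_id} declared as both {existing} and {node_class}"
            )
    else:
        g.add_node(node_id, node_class=node_class, host_protein=host)


def add_edge(
    g: nx.DiGraph,
    source: str,
    target: str,
    interaction_class: str,
    sign: int = 1,
    references: frozenset[str] = frozenset(),
) -> None:
    """Add a typed edge, merging references with any duplicate."""
    if interaction_class not in EDGE_CLASSES:
        raise ValueError(f"unknown interaction class {interaction_class!r}")
    if sign not in (1, -1):
        raise ValueError(f"sign must be +1 or -1, got {sign!r}")
    if g.has_edge(source, target) and g[source][target]["interaction_class"] == interaction_class:
        data = g[source][target]
        if data["sign"] == sign:
            data["references"] = data["references"] | frozenset(references)
            return
    g.add_edge(
        source,
        target,
        interaction_class=interaction_class,
        sign=sign,
        references=frozenset(references),
    )


def parse_site_id(site_id: str) -> tuple[str, str, int]:
    """Split "PROTEIN_S473" into (protein, residue, position)."""
    protein, _, tail = site_id.rpartition("_")
    if not protein or len(tail) < 2 or tail[0] not in "STY" or not tail[1:].isdigit():
        raise ValueError(f"malformed site id {site_id!r}")
    return protein, tail[0], int(tail[1:])


def load_pkn(ks_file, ppi_file, receptor: str | None = None) -> nx.DiGraph:
    """Load kinase->site and signed directed protein-protein edge files.

    Both are SIF-like TSVs with columns
    ``source  interaction_class  target  sign  references`` (references
    semicolon-separated; may be empty).  Duplicate edges merge their
    reference sets.  Malformed rows and unknown signs raise with the
    offending line number.
    """
    g = nx.DiGraph()
    for path, allowed in ((ks_file, {"kinase_site"}), (ppi_file, {"ppi"})):
        if path is None:
            continue
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected >= 4 columns")
            source, iclass, target, sign_s = parts[:4]
            refs = frozenset(r for r in (parts[4].split(";") if len(parts) > 4 else []) if r)
            if iclass not in allowed:
                raise ValueError(f"{path}:{lineno}: class {iclass!r} not allowed here")
            try:
                sign = int(sign_s)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: unknown sign {sign_s!r}") from None
            if sign not in (1, -1):
                raise ValueError(f"{path}:{lineno}: unknown sign {sign_s!r}")
            if iclass == "kinase_site":
                host, _res, _pos = parse_site_id(target)
                _ensure_node(g, source, "protein")
                _ensure_node(g, target, "site", host=host)
            else:
                _ensure_node(g, source, "protein")
                _ensure_node(g, target, "protein")
            add_edge(g, source, target, iclass, sign, refs)
    if receptor is not None:
        set_receptor(g, receptor)
    return g


def set_receptor(g: nx.DiGraph, receptor: str) -> None:
    """Mark the receptor node; exactly one receptor is allowed."""
    if receptor not in g:
        g.add_node(receptor, node_class="receptor", host_protein=None)
    else:
        g.nodes[receptor]["node_class"] = "receptor"
    others = [n for n, d in g.nodes(data=True) if d["node_class"] == "receptor" and n != receptor]
    if others:
        raise ValueError(f"multiple receptor nodes: {[receptor, *others]}")


def apply_grouping(g: nx.DiGraph, grouping: dict[str, str]) -> nx.DiGraph:
    """Merge isoform/subunit member nodes into group nodes.

    Edge endpoints are rewritten, parallel edges merged with reference union,
    self-loops produced by merging are dropped (their reference loss logged),
    and site host annotations are rewritten.  Merging the receptor into a
    group is an error.  Members absent from the graph are ignored.
    """
    receptors = [n for n, d in g.nodes(data=True) if d["node_class"] == "receptor"]
    for member, group in grouping.items():
        if member in receptors and member != group:
            raise ValueError("grouping would merge the receptor")
    out = nx.DiGraph()
    rename = {n: grouping.get(n, n) for n in g.nodes}
    for n, d in g.nodes(data=True):
        host = d.get("host_protein")
        _ensure_node(out, rename[n], d["node_class"],
                     host=grouping.get(host, host) if host else None)
    dropped_refs = 0
    for u, v, d in g.edges(data=True):
        nu, nv = rename[u], rename[v]
        # merging can create loops two ways: a literal node self-loop (ppi
        # between merged members) or an autophosphorylation loop (kinase ->
        # site hosted on the merged kinase); both are dropped when the loop
        # did not exist before grouping
        host = g.nodes[v].get("host_protein") if g.nodes[v]["node_class"] == "site" else None
        auto_loop = (
            d["interaction_class"] == "kinase_site"
            and host is not None
            and rename.get(host, host) == nu
            and host != u
        )
        if nu == nv or auto_loop:
            dropped_refs += len(d["references"])
            logger.info("dropping self-loop %s->%s created by grouping", u, v)
            continue
        add_edge(out, nu, nv, d["interaction_class"], d["sign"], d["references"])
    if dropped_refs:
        logger.info("grouping dropped %d references with self-loops", dropped_refs)
    return out


def attach_site_coupling(
    g: nx.DiGraph,
    measured_sites: set[str] | None = None,
    inhibitory_sites: set[str] = frozenset(),
) -> nx.DiGraph:
    """Add site->host-protein coupling edges so paths can traverse kinases.

    For every site whose host protein has outgoing edges, a ``site_protein``
    edge is added (default sign +1; sites listed in ``inhibitory_sites`` get
    sign -1).  Sites on terminal proteins get no coupling edge.
    """
    g = g.copy()
    for n, d in list(g.nodes(data=True)):
        if d["node_class"] != "site":
            continue
        if measured_sites is not None and n not in measured_sites:
            continue
        host = d.get("host_protein")
        if host in g and g.out_degree(host) > 0:
            sign = -1 if n in inhibitory_sites else 1
            add_edge(g, n, host, "site_protein", sign)
    return g


def prune_to_reachable(
    g: nx.DiGraph, receptor: str, regulated_sites: set[str]
) -> tuple[nx.DiGraph, list[str]]:
    """Keep exactly the nodes/edges on a receptor -> regulated-site path.

    An edge (u, v) lies on such a path iff u is reachable from the receptor
    and some regulated site is reachable from v.  Unreachable regulated sites
    are reported, not fatal.
    """
    if receptor not in g:
        raise ValueError(f"receptor {receptor!r} not in graph")
    from_receptor = {receptor} | nx.descendants(g, receptor)
    reachable_sites = [s for s in sorted(regulated_sites) if s in from_receptor]
    unreachable = [s for s in sorted(regulated_sites) if s not in from_receptor]
    rev = g.reverse(copy=False)
    to_sites: set[str] = set()
    for s in reachable_sites:
        to_sites |= {s} | nx.descendants(rev, s)
    keep_edges = [(u, v) for u, v in g.edges if u in from_receptor and v in to_sites]
    pruned = nx.DiGraph()
    for u, v in keep_edges:
        for n in (u, v):
            d = g.nodes[n]
            _ensure_node(pruned, n, d["node_class"], host=d.get("host_protein"))
        d = g.edges[u, v]
        add_edge(pruned, u, v, d["interaction_class"], d["sign"], d["references"])
    if receptor not in pruned:
        _ensure_node(pruned, receptor, "receptor")
    return pruned, unreachable


# ---------------------------------------------------------------------------
# I/O


def read_grouping(path) -> dict[str, str]:
    """Two-column TSV member_id -> group_id."""
    df = pd.read_csv(path, sep="\t", header=None, names=["member_id", "group_id"],
                     dtype=str, comment="#")
    if df["member_id"].duplicated().any():
        raise ValueError("a member maps to more than one group")
    return dict(zip(df["member_id"], df["group_id"]))


def write_pkn(g: nx.DiGraph, edges_path, nodes_path=None) -> None:
    """Export SIF-like edge TSV and optional node-attribute TSV."""
    with open(edges_path, "w") as fh:
        for u, v, d in sorted(g.edges(data=True)):
            refs = ";".join(sorted(d["references"]))
            fh.write(f"{u}\t{d['interaction_class']}\t{v}\t{d['sign']:+d}\t{refs}\n")
    if nodes_path is not None:
        with open(nodes_path, "w") as fh:
            fh.write("node_id\tnode_class\thost_protein\n")
            for n, d in sorted(g.nodes(data=True)):
                fh.write(f"{n}\t{d['node_class']}\t{d.get('host_protein') or ''}\n")
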