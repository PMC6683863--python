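"""Ground-truth network and time-course dataset generation.

Emulates the structure of a receptor-stimulation phosphoproteomics study:
a receptor feeding branched kinase cascades, five sampling time points,
biological triplicates, mock and stimulated conditions in wild-type and
receptor-knockout genotypes, a pooled heavy internal-standard channel with
per-sample mixing errors, multiplicative measurement noise calibrated to a
~12% replicate CV after normalization, and regulated sites stepping to a
>= 1.5 fold change at a depth-dependent onset time.

The generated prior-knowledge graph is layered: receptor -> first-layer
transducer proteins (G-protein-like, ppi edges) -> kinase chains, where each
kinase phosphorylates leaf substrate sites and the next kinase in its chain
through a linking site (kinase_site + site_protein edges), plus random extra
ppi edges as confounders.  A ground truth selects a subset of branches as
the active modules; everything else (other branches plus a large pool of
background sites outside the graph) is measured but unregulated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .inference import Edge, SolutionNetwork
from .normalize import PhosphopeptideRecord
from .pkn import add_edge, parse_site_id, set_receptor

logger = logging.getLogger(__name__)

RECEPTOR_ID = "RCPT"


@dataclass(frozen=True)
class GeneratorParams:
    """Study-design parameters of the synthetic generator.

    ``cv`` is the target coefficient of variation of the normalized
    light/heavy ratio between replicates; the per-channel noise sigma is
    derived from it.  ``fold_change`` is the multiplicative step regulated
    sites take at onset (divided for down-regulated sites).
    """

    n_kinases: int = 10
    substrates_per_kinase: int = 3
    extra_edges: int = 3
    n_branches: int = 5
    n_background_sites: int = 200
    time_points: tuple[float, ...] = (2.0, 10.0, 30.0, 60.0, 90.0)
    replicates: int = 3
    genotypes: tuple[str, ...] = ("WT", "KO")
    cv: float = 0.12
    fold_change: float = 2.5
    down_fraction: float = 0.2
    sample_loading_sd: float = 0.35
    baseline_log2_mean: float = 20.0
    baseline_log2_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_kinases, self.substrates_per_kinase, self.n_branches,
               self.replicates) < 1:
            raise ValueError("counts must be positive")
        if self.cv <= 0:
            raise ValueError("cv must be > 0")
        if self.n_kinases < self.n_branches:
            raise ValueError("need at least one kinase per branch")


@dataclass
class SyntheticTruth:
    """Ground truth: active subnetwork and regulated-site schedule."""

    pkn: nx.DiGraph
    receptor: str
    true_edges: set[Edge]
    site_schedule: dict[str, tuple[float, str, float]]  # site -> (onset, up/down, fc)
    decoy_sites: set[str]

    @property
    def measured_sites(self) -> list[str]:
        return sorted(set(self.site_schedule) | self.decoy_sites)


# ---------------------------------------------------------------------------
# Graph generation


def generate_pkn(params: GeneratorParams) -> tuple[nx.DiGraph, str]:
    """Layered random kinase-cascade graph rooted at the receptor.

    Deterministic given the seed.  Node and edge counts are closed-form in
    the parameters: nodes = 1 + branches + kinases + sites with
    sites = kinases*substrates_per_kinase + (kinases - branches) linking
    sites; edges = 2*branches + 2*(kinases - branches)
    + kinases*substrates_per_kinase + extra_edges.
    """
    rng = np.random.default_rng(params.seed)
    g = nx.DiGraph()
    set_receptor(g, RECEPTOR_ID)
    branches = [f"GPROT{b + 1}" for b in range(params.n_branches)]
    for gp in branches:
        g.add_node(gp, node_class="protein", host_protein=None)
        add_edge(g, RECEPTOR_ID, gp, "ppi", 1)

    kinases = [f"K{i + 1:02d}" for i in range(params.n_kinases)]
    chains: list[list[str]] = [[] for _ in branches]
    for i, k in enumerate(kinases):
        chains[i % params.n_branches].append(k)
    for b, (gp, chain) in enumerate(zip(branches, chains)):
        prev = gp
        for pos, k in enumerate(chain):
            g.add_node(k, node_class="protein", host_protein=None,
                       branch=b, chain_pos=pos)
            if pos == 0:
                add_edge(g, gp, k, "ppi", 1)
            else:
                link_site = f"{k}_S10"
                g.add_node(link_site, node_class="site", host_protein=k,
                           branch=b, chain_pos=pos)
                add_edge(g, prev, link_site, "kinase_site", 1)
                add_edge(g, link_site, k, "site_protein", 1)
            for j in range(params.substrates_per_kinase):
                leaf = f"SUB{k[1:]}{chr(ord('a') + j)}_S{j + 1}"
                g.add_node(leaf, node_class="site", host_protein=f"SUB{k[1:]}{chr(ord('a') + j)}",
                           branch=b, chain_pos=pos)
                add_edge(g, k, leaf, "kinase_site", 1)
            prev = k
    # confounder ppi edges between kinases in different branches
    added = 0
    while added < params.extra_edges:
        u, v = (kinases[i] for i in rng.integers(0, len(kinases), 2))
        if u == v or g.has_edge(u, v):
            continue
        add_edge(g, u, v, "ppi", 1)
        g.edges[u, v]["extra"] = True
        added += 1
    g.graph["branches"] = branches
    g.graph["chains"] = chains
    return g, RECEPTOR_ID


def choose_truth(
    pkn: nx.DiGraph, n_modules: int = 3, seed: int = 0,
    params: GeneratorParams = GeneratorParams(),
) -> SyntheticTruth:
    """Select ``n_modules`` receptor-rooted branches as the active subnetwork.

    Onset time of each regulated site follows its kinase's position in the
    chain (first kinase's substrates switch at the first time point, deeper
    kinases at later ones), so later-entering edges sit farther from the
    receptor.  A ``down_fraction`` of leaf sites is down-regulated.
    Sites in unchosen branches plus a pool of background sites outside the
    graph form the unregulated decoys.
    """
    branches = pkn.graph.get("branches")
    chains = pkn.graph.get("chains")
    if branches is None or len(branches) < n_modules:
        raise ValueError(f"need >= {n_modules} receptor-rooted branches")
    rng = np.random.default_rng(seed)
    chosen = sorted(rng.choice(len(branches), size=n_modules, replace=False))
    times = list(params.time_points)
    true_edges: set[Edge] = set()
    schedule: dict[str, tuple[float, str, float]] = {}
    for b in chosen:
        gp, chain = branches[b], chains[b]
        true_edges.add((RECEPTOR_ID, gp))
        prev = gp
        for pos, k in enumerate(chain):
            onset = times[min(pos, len(times) - 1)]
            if pos == 0:
                true_edges.add((gp, k))
            else:
                link_site = f"{k}_S10"
                true_edges.add((prev, link_site))
                true_edges.add((link_site, k))
                schedule[link_site] = (onset, "up", params.fold_change)
            for _, s in sorted(pkn.out_edges(k)):
                if pkn.nodes[s]["node_class"] == "site" and s.startswith("SUB"):
                    true_edges.add((k, s))
                    direction = "down" if rng.random() < params.down_fraction else "up"
                    schedule[s] = (onset, direction, params.fold_change)
            prev = k
    decoys: set[str] = {
        n for n, d in pkn.nodes(data=True)
        if d["node_class"] == "site" and n not in schedule
    }
    decoys |= {f"BG{i + 1:03d}_S1" for i in range(params.n_background_sites)}
    return SyntheticTruth(
        pkn=pkn, receptor=RECEPTOR_ID, true_edges=true_edges,
        site_schedule=schedule, decoy_sites=decoys,
    )


# ---------------------------------------------------------------------------
# Data simulation


def _make_annotation(params: GeneratorParams) -> pd.DataFrame:
    rows = []
    for genotype in params.genotypes:
        for treatment in ("stimulated", "mock"):
            for t in params.time_points:
                for rep in range(1, params.replicates + 1):
                    sid = f"{genotype}_{treatment}_t{t:g}_r{rep}"
                    rows.append((sid, "SYN1", genotype, treatment, float(t), rep))
    ann = pd.DataFrame(
        rows,
        columns=["sample_id", "cell_line", "genotype", "treatment", "time_min", "replicate"],
    )
    return ann.set_index("sample_id", drop=False)


def simulate_dataset(
    truth: SyntheticTruth, params: GeneratorParams
) -> tuple[list[PhosphopeptideRecord], pd.DataFrame]:
    """Simulate the phosphopeptide table and sample annotation.

    One singly phosphorylated, confidently localized peptide per measured
    site.  Light intensity = baseline x regulation signal x per-sample light
    loading factor x lognormal noise; heavy intensity = baseline x per-sample
    heavy loading factor x lognormal noise, so the light/heavy ratio carries
    the signal plus a per-sample mixing error that median normalization
    removes.  The per-channel noise sigma is cv/sqrt(2) on the log scale (in
    lognormal terms) so the replicate CV of the normalized ratio matches
    ``params.cv``.
    """
    ann = _make_annotation(params)
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 7]))
    sites = truth.measured_sites
    sample_ids = list(ann.index)
    # sample CVs over n replicates underestimate the population CV; the c4
    # correction keeps the *observed* median replicate CV at params.cv
    from scipy.special import gamma as _gamma

    n = params.replicates
    c4 = np.sqrt(2.0 / (n - 1)) * _gamma(n / 2) / _gamma((n - 1) / 2) if n > 1 else 1.0
    sigma_ratio = np.sqrt(np.log1p(params.cv**2)) / c4
    sigma_c = sigma_ratio / np.sqrt(2.0)
    load_light = rng.lognormal(0.0, params.sample_loading_sd, size=len(sample_ids))
    load_heavy = rng.lognormal(0.0, params.sample_loading_sd, size=len(sample_ids))

    baselines = 2.0 ** rng.normal(
        params.baseline_log2_mean, params.baseline_log2_sd, size=len(sites)
    )
    records = []
    for p_idx, site in enumerate(sites):
        protein, residue, position = parse_site_id(site)
        sched = truth.site_schedule.get(site)
        light: dict[str, float] = {}
        heavy: dict[str, float] = {}
        noise_l = rng.lognormal(0.0, sigma_c, size=len(sample_ids))
        noise_h = rng.lognormal(0.0, sigma_c, size=len(sample_ids))
        for s_idx, sid in enumerate(sample_ids):
            a = ann.loc[sid]
            signal = 1.0
            if (
                sched is not None
                and a["genotype"] == "WT"
                and a["treatment"] == "stimulated"
                and a["time_min"] >= sched[0]
            ):
                signal = sched[2] if sched[1] == "up" else 1.0 / sched[2]
            light[sid] = baselines[p_idx] * signal * load_light[s_idx] * noise_l[s_idx]
            heavy[sid] = baselines[p_idx] * load_heavy[s_idx] * noise_h[s_idx]
        records.append(
            PhosphopeptideRecord(
                peptide_id=f"pep_{site}",
                backbone_sequence=f"PEPTIDE{p_idx:04d}K",
                protein_id=protein,
                phospho_positions=[position],
                phospho_residues=[residue],
                n_phospho=1,
                flr=0.001,
                localization_score=10.0,
                light_intensity=light,
                heavy_intensity=heavy,
            )
        )
    return records, ann


def generate_study(
    params: GeneratorParams = GeneratorParams(), n_modules: int = 3
) -> tuple[SyntheticTruth, list[PhosphopeptideRecord], pd.DataFrame]:
    """Convenience chain: graph -> truth -> simulated dataset."""
    pkn, _receptor = generate_pkn(params)
    truth = choose_truth(pkn, n_modules=n_modules, seed=params.seed, params=params)
    records, ann = simulate_dataset(truth, params)
    return truth, records, ann


def truth_ks_map(truth: SyntheticTruth) -> dict[str, set[str]]:
    """Kinase -> substrate-site sets read off the generated graph."""
    ks: dict[str, set[str]] = {}
    for u, v, d in truth.pkn.edges(data=True):
        if d["interaction_class"] == "kinase_site":
            ks.setdefault(u, set()).add(v)
    return ks


# ---------------------------------------------------------------------------
# Recovery scoring


def evaluate_recovery(
    inferred: SolutionNetwork,
    truth: SyntheticTruth,
    weight_threshold: int | None = None,
) -> dict[str, float]:
    """Edge precision/recall/F1 of the consensus network against the truth.

    Consensus edges are those whose final-time-point weight meets the
    threshold.  An empty inferred set has precision 1 by convention.  Target
    sensitivity is the fraction of scheduled sites with a selected incoming
    edge in the consensus.
    """
    inferred_edges = inferred.consensus_edges(weight_threshold)
    tp = inferred_edges & truth.true_edges
    precision = len(tp) / len(inferred_edges) if inferred_edges else 1.0
    recall = len(tp) / len(truth.true_edges) if truth.true_edges else 1.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    covered = {v for _u, v in inferred_edges if v in truth.site_schedule}
    sensitivity = (
        len(covered) / len(truth.site_schedule) if truth.site_schedule else 1.0
    )
    return {
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "target_sensitivity": sensitivity,
        "n_inferred": float(len(inferred_edges)),
        "n_true": float(len(truth.true_edges)),
    }


# ---------------------------------------------------------------------------
# Serialization (TSV dialects consumed by the other modules; truth as JSON)


def write_peptide_table(records: list[PhosphopeptideRecord], path) -> None:
    sample_ids = sorted({s for r in records for s in r.light_intensity})
    cols = [
        "peptide_id", "backbone_sequence", "protein_id", "positions", "residues",
        "n_phospho", "flr", "localization_score",
        *(f"light:{s}" for s in sample_ids), *(f"heavy:{s}" for s in sample_ids),
    ]
    rows = []
    for r in records:
        row = [
            r.peptide_id, r.backbone_sequence, r.protein_id,
            ";".join(str(p) for p in r.phospho_positions), "".join(r.phospho_residues),
            r.n_phospho, r.flr, r.localization_score,
            *(r.light_intensity.get(s, np.nan) for s in sample_ids),
            *(r.heavy_intensity.get(s, np.nan) for s in sample_ids),
        ]
        rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def write_annotation(ann: pd.DataFrame, path) -> None:
    ann.to_csv(path, sep="\t", index=False)


def write_truth(truth: SyntheticTruth, path) -> None:
    import json

    doc = {
        "receptor": truth.receptor,
        "true_edges": sorted(list(e) for e in truth.true_edges),
        "site_schedule": {
            s: {"onset": o, "direction": d, "fold_change": f}
            for s, (o, d, f) in sorted(truth.site_schedule.items())
        },
        "decoy_sites": sorted(truth.decoy_sites),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
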