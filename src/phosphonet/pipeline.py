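"""End-to-end pipeline orchestration behind a flat configuration.

Stages run in method order: normalization -> differential calling -> kinase
activity -> clustering -> PKN assembly -> ILP bootstrap ensemble -> reports.
Every stage writes its outputs under ``out_dir`` and the run manifest records
parameters, per-stage seeds (all expanded from one master seed) and sha256
hashes of every artifact, so a rerun with the same configuration is
byte-identical and verifiable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import differential, inference, kinase_activity, normalize, pkn

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Flat pipeline configuration; defaults follow the study settings."""

    peptide_table: str = ""
    annotation: str = ""
    ks_network: str = ""        # kinase->site SIF-like TSV
    ppi_network: str = ""       # signed directed PPI SIF-like TSV
    grouping_map: str = ""      # optional isoform/subunit grouping TSV
    ks_sets: str = ""           # optional GMT-like kinase-substrate sets
    receptor_id: str = ""
    time_points: list[float] = field(default_factory=list)
    flr_threshold: float = 0.01
    q_thresh: float = 0.1
    fc_thresh: float = 1.5
    n_perm: int = 10_000
    min_substrates: int = 3
    k_clusters: int = 6
    fuzzifier: float = 2.0
    n_runs: int = 100
    weight_threshold: int = 20
    epsilon: float = 0.01
    seed: int = 0
    out_dir: str = "results"

    def validate(self) -> None:
        if not (0 < self.q_thresh < 1):
            raise ValueError(f"q_thresh {self.q_thresh} outside (0, 1)")
        if self.fc_thresh <= 1:
            raise ValueError("fc_thresh must be > 1")
        if not (0 <= self.flr_threshold <= 1):
            raise ValueError("flr_threshold outside [0, 1]")
        if not (0 < self.weight_threshold <= self.n_runs):
            raise ValueError("0 < weight_threshold <= n_runs required")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.k_clusters < 1 or self.n_perm < 1:
            raise ValueError("k_clusters and n_perm must be positive")
        for name in ("peptide_table", "annotation", "ks_network", "receptor_id"):
            if not getattr(self, name):
                raise ValueError(f"config field {name} is required")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest (also written to disk).

    Any stage failure aborts with the stage name; outputs of completed
    stages are left in place.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_seeds = [int(s) for s in np.random.SeedSequence(config.seed).generate_state(4)]
    manifest: dict = {
        "config": asdict(config),
        "stage_seeds": {
            "kinase_activity": stage_seeds[0] % 2**31,
            "clustering": stage_seeds[1] % 2**31,
            "ensemble": stage_seeds[2] % 2**31,
        },
        "stages": {},
        "artifacts": {},
    }
    stage = "init"
    try:
        # -- normalization ---------------------------------------------------
        stage = "normalize"
        records = normalize.read_peptide_table(config.peptide_table)
        ann = normalize.read_annotation(config.annotation)
        records = normalize.filter_and_group_localization(records, config.flr_threshold)
        records = normalize.normalize_records(records)
        site_table = normalize.peptides_to_sites(records)
        site_path = out / "site_table.tsv"
        normalize.write_site_table(site_table, site_path)
        groups = {
            f"{g}_{tr}_t{t:g}": list(sub.index)
            for (g, tr, t), sub in ann.groupby(["genotype", "treatment", "time_min"])
        }
        abundance = site_table.drop(columns=["protein_id", "localized"])
        _cv_table, median_cv, n_skipped = normalize.compute_cv(abundance, groups)
        manifest["stages"][stage] = {
            "n_peptides": len(records),
            "n_sites": len(site_table),
            "median_cv_percent": median_cv,
            "cv_rows_skipped": n_skipped,
        }

        # -- differential calling -------------------------------------------
        stage = "differential"
        params = differential.TargetCallParams(config.q_thresh, config.fc_thresh)
        time_points = config.time_points or None
        results = differential.differential_analysis(
            abundance, ann, time_points, params, genotype="WT"
        )
        results, union = differential.call_targets(results, params)
        diff_path = out / "differential.tsv"
        results.to_csv(diff_path, sep="\t", index=False)
        manifest["stages"][stage] = {
            "targets_per_time": {
                f"{t:g}": int(grp["is_target"].sum())
                for t, grp in results.groupby("time_min")
            },
            "union_targets": len(union),
        }

        # -- kinase activity -------------------------------------------------
        stage = "kinase_activity"
        if config.ks_sets:
            ks_map = kinase_activity.read_ks_map(config.ks_sets)
            activity = kinase_activity.kinase_activity_analysis(
                results, ks_map, n_perm=config.n_perm,
                min_substrates=config.min_substrates,
                seed=manifest["stage_seeds"]["kinase_activity"],
            )
            activity.to_csv(out / "kinase_activity.tsv", sep="\t", index=False)
            manifest["stages"][stage] = {"n_kinase_timepoints": len(activity)}
        else:
            manifest["stages"][stage] = {"skipped": "no ks_sets configured"}

        # -- clustering ------------------------------------------------------
        stage = "clustering"
        profiles = kinase_activity.zscore_profiles(abundance, ann)
        target_profiles = profiles.loc[profiles.index.intersection(sorted(union))]
        if len(target_profiles) >= config.k_clusters:
            model = kinase_activity.fuzzy_cmeans(
                target_profiles, k=config.k_clusters, m=config.fuzzifier,
                seed=manifest["stage_seeds"]["clustering"],
            )
            memb = pd.DataFrame(
                model.membership, index=target_profiles.index,
                columns=[f"cluster_{i}" for i in range(config.k_clusters)],
            )
            memb.insert(0, "cluster", model.assignments())
            memb.to_csv(out / "cluster_membership.tsv", sep="\t")
            manifest["stages"][stage] = {"k": config.k_clusters, "n_sites": len(memb)}
            if config.ks_sets:
                enr = kinase_activity.cluster_enrichment(
                    model.assignments(), ks_map, background=set(site_table.index)
                )
                enr.to_csv(out / "cluster_enrichment.tsv", sep="\t", index=False)
        else:
            manifest["stages"][stage] = {
                "skipped": f"only {len(target_profiles)} targets for k={config.k_clusters}"
            }

        # -- PKN assembly ----------------------------------------------------
        stage = "pkn"
        graph = pkn.load_pkn(config.ks_network, config.ppi_network or None,
                             receptor=config.receptor_id)
        if config.grouping_map:
            graph = pkn.apply_grouping(graph, pkn.read_grouping(config.grouping_map))
        graph = pkn.attach_site_coupling(graph)
        pruned, unreachable = pkn.prune_to_reachable(graph, config.receptor_id, union)
        pkn.write_pkn(pruned, out / "pkn_pruned_edges.tsv", out / "pkn_pruned_nodes.tsv")
        manifest["stages"][stage] = {
            "n_nodes": pruned.number_of_nodes(),
            "n_edges": pruned.number_of_edges(),
            "unreachable_targets": unreachable,
        }

        # -- network inference ----------------------------------------------
        stage = "inference"
        scores = differential.scores_by_time(results)
        ens = inference.EnsembleParams(
            n_runs=config.n_runs, weight_threshold=config.weight_threshold,
            epsilon=config.epsilon, seed=manifest["stage_seeds"]["ensemble"],
        )
        solution = inference.bootstrap_ensemble(pruned, scores, ens)
        inference.export_solution(solution, out, prefix="network")
        manifest["stages"][stage] = {
            "consensus_edges": len(solution.consensus_edges()),
            "mean_unique_site_fraction": float(np.mean(solution.unique_site_fractions)),
            "n_failed_runs": solution.n_failed_runs,
        }
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    for p in sorted(out.glob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["artifacts"][p.name] = _sha256(p)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    summarize(out)
    return manifest


def summarize(results_dir) -> str:
    """Plain-text report over the pipeline outputs (absent stages marked)."""
    out = Path(results_dir)
    lines = ["# pipeline summary"]

    diff_path = out / "differential.tsv"
    if diff_path.exists():
        res = pd.read_csv(diff_path, sep="\t")
        lines.append("## targets per time point")
        for t, grp in res.groupby("time_min"):
            lines.append(f"t={t:g} min\t{int(grp['is_target'].sum())}")
        union = res.loc[res["is_target"], "site_id"].nunique()
        lines.append(f"union\t{union}")
    else:
        lines.append("## targets per time point: absent")

    act_path = out / "kinase_activity.tsv"
    if act_path.exists():
        act = pd.read_csv(act_path, sep="\t")
        lines.append("## significant kinases per time point (q < 0.05)")
        for t, grp in act.groupby("time_min"):
            lines.append(f"t={t:g} min\t{int((grp['q'] < 0.05).sum())}")
    else:
        lines.append("## kinase activity: absent")

    net_path = out / "network.json"
    if net_path.exists():
        doc = json.loads(net_path.read_text())
        weights = [
            e["weights"][str(doc["time_points"][-1])] for e in doc["edges"]
        ]
        lines.append("## network")
        lines.append(f"nodes\t{len(doc['nodes'])}")
        lines.append(f"edges_with_any_weight\t{len(doc['edges'])}")
        thr = doc["weight_threshold"]
        lines.append(f"consensus_edges(w>={thr})\t{sum(w >= thr for w in weights)}")
        hist, edges_ = np.histogram(weights, bins=[0, 20, 40, 60, 80, 100, 10**9])
        lines.append("weights_histogram\t" + ",".join(
            f"[{int(lo)},{int(hi)}):{int(n)}"
            for lo, hi, n in zip(edges_[:-1], edges_[1:], hist)
        ))
    else:
        lines.append("## network: absent")

    text = "\n".join(lines) + "\n"
    (out / "summary.txt").write_text(text)
    return text
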