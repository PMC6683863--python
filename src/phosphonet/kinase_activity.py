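"""Kinase-activity inference from regulated phosphosites.

Two complementary routes:

1. Per-time-point substrate-set enrichment: sites are ranked by log2 fold
   change and each kinase's validated substrate set is scored with a weighted
   Kolmogorov-Smirnov running sum (GSEA-style).  Significance and a normalized
   enrichment value (NEV) come from a substrate-label permutation null —
   positive NEV reads as kinase activation, negative as inhibition.

2. Time-course clustering: replicate-averaged, z-scored target profiles are
   split into k fuzzy c-means clusters, and predicted kinase-substrate sets
   are tested for over-representation in each cluster with one-sided Fisher
   exact tests against the full identified-site background, BH-corrected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .differential import bh_adjust

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Kinase-substrate maps (GMT-like TSV: kinase, source, site, site, ...)


def read_ks_map(path) -> dict[str, set[str]]:
    ks: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            kinase, _source, *sites = parts
            ks.setdefault(kinase, set()).update(s for s in sites if s)
    if any(not v for v in ks.values()):
        raise ValueError("empty substrate set in kinase-substrate map")
    return ks


def write_ks_map(ks: dict[str, set[str]], path, source: str = "validated") -> None:
    with open(path, "w") as fh:
        for kinase in sorted(ks):
            fh.write("\t".join([kinase, source, *sorted(ks[kinase])]) + "\n")


# ---------------------------------------------------------------------------
# Running-sum enrichment


def rank_sites(diff_results: pd.DataFrame) -> list[tuple[str, float]]:
    """Order sites by descending log2 fold change; ties break by site_id."""
    sub = diff_results[["site_id", "log2fc"]].dropna()
    ordered = sorted(zip(sub["site_id"], sub["log2fc"]), key=lambda x: (-x[1], x[0]))
    return [(s, float(m)) for s, m in ordered]


def enrichment_score(
    ranked: list[tuple[str, float]],
    substrates: set[str],
    min_substrates: int = 3,
) -> float | None:
    """Signed maximal deviation of the weighted KS running sum.

    Hits (measured substrates) increment the running sum proportionally to
    |metric|; misses decrement uniformly.  Kinases with fewer than
    ``min_substrates`` measured substrates are excluded (returns None).
    """
    if not ranked:
        raise ValueError("ranked list is empty")
    site_ids = [s for s, _ in ranked]
    metrics = np.array([m for _, m in ranked], dtype=float)
    hit = np.array([s in substrates for s in site_ids], dtype=bool)
    n_hits = int(hit.sum())
    if n_hits < min_substrates:
        logger.info("kinase set excluded: %d measured substrates", n_hits)
        return None
    return float(_running_sum_es(metrics, hit[None, :])[0])


def _running_sum_es(metrics: np.ndarray, hit: np.ndarray) -> np.ndarray:
    """Vectorized es for a (B, N) boolean hit matrix over one ranking."""
    B, N = hit.shape
    absm = np.abs(metrics)[None, :]
    hit_weight_sum = (absm * hit).sum(axis=1, keepdims=True)
    # all-zero hit metrics: fall back to unweighted hits
    inc = np.where(
        hit,
        np.where(hit_weight_sum > 0, absm / np.where(hit_weight_sum > 0, hit_weight_sum, 1.0),
                 1.0 / hit.sum(axis=1, keepdims=True)),
        -1.0 / (N - hit.sum(axis=1, keepdims=True)),
    )
    run = np.cumsum(inc, axis=1)
    idx = np.argmax(np.abs(run), axis=1)
    return run[np.arange(B), idx]


def normalized_enrichment(
    es: float,
    ranked: list[tuple[str, float]],
    substrates: set[str],
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Permutation-normalized enrichment value and permutation p-value.

    The null re-draws random substrate sets of the same size from the ranked
    sites.  nev = es / mean(|es_perm| of matching sign); p = add-one
    permutation p among matching-sign permutations.  Returns (nan, nan) if no
    permutation matches the sign of es.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    metrics = np.array([m for _, m in ranked], dtype=float)
    N = len(ranked)
    n = len({s for s, _ in ranked} & substrates)
    es_perm = np.empty(n_perm)
    chunk = 512
    for start in range(0, n_perm, chunk):
        b = min(chunk, n_perm - start)
        u = rng.random((b, N))
        cut = np.partition(u, n - 1, axis=1)[:, n - 1 : n]
        hit = u <= cut
        es_perm[start : start + b] = _running_sum_es(metrics, hit)
    same_sign = es_perm * es > 0
    n_same = int(same_sign.sum())
    if n_same == 0:
        logger.warning("no same-sign permutations; nev undefined")
        return float("nan"), float("nan")
    mean_abs = np.abs(es_perm[same_sign]).mean()
    nev = es / mean_abs
    p = (1 + int((np.abs(es_perm[same_sign]) >= abs(es)).sum())) / (n_same + 1)
    return float(nev), float(p)


@dataclass
class KinaseActivityResult:
    kinase_id: str
    time_min: float
    n_sites: int
    es: float
    nev: float
    p_perm: float
    q: float = float("nan")


def kinase_activity_analysis(
    diff_results: pd.DataFrame,
    ks_map: dict[str, set[str]],
    n_perm: int = 10_000,
    min_substrates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-time-point substrate enrichment for every kinase set.

    BH correction is applied across kinases within each time point.
    """
    frames = []
    root = np.random.SeedSequence(seed)
    for t, grp in diff_results.groupby("time_min"):
        ranked = rank_sites(grp)
        measured = {s for s, _ in ranked}
        rng = np.random.default_rng(root.spawn(1)[0])
        rows = []
        for kinase in sorted(ks_map):
            subs = ks_map[kinase] & measured
            es = enrichment_score(ranked, subs, min_substrates)
            if es is None:
                continue
            nev, p = normalized_enrichment(es, ranked, subs, n_perm, rng)
            rows.append((kinase, float(t), len(subs), es, nev, p))
        df = pd.DataFrame(
            rows, columns=["kinase_id", "time_min", "n_sites", "es", "nev", "p_perm"]
        )
        if len(df):
            df["q"] = bh_adjust(df["p_perm"].to_numpy())
        frames.append(df)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["kinase_id", "time_min", "n_sites", "es", "nev", "p_perm", "q"]
    )


# ---------------------------------------------------------------------------
# Fuzzy c-means clustering of target time courses


@dataclass
class ClusterModel:
    """Fitted fuzzy c-means model over site x time profiles."""

    profiles: pd.DataFrame
    k: int
    m: float
    membership: np.ndarray  # sites x k, rows sum to 1
    centers: np.ndarray  # k x time
    objective_trace: list[float] = field(default_factory=list)
    seed: int | None = None

    def assignments(self) -> pd.Series:
        """Hard cluster labels by argmax membership."""
        return pd.Series(self.membership.argmax(axis=1), index=self.profiles.index)


def zscore_profiles(site_table: pd.DataFrame, annotation: pd.DataFrame,
                    genotype: str = "WT", treatment: str = "stimulated") -> pd.DataFrame:
    """Replicate-averaged, per-site z-scored time profiles."""
    sel = annotation[(annotation["genotype"] == genotype) & (annotation["treatment"] == treatment)]
    by_time = {
        float(t): site_table[list(g.index)].mean(axis=1, skipna=True)
        for t, g in sel.groupby("time_min")
    }
    prof = pd.DataFrame(by_time).sort_index(axis=1)
    prof = prof.dropna()
    mu = prof.mean(axis=1)
    sd = prof.std(axis=1, ddof=0)
    return prof.sub(mu, axis=0).div(sd.where(sd > 0, 1.0), axis=0)


def fuzzy_cmeans(
    profiles: pd.DataFrame,
    k: int = 6,
    m: float = 2.0,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> ClusterModel:
    """Standard fuzzy c-means with alternating membership/center updates.

    Deterministic given the seed; iterates until the largest center shift
    falls below ``tol``.  The weighted within-cluster objective is recorded
    per iteration and is non-increasing.
    """
    X = profiles.to_numpy(dtype=float)
    n = X.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of sites {n}")
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    rng = np.random.default_rng(seed)
    u = rng.random((n, k))
    u /= u.sum(axis=1, keepdims=True)
    trace: list[float] = []
    centers = np.empty((k, X.shape[1]))
    for _ in range(max_iter):
        w = u**m
        centers_new = (w.T @ X) / w.sum(axis=0)[:, None]
        d2 = ((X[:, None, :] - centers_new[None, :, :]) ** 2).sum(axis=2)
        trace.append(float((w * d2).sum()))
        d2c = np.maximum(d2, 1e-12)
        inv = d2c ** (-1.0 / (m - 1.0))
        u = inv / inv.sum(axis=1, keepdims=True)
        zero = d2 <= 1e-12  # site coincides with a center
        if zero.any():
            rows = zero.any(axis=1)
            u[rows] = zero[rows] / zero[rows].sum(axis=1, keepdims=True)
        shift = np.abs(centers_new - centers).max() if _ else np.inf
        centers = centers_new
        if shift < tol:
            break
    return ClusterModel(profiles=profiles, k=k, m=m, membership=u, centers=centers,
                        objective_trace=trace, seed=seed)


# ---------------------------------------------------------------------------
# Per-cluster Fisher enrichment


@dataclass
class ClusterEnrichment:
    cluster_id: int
    kinase_id: str
    a: int  # in-cluster substrates
    b: int  # in-cluster non-substrates
    c: int  # out-of-cluster substrates (within background)
    d: int  # out-of-cluster non-substrates
    odds_ratio: float
    p: float
    q: float = float("nan")


def cluster_enrichment(
    assignments: pd.Series,
    ks_map: dict[str, set[str]],
    background: set[str],
) -> pd.DataFrame:
    """One-sided Fisher enrichment of substrate sets per cluster.

    The 2x2 table partitions the full identified-site ``background``:
    in-cluster substrates / in-cluster non-substrates / out-of-cluster
    substrates / out-of-cluster non-substrates.  BH over all
    (cluster, kinase) pairs.  Kinases with no measured substrates are skipped.
    """
    rows = []
    n_bg = len(background)
    for cluster_id in sorted(assignments.unique()):
        in_cluster = set(assignments.index[assignments == cluster_id]) & background
        for kinase in sorted(ks_map):
            subs = ks_map[kinase] & background
            if not subs:
                continue
            a = len(in_cluster & subs)
            b = len(in_cluster) - a
            c = len(subs) - a
            d = n_bg - a - b - c
            odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
            rows.append((int(cluster_id), kinase, a, b, c, d, float(odds), float(p)))
    df = pd.DataFrame(
        rows, columns=["cluster_id", "kinase_id", "a", "b", "c", "d", "odds_ratio", "p"]
    )
    if len(df):
        df["q"] = bh_adjust(df["p"].to_numpy())
    return df
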