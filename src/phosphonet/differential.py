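"""Per-time-point differential testing of phosphosite abundances.

Stimulated and mock replicate groups are compared site-by-site with two-tailed
unpaired (pooled-variance) t-tests at each time point, corrected with
Benjamini-Hochberg within the time point.  A site is a regulated target when
q < qThresh and |fold change| exceeds fcThresh.  Every measured site then gets
the network-inference score s = log2(q / qThresh): negative for regulated
sites (rewarded by the ILP objective) and positive for unregulated ones
(penalized when the network must pass through them).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

_TINY = np.finfo(float).tiny


@dataclass(frozen=True)
class TargetCallParams:
    """Thresholds for calling a site a regulated target."""

    q_thresh: float = 0.1
    fc_thresh: float = 1.5

    def __post_init__(self) -> None:
        if not (0.0 < self.q_thresh < 1.0):
            raise ValueError("q_thresh must be in (0, 1)")
        if self.fc_thresh <= 1.0:
            raise ValueError("fc_thresh must be > 1")


def differential_test(
    site_table: pd.DataFrame,
    annotation: pd.DataFrame,
    time_min: float,
    genotype: str = "WT",
    equal_var: bool = True,
) -> pd.DataFrame:
    """Two-sided two-sample t-test of stimulated vs mock at one time point.

    Sites with fewer than two non-missing replicates in either group are
    dropped (count logged).  Zero-variance degeneracies, which triplicate MS
    data can produce, are resolved rather than raised: equal means give p = 1,
    unequal means give the smallest positive p.

    Returns a DataFrame indexed by site_id with columns log2fc, t_stat, p.
    """
    sel = (annotation["time_min"] == time_min) & (annotation["genotype"] == genotype)
    stim_ids = annotation.index[sel & (annotation["treatment"] == "stimulated")]
    mock_ids = annotation.index[sel & (annotation["treatment"] == "mock")]
    if len(stim_ids) < 2 or len(mock_ids) < 2:
        raise ValueError(f"need >= 2 replicates per group at t={time_min}")

    stim = site_table[list(stim_ids)].astype(float)
    mock = site_table[list(mock_ids)].astype(float)
    ok = (stim.notna().sum(axis=1) >= 2) & (mock.notna().sum(axis=1) >= 2)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("t=%s: dropped %d sites with insufficient replicates", time_min, n_dropped)
    stim, mock = stim[ok], mock[ok]

    rows = []
    for site_id in stim.index:
        a = stim.loc[site_id].dropna().to_numpy()
        b = mock.loc[site_id].dropna().to_numpy()
        mean_a, mean_b = a.mean(), b.mean()
        log2fc = float(np.log2(mean_a / mean_b)) if mean_a > 0 and mean_b > 0 else np.nan
        if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
            if mean_a == mean_b:
                t, p = 0.0, 1.0
            else:
                t = np.inf if mean_a > mean_b else -np.inf
                p = _TINY
                logger.warning("site %s: zero variance, unequal means", site_id)
        else:
            t, p = stats.ttest_ind(a, b, equal_var=equal_var)
            t, p = float(t), float(p)
        rows.append((site_id, log2fc, t, p))
    return pd.DataFrame(
        rows, columns=["site_id", "log2fc", "t_stat", "p"]
    ).set_index("site_id")


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def ilp_scores(q: np.ndarray, q_thresh: float = 0.1) -> np.ndarray:
    """Network-inference scores s = log2(q / qThresh).

    Zero at the threshold, negative for sites below it (regulated), strictly
    increasing in q.  q = 0 is clamped to the smallest positive float with a
    warning.
    """
    if not (0.0 < q_thresh < 1.0):
        raise ValueError("q_thresh must be in (0, 1)")
    q = np.asarray(q, dtype=float)
    if np.any((q < 0) | (q > 1)):
        raise ValueError("q-values must be in [0, 1]")
    if np.any(q == 0):
        logger.warning("q = 0 clamped to smallest positive float")
        q = np.maximum(q, _TINY)
    return np.log2(q / q_thresh)


def differential_analysis(
    site_table: pd.DataFrame,
    annotation: pd.DataFrame,
    time_points: list[float] | None = None,
    params: TargetCallParams = TargetCallParams(),
    genotype: str = "WT",
) -> pd.DataFrame:
    """Full per-time-point differential workflow.

    For every time point: t-tests, BH correction over that time point's sites
    (the correction family), target calls and ILP scores.  Returns one long
    DataFrame with columns site_id, time_min, log2fc, t_stat, p, q, is_target,
    score.
    """
    if time_points is None:
        time_points = sorted(
            annotation.loc[annotation["genotype"] == genotype, "time_min"].unique()
        )
    frames = []
    for t in time_points:
        res = differential_test(site_table, annotation, t, genotype=genotype)
        res = res[np.isfinite(res["log2fc"])].copy()
        res["q"] = bh_adjust(res["p"].to_numpy())
        res["is_target"] = (res["q"] < params.q_thresh) & (
            np.abs(res["log2fc"]) > np.log2(params.fc_thresh)
        )
        res["score"] = ilp_scores(res["q"].to_numpy(), params.q_thresh)
        res["time_min"] = t
        frames.append(res.reset_index())
    cols = ["site_id", "time_min", "log2fc", "t_stat", "p", "q", "is_target", "score"]
    return pd.concat(frames, ignore_index=True)[cols]


def call_targets(
    results: pd.DataFrame, params: TargetCallParams = TargetCallParams()
) -> tuple[pd.DataFrame, set[str]]:
    """(Re)apply target thresholds and form the union set over time points.

    The union — sites flagged at one or more time points — is the regulated
    target set the network model must explain.
    """
    results = results.copy()
    results["is_target"] = (results["q"] < params.q_thresh) & (
        np.abs(results["log2fc"]) > np.log2(params.fc_thresh)
    )
    union = set(results.loc[results["is_target"], "site_id"])
    return results, union


def scores_by_time(results: pd.DataFrame) -> dict[float, dict[str, float]]:
    """Pivot a differential result table to {time: {site_id: score}}."""
    out: dict[float, dict[str, float]] = {}
    for t, grp in results.groupby("time_min"):
        out[float(t)] = dict(zip(grp["site_id"], grp["score"]))
    return out
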