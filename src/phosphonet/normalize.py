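"""Phosphopeptide input handling, localization filtering and spike-in normalization.

The quantification scheme assumes every sample (light channel) was mixed with a
pooled, isotope-labelled internal-standard sample (heavy channel) before LC-MS.
Normalization then works on light-to-heavy ratios: a per-sample median scaling
removes mixing errors, and the peptide-specific heavy intensity removes
peptide-level ionization differences.  Phosphopeptides with poorly localized
phosphate positions (false localisation rate above threshold) are retained as
grouped "positional isomer" records carrying the most likely localization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_PHOSPHO_RESIDUES = frozenset("STY")


@dataclass
class PhosphopeptideRecord:
    """One quantified phosphopeptide with per-sample light/heavy MS1 intensities.

    Intensities are keyed by sample id; missing values are simply absent from
    the maps.  ``phospho_positions`` are 1-based residue coordinates on the
    host protein.
    """

    peptide_id: str
    backbone_sequence: str
    protein_id: str
    phospho_positions: list[int]
    phospho_residues: list[str]
    n_phospho: int
    flr: float
    localization_score: float
    light_intensity: dict[str, float] = field(default_factory=dict)
    heavy_intensity: dict[str, float] = field(default_factory=dict)
    localized: bool = True

    def __post_init__(self) -> None:
        if self.n_phospho < 1:
            raise ValueError(f"{self.peptide_id}: n_phospho must be >= 1")
        if not (0.0 <= self.flr <= 1.0):
            raise ValueError(f"{self.peptide_id}: flr must be in [0, 1]")
        if len(self.phospho_positions) != self.n_phospho:
            raise ValueError(
                f"{self.peptide_id}: {len(self.phospho_positions)} positions "
                f"for n_phospho={self.n_phospho}"
            )
        bad = set(self.phospho_residues) - VALID_PHOSPHO_RESIDUES
        if bad:
            raise ValueError(f"{self.peptide_id}: invalid phospho residues {bad}")
        for m in (self.light_intensity, self.heavy_intensity):
            for s, v in m.items():
                if v < 0:
                    raise ValueError(f"{self.peptide_id}: negative intensity in {s}")


def filter_and_group_localization(
    records: list[PhosphopeptideRecord], flr_threshold: float = 0.01
) -> list[PhosphopeptideRecord]:
    """Split records into confidently localized and grouped ambiguous ones.

    Records at or below ``flr_threshold`` pass unchanged (``localized=True``).
    Records above the threshold are positional isomers: all isomers sharing a
    backbone sequence and phosphate count collapse to a single record that
    carries the positions and intensities of the isomer with the highest
    localization score, flagged ``localized=False``.

    Groups in which any member lacks a localization score cannot be ranked and
    are dropped with a logged diagnostic.
    """
    passed: list[PhosphopeptideRecord] = []
    ambiguous: dict[tuple[str, int], list[PhosphopeptideRecord]] = {}
    for rec in records:
        if rec.flr <= flr_threshold:
            passed.append(replace(rec, localized=True))
        else:
            ambiguous.setdefault((rec.backbone_sequence, rec.n_phospho), []).append(rec)

    out = passed
    for key, group in sorted(ambiguous.items()):
        if any(g.localization_score is None or np.isnan(g.localization_score) for g in group):
            logger.warning(
                "dropping ambiguous isomer group %s: missing localization score", key
            )
            continue
        best = max(group, key=lambda g: g.localization_score)
        out.append(replace(best, localized=False))
    return out


def gist_normalize(light: pd.DataFrame, heavy: pd.DataFrame) -> pd.DataFrame:
    """Two-step internal-standard normalization of light MS1 intensities.

    Step 1 equalizes the per-sample medians of the light-to-heavy ratio
    distributions (compensating sample/standard mixing errors): each sample's
    ratios are scaled so its median is 1, the natural scale for a ratio to
    the internal standard.  Step 2 is the peptide-specific normalization
    itself: the reported abundance is the (scaled) light/heavy ratio.
    Anchoring medians at 1 rather than at a data-derived global constant
    makes the output exactly invariant to multiplying any sample's entire
    light column by a constant — a data-derived anchor would itself shift
    under such an error.

    Entries where the heavy intensity is missing or zero while light is
    present become missing (NaN), never zero.

    Parameters
    ----------
    light, heavy
        Aligned peptide x sample matrices (same index and columns).
    """
    if not light.index.equals(heavy.index) or not light.columns.equals(heavy.columns):
        raise ValueError("light and heavy matrices must share index and columns")
    heavy_ok = heavy.where(heavy > 0)
    ratio = light / heavy_ok  # NaN where either channel missing or heavy == 0
    sample_medians = ratio.median(axis=0, skipna=True)
    return ratio / sample_medians


def peptides_to_sites(records: list[PhosphopeptideRecord]) -> pd.DataFrame:
    """Convert normalized peptide records to a one-row-per-phosphosite table.

    Every phosphate position on every peptide nominates a candidate row for the
    site ``PROTEIN_<residue><position>``.  When several peptides cover the same
    site, the representative is the peptide with the fewest phosphates (the
    least ambiguous quantification), ties broken by highest median abundance.
    Ambiguous (``localized=False``) records contribute their most likely
    positions.

    Records are expected to carry normalized abundances in
    ``light_intensity`` (the normalization step rewrites them in the
    pipeline); the abundance map is emitted per site as sample columns.
    """
    candidates: dict[str, PhosphopeptideRecord] = {}

    def _median_abundance(rec: PhosphopeptideRecord) -> float:
        vals = [v for v in rec.light_intensity.values() if np.isfinite(v)]
        return float(np.median(vals)) if vals else -np.inf

    for rec in records:
        for pos, res in zip(rec.phospho_positions, rec.phospho_residues):
            site_id = f"{rec.protein_id}_{res}{pos}"
            cur = candidates.get(site_id)
            if cur is None:
                candidates[site_id] = rec
                continue
            if (rec.n_phospho, -_median_abundance(rec)) < (
                cur.n_phospho,
                -_median_abundance(cur),
            ):
                candidates[site_id] = rec

    sample_ids = sorted({s for r in records for s in r.light_intensity})
    rows = []
    for site_id in sorted(candidates):
        rec = candidates[site_id]
        row = {"site_id": site_id, "protein_id": rec.protein_id, "localized": rec.localized}
        for s in sample_ids:
            row[s] = rec.light_intensity.get(s, np.nan)
        rows.append(row)
    table = pd.DataFrame(rows, columns=["site_id", "protein_id", "localized", *sample_ids])
    return table.set_index("site_id")


def compute_cv(
    table: pd.DataFrame, groups: dict[str, list[str]]
) -> tuple[pd.DataFrame, float, int]:
    """Per-row coefficient of variation (%) within replicate groups.

    ``groups`` maps a group label to its replicate sample columns.  CV is the
    sample standard deviation over the mean, in percent.  Rows with fewer than
    two non-missing replicates or a zero mean in a group are skipped for that
    group; the skip count is returned.

    Returns
    -------
    (cv_table, median_cv, n_skipped) where cv_table is row x group CVs in %.
    """
    cv_cols = {}
    n_skipped = 0
    for label, cols in groups.items():
        sub = table[cols].astype(float)
        n = sub.notna().sum(axis=1)
        mean = sub.mean(axis=1, skipna=True)
        sd = sub.std(axis=1, ddof=1, skipna=True)
        cv = sd / mean * 100.0
        bad = (n < 2) | (mean == 0) | ~np.isfinite(cv)
        n_skipped += int(bad.sum())
        cv_cols[label] = cv.where(~bad)
    cv_table = pd.DataFrame(cv_cols, index=table.index)
    median_cv = float(np.nanmedian(cv_table.to_numpy())) if cv_table.size else float("nan")
    return cv_table, median_cv, n_skipped


# ---------------------------------------------------------------------------
# TSV interfaces


def read_peptide_table(path) -> list[PhosphopeptideRecord]:
    """Read a phosphopeptide TSV (light:/heavy: paired intensity columns)."""
    df = pd.read_csv(path, sep="\t")
    light_cols = [c for c in df.columns if c.startswith("light:")]
    heavy_cols = [c for c in df.columns if c.startswith("heavy:")]
    records = []
    for _, row in df.iterrows():
        positions = [int(x) for x in str(row["positions"]).split(";")]
        residues = list(str(row["residues"]).replace(";", ""))
        light = {
            c.split(":", 1)[1]: float(row[c]) for c in light_cols if np.isfinite(row[c])
        }
        heavy = {
            c.split(":", 1)[1]: float(row[c]) for c in heavy_cols if np.isfinite(row[c])
        }
        records.append(
            PhosphopeptideRecord(
                peptide_id=str(row["peptide_id"]),
                backbone_sequence=str(row["backbone_sequence"]),
                protein_id=str(row["protein_id"]),
                phospho_positions=positions,
                phospho_residues=residues,
                n_phospho=int(row["n_phospho"]),
                flr=float(row["flr"]),
                localization_score=float(row["localization_score"]),
                light_intensity=light,
                heavy_intensity=heavy,
            )
        )
    return records


def read_annotation(path) -> pd.DataFrame:
    """Read the sample annotation TSV and validate replicate uniqueness."""
    ann = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "cell_line", "genotype", "treatment", "time_min", "replicate"}
    missing = required - set(ann.columns)
    if missing:
        raise ValueError(f"annotation missing columns: {sorted(missing)}")
    key = ["genotype", "treatment", "time_min", "replicate", "cell_line"]
    if ann.duplicated(subset=key).any():
        raise ValueError("duplicate (genotype, treatment, time, replicate) rows")
    return ann.set_index("sample_id", drop=False)


def records_to_matrices(
    records: list[PhosphopeptideRecord],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stack record intensity maps into aligned light/heavy matrices."""
    sample_ids = sorted(
        {s for r in records for s in r.light_intensity}
        | {s for r in records for s in r.heavy_intensity}
    )
    idx = [r.peptide_id for r in records]
    light = pd.DataFrame(
        [[r.light_intensity.get(s, np.nan) for s in sample_ids] for r in records],
        index=idx,
        columns=sample_ids,
    )
    heavy = pd.DataFrame(
        [[r.heavy_intensity.get(s, np.nan) for s in sample_ids] for r in records],
        index=idx,
        columns=sample_ids,
    )
    return light, heavy


def normalize_records(
    records: list[PhosphopeptideRecord],
) -> list[PhosphopeptideRecord]:
    """Apply :func:`gist_normalize` and rewrite each record's abundances."""
    light, heavy = records_to_matrices(records)
    norm = gist_normalize(light, heavy)
    out = []
    for rec in records:
        row = norm.loc[rec.peptide_id]
        if isinstance(row, pd.DataFrame):  # duplicate peptide ids
            row = row.iloc[0]
        vals = {s: float(v) for s, v in row.items() if np.isfinite(v)}
        out.append(replace(rec, light_intensity=vals))
    return out


def write_site_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t")


def read_site_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="site_id")
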