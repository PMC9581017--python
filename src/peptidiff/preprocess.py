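"""The pre-processing chain: log10 transform, normalization, cutoffs.

Order is fixed: log10 transform of intensities, then optional
normalization (global or on a housekeeping protein), then peptide-level
cutoffs (abundance thresholds, 3-sigma retention-time / collision-cross-
section outlier removal per sample), then protein-level cutoffs.
Protein cutoffs always run after peptide cutoffs, so a protein whose
peptides are individually weak is removed even if its original
cumulative abundance was high.

Normalization rescales every value in a sample by a single factor so
that sample totals (global mode) or housekeeping-protein totals
(housekeeping mode) coincide with their across-sample mean.  Intensity
and spectral count are normalized independently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .ingest import GroupedDataset

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessError",
    "NormalizationSpec",
    "CutoffSpec",
    "log10_transform",
    "normalize_global",
    "normalize_housekeeping",
    "flag_sigma_outliers",
    "apply_peptide_cutoffs",
    "apply_protein_cutoffs",
    "run_preprocessing",
]

METRIC_COLUMNS = ("intensity", "spectral_count")


class PreprocessError(ValueError):
    pass


@dataclass
class NormalizationSpec:
    """How (and whether) to normalize, and whether to skip the log10 step."""

    mode: str = "none"  # none | global | housekeeping
    housekeeping_accession: str | None = None
    skip_log10: bool = False

    def __post_init__(self):
        if self.mode not in ("none", "global", "housekeeping"):
            raise PreprocessError(f"unknown normalization mode {self.mode!r}")
        if self.mode == "housekeeping" and not self.housekeeping_accession:
            raise PreprocessError(
                "housekeeping normalization requires housekeeping_accession")


@dataclass
class CutoffSpec:
    """Peptide- and protein-level removal thresholds.

    Values *below* a threshold are removed, so equality survives; all
    thresholds default to 0 (no-op) and the outlier filters to off.
    """

    peptide_min_intensity: float = 0.0
    peptide_min_spectral_count: float = 0.0
    drop_rt_outliers: bool = False
    drop_ccs_outliers: bool = False
    protein_min_total_intensity: float = 0.0
    protein_min_total_spectral_count: float = 0.0
    protein_min_peptides: int = 0

    def __post_init__(self):
        for name in ("peptide_min_intensity", "peptide_min_spectral_count",
                     "protein_min_total_intensity",
                     "protein_min_total_spectral_count",
                     "protein_min_peptides"):
            if getattr(self, name) < 0:
                raise PreprocessError(f"{name} must be non-negative")


def log10_transform(dataset: GroupedDataset,
                    skip_log10: bool = False) -> GroupedDataset:
    """Replace every positive intensity by its base-10 logarithm.

    Zero intensities stay 0 and are flagged in an ``intensity_missing``
    column (a zero means "not quantified", not "abundance 1").  Spectral
    counts are untouched.  With ``skip_log10`` the data are returned
    unchanged, for inputs that are already on a log scale.
    """
    ds = dataset.copy()
    if skip_log10:
        return ds
    for s in ds.samples():
        v = s.records["intensity"].to_numpy(dtype=float, copy=True)
        if (v < 0).any():
            row = int(np.flatnonzero(v < 0)[0])
            raise PreprocessError(
                f"negative intensity in sample {s.sample_id!r}, row {row}")
        s.records["intensity_missing"] = v == 0
        pos = v > 0
        v[pos] = np.log10(v[pos])
        s.records["intensity"] = v
    ds.log_transformed = True
    return ds


def _scale_sample(sample, factors: dict[str, float]) -> None:
    for col, f in factors.items():
        sample.records[col] = sample.records[col].astype(float) * f


def normalize_global(dataset: GroupedDataset) -> GroupedDataset:
    """Equalize every sample's total to the across-sample mean total.

    Each value p in sample s becomes mean_j(total_j) * p / total_s,
    independently for intensity and spectral count.  Samples with a zero
    total are left unaltered (with a warning).
    """
    ds = dataset.copy()
    samples = ds.samples()
    if not samples:
        return ds
    for col in METRIC_COLUMNS:
        totals = np.array([s.records[col].sum() for s in samples], dtype=float)
        if not (totals > 0).any():
            logger.warning("all samples have zero %s total; skipped", col)
            continue
        mean_total = totals.mean()
        for s, t in zip(samples, totals):
            if t > 0:
                _scale_sample(s, {col: mean_total / t})
            else:
                logger.warning("sample %s has zero %s total; left unaltered",
                               s.sample_id, col)
    ds.normalization = "global"
    return ds


def normalize_housekeeping(dataset: GroupedDataset,
                           accession: str) -> GroupedDataset:
    """Scale each sample so the housekeeping protein's total matches the
    mean over the samples that contain it.

    Every value in sample s (all proteins, each metric independently) is
    multiplied by mean_j(P_j) / P_s where P is the housekeeping
    protein's per-sample total.  Samples lacking the protein are left
    unaltered.
    """
    ds = dataset.copy()
    acc = ds.proteome.resolve(accession)
    if acc is None:
        raise PreprocessError(f"accession {accession!r} not in proteome")
    samples = ds.samples()
    for col in METRIC_COLUMNS:
        totals = np.array([
            s.records.loc[s.records["accession"] == acc, col].sum()
            for s in samples
        ], dtype=float)
        present = totals > 0
        if not present.any():
            logger.warning("housekeeping protein %s absent from every sample; "
                           "%s left unaltered", acc, col)
            continue
        mean_total = totals[present].mean()
        for s, t, ok in zip(samples, totals, present):
            if ok:
                _scale_sample(s, {col: mean_total / t})
    ds.normalization = f"housekeeping:{acc}"
    return ds


def flag_sigma_outliers(values) -> np.ndarray:
    """Flag values lying strictly more than 3 population SDs from the mean.

    This is the 3-sigma rule (68-95-99.7): under a Gaussian ~99.7% of
    values survive.  NaNs are excluded from the mean/SD and never
    flagged; with fewer than 3 finite values or zero SD nothing is
    flagged.  Returns a boolean array aligned with the input.
    """
    v = np.asarray(values, dtype=float)
    flags = np.zeros(v.shape, dtype=bool)
    finite = np.isfinite(v)
    if finite.sum() < 3:
        return flags
    mean = v[finite].mean()
    sd = v[finite].std()  # population SD
    if sd == 0:
        return flags
    flags[finite] = np.abs(v[finite] - mean) > 3.0 * sd
    return flags


def apply_peptide_cutoffs(
    dataset: GroupedDataset, cutoffs: CutoffSpec
) -> tuple[GroupedDataset, dict[str, dict[str, int]]]:
    """Remove peptide records below the abundance thresholds and, when
    requested, per-sample RT / CCS 3-sigma outliers.

    Returns the filtered dataset and a per-sample report of removal
    counts.  An outlier filter requested on a sample whose column is
    entirely missing is skipped with a warning.
    """
    ds = dataset.copy()
    report: dict[str, dict[str, int]] = {}
    outlier_cols = [("rt", cutoffs.drop_rt_outliers),
                    ("ccs", cutoffs.drop_ccs_outliers)]
    for s in ds.samples():
        r = s.records
        drop = np.zeros(len(r), dtype=bool)
        counts: dict[str, int] = {}

        below_int = r["intensity"].to_numpy(float) < cutoffs.peptide_min_intensity
        below_spc = (r["spectral_count"].to_numpy(float)
                     < cutoffs.peptide_min_spectral_count)
        counts["below_intensity"] = int(below_int.sum())
        counts["below_spectral_count"] = int((below_spc & ~below_int).sum())
        drop |= below_int | below_spc

        for col, enabled in outlier_cols:
            if not enabled:
                continue
            vals = r[col].to_numpy(float)
            if len(vals) and not np.isfinite(vals).any():
                logger.warning("sample %s has no %s values; outlier filter "
                               "skipped", s.sample_id, col)
                continue
            out = flag_sigma_outliers(vals)
            counts[f"{col}_outliers"] = int((out & ~drop).sum())
            drop |= out

        counts["removed_total"] = int(drop.sum())
        s.records = r.loc[~drop].reset_index(drop=True)
        report[s.sample_id] = counts
    return ds, report


def apply_protein_cutoffs(
    dataset: GroupedDataset, cutoffs: CutoffSpec
) -> tuple[GroupedDataset, dict[str, dict[str, int]]]:
    """Remove, per sample, every record of a protein whose per-sample
    cumulative intensity or spectral count is below its threshold, or
    which retains fewer peptide records than ``protein_min_peptides``.

    Run after :func:`apply_peptide_cutoffs` (the pipeline enforces the
    order), so cumulative abundances reflect surviving peptides only.
    """
    ds = dataset.copy()
    report: dict[str, dict[str, int]] = {}
    for s in ds.samples():
        r = s.records
        if r.empty:
            report[s.sample_id] = {"proteins_removed": 0, "records_removed": 0}
            continue
        g = r.groupby("accession")
        agg = g.agg(total_intensity=("intensity", "sum"),
                    total_spc=("spectral_count", "sum"),
                    n_peptides=("clean_sequence", "size"))
        bad = agg.index[
            (agg["total_intensity"] < cutoffs.protein_min_total_intensity)
            | (agg["total_spc"] < cutoffs.protein_min_total_spectral_count)
            | (agg["n_peptides"] < cutoffs.protein_min_peptides)
        ]
        drop = r["accession"].isin(bad)
        report[s.sample_id] = {"proteins_removed": len(bad),
                               "records_removed": int(drop.sum())}
        s.records = r.loc[~drop].reset_index(drop=True)
    return ds, report


def run_preprocessing(
    dataset: GroupedDataset,
    normalization: NormalizationSpec | None = None,
    cutoffs: CutoffSpec | None = None,
) -> tuple[GroupedDataset, dict]:
    """Full chain in canonical order: log10 -> normalization -> peptide
    cutoffs -> protein cutoffs.  Returns the processed dataset and a
    report with per-sample removal counts."""
    norm = normalization or NormalizationSpec()
    cuts = cutoffs or CutoffSpec()
    ds = log10_transform(dataset, skip_log10=norm.skip_log10)
    if norm.mode == "global":
        ds = normalize_global(ds)
    elif norm.mode == "housekeeping":
        ds = normalize_housekeeping(ds, norm.housekeeping_accession)
    ds, pep_report = apply_peptide_cutoffs(ds, cuts)
    ds, prot_report = apply_protein_cutoffs(ds, cuts)
    return ds, {"peptide_cutoffs": pep_report, "protein_cutoffs": prot_report}
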