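"""Peptide-level view: mapping peptides onto their precursor sequence.

Each peptide is located at its first occurrence in the precursor's FASTA
sequence (1-based inclusive coordinates).  A coverage profile then gives,
for every residue position, the number of overlapping peptide records
and the summed abundance ("height"); groups can be profiled either as
stacked individual samples or as a group mean (per-position sum divided
by the number of samples in the group).  The difference of the two group
height traces points to regions of differential proteolysis.

Peptides that cannot be found in the FASTA sequence (isoform mismatches,
ambiguous residues) are excluded from profiles and reported, never
silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._filters import apply_filter
from .ingest import GroupedDataset, SampleTable
from .protein_view import AbundanceMetric, group_compare_pvalue

logger = logging.getLogger(__name__)

__all__ = [
    "P_VALUE_SENTINEL",
    "LocatedPeptide",
    "CoverageProfile",
    "locate_peptide",
    "coverage_profile",
    "difference_trace",
    "peptide_table",
    "coverage_table",
    "coverage_figure",
]

#: rendered in peptide tables when a p-value is not computed
P_VALUE_SENTINEL = -1.0


@dataclass
class LocatedPeptide:
    """A peptide anchored in its precursor (1-based inclusive coords)."""

    clean_sequence: str
    accession: str
    start: int
    end: int


@dataclass
class CoverageProfile:
    """Per-residue coverage of one protein within one scope
    (a group or a single sample)."""

    accession: str
    scope: str  # group label or "group:sample" identifier
    overlap_count: np.ndarray  # int, len == protein length
    height: np.ndarray  # float, len == protein length
    weight: float  # sum of the metric over the scope's located records
    n_samples: int = 1
    #: clean sequences that could not be located in the FASTA sequence
    unlocated: list[str] = field(default_factory=list)


def locate_peptide(clean_sequence: str,
                   protein_sequence: str) -> tuple[int, int] | None:
    """1-based inclusive coordinates of the first occurrence of the
    peptide in the protein, or ``None`` if absent."""
    idx = protein_sequence.find(clean_sequence)
    if idx < 0 or not clean_sequence:
        return None
    return idx + 1, idx + len(clean_sequence)


def _locate_unique(sequences, protein_seq: str) -> dict[str, tuple[int, int]]:
    locs = {}
    for seq in set(sequences):
        pos = locate_peptide(seq, protein_seq)
        if pos is not None:
            locs[seq] = pos
    return locs


def _sample_arrays(records: pd.DataFrame, locs: dict, length: int,
                   quantity: str):
    """Overlap/height arrays for one sample's records of one protein."""
    overlap = np.zeros(length, dtype=int)
    height = np.zeros(length, dtype=float)
    weight = 0.0
    unlocated: list[str] = []
    for seq, val in zip(records["clean_sequence"],
                        records[quantity].astype(float)):
        pos = locs.get(seq)
        if pos is None:
            unlocated.append(seq)
            continue
        start, end = pos
        overlap[start - 1:end] += 1
        height[start - 1:end] += val
        weight += val
    return overlap, height, weight, unlocated


def coverage_profile(dataset: GroupedDataset, accession: str,
                     metric: AbundanceMetric, scope: str = "group_mean"):
    """Coverage profiles of one protein for both groups.

    ``scope="group_mean"`` returns ``{group_label: CoverageProfile}``
    with per-position heights averaged over the group's samples (all
    samples count, including those without the protein).
    ``scope="per_sample"`` returns ``{group_label: [CoverageProfile per
    sample]}`` for stacked display; summing the per-sample heights gives
    n_samples times the group-mean height.

    Peptide multiplicity within the protein is resolved to the first
    occurrence; records whose sequence is not found in the FASTA entry
    are excluded and listed in ``unlocated``.
    """
    if scope not in ("group_mean", "per_sample"):
        raise ValueError(f"unknown scope {scope!r}")
    acc = dataset.proteome.resolve(accession)
    if acc is None:
        raise KeyError(f"accession {accession!r} not in proteome")
    protein_seq = dataset.proteome.sequence(acc)
    length = len(protein_seq)

    out: dict[str, object] = {}
    for label, samples in zip(dataset.labels,
                              (dataset.group_a, dataset.group_b)):
        per_sample: list[CoverageProfile] = []
        for s in samples:
            recs = s.records[s.records["accession"] == acc]
            locs = _locate_unique(recs["clean_sequence"], protein_seq)
            overlap, height, weight, unloc = _sample_arrays(
                recs, locs, length, metric.quantity)
            if unloc:
                logger.info("%s/%s: %d records not locatable in %s",
                            label, s.sample_id, len(unloc), acc)
            per_sample.append(CoverageProfile(
                acc, f"{label}:{s.sample_id}", overlap, height, weight,
                n_samples=1, unlocated=sorted(set(unloc))))
        if scope == "per_sample":
            out[label] = per_sample
        else:
            n = len(samples)
            overlap = np.sum([p.overlap_count for p in per_sample], axis=0)
            height = np.sum([p.height for p in per_sample], axis=0) / n
            weight = float(sum(p.weight for p in per_sample))
            unloc = sorted({u for p in per_sample for u in p.unlocated})
            out[label] = CoverageProfile(acc, label, overlap.astype(int),
                                         height, weight, n_samples=n,
                                         unlocated=unloc)
    return out


def difference_trace(profile_a: CoverageProfile,
                     profile_b: CoverageProfile) -> np.ndarray:
    """Signed per-position height difference (A minus B)."""
    if len(profile_a.height) != len(profile_b.height):
        raise ValueError("profiles have different lengths "
                         f"({len(profile_a.height)} vs {len(profile_b.height)})")
    return profile_a.height - profile_b.height


def peptide_table(dataset: GroupedDataset, accession: str,
                  metric: AbundanceMetric, filter_expression: str = "",
                  sort_by: str | None = None,
                  ascending: bool = True) -> pd.DataFrame:
    """One row per unique located peptide sequence of the protein.

    Per group: mean and SD of the metric over samples where the sequence
    is present (a sequence's per-sample value sums duplicate records,
    e.g. modification variants).  The p-value column holds the Welch
    p-value, or the literal −1 when the sequence is present in fewer
    than three samples of either group.
    """
    acc = dataset.proteome.resolve(accession)
    if acc is None:
        raise KeyError(f"accession {accession!r} not in proteome")
    protein_seq = dataset.proteome.sequence(acc)

    def _per_sample_values(samples: list[SampleTable]) -> pd.DataFrame:
        rows = []
        for s in samples:
            recs = s.records[s.records["accession"] == acc]
            if recs.empty:
                continue
            v = recs.groupby("clean_sequence")[metric.quantity].sum()
            rows.append(pd.DataFrame({"clean_sequence": v.index,
                                      "value": v.to_numpy(float),
                                      "sample_id": s.sample_id}))
        if not rows:
            return pd.DataFrame(columns=["clean_sequence", "value",
                                         "sample_id"])
        return pd.concat(rows, ignore_index=True)

    va, vb = (_per_sample_values(dataset.group_a),
              _per_sample_values(dataset.group_b))
    sequences = sorted(set(va["clean_sequence"]) | set(vb["clean_sequence"]))
    locs = _locate_unique(sequences, protein_seq)

    rows = []
    for seq in sequences:
        pos = locs.get(seq)
        if pos is None:
            continue
        a = va.loc[va["clean_sequence"] == seq, "value"].to_numpy(float)
        b = vb.loc[vb["clean_sequence"] == seq, "value"].to_numpy(float)
        p = group_compare_pvalue(a, b)
        rows.append({
            "sequence": seq,
            "start": pos[0],
            "end": pos[1],
            "mean_a": float(a.mean()) if len(a) else 0.0,
            "sd_a": float(np.std(a, ddof=1)) if len(a) > 1 else 0.0,
            "mean_b": float(b.mean()) if len(b) else 0.0,
            "sd_b": float(np.std(b, ddof=1)) if len(b) > 1 else 0.0,
            "n_samples_a": len(a),
            "n_samples_b": len(b),
            "p_value": P_VALUE_SENTINEL if p is None else p,
        })
    table = pd.DataFrame(rows, columns=[
        "sequence", "start", "end", "mean_a", "sd_a", "mean_b", "sd_b",
        "n_samples_a", "n_samples_b", "p_value"])
    table = apply_filter(table, filter_expression)
    if sort_by is not None:
        table = table.sort_values(sort_by, ascending=ascending,
                                  kind="mergesort")
    return table.reset_index(drop=True)


def coverage_table(dataset: GroupedDataset, accession: str,
                   metric: AbundanceMetric) -> pd.DataFrame:
    """Per-position export: position, residue, per-group overlap and
    height, and the signed height difference."""
    profiles = coverage_profile(dataset, accession, metric,
                                scope="group_mean")
    pa, pb = (profiles[dataset.labels[0]], profiles[dataset.labels[1]])
    acc = dataset.proteome.resolve(accession)
    seq = dataset.proteome.sequence(acc)
    return pd.DataFrame({
        "position": np.arange(1, len(seq) + 1),
        "residue": list(seq),
        "overlap_a": pa.overlap_count,
        "height_a": pa.height,
        "overlap_b": pb.overlap_count,
        "height_b": pb.height,
        "difference": difference_trace(pa, pb),
    })


def coverage_figure(dataset: GroupedDataset, accession: str,
                    metric: AbundanceMetric, path) -> None:
    """Static coverage barchart: per-group height bars coloured by
    overlap count, the A−B difference trace, and per-group weight lines."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    profiles = coverage_profile(dataset, accession, metric,
                                scope="group_mean")
    la, lb = dataset.labels
    pa, pb = profiles[la], profiles[lb]
    pos = np.arange(1, len(pa.height) + 1)

    fig, axes = plt.subplots(3, 1, figsize=(10, 7), sharex=True,
                             height_ratios=[2, 2, 1])
    for ax, prof, label in ((axes[0], pa, la), (axes[1], pb, lb)):
        vmax = max(prof.overlap_count.max(), 1)
        colors = plt.cm.viridis(prof.overlap_count / vmax)
        ax.bar(pos, prof.height, width=1.0, color=colors)
        ax.axhline(prof.weight / max(len(pos), 1), ls=":", c="red", lw=1,
                   label="weight / length")
        ax.set_ylabel(f"{label}\nheight")
        ax.legend(loc="upper right", fontsize=8)
    axes[2].plot(pos, difference_trace(pa, pb), c="black", lw=1)
    axes[2].axhline(0, c="grey", lw=0.5)
    axes[2].set_ylabel("difference")
    axes[2].set_xlabel("residue position")
    fig.suptitle(f"{dataset.proteome.mnemonic(pa.accession)} "
                 f"({pa.accession}) — {metric}")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
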