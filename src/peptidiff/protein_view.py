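"""Protein-level group comparison.

Peptide records are aggregated to one abundance value per protein and
sample under one of four metrics (sum/mean of intensity/spectral count),
then averaged across the samples of each group.  The absolute difference
of the two group means ranks proteins by differential abundance; a
two-sided Welch t-test on the per-sample values gives a p-value wherever
the protein is present in at least three samples of each group.  A
protein absent from a sample contributes no value there (absence is not
zero), matching the presence-based statistics of the source convention.

No multiple-testing correction is applied: p-values are raw and intended
for exploratory ranking, not confirmatory inference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._filters import apply_filter
from .ingest import GroupedDataset, SampleTable

__all__ = [
    "AbundanceMetric",
    "protein_sample_value",
    "protein_group_summary",
    "group_compare_pvalue",
    "protein_table",
    "per_sample_table",
    "scatter_plot",
]

_QUANTITIES = ("intensity", "spectral_count")
_AGGREGATORS = ("sum", "mean")


@dataclass(frozen=True)
class AbundanceMetric:
    """One of the four abundance metrics: {sum,mean} x {intensity,SpC}."""

    quantity: str = "intensity"
    aggregator: str = "sum"

    def __post_init__(self):
        if self.quantity not in _QUANTITIES:
            raise ValueError(f"quantity must be one of {_QUANTITIES}")
        if self.aggregator not in _AGGREGATORS:
            raise ValueError(f"aggregator must be one of {_AGGREGATORS}")

    @classmethod
    def from_string(cls, name: str) -> "AbundanceMetric":
        """Parse CLI-style names: sum-intensity, mean-intensity,
        sum-spc, mean-spc."""
        agg, _, quant = name.strip().lower().partition("-")
        quant = {"spc": "spectral_count",
                 "spectral_count": "spectral_count",
                 "intensity": "intensity"}.get(quant, quant)
        return cls(quantity=quant, aggregator=agg)

    def __str__(self) -> str:
        q = "spc" if self.quantity == "spectral_count" else self.quantity
        return f"{self.aggregator}-{q}"


def protein_sample_value(sample: SampleTable, accession: str,
                         metric: AbundanceMetric) -> float | None:
    """Aggregate of the metric over the protein's records in one sample;
    ``None`` when the protein has no records there (absence, not zero)."""
    vals = sample.records.loc[sample.records["accession"] == accession,
                              metric.quantity]
    if vals.empty:
        return None
    return float(vals.sum() if metric.aggregator == "sum" else vals.mean())


def group_compare_pvalue(values_a, values_b) -> float | None:
    """Two-sided Welch (unequal-variance) t-test p-value, or ``None``
    when either group has fewer than 3 values.

    Degenerate zero-variance cases: identical constant groups give 1.0
    (identical data is no evidence of difference); constant groups with
    different values give 0.0.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if len(a) < 3 or len(b) < 3:
        return None
    if a.std() == 0 and b.std() == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def _group_values(samples: list[SampleTable], metric: AbundanceMetric
                  ) -> pd.DataFrame:
    """Per-(accession, sample) metric values for one group (long form)."""
    rows = []
    for s in samples:
        if s.records.empty:
            continue
        g = s.records.groupby("accession")[metric.quantity]
        agg = g.sum() if metric.aggregator == "sum" else g.mean()
        counts = s.records.groupby("accession")["clean_sequence"]
        rows.append(pd.DataFrame({
            "accession": agg.index,
            "value": agg.to_numpy(float),
            "n_records": counts.size().to_numpy(int),
            "sample_id": s.sample_id,
        }))
    if not rows:
        return pd.DataFrame(columns=["accession", "value", "n_records",
                                     "sample_id"])
    return pd.concat(rows, ignore_index=True)


def _presence_sd(x: np.ndarray) -> float:
    # sample SD (ddof=1); a single observation has no spread estimate -> 0
    return float(np.std(x, ddof=1)) if len(x) > 1 else 0.0


def protein_group_summary(dataset: GroupedDataset,
                          metric: AbundanceMetric) -> pd.DataFrame:
    """One row per protein present in at least one group.

    Columns: accession, mnemonic, and per group the mean and SD of the
    per-sample metric over samples where the protein is present, peptide
    record and unique-sequence counts, number of samples present; plus
    the absolute difference of group means and the conditional Welch
    p-value (NaN when either group has < 3 samples with the protein).
    """
    la, lb = _group_values(dataset.group_a, metric), _group_values(
        dataset.group_b, metric)
    tidy = dataset.to_tidy()
    uniq = (tidy.groupby(["group_id", "accession"])["clean_sequence"]
            .nunique() if not tidy.empty else pd.Series(dtype=int))

    accessions = sorted(set(la["accession"]) | set(lb["accession"]))
    rows = []
    label_a, label_b = dataset.labels
    for acc in accessions:
        va = la.loc[la["accession"] == acc, "value"].to_numpy(float)
        vb = lb.loc[lb["accession"] == acc, "value"].to_numpy(float)
        mean_a = float(va.mean()) if len(va) else np.nan
        mean_b = float(vb.mean()) if len(vb) else np.nan
        diff = abs((0.0 if np.isnan(mean_a) else mean_a)
                   - (0.0 if np.isnan(mean_b) else mean_b))
        p = group_compare_pvalue(va, vb) if (len(va) >= 3 and len(vb) >= 3) \
            else None
        rows.append({
            "accession": acc,
            "mnemonic": dataset.proteome.mnemonic(acc),
            "n_peptides_a": int(la.loc[la["accession"] == acc,
                                       "n_records"].sum()),
            "n_peptides_b": int(lb.loc[lb["accession"] == acc,
                                       "n_records"].sum()),
            "n_unique_a": int(uniq.get((label_a, acc), 0)),
            "n_unique_b": int(uniq.get((label_b, acc), 0)),
            "n_samples_a": len(va),
            "n_samples_b": len(vb),
            "mean_a": mean_a,
            "sd_a": _presence_sd(va) if len(va) else np.nan,
            "mean_b": mean_b,
            "sd_b": _presence_sd(vb) if len(vb) else np.nan,
            "difference": diff,
            "p_value": np.nan if p is None else p,
        })
    return pd.DataFrame(rows)


def protein_table(summaries: pd.DataFrame, filter_expression: str = "",
                  sort_by: str | None = None,
                  ascending: bool = True) -> pd.DataFrame:
    """Filter/sort the summary table.  The p-value stays NaN (rendered
    blank on CSV export) where it was not computed."""
    out = apply_filter(summaries, filter_expression)
    if sort_by is not None:
        out = out.sort_values(sort_by, ascending=ascending, kind="mergesort")
    return out.reset_index(drop=True)


def per_sample_table(dataset: GroupedDataset,
                     metric: AbundanceMetric) -> pd.DataFrame:
    """Per-protein, per-sample metric values (long form) — the flat-file
    counterpart of the interactive per-sample popup."""
    frames = []
    for label, samples in zip(dataset.labels,
                              (dataset.group_a, dataset.group_b)):
        f = _group_values(samples, metric)
        f["group_id"] = label
        frames.append(f)
    out = pd.concat(frames, ignore_index=True)
    out["mnemonic"] = out["accession"].map(dataset.proteome.mnemonic)
    return out[["accession", "mnemonic", "group_id", "sample_id", "value",
                "n_records"]]


def scatter_plot(summaries: pd.DataFrame, path, labels=("group A", "group B"),
                 metric_name: str = "abundance") -> None:
    """Group-A vs group-B abundance scatter; dot size tracks peptide
    count, the diagonal marks equal abundance."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = summaries["mean_a"].fillna(0.0)
    y = summaries["mean_b"].fillna(0.0)
    npep = summaries["n_peptides_a"] + summaries["n_peptides_b"]
    size = 10 + 90 * npep / max(npep.max(), 1)
    fig, ax = plt.subplots(figsize=(6, 6))
    sc = ax.scatter(x, y, s=size, c=summaries["difference"], cmap="RdYlGn_r",
                    alpha=0.7, edgecolors="k", linewidths=0.3)
    lim = max(x.max(), y.max(), 1.0) * 1.05
    ax.plot([0, lim], [0, lim], ls="--", c="grey", lw=1)
    ax.set_xlabel(f"{labels[0]} ({metric_name})")
    ax.set_ylabel(f"{labels[1]} ({metric_name})")
    fig.colorbar(sc, ax=ax, label="|difference|")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
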