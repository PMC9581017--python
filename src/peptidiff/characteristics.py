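"""Abundance-weighted peptidome characteristics.

Three per-group summaries, computed over the pooled records of all
samples in a group, for the whole peptidome or a single precursor
protein: a length distribution where each peptide contributes its
abundance-metric value to its length bin (a spectral count of 10 weighs
twice a spectral count of 5); Venn counts of unique/shared peptide
sequences between the groups; and abundance-weighted amino-acid
frequency profiles for the full sequence and for the N- and C-terminal
residues.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .ingest import GroupedDataset
from .protein_view import AbundanceMetric

logger = logging.getLogger(__name__)

__all__ = [
    "STANDARD_AA",
    "VennCounts",
    "weighted_length_distribution",
    "venn_counts",
    "amino_acid_profile",
    "characteristics_summary",
    "characteristics_figure",
]

#: the 20 standard amino-acid letters; others (B J O U X Z) are skipped
STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class VennCounts:
    """Unique/shared partition of the two groups' peptide sequence sets."""

    unique_a: int
    shared: int
    unique_b: int


def _scoped(dataset: GroupedDataset, scope: str | None) -> pd.DataFrame:
    """Tidy records, optionally restricted to one protein accession."""
    tidy = dataset.to_tidy()
    if scope is None or tidy.empty:
        return tidy
    acc = dataset.proteome.resolve(scope)
    if acc is None:
        raise KeyError(f"accession {scope!r} not in proteome")
    return tidy[tidy["accession"] == acc]


def weighted_length_distribution(
    dataset: GroupedDataset, metric: AbundanceMetric,
    scope: str | None = None,
) -> dict[str, dict[int, float]]:
    """Per group: peptide length -> total metric weight.

    Each record adds its metric value (its ``quantity`` column) to the
    bin of its sequence length; the total bin mass therefore equals the
    total metric over the scope.
    """
    tidy = _scoped(dataset, scope)
    out: dict[str, dict[int, float]] = {lab: {} for lab in dataset.labels}
    if tidy.empty:
        return out
    tidy = tidy.assign(length=tidy["clean_sequence"].str.len())
    for label, grp in tidy.groupby("group_id"):
        weights = grp.groupby("length")[metric.quantity].sum()
        out[str(label)] = {int(k): float(v) for k, v in weights.items()}
    return out


def venn_counts(dataset: GroupedDataset, scope: str | None = None
                ) -> VennCounts:
    """Set arithmetic over unique clean sequences of each group.

    Sequence identity alone defines membership: a sequence shared by two
    precursor proteins counts once.
    """
    tidy = _scoped(dataset, scope)
    la, lb = dataset.labels
    if tidy.empty:
        return VennCounts(0, 0, 0)
    seqs_a = set(tidy.loc[tidy["group_id"] == la, "clean_sequence"])
    seqs_b = set(tidy.loc[tidy["group_id"] == lb, "clean_sequence"])
    return VennCounts(len(seqs_a - seqs_b), len(seqs_a & seqs_b),
                      len(seqs_b - seqs_a))


def amino_acid_profile(
    dataset: GroupedDataset, metric: AbundanceMetric,
    scope: str | None = None,
) -> dict[str, dict[str, dict[str, float]]]:
    """Per group, three weight-fraction distributions over amino acids:
    every residue of the sequence ("full"), the N-terminal residue
    ("first") and the C-terminal residue ("last").

    Each residue contributes its record's metric value; distributions
    are normalized to fractions summing to 1.  Nonstandard letters are
    skipped with a logged count.
    """
    tidy = _scoped(dataset, scope)
    out: dict[str, dict[str, dict[str, float]]] = {
        lab: {"full": {}, "first": {}, "last": {}} for lab in dataset.labels}
    if tidy.empty:
        return out
    skipped = 0
    for label, grp in tidy.groupby("group_id"):
        acc: dict[str, dict[str, float]] = {"full": {}, "first": {},
                                            "last": {}}
        for seq, w in zip(grp["clean_sequence"],
                          grp[metric.quantity].astype(float)):
            for aa in seq:
                if aa not in STANDARD_AA:
                    skipped += 1
                    continue
                acc["full"][aa] = acc["full"].get(aa, 0.0) + w
            for key, aa in (("first", seq[0]), ("last", seq[-1])):
                if aa in STANDARD_AA:
                    acc[key][aa] = acc[key].get(aa, 0.0) + w
        for key, dist in acc.items():
            total = sum(dist.values())
            out[str(label)][key] = (
                {aa: w / total for aa, w in sorted(dist.items())}
                if total > 0 else {})
    if skipped:
        logger.info("amino_acid_profile: skipped %d nonstandard residues",
                    skipped)
    return out


def characteristics_summary(dataset: GroupedDataset, metric: AbundanceMetric,
                            scope: str | None = None) -> dict:
    """JSON-ready bundle of all three characteristics for one scope."""
    venn = venn_counts(dataset, scope)
    return {
        "scope": scope or "peptidome",
        "metric": str(metric),
        "length_distribution": weighted_length_distribution(dataset, metric,
                                                            scope),
        "venn": {"unique_a": venn.unique_a, "shared": venn.shared,
                 "unique_b": venn.unique_b},
        "aa_profile": amino_acid_profile(dataset, metric, scope),
    }


def characteristics_figure(dataset: GroupedDataset, metric: AbundanceMetric,
                           path, scope: str | None = None) -> None:
    """Static figure: weighted length histograms, Venn bars, and
    terminal amino-acid profiles."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    summary = characteristics_summary(dataset, metric, scope)
    la, lb = dataset.labels
    fig, axes = plt.subplots(2, 2, figsize=(10, 8))

    ax = axes[0, 0]
    for label, color in ((la, "tab:blue"), (lb, "tab:orange")):
        dist = summary["length_distribution"][label]
        if dist:
            ax.bar([int(k) for k in dist], list(dist.values()), alpha=0.5,
                   label=label, color=color)
    ax.set_xlabel("peptide length")
    ax.set_ylabel(f"total {metric.quantity} weight")
    ax.legend()

    ax = axes[0, 1]
    v = summary["venn"]
    ax.bar(["unique A", "shared", "unique B"],
           [v["unique_a"], v["shared"], v["unique_b"]],
           color=["tab:blue", "tab:green", "tab:orange"])
    ax.set_ylabel("unique peptide sequences")

    for ax, key in ((axes[1, 0], "first"), (axes[1, 1], "last")):
        prof = summary["aa_profile"]
        aas = sorted(set(prof[la][key]) | set(prof[lb][key]))
        x = range(len(aas))
        ax.bar([i - 0.2 for i in x], [prof[la][key].get(a, 0) for a in aas],
               width=0.4, label=la, color="tab:blue")
        ax.bar([i + 0.2 for i in x], [prof[lb][key].get(a, 0) for a in aas],
               width=0.4, label=lb, color="tab:orange")
        ax.set_xticks(list(x), aas)
        ax.set_ylabel("weight fraction")
        ax.set_title(f"{key} residue")
        ax.legend(fontsize=8)

    fig.suptitle(f"peptidome characteristics — {summary['scope']}")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
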