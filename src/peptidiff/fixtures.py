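"""Deterministic synthetic peptidomics data with known ground truth.

Emulates the shape of PEAKS-style label-free peptidomics exports: a toy
proteome FASTA with UniProt-style headers, and per-sample CSVs whose
peptides are true substrings of the fixture proteins.  Intensities are
log-normal (generated on the linear scale so the pipeline's log10 step
is exercised), spectral counts are Poisson, and each sample carries a
multiplicative global intensity bias emulating loading/instrument drift.
Retention time and collision cross section are Gaussian with an injected
fraction of gross outliers.  Selected proteins can be given a log-scale
abundance offset in group B to plant a recoverable differential signal.

A JSON-ready manifest records every peptide's true location, every
sample's bias, the injected outliers and the differential offsets, so
each pipeline stage can be checked against ground truth.

Every sample draws from its own pseudo-random stream derived from
(seed, sample id): adding samples never perturbs existing ones.
"""

from __future__ import annotations

import io
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["FixtureSpec", "generate_proteome", "generate_samples",
           "write_fixture_set"]

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: PEAKS-style column names used in generated CSVs
_CSV_COLUMNS = ["Peptide", "Accession", "Area", "#Feature", "RT", "CCS"]


@dataclass
class FixtureSpec:
    """Study conditions for one synthetic two-group experiment.

    Defaults model a modest urine-peptidomics-like comparison: 20
    proteins of 200–400 residues, 5 samples per group, 10–30 peptides
    per protein, intensities around 10^6 with ~0.8 log-units of
    biological spread, a 0.15 log-unit per-sample global bias, spectral
    counts averaging ~5, and 1% gross RT/CCS outliers.
    """

    seed: int = 0
    n_proteins: int = 20
    protein_length_range: tuple[int, int] = (200, 400)
    n_samples_per_group: int = 5
    peptides_per_protein: tuple[int, int] = (10, 30)
    peptide_length_range: tuple[int, int] = (7, 25)
    log_intensity_mean: float = 6.0
    log_intensity_sd: float = 0.8
    spectral_count_rate: float = 5.0
    sample_bias_sd: float = 0.15
    outlier_fraction: float = 0.01
    #: peptide is present in a given sample with this probability
    presence_probability: float = 0.9
    rt_mean: float = 30.0
    rt_sd: float = 5.0
    ccs_mean: float = 400.0
    ccs_sd: float = 40.0
    #: (accession, log10-fold offset added to group-B intensities)
    differential_proteins: list[tuple[str, float]] = field(
        default_factory=list)
    group_labels: tuple[str, str] = ("groupA", "groupB")

    def __post_init__(self):
        if self.n_proteins <= 0 or self.n_samples_per_group <= 0:
            raise ValueError("counts must be positive")
        if not (0 <= self.outlier_fraction < 0.5):
            raise ValueError("outlier_fraction must be in [0, 0.5)")

    def accession(self, i: int) -> str:
        return f"PX{i + 1:04d}"

    def mnemonic(self, i: int) -> str:
        return f"SYN{i + 1:03d}_TOY"


def _rng(seed: int, stream: str) -> np.random.Generator:
    # stable per-stream generator: crc32 keeps the spawn key deterministic
    return np.random.default_rng([seed & 0x7FFFFFFF,
                                  zlib.crc32(stream.encode())])


def generate_proteome(spec: FixtureSpec) -> str:
    """FASTA text with ``spec.n_proteins`` random protein sequences,
    UniProt-style headers, byte-identical for a given seed."""
    rng = _rng(spec.seed, "proteome")
    lo, hi = spec.protein_length_range
    lines = []
    for i in range(spec.n_proteins):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(_AA, size=length))
        lines.append(f">sp|{spec.accession(i)}|{spec.mnemonic(i)} "
                     f"synthetic protein {i + 1}")
        lines.extend(seq[j:j + 60] for j in range(0, length, 60))
    return "\n".join(lines) + "\n"


def _parse_fasta(text: str) -> dict[str, str]:
    seqs: dict[str, str] = {}
    acc = None
    for line in text.splitlines():
        if line.startswith(">"):
            acc = line[1:].split()[0].split("|")[1]
            seqs[acc] = ""
        elif acc:
            seqs[acc] += line.strip()
    return seqs


def _peptide_pool(spec: FixtureSpec, proteins: dict[str, str]) -> list[dict]:
    """The shared peptide universe: per protein, a deterministic set of
    substrings with their true positions (1-based inclusive)."""
    rng = _rng(spec.seed, "pool")
    klo, khi = spec.peptides_per_protein
    llo, lhi = spec.peptide_length_range
    pool = []
    for acc, seq in proteins.items():
        k = int(rng.integers(klo, khi + 1))
        for _ in range(k):
            plen = int(rng.integers(llo, min(lhi, len(seq)) + 1))
            start = int(rng.integers(0, len(seq) - plen + 1))
            pool.append({
                "accession": acc,
                "sequence": seq[start:start + plen],
                "start": start + 1,
                "end": start + plen,
            })
    return pool


def generate_samples(spec: FixtureSpec,
                     proteome_fasta: str) -> tuple[dict[str, str], dict]:
    """Per-sample CSV texts plus the ground-truth manifest.

    Returns ``({sample_id: csv_text}, manifest)``.  Sample ids are
    ``A1..An`` / ``B1..Bn``; the manifest holds the peptide pool with
    true locations, per-sample bias factors (log10 scale), injected
    RT/CCS outlier row identities and the differential offsets.
    """
    proteins = _parse_fasta(proteome_fasta)
    pool = _peptide_pool(spec, proteins)
    offsets = {acc: off for acc, off in spec.differential_proteins}

    csvs: dict[str, str] = {}
    manifest: dict = {
        "seed": spec.seed,
        "group_labels": list(spec.group_labels),
        "peptide_pool": pool,
        "samples": {},
        "differential_proteins": [list(t) for t in
                                  spec.differential_proteins],
    }

    for gi, glabel in enumerate(spec.group_labels):
        for si in range(spec.n_samples_per_group):
            sample_id = f"{'AB'[gi]}{si + 1}"
            rng = _rng(spec.seed, f"sample:{sample_id}")
            bias = float(rng.normal(0.0, spec.sample_bias_sd))

            rows = []
            outlier_rows: list[dict] = []
            for pep in pool:
                if rng.random() > spec.presence_probability:
                    continue
                offset = offsets.get(pep["accession"], 0.0) if gi == 1 else 0.0
                log_int = rng.normal(
                    spec.log_intensity_mean + bias + offset,
                    spec.log_intensity_sd)
                spc = int(rng.poisson(spec.spectral_count_rate)) + 1
                rt = float(rng.normal(spec.rt_mean, spec.rt_sd))
                ccs = float(rng.normal(spec.ccs_mean, spec.ccs_sd))
                row_outliers = []
                if rng.random() < spec.outlier_fraction:
                    rt = spec.rt_mean + float(rng.choice([-1, 1])) * \
                        spec.rt_sd * float(rng.uniform(8, 12))
                    row_outliers.append("rt")
                if rng.random() < spec.outlier_fraction:
                    ccs = spec.ccs_mean + float(rng.choice([-1, 1])) * \
                        spec.ccs_sd * float(rng.uniform(8, 12))
                    row_outliers.append("ccs")
                if row_outliers:
                    outlier_rows.append({"row": len(rows),
                                         "columns": row_outliers})
                rows.append([pep["sequence"], pep["accession"],
                             round(10.0 ** log_int, 4), spc,
                             round(rt, 4), round(ccs, 4)])

            frame = pd.DataFrame(rows, columns=_CSV_COLUMNS)
            buf = io.StringIO()
            frame.to_csv(buf, index=False)
            csvs[sample_id] = buf.getvalue()
            manifest["samples"][sample_id] = {
                "group": glabel,
                "log10_bias": bias,
                "n_rows": len(rows),
                "outliers": outlier_rows,
            }
    return csvs, manifest


def write_fixture_set(spec: FixtureSpec, outdir) -> dict:
    """Write proteome.fasta, one CSV per sample and manifest.json under
    ``outdir``; returns the paths grouped for direct pipeline use."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = generate_proteome(spec)
    (outdir / "proteome.fasta").write_text(fasta)
    csvs, manifest = generate_samples(spec, fasta)
    paths: dict = {"proteome": outdir / "proteome.fasta",
                   "group_a": [], "group_b": [],
                   "manifest": outdir / "manifest.json"}
    for sample_id, text in csvs.items():
        p = outdir / f"{sample_id}.csv"
        p.write_text(text)
        key = "group_a" if manifest["samples"][sample_id]["group"] == \
            spec.group_labels[0] else "group_b"
        paths[key].append(p)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return paths
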