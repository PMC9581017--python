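"""Reading per-sample peptide CSV exports and proteome FASTA files.

Peptide tables come from search engines such as PEAKS as one CSV per
sample, with one row per identified peptide feature.  Column naming
varies between tools, so headers are resolved case-insensitively against
a small alias table.  Precursor proteins are identified by UniProt
accession and must be present in a user-supplied proteome FASTA; records
whose precursor cannot be matched are discarded (and counted).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "IngestionError",
    "AmbiguousColumnError",
    "PeptideRecord",
    "SampleTable",
    "ProteomeDB",
    "GroupedDataset",
    "resolve_columns",
    "read_sample_csv",
    "load_proteome_fasta",
    "match_precursors",
    "RECORD_COLUMNS",
]


class IngestionError(ValueError):
    """A sample file or proteome could not be ingested."""


class AmbiguousColumnError(IngestionError):
    """Two header columns resolve to the same role."""


#: roles that every input file must provide
MANDATORY_ROLES = ("sequence", "accession", "intensity", "spectral_count")

#: accepted header spellings per role (matched case-insensitively,
#: surrounding whitespace ignored)
COLUMN_ALIASES: dict[str, frozenset[str]] = {
    "sequence": frozenset({"peptide", "sequence"}),
    "accession": frozenset({"accession", "protein", "uniprot id"}),
    "intensity": frozenset({"area", "intensity"}),
    "spectral_count": frozenset({"spc", "spectral count", "#feature"}),
    "rt": frozenset({"rt", "retention time"}),
    "ccs": frozenset({"ccs", "collision cross section"}),
}

#: canonical column order of a records table
RECORD_COLUMNS = [
    "raw_sequence",
    "clean_sequence",
    "accession",
    "intensity",
    "spectral_count",
    "rt",
    "ccs",
]

_PAREN_RE = re.compile(r"\([^)]*\)")
_NON_LETTER_RE = re.compile(r"[^A-Za-z]")


def clean_sequence(raw: str) -> str:
    """Strip parenthesised modification annotations (e.g. ``M(+15.99)``)
    and any non-letter characters, then uppercase.

    The result is directly locatable in a FASTA protein sequence.
    """
    s = _PAREN_RE.sub("", str(raw))
    return _NON_LETTER_RE.sub("", s).upper()


@dataclass
class PeptideRecord:
    """One row of an input CSV."""

    raw_sequence: str
    clean_sequence: str
    accession: str
    intensity: float
    spectral_count: float
    rt: float | None = None
    ccs: float | None = None


@dataclass
class SampleTable:
    """All peptide records of one sample file.

    ``records`` is a DataFrame with the columns in :data:`RECORD_COLUMNS`;
    ``rt``/``ccs`` hold NaN where the input file lacked those columns.
    """

    sample_id: str
    group_id: str
    records: pd.DataFrame
    #: ingestion bookkeeping: rows read, rows dropped, blank numeric cells
    report: dict = field(default_factory=dict)

    def copy(self) -> "SampleTable":
        return SampleTable(self.sample_id, self.group_id,
                           self.records.copy(), dict(self.report))

    def __len__(self) -> int:
        return len(self.records)


class ProteomeDB:
    """Mapping UniProt accession -> (mnemonic identifier, sequence)."""

    def __init__(self, entries: dict[str, tuple[str, str]]):
        if not entries:
            raise IngestionError("proteome contains no records")
        self.entries = entries
        self._by_mnemonic = {m.upper(): acc for acc, (m, _) in entries.items()}

    def __contains__(self, accession: str) -> bool:
        return self.resolve(accession) is not None

    def __len__(self) -> int:
        return len(self.entries)

    def resolve(self, accession: str) -> str | None:
        """Return the stored accession for ``accession``.

        Isoform suffixes fall back to the base accession: ``P07911-2``
        matches an entry for ``P07911`` when the full form is absent.
        Mnemonic identifiers (e.g. ``UROM_HUMAN``) are accepted too.
        """
        if accession in self.entries:
            return accession
        if "-" in accession:
            base = accession.split("-", 1)[0]
            if base in self.entries:
                return base
        return self._by_mnemonic.get(str(accession).upper())

    def mnemonic(self, accession: str) -> str:
        return self.entries[accession][0]

    def sequence(self, accession: str) -> str:
        return self.entries[accession][1]

    def nearest_mnemonics(self, query: str, limit: int = 5) -> list[str]:
        """Mnemonics containing ``query`` as a substring (for error hints)."""
        q = query.upper()
        hits = [m for m in self._by_mnemonic if q in m]
        return sorted(hits)[:limit]


@dataclass
class GroupedDataset:
    """Two groups of samples matched against a proteome."""

    group_a: list[SampleTable]
    group_b: list[SampleTable]
    proteome: ProteomeDB
    labels: tuple[str, str] = ("group_a", "group_b")
    log_transformed: bool = False
    normalization: str = "none"

    def __post_init__(self):
        if not self.group_a or not self.group_b:
            raise IngestionError("each group must contain at least one sample")

    def samples(self) -> list[SampleTable]:
        return list(self.group_a) + list(self.group_b)

    def group(self, label: str) -> list[SampleTable]:
        if label == self.labels[0]:
            return self.group_a
        if label == self.labels[1]:
            return self.group_b
        raise KeyError(label)

    def copy(self) -> "GroupedDataset":
        return GroupedDataset(
            [s.copy() for s in self.group_a],
            [s.copy() for s in self.group_b],
            self.proteome,
            self.labels,
            self.log_transformed,
            self.normalization,
        )

    def to_tidy(self) -> pd.DataFrame:
        """All records of all samples as one tidy frame with
        ``sample_id`` and ``group_id`` columns."""
        frames = []
        for s in self.samples():
            f = s.records.copy()
            f["sample_id"] = s.sample_id
            f["group_id"] = s.group_id
            frames.append(f)
        if not frames:
            return pd.DataFrame(columns=RECORD_COLUMNS + ["sample_id", "group_id"])
        return pd.concat(frames, ignore_index=True)


def resolve_columns(header_names: list[str]) -> dict[str, str]:
    """Map each column role to the header that provides it.

    Matching is case-insensitive.  The four mandatory roles (sequence,
    accession, intensity, spectral count) must each match exactly one
    header; ``rt`` and ``ccs`` are optional.
    """
    if not header_names:
        raise IngestionError("empty header")
    mapping: dict[str, str] = {}
    for role, aliases in COLUMN_ALIASES.items():
        hits = [h for h in header_names if str(h).strip().lower() in aliases]
        if len(hits) > 1:
            raise AmbiguousColumnError(
                f"columns {hits!r} both match the {role!r} role")
        if hits:
            mapping[role] = hits[0]
    missing = [r for r in MANDATORY_ROLES if r not in mapping]
    if missing:
        raise IngestionError(
            "no column found for mandatory role(s): " + ", ".join(missing)
            + f" (header was {list(header_names)!r})")
    return mapping


def read_sample_csv(path, sample_id: str, group_id: str) -> SampleTable:
    """Parse one per-sample CSV into a :class:`SampleTable`.

    Rows with an empty sequence or accession are dropped (counted in the
    sample report); blank or non-numeric intensity / spectral-count cells
    become 0, as PEAKS exports blanks for unquantified features.
    """
    try:
        raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    except (OSError, pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise IngestionError(f"cannot read {path}: {exc}") from exc
    except pd.errors.EmptyDataError as exc:
        raise IngestionError(f"{path} has no header row") from exc

    roles = resolve_columns(list(raw.columns))
    n_read = len(raw)

    out = pd.DataFrame()
    out["raw_sequence"] = raw[roles["sequence"]].fillna("")
    out["clean_sequence"] = out["raw_sequence"].map(clean_sequence)
    out["accession"] = raw[roles["accession"]].fillna("").str.strip()

    blank_cells = 0
    for role in ("intensity", "spectral_count"):
        vals = pd.to_numeric(raw[roles[role]], errors="coerce")
        blank_cells += int(vals.isna().sum())
        out[role] = vals.fillna(0.0).astype(float)
    for role in ("rt", "ccs"):
        if role in roles:
            out[role] = pd.to_numeric(raw[roles[role]], errors="coerce")
        else:
            out[role] = float("nan")

    keep = (out["clean_sequence"] != "") & (out["accession"] != "")
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("%s: dropped %d rows with empty sequence/accession",
                    sample_id, n_dropped)
    out = out.loc[keep, RECORD_COLUMNS].reset_index(drop=True)

    report = {"rows_read": n_read, "rows_dropped": n_dropped,
              "blank_numeric_cells": blank_cells}
    return SampleTable(sample_id, group_id, out, report)


def load_proteome_fasta(path) -> ProteomeDB:
    """Load a proteome FASTA into a :class:`ProteomeDB`.

    UniProt-style headers (``>db|ACCESSION|MNEMONIC description``) yield
    both accession and mnemonic; for plain headers (``>ID ...``) the
    mnemonic defaults to the id.  On duplicate accessions the first
    record wins and a warning is logged.
    """
    entries: dict[str, tuple[str, str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        if len(parts) >= 3 and parts[1]:
            accession, mnemonic = parts[1], parts[2]
        else:
            accession = mnemonic = rec.id
        seq = str(rec.seq).upper()
        if not seq:
            continue
        if accession in entries:
            logger.warning("duplicate accession %s in %s: keeping first",
                           accession, path)
            continue
        entries[accession] = (mnemonic, seq)
    if not entries:
        raise IngestionError(f"no FASTA records found in {path}")
    return ProteomeDB(entries)


def match_precursors(
    group_a: list[SampleTable],
    group_b: list[SampleTable],
    proteome: ProteomeDB,
    labels: tuple[str, str] | None = None,
) -> GroupedDataset:
    """Discard records whose precursor accession is absent from the
    proteome; isoform accessions are rewritten to their base form.

    The number of discarded records is stored per sample under
    ``report["records_discarded_unmatched"]``.  When ``labels`` is not
    given, the group labels default to the samples' own group ids.
    """
    if not group_a or not group_b:
        raise IngestionError("each group must contain at least one sample")
    if labels is None:
        labels = (group_a[0].group_id, group_b[0].group_id)
        if labels[0] == labels[1]:
            labels = ("group_a", "group_b")

    def _match(sample: SampleTable) -> SampleTable:
        s = sample.copy()
        resolved = s.records["accession"].map(
            lambda a: proteome.resolve(a) or "")
        n_discard = int((resolved == "").sum())
        if n_discard:
            logger.info("%s: discarded %d records with unmatched precursors",
                        s.sample_id, n_discard)
        s.records = s.records.loc[resolved != ""].reset_index(drop=True)
        s.records["accession"] = resolved[resolved != ""].values
        s.report["records_discarded_unmatched"] = n_discard
        return s

    ga = [_match(s) for s in group_a]
    gb = [_match(s) for s in group_b]
    seen: set[str] = set()
    for s in ga + gb:
        if s.sample_id in seen:
            raise IngestionError(f"duplicate sample_id {s.sample_id!r}")
        seen.add(s.sample_id)
    return GroupedDataset(ga, gb, proteome, labels)
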