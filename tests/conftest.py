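import math

import pandas as pd
import pytest

from peptidiff.fixtures import FixtureSpec, write_fixture_set
from peptidiff.ingest import (RECORD_COLUMNS, GroupedDataset, ProteomeDB,
                              SampleTable)


def make_sample(sample_id, group_id, rows):
    """rows: iterable of (seq, accession, intensity, spc[, rt[, ccs]])."""
    recs = []
    for row in rows:
        seq, acc, inten, spc = row[:4]
        rt = row[4] if len(row) > 4 else math.nan
        ccs = row[5] if len(row) > 5 else math.nan
        recs.append({"raw_sequence": seq, "clean_sequence": seq,
                     "accession": acc, "intensity": float(inten),
                     "spectral_count": float(spc), "rt": rt, "ccs": ccs})
    frame = pd.DataFrame(recs, columns=RECORD_COLUMNS)
    return SampleTable(sample_id, group_id, frame)


def make_dataset(proteome, samples_a, samples_b, labels=("A", "B")):
    """samples_*: dict sample_id -> rows (see make_sample)."""
    ga = [make_sample(sid, labels[0], rows) for sid, rows in samples_a.items()]
    gb = [make_sample(sid, labels[1], rows) for sid, rows in samples_b.items()]
    return GroupedDataset(ga, gb, proteome, labels)


@pytest.fixture
def toy_proteome():
    return ProteomeDB({
        # all 20 standard residues once; handy for coverage arithmetic
        "P1": ("TOY1_TEST", "ACDEFGHIKLMNPQRSTVWY"),
        "P2": ("TOY2_TEST", "MKWVTFISLL"),
        "P3": ("HOUSE_TEST", "GGGGGGGGGGGGGGGGGGGG"),
    })


@pytest.fixture(scope="session")
def fixture_spec():
    return FixtureSpec(seed=7, n_proteins=6, n_samples_per_group=5,
                       differential_proteins=[("PX0003", 5.0)])


@pytest.fixture(scope="session")
def fixture_paths(fixture_spec, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("fixture_set")
    return write_fixture_set(fixture_spec, outdir)
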