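from __future__ import annotations

import numpy as np
import pytest

from cvbarcode.sequence_io import LocusRecord, TaxonLabel, assemble_dataset
from cvbarcode.synthetic_data import easy_preset, simulate_dataset


def make_record(seq_id: str, locus: str, residues: str) -> LocusRecord:
    genus, species, *rest = seq_id.split("_")
    label = TaxonLabel(
        genus=genus, species=species, individual="_".join(rest), sequence_id=seq_id
    )
    return LocusRecord(label=label, locus=locus, residues=residues)


def make_dataset(per_locus: dict[str, dict[str, str]], strict: bool = True):
    """Build a dataset from {locus: {seq_id: residues}} shorthand."""
    return assemble_dataset(
        {
            locus: [make_record(sid, locus, seq) for sid, seq in recs.items()]
            for locus, recs in per_locus.items()
        },
        strict=strict,
    )


def random_dataset(rng: np.random.Generator, n_taxa: int, loci: dict[str, int]):
    """Random unrelated sequences: {locus: length}; taxa Genus{i}_sp{i}_01."""
    per_locus = {}
    for locus, length in loci.items():
        per_locus[locus] = {
            f"Genus{i}_sp{i}_01": "".join(rng.choice(list("ACGT"), size=length))
            for i in range(n_taxa)
        }
    return make_dataset(per_locus)


@pytest.fixture(scope="session")
def easy_dataset():
    dataset, truth = simulate_dataset(easy_preset(seed=42))
    return dataset, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20260925)
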