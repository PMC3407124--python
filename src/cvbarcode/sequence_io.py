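"""Multi-locus FASTA input, taxon-label parsing, and PHYLIP matrix I/O.

Input is one FASTA file per locus (e.g. matK, rbcL, trnH-psbA). Record
identifiers encode taxon identity; the default grammar splits the header on
underscores as ``Genus_species_individual`` (first token genus, second
species, remainder the individual tag). A tab-separated taxonomy map
(columns: sequence_id, genus, species, individual) overrides the grammar.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "TaxonLabel",
    "LocusRecord",
    "MultiLocusDataset",
    "parse_underscore_label",
    "read_taxonomy_map",
    "read_locus_fasta",
    "assemble_dataset",
    "write_locus_fasta",
    "write_taxonomy_map",
    "write_phylip_distmatrix",
    "read_phylip_distmatrix",
]

_VALID_RESIDUES = frozenset("ACGTUNRYSWKMBDHV-")


@dataclass(frozen=True, order=True)
class TaxonLabel:
    """Identity of one specimen: genus, species, individual, sequence id."""

    genus: str
    species: str
    individual: str
    sequence_id: str

    @property
    def binomial(self) -> str:
        return f"{self.genus} {self.species}"


@dataclass(frozen=True)
class LocusRecord:
    """One DNA sequence of one locus for one specimen."""

    label: TaxonLabel
    locus: str
    residues: str  # upper-case on ingestion

    @property
    def length_L(self) -> int:
        return len(self.residues)


def parse_underscore_label(sequence_id: str) -> TaxonLabel:
    """Parse ``Genus_species_individual`` headers (individual may be empty)."""
    parts = sequence_id.split("_")
    if len(parts) < 2 or not parts[0] or not parts[1]:
        raise ValueError(
            f"cannot parse taxon from header {sequence_id!r}: expected "
            "'Genus_species[_individual]' (or supply a taxonomy map)"
        )
    return TaxonLabel(
        genus=parts[0],
        species=parts[1],
        individual="_".join(parts[2:]),
        sequence_id=sequence_id,
    )


def read_taxonomy_map(path: str | Path) -> dict[str, TaxonLabel]:
    """Read a TSV taxonomy map: sequence_id, genus, species[, individual]."""
    labels: dict[str, TaxonLabel] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "sequence_id":  # header row
                continue
            if len(fields) < 3 or not fields[1] or not fields[2]:
                raise ValueError(
                    f"{path}:{lineno}: expected sequence_id<TAB>genus<TAB>"
                    f"species[<TAB>individual], got {line!r}"
                )
            individual = fields[3] if len(fields) > 3 else ""
            labels[fields[0]] = TaxonLabel(
                genus=fields[1],
                species=fields[2],
                individual=individual,
                sequence_id=fields[0],
            )
    return labels


def _validate_residues(seq_id: str, residues: str) -> str:
    residues = residues.upper().replace("U", "T")
    bad = set(residues) - _VALID_RESIDUES
    if bad:
        raise ValueError(
            f"record {seq_id!r}: invalid residue(s) {sorted(bad)!r}"
        )
    # gap characters from pre-aligned exports are dropped: method is alignment-free
    return residues.replace("-", "")


def read_locus_fasta(
    path: str | Path,
    locus: str,
    taxonomy: dict[str, TaxonLabel] | None = None,
) -> list[LocusRecord]:
    """Read one locus FASTA into LocusRecords.

    Taxon labels come from ``taxonomy`` when given, otherwise from the
    underscore header grammar. Duplicate sequence ids within one locus and
    empty sequences are errors; an empty file yields an empty list with a
    logged warning.
    """
    records: list[LocusRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq_id = rec.id
        if seq_id in seen:
            raise ValueError(f"{path}: duplicate sequence id {seq_id!r} in locus {locus}")
        seen.add(seq_id)
        residues = _validate_residues(seq_id, str(rec.seq))
        if not residues:
            raise ValueError(f"{path}: record {seq_id!r} has an empty sequence")
        if taxonomy is not None:
            if seq_id not in taxonomy:
                raise ValueError(
                    f"{path}: sequence id {seq_id!r} missing from taxonomy map"
                )
            label = taxonomy[seq_id]
        else:
            label = parse_underscore_label(seq_id)
        records.append(LocusRecord(label=label, locus=locus, residues=residues))
    if not records:
        logger.warning("FASTA file %s for locus %s contains no records", path, locus)
    return records


@dataclass
class MultiLocusDataset:
    """Specimens x loci collection of sequences with stable orderings.

    ``taxa`` is the stable specimen order used by every downstream matrix;
    ``loci`` the stable locus order. In strict mode every taxon has exactly
    one record per locus; in non-strict mode missing (taxon, locus) cells are
    simply absent.
    """

    loci: list[str]
    taxa: list[TaxonLabel]
    records: dict[tuple[str, str], LocusRecord] = field(repr=False)  # (seq_id, locus)
    strict: bool = True

    def record(self, taxon: TaxonLabel | str, locus: str) -> LocusRecord | None:
        seq_id = taxon if isinstance(taxon, str) else taxon.sequence_id
        return self.records.get((seq_id, locus))

    def has_locus(self, taxon: TaxonLabel | str, locus: str) -> bool:
        return self.record(taxon, locus) is not None

    def lengths(self, locus: str) -> np.ndarray:
        """Per-taxon sequence length at a locus (0 where absent)."""
        out = np.zeros(len(self.taxa), dtype=np.int64)
        for i, t in enumerate(self.taxa):
            rec = self.records.get((t.sequence_id, locus))
            if rec is not None:
                out[i] = rec.length_L
        return out

    @property
    def sequence_ids(self) -> list[str]:
        return [t.sequence_id for t in self.taxa]

    def taxonomy(self) -> dict[str, TaxonLabel]:
        return {t.sequence_id: t for t in self.taxa}

    def min_length(self, locus: str) -> int:
        lens = [int(x) for x in self.lengths(locus) if x > 0]
        if not lens:
            raise ValueError(f"no sequences for locus {locus!r}")
        return min(lens)


def assemble_dataset(
    per_locus_records: dict[str, list[LocusRecord]],
    strict: bool = True,
) -> MultiLocusDataset:
    """Assemble per-locus record lists into one dataset.

    Taxon order follows first appearance across loci in the given locus
    order. Strict mode (default) requires every taxon to carry every locus
    and errors with the offending taxa otherwise; non-strict keeps the union
    of taxa with missing cells recorded as absent.
    """
    if not per_locus_records:
        raise ValueError("at least one locus is required")
    loci = list(per_locus_records)
    records: dict[tuple[str, str], LocusRecord] = {}
    taxa: list[TaxonLabel] = []
    seen_ids: dict[str, TaxonLabel] = {}
    for locus in loci:
        recs = per_locus_records[locus]
        if not recs:
            raise ValueError(f"locus {locus!r} has no records")
        for rec in recs:
            sid = rec.label.sequence_id
            if sid in seen_ids:
                if seen_ids[sid] != rec.label:
                    raise ValueError(
                        f"sequence id {sid!r} carries conflicting taxon labels "
                        f"across loci"
                    )
            else:
                seen_ids[sid] = rec.label
                taxa.append(rec.label)
            records[(sid, locus)] = rec

    if strict:
        missing = [
            (t.sequence_id, locus)
            for t in taxa
            for locus in loci
            if (t.sequence_id, locus) not in records
        ]
        if missing:
            detail = ", ".join(f"{sid} lacks {locus}" for sid, locus in missing[:10])
            raise ValueError(
                f"strict mode: {len(missing)} missing (taxon, locus) pairs: {detail}"
            )
    return MultiLocusDataset(loci=loci, taxa=taxa, records=records, strict=strict)


def write_locus_fasta(records: list[LocusRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.label.sequence_id}\n")
            for i in range(0, len(rec.residues), 70):
                fh.write(rec.residues[i : i + 70] + "\n")


def write_taxonomy_map(taxa: list[TaxonLabel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sequence_id\tgenus\tspecies\tindividual\n")
        for t in taxa:
            fh.write(f"{t.sequence_id}\t{t.genus}\t{t.species}\t{t.individual}\n")


# --- PHYLIP square distance-matrix format ---------------------------------

def write_phylip_distmatrix(
    ids: list[str],
    values: np.ndarray,
    path: str | Path,
    relaxed: bool = False,
) -> None:
    """Write a square PHYLIP distance matrix.

    Strict dialect (default) pads/truncates names to 10 characters and
    errors when two names collide after truncation; the relaxed dialect
    writes full names followed by two spaces.
    """
    values = np.asarray(values, dtype=float)
    n = len(ids)
    if values.shape != (n, n):
        raise ValueError(f"matrix shape {values.shape} does not match {n} ids")
    if not np.allclose(values, values.T, atol=1e-9):
        raise ValueError("distance matrix is not symmetric")
    if relaxed:
        names = [f"{i}  " for i in ids]
    else:
        names = [f"{i[:10]:<10}" for i in ids]
        if len({nm.strip() for nm in names}) != n:
            raise ValueError(
                "taxon names collide after 10-character PHYLIP truncation; "
                "relabel or use the relaxed dialect"
            )
    with open(path, "w") as fh:
        fh.write(f"{n}\n")
        for name, row in zip(names, values):
            fh.write(name + " ".join(f"{v:.6f}" for v in row) + "\n")


def read_phylip_distmatrix(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read a square PHYLIP distance matrix (strict or relaxed names)."""
    with open(path) as fh:
        tokens_first = fh.readline().split()
        if not tokens_first:
            raise ValueError(f"{path}: empty file")
        n = int(tokens_first[0])
        ids: list[str] = []
        rows: list[list[float]] = []
        for line in fh:
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < n + 1:
                raise ValueError(f"{path}: malformed row {line!r}")
            ids.append(parts[0])
            rows.append([float(x) for x in parts[-n:]])
    if len(ids) != n:
        raise ValueError(f"{path}: expected {n} rows, found {len(ids)}")
    return ids, np.asarray(rows, dtype=float)
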