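"""Taxonomy-annotated reference databases in Silva-style FASTA.

A Silva SSU export carries the full taxonomic path in the FASTA header,
semicolon-separated after the accession::

    >AB000001.1.1700 Eukaryota;Opisthokonta;Metazoa;Mollusca;...

Records are normalised on ingest (U->T, uppercase, alignment gaps
stripped) so every downstream primer comparison operates on plain
uppercase IUPAC DNA.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio.SeqIO.FastaIO import SimpleFastaParser

from .insilico_pcr import IUPAC_SETS

__all__ = [
    "ReferenceRecord",
    "TaxonomyPath",
    "read_reference_fasta",
    "write_fasta",
    "partition_by_label",
    "write_taxonomy_tsv",
]

# fraction of ambiguity codes above which a record is flagged (not dropped)
AMBIGUITY_FLAG_FRACTION = 0.10
_CONCRETE = frozenset("ACGT")


@dataclass(frozen=True)
class TaxonomyPath:
    """An ordered root-to-leaf list of rank labels."""

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.labels:
            raise ValueError("taxonomy must have at least one label")
        if any(not lab for lab in self.labels):
            raise ValueError("taxonomy labels must be non-empty")

    @classmethod
    def from_string(cls, text: str) -> "TaxonomyPath":
        labels = tuple(lab.strip() for lab in text.split(";") if lab.strip())
        return cls(labels)

    def contains(self, label: str) -> bool:
        """Case-insensitive exact-label membership test."""
        needle = label.lower()
        return any(lab.lower() == needle for lab in self.labels)

    def at_rank(self, rank: int) -> str | None:
        """Label at 0-based depth *rank*, or None if the path is shallower."""
        return self.labels[rank] if rank < len(self.labels) else None

    def __str__(self) -> str:
        return ";".join(self.labels)

    def __iter__(self):
        return iter(self.labels)


@dataclass(frozen=True)
class ReferenceRecord:
    """One annotated SSU sequence."""

    id: str
    taxonomy: TaxonomyPath
    sequence: str
    ambiguous_flag: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - set(IUPAC_SETS)
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid nucleotide characters {sorted(bad)}"
            )

    @classmethod
    def from_raw(cls, rid: str, taxonomy: TaxonomyPath, raw_seq: str) -> "ReferenceRecord":
        """Build a record from an un-normalised sequence string.

        Applies the ingest normalisation: uppercase, U->T, alignment gap
        characters ('-', '.') removed.  Records whose ambiguity-code
        fraction exceeds 10% are flagged but kept.
        """
        seq = raw_seq.upper().replace("U", "T").replace("-", "").replace(".", "")
        if not seq:
            raise ValueError(f"record {rid!r}: empty sequence after gap removal")
        n_amb = sum(1 for c in seq if c not in _CONCRETE)
        return cls(
            id=rid,
            taxonomy=taxonomy,
            sequence=seq,
            ambiguous_flag=n_amb / len(seq) > AMBIGUITY_FLAG_FRACTION,
        )


def read_reference_fasta(path: str | Path) -> list[ReferenceRecord]:
    """Read a Silva-style FASTA into a list of records, order preserved.

    Header dialect: the token before the first whitespace is the id; the
    remainder is the semicolon-separated taxonomy.  A header with no
    taxonomy is a record-level error reported with its entry number.
    """
    path = Path(path)
    records: list[ReferenceRecord] = []
    seen: set[str] = set()
    with path.open() as fh:
        for entry_no, (header, seq) in enumerate(SimpleFastaParser(fh), start=1):
            parts = header.split(None, 1)
            rid = parts[0] if parts else ""
            if len(parts) < 2 or not parts[1].strip(" ;"):
                raise ValueError(
                    f"{path}: entry {entry_no} ({rid or 'unnamed'}): "
                    "header lacks a taxonomy annotation"
                )
            if rid in seen:
                raise ValueError(f"{path}: duplicate record id {rid!r}")
            seen.add(rid)
            taxonomy = TaxonomyPath.from_string(parts[1])
            records.append(ReferenceRecord.from_raw(rid, taxonomy, seq))
    return records


def write_fasta(records: Iterable[ReferenceRecord], path: str | Path, width: int = 80) -> None:
    """Write records as Silva-style FASTA, sequences wrapped at *width* columns."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            fh.write(f">{rec.id} {rec.taxonomy}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def partition_by_label(
    records: Sequence[ReferenceRecord], label: str
) -> tuple[list[ReferenceRecord], list[ReferenceRecord]]:
    """Split records into (taxonomy contains label, does not), order preserved.

    This is the metazoan / non-metazoan split when called with
    ``label="Metazoa"``; any rank label works (e.g. ``"Ostreoida"``).
    """
    matching: list[ReferenceRecord] = []
    non_matching: list[ReferenceRecord] = []
    for rec in records:
        (matching if rec.taxonomy.contains(label) else non_matching).append(rec)
    return matching, non_matching


def write_taxonomy_tsv(records: Iterable[ReferenceRecord], path: str | Path) -> None:
    """Export (id, taxonomy, length) as TSV."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["id", "taxonomy", "length"])
        for rec in records:
            writer.writerow([rec.id, str(rec.taxonomy), len(rec.sequence)])
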