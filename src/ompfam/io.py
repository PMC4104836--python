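"""Core domain types and FASTA/TSV input-output.

Sequences are plain upper-case strings over the 20 standard amino acids,
with ``X`` allowed as a wildcard. Identical full-length sequences can be
collapsed into duplicate groups (the desk-scale analogue of UniRef100
grouping) so that downstream all-vs-all stages see each distinct string
once.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: residues legal in a SequenceRecord; X is a wildcard scoring 0 everywhere
VALID_RESIDUES = frozenset(AMINO_ACIDS) | {"X"}
GAP_CHARS = frozenset("-.")

#: Robinson-Robinson amino-acid frequencies (AMINO_ACIDS order) — the
#: average composition of real proteins, used as the default background
#: for profiles and for random-sequence generation
BACKGROUND_FREQUENCIES = {
    "A": 0.0780, "C": 0.0192, "D": 0.0536, "E": 0.0629, "F": 0.0385,
    "G": 0.0738, "H": 0.0219, "I": 0.0514, "K": 0.0574, "L": 0.0901,
    "M": 0.0224, "N": 0.0448, "P": 0.0520, "Q": 0.0426, "R": 0.0512,
    "S": 0.0712, "T": 0.0584, "V": 0.0644, "W": 0.0132, "Y": 0.0321,
}


class FastaError(ValueError):
    """Raised for malformed sequence input."""


@dataclass
class SequenceRecord:
    """A protein sequence: the unit every pipeline stage operates on."""

    id: str
    residues: str
    taxon_id: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FastaError("sequence id must be non-empty")
        if len(self.residues) < 1:
            raise FastaError(f"sequence {self.id!r} is empty")
        for pos, ch in enumerate(self.residues, start=1):
            if ch not in VALID_RESIDUES:
                raise FastaError(
                    f"illegal residue {ch!r} at position {pos} in sequence {self.id!r}"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class TaxonRecord:
    """One taxon (genome) with its phylum and complete-proteome flag."""

    taxon_id: str
    name: str
    phylum: str
    complete_proteome: bool

    def __post_init__(self) -> None:
        if not self.taxon_id:
            raise ValueError("taxon_id must be non-empty")
        if not self.phylum:
            raise ValueError(f"taxon {self.taxon_id!r}: phylum must be non-empty")


@dataclass
class DuplicateGroup:
    """A set of ids whose residue strings are identical."""

    representative_id: str
    member_ids: list[str]


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into validated records.

    The id is the first whitespace-delimited header token; the rest of
    the header becomes the description. Residues are upper-cased. Gap
    characters, duplicate ids and illegal residues raise :class:`FastaError`.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaError(f"duplicate id {rec.id!r} in {path}")
        seen.add(rec.id)
        residues = str(rec.seq).upper()
        if any(ch in GAP_CHARS for ch in residues):
            raise FastaError(f"gap character in sequence {rec.id!r} in {path}")
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(SequenceRecord(id=rec.id, residues=residues, description=desc))
    if not records:
        raise FastaError(f"no sequences found in {path}")
    return records


def read_aligned_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read an aligned FASTA (gaps permitted) as ``(id, row)`` pairs.

    All rows must have equal padded length.
    """
    path = Path(path)
    rows: list[tuple[str, str]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        row = str(rec.seq).upper().replace(".", "-")
        for pos, ch in enumerate(row, start=1):
            if ch != "-" and ch not in VALID_RESIDUES:
                raise FastaError(
                    f"illegal residue {ch!r} at position {pos} in aligned row {rec.id!r}"
                )
        rows.append((rec.id, row))
    if not rows:
        raise FastaError(f"no sequences found in {path}")
    width = len(rows[0][1])
    for rid, row in rows:
        if len(row) != width:
            raise FastaError(f"aligned row {rid!r} has length {len(row)}, expected {width}")
    return rows


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> Path:
    """Write records to FASTA. Round-trips through :func:`read_fasta`."""
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n{rec.residues}\n")
    return path


def collapse_identical(
    records: Sequence[SequenceRecord],
) -> tuple[list[DuplicateGroup], list[SequenceRecord]]:
    """Group records with identical residue strings; keep one representative each.

    The representative is the lexicographically smallest id of the group.
    The returned groups partition the input; representatives are returned
    in input order of their group's first occurrence.
    """
    by_string: dict[str, list[SequenceRecord]] = {}
    order: list[str] = []
    for rec in records:
        if rec.residues not in by_string:
            order.append(rec.residues)
            by_string[rec.residues] = []
        by_string[rec.residues].append(rec)
    groups: list[DuplicateGroup] = []
    reps: list[SequenceRecord] = []
    for residues in order:
        members = by_string[residues]
        rep_id = min(m.id for m in members)
        rep = next(m for m in members if m.id == rep_id)
        groups.append(DuplicateGroup(representative_id=rep_id,
                                     member_ids=[m.id for m in members]))
        reps.append(rep)
    return groups, reps


def read_taxa(path: str | Path) -> list[TaxonRecord]:
    """Read the taxon table (TSV with header: taxon_id, name, phylum, complete_proteome)."""
    path = Path(path)
    taxa: list[TaxonRecord] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            tid = row["taxon_id"]
            if tid in seen:
                raise ValueError(f"duplicate taxon_id {tid!r} in {path}")
            seen.add(tid)
            taxa.append(TaxonRecord(
                taxon_id=tid,
                name=row.get("name", tid),
                phylum=row["phylum"],
                complete_proteome=row["complete_proteome"] in ("1", "true", "True"),
            ))
    if not taxa:
        raise ValueError(f"no taxa found in {path}")
    return taxa


def write_taxa(taxa: Iterable[TaxonRecord], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["taxon_id", "name", "phylum", "complete_proteome"])
        for t in taxa:
            writer.writerow([t.taxon_id, t.name, t.phylum, int(t.complete_proteome)])
    return path


def write_duplicate_groups(groups: Iterable[DuplicateGroup], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["representative_id", "member_id"])
        for g in groups:
            for m in g.member_ids:
                writer.writerow([g.representative_id, m])
    return path
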