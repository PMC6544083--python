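"""Protein multiple-sequence alignments: containers, I/O, coordinates.

Sequences use the 20 standard amino acids plus ``X`` (ambiguous) and
``-`` (gap).  Every record carries a ``genome_id`` so downstream steps can
partition records into in-group and out-group; the on-disk convention is
``record_id|genome_id`` in the header, or a sidecar ``record_id<TAB>
genome_id`` mapping file.

All coordinates in this package are 1-based closed intervals, matching how
indel positions are conventionally reported for proteins.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
ALPHABET = frozenset(AMINO_ACIDS + "X" + GAP)

#: Clustal "strong similarity" residue classes, the de facto convention
#: for deciding whether non-identical residues still count as conserved.
STRONG_GROUPS: tuple[frozenset[str], ...] = tuple(
    frozenset(g) for g in
    ("STA", "NEQK", "NHQK", "NDEQ", "QHRK", "MILV", "MILF", "HY", "FYW")
)


class AlignmentFormatError(ValueError):
    """Malformed alignment input (ragged rows, duplicate ids, ...)."""


class AlphabetError(AlignmentFormatError):
    """Sequence contains a symbol outside the amino-acid alphabet."""


@dataclass
class SequenceRecord:
    """One aligned sequence with genome attribution."""

    record_id: str
    genome_id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.record_id:
            raise AlignmentFormatError("record_id must be non-empty")
        if not self.residues:
            raise AlignmentFormatError(
                f"record {self.record_id!r}: empty sequence")
        self.residues = self.residues.upper()
        for pos, symbol in enumerate(self.residues, start=1):
            if symbol not in ALPHABET:
                raise AlphabetError(
                    f"record {self.record_id!r}: illegal symbol {symbol!r} "
                    f"at column {pos}")

    @property
    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")

    @property
    def ungapped_length(self) -> int:
        return len(self.residues) - self.residues.count(GAP)


@dataclass
class Alignment:
    """An ordered set of equal-length gapped records."""

    records: list[SequenceRecord]
    name: str = "alignment"

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise AlignmentFormatError("alignment needs at least 2 records")
        lengths = {len(r.residues) for r in self.records}
        if len(lengths) != 1:
            bad = [r.record_id for r in self.records
                   if len(r.residues) != len(self.records[0].residues)]
            raise AlignmentFormatError(
                f"ragged alignment; offending records: {bad}")
        ids = [r.record_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise AlignmentFormatError(f"duplicate record ids: {dupes}")

    @property
    def n_cols(self) -> int:
        return len(self.records[0].residues)

    @property
    def n_records(self) -> int:
        return len(self.records)

    def record_ids(self) -> list[str]:
        return [r.record_id for r in self.records]

    def get(self, record_id: str) -> SequenceRecord:
        for r in self.records:
            if r.record_id == record_id:
                return r
        raise KeyError(record_id)

    def column(self, col: int) -> str:
        """Residues of 1-based column ``col``, one per record."""
        if not 1 <= col <= self.n_cols:
            raise IndexError(f"column {col} outside [1, {self.n_cols}]")
        return "".join(r.residues[col - 1] for r in self.records)

    def genomes(self) -> list[str]:
        """Genome ids in record order, de-duplicated."""
        seen: list[str] = []
        for r in self.records:
            if r.genome_id not in seen:
                seen.append(r.genome_id)
        return seen

    def subalignment(self, col_start: int, col_end: int,
                     record_ids: Optional[Sequence[str]] = None) -> "Alignment":
        """Columns ``[col_start, col_end]`` (1-based closed), optionally
        restricted to ``record_ids`` in the given order."""
        if not (1 <= col_start <= col_end <= self.n_cols):
            raise IndexError(f"interval [{col_start}, {col_end}] outside "
                             f"[1, {self.n_cols}]")
        recs = (self.records if record_ids is None
                else [self.get(i) for i in record_ids])
        return Alignment(
            [SequenceRecord(r.record_id, r.genome_id,
                            r.residues[col_start - 1:col_end], r.description)
             for r in recs],
            name=f"{self.name}[{col_start}:{col_end}]")


# ---------------------------------------------------------------------------
# header conventions


def split_header(record_id: str,
                 genome_map: Optional[Mapping[str, str]] = None) -> tuple[str, str]:
    """Resolve ``(record_id, genome_id)`` from a sequence header token.

    Resolution order: sidecar ``genome_map``, then the ``record_id|genome_id``
    convention, then the record id itself (records already keyed by genome).
    """
    if genome_map is not None and record_id in genome_map:
        return record_id, genome_map[record_id]
    if "|" in record_id:
        rid, _, gid = record_id.rpartition("|")
        if rid and gid:
            return rid, gid
    return record_id, record_id


def join_header(record: SequenceRecord) -> str:
    if record.genome_id and record.genome_id != record.record_id:
        return f"{record.record_id}|{record.genome_id}"
    return record.record_id


def read_genome_map(path) -> dict[str, str]:
    """Read a ``record_id<TAB>genome_id`` sidecar mapping file."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise AlignmentFormatError(
                    f"{path}:{lineno}: expected 2 columns")
            mapping[parts[0].strip()] = parts[1].strip()
    return mapping


# ---------------------------------------------------------------------------
# I/O


def _parse_fasta(path) -> list[tuple[str, str, str]]:
    """Minimal strict FASTA reader returning (id, description, sequence)."""
    entries: list[tuple[str, str, str]] = []
    header: Optional[str] = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if header is not None:
                    entries.append((*_split_desc(header), "".join(chunks)))
                header = line[1:].strip()
                chunks = []
            elif line.strip():
                if header is None:
                    raise AlignmentFormatError(f"{path}: sequence before header")
                chunks.append(line.strip())
    if header is not None:
        entries.append((*_split_desc(header), "".join(chunks)))
    if not entries:
        raise AlignmentFormatError(f"{path}: no FASTA records")
    return entries


def _split_desc(header: str) -> tuple[str, str]:
    token, _, desc = header.partition(" ")
    return token, desc.strip()


def read_alignment(path, format: str = "fasta",
                   genome_map: Optional[Mapping[str, str]] = None,
                   name: Optional[str] = None) -> Alignment:
    """Read an aligned FASTA or Clustal file into an :class:`Alignment`.

    Record order is preserved.  Raggedness raises
    :class:`AlignmentFormatError` naming the offending records; symbols
    outside the amino-acid alphabet raise :class:`AlphabetError` with the
    position.
    """
    if format == "fasta":
        raw = _parse_fasta(path)
    elif format == "clustal":
        try:
            msa = AlignIO.read(str(path), "clustal")
        except ValueError as exc:
            raise AlignmentFormatError(f"{path}: {exc}") from exc
        raw = [(rec.id, "", str(rec.seq)) for rec in msa]
    else:
        raise ValueError(f"unsupported format {format!r}")
    records = []
    for token, desc, seq in raw:
        rid, gid = split_header(token, genome_map)
        records.append(SequenceRecord(rid, gid, seq, desc))
    return Alignment(records, name=name or Path(str(path)).stem)


def write_alignment(alignment: Alignment, path, format: str = "fasta") -> None:
    """Write an alignment; ``read_alignment`` round-trips ids, order and
    residues exactly."""
    if format == "fasta":
        with open(path, "w") as fh:
            for rec in alignment.records:
                header = join_header(rec)
                if rec.description:
                    header = f"{header} {rec.description}"
                fh.write(f">{header}\n{rec.residues}\n")
    elif format == "clustal":
        msa = MultipleSeqAlignment(
            SeqRecord(Seq(rec.residues), id=join_header(rec), description="")
            for rec in alignment.records)
        AlignIO.write(msa, str(path), "clustal")
    else:
        raise ValueError(f"unsupported format {format!r}")


# ---------------------------------------------------------------------------
# coordinate mapping


def column_to_residue_position(record: SequenceRecord,
                               column: int) -> Optional[int]:
    """Map a 1-based alignment column to the record's 1-based ungapped
    residue position, or ``None`` when the column holds a gap."""
    if not 1 <= column <= len(record.residues):
        raise IndexError(
            f"column {column} outside [1, {len(record.residues)}]")
    if record.residues[column - 1] == GAP:
        return None
    return column - record.residues.count(GAP, 0, column)


def residue_position_to_column(record: SequenceRecord,
                               position: int) -> int:
    """Inverse of :func:`column_to_residue_position` on non-gap columns."""
    if position < 1 or position > record.ungapped_length:
        raise IndexError(
            f"position {position} outside [1, {record.ungapped_length}]")
    count = 0
    for col, symbol in enumerate(record.residues, start=1):
        if symbol != GAP:
            count += 1
            if count == position:
                return col
    raise AssertionError("unreachable")  # pragma: no cover


def is_conserved_column(residues: str,
                        groups: Sequence[frozenset[str]] = STRONG_GROUPS) -> bool:
    """A column is conserved iff no record has a gap or ``X`` there and all
    residues are identical or fall within one similarity class."""
    if GAP in residues or "X" in residues:
        return False
    distinct = set(residues)
    if len(distinct) == 1:
        return True
    return any(distinct <= g for g in groups)
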