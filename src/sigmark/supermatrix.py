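"""Concatenated marker supermatrices for phylogenomic tree building.

Per-marker alignments (records keyed by genome) are concatenated into a
single partitioned alignment; genomes lacking a marker are gap-filled or
dropped.  A simple two-threshold column filter removes gap-rich and
poorly conserved columns before the matrix is handed to an external tree
builder.  The filter is a transparent column-wise rule — deliberately not
a re-implementation of block-based trimmers such as Gblocks — and reports
the kept columns so externally trimmed alignments can be substituted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .alignments import (GAP, STRONG_GROUPS, Alignment, SequenceRecord)


class SupermatrixError(ValueError):
    pass


@dataclass
class Supermatrix:
    """A concatenated alignment plus its marker partition map."""

    alignment: Alignment
    partitions: list[tuple[str, int, int]]  # (marker_id, col_start, col_end)

    def __post_init__(self) -> None:
        expected = 1
        for marker_id, start, end in self.partitions:
            if start != expected or end < start:
                raise SupermatrixError(
                    f"partition {marker_id!r} [{start},{end}] does not tile")
            expected = end + 1
        if expected != self.alignment.n_cols + 1:
            raise SupermatrixError("partitions do not cover the alignment")


def concatenate_markers(markers: Mapping[str, Alignment],
                        genomes: Sequence[str],
                        missing_policy: str = "gap_fill") -> Supermatrix:
    """Concatenate marker alignments over an ordered genome set.

    Each marker alignment must have at most one record per genome.  Under
    ``gap_fill`` a genome lacking a marker receives an all-gap filler of
    that marker's width (a genome absent from *every* marker is an
    error); under ``drop_genome`` such genomes are removed entirely.
    Column count equals the sum of marker widths and the partition map
    records each marker's column interval.  Deterministic in marker and
    genome order.
    """
    if not genomes:
        raise SupermatrixError("genome list must be non-empty")
    if missing_policy not in ("gap_fill", "drop_genome"):
        raise SupermatrixError(f"unknown missing_policy {missing_policy!r}")
    if not markers:
        raise SupermatrixError("no markers to concatenate")
    by_marker: dict[str, dict[str, str]] = {}
    widths: dict[str, int] = {}
    for marker_id, aln in markers.items():
        rows: dict[str, str] = {}
        for rec in aln.records:
            if rec.genome_id in rows:
                raise SupermatrixError(
                    f"marker {marker_id!r}: duplicate genome {rec.genome_id!r}")
            rows[rec.genome_id] = rec.residues
        by_marker[marker_id] = rows
        widths[marker_id] = aln.n_cols

    kept = list(genomes)
    if missing_policy == "drop_genome":
        kept = [g for g in kept
                if all(g in by_marker[m] for m in markers)]
        if not kept:
            raise SupermatrixError("every genome lacks at least one marker")
    records = []
    for genome in kept:
        pieces = []
        n_present = 0
        for marker_id in markers:
            row = by_marker[marker_id].get(genome)
            if row is None:
                pieces.append(GAP * widths[marker_id])
            else:
                pieces.append(row)
                n_present += 1
        if n_present == 0:
            raise SupermatrixError(
                f"genome {genome!r} is absent from every marker")
        records.append(SequenceRecord(genome, genome, "".join(pieces)))

    partitions: list[tuple[str, int, int]] = []
    pos = 1
    for marker_id in markers:
        partitions.append((marker_id, pos, pos + widths[marker_id] - 1))
        pos += widths[marker_id]
    return Supermatrix(Alignment(records, name="supermatrix"), partitions)


def _modal_class_fraction(residues: str,
                          groups: Sequence[frozenset[str]]) -> float:
    """Largest fraction of non-gap residues falling in one similarity
    class (or one identical residue); ``X`` never matches anything."""
    nongap = [r for r in residues if r != GAP]
    if not nongap:
        return 0.0
    best = 0
    classes = list(groups) + [frozenset(r) for r in set(nongap) if r != "X"]
    for cls in classes:
        best = max(best, sum(r in cls for r in nongap))
    return best / len(nongap)


def trim_columns(alignment: Alignment, max_gap_frac: float = 0.5,
                 min_conserved_frac: float = 0.5,
                 conservation_groups: Sequence[frozenset[str]] = STRONG_GROUPS
                 ) -> tuple[Alignment, list[int]]:
    """Remove gap-rich and poorly conserved columns.

    Keeps exactly the columns whose gap fraction is at most
    ``max_gap_frac`` *and* whose modal similarity-class fraction among
    non-gap residues is at least ``min_conserved_frac``.  Returns the
    trimmed alignment and the kept 1-based column indices (strictly
    increasing).  Idempotent; records are never reordered or dropped.
    """
    if not (0 <= max_gap_frac <= 1 and 0 <= min_conserved_frac <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    n = alignment.n_records
    kept: list[int] = []
    for col in range(1, alignment.n_cols + 1):
        residues = alignment.column(col)
        gap_frac = residues.count(GAP) / n
        if gap_frac > max_gap_frac:
            continue
        if _modal_class_fraction(residues, conservation_groups) < min_conserved_frac:
            continue
        kept.append(col)
    if not kept:
        raise SupermatrixError("no columns survive trimming")
    trimmed = Alignment(
        [SequenceRecord(r.record_id, r.genome_id,
                        "".join(r.residues[c - 1] for c in kept),
                        r.description)
         for r in alignment.records],
        name=f"{alignment.name}.trimmed")
    return trimmed, kept


def write_phylip(alignment: Alignment, path) -> None:
    """Write relaxed PHYLIP (name, two spaces, full sequence per line)."""
    with open(path, "w") as fh:
        fh.write(f" {alignment.n_records} {alignment.n_cols}\n")
        for rec in alignment.records:
            fh.write(f"{rec.record_id}  {rec.residues}\n")


def write_partitions(partitions: Sequence[tuple[str, int, int]], path) -> None:
    """Write the partition map, one ``marker = start-end`` line each."""
    with open(path, "w") as fh:
        for marker_id, start, end in partitions:
            fh.write(f"{marker_id} = {start}-{end}\n")
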