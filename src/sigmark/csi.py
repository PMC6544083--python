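"""Conserved signature indel (CSI) detection.

A CSI is an insertion or deletion restricted to the members of one clade
(the in-group) and embedded in a well-conserved region of a protein: the
indel must be flanked, within a fixed window of alignment columns on each
side, by a minimum number of columns in which every compared sequence is
identical or within one residue-similarity class.

The scan proceeds in three stages:

1. :func:`find_candidate_blocks` finds the maximal column intervals whose
   gap pattern separates in-group from out-group — out-group entirely
   gapped while every in-group record carries residues (insertion), or
   the symmetric pattern (deletion).
2. :func:`score_flanks` counts conserved columns in the windows adjacent
   to a block; candidates whose flanks fall below the threshold are
   discarded.
3. :func:`call_csis` assembles the surviving candidates into
   :class:`CSIRecord` rows: indel type, size range, position on an
   ungapped reference sequence, per-genome presence pattern, and the
   clade the pattern defines.

Specificity can then be re-checked on an extended alignment (e.g. one
rebuilt to include the closest database homologs of an indel-containing
fragment) with :func:`check_presence`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .alignments import (GAP, STRONG_GROUPS, Alignment, SequenceRecord,
                         column_to_residue_position, is_conserved_column)
from .taxonomy import CladeTree, SpecificityResult, infer_specificity

PRESENT = "present"
ABSENT = "absent"
MISSING = "missing_data"


class ScanConfigError(ValueError):
    """Invalid scanner configuration or group sizes."""


@dataclass(frozen=True)
class ScanConfig:
    """Tunable parameters of the CSI scan.

    ``window_len`` and ``min_conserved`` encode the flank-conservation
    filter: at least ``min_conserved`` conserved columns within the
    ``window_len`` alignment columns neighbouring the indel on each side.
    Defaults (40-column window, 5 conserved) take the widest window and
    the lower admission bound of the conventional 5–6-in-30–40 rule, with
    both knobs exposed for stricter scans.
    """

    window_len: int = 40
    min_conserved: int = 5
    conservation_groups: tuple[frozenset[str], ...] = STRONG_GROUPS
    min_indel_len: int = 1
    max_indel_len: int = 30
    min_ingroup: int = 2
    min_outgroup: int = 2

    def __post_init__(self) -> None:
        if self.min_conserved > self.window_len:
            raise ScanConfigError("min_conserved cannot exceed window_len")
        if not 1 <= self.min_indel_len <= self.max_indel_len:
            raise ScanConfigError("need 1 <= min_indel_len <= max_indel_len")
        if self.window_len < 1:
            raise ScanConfigError("window_len must be positive")


@dataclass(frozen=True)
class IndelCandidate:
    """A maximal column interval with a group-specific gap pattern."""

    col_start: int  # 1-based inclusive
    col_end: int
    indel_type: str  # "insertion" | "deletion" (relative to the out-group)
    per_record_len: Mapping[str, int]  # record_id -> residues inside block

    def __post_init__(self) -> None:
        if self.col_start > self.col_end:
            raise ValueError("col_start must be <= col_end")
        if self.indel_type not in ("insertion", "deletion"):
            raise ValueError(f"bad indel_type {self.indel_type!r}")


@dataclass
class CSIRecord:
    """One called signature indel (a row of a signature-indel table)."""

    marker_id: str
    reference_id: str
    indel_type: str
    size_min: int
    size_max: int
    col_start: int
    col_end: int
    ref_span: tuple[int, int]  # 1-based closed, ungapped reference coords
    flank_left: int
    flank_right: int
    presence: dict[str, str]  # genome_id -> present|absent|missing_data
    specificity: SpecificityResult

    @property
    def size_label(self) -> str:
        if self.size_min == self.size_max:
            return f"{self.size_min}aa"
        return f"{self.size_min}-{self.size_max}aa"


def _split_groups(alignment: Alignment, ingroup: Iterable[str],
                  config: ScanConfig) -> tuple[list[int], list[int]]:
    ingroup = set(ingroup)
    in_idx = [i for i, r in enumerate(alignment.records)
              if r.genome_id in ingroup]
    out_idx = [i for i, r in enumerate(alignment.records)
               if r.genome_id not in ingroup]
    if len(in_idx) < config.min_ingroup:
        raise ScanConfigError(
            f"in-group has {len(in_idx)} records, need >= {config.min_ingroup}")
    if len(out_idx) < config.min_outgroup:
        raise ScanConfigError(
            f"out-group has {len(out_idx)} records, need >= {config.min_outgroup}")
    return in_idx, out_idx


def _gap_matrix(alignment: Alignment) -> np.ndarray:
    arr = np.array([list(r.residues) for r in alignment.records])
    return arr == GAP


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in a 1-D boolean mask, as 0-based [a, b]."""
    out: list[tuple[int, int]] = []
    start: Optional[int] = None
    for i, val in enumerate(mask):
        if val and start is None:
            start = i
        elif not val and start is not None:
            out.append((start, i - 1))
            start = None
    if start is not None:
        out.append((start, len(mask) - 1))
    return out


def find_candidate_blocks(alignment: Alignment, ingroup: Iterable[str],
                          config: ScanConfig = ScanConfig()
                          ) -> list[IndelCandidate]:
    """Find maximal group-specific indel blocks.

    The indel locus is taken to be a maximal run of *gap-containing*
    columns (columns in which at least one record is gapped); runs are
    therefore structural, never overlap, and cannot be extended without
    crossing a fully residue-bearing column.  A run is an *insertion*
    block when every out-group record has zero residues across it and
    every in-group record carries between ``min_indel_len`` and
    ``max_indel_len`` residues (per-record lengths may differ:
    variable-length insertions are admitted).  It is a *deletion* block
    in the symmetric case — every in-group record empty — with the
    additional requirement that all out-group records carry the same
    number of residues (deletions are fixed-size).  Evaluating the
    pattern over the whole gap run means an out-group record aligning
    even one residue inside the indel region (a shorter out-group indel
    at the same locus) disqualifies the block: the signature would not
    be clade-exclusive.  Output is sorted by ``col_start``.
    """
    in_idx, out_idx = _split_groups(alignment, ingroup, config)
    gaps = _gap_matrix(alignment)
    residues = ~gaps
    ids = alignment.record_ids()
    candidates: list[IndelCandidate] = []

    gappy = gaps.any(axis=0)
    for a, b in _runs(gappy):
        counts = residues[:, a:b + 1].sum(axis=1)
        in_counts = counts[in_idx]
        out_counts = counts[out_idx]
        if ((out_counts == 0).all()
                and (in_counts >= config.min_indel_len).all()
                and (in_counts <= config.max_indel_len).all()):
            candidates.append(IndelCandidate(
                a + 1, b + 1, "insertion",
                {ids[i]: int(counts[i]) for i in range(len(ids))}))
        elif ((in_counts == 0).all()
              and len(set(out_counts.tolist())) == 1
              and config.min_indel_len <= int(out_counts[0])
              <= config.max_indel_len):
            candidates.append(IndelCandidate(
                a + 1, b + 1, "deletion",
                {ids[i]: int(counts[i]) for i in range(len(ids))}))
    return candidates


def score_flanks(alignment: Alignment, block: IndelCandidate,
                 config: ScanConfig = ScanConfig()) -> tuple[int, int]:
    """Count conserved columns in the windows flanking a block.

    Each side examines up to ``window_len`` columns adjacent to the block
    (fewer where the alignment ends).  A column counts as conserved iff no
    record has a gap or ``X`` there and all residues are identical or fall
    within a single similarity class — conservation is required across
    *all* records in the alignment, in-group and out-group alike.
    """
    if not (1 <= block.col_start <= block.col_end <= alignment.n_cols):
        raise IndexError("block outside alignment bounds")
    left_cols = range(max(1, block.col_start - config.window_len),
                      block.col_start)
    right_cols = range(block.col_end + 1,
                       min(alignment.n_cols, block.col_end + config.window_len) + 1)
    groups = config.conservation_groups
    flank_left = sum(is_conserved_column(alignment.column(c), groups)
                     for c in left_cols)
    flank_right = sum(is_conserved_column(alignment.column(c), groups)
                      for c in right_cols)
    return flank_left, flank_right


def _record_status(record: SequenceRecord, col_start: int, col_end: int,
                   window_len: int, indel_type: str,
                   size_min: int, size_max: int) -> str:
    block = record.residues[col_start - 1:col_end]
    count = len(block) - block.count(GAP)
    win_a = max(0, col_start - 1 - window_len)
    win_b = min(len(record.residues), col_end + window_len)
    span = record.residues[win_a:win_b]
    if span.count(GAP) == len(span):  # truncated homolog: no data at locus
        return MISSING
    if indel_type == "insertion":
        return PRESENT if size_min <= count <= size_max else ABSENT
    return PRESENT if count == 0 else ABSENT


def check_presence(alignment: Alignment, csi: CSIRecord,
                   window_len: int = 40) -> dict[str, str]:
    """Classify every record as carrying / lacking the signature indel.

    ``present``: residue count inside the block within the recorded size
    range (insertion) or zero (deletion).  ``absent``: the opposite
    pattern.  ``missing_data``: the record is gap-only across the block
    *and* both flanking windows, i.e. a truncated homolog with no
    information at the locus.  Works on the discovery alignment or on one
    rebuilt to include additional homologs, as long as the block columns
    are valid.
    """
    if not (1 <= csi.col_start <= csi.col_end <= alignment.n_cols):
        raise IndexError("CSI block columns outside this alignment")
    return {r.record_id: _record_status(r, csi.col_start, csi.col_end,
                                        window_len, csi.indel_type,
                                        csi.size_min, csi.size_max)
            for r in alignment.records}


def _reference_span(reference: SequenceRecord, col_start: int, col_end: int,
                    indel_type: str) -> tuple[int, int]:
    """Ungapped reference coordinates of the indel.

    For an insertion the reference carries the inserted residues and the
    span covers them.  For a deletion the reference is gapped inside the
    block, so the span brackets the deletion site: the residues
    immediately left and right of the block.
    """
    prefix = reference.residues[:col_start - 1]
    left = len(prefix) - prefix.count(GAP)
    if indel_type == "insertion":
        block = reference.residues[col_start - 1:col_end]
        n = len(block) - block.count(GAP)
        return (left + 1, left + n) if n else (max(left, 1), left + 1)
    hi = min(left + 1, reference.ungapped_length)
    return (max(left, 1), hi)


def call_csis(alignment: Alignment, ingroup: Iterable[str],
              config: ScanConfig = ScanConfig(),
              tree: Optional[CladeTree] = None,
              reference_id: Optional[str] = None,
              marker_id: Optional[str] = None,
              min_coverage: float = 0.75,
              max_exceptions: int = 0) -> list[CSIRecord]:
    """Run the full scan and return one :class:`CSIRecord` per signature.

    A candidate is called iff both flanks reach ``config.min_conserved``
    conserved columns; candidates in poorly conserved regions are
    discarded.  The size range comes from the in-group per-record lengths
    (insertion) or the uniform out-group length (deletion).  The reference
    record defaults to the first in-group record in alignment order and
    must belong to the in-group.
    """
    ingroup = set(ingroup)
    in_idx, _ = _split_groups(alignment, ingroup, config)
    if reference_id is None:
        reference_id = alignment.records[in_idx[0]].record_id
    reference = alignment.get(reference_id)
    if reference.genome_id not in ingroup:
        raise ValueError(f"reference record {reference_id!r} is not in-group")
    marker_id = marker_id or alignment.name

    out: list[CSIRecord] = []
    for cand in find_candidate_blocks(alignment, ingroup, config):
        fl, fr = score_flanks(alignment, cand, config)
        if fl < config.min_conserved or fr < config.min_conserved:
            continue
        if cand.indel_type == "insertion":
            sizes = [cand.per_record_len[alignment.records[i].record_id]
                     for i in in_idx]
        else:
            sizes = [n for rid, n in cand.per_record_len.items()
                     if alignment.get(rid).genome_id not in ingroup]
        size_min, size_max = min(sizes), max(sizes)
        presence_by_record = {
            r.record_id: _record_status(r, cand.col_start, cand.col_end,
                                        config.window_len, cand.indel_type,
                                        size_min, size_max)
            for r in alignment.records}
        presence: dict[str, str] = {}
        rank = {PRESENT: 2, ABSENT: 1, MISSING: 0}
        for r in alignment.records:
            status = presence_by_record[r.record_id]
            prev = presence.get(r.genome_id)
            if prev is None or rank[status] > rank[prev]:
                presence[r.genome_id] = status
        present_genomes = {g for g, s in presence.items() if s == PRESENT}
        if tree is not None and present_genomes:
            spec = infer_specificity(present_genomes, tree,
                                     min_coverage=min_coverage,
                                     max_exceptions=max_exceptions)
        else:
            spec = SpecificityResult(None, 0.0, frozenset())
        out.append(CSIRecord(
            marker_id=marker_id, reference_id=reference_id,
            indel_type=cand.indel_type, size_min=size_min, size_max=size_max,
            col_start=cand.col_start, col_end=cand.col_end,
            ref_span=_reference_span(reference, cand.col_start, cand.col_end,
                                     cand.indel_type),
            flank_left=fl, flank_right=fr,
            presence=presence, specificity=spec))
    return out


def extract_indel_fragment(record: SequenceRecord, csi: CSIRecord,
                           target_len: int = 80) -> str:
    """Extract the ungapped indel-containing fragment of a record.

    Returns a subsequence of length ``min(target_len, ungapped length)``
    that contains the whole indel, centred on it as nearly as the protein
    termini allow.  The fragment length must lie in [60, 100] residues —
    long enough to seed a specific homology search, short enough that the
    indel dominates the match.  Deterministic.
    """
    if not 60 <= target_len <= 100:
        raise ValueError("target_len must be within [60, 100]")
    status = _record_status(record, csi.col_start, csi.col_end,
                            40, csi.indel_type, csi.size_min, csi.size_max)
    if status != PRESENT:
        raise ValueError(
            f"record {record.record_id!r} does not carry the indel "
            f"(status {status})")
    # ungapped span of the indel in this record
    prefix = record.residues[:csi.col_start - 1]
    left = len(prefix) - prefix.count(GAP)
    if csi.indel_type == "insertion":
        block = record.residues[csi.col_start - 1:csi.col_end]
        n = len(block) - block.count(GAP)
        s, e = left + 1, left + n
    else:  # deletion carrier: the indel is the junction between residues
        s, e = max(left, 1), min(left + 1, record.ungapped_length)
    length = record.ungapped_length
    if length < target_len:
        if length < 60:
            warnings.warn(
                f"record {record.record_id!r} is only {length} aa; returning "
                f"the whole sequence", stacklevel=2)
        return record.ungapped
    start = (s + e - target_len + 1) // 2
    start = max(1, min(start, length - target_len + 1))
    end = start + target_len - 1
    if e > end:  # indel wider than centring allows: shift right to cover it
        end = min(e, length)
        start = max(1, end - target_len + 1)
    return record.ungapped[start - 1:end]
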