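"""Publication-style signature alignment excerpts.

Signature indels are conventionally illustrated as a short alignment
window around the indel in which the top line shows the reference
sequence verbatim and every other line shows a dash wherever its residue
matches the reference ("dash-identity" encoding), making the indel and
the conservation of its flanks visible at a glance.

Because a dash doubles as the gap symbol in plain alignments, encoded
rows here use ``.`` for gaps and reserve ``-`` strictly for identity;
the reference row shows gaps as ``.`` too, so it never contains a dash.
Excerpts are lossless: :func:`decode_signature` reconstructs the exact
sub-alignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .alignments import GAP, Alignment, SequenceRecord
from .csi import ABSENT, MISSING, PRESENT, CSIRecord, check_presence

ENCODED_GAP = "."
IDENTITY = "-"


class ReportError(ValueError):
    pass


@dataclass(frozen=True)
class ExcerptRow:
    record_id: str
    genome_id: str
    start_position: int  # 1-based ungapped position of the window start
    encoded: str


@dataclass
class SignatureExcerpt:
    """A rendered alignment window around one signature indel."""

    header: str
    col_start: int  # window bounds in the source alignment (1-based)
    col_end: int
    rows: list[ExcerptRow]
    n_ingroup: int  # rows [0, n_ingroup) are indel carriers / in-group

    def __post_init__(self) -> None:
        if not self.rows:
            raise ReportError("excerpt has no rows")
        width = len(self.rows[0].encoded)
        if any(len(r.encoded) != width for r in self.rows):
            raise ReportError("ragged excerpt rows")
        if IDENTITY in self.rows[0].encoded:
            raise ReportError("reference row may not contain identity dashes")

    @property
    def width(self) -> int:
        return len(self.rows[0].encoded)


def _start_position(record: SequenceRecord, col: int) -> int:
    """Ungapped position at which the window starting at ``col`` begins:
    one past the residues preceding the window."""
    prefix = record.residues[:col - 1]
    return len(prefix) - prefix.count(GAP) + 1


def render_signature(alignment: Alignment, csi: CSIRecord,
                     context_cols: int = 40,
                     outgroup_sample: int = 10) -> SignatureExcerpt:
    """Render the dash-identity excerpt for one signature indel.

    The window spans the indel block plus ``context_cols`` columns on each
    side (clipped at the alignment ends).  The reference record comes
    first and is shown verbatim (gaps as ``.``); every other row encodes a
    residue as ``-`` when identical to the reference at that column.
    Indel carriers are listed first, then up to ``outgroup_sample``
    non-carrier rows in input order (representative subsampling is
    deterministic).
    """
    if context_cols < 1:
        raise ReportError("context_cols must be >= 1")
    if not (1 <= csi.col_start <= csi.col_end <= alignment.n_cols):
        raise ReportError("CSI block does not fit this alignment")
    try:
        reference = alignment.get(csi.reference_id)
    except KeyError:
        raise ReportError(
            f"reference record {csi.reference_id!r} not in alignment") from None
    a = max(1, csi.col_start - context_cols)
    b = min(alignment.n_cols, csi.col_end + context_cols)

    status = check_presence(alignment, csi)
    carriers = [r for r in alignment.records
                if status[r.record_id] == PRESENT and r is not reference]
    others = [r for r in alignment.records
              if status[r.record_id] != PRESENT][:outgroup_sample]

    ref_window = reference.residues[a - 1:b]
    rows = [ExcerptRow(reference.record_id, reference.genome_id,
                       _start_position(reference, a),
                       ref_window.replace(GAP, ENCODED_GAP))]
    for rec in carriers + others:
        window = rec.residues[a - 1:b]
        encoded = []
        for res, ref_res in zip(window, ref_window):
            if res == GAP:
                encoded.append(ENCODED_GAP)
            elif ref_res != GAP and res == ref_res:
                encoded.append(IDENTITY)
            else:
                encoded.append(res)
        rows.append(ExcerptRow(rec.record_id, rec.genome_id,
                               _start_position(rec, a), "".join(encoded)))
    header = (f"{csi.marker_id} {csi.size_label} "
              f"{'ins' if csi.indel_type == 'insertion' else 'del'} "
              f"{csi.ref_span[0]}-{csi.ref_span[1]}")
    return SignatureExcerpt(header=header, col_start=a, col_end=b,
                            rows=rows, n_ingroup=1 + len(carriers))


def decode_signature(excerpt: SignatureExcerpt) -> Alignment:
    """Reconstruct the residue sub-alignment from an excerpt.

    Exact inverse of :func:`render_signature` over the excerpted window
    and selected rows.  A dash in the reference row, ragged rows, or a
    dash aligned with a reference gap are format errors.
    """
    ref = excerpt.rows[0]
    ref_residues = ref.encoded.replace(ENCODED_GAP, GAP)
    records = [SequenceRecord(ref.record_id, ref.genome_id, ref_residues)]
    for row in excerpt.rows[1:]:
        if len(row.encoded) != len(ref.encoded):
            raise ReportError(f"ragged row {row.record_id!r}")
        decoded = []
        for i, symbol in enumerate(row.encoded):
            if symbol == ENCODED_GAP:
                decoded.append(GAP)
            elif symbol == IDENTITY:
                if ref_residues[i] == GAP:
                    raise ReportError(
                        f"row {row.record_id!r}: identity dash over a "
                        f"reference gap at column {i + 1}")
                decoded.append(ref_residues[i])
            else:
                decoded.append(symbol)
        records.append(SequenceRecord(row.record_id, row.genome_id,
                                      "".join(decoded)))
    return Alignment(records, name="decoded_excerpt")


def excerpt_to_text(excerpt: SignatureExcerpt,
                    id_width: Optional[int] = None) -> str:
    """Human-readable layout: header, then one line per row with the
    record id, its window start position, and the encoded residues; a
    rule separates carriers from the comparison rows."""
    if id_width is None:
        id_width = max(len(r.record_id) for r in excerpt.rows) + 2
    pos_width = max(len(str(r.start_position)) for r in excerpt.rows)
    lines = [excerpt.header]
    for i, row in enumerate(excerpt.rows):
        if i == excerpt.n_ingroup:
            lines.append("-" * (id_width + pos_width + 2 + excerpt.width))
        lines.append(f"{row.record_id:<{id_width}}"
                     f"{row.start_position:>{pos_width}}  {row.encoded}")
    return "\n".join(lines) + "\n"


def excerpt_to_tsv(excerpt: SignatureExcerpt) -> str:
    """Machine-readable excerpt: one tab-separated line per row."""
    lines = [f"#header\t{excerpt.header}",
             f"#window\t{excerpt.col_start}\t{excerpt.col_end}",
             f"#n_ingroup\t{excerpt.n_ingroup}"]
    for row in excerpt.rows:
        lines.append(f"{row.record_id}\t{row.genome_id}\t"
                     f"{row.start_position}\t{row.encoded}")
    return "\n".join(lines) + "\n"
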