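"""Conserved signature protein (CSP) classification from homology hits.

A protein is a CSP for a clade when its significant database matches
(E-value below ``e_sig``, default 0.01) come exclusively from genomes of
that clade, and genomes outside the clade show at most weak similarity
(E-value above ``e_excl``, default 1.0).  Out-group hits falling in the
gray zone between the two thresholds disqualify the protein unless an
explicit tolerance (``max_gray_outgroup``) admits them.

Hit tables are 12-column tab-separated rows in the conventional tabular
output of protein homology searches (qseqid, sseqid, pident, length,
mismatch, gapopen, qstart, qend, sstart, send, evalue, bitscore), plus a
13th subject-genome column or a sidecar ``subject_id<TAB>genome_id``
mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .csi import CSIRecord
from .taxonomy import CladeTree, SpecificityResult, infer_specificity


class HitTableError(ValueError):
    """Malformed homology hit table."""


@dataclass
class HomologyHit:
    """One query-subject homology match."""

    query_id: str
    subject_id: str
    subject_genome: str
    e_value: float
    bit_score: Optional[float] = None
    coverage_frac: Optional[float] = None
    beyond_cap: bool = False  # past the per-query hit cap; kept, not classified

    def __post_init__(self) -> None:
        if not self.query_id or not self.subject_id:
            raise HitTableError("query_id and subject_id must be non-empty")
        if self.e_value < 0:
            raise HitTableError(f"negative E-value for {self.query_id!r}")


@dataclass(frozen=True)
class CSPConfig:
    """Thresholds of the E-value partition rule.

    ``e_sig`` bounds significance (a hit below it marks real homology);
    ``e_excl`` bounds exclusion (an out-group hit above it is noise).
    ``max_hits`` caps hits per query at read time, emulating the search
    interface's max-target-sequences setting.
    """

    e_sig: float = 0.01
    e_excl: float = 1.0
    max_hits: int = 500
    min_coverage: float = 0.75
    max_exceptions: int = 0
    max_gray_outgroup: int = 0

    def __post_init__(self) -> None:
        if not self.e_sig < self.e_excl:
            raise ValueError("need e_sig < e_excl")
        if self.max_hits < 1:
            raise ValueError("max_hits must be >= 1")


@dataclass
class CSPRecord:
    """Classification outcome for one query protein."""

    query_id: str
    status: str  # "csp" | "rejected"
    presence: frozenset[str]  # genomes with a hit below e_sig (plus self)
    disqualifiers: list[HomologyHit]
    specificity: SpecificityResult
    reasons: tuple[str, ...] = ()

    @property
    def accepted(self) -> bool:
        return self.status == "csp"


def read_hit_table(path, genome_map: Optional[Mapping[str, str]] = None,
                   max_hits: int = 500) -> dict[str, list[HomologyHit]]:
    """Parse a tabular hit file into per-query hit lists.

    Input order is preserved.  Each query's hits are capped at
    ``max_hits`` by ascending ``(e_value, subject_id)``; hits past the cap
    are retained but flagged ``beyond_cap`` so nothing is silently
    dropped.  Scientific-notation E-values (``3e-52``) parse exactly.
    """
    hits: dict[str, list[HomologyHit]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise HitTableError(
                    f"{path}:{lineno}: expected >= 12 tab-separated columns, "
                    f"got {len(cols)}")
            qseqid, sseqid = cols[0], cols[1]
            try:
                e_value = float(cols[10])
                bit_score = float(cols[11])
            except ValueError as exc:
                raise HitTableError(f"{path}:{lineno}: {exc}") from exc
            if len(cols) >= 13 and cols[12]:
                genome = cols[12]
            elif genome_map is not None and sseqid in genome_map:
                genome = genome_map[sseqid]
            else:
                raise HitTableError(
                    f"{path}:{lineno}: no genome attribution for subject "
                    f"{sseqid!r} (add a 13th column or a mapping file)")
            # optional 14th column: query coverage fraction
            coverage = None
            if len(cols) >= 14 and cols[13]:
                try:
                    coverage = float(cols[13])
                except ValueError as exc:
                    raise HitTableError(f"{path}:{lineno}: {exc}") from exc
            hits.setdefault(qseqid, []).append(HomologyHit(
                qseqid, sseqid, genome, e_value, bit_score, coverage))
    for query, lst in hits.items():
        if len(lst) > max_hits:
            order = sorted(range(len(lst)),
                           key=lambda i: (lst[i].e_value, lst[i].subject_id))
            for i in order[max_hits:]:
                lst[i].beyond_cap = True
    return hits


def classify_csp(query_id: str, hits: Sequence[HomologyHit], tree: CladeTree,
                 ingroup: str, config: CSPConfig = CSPConfig(),
                 query_genome: Optional[str] = None) -> CSPRecord:
    """Apply the E-value partition rule to one query's hits.

    Accepts (``status="csp"``) iff every significant hit (E < ``e_sig``)
    comes from an in-group genome, at most ``max_gray_outgroup`` out-group
    hits fall below ``e_excl``, and the resulting presence set defines a
    clade under the coverage/exception tolerances.  Every rejection
    carries machine-readable reasons and the disqualifying hits.  The
    query's own genome, when given, always counts as present (the self
    match is real even if the table omits it).  Order-invariant and
    deterministic.
    """
    in_genomes = tree.genomes_under(ingroup)
    active = [h for h in hits if not h.beyond_cap]
    for h in active:
        if h.query_id != query_id:
            raise ValueError(f"hit for {h.query_id!r} passed to classify_csp "
                             f"of {query_id!r}")
    significant = [h for h in active if h.e_value < config.e_sig]
    presence = {h.subject_genome for h in significant}
    if query_genome is not None:
        presence.add(query_genome)
    out_significant = [h for h in significant
                       if h.subject_genome not in in_genomes]
    gray_outgroup = [h for h in active
                     if h.subject_genome not in in_genomes
                     and config.e_sig <= h.e_value < config.e_excl]

    reasons: list[str] = []
    disqualifiers: list[HomologyHit] = []
    if not significant and query_genome is None:
        reasons.append("no_significant_hits")
    if out_significant:
        reasons.append("outgroup_significant_hit")
        disqualifiers.extend(out_significant)
    if len(gray_outgroup) > config.max_gray_outgroup:
        reasons.append("outgroup_gray_zone_hits")
        disqualifiers.extend(gray_outgroup)

    if presence and not reasons:
        spec = infer_specificity(presence, tree,
                                 min_coverage=config.min_coverage,
                                 max_exceptions=config.max_exceptions)
        if spec.clade is None:
            reasons.append("no_qualifying_clade")
    else:  # already rejected (or nothing present): skip the clade scan
        spec = SpecificityResult(None, 0.0, frozenset())

    disqualifiers.sort(key=lambda h: (h.e_value, h.subject_id))
    status = "csp" if not reasons else "rejected"
    return CSPRecord(query_id=query_id, status=status,
                     presence=frozenset(presence),
                     disqualifiers=disqualifiers,
                     specificity=spec, reasons=tuple(reasons))


def classify_all(hits_by_query: Mapping[str, Sequence[HomologyHit]],
                 tree: CladeTree, ingroup: str,
                 config: CSPConfig = CSPConfig(),
                 query_genomes: Optional[Mapping[str, str]] = None
                 ) -> list[CSPRecord]:
    """Classify every query of a hit table, preserving query order."""
    return [classify_csp(q, hits_by_query[q], tree, ingroup, config,
                         None if query_genomes is None
                         else query_genomes.get(q))
            for q in hits_by_query]


def summarize_specificity(records: Iterable[Union[CSPRecord, CSIRecord]],
                          tree: CladeTree) -> pd.DataFrame:
    """Count accepted markers per specificity clade.

    CSP records contribute only when accepted; CSI records are already
    filtered by the scan.  Rows follow the tree's preorder so broader taxa
    come first; the counts partition the accepted records (total
    preserved).
    """
    counts: dict[str, int] = {}
    for rec in records:
        if isinstance(rec, CSPRecord) and not rec.accepted:
            continue
        clade = rec.specificity.clade
        if clade is None:
            continue
        counts[clade] = counts.get(clade, 0) + 1
    order = [c for c in tree.clades() if c in counts]
    extra = sorted(set(counts) - set(order))  # clades outside this tree
    return pd.DataFrame({"clade": order + extra,
                         "n_markers": [counts[c] for c in order + extra]})


def write_csp_table(records: Sequence[CSPRecord], path) -> None:
    """Write classification results as a tab-separated table."""
    with open(path, "w") as fh:
        fh.write("query_id\tstatus\tspecificity\tcoverage\tpresence\t"
                 "reasons\tdisqualifiers\n")
        for rec in records:
            disq = ",".join(f"{h.subject_id}@{h.e_value:g}"
                            for h in rec.disqualifiers)
            fh.write("\t".join([
                rec.query_id, rec.status,
                rec.specificity.clade or "none",
                f"{rec.specificity.coverage:.3f}",
                ",".join(sorted(rec.presence)),
                ",".join(rec.reasons), disq]) + "\n")
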