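"""Independent brute-force oracles used to cross-check the implementation.

Each function here evaluates the defining predicate of an operation by
exhaustive enumeration, deliberately sharing no code with the scanning /
classification routines it checks.
"""

from __future__ import annotations

from sigmark.alignments import GAP, Alignment


def brute_force_candidate_blocks(alignment: Alignment, ingroup: set[str],
                                 min_indel_len: int = 1,
                                 max_indel_len: int = 30) -> list[tuple]:
    """Enumerate every column interval and keep the maximal group-specific
    blocks: (col_start, col_end, indel_type) sorted like the scanner."""
    rows = {r.record_id: r.residues for r in alignment.records}
    in_ids = [r.record_id for r in alignment.records if r.genome_id in ingroup]
    out_ids = [r.record_id for r in alignment.records
               if r.genome_id not in ingroup]
    n = alignment.n_cols

    def has_gap(col):  # some record gapped at 1-based column col
        return any(rows[i][col - 1] == GAP for i in rows)

    def count(rid, a, b):
        seg = rows[rid][a - 1:b]
        return len(seg) - seg.count(GAP)

    found = []
    for a in range(1, n + 1):
        for b in range(a, n + 1):
            # the indel locus: every column gap-containing, maximal
            if not all(has_gap(c) for c in range(a, b + 1)):
                continue
            if (a > 1 and has_gap(a - 1)) or (b < n and has_gap(b + 1)):
                continue
            in_counts = [count(i, a, b) for i in in_ids]
            out_counts = [count(i, a, b) for i in out_ids]
            if (all(c == 0 for c in out_counts)
                    and all(min_indel_len <= c <= max_indel_len
                            for c in in_counts)):
                found.append((a, b, "insertion"))
            elif (all(c == 0 for c in in_counts)
                  and len(set(out_counts)) == 1
                  and min_indel_len <= out_counts[0] <= max_indel_len):
                found.append((a, b, "deletion"))
    return sorted(set(found), key=lambda t: (t[0], t[2]))


def brute_force_specificity(presence: set[str], tree, min_coverage: float,
                            max_exceptions: int):
    """Evaluate the qualifying predicate over every clade and pick the
    smallest, mirroring the documented tie-break."""
    qualifying = []
    for clade in tree.clades():
        members = tree.genomes_under(clade)
        if not members:
            continue
        coverage = len(presence & members) / len(members)
        external = presence - members
        if coverage >= min_coverage and len(external) <= max_exceptions:
            qualifying.append((len(members), -tree.depth(clade), clade))
    if not qualifying:
        return None
    return min(qualifying)[2]


def brute_force_prefix_position(residues: str, column: int):
    """Ungapped position by direct prefix scan (1-based), or None on gap."""
    if residues[column - 1] == GAP:
        return None
    return sum(1 for c in residues[:column] if c != GAP)
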