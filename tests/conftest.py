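"""Shared fixtures: a small labelled taxonomy, hand-built alignments with a
planted clade-specific indel, and a random-alignment generator."""

from __future__ import annotations

import numpy as np
import pytest

from sigmark.alignments import AMINO_ACIDS, Alignment, SequenceRecord
from sigmark.simulate import default_benchmark_tree
from sigmark.taxonomy import build_clade_tree


@pytest.fixture(scope="session")
def tree():
    """12 in-group (CladeA: FamA1+FamA2) + 12 out-group (CladeB) genomes."""
    return default_benchmark_tree()


@pytest.fixture(scope="session")
def small_tree():
    """Hand-enumerable 3-level tree over 6 genomes."""
    return build_clade_tree([
        ("g1", ["root", "left", "leafA"]),
        ("g2", ["root", "left", "leafA"]),
        ("g3", ["root", "left", "leafB"]),
        ("g4", ["root", "right", "leafC"]),
        ("g5", ["root", "right", "leafC"]),
        ("g6", ["root", "right", "leafD"]),
    ])


def make_toy_alignment(block_rows: dict[str, str], left: str, right: str,
                       genome_of=None) -> Alignment:
    """Build an alignment from a shared left flank, per-record block
    content, and a shared right flank."""
    records = []
    for rid, block in block_rows.items():
        genome = genome_of[rid] if genome_of else rid
        records.append(SequenceRecord(rid, genome, left + block + right))
    return Alignment(records, name="toy")


@pytest.fixture
def toy_insertion_alignment():
    """6 records; 4-column insertion block carried by the 3 in-group
    records (a1..a3) and all-gap in the 3 out-group records (b1..b3),
    between 10-column perfectly conserved flanks."""
    left = "MKLVAEQRST"
    right = "WYHGFDNCIP"
    rows = {
        "a1": "GGGG", "a2": "GGGG", "a3": "GGGG",
        "b1": "----", "b2": "----", "b3": "----",
    }
    return make_toy_alignment(rows, left, right)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240101)


def random_gapped_alignment(rng, n_records: int, n_cols: int,
                            gap_prob: float = 0.25) -> Alignment:
    """Random residues with i.i.d. gaps; at least one residue per record."""
    aa = np.array(list(AMINO_ACIDS))
    records = []
    for i in range(n_records):
        symbols = aa[rng.integers(0, 20, size=n_cols)]
        gaps = rng.random(n_cols) < gap_prob
        if gaps.all():
            gaps[int(rng.integers(0, n_cols))] = False
        residues = "".join("-" if g else s for s, g in zip(symbols, gaps))
        records.append(SequenceRecord(f"r{i}", f"g{i}", residues))
    return Alignment(records, name="random")
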