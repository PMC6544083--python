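"""Signature-indel scanning: candidate detection, flank filter, calling,
fragment extraction and presence checking."""

import numpy as np
import pytest

from sigmark.alignments import Alignment, SequenceRecord
from sigmark.csi import (ABSENT, MISSING, PRESENT, CSIRecord, ScanConfig,
                         ScanConfigError, call_csis, check_presence,
                         extract_indel_fragment, find_candidate_blocks,
                         score_flanks)
from sigmark.simulate import benchmark_families

from conftest import random_gapped_alignment
from oracles import brute_force_candidate_blocks

INGROUP3 = {"a1", "a2", "a3"}


class TestFindCandidateBlocks:
    def test_planted_insertion_block_found(self, toy_insertion_alignment):
        blocks = find_candidate_blocks(toy_insertion_alignment, INGROUP3)
        assert len(blocks) == 1
        (b,) = blocks
        assert (b.col_start, b.col_end, b.indel_type) == (11, 14, "insertion")
        assert [b.per_record_len[r] for r in ("a1", "a2", "a3")] == [4, 4, 4]

    def test_outgroup_residue_kills_specificity(self):
        left, right = "MKLVAEQRST", "WYHGFDNCIP"
        rows = {"a1": "GGGG", "a2": "GGGG", "a3": "GGGG",
                "b1": "G---", "b2": "----", "b3": "----"}
        aln = Alignment([SequenceRecord(r, r, left + s + right)
                         for r, s in rows.items()])
        assert find_candidate_blocks(aln, INGROUP3) == []

    def test_deletion_block_with_uniform_size(self):
        left, right = "MKLVAEQRST", "WYHGFDNCIP"
        rows = {"a1": "---", "a2": "---", "a3": "---",
                "b1": "GGG", "b2": "GGG", "b3": "GGG"}
        aln = Alignment([SequenceRecord(r, r, left + s + right)
                         for r, s in rows.items()])
        (b,) = find_candidate_blocks(aln, INGROUP3)
        assert b.indel_type == "deletion"
        assert b.per_record_len["b1"] == 3

    def test_nonuniform_deletion_rejected(self):
        left, right = "MKLVAEQRST", "WYHGFDNCIP"
        rows = {"a1": "---", "a2": "---", "a3": "---",
                "b1": "GGG", "b2": "GG-", "b3": "GGG"}
        aln = Alignment([SequenceRecord(r, r, left + s + right)
                         for r, s in rows.items()])
        assert find_candidate_blocks(aln, INGROUP3) == []

    def test_group_size_minimums_enforced(self, toy_insertion_alignment):
        with pytest.raises(ScanConfigError):
            find_candidate_blocks(toy_insertion_alignment, {"a1"})

    def test_equals_brute_force_oracle_on_random_alignments(self, rng):
        """Scanner output equals exhaustive interval enumeration filtered
        by the group-specific gap-pattern predicate."""
        for trial in range(100):
            n = int(rng.integers(4, 13))
            aln = random_gapped_alignment(rng, n, int(rng.integers(10, 121)))
            ingroup = {f"g{i}" for i in range(n // 2)}
            config = ScanConfig(min_ingroup=2, min_outgroup=2)
            got = [(b.col_start, b.col_end, b.indel_type)
                   for b in find_candidate_blocks(aln, ingroup, config)]
            want = brute_force_candidate_blocks(aln, ingroup)
            assert got == want, f"trial {trial}"


class TestScoreFlanks:
    def test_fully_conserved_flanks_count_full_window(self, tree):
        aln, truth = next(benchmark_families(1, 11, tree, sub_prob=0.0))
        (block,) = find_candidate_blocks(aln, tree.genomes_under("CladeA"))
        assert score_flanks(aln, block) == (40, 40)

    def test_gap_or_x_column_never_conserved(self, toy_insertion_alignment):
        aln = toy_insertion_alignment
        (block,) = find_candidate_blocks(aln, INGROUP3)
        base_l, base_r = score_flanks(aln, block,
                                      ScanConfig(window_len=10))
        assert (base_l, base_r) == (10, 10)
        # poke a gap into one flank column of one record
        recs = [SequenceRecord(r.record_id, r.genome_id,
                               ("-" + r.residues[1:]) if r.record_id == "a1"
                               else r.residues)
                for r in aln.records]
        poked = Alignment(recs)
        assert score_flanks(poked, block, ScanConfig(window_len=10)) == (9, 10)

    def test_similarity_class_column_counts_as_conserved(self):
        # column of {M, I, L, V} is conserved under the strong classes
        left_a, left_b = "MKLVAEQRSM", "MKLVAEQRSI"
        right = "WYHGFDNCIP"
        rows = [SequenceRecord("a1", "a1", left_a + "GGGG" + right),
                SequenceRecord("a2", "a2", left_b + "GGGG" + right),
                SequenceRecord("b1", "b1", left_a + "----" + right),
                SequenceRecord("b2", "b2", left_b + "----" + right)]
        aln = Alignment(rows)
        (block,) = find_candidate_blocks(aln, {"a1", "a2"})
        assert score_flanks(aln, block, ScanConfig(window_len=10)) == (10, 10)

    def test_counts_match_per_column_recount(self, rng, tree):
        from sigmark.alignments import is_conserved_column
        aln, _ = next(benchmark_families(1, 17, tree, sub_prob=0.2,
                                         flank_protect=5))
        blocks = find_candidate_blocks(aln, tree.genomes_under("CladeA"))
        cfg = ScanConfig()
        for b in blocks:
            fl, fr = score_flanks(aln, b, cfg)
            manual_l = sum(is_conserved_column(aln.column(c))
                           for c in range(max(1, b.col_start - 40),
                                          b.col_start))
            manual_r = sum(is_conserved_column(aln.column(c))
                           for c in range(b.col_end + 1,
                                          min(aln.n_cols, b.col_end + 40) + 1))
            assert (fl, fr) == (manual_l, manual_r)


class TestCallCsis:
    def test_planted_insertion_called_with_full_flanks(self, tree):
        aln, truth = next(benchmark_families(1, 3, tree, sub_prob=0.0))
        (csi,) = call_csis(aln, tree.genomes_under("CladeA"), tree=tree)
        assert csi.indel_type == truth.indel_type
        assert (csi.col_start, csi.col_end) == (truth.col_start, truth.col_end)
        assert (csi.size_min, csi.size_max) == (truth.size_min, truth.size_max)
        assert csi.flank_left == csi.flank_right == 40
        assert csi.specificity.clade == "CladeA"

    def test_weak_flank_filtered_out(self, toy_insertion_alignment):
        # flanks are only 10 columns long; demand more conserved columns
        # than the flank can offer and the candidate must be dropped
        cfg = ScanConfig(window_len=12, min_conserved=11)
        assert call_csis(toy_insertion_alignment, INGROUP3, cfg) == []

    def test_raising_min_conserved_never_adds_calls(self, tree):
        aln, _ = next(benchmark_families(1, 5, tree, sub_prob=0.1,
                                         flank_protect=10))
        counts = []
        for mc in range(0, 41, 5):
            cfg = ScanConfig(min_conserved=mc)
            counts.append(len(call_csis(aln, tree.genomes_under("CladeA"),
                                        cfg, tree=tree)))
        assert counts == sorted(counts, reverse=True)

    def test_reference_must_be_ingroup(self, toy_insertion_alignment):
        with pytest.raises(ValueError, match="not in-group"):
            call_csis(toy_insertion_alignment, INGROUP3, reference_id="b1")

    def test_ref_span_in_ungapped_reference_coordinates(self, tree):
        aln, truth = next(benchmark_families(1, 9, tree))
        (csi,) = call_csis(aln, tree.genomes_under("CladeA"), tree=tree)
        ref = aln.get(csi.reference_id)
        if csi.indel_type == "insertion":
            # the span's residues are exactly the block content
            block = ref.residues[csi.col_start - 1:csi.col_end]
            inner = block.replace("-", "")
            s, e = csi.ref_span
            assert ref.ungapped[s - 1:e] == inner
        else:
            s, e = csi.ref_span
            assert e - s <= 1


class TestCheckPresence:
    def test_matching_count_is_present(self, toy_insertion_alignment, tree):
        csis = call_csis(toy_insertion_alignment, INGROUP3,
                         ScanConfig(window_len=10, min_conserved=5))
        (csi,) = csis
        status = check_presence(toy_insertion_alignment, csi)
        assert all(status[r] == PRESENT for r in ("a1", "a2", "a3"))
        assert all(status[r] == ABSENT for r in ("b1", "b2", "b3"))

    def test_truncated_homolog_is_missing_data(self, toy_insertion_alignment):
        (csi,) = call_csis(toy_insertion_alignment, INGROUP3,
                           ScanConfig(window_len=10, min_conserved=5))
        n = toy_insertion_alignment.n_cols
        extended = Alignment(
            toy_insertion_alignment.records
            + [SequenceRecord("trunc", "trunc", "-" * n)])
        status = check_presence(extended, csi, window_len=10)
        assert status["trunc"] == MISSING

    def test_hand_labeled_block_counts(self):
        """20 constructed records labelled by hand against the rule:
        count within size range -> present; otherwise absent; no data
        across block and windows -> missing."""
        left, right = "MKLVAEQRST", "WYHGFDNCIP"
        cases = []
        for i in range(20):
            k = i % 5  # residues inside the 4-column block
            block = "G" * k + "-" * (4 - k)
            cases.append((f"r{i:02d}", block))
        rows = ([SequenceRecord(r, r, left + b + right) for r, b in cases]
                + [SequenceRecord("gone", "gone", "-" * 24)])
        aln = Alignment(rows)
        csi = CSIRecord("m", "r04", "insertion", 3, 4, 11, 14, (11, 14),
                        10, 10, {}, None)
        status = check_presence(aln, csi, window_len=10)
        for r, b in cases:
            k = len(b.replace("-", ""))
            assert status[r] == (PRESENT if 3 <= k <= 4 else ABSENT)
        assert status["gone"] == MISSING

    def test_reproduces_call_time_presence(self, tree):
        for aln, _ in benchmark_families(5, 23, tree):
            (csi,) = call_csis(aln, tree.genomes_under("CladeA"), tree=tree)
            status = check_presence(aln, csi)
            by_genome = {aln.get(r).genome_id: s for r, s in status.items()}
            assert by_genome == csi.presence


class TestExtractFragment:
    def _make_record_with_csi(self, indel_span, length, target=80):
        residues = "ACDEFGHIKLMNPQRSTVWY" * (length // 20 + 1)
        rec = SequenceRecord("r", "g", residues[:length])
        s, e = indel_span
        csi = CSIRecord("m", "r", "insertion", e - s + 1, e - s + 1,
                        s, e, (s, e), 40, 40, {}, None)
        return rec, csi

    def test_centering_arithmetic(self):
        # indel at ungapped 50-53 of a 200 aa gapless protein, target 80:
        # centred window is positions 12-91
        rec, csi = self._make_record_with_csi((50, 53), 200)
        frag = extract_indel_fragment(rec, csi, 80)
        assert frag == rec.ungapped[11:91]
        assert len(frag) == 80

    def test_clipped_at_n_terminus(self):
        rec, csi = self._make_record_with_csi((2, 5), 200)
        frag = extract_indel_fragment(rec, csi, 80)
        assert frag == rec.ungapped[:80]

    def test_short_protein_returned_whole_with_warning(self):
        rec, csi = self._make_record_with_csi((10, 13), 50)
        with pytest.warns(UserWarning, match="whole sequence"):
            frag = extract_indel_fragment(rec, csi, 80)
        assert frag == rec.ungapped

    def test_absent_record_refused(self, toy_insertion_alignment):
        (csi,) = call_csis(toy_insertion_alignment, INGROUP3,
                           ScanConfig(window_len=10, min_conserved=5))
        with pytest.raises(ValueError, match="does not carry"):
            extract_indel_fragment(toy_insertion_alignment.get("b1"), csi)

    def test_target_len_bounds(self):
        rec, csi = self._make_record_with_csi((50, 53), 200)
        with pytest.raises(ValueError):
            extract_indel_fragment(rec, csi, 50)
        with pytest.raises(ValueError):
            extract_indel_fragment(rec, csi, 120)

    def test_fragment_contains_indel_across_benchmark(self, tree):
        for aln, truth in benchmark_families(10, 41, tree):
            (csi,) = call_csis(aln, tree.genomes_under("CladeA"), tree=tree)
            ref = aln.get(csi.reference_id)
            frag = extract_indel_fragment(ref, csi)
            assert len(frag) == 80
            assert frag in ref.ungapped
            if csi.indel_type == "insertion":
                s, e = csi.ref_span
                assert ref.ungapped.index(frag) + 1 <= s
                assert ref.ungapped.index(frag) + len(frag) >= e
            # determinism
            assert frag == extract_indel_fragment(ref, csi)
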