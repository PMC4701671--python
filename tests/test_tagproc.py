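"""Demultiplexing, trimming grammar, mapping and tail extraction."""


import numpy as np
import pytest

import patseq as ps
from patseq.sequtil import revcomp
from patseq.tagproc import (GenomeIndex, MapReason, MapRejection, PolyATag,
                            TagAlignment, TrimReason, TrimRejection,
                            demultiplex, extract_tail, map_tag,
                            reduce_to_site, trim_tag)

BCS = {"lib1": "ACGTAC", "lib2": "TTGGCA"}


class TestDemultiplex:
    def test_exact_prefix_assigned_and_stripped(self):
        reads = [("r1", "ACGTAC" + "T" * 30, "I" * 36)]
        by_lib, unassigned = demultiplex(reads, BCS)
        assert unassigned == 0
        rid, seq, qual = by_lib["lib1"][0]
        assert seq == "T" * 30 and len(qual) == 30

    def test_empty_stream(self):
        by_lib, unassigned = demultiplex([], BCS)
        assert unassigned == 0
        assert all(len(v) == 0 for v in by_lib.values())

    def test_mismatched_prefix_unassigned_and_counts_conserve(self):
        reads = [("r1", "GGGGGG" + "T" * 30, "I" * 36),
                 ("r2", "ACGTAC" + "T" * 30, "I" * 36)]
        by_lib, unassigned = demultiplex(reads, BCS)
        assert unassigned == 1
        assert sum(map(len, by_lib.values())) + unassigned == len(reads)

    def test_ambiguous_within_tolerance_is_unassigned(self):
        barcodes = {"a": "AAAAAA", "b": "AAAAAT"}
        reads = [("r1", "AAAAAC" + "T" * 30, "I" * 36)]  # 1 mm from both
        by_lib, unassigned = demultiplex(reads, barcodes, max_bc_mismatch=1)
        assert unassigned == 1

    def test_one_mismatch_rescued_when_unique(self):
        reads = [("r1", "ACGTAG" + "T" * 30, "I" * 36)]
        by_lib, unassigned = demultiplex(reads, BCS, max_bc_mismatch=1)
        assert len(by_lib["lib1"]) == 1 and unassigned == 0


class TestTrim:
    def test_plain_tract_stripped(self):
        s = "ACGCGGTGCAATGCAGGCATCGCAGCGATA"
        tag = trim_tag("T" * 10 + s)
        assert isinstance(tag, PolyATag)
        assert tag.sequence == s
        assert tag.t_tract_length == 10
        assert tag.tail_non_t_positions == ()

    def test_isolated_interruption_absorbed_and_recorded(self):
        s = "ACGCGGTGCAATGCAGGCATCGCAGCGATA"
        tag = trim_tag("TTTTATTTTT" + s)
        assert tag.t_tract_length == 10
        assert tag.tail_non_t_positions == ((4, "A"),)

    def test_interruption_requires_three_t_flanks(self):
        s = "ACGCGGTGCAATGCAGGCATCGCAGCGATA"
        # second non-T only 2 T after the first: tract stops at first non-T
        tag = trim_tag("TTTTATTATTTT" + s, min_t_tract=4, min_tag_length=5)
        assert tag.t_tract_length == 4
        assert tag.sequence.startswith("ATTAT")

    def test_short_tract_rejected(self):
        s = "ACGCGGTGCAATGCAGGCATCGCAGCGATA"
        rej = trim_tag("TTTTT" + s)
        assert isinstance(rej, TrimRejection)
        assert rej.reason is TrimReason.NO_T_TRACT

    def test_all_t_read_rejected_too_short(self):
        rej = trim_tag("T" * 15)
        assert isinstance(rej, TrimRejection)
        assert rej.reason is TrimReason.TOO_SHORT

    def test_adapter_suffix_removed(self):
        s = "ACGCGGTGCAATGCAGGCATCGCAGCGATA"
        read = "T" * 12 + s + ps.DEFAULT_ADAPTER[:9]
        tag = trim_tag(read)
        assert tag.sequence == s

    def test_adapter_only_insert_rejected(self):
        rej = trim_tag("T" * 12 + ps.DEFAULT_ADAPTER)
        assert isinstance(rej, TrimRejection)
        assert rej.reason is TrimReason.ADAPTER_ONLY


@pytest.fixture(scope="module")
def toy_genome():
    rng = np.random.default_rng(99)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 3000))
    return {"c1": seq}


@pytest.fixture(scope="module")
def toy_index(toy_genome):
    return GenomeIndex(toy_genome)


class TestMap:
    def test_unique_forward_match_site_on_minus_mrna(self, toy_genome, toy_index):
        # tag equal to the + strand at [100,130): tag_strand '+', mRNA '-'
        tag = toy_genome["c1"][100:130]
        aln = map_tag(tag, toy_index)
        assert isinstance(aln, TagAlignment)
        assert (aln.tag_strand, aln.mrna_strand) == ("+", "-")
        assert (aln.start, aln.end) == (100, 130)
        assert reduce_to_site(aln) == ("c1", "-", 100)

    def test_revcomp_match_site_on_plus_mrna(self, toy_genome, toy_index):
        tag = revcomp(toy_genome["c1"][100:130])
        aln = map_tag(tag, toy_index)
        assert (aln.tag_strand, aln.mrna_strand) == ("-", "+")
        assert reduce_to_site(aln) == ("c1", "+", 129)

    def test_duplicated_locus_multimapped(self, toy_genome):
        seq = toy_genome["c1"]
        dup = {"c1": seq + "N" * 10 + seq[100:160]}
        idx = GenomeIndex(dup)
        out = map_tag(seq[110:140], idx)
        assert isinstance(out, MapRejection)
        assert out.reason is MapReason.MULTIMAPPED

    def test_unmappable_tag(self, toy_index):
        out = map_tag("A" * 30, toy_index, max_mismatches=0)
        assert isinstance(out, MapRejection)
        assert out.reason is MapReason.UNMAPPED

    def test_nonmatching_prefix_clipped(self, toy_genome, toy_index):
        seq = toy_genome["c1"]
        # pick a locus not followed by T so the clip length is unambiguous
        start = next(i for i in range(100, 500) if seq[i + 30] != "T")
        tag = "AAAA" + revcomp(seq[start:start + 30])
        aln = map_tag(tag, toy_index, max_clip5=6)
        assert isinstance(aln, TagAlignment)
        assert aln.clip5_sequence == "AAAA"
        assert reduce_to_site(aln) == ("c1", "+", start + 29)

    def test_one_mismatch_tolerated_and_counted(self, toy_genome, toy_index):
        tag = list(toy_genome["c1"][200:232])
        tag[15] = {"A": "C", "C": "A", "G": "T", "T": "G"}[tag[15]]
        aln = map_tag("".join(tag), toy_index, max_mismatches=1)
        assert isinstance(aln, TagAlignment)
        assert aln.mismatches == 1 and aln.start == 200

    def test_mapping_is_order_invariant(self, toy_genome, toy_index):
        tags = [toy_genome["c1"][i:i + 30] for i in range(100, 400, 30)]
        fwd = [map_tag(t, toy_index) for t in tags]
        rev = [map_tag(t, toy_index) for t in reversed(tags)][::-1]
        assert [(a.start, a.end) for a in fwd] == [(a.start, a.end) for a in rev]


class TestReduceAndTail:
    def test_reduction_coordinates_both_strands(self):
        plus = TagAlignment("c", "-", "+", 100, 130, 129, 0, "")
        minus = TagAlignment("c", "+", "-", 100, 130, 100, 0, "")
        assert reduce_to_site(plus) == ("c", "+", 129)
        assert reduce_to_site(minus) == ("c", "-", 100)

    def test_plain_tract_tail(self):
        tag = PolyATag("X" * 30, t_tract_length=12)
        aln = TagAlignment("c", "+", "-", 0, 30, 0, 0, "")
        rec = extract_tail(tag, aln)
        assert (rec.tail_length, rec.non_a_count, rec.heteropolymeric) == (12, 0, False)

    def test_interrupted_tract_plus_t_rich_clip(self):
        tag = PolyATag("X" * 30, t_tract_length=10,
                       tail_non_t_positions=((4, "C"),))
        aln = TagAlignment("c", "+", "-", 0, 30, 0, 0, "TTCT")
        rec = extract_tail(tag, aln)
        assert (rec.tail_length, rec.non_a_count) == (14, 2)
        assert rec.heteropolymeric and not rec.clip_excluded

    def test_low_t_clip_excluded(self):
        tag = PolyATag("X" * 30, t_tract_length=12)
        aln = TagAlignment("c", "+", "-", 0, 30, 0, 0, "GGGG")
        rec = extract_tail(tag, aln)
        assert rec.tail_length == 12 and rec.clip_excluded
        assert not rec.heteropolymeric


class TestSamRoundTrip:
    def test_alignments_survive_sam_round_trip(self, toy_genome, toy_index, tmp_path):
        tags, alns = [], []
        for i, start in enumerate((100, 200, 300)):
            seq = toy_genome["c1"][start:start + 30]
            if i == 1:
                seq = revcomp(seq)
            if i == 2:
                seq = "AAAA" + seq
            tag = PolyATag(seq, t_tract_length=10, read_id=f"r{i}")
            aln = map_tag(tag, toy_index, max_clip5=6)
            assert isinstance(aln, TagAlignment)
            aln.read_id = f"r{i}"
            tags.append(tag)
            alns.append(aln)
        path = str(tmp_path / "tags.sam")
        ps.write_sam(path, zip(tags, alns), toy_genome)
        back = list(ps.read_sam(path))
        assert len(back) == 3
        for orig, rt in zip(alns, back):
            assert (rt.contig, rt.tag_strand, rt.start, rt.end) == \
                (orig.contig, orig.tag_strand, orig.start, orig.end)
            assert rt.site_position == orig.site_position
            assert rt.clip5_sequence == orig.clip5_sequence


class TestTrimProperties:
    """Grammar invariants on arbitrary reads."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(st.text(alphabet="ACGT", min_size=0, max_size=80))
    @settings(derandomize=True, max_examples=200)
    def test_trim_partitions_the_read(self, seq):
        out = trim_tag(seq, adapter="")
        if isinstance(out, PolyATag):
            assert seq == seq[:out.t_tract_length] + out.sequence
            tract = seq[:out.t_tract_length]
            assert all(tract[o] == b for o, b in out.tail_non_t_positions)
            non_t = [i for i, c in enumerate(tract) if c != "T"]
            assert non_t == [o for o, _ in out.tail_non_t_positions]
            assert out.t_tract_length >= 8 and len(out.sequence) >= 20
        else:
            assert out.reason in (TrimReason.NO_T_TRACT, TrimReason.TOO_SHORT)

    @given(st.integers(8, 30), st.text(alphabet="ACG", min_size=20, max_size=40))
    @settings(derandomize=True, max_examples=100)
    def test_pure_tract_fully_removed(self, tract_len, tag):
        out = trim_tag("T" * tract_len + tag, adapter="")
        assert isinstance(out, PolyATag)
        assert out.t_tract_length == tract_len
        assert out.sequence == tag
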