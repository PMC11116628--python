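"""Signature extraction: CIGAR walking, gap merging, split-read Distance."""

from __future__ import annotations

import random

import pytest
from hypothesis import given, settings, strategies as st

from delclust import (
    ExtractionConfig,
    SplitSegment,
    collect_signatures,
    extract_cigar_signatures,
    extract_split_signatures,
    merge_intra_read,
    read_alignments,
)
from delclust.signatures import AlignmentRecord, split_segment_from_record

from conftest import sig, write_sam

CFG = ExtractionConfig()


def rec(cigar, ref_start=0, mapq=60, orient="+", name="r1", chrom="chr1"):
    ops = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            ops.append((ch, int(num)))
            num = ""
    return AlignmentRecord(
        read_name=name, chrom=chrom, ref_start=ref_start, mapq=mapq,
        cigar=tuple(ops), orient=orient,
    )


class TestCigarExtraction:
    @pytest.mark.parametrize(
        "cigar,ref_start,expected",
        [
            # deletion start = ref_start + reference consumed before the D
            ("100M50D100M", 1000, [(1100, 50, 1150)]),
            # 20D does not exceed the strict >30 threshold
            ("100M20D100M", 1000, []),
            # soft clip consumes no reference; two qualifying D runs
            ("10S50M40D50M60D50M", 0, [(50, 40, 90), (140, 60, 200)]),
        ],
    )
    def test_reference_walk(self, cigar, ref_start, expected):
        got = extract_cigar_signatures(rec(cigar, ref_start), CFG)
        assert [(s.start, s.svlen, s.end) for s in got] == expected
        assert all(s.source == "cigar" for s in got)

    def test_boundary_is_strict(self):
        assert extract_cigar_signatures(rec("10M30D10M"), CFG) == []
        assert len(extract_cigar_signatures(rec("10M31D10M"), CFG)) == 1

    def test_skip_op_consumes_reference_but_is_not_a_deletion(self):
        got = extract_cigar_signatures(rec("10M100N10M40D10M"), CFG)
        assert [(s.start, s.svlen) for s in got] == [(120, 40)]

    def test_unknown_op_skips_record(self, caplog):
        bad = AlignmentRecord(
            read_name="r1", chrom="chr1", ref_start=0, mapq=60,
            cigar=(("M", 10), ("Q", 5)), orient="+",
        )
        with caplog.at_level("WARNING", logger="delclust"):
            assert extract_cigar_signatures(bad, CFG) == []
        assert "unknown CIGAR op" in caplog.text

    def test_lower_min_del_never_loses_signatures(self):
        r = rec("50M35D50M31D50M100D50M")
        strict = extract_cigar_signatures(r, ExtractionConfig(min_cigar_del=40))
        loose = extract_cigar_signatures(r, ExtractionConfig(min_cigar_del=30))
        assert len(loose) >= len(strict)
        assert {(s.start, s.svlen) for s in strict} <= {(s.start, s.svlen) for s in loose}


class TestMergeIntraRead:
    @pytest.mark.parametrize(
        "pairs,expected",
        [
            # gap 20: merged end is the second end, gap bases not in svlen
            ([(100, 50, 150), (170, 40, 210)], [(100, 90, 210)]),
            # gap 0 excluded by strict inequality
            ([(100, 50, 150), (150, 40, 190)], [(100, 50, 150), (150, 40, 190)]),
            # gap 31 exceeds the threshold
            ([(100, 50, 150), (181, 40, 221)], [(100, 50, 150), (181, 40, 221)]),
            # cascade: merged signature immediately merges with the next
            ([(100, 50, 150), (170, 40, 210), (230, 60, 290)], [(100, 150, 290)]),
        ],
    )
    def test_merge_rule(self, pairs, expected):
        sigs = [sig(s, l, e) for s, l, e in pairs]
        got = merge_intra_read(sigs, CFG)
        assert [(s.start, s.svlen, s.end) for s in got] == expected

    def test_overlapping_signatures_kept_apart(self):
        sigs = [sig(100, 50, 150), sig(140, 40, 180)]
        assert merge_intra_read(sigs, CFG) == sigs

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            merge_intra_read([sig(200, 40), sig(100, 50)], CFG)

    @given(
        st.lists(
            st.tuples(st.integers(0, 5000), st.integers(31, 500), st.integers(0, 40)),
            max_size=8,
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_idempotent(self, triples):
        """Applying the merge twice equals applying it once."""
        sigs = []
        pos = 0
        for gap_before, svlen, _ in triples:
            start = pos + gap_before
            sigs.append(sig(start, svlen))
            pos = start + svlen
        once = merge_intra_read(sigs, CFG)
        assert merge_intra_read(once, CFG) == once

    @given(st.lists(st.tuples(st.integers(31, 300), st.integers(1, 60)), max_size=8))
    @settings(max_examples=200, deadline=None)
    def test_total_deleted_length_conserved(self, runs):
        """Merging reorganises but never changes the summed svlen."""
        sigs = []
        pos = 100
        for svlen, gap in runs:
            sigs.append(sig(pos, svlen))
            pos += svlen + gap
        merged = merge_intra_read(sigs, CFG)
        assert sum(s.svlen for s in merged) == sum(s.svlen for s in sigs)


class TestSplitSignatures:
    def seg(self, chrom, rs, re_, qs, qe, orient, read="r1"):
        return SplitSegment(
            chrom=chrom, ref_start=rs, ref_end=re_, read_start=qs,
            read_end=qe, orient=orient, read_name=read,
        )

    def test_distance_formula(self):
        # Distance_ref=500, Distance_read=10 -> Distance=490
        got = extract_split_signatures(
            [
                self.seg("c1", 1000, 2000, 0, 1000, "+"),
                self.seg("c1", 2500, 3500, 1010, 2010, "+"),
            ],
            CFG,
        )
        assert [(s.chrom, s.start, s.svlen, s.end) for s in got] == [
            ("c1", 2000, 490, 2500)
        ]
        assert got[0].source == "split"

    def test_below_lower_gate(self):
        got = extract_split_signatures(
            [
                self.seg("c1", 1000, 2000, 0, 1000, "+"),
                self.seg("c1", 2045, 3045, 1010, 2010, "+"),
            ],
            CFG,
        )
        assert got == []

    def test_opposite_orientation_excluded(self):
        got = extract_split_signatures(
            [
                self.seg("c1", 1000, 2000, 0, 1000, "+"),
                self.seg("c1", 2500, 3500, 1010, 2010, "-"),
            ],
            CFG,
        )
        assert got == []

    def test_different_chromosome_excluded(self):
        got = extract_split_signatures(
            [
                self.seg("c1", 1000, 2000, 0, 1000, "+"),
                self.seg("c2", 2500, 3500, 1010, 2010, "+"),
            ],
            CFG,
        )
        assert got == []

    def test_above_upper_gate(self):
        got = extract_split_signatures(
            [
                self.seg("c1", 0, 1000, 0, 1000, "+"),
                self.seg("c1", 200_000, 201_000, 1000, 2000, "+"),
            ],
            CFG,
        )
        assert got == []

    def test_reverse_strand_pair(self):
        """A reverse read's segments descend on the reference; the implied
        deletion is identical to the forward case."""
        # read-order first segment is the reference-rightmost one
        got = extract_split_signatures(
            [
                self.seg("c1", 7000, 8000, 0, 1000, "-"),
                self.seg("c1", 1000, 2000, 1000, 2000, "-"),
            ],
            CFG,
        )
        assert [(s.start, s.svlen, s.end) for s in got] == [(2000, 5000, 7000)]

    def test_only_read_adjacent_pairs(self):
        """Three collinear segments yield two signatures, not three."""
        got = extract_split_signatures(
            [
                self.seg("c1", 0, 1000, 0, 1000, "+"),
                self.seg("c1", 2000, 3000, 1000, 2000, "+"),
                self.seg("c1", 4000, 5000, 2000, 3000, "+"),
            ],
            CFG,
        )
        assert [(s.start, s.svlen) for s in got] == [(1000, 1000), (3000, 1000)]


class TestSplitSegmentProjection:
    def test_forward_record(self):
        s = split_segment_from_record(rec("100S800M5000D200M100S", ref_start=1000))
        assert (s.ref_start, s.ref_end) == (1000, 7000)
        assert (s.read_start, s.read_end) == (100, 1100)

    def test_reverse_record_flips_query_interval(self):
        s = split_segment_from_record(
            rec("100S800M100S", ref_start=1000, orient="-")
        )
        # full read 1000 bp; alignment-orientation span [100, 900) flips
        assert (s.read_start, s.read_end) == (100, 900)
        s2 = split_segment_from_record(
            rec("300S600M100S", ref_start=1000, orient="-")
        )
        assert (s2.read_start, s2.read_end) == (100, 700)

    def test_hard_clips_count_toward_read_length(self):
        fwd = split_segment_from_record(rec("200H700M100S", ref_start=0))
        rev = split_segment_from_record(rec("200H700M100S", ref_start=0, orient="-"))
        assert (fwd.read_start, fwd.read_end) == (200, 900)
        assert (rev.read_start, rev.read_end) == (100, 800)


class TestReadAlignments:
    def test_mapq_and_unmapped_filter(self, tmp_path):
        path = write_sam(
            tmp_path / "a.sam",
            [
                ("r1", 0, "chr1", 100, 60, "100M"),
                ("r2", 0, "chr1", 200, 10, "100M"),
                ("r3", 4, None, 0, 0, None),
            ],
        )
        groups = list(read_alignments(path, CFG))
        assert [g[0].read_name for g in groups] == ["r1"]

    def test_primary_and_supplementary_grouped(self, tmp_path):
        path = write_sam(
            tmp_path / "a.sam",
            [
                ("r1", 0, "chr1", 100, 60, "500M500S"),
                ("r1", 2048, "chr1", 5000, 60, "500S500M"),
            ],
        )
        (group,) = read_alignments(path, CFG)
        assert len(group) == 2
        assert {g.is_supplementary for g in group} == {False, True}

    def test_secondary_records_excluded(self, tmp_path):
        path = write_sam(
            tmp_path / "a.sam",
            [
                ("r1", 0, "chr1", 100, 60, "100M"),
                ("r1", 256, "chr1", 900, 60, "100M"),
            ],
        )
        (group,) = read_alignments(path, CFG)
        assert len(group) == 1

    def test_low_mapq_supplementary_dropped_independently(self, tmp_path):
        path = write_sam(
            tmp_path / "a.sam",
            [
                ("r1", 0, "chr1", 100, 60, "500M500S"),
                ("r1", 2048, "chr1", 5000, 5, "500S500M"),
            ],
        )
        (group,) = read_alignments(path, CFG)
        assert len(group) == 1 and not group[0].is_supplementary

    def test_empty_file(self, tmp_path):
        path = write_sam(tmp_path / "a.sam", [])
        assert list(read_alignments(path, CFG)) == []

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(OSError):
            list(read_alignments(str(tmp_path / "missing.bam"), CFG))


class TestCollectSignatures:
    def cigar_read(self, name="r1", pos=1000):
        return (name, 0, "chr1", pos, 60, "100M50D100M")

    def split_read(self, name="r2"):
        return [
            (name, 0, "chr1", 1000, 60, "1000M1000S"),
            (name, 2048, "chr1", 2490, 60, "1000S1000M"),
        ]

    def test_single_cigar_read(self, tmp_path):
        path = write_sam(tmp_path / "a.sam", [self.cigar_read()])
        sigs = collect_signatures(path, CFG)
        assert [(s.start, s.svlen) for s in sigs["chr1"]] == [(1100, 50)]

    def test_single_split_read(self, tmp_path):
        path = write_sam(tmp_path / "a.sam", self.split_read())
        sigs = collect_signatures(path, CFG)
        assert [(s.start, s.svlen, s.source) for s in sigs["chr1"]] == [
            (2000, 490, "split")
        ]

    def test_both_evidence_types_sorted(self, tmp_path):
        path = write_sam(
            tmp_path / "a.sam", [self.cigar_read()] + self.split_read()
        )
        sigs = collect_signatures(path, CFG)["chr1"]
        assert [(s.start, s.svlen) for s in sigs] == [(1100, 50), (2000, 490)]
        assert sigs == sorted(sigs, key=lambda s: (s.start, s.svlen, s.read_name))

    def test_invariant_under_record_order(self, tmp_path):
        rows = [self.cigar_read("rA", 1000), self.cigar_read("rB", 50_000)]
        rows += self.split_read("rC")
        shuffled = rows[:]
        random.Random(0).shuffle(shuffled)
        a = collect_signatures(write_sam(tmp_path / "a.sam", rows), CFG)
        b = collect_signatures(write_sam(tmp_path / "b.sam", shuffled), CFG)
        assert a == b

    def test_fragmented_deletion_merged_before_pooling(self, tmp_path):
        path = write_sam(
            tmp_path / "a.sam", [("r1", 0, "chr1", 0, 60, "100M150D10M140D100M")]
        )
        sigs = collect_signatures(path, CFG)["chr1"]
        assert [(s.start, s.svlen, s.end) for s in sigs] == [(100, 290, 400)]

    def test_lowering_mapq_never_decreases_count(self, tmp_path):
        path = write_sam(
            tmp_path / "a.sam",
            [
                ("r1", 0, "chr1", 1000, 60, "100M50D100M"),
                ("r2", 0, "chr1", 3000, 15, "100M50D100M"),
            ],
        )
        high = collect_signatures(path, ExtractionConfig(min_mapq=20))
        low = collect_signatures(path, ExtractionConfig(min_mapq=10))
        assert len(low.get("chr1", [])) >= len(high.get("chr1", []))
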