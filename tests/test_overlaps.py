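"""Frame-offset maps, multiphasic/bidirectional regions and overlap calls."""

import pytest

from gffaudit import vocab
from gffaudit.model import AnnotationError
from gffaudit.overlaps import (
    MultiphasicRegion,
    aa_bound_for_extent,
    classify_multiphasic,
    classify_noncoding_overlap,
    codon_offset_map,
    detect_bidirectional,
    detect_cds_overlap_same_frame,
    multiphasic_regions,
)
from helpers import aset_of, iv, orf, transcript


class TestCodonOffsetMap:
    def test_single_exon(self):
        m = codon_offset_map(orf("g", iv(0, 6)))
        assert [m[p] for p in range(6)] == [0, 1, 2, 0, 1, 2]

    def test_offsets_continue_across_intron(self):
        m = codon_offset_map(orf("g", iv(0, 4), iv(10, 15)))
        assert [m[p] for p in range(4)] == [0, 1, 2, 0]
        assert [m[p] for p in range(10, 15)] == [1, 2, 0, 1, 2]

    def test_minus_strand_decreasing_genomic_coordinate(self):
        m = codon_offset_map(orf("g", iv(0, 6, "-")))
        assert [m[p] for p in (5, 4, 3, 2, 1, 0)] == [0, 1, 2, 0, 1, 2]


class TestMultiphasicRegions:
    def test_identical_orfs_share_frame_everywhere(self):
        a = orf("g", iv(0, 30))
        assert multiphasic_regions(a, orf("g", iv(0, 30))) == []

    def test_shifting_splice_creates_region_with_stop(self):
        # isoforms share a first coding exon, then isoform B's acceptor
        # shift puts a 26-nt run (including B's stop) out of frame
        a = orf("g", iv(6, 15), iv(35, 74))
        b = orf("g", iv(6, 15), iv(31, 61))
        (region,) = multiphasic_regions(a, b)
        assert (region.interval.start, region.interval.end) == (35, 61)
        assert region.length_nt == 26
        assert region.includes_stop
        assert not region.involves_first_coding_exon
        assert not region.cross_gene

    def test_symmetric_in_arguments(self):
        a = orf("g", iv(6, 15), iv(35, 74))
        b = orf("g", iv(6, 15), iv(31, 61))
        ab = [(r.interval, r.length_nt) for r in multiphasic_regions(a, b)]
        ba = [(r.interval, r.length_nt) for r in multiphasic_regions(b, a)]
        assert ab == ba

    def test_cross_gene_70nt_on_dicistronic_transcript(self):
        a = orf("gA", iv(0, 126))
        b = orf("gB", iv(56, 158))
        (region,) = multiphasic_regions(a, b)
        assert region.length_nt == 70
        assert region.cross_gene
        comment = classify_multiphasic(region)
        assert comment == vocab.COMMENT_MULTIPHASIC_CROSS_GENE
        assert region.long_overlap

    def test_opposite_strands_rejected(self):
        with pytest.raises(AnnotationError, match="bidirectional"):
            multiphasic_regions(orf("gA", iv(0, 30)), orf("gB", iv(0, 30, "-")))


def _region(length, *, cross=False, first=False, stop=False):
    return MultiphasicRegion(
        interval=iv(100, 100 + length),
        length_nt=length,
        members=("gA", "gA" if not cross else "gB"),
        involves_first_coding_exon=first,
        cross_gene=cross,
        includes_stop=stop,
    )


class TestClassifyMultiphasic:
    @pytest.mark.parametrize(
        "length,kwargs,comment,long",
        [
            (30, {"stop": True}, vocab.COMMENT_MULTIPHASIC_ALT_STOP, False),
            (39, {"stop": True}, vocab.COMMENT_MULTIPHASIC_ALT_STOP, False),
            (40, {"stop": True}, vocab.COMMENT_MULTIPHASIC_EXON, False),
            (80, {}, vocab.COMMENT_MULTIPHASIC_EXON, True),
            (63, {}, vocab.COMMENT_MULTIPHASIC_EXON, False),
            (64, {}, vocab.COMMENT_MULTIPHASIC_EXON, True),
            (
                30,
                {"stop": True, "first": True},
                vocab.COMMENT_MULTIPHASIC_FIRST_EXON,
                False,
            ),
            (553, {"cross": True}, vocab.COMMENT_MULTIPHASIC_CROSS_GENE, True),
        ],
    )
    def test_threshold_rules(self, length, kwargs, comment, long):
        region = _region(length, **kwargs)
        assert classify_multiphasic(region) == comment
        assert region.long_overlap is long

    def test_short_extent_implies_under_13_aa(self):
        assert aa_bound_for_extent(40) == 13


class TestBidirectional:
    def test_disjoint_is_none(self):
        assert detect_bidirectional(orf("gA", iv(0, 30)), orf("gB", iv(60, 90, "-"))) is None

    def test_fifty_nt_intersection(self):
        call = detect_bidirectional(orf("gA", iv(0, 60)), orf("gB", iv(10, 70, "-")))
        assert call.length_nt == 50
        assert call.comment == vocab.COMMENT_BIDIRECTIONAL

    def test_abutting_half_open_is_none(self):
        assert detect_bidirectional(orf("gA", iv(0, 30)), orf("gB", iv(30, 60, "-"))) is None

    def test_same_strand_rejected(self):
        with pytest.raises(AnnotationError, match="opposite"):
            detect_bidirectional(orf("gA", iv(0, 30)), orf("gB", iv(0, 30)))


class TestSameFrameOverlap:
    def test_shared_240nt_n_terminus(self):
        # genes share promoter, start codon and 80 N-terminal codons
        aset = aset_of(
            transcript("t1", ["gA"], [iv(0, 310)], [orf("gA", iv(0, 300))]),
            transcript("t2", ["gB"], [iv(0, 400)], [orf("gB", iv(0, 240), iv(300, 312))]),
        )
        call = detect_cds_overlap_same_frame("gA", "gB", aset)
        assert call.length_nt == 240
        assert call.comment.startswith(vocab.COMMENT_CDS_OVERLAP_PREFIX)

    def test_no_shared_cds_is_none(self):
        aset = aset_of(
            transcript("t1", ["gA"], [iv(0, 40)], [orf("gA", iv(0, 30))]),
            transcript("t2", ["gB"], [iv(50, 100)], [orf("gB", iv(60, 90))]),
        )
        assert detect_cds_overlap_same_frame("gA", "gB", aset) is None

    def test_different_frames_route_to_multiphasic(self):
        aset = aset_of(
            transcript("t1", ["gA"], [iv(0, 70)], [orf("gA", iv(0, 60))]),
            transcript("t2", ["gB"], [iv(0, 70)], [orf("gB", iv(1, 61))]),
        )
        assert detect_cds_overlap_same_frame("gA", "gB", aset) is None
        (region,) = multiphasic_regions(
            aset.transcripts["t1"].orfs[0], aset.transcripts["t2"].orfs[0]
        )
        assert region.length_nt == 59  # shared bases [1, 60)

    def test_partition_every_shared_base_exactly_once(self):
        # mixed case: a same-frame prefix and a shifted suffix
        a = orf("gA", iv(0, 90))
        b = orf("gB", iv(0, 30), iv(31, 91))
        map_a = codon_offset_map(a)
        map_b = codon_offset_map(b)
        shared = map_a.keys() & map_b.keys()
        same = {p for p in shared if map_a[p] == map_b[p]}
        regions = multiphasic_regions(a, b)
        multi = set()
        for r in regions:
            multi.update(range(r.interval.start, r.interval.end))
        assert same | multi == shared
        assert same & multi == set()


class TestNoncodingOverlap:
    def test_identical_first_exon(self):
        aset = aset_of(
            transcript("t1", ["gA"], [iv(0, 30), iv(60, 100)], [orf("gA", iv(60, 90))]),
            transcript("t2", ["gB"], [iv(0, 30), iv(120, 160)], [orf("gB", iv(120, 150))]),
        )
        call = classify_noncoding_overlap("gA", "gB", aset)
        assert call.category == "shared_5_exons"
        assert call.comment == vocab.COMMENT_SHARES_5_EXONS

    def test_identical_last_exon(self):
        aset = aset_of(
            transcript("t1", ["gA"], [iv(0, 40), iv(200, 230)], [orf("gA", iv(5, 35))]),
            transcript("t2", ["gB"], [iv(100, 140), iv(200, 230)], [orf("gB", iv(105, 135))]),
        )
        call = classify_noncoding_overlap("gA", "gB", aset)
        assert call.category == "shared_3_utr"
        assert call.comment == vocab.COMMENT_SHARES_3_UTR

    def test_both_ends_shared_is_complex(self):
        aset = aset_of(
            transcript("t1", ["gA"], [iv(0, 30), iv(60, 90), iv(200, 230)], [orf("gA", iv(60, 90))]),
            transcript("t2", ["gB"], [iv(0, 30), iv(120, 150), iv(200, 230)], [orf("gB", iv(120, 150))]),
        )
        call = classify_noncoding_overlap("gA", "gB", aset)
        assert call.category == "complex_atypical"
        assert call.comment == vocab.COMMENT_COMPLEX_ATYPICAL

    def test_nested_in_intron_unflagged(self):
        aset = aset_of(
            transcript("t1", ["gA"], [iv(0, 30), iv(90, 130)], [orf("gA", iv(90, 120))]),
            transcript("t2", ["gB"], [iv(40, 80)], [orf("gB", iv(45, 75))]),
        )
        call = classify_noncoding_overlap("gA", "gB", aset)
        assert call.category == "nested_unflagged"
        assert call.comment == ""

    def test_utr_chain_unflagged(self):
        aset = aset_of(
            transcript("t1", ["gA"], [iv(0, 100)], [orf("gA", iv(10, 40))]),
            transcript("t2", ["gB"], [iv(80, 200)], [orf("gB", iv(110, 140))]),
        )
        call = classify_noncoding_overlap("gA", "gB", aset)
        assert call.category == "utr_chain_unflagged"
        assert call.comment == ""
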