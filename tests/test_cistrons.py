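"""Cistronic arity, intercistronic distances and small-ORF bins."""

import pytest

from gffaudit.cistrons import (
    cistronic_arity,
    gene_cistronic_profile,
    intercistronic_distance,
    shared_transcript_pairs,
    small_polypeptide_class,
    transcript_intercistronic_distances,
)
from gffaudit.model import (
    AnnotationError,
    AnnotationSet,
    GeneRecord,
    GenomicInterval,
    OrfAnnotation,
    TranscriptModel,
)


def _transcript(tid, orf_spans, exons=None, total=300):
    """Single-exon (or given-exon) plus-strand transcript with one ORF per span."""
    gene_ids = [g for g, _, _ in orf_spans]
    exons = exons or [GenomicInterval("c", 0, total, "+")]
    orfs = [
        OrfAnnotation(g, [GenomicInterval("c", s, e, "+")]) for g, s, e in orf_spans
    ]
    return TranscriptModel(tid, gene_ids, exons, orfs)


def _aset(*transcripts):
    aset = AnnotationSet()
    for t in transcripts:
        aset.transcripts[t.transcript_id] = t
        for gid in t.gene_ids:
            rec = aset.genes.setdefault(
                gid, GeneRecord(gid, t.span(), [])
            )
            rec.transcript_ids.append(t.transcript_id)
    return aset


class TestArity:
    @pytest.mark.parametrize(
        "spans,expected",
        [
            ([("gA", 10, 40)], 1),
            ([("gA", 10, 40), ("gB", 50, 80)], 2),
            (
                [("gA", 10, 40), ("gB", 50, 80), ("gC", 90, 120), ("gD", 130, 160)],
                4,
            ),
        ],
    )
    def test_counts_orfs(self, spans, expected):
        assert cistronic_arity(_transcript("t", spans)) == expected

    def test_mono_profile(self):
        aset = _aset(_transcript("t1", [("gA", 10, 40)]))
        p = gene_cistronic_profile("gA", aset)
        assert p.arity_set == {1} and not p.exclusively_polycistronic

    def test_mixed_mono_and_dicistronic(self):
        aset = _aset(
            _transcript("t1", [("gA", 10, 40)]),
            _transcript("t2", [("gA", 10, 40), ("gB", 50, 80)]),
        )
        p = gene_cistronic_profile("gA", aset)
        assert p.arity_set == {1, 2} and not p.exclusively_polycistronic

    def test_exclusively_dicistronic(self):
        aset = _aset(_transcript("t1", [("gA", 10, 40), ("gB", 50, 80)]))
        p = gene_cistronic_profile("gB", aset)
        assert p.arity_set == {2} and p.exclusively_polycistronic

    def test_unknown_gene_errors(self):
        with pytest.raises(AnnotationError, match="unknown gene"):
            gene_cistronic_profile("nope", _aset(_transcript("t1", [("gA", 10, 40)])))


class TestIntercistronicDistance:
    def test_abutting_start_is_zero(self):
        t = _transcript("t", [("gA", 0, 30), ("gB", 30, 60)])
        assert intercistronic_distance(t.orfs[0], t.orfs[1], t) == 0

    def test_ten_nt_gap(self):
        t = _transcript("t", [("gA", 0, 30), ("gB", 40, 70)])
        assert intercistronic_distance(t.orfs[0], t.orfs[1], t) == 10

    def test_overlap_in_different_frames_is_negative_34(self):
        # downstream start begins 34 nt before the upstream stop's last base
        t = _transcript("t", [("gA", 0, 90), ("gB", 56, 128)], total=200)
        assert (56 - 0) % 3 != 0  # frames differ
        assert intercistronic_distance(t.orfs[0], t.orfs[1], t) == -34

    def test_invariant_under_upstream_intron(self):
        # same CDS layout measured across an intron 5' of both ORFs
        exons = [GenomicInterval("c", 0, 5, "+"), GenomicInterval("c", 105, 400, "+")]
        t_spliced = TranscriptModel(
            "t",
            ["gA", "gB"],
            exons,
            [
                OrfAnnotation("gA", [GenomicInterval("c", 110, 140, "+")]),
                OrfAnnotation("gB", [GenomicInterval("c", 150, 180, "+")]),
            ],
        )
        t_plain = _transcript("t2", [("gA", 110, 140), ("gB", 150, 180)], total=400)
        d1 = intercistronic_distance(t_spliced.orfs[0], t_spliced.orfs[1], t_spliced)
        d2 = intercistronic_distance(t_plain.orfs[0], t_plain.orfs[1], t_plain)
        assert d1 == d2 == 10

    def test_foreign_orf_rejected(self):
        t = _transcript("t", [("gA", 0, 30), ("gB", 40, 70)])
        other = OrfAnnotation("gC", [GenomicInterval("c", 0, 30, "+")])
        with pytest.raises(AnnotationError):
            intercistronic_distance(other, t.orfs[1], t)

    def test_fixture_distances_match_manifest(self, audit1, fixture1):
        for tid, want in fixture1.manifest["expected"]["intercistronic"].items():
            got = [list(x) for x in audit1.intercistronic[tid]]
            assert got == [list(x) for x in want]


class TestSmallPolypeptideClass:
    @pytest.mark.parametrize(
        "n_aa,label", [(24, "<25 aa"), (25, "25–45 aa"), (45, "25–45 aa"), (46, ">45 aa")]
    )
    def test_bin_boundaries(self, n_aa, label):
        length = 3 * (n_aa + 1)  # CDS includes the stop codon
        orf = OrfAnnotation("g", [GenomicInterval("c", 0, length, "+")])
        assert small_polypeptide_class(orf) == label


class TestSharedTranscriptPairs:
    def test_no_multi_gene_transcripts(self):
        aset = _aset(_transcript("t1", [("gA", 10, 40)]))
        assert shared_transcript_pairs(aset) == []

    def test_dicistronic_pair(self):
        aset = _aset(_transcript("t1", [("gA", 10, 40), ("gB", 50, 80)]))
        assert shared_transcript_pairs(aset) == [(("gA", "gB"), 1)]

    def test_tricistronic_yields_three_pairs(self):
        aset = _aset(
            _transcript("t1", [("gA", 10, 40), ("gB", 50, 80), ("gC", 90, 120)])
        )
        pairs = [p for p, _ in shared_transcript_pairs(aset)]
        assert pairs == [("gA", "gB"), ("gA", "gC"), ("gB", "gC")]

    def test_fixture_polycistronic_genes_match_manifest(self, fixture1):
        planted = set()
        for entry in fixture1.manifest["entries"]:
            if entry["category"] in (
                "dicistronic",
                "tricistronic",
                "tetracistronic",
                "dicistronic_overlap",
            ):
                planted.update(entry["genes"])
        flagged = set()
        for (a, b), _ in shared_transcript_pairs(fixture1.aset):
            flagged.update((a, b))
        assert flagged == planted

    def test_consecutive_distances_ordering(self):
        t = _transcript(
            "t", [("gA", 0, 30), ("gB", 40, 70), ("gC", 90, 120)], total=200
        )
        assert transcript_intercistronic_distances(t) == [
            ("gA", "gB", 10),
            ("gB", "gC", 20),
        ]
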