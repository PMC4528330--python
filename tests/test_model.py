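"""Genome/annotation I/O, spliced-sequence and intron extraction."""

import pytest

from gffaudit.model import (
    AnnotationError,
    GenomeError,
    GenomeSequence,
    GenomicInterval,
    OrfAnnotation,
    TranscriptModel,
    introns_of,
    read_annotation,
    read_genome,
    revcomp,
    spliced_sequence,
    write_annotation,
)


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadGenome:
    def test_lowercase_is_normalized(self, tmp_path):
        g = read_genome(_write(tmp_path, "g.fa", ">chr1\nacgt\n"))
        assert g.records == {"chr1": "ACGT"}

    def test_duplicate_identifier_rejected(self, tmp_path):
        with pytest.raises(GenomeError, match="duplicate"):
            read_genome(_write(tmp_path, "g.fa", ">a\nACGT\n>a\nAC\n"))

    def test_non_iupac_character_named_with_position(self, tmp_path):
        with pytest.raises(GenomeError, match="position 2"):
            read_genome(_write(tmp_path, "g.fa", ">a\nACXT\n"))

    def test_fixture_contig_count_matches_manifest(self, fixture1, tmp_path):
        from gffaudit.fixtures import write_fixture

        paths = write_fixture(fixture1, tmp_path)
        g = read_genome(paths["genome"])
        assert len(g.records) == fixture1.manifest["n_contigs"]
        assert "mito" in g.circular


class TestReadAnnotation:
    GFF = (
        "##gff-version 3\n"
        "c\tx\tgene\t1\t60\t.\t+\t.\tID=gA\n"
        "c\tx\tmRNA\t1\t60\t.\t+\t.\tID=t1;Parent=gA\n"
        "c\tx\texon\t1\t60\t.\t+\t.\tParent=t1\n"
        "c\tx\tCDS\t10\t20\t.\t+\t0\tParent=t1;gene=gA\n"
    )

    def test_one_based_inclusive_converts_to_half_open(self, tmp_path):
        # a 1-based [10, 20] CDS becomes the internal interval [9, 20)
        gff = self.GFF.replace("10\t20", "10\t21")  # 12 nt, a multiple of 3
        aset = read_annotation(_write(tmp_path, "a.gff3", gff))
        seg = aset.transcripts["t1"].orfs[0].cds_segments[0]
        assert (seg.start, seg.end) == (9, 21)

    def test_cds_outside_exon_union_rejected(self, tmp_path):
        gff = self.GFF.replace("CDS\t10\t20", "CDS\t55\t66")
        with pytest.raises(AnnotationError, match="exon union"):
            read_annotation(_write(tmp_path, "a.gff3", gff))

    def test_undeclared_parent_gene_rejected(self, tmp_path):
        gff = self.GFF.replace("Parent=gA", "Parent=gB", 1)
        with pytest.raises(AnnotationError, match="undeclared gene"):
            read_annotation(_write(tmp_path, "a.gff3", gff))

    def test_unknown_exception_token_rejected(self, tmp_path):
        gff = self.GFF.replace("ID=t1;Parent=gA", "ID=t1;Parent=gA;flags=bogus_flag")
        with pytest.raises(AnnotationError, match="bogus_flag"):
            read_annotation(_write(tmp_path, "a.gff3", gff))

    def test_dicistronic_mrna_yields_two_orfs(self, tmp_path):
        gff = (
            "##gff-version 3\n"
            "c\tx\tgene\t1\t100\t.\t+\t.\tID=gA\n"
            "c\tx\tgene\t1\t100\t.\t+\t.\tID=gB\n"
            "c\tx\tmRNA\t1\t100\t.\t+\t.\tID=t1;Parent=gA,gB\n"
            "c\tx\texon\t1\t100\t.\t+\t.\tParent=t1\n"
            "c\tx\tCDS\t11\t19\t.\t+\t0\tParent=t1;gene=gA\n"
            "c\tx\tCDS\t31\t39\t.\t+\t0\tParent=t1;gene=gB\n"
        )
        aset = read_annotation(_write(tmp_path, "a.gff3", gff))
        t = aset.transcripts["t1"]
        assert t.gene_ids == ["gA", "gB"]
        assert [o.gene_id for o in t.orfs] == ["gA", "gB"]

    def test_round_trip_is_identity(self, fixture1, tmp_path):
        p1 = _write(tmp_path, "a.gff3", write_annotation(fixture1.aset))
        aset = read_annotation(p1)
        assert write_annotation(aset) == p1.read_text()
        aset2 = read_annotation(_write(tmp_path, "b.gff3", write_annotation(aset)))
        assert aset2 == aset

    def test_undeclared_mixed_strand_rejected(self):
        t = TranscriptModel(
            "t1",
            ["g1"],
            [GenomicInterval("c", 0, 10, "+"), GenomicInterval("c", 20, 30, "-")],
        )
        with pytest.raises(AnnotationError, match="trans_spliced"):
            t.validate()


class TestSplicedSequence:
    def test_single_plus_exon(self):
        g = GenomeSequence({"c": "ATGTAA"})
        t = TranscriptModel("t", ["g"], [GenomicInterval("c", 0, 6, "+")])
        assert spliced_sequence(t, g) == "ATGTAA"

    def test_minus_exon_reverse_complemented(self):
        g = GenomeSequence({"c": "ATG"})
        t = TranscriptModel("t", ["g"], [GenomicInterval("c", 0, 3, "-")])
        assert spliced_sequence(t, g) == "CAT"

    def test_two_exons_excise_intron(self):
        contig = "ATGGTCCCCCAGTAA"
        g = GenomeSequence({"c": contig})
        t = TranscriptModel(
            "t",
            ["g"],
            [GenomicInterval("c", 0, 3, "+"), GenomicInterval("c", 12, 15, "+")],
        )
        assert spliced_sequence(t, g) == contig[0:3] + contig[12:15]

    def test_exon_beyond_contig_end_errors(self):
        g = GenomeSequence({"c": "ACGT"})
        t = TranscriptModel("t", ["g"], [GenomicInterval("c", 0, 10, "+")])
        with pytest.raises(GenomeError, match="beyond"):
            spliced_sequence(t, g)

    def test_exon_lengths_sum_to_spliced_length(self, fixture1):
        for t in fixture1.aset.transcripts.values():
            assert len(spliced_sequence(t, fixture1.genome)) == t.exon_length()


class TestIntronsOf:
    def _transcript(self, strand, e1, e2):
        return TranscriptModel(
            "t", ["g"], [GenomicInterval("c", *e1, strand), GenomicInterval("c", *e2, strand)]
        )

    def test_canonical_donor_acceptor(self):
        g = GenomeSequence({"c": "ATGGTCCCAGTAA"})
        t = self._transcript("+", (0, 3), (10, 13))
        (rec,) = introns_of(t, g)
        assert (rec.donor, rec.acceptor) == ("GT", "AG")
        assert (rec.interval.start, rec.interval.end) == (3, 10)

    def test_strand_symmetry(self):
        contig = "ATGGTCCCAGTAA"
        g_plus = GenomeSequence({"c": contig})
        t_plus = self._transcript("+", (0, 3), (10, 13))
        g_minus = GenomeSequence({"c": revcomp(contig)})
        L = len(contig)
        t_minus = TranscriptModel(
            "t",
            ["g"],
            [
                GenomicInterval("c", L - 3, L, "-"),
                GenomicInterval("c", L - 13, L - 10, "-"),
            ],
        )
        (a,) = introns_of(t_plus, g_plus)
        (b,) = introns_of(t_minus, g_minus)
        assert (a.donor, a.acceptor) == (b.donor, b.acceptor)

    def test_hac1_style_23nt_ca_tg_intron(self):
        intron = "CA" + "G" * 19 + "TG"
        assert len(intron) == 23
        contig = "AAAA" + intron + "CCCC"
        g = GenomeSequence({"c": contig})
        t = self._transcript("+", (0, 4), (27, 31))
        (rec,) = introns_of(t, g)
        assert (rec.donor, rec.acceptor, len(rec.interval)) == ("CA", "TG", 23)

    def test_short_intron_rejected(self):
        g = GenomeSequence({"c": "A" * 20})
        t = self._transcript("+", (0, 5), (8, 12))  # 3-nt gap
        with pytest.raises(AnnotationError, match="at least 4"):
            introns_of(t, g)

    def test_fixture_introns_recover_planted_pairs(self, fixture1):
        from gffaudit.model import iter_all_introns

        expected = fixture1.manifest["expected"]["intron_classes"]
        got = {
            rec.key: rec.pair
            for rec in iter_all_introns(fixture1.aset, fixture1.genome)
        }
        assert got == {k: v["pair"] for k, v in expected.items()}
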