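"""Splice-pair taxonomy, U12 tagging, junction audits and the census."""

from itertools import product

import pytest

from gffaudit.config import AuditConfig
from gffaudit.model import GenomeSequence, GenomicInterval, IntronRecord
from gffaudit.splices import (
    CANDIDATE_NONCANONICAL_PAIRS,
    CENSUS_PAIR_ROWS,
    JunctionCall,
    JunctionAuditor,
    add_total_row,
    classify_intron,
    enumerate_candidate_noncanonical_pairs,
    load_reference_census,
    observed_candidate_pairs,
    similar_alternative_splice,
    splice_summary,
    tag_u12,
)
from gffaudit.vocab import FLAG_ENDONUCLEASE_SPLICED, FLAG_SEQUENCE_ERROR_OR_GAP


def _intron(donor, acceptor, start=100, end=160, strand="+"):
    return IntronRecord(
        interval=GenomicInterval("c", start, end, strand),
        donor=donor,
        acceptor=acceptor,
    )


class TestCandidatePairs:
    def test_exactly_eight_pairs(self):
        assert len(enumerate_candidate_noncanonical_pairs()) == 8

    def test_canonical_pairs_excluded(self):
        pairs = enumerate_candidate_noncanonical_pairs()
        assert "GT-AG" not in pairs and "GC-AG" not in pairs

    def test_matches_exhaustive_bruteforce_oracle(self):
        reference = "GTAG"
        oracle = set()
        for combo in product("ACGT", repeat=4):
            cand = "".join(combo)
            mismatches = sum(a != b for a, b in zip(cand, reference))
            if mismatches == 1 and cand[0] == "G":
                pair = f"{cand[:2]}-{cand[2:]}"
                if pair not in ("GT-AG", "GC-AG"):
                    oracle.add(pair)
        assert enumerate_candidate_noncanonical_pairs() == oracle

    def test_at_ac_is_not_a_candidate(self):
        # its donor does not keep the invariant G
        assert "AT-AC" not in CANDIDATE_NONCANONICAL_PAIRS


class TestClassifyIntron:
    @pytest.mark.parametrize(
        "donor,acceptor,flags,label",
        [
            ("GT", "AG", (), "canonical_GT_AG"),
            ("GC", "AG", (), "canonical_GC_AG"),
            ("GT", "AT", (), "noncanonical:GT-AT"),
            ("GA", "AG", (), "noncanonical:GA-AG"),
            ("AT", "AC", (), "noncanonical_AT_AC"),
            ("CA", "TG", (FLAG_ENDONUCLEASE_SPLICED,), "endonuclease_spliced"),
            ("CA", "TG", (), "other_nonconforming"),
            ("CT", "GC", (FLAG_SEQUENCE_ERROR_OR_GAP,), "convenience"),
        ],
    )
    def test_labels(self, donor, acceptor, flags, label):
        assert classify_intron(_intron(donor, acceptor), flags) == label

    def test_every_noncanonical_label_is_in_candidate_set(self):
        for donor in ("GA", "GG"):
            label = classify_intron(_intron(donor, "AG"))
            assert label.split(":", 1)[1] in CANDIDATE_NONCANONICAL_PAIRS


class TestU12Tag:
    def _genome(self, intron_seq, pad=20):
        return (
            GenomeSequence({"c": "A" * pad + intron_seq + "A" * pad}),
            _intron(intron_seq[:2], intron_seq[-2:], pad, pad + len(intron_seq)),
        )

    def test_u12_donor_consensus(self):
        genome, intron = self._genome("GTATCCTT" + "C" * 20 + "AG")
        assert tag_u12(intron, genome)

    def test_u2_donor_rejected(self):
        genome, intron = self._genome("GTAAGT" + "C" * 20 + "AG")
        assert not tag_u12(intron, genome)

    def test_at_ac_u12_subtype(self):
        genome, intron = self._genome("ATATCCTT" + "C" * 20 + "AC")
        assert tag_u12(intron, genome)
        assert classify_intron(intron) == "noncanonical_AT_AC"


class TestSimilarAlternativeSplice:
    def test_fixture_noncanonical_introns_find_planted_alternative(
        self, fixture1, audit1
    ):
        expected = fixture1.manifest["expected"]["similar_alternative"]
        assert audit1.intron_similar == expected
        # at least the six one-base-off pairs have alternatives
        assert sum(v is not None for v in expected.values()) >= 6

    def test_no_alternative_in_single_intron_gene(self, fixture1, audit1):
        # AT-AC introns are planted without alternatives
        at_ac = [
            rec
            for rec in audit1.introns
            if rec.classification[0] == "noncanonical_AT_AC"
        ]
        assert at_ac
        for rec in at_ac:
            assert audit1.intron_similar[rec.key] is None

    def test_equidistant_alternatives_prefer_upstream(self):
        # one noncanonical acceptor flanked by two equidistant canonical
        # acceptors (±6 nt) within the same gene, all sharing the donor
        from helpers import aset_of, iv, transcript

        bases = list("C" * 80)
        bases[10:12] = "GT"  # shared donor at position 10
        bases[32:34] = "AG"  # canonical acceptor, intron end 34
        bases[38:40] = "TT"  # noncanonical acceptor, intron end 40
        bases[44:46] = "AG"  # canonical acceptor, intron end 46
        genome = GenomeSequence({"c": "".join(bases)})
        aset = aset_of(
            transcript("tn", ["g"], [iv(0, 10), iv(40, 70)]),
            transcript("tu", ["g"], [iv(0, 10), iv(34, 70)]),
            transcript("td", ["g"], [iv(0, 10), iv(46, 70)]),
        )
        target = _intron("GT", "TT", 10, 40)
        target.transcript_ids = ["tn"]
        alt = similar_alternative_splice(target, aset, genome)
        assert alt is not None
        assert alt.interval.end == 34  # upstream of the two equidistant options


class TestJunctionAudit:
    def test_fixture_verdicts_match_manifest(self, audit1, fixture1):
        got = {
            (j.seqid, j.start, j.end, j.strand, j.read_count): d.verdict
            for j, d in audit1.junction_audits
        }
        for e in fixture1.manifest["expected"]["junction_verdicts"]:
            key = (e["seqid"], e["start"], e["end"], e["strand"], e["read_count"])
            assert got[key] == e["verdict"]

    def test_strand_flip_and_restore(self, fixture1):
        """Stripping strand from a GT-AT junction flips the verdict;
        restoring it yields an exact match."""
        auditor = JunctionAuditor(fixture1.aset, fixture1.genome)
        gt_at = [r for r in auditor.introns if r.pair == "GT-AT"]
        assert gt_at
        for rec in gt_at:
            iv_ = rec.interval
            stranded = JunctionCall(iv_.seqid, iv_.start, iv_.end, iv_.strand, 10, 50.0)
            stripped = JunctionCall(iv_.seqid, iv_.start, iv_.end, None, 10, 50.0)
            assert auditor.audit(stranded).verdict == "matches_annotated"
            assert auditor.audit(stripped).verdict == "strand_flip_gt_at"

    def test_offset_zero_only_for_exact_matches(self, audit1):
        for j, d in audit1.junction_audits:
            if d.verdict == "matches_annotated":
                assert d.offset == 0

    def test_shifted_canonical_is_off_by_one(self, fixture1):
        auditor = JunctionAuditor(fixture1.aset, fixture1.genome)
        canon = next(r for r in auditor.introns if r.pair == "GT-AG")
        iv_ = canon.interval
        for delta in (+1, -1):
            j = JunctionCall(
                iv_.seqid, iv_.start + delta, iv_.end + delta, iv_.strand, 10, 50.0
            )
            assert auditor.audit(j).verdict == "off_by_one_artifact"

    def test_low_frequency_culling_threshold(self, fixture1):
        auditor = JunctionAuditor(
            fixture1.aset, fixture1.genome, AuditConfig(junction_min_count=2)
        )
        j = JunctionCall("ctg1", 1, 30, None, 1, 5.0)
        assert auditor.audit(j).verdict == "low_frequency"


class TestCensus:
    def test_total_row_sums_pair_rows(self, audit1):
        census = audit1.census
        for col in census.columns:
            assert census.loc["Total", col] == census.loc[list(CENSUS_PAIR_ROWS), col].sum()

    def test_planted_noncanonical_counts(self, audit1):
        census = audit1.census
        # one of each of the six observed one-base-off pairs plus 2 AT-AC
        assert census.loc["Total", "n_introns"] == 8
        assert census.loc["Total", "junction_support"] == 8
        assert census.loc["AT-AC (U12)", "n_introns"] == 1
        assert census.loc["GT-AG (U12)", "n_introns"] == 1
        assert census.loc["GT-AT", "n_introns"] == 1

    def test_convenience_splices_excluded(self, audit1):
        assert all(
            "CT-GC" not in row for row in audit1.census.index
        )  # arbitrary pair never becomes a census row

    def test_empty_annotation_gives_all_zero_table(self):
        from gffaudit.model import AnnotationSet

        census = splice_summary(AnnotationSet(), GenomeSequence({"c": "ACGT"}))
        assert (census.to_numpy() == 0).all()

    def test_reference_census_reproduces_printed_totals(self):
        df = add_total_row(load_reference_census())
        assert df.loc["Total", "n_introns"] == 79
        assert df.loc["Total", "junction_support"] == 71
        assert df.loc["Total", "similar_alternative"] == 60
        assert observed_candidate_pairs(df) == 6
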