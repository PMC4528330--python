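"""Peptide derivation under declared translation exceptions."""

import random

import pytest
from Bio.Seq import Seq

from gffaudit.model import Frameshift, GenomicInterval, OrfAnnotation
from gffaudit.translate import (
    TranslationError,
    apply_frameshift,
    complete_incomplete_stop,
    genetic_code,
    translate_cds,
)


def _orf(**kwargs):
    # coordinates are irrelevant for translate_cds; a placeholder segment
    return OrfAnnotation("g", [GenomicInterval("c", 0, 3, "+")], **kwargs)


class TestWorkedExamples:
    def test_plain_orf(self):
        assert translate_cds("ATGGCTTAA", _orf()).peptide == "MA"

    def test_cug_start_initiates_with_methionine(self):
        result = translate_cds("CTGGCTTAA", _orf(start_codon_kind="CTG"))
        assert result.peptide == "MA"  # not "LA"
        assert ("non_aug_start", 1) in result.events

    def test_readthrough_places_x(self):
        result = translate_cds(
            "ATGTGAGCTTAA", _orf(readthrough_positions=[2])
        )
        assert result.peptide == "MXA"

    def test_selenocysteine_places_u(self):
        result = translate_cds("ATGTGATAA", _orf(selenocysteine_positions=[2]))
        assert result.peptide == "MU"

    def test_double_readthrough_places_two_x(self):
        result = translate_cds(
            "ATGTGAGCTTAGGCTTAA", _orf(readthrough_positions=[2, 4])
        )
        assert result.peptide == "MXAXA"

    def test_frameshift_example(self):
        result = translate_cds(
            "ATGAAACGGTTAG", _orf(frameshift=Frameshift(codon_index=2))
        )
        assert result.peptide == "MKG"

    def test_undetermined_start_translated_as_annotated(self):
        result = translate_cds(
            "ATTGCTTAA",
            _orf(start_codon_kind="undetermined", genetic_code="invertebrate_mitochondrial"),
        )
        assert result.peptide == "IA"
        assert ("start_codon_not_determined", 1) in result.events


class TestErrors:
    def test_undeclared_internal_stop_names_codon(self):
        with pytest.raises(TranslationError, match="codon 2"):
            translate_cds("ATGTGAGCTTAA", _orf())

    def test_declared_exception_at_non_stop_codon(self):
        with pytest.raises(TranslationError, match="not a stop"):
            translate_cds("ATGGCTGCTTAA", _orf(readthrough_positions=[2]))

    def test_orf_must_end_in_stop(self):
        with pytest.raises(TranslationError, match="stop"):
            translate_cds("ATGGCTGCT", _orf())

    def test_n_codon_translates_to_x(self):
        assert translate_cds("ATGGNTTAA", _orf()).peptide == "MX"


class TestFrameshift:
    def test_no_event_is_identity(self):
        assert apply_frameshift("ATGAAATAG", None) == "ATGAAATAG"

    def test_plus_one_skips_one_base(self):
        assert apply_frameshift("ATGAAACGGTTAG", Frameshift(2)) == "ATGAAAGGTTAG"

    def test_shift_after_final_codon_errors(self):
        with pytest.raises(TranslationError, match="resume"):
            apply_frameshift("ATGTAG", Frameshift(2))

    def test_only_plus_one_supported(self):
        with pytest.raises(Exception, match=r"\+1"):
            Frameshift(codon_index=2, shift=2)


class TestIncompleteStop:
    def test_trailing_t_completed(self):
        code = genetic_code("invertebrate_mitochondrial")
        assert complete_incomplete_stop("ATGGCTT", code) == ("ATGGCTTAA", True)

    def test_trailing_ta_completed(self):
        code = genetic_code("invertebrate_mitochondrial")
        assert complete_incomplete_stop("ATGGCTTA", code) == ("ATGGCTTAA", True)

    def test_impossible_completion_errors(self):
        code = genetic_code("invertebrate_mitochondrial")
        with pytest.raises(TranslationError, match="polyadenylation"):
            complete_incomplete_stop("ATGGCTGG", code)


class TestGeneticCode:
    def test_standard_stops(self):
        code = genetic_code("standard")
        assert code.is_stop("TGA") and code.is_stop("TAA") and code.is_stop("TAG")

    def test_invertebrate_mitochondrial_reassignments(self):
        code = genetic_code("invertebrate_mitochondrial")
        assert code.translate_codon("TGA") == "W"
        assert code.translate_codon("ATA") == "M"
        assert code.translate_codon("AGA") == "S"
        assert not code.is_stop("TGA")

    def test_both_codes_map_atg_to_m(self):
        for cid in ("standard", "invertebrate_mitochondrial"):
            assert genetic_code(cid).translate_codon("ATG") == "M"

    def test_unknown_code_rejected(self):
        with pytest.raises(TranslationError):
            genetic_code("vertebrate_mitochondrial")


class TestOracleEquivalence:
    def test_exception_free_orfs_match_biopython(self):
        """1,000 random valid ORFs: peptides equal Biopython's translation."""
        rng = random.Random(20240731)
        non_stop = [
            a + b + c
            for a in "ACGT"
            for b in "ACGT"
            for c in "ACGT"
            if a + b + c not in ("TAA", "TAG", "TGA")
        ]
        for _ in range(1000):
            n = rng.randint(1, 40)
            cds = "ATG" + "".join(rng.choice(non_stop) for _ in range(n)) + rng.choice(
                ["TAA", "TAG", "TGA"]
            )
            ours = translate_cds(cds, _orf()).peptide
            naive = str(Seq(cds).translate())
            assert naive.endswith("*")
            assert ours == naive[:-1]

    def test_peptide_length_bookkeeping(self, fixture1, audit1):
        """len(peptide) = (effective CDS length − 3) / 3 for every fixture ORF."""
        from gffaudit.model import orf_sequence

        for tid in fixture1.aset.transcripts:
            t = fixture1.aset.transcripts[tid]
            for orf in t.orfs:
                eff = len(orf_sequence(orf, fixture1.genome))
                if orf.incomplete_stop:
                    eff += 3 - eff % 3
                if orf.frameshift is not None:
                    eff -= 1
                pep = audit1.translations[f"{tid}:{orf.gene_id}"].peptide
                assert len(pep) == (eff - 3) // 3

    def test_u_and_x_only_at_declared_positions(self, fixture1, audit1):
        for tid in fixture1.aset.transcripts:
            t = fixture1.aset.transcripts[tid]
            for orf in t.orfs:
                pep = audit1.translations[f"{tid}:{orf.gene_id}"].peptide
                u_at = {i + 1 for i, aa in enumerate(pep) if aa == "U"}
                x_at = {i + 1 for i, aa in enumerate(pep) if aa == "X"}
                assert u_at == set(orf.selenocysteine_positions)
                assert x_at == set(orf.readthrough_positions)
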