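"""Controlled vocabularies for flagging exceptional gene models.

Gene-level classes are Sequence Ontology (SO) terms; transcript-level flags
and gene-model comments are standardized strings used verbatim in reports
and FASTA headers.  The strings here are the exchange format — downstream
consumers match them character for character, so they must never be edited.
"""

from __future__ import annotations

# ---------------------------------------------------------------------------
# Gene-level Sequence Ontology terms
# ---------------------------------------------------------------------------

GENE_SO_TERMS: dict[str, str] = {
    "gene_with_dicistronic_mRNA": "SO:0000722",
    "gene_with_polycistronic_transcript": "SO:0000690",
    "gene_with_trans_spliced_transcript": "SO:0000459",
    "gene_with_unconventional_translation_start_codon": "SO:0001739",
    "gene_with_translation_start_codon_CUG": "SO:0001740",
    "gene_with_stop_codon_redefined_as_selenocysteine": "SO:0000710",
    "gene_with_stop_codon_read_through": "SO:0000697",
    "gene_with_transcript_with_translational_frameshift": "SO:0000712",
    "mt_gene": "SO:0000088",
    "gene_with_edited_transcript": "SO:0000548",
}

#: Site-level SO term attached to individual A-to-I editing positions.
MODIFIED_RNA_BASE_FEATURE = ("modified_RNA_base_feature", "SO:0000250")

SO_ID_TO_TERM = {v: k for k, v in GENE_SO_TERMS.items()}

# ---------------------------------------------------------------------------
# Transcript-level flags (FASTA bulk-file vocabulary)
# ---------------------------------------------------------------------------

FLAG_DICISTRONIC = "dicistronic_mRNA"
FLAG_POLYCISTRONIC = "polycistronic_transcript"
FLAG_NONCANONICAL_SPLICE = "non_canonical_splice_site"
FLAG_ENDONUCLEASE_SPLICED = "endonuclease_spliced_intron"
FLAG_TRANS_SPLICED = "trans_spliced_transcript"
FLAG_NON_AUG_START = "non-canonical_start_codon"  # hyphen is part of the token
FLAG_SELENOCYSTEINE = "stop_codon_redefined_as_selenocysteine"
FLAG_READTHROUGH = "stop_codon_read_through"
FLAG_FRAMESHIFT = "transcript_with_translational_frameshift"
FLAG_MITO_CODE = "mitochondrial_genetic_code"
FLAG_MITO_INCOMPLETE_STOP = "mitochondrial_incomplete_stop_codon"
FLAG_START_NOT_DETERMINED = "start_codon_not_determined"
FLAG_MUTATION_IN_STRAIN = "mutation in strain"
FLAG_SEQUENCE_ERROR_OR_GAP = "genomic sequence error or gap"

TRANSCRIPT_FLAG_TYPES: dict[str, str] = {
    FLAG_DICISTRONIC: "Transcript exception",
    FLAG_POLYCISTRONIC: "Transcript exception",
    FLAG_NONCANONICAL_SPLICE: "Transcript exception",
    FLAG_ENDONUCLEASE_SPLICED: "Transcript exception",
    FLAG_TRANS_SPLICED: "Transcript exception",
    FLAG_NON_AUG_START: "Translation exception",
    FLAG_SELENOCYSTEINE: "Translation exception",
    FLAG_READTHROUGH: "Translation exception",
    FLAG_FRAMESHIFT: "Translation exception",
    FLAG_MITO_CODE: "Translation exception",
    FLAG_MITO_INCOMPLETE_STOP: "Translation exception",
    FLAG_START_NOT_DETERMINED: "Translation exception",
    FLAG_MUTATION_IN_STRAIN: "Sequence alteration",
    FLAG_SEQUENCE_ERROR_OR_GAP: "Sequence alteration",
}

TRANSCRIPT_FLAGS = frozenset(TRANSCRIPT_FLAG_TYPES)

#: Flags that may appear in input annotations as declarations (everything
#: detectable is recomputed by the auditor; these are passed through).
DECLARABLE_FLAGS = frozenset(
    {
        FLAG_TRANS_SPLICED,
        FLAG_ENDONUCLEASE_SPLICED,
        FLAG_MUTATION_IN_STRAIN,
        FLAG_SEQUENCE_ERROR_OR_GAP,
    }
)

#: Declarations that mark an intron as a representational convenience
#: (gene model interrupted by a transposon insertion, sequence gap, or
#: strain-variable heterochromatin) rather than a supported splice.
CONVENIENCE_FLAGS = frozenset({FLAG_MUTATION_IN_STRAIN, FLAG_SEQUENCE_ERROR_OR_GAP})

# ---------------------------------------------------------------------------
# Standardized gene-model comments
# ---------------------------------------------------------------------------

COMMENT_SHARES_5_UTR = "Shares 5′ UTR"
COMMENT_SHARES_3_UTR = "Shares 3′ UTR"
COMMENT_SHARES_5_EXONS = "Shares 5′ exon(s)"
COMMENT_COMPLEX_ATYPICAL = "Complex/atypical overlap"
COMMENT_CDS_OVERLAP_PREFIX = "Genes with CDS overlap"

COMMENT_MULTIPHASIC_ALT_STOP = (
    "Alternative translation stop created by use of multiphasic reading "
    "frames within coding region"
)
COMMENT_MULTIPHASIC_EXON = (
    "Multiphase exon postulated: exon reading frame differs in alternative transcripts"
)
COMMENT_MULTIPHASIC_FIRST_EXON = (
    "Multiphase exon postulated: reading frame of first coding exon differs "
    "in alternative transcripts"
)
COMMENT_MULTIPHASIC_CROSS_GENE = (
    "Multiphase exon postulated: this gene shares a region of coding sequence "
    "with an overlapping gene, but different reading frames are utilized in "
    "the overlapping coding region"
)
COMMENT_BIDIRECTIONAL = (
    "Bidirectional region of coding sequence postulated: a portion of the CDS "
    "of this gene overlaps a portion of the CDS of a gene on opposite strand."
)
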