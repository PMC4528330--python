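"""Bind classifications to the controlled flag vocabularies and emit output.

Gene-level classes become Sequence Ontology assignments; transcript-level
classes become the exact bulk-file flag tokens.  Everything emitted here
string-matches the vocabularies in :mod:`gffaudit.vocab` character for
character (including ``non-canonical_start_codon``, whose hyphen/underscore
mix is part of the token).
"""

from __future__ import annotations

import dataclasses
import json
from typing import Mapping, Optional

from .model import AnnotationSet, GenomeSequence, TranscriptModel, spliced_sequence
from .translate import TranslationResult
from .vocab import (
    FLAG_DICISTRONIC,
    FLAG_ENDONUCLEASE_SPLICED,
    FLAG_FRAMESHIFT,
    FLAG_MITO_CODE,
    FLAG_MITO_INCOMPLETE_STOP,
    FLAG_MUTATION_IN_STRAIN,
    FLAG_NON_AUG_START,
    FLAG_NONCANONICAL_SPLICE,
    FLAG_POLYCISTRONIC,
    FLAG_READTHROUGH,
    FLAG_SELENOCYSTEINE,
    FLAG_SEQUENCE_ERROR_OR_GAP,
    FLAG_START_NOT_DETERMINED,
    FLAG_TRANS_SPLICED,
    GENE_SO_TERMS,
)


@dataclasses.dataclass(frozen=True)
class FlagAssignment:
    """One flag bound to a gene or transcript."""

    target_id: str
    level: str  # "gene_SO" | "transcript_flag" | "comment"
    token: str
    so_id: Optional[str] = None
    provenance: str = "detected"  # or "declared"


@dataclasses.dataclass
class GeneClassification:
    """Per-gene classification summary feeding SO-term assignment."""

    gene_id: str
    arity_set: set[int] = dataclasses.field(default_factory=set)
    trans_spliced: bool = False
    non_aug_start_codons: set[str] = dataclasses.field(default_factory=set)
    selenocysteine: bool = False
    readthrough: bool = False
    frameshift: bool = False
    mitochondrial: bool = False
    edited: bool = False


@dataclasses.dataclass
class TranscriptClassification:
    """Per-transcript classification summary feeding flag assignment."""

    transcript_id: str
    arity: int = 0
    noncanonical_splice: bool = False
    endonuclease_spliced: bool = False
    endonuclease_declared: bool = False
    trans_spliced: bool = False
    non_aug_start: bool = False
    selenocysteine: bool = False
    readthrough: bool = False
    frameshift: bool = False
    mitochondrial_code: bool = False
    incomplete_stop: bool = False
    start_not_determined: bool = False
    passthrough: list[str] = dataclasses.field(default_factory=list)


def assign_gene_so_terms(
    gene_id: str, classification: GeneClassification
) -> list[FlagAssignment]:
    """SO terms for one gene given its classification summary."""
    tokens: list[str] = []
    if 2 in classification.arity_set:
        tokens.append("gene_with_dicistronic_mRNA")
    if any(a >= 3 for a in classification.arity_set):
        tokens.append("gene_with_polycistronic_transcript")
    if classification.trans_spliced:
        tokens.append("gene_with_trans_spliced_transcript")
    if classification.non_aug_start_codons:
        tokens.append("gene_with_unconventional_translation_start_codon")
        if "CTG" in classification.non_aug_start_codons:
            tokens.append("gene_with_translation_start_codon_CUG")
    if classification.selenocysteine:
        tokens.append("gene_with_stop_codon_redefined_as_selenocysteine")
    if classification.readthrough:
        tokens.append("gene_with_stop_codon_read_through")
    if classification.frameshift:
        tokens.append("gene_with_transcript_with_translational_frameshift")
    if classification.mitochondrial:
        tokens.append("mt_gene")
    if classification.edited:
        tokens.append("gene_with_edited_transcript")
    out = []
    for token in tokens:
        try:
            so_id = GENE_SO_TERMS[token]
        except KeyError:
            raise ValueError(f"unknown gene classification token {token!r}") from None
        out.append(
            FlagAssignment(target_id=gene_id, level="gene_SO", token=token, so_id=so_id)
        )
    return out


def assign_transcript_flags(
    t: TranscriptModel, classification: TranscriptClassification
) -> list[FlagAssignment]:
    """Bulk-file flag tokens for one transcript, in vocabulary order."""
    flags: list[tuple[str, str]] = []
    if classification.arity == 2:
        flags.append((FLAG_DICISTRONIC, "detected"))
    elif classification.arity >= 3:
        flags.append((FLAG_POLYCISTRONIC, "detected"))
    if classification.noncanonical_splice:
        flags.append((FLAG_NONCANONICAL_SPLICE, "detected"))
    if classification.endonuclease_spliced:
        prov = "declared" if classification.endonuclease_declared else "detected"
        flags.append((FLAG_ENDONUCLEASE_SPLICED, prov))
    if classification.trans_spliced:
        flags.append((FLAG_TRANS_SPLICED, "declared"))
    if classification.non_aug_start:
        flags.append((FLAG_NON_AUG_START, "declared"))
    if classification.selenocysteine:
        flags.append((FLAG_SELENOCYSTEINE, "declared"))
    if classification.readthrough:
        flags.append((FLAG_READTHROUGH, "declared"))
    if classification.frameshift:
        flags.append((FLAG_FRAMESHIFT, "declared"))
    if classification.mitochondrial_code:
        flags.append((FLAG_MITO_CODE, "detected"))
    if classification.incomplete_stop:
        flags.append((FLAG_MITO_INCOMPLETE_STOP, "declared"))
    if classification.start_not_determined:
        flags.append((FLAG_START_NOT_DETERMINED, "declared"))
    for token in (FLAG_MUTATION_IN_STRAIN, FLAG_SEQUENCE_ERROR_OR_GAP):
        if token in classification.passthrough:
            flags.append((token, "declared"))
    return [
        FlagAssignment(
            target_id=t.transcript_id, level="transcript_flag", token=tok, provenance=prov
        )
        for tok, prov in flags
    ]


# ---------------------------------------------------------------------------
# Output emission
# ---------------------------------------------------------------------------


def _wrap(seq: str, width: int = 60) -> str:
    return "\n".join(seq[i : i + width] for i in range(0, len(seq), width))


def emit_flagged_fasta(
    aset: AnnotationSet,
    genome: GenomeSequence,
    translations: Mapping[str, TranslationResult],
    transcript_flags: Mapping[str, list[FlagAssignment]],
) -> str:
    """FASTA with one nucleotide record per transcript and one protein
    record per ORF.  Headers carry space-separated ``key=value`` fields with
    semicolon-joined flag tokens; field order is fixed, so output is
    byte-identical across runs on the same inputs."""
    blocks: list[str] = []
    for tid in sorted(aset.transcripts):
        t = aset.transcripts[tid]
        tokens = ";".join(a.token for a in transcript_flags.get(tid, []))
        header = f">{tid} genes={','.join(t.gene_ids)} flags={tokens}"
        blocks.append(header + "\n" + _wrap(spliced_sequence(t, genome)))
    for key in sorted(translations):
        tid, gene_id = key.split(":", 1)
        tokens = ";".join(
            a.token
            for a in transcript_flags.get(tid, [])
            if a.token != ""
        )
        result = translations[key]
        header = f">{key} gene={gene_id} transcript={tid} flags={tokens}"
        blocks.append(header + "\n" + _wrap(result.peptide))
    return "\n".join(blocks) + "\n"


def emit_report(payload: dict) -> str:
    """Serialize the audit report to JSON with stable key order."""
    return json.dumps(payload, indent=2, sort_keys=True) + "\n"
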