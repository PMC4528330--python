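"""Derive polypeptides from annotated ORFs under declared translation exceptions.

The rules implemented here:

* a declared non-AUG start codon is translated as methionine (initiation
  uses Met-tRNAi regardless of the codon's elongation meaning);
* a declared stop-codon readthrough places ``X`` at the suppressed stop and
  translation continues;
* a declared selenocysteine recoding places ``U`` (Sec) at the UGA codon;
* a declared +1 ribosomal frameshift skips one template base after the
  declared codon before translation resumes;
* a mitochondrial incomplete stop codon (a trailing ``T`` or ``TA``) is
  completed to ``TAA`` as happens on 3' polyadenylation;
* mitochondrial ORFs use the invertebrate mitochondrial genetic code
  (NCBI translation table 5);
* an undetermined start codon is translated from the annotated first codon
  and recorded as a caveat, not forced to methionine;
* codons containing N translate to ``X``.

Translation must end at the first *undeclared* in-frame stop, and that stop
must be the ORF's final codon; anything else is an annotation inconsistency
and raises :class:`TranslationError`.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

from Bio.Data import CodonTable

from .model import (
    Frameshift,
    GenomeSequence,
    OrfAnnotation,
    TranscriptModel,
    orf_sequence,
)


class TranslationError(ValueError):
    """Annotation and sequence disagree about how to translate an ORF."""


@dataclasses.dataclass(frozen=True)
class GeneticCode:
    """Complete codon→amino-acid table plus stop set."""

    code_id: str
    table: dict[str, str]  # 64 codons → single-letter amino acid ('*' for stop)
    stop_codons: frozenset[str]

    def translate_codon(self, codon: str) -> str:
        if "N" in codon:
            return "X"
        return self.table[codon]

    def is_stop(self, codon: str) -> bool:
        return codon in self.stop_codons


_NCBI_TABLE_IDS = {"standard": 1, "invertebrate_mitochondrial": 5}


def genetic_code(code_id: str) -> GeneticCode:
    """Build a :class:`GeneticCode` from the NCBI tables (1 or 5)."""
    if code_id not in _NCBI_TABLE_IDS:
        raise TranslationError(f"unknown genetic code {code_id!r}")
    ncbi = CodonTable.unambiguous_dna_by_id[_NCBI_TABLE_IDS[code_id]]
    table = dict(ncbi.forward_table)
    for stop in ncbi.stop_codons:
        table[stop] = "*"
    assert len(table) == 64
    return GeneticCode(
        code_id=code_id, table=table, stop_codons=frozenset(ncbi.stop_codons)
    )


@dataclasses.dataclass
class TranslationResult:
    peptide: str
    events: list[tuple[str, int]]  # (event kind, 1-based codon index; 0 = whole ORF)
    completed_stop: bool = False

    def event_kinds(self) -> set[str]:
        return {kind for kind, _ in self.events}


def apply_frameshift(cds_nt: str, event: Optional[Frameshift]) -> str:
    """Effective coding sequence after a +1 ribosomal frameshift: bases up to
    the end of the declared codon, skip one, then the remainder."""
    if event is None:
        return cds_nt
    if event.shift != 1:
        raise TranslationError("only +1 frameshifts are supported")
    cut = 3 * event.codon_index
    if cut + 1 >= len(cds_nt):
        raise TranslationError(
            f"frameshift after codon {event.codon_index} leaves no sequence "
            "to resume translation"
        )
    return cds_nt[:cut] + cds_nt[cut + 1 :]


def complete_incomplete_stop(cds_nt: str, code: GeneticCode) -> tuple[str, bool]:
    """Complete a 3'-truncated stop codon by appending adenosines.

    Mitochondrial transcripts may end in ``T`` or ``TA``; polyadenylation
    completes the codon to ``TAA``.  Any other remainder cannot form a stop
    this way and is an error.
    """
    rem = len(cds_nt) % 3
    if rem == 0:
        raise TranslationError(
            "CDS flagged with an incomplete stop codon has no trailing remainder"
        )
    tail = cds_nt[-rem:]
    if tail == "T":
        return cds_nt + "AA", True
    if tail == "TA":
        return cds_nt + "A", True
    raise TranslationError(
        f"trailing {tail!r} cannot be completed to a TAA stop by polyadenylation"
    )


def translate_cds(
    cds_nt: str,
    orf: OrfAnnotation,
    code: Optional[GeneticCode] = None,
) -> TranslationResult:
    """Translate an effective-CDS nucleotide string under ``orf``'s declared
    exceptions.  ``cds_nt`` is the annotated CDS sequence (stop included,
    before frameshift/stop-completion, which are applied here)."""
    if code is None:
        code = genetic_code(orf.genetic_code)
    events: list[tuple[str, int]] = []
    completed = False
    if orf.incomplete_stop:
        cds_nt, completed = complete_incomplete_stop(cds_nt, code)
        events.append(("incomplete_stop_completed", 0))
    if orf.frameshift is not None:
        cds_nt = apply_frameshift(cds_nt, orf.frameshift)
        events.append(("frameshift", orf.frameshift.codon_index))
    if len(cds_nt) % 3:
        raise TranslationError(
            f"effective CDS length {len(cds_nt)} is not a multiple of 3"
        )
    n_codons = len(cds_nt) // 3
    if n_codons < 2:
        raise TranslationError("CDS shorter than two codons")
    readthrough = set(orf.readthrough_positions)
    selenocysteine = set(orf.selenocysteine_positions)
    for idx in sorted(readthrough | selenocysteine):
        if not 1 <= idx < n_codons:
            raise TranslationError(
                f"declared exception at codon {idx} is outside the ORF"
            )
    peptide = []
    for i in range(n_codons - 1):
        codon = cds_nt[3 * i : 3 * i + 3]
        index1 = i + 1
        if i == 0:
            peptide.append(_translate_start(codon, orf, code, events))
            continue
        if index1 in selenocysteine:
            if codon != "TGA":
                raise TranslationError(
                    f"selenocysteine declared at codon {index1}, but the codon "
                    f"is {codon!r}, not TGA"
                )
            peptide.append("U")
            events.append(("selenocysteine", index1))
            continue
        if index1 in readthrough:
            if not code.is_stop(codon):
                raise TranslationError(
                    f"readthrough declared at codon {index1}, but {codon!r} "
                    "is not a stop codon"
                )
            peptide.append("X")
            events.append(("readthrough", index1))
            continue
        if code.is_stop(codon):
            raise TranslationError(
                f"undeclared internal stop codon {codon!r} at codon {index1}"
            )
        peptide.append(code.translate_codon(codon))
    final = cds_nt[-3:]
    if not code.is_stop(final):
        raise TranslationError(
            f"ORF does not end in a stop codon (final codon {final!r})"
        )
    return TranslationResult(
        peptide="".join(peptide), events=events, completed_stop=completed
    )


def _translate_start(
    codon: str, orf: OrfAnnotation, code: GeneticCode, events: list
) -> str:
    kind = orf.start_codon_kind
    if kind == "undetermined":
        events.append(("start_codon_not_determined", 1))
        if code.is_stop(codon):
            raise TranslationError("annotated first codon is a stop codon")
        return code.translate_codon(codon)
    if kind == "AUG":
        if codon != "ATG":
            raise TranslationError(
                f"first codon is {codon!r} but no non-AUG start is declared"
            )
        return "M"
    declared = kind.replace("U", "T")
    if codon != declared:
        raise TranslationError(
            f"declared start codon {kind!r} does not match sequence {codon!r}"
        )
    events.append(("non_aug_start", 1))
    return "M"  # initiation pairs the near-cognate codon with Met-tRNAi


def translate_orf(
    orf: OrfAnnotation, t: TranscriptModel, genome: GenomeSequence
) -> TranslationResult:
    """Translate an annotated ORF of transcript ``t`` against the genome."""
    return translate_cds(orf_sequence(orf, genome), orf)


def next_in_frame_stop(
    seq: str, offset: int, code: Optional[GeneticCode] = None
) -> Optional[int]:
    """Index of the first in-frame stop codon at or after ``offset`` in
    ``seq`` (a plus-strand nucleotide string), or None.  Utility for
    constructing candidate readthrough extensions."""
    if code is None:
        code = genetic_code("standard")
    for i in range(offset, len(seq) - 2, 3):
        if code.is_stop(seq[i : i + 3]):
            return i
    return None
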