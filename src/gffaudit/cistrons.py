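"""Cistronic arity of transcripts and genes, and intercistronic metrics.

A transcript's arity is the number of ORFs it carries (mono=1, di=2, tri=3,
tetra=4).  Distances between consecutive cistrons are measured on the
mature transcript: the number of nucleotides between the last base of the
upstream stop codon and the first base of the downstream start codon, so an
immediately adjacent start scores 0 and coding regions overlapping in
different frames score negative.
"""

from __future__ import annotations

import dataclasses
from itertools import combinations

from .model import (
    AnnotationSet,
    AnnotationError,
    OrfAnnotation,
    TranscriptModel,
)

SMALL_BIN_UNDER_25 = "<25 aa"
SMALL_BIN_25_45 = "25–45 aa"
SMALL_BIN_OVER_45 = ">45 aa"


@dataclasses.dataclass
class CistronicProfile:
    gene_id: str
    arity_set: set[int]
    exclusively_polycistronic: bool

    def __post_init__(self) -> None:
        assert self.exclusively_polycistronic == (1 not in self.arity_set)


def cistronic_arity(t: TranscriptModel) -> int:
    """Number of cistrons (ORFs) on the transcript."""
    return len(t.orfs)


def gene_cistronic_profile(gene_id: str, aset: AnnotationSet) -> CistronicProfile:
    """Arity profile of a gene over all of its transcripts.

    A gene is exclusively polycistronic when it has no monocistronic
    isoform; noncoding isoforms (arity of the transcript counted over all
    its ORFs) do not contribute a monocistronic arity.
    """
    transcripts = aset.transcripts_of(gene_id)  # raises for unknown gene
    arities = {cistronic_arity(t) for t in transcripts if t.orfs}
    return CistronicProfile(
        gene_id=gene_id,
        arity_set=arities,
        exclusively_polycistronic=1 not in arities,
    )


def intercistronic_distance(
    upstream: OrfAnnotation, downstream: OrfAnnotation, t: TranscriptModel
) -> int:
    """Signed mature-transcript distance between two cistrons of ``t``.

    Defined as (transcript coordinate of the first base of the downstream
    start codon) − (transcript coordinate of the last base of the upstream
    stop codon) − 1.  Zero when the start abuts the stop; negative when the
    coding regions overlap in different frames.
    """
    if upstream not in t.orfs or downstream not in t.orfs:
        raise AnnotationError(
            f"both ORFs must belong to transcript {t.transcript_id!r}"
        )
    index = t.transcript_index()
    up_last = index[upstream.genomic_positions()[-1]]
    down_first = index[downstream.genomic_positions()[0]]
    if down_first <= index[upstream.genomic_positions()[0]]:
        raise AnnotationError("upstream ORF must precede downstream ORF on the transcript")
    return down_first - up_last - 1


def small_polypeptide_class(o: OrfAnnotation) -> str:
    """Size bin of the predicted polypeptide (stop codon excluded).

    Small-protein genes are binned as under 25 aa, 25–45 aa, or over 45 aa;
    the boundaries are inclusive on the 25–45 side.
    """
    length_nt = o.cds_length
    if o.incomplete_stop:
        length_nt += 3 - length_nt % 3  # completed stop
    if o.frameshift is not None:
        length_nt -= 1  # skipped template base
    n_aa = length_nt // 3 - 1
    if n_aa < 25:
        return SMALL_BIN_UNDER_25
    if n_aa <= 45:
        return SMALL_BIN_25_45
    return SMALL_BIN_OVER_45


def shared_transcript_pairs(aset: AnnotationSet) -> list[tuple[tuple[str, str], int]]:
    """Unordered unique gene pairs co-occurring on at least one transcript,
    with the number of shared transcripts for each pair."""
    counts: dict[tuple[str, str], int] = {}
    for tid in sorted(aset.transcripts):
        t = aset.transcripts[tid]
        for a, b in combinations(sorted(set(t.gene_ids)), 2):
            counts[(a, b)] = counts.get((a, b), 0) + 1
    return sorted(counts.items())


def transcript_intercistronic_distances(
    t: TranscriptModel,
) -> list[tuple[str, str, int]]:
    """(upstream gene, downstream gene, distance) for consecutive ORF pairs."""
    out = []
    for up, down in zip(t.orfs, t.orfs[1:]):
        out.append((up.gene_id, down.gene_id, intercistronic_distance(up, down, t)))
    return out
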