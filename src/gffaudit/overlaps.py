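"""Classify coding and noncoding overlaps between gene models.

Same-strand coding overlaps partition base-by-base into *same-frame*
(codon offsets agree; the shared-CDS gene-fusion pattern) and *multiphasic*
(offsets disagree; more than one reading frame in use).  Opposite-strand
coding overlaps are *bidirectional*.  Noncoding overlaps are classified by
which ends of the gene models are shared (5' exons/promoter, 3' UTR, both,
nested-in-intron, or a 3'-UTR-over-5'-UTR chain, the last two of which are
not flagged).
"""

from __future__ import annotations

import dataclasses
from typing import Optional

from .config import AuditConfig
from .model import AnnotationError, AnnotationSet, GenomicInterval, OrfAnnotation, TranscriptModel
from .vocab import (
    COMMENT_BIDIRECTIONAL,
    COMMENT_CDS_OVERLAP_PREFIX,
    COMMENT_COMPLEX_ATYPICAL,
    COMMENT_MULTIPHASIC_ALT_STOP,
    COMMENT_MULTIPHASIC_CROSS_GENE,
    COMMENT_MULTIPHASIC_EXON,
    COMMENT_MULTIPHASIC_FIRST_EXON,
    COMMENT_SHARES_3_UTR,
    COMMENT_SHARES_5_EXONS,
    COMMENT_SHARES_5_UTR,
)


@dataclasses.dataclass
class MultiphasicRegion:
    """Maximal run of genomic bases coding in two ORFs in different frames."""

    interval: GenomicInterval
    length_nt: int
    members: tuple[str, str]  # gene ids of the two ORFs
    involves_first_coding_exon: bool
    cross_gene: bool
    includes_stop: bool
    transcript_members: tuple[str, str] = ("", "")
    long_overlap: bool = False
    comment: str = ""

    def __post_init__(self) -> None:
        assert self.length_nt == len(self.interval) >= 1


@dataclasses.dataclass
class OverlapCall:
    genes: tuple[str, str]
    category: str
    comment: str = ""
    length_nt: int = 0
    intervals: list[GenomicInterval] = dataclasses.field(default_factory=list)


def codon_offset_map(
    o: OrfAnnotation, t: Optional[TranscriptModel] = None
) -> dict[int, int]:
    """Genomic position → codon offset (0/1/2) for every CDS base of ``o``.

    The offset is the base's index within the spliced coding sequence mod 3,
    so offsets continue across introns and, on the minus strand, increase
    with decreasing genomic coordinate.  Assumes a single-contig CDS.
    """
    positions = o.genomic_positions()
    seqids = {s for s, _ in positions}
    if len(seqids) != 1:
        raise AnnotationError("codon offsets require a single-contig CDS")
    return {pos: i % 3 for i, (_, pos) in enumerate(positions)}


def _maximal_runs(positions: set[int]) -> list[tuple[int, int]]:
    """Half-open (start, end) runs of consecutive integers."""
    runs = []
    for pos in sorted(positions):
        if runs and pos == runs[-1][1]:
            runs[-1][1] = pos + 1
        else:
            runs.append([pos, pos + 1])
    return [tuple(r) for r in runs]


def _stop_positions(o: OrfAnnotation) -> set[int]:
    return {pos for _, pos in o.genomic_positions()[-3:]}


def _start_codon_positions(o: OrfAnnotation) -> set[int]:
    """First-codon bases: a region containing an ORF's translation start is
    what makes it a first-coding-exon frame conflict."""
    return {pos for _, pos in o.genomic_positions()[:3]}


def multiphasic_regions(
    a: OrfAnnotation, b: OrfAnnotation, aset: Optional[AnnotationSet] = None
) -> list[MultiphasicRegion]:
    """Maximal genomic runs coding in both ORFs with unequal codon offsets.

    Symmetric in (a, b).  Raises for opposite-strand ORFs — those belong to
    :func:`detect_bidirectional`.
    """
    strand_a = {seg.strand for seg in a.cds_segments}
    strand_b = {seg.strand for seg in b.cds_segments}
    if strand_a != strand_b:
        raise AnnotationError(
            "multiphasic classification applies to same-strand ORFs; use "
            "detect_bidirectional for opposite strands"
        )
    seqid = a.cds_segments[0].seqid
    if seqid != b.cds_segments[0].seqid:
        return []
    map_a = codon_offset_map(a)
    map_b = codon_offset_map(b)
    conflict = {
        pos for pos in map_a.keys() & map_b.keys() if map_a[pos] != map_b[pos]
    }
    strand = a.cds_segments[0].strand
    stops = _stop_positions(a) | _stop_positions(b)
    first_exons = _start_codon_positions(a) | _start_codon_positions(b)
    regions = []
    for start, end in _maximal_runs(conflict):
        run = set(range(start, end))
        regions.append(
            MultiphasicRegion(
                interval=GenomicInterval(seqid, start, end, strand),
                length_nt=end - start,
                members=(a.gene_id, b.gene_id),
                involves_first_coding_exon=bool(run & first_exons),
                cross_gene=a.gene_id != b.gene_id,
                includes_stop=bool(run & stops),
            )
        )
    return regions


def classify_multiphasic(
    r: MultiphasicRegion, config: Optional[AuditConfig] = None
) -> str:
    """Standardized comment for a multiphasic region; also sets
    ``r.long_overlap`` when the extent exceeds the long-overlap threshold
    (more than 20 amino acids).

    Cross-gene regions always take the cross-gene comment (the short-extent
    rule is a within-gene rule); within a gene, involvement of the first
    coding exon takes precedence over the short-extent alternative-stop
    comment.
    """
    cfg = config or AuditConfig()
    r.long_overlap = r.length_nt > cfg.long_overlap_nt
    if r.cross_gene:
        comment = COMMENT_MULTIPHASIC_CROSS_GENE
    elif r.involves_first_coding_exon:
        comment = COMMENT_MULTIPHASIC_FIRST_EXON
    elif r.length_nt < cfg.multiphasic_short_nt and r.includes_stop:
        comment = COMMENT_MULTIPHASIC_ALT_STOP
    else:
        comment = COMMENT_MULTIPHASIC_EXON
    r.comment = comment
    return comment


def aa_bound_for_extent(max_nt_exclusive: int = 40) -> int:
    """Strict amino-acid upper bound implied by a multiphasic extent below
    ``max_nt_exclusive`` nucleotides when the extent includes the stop codon.

    An extent of at most ``max_nt_exclusive − 1`` nt spans at most
    ``⌊(max_nt_exclusive − 1)/3⌋`` codons, one of which is the stop, so the
    encoded amino acids number strictly fewer than that codon count.
    With the default threshold of 40 nt this gives 13.
    """
    return (max_nt_exclusive - 1) // 3


def detect_bidirectional(
    a: OrfAnnotation, b: OrfAnnotation
) -> Optional[OverlapCall]:
    """Opposite-strand CDS intersection, with the standardized comment."""
    strand_a = {seg.strand for seg in a.cds_segments}
    strand_b = {seg.strand for seg in b.cds_segments}
    if strand_a == strand_b:
        raise AnnotationError(
            "bidirectional classification applies to opposite-strand ORFs"
        )
    seqid = a.cds_segments[0].seqid
    if seqid != b.cds_segments[0].seqid:
        return None
    pos_a = {pos for _, pos in a.genomic_positions()}
    pos_b = {pos for _, pos in b.genomic_positions()}
    shared = pos_a & pos_b
    if not shared:
        return None
    runs = _maximal_runs(shared)
    return OverlapCall(
        genes=(a.gene_id, b.gene_id),
        category="bidirectional",
        comment=COMMENT_BIDIRECTIONAL,
        length_nt=len(shared),
        intervals=[GenomicInterval(seqid, s, e, "+") for s, e in runs],
    )


# ---------------------------------------------------------------------------
# Noncoding and same-frame overlaps between genes
# ---------------------------------------------------------------------------


def _five_prime_exon(t: TranscriptModel) -> GenomicInterval:
    return t.exons[0]


def _three_prime_exon(t: TranscriptModel) -> GenomicInterval:
    return t.exons[-1]


def _five_prime_start(exon: GenomicInterval) -> int:
    return exon.start if exon.strand == "+" else exon.end


def _cds_positions_of_gene(gene_id: str, aset: AnnotationSet) -> set[int]:
    out: set[int] = set()
    for _, orf in aset.orfs_of(gene_id):
        out.update(pos for _, pos in orf.genomic_positions())
    return out


def _intron_intervals(t: TranscriptModel) -> list[GenomicInterval]:
    ivs = []
    for prev, nxt in zip(t.exons, t.exons[1:]):
        if prev.seqid != nxt.seqid or prev.strand != nxt.strand:
            continue
        start, end = (prev.end, nxt.start) if prev.strand == "+" else (nxt.end, prev.start)
        ivs.append(GenomicInterval(prev.seqid, start, end, prev.strand))
    return ivs


def classify_noncoding_overlap(
    gene_a: str,
    gene_b: str,
    aset: AnnotationSet,
    config: Optional[AuditConfig] = None,
) -> OverlapCall:
    """Classify a same-strand overlap between two genes sharing no CDS base.

    Categories: ``shared_5_exons`` (identical 5'-terminal exon, or identical
    5' exon start, i.e. a shared promoter), ``shared_3_utr`` (identical
    3'-terminal exon), ``complex_atypical`` (both ends), ``nested_unflagged``
    (one gene inside an intron of the other) and ``utr_chain_unflagged``
    (3' UTR of the upstream gene over the 5' UTR of the downstream gene);
    the last two carry no comment.
    """
    cfg = config or AuditConfig()
    ta_list = aset.transcripts_of(gene_a)
    tb_list = aset.transcripts_of(gene_b)
    shared5_exon = shared_promoter = shared3 = False
    for ta in ta_list:
        for tb in tb_list:
            if ta.seqid != tb.seqid or ta.strand != tb.strand:
                continue
            e5a, e5b = _five_prime_exon(ta), _five_prime_exon(tb)
            if e5a == e5b:
                shared5_exon = True
            elif cfg.shared_promoter_exact and _five_prime_start(e5a) == _five_prime_start(e5b):
                shared_promoter = True
            if _three_prime_exon(ta) == _three_prime_exon(tb):
                shared3 = True
    shared5 = shared5_exon or shared_promoter
    pair = tuple(sorted((gene_a, gene_b)))
    if shared5 and shared3:
        return OverlapCall(pair, "complex_atypical", COMMENT_COMPLEX_ATYPICAL)
    if shared5_exon:
        return OverlapCall(pair, "shared_5_exons", COMMENT_SHARES_5_EXONS)
    if shared_promoter:
        return OverlapCall(pair, "shared_5_exons", COMMENT_SHARES_5_UTR)
    if shared3:
        return OverlapCall(pair, "shared_3_utr", COMMENT_SHARES_3_UTR)
    # nested: one gene's span inside an intron of the other, same strand
    span_a = aset.genes[gene_a].span
    span_b = aset.genes[gene_b].span
    for host, guest_span in ((gene_b, span_a), (gene_a, span_b)):
        for t in aset.transcripts_of(host):
            for intron in _intron_intervals(t):
                if intron.strand == guest_span.strand and intron.contains(guest_span):
                    return OverlapCall(pair, "nested_unflagged", "")
    if _is_utr_chain(gene_a, gene_b, aset):
        return OverlapCall(pair, "utr_chain_unflagged", "")
    return OverlapCall(pair, "none", "")


def _is_utr_chain(gene_a: str, gene_b: str, aset: AnnotationSet) -> bool:
    """Upstream gene's CDS ends strictly 5' of the downstream gene's CDS
    start while their spans overlap — the 3'-UTR-over-5'-UTR chain."""
    cds_a = _cds_positions_of_gene(gene_a, aset)
    cds_b = _cds_positions_of_gene(gene_b, aset)
    if not cds_a or not cds_b:
        return False
    span_a = aset.genes[gene_a].span
    strand = span_a.strand
    if strand == "+":
        up, down = (
            (cds_a, cds_b) if min(cds_a) <= min(cds_b) else (cds_b, cds_a)
        )
        return max(up) < min(down)
    up, down = (cds_a, cds_b) if max(cds_a) >= max(cds_b) else (cds_b, cds_a)
    return min(up) > max(down)


def detect_cds_overlap_same_frame(
    gene_a: str, gene_b: str, aset: AnnotationSet
) -> Optional[OverlapCall]:
    """Maximal shared-CDS runs where the codon offsets of the two genes
    agree (shared reading frame), as in N-terminal gene fusions."""
    shared_pos: set[int] = set()
    seqid = None
    for _, oa in aset.orfs_of(gene_a):
        for _, ob in aset.orfs_of(gene_b):
            sa = {seg.strand for seg in oa.cds_segments}
            sb = {seg.strand for seg in ob.cds_segments}
            if sa != sb or oa.cds_segments[0].seqid != ob.cds_segments[0].seqid:
                continue
            map_a = codon_offset_map(oa)
            map_b = codon_offset_map(ob)
            seqid = oa.cds_segments[0].seqid
            shared_pos.update(
                pos
                for pos in map_a.keys() & map_b.keys()
                if map_a[pos] == map_b[pos]
            )
    if not shared_pos:
        return None
    runs = _maximal_runs(shared_pos)
    length = len(shared_pos)
    comment = (
        f"{COMMENT_CDS_OVERLAP_PREFIX}: genes share {length} nt of coding "
        "sequence in the same reading frame"
    )
    return OverlapCall(
        genes=tuple(sorted((gene_a, gene_b))),
        category="cds_overlap_same_frame",
        comment=comment,
        length_nt=length,
        intervals=[GenomicInterval(seqid, s, e, "+") for s, e in runs],
    )
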