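"""Small builders for hand-constructed gene models in tests."""

from gffaudit.model import (
    AnnotationSet,
    GeneRecord,
    GenomicInterval,
    OrfAnnotation,
    TranscriptModel,
)


def iv(start, end, strand="+", seqid="c"):
    return GenomicInterval(seqid, start, end, strand)


def orf(gene_id, *segments):
    return OrfAnnotation(gene_id, list(segments))


def transcript(tid, gene_ids, exons, orfs=()):
    return TranscriptModel(tid, list(gene_ids), list(exons), list(orfs))


def aset_of(*transcripts):
    aset = AnnotationSet()
    for t in transcripts:
        aset.transcripts[t.transcript_id] = t
        for gid in t.gene_ids:
            rec = aset.genes.get(gid)
            if rec is None:
                rec = GeneRecord(gid, t.span(), [])
                aset.genes[gid] = rec
            else:
                sp = rec.span
                rec.span = GenomicInterval(
                    sp.seqid,
                    min(sp.start, t.span().start),
                    max(sp.end, t.span().end),
                    sp.strand,
                )
            rec.transcript_ids.append(t.transcript_id)
    return aset
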