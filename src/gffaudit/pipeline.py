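"""End-to-end annotation audit: classify every transcript, gene, intron,
overlap and junction, derive peptides, and emit reports."""

from __future__ import annotations

import dataclasses
from itertools import combinations
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from intervaltree import IntervalTree

from . import cistrons, overlaps, splices
from .config import AuditConfig
from .flags import (
    FlagAssignment,
    GeneClassification,
    TranscriptClassification,
    assign_gene_so_terms,
    assign_transcript_flags,
    emit_flagged_fasta,
    emit_report,
)
from .model import (
    AnnotationSet,
    GenomeSequence,
    IntronRecord,
    iter_all_introns,
)
from .translate import TranslationResult, translate_orf
from .vocab import CONVENIENCE_FLAGS, FLAG_ENDONUCLEASE_SPLICED, FLAG_TRANS_SPLICED


@dataclasses.dataclass
class AuditResult:
    aset: AnnotationSet
    genome: GenomeSequence
    config: AuditConfig
    gene_profiles: dict[str, cistrons.CistronicProfile]
    intercistronic: dict[str, list[tuple[str, str, int]]]  # tid → (up, down, nt)
    introns: list[IntronRecord]
    intron_similar: dict[str, Optional[str]]  # intron key → similar-splice key
    multiphasic: list[overlaps.MultiphasicRegion]
    overlap_calls: list[overlaps.OverlapCall]
    junction_audits: list[tuple[splices.JunctionCall, splices.JunctionDiagnosis]]
    census: pd.DataFrame
    translations: dict[str, TranslationResult]  # "tid:gene" → result
    gene_so: dict[str, list[FlagAssignment]]
    transcript_flags: dict[str, list[FlagAssignment]]
    editing_sites: list[tuple[str, int]]
    edited_genes: set[str]


def read_editing_sites(path: str | Path) -> list[tuple[str, int]]:
    """Tab-separated A-to-I editing sites: seqid, 1-based genomic position.
    Returned zero-based."""
    sites = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        seqid, pos = line.split("\t")[:2]
        sites.append((seqid, int(pos) - 1))
    return sites


def run_audit(
    genome: GenomeSequence,
    aset: AnnotationSet,
    junctions: Iterable[splices.JunctionCall] = (),
    editing_sites: Iterable[tuple[str, int]] = (),
    config: Optional[AuditConfig] = None,
) -> AuditResult:
    cfg = config or AuditConfig()
    aset.validate()
    genome.validate()
    junctions = list(junctions)
    editing_sites = list(editing_sites)

    # --- introns -----------------------------------------------------------
    introns = sorted(
        iter_all_introns(aset, genome), key=lambda r: (r.interval.seqid, r.interval.start)
    )
    intron_similar: dict[str, Optional[str]] = {}
    for rec in introns:
        declared: set[str] = set()
        for tid in rec.transcript_ids:
            declared.update(aset.transcripts[tid].declared_flags)
        label = splices.classify_intron(rec, declared, cfg)
        rec.classification = [label]
        if splices.tag_u12(rec, genome, cfg):
            rec.classification.append("U12")
        if label.startswith("noncanonical"):
            similar = splices.similar_alternative_splice(rec, aset, genome)
            intron_similar[rec.key] = similar.key if similar else None

    # --- translation -------------------------------------------------------
    translations: dict[str, TranslationResult] = {}
    for tid in sorted(aset.transcripts):
        t = aset.transcripts[tid]
        for orf in t.orfs:
            translations[f"{tid}:{orf.gene_id}"] = translate_orf(orf, t, genome)

    # --- cistronic profiles ------------------------------------------------
    gene_profiles = {
        gid: cistrons.gene_cistronic_profile(gid, aset) for gid in sorted(aset.genes)
    }
    intercistronic = {
        tid: cistrons.transcript_intercistronic_distances(aset.transcripts[tid])
        for tid in sorted(aset.transcripts)
        if len(aset.transcripts[tid].orfs) >= 2
    }

    # --- overlaps ----------------------------------------------------------
    multiphasic, overlap_calls = _classify_overlaps(aset, cfg)

    # --- junctions ---------------------------------------------------------
    auditor = splices.JunctionAuditor(aset, genome, cfg)
    junction_audits = [(j, auditor.audit(j)) for j in junctions]

    # --- census ------------------------------------------------------------
    census = splices.splice_summary(aset, genome, junctions, cfg)

    # --- A-to-I editing passthrough ---------------------------------------
    edited_genes: set[str] = set()
    for seqid, pos in editing_sites:
        for gid, gene in aset.genes.items():
            sp = gene.span
            if sp.seqid == seqid and sp.start <= pos < sp.end:
                edited_genes.add(gid)

    # --- flag assignment ---------------------------------------------------
    transcript_cls = _transcript_classifications(aset, introns)
    transcript_flags = {
        tid: assign_transcript_flags(aset.transcripts[tid], transcript_cls[tid])
        for tid in sorted(aset.transcripts)
    }
    gene_cls = _gene_classifications(aset, gene_profiles, edited_genes)
    gene_so = {
        gid: assign_gene_so_terms(gid, gene_cls[gid]) for gid in sorted(aset.genes)
    }

    return AuditResult(
        aset=aset,
        genome=genome,
        config=cfg,
        gene_profiles=gene_profiles,
        intercistronic=intercistronic,
        introns=introns,
        intron_similar=intron_similar,
        multiphasic=multiphasic,
        overlap_calls=overlap_calls,
        junction_audits=junction_audits,
        census=census,
        translations=translations,
        gene_so=gene_so,
        transcript_flags=transcript_flags,
        editing_sites=editing_sites,
        edited_genes=edited_genes,
    )


# ---------------------------------------------------------------------------
# Overlap orchestration
# ---------------------------------------------------------------------------


def _classify_overlaps(
    aset: AnnotationSet, cfg: AuditConfig
) -> tuple[list[overlaps.MultiphasicRegion], list[overlaps.OverlapCall]]:
    regions: dict[tuple, overlaps.MultiphasicRegion] = {}
    calls: list[overlaps.OverlapCall] = []

    def add_regions(found, ta_id: str, tb_id: str) -> None:
        for r in found:
            overlaps.classify_multiphasic(r, cfg)
            key = (r.interval, tuple(sorted(r.members)), r.comment)
            if key not in regions:
                r.transcript_members = (ta_id, tb_id)
                regions[key] = r

    # within-gene: alternative isoforms of one gene using different frames
    for gid in sorted(aset.genes):
        entries = aset.orfs_of(gid)
        for (ta, oa), (tb, ob) in combinations(entries, 2):
            if ta.transcript_id == tb.transcript_id:
                continue
            if oa.cds_segments == ob.cds_segments:
                continue
            sa = {seg.strand for seg in oa.cds_segments}
            sb = {seg.strand for seg in ob.cds_segments}
            if sa != sb:
                continue
            add_regions(
                overlaps.multiphasic_regions(oa, ob), ta.transcript_id, tb.transcript_id
            )

    # cross-gene, on shared (polycistronic) transcripts
    shared_pairs: set[tuple[str, str]] = set()
    for tid in sorted(aset.transcripts):
        t = aset.transcripts[tid]
        for oa, ob in combinations(t.orfs, 2):
            shared_pairs.add(tuple(sorted((oa.gene_id, ob.gene_id))))
            add_regions(overlaps.multiphasic_regions(oa, ob), tid, tid)

    # gene pairs with overlapping spans (not sharing a transcript)
    trees: dict[str, IntervalTree] = {}
    for gid in sorted(aset.genes):
        sp = aset.genes[gid].span
        trees.setdefault(sp.seqid, IntervalTree()).addi(sp.start, sp.end, gid)
    seen_pairs: set[tuple[str, str]] = set()
    for gid in sorted(aset.genes):
        sp = aset.genes[gid].span
        for hit in trees[sp.seqid].overlap(sp.start, sp.end):
            other = hit.data
            if other == gid:
                continue
            pair = tuple(sorted((gid, other)))
            if pair in seen_pairs or pair in shared_pairs:
                continue
            seen_pairs.add(pair)
            calls.extend(_classify_gene_pair(pair[0], pair[1], aset, cfg, add_regions))

    ordered = sorted(
        regions.values(), key=lambda r: (r.interval.seqid, r.interval.start, r.members)
    )
    calls.sort(key=lambda c: c.genes)
    return ordered, calls


def _classify_gene_pair(
    gene_a: str, gene_b: str, aset: AnnotationSet, cfg: AuditConfig, add_regions
) -> list[overlaps.OverlapCall]:
    strands_a = {t.strand for t in aset.transcripts_of(gene_a)}
    strands_b = {t.strand for t in aset.transcripts_of(gene_b)}
    calls: list[overlaps.OverlapCall] = []
    if strands_a != strands_b:
        # opposite strands: bidirectional coding overlap or nothing
        seen = set()
        for ta, oa in aset.orfs_of(gene_a):
            for tb, ob in aset.orfs_of(gene_b):
                sa = {seg.strand for seg in oa.cds_segments}
                sb = {seg.strand for seg in ob.cds_segments}
                if sa == sb:
                    continue
                call = overlaps.detect_bidirectional(oa, ob)
                if call is not None and tuple(sorted(call.genes)) not in seen:
                    seen.add(tuple(sorted(call.genes)))
                    calls.append(call)
        return calls
    # same strand: partition any shared CDS into same-frame and multiphasic
    shared_cds = False
    for ta, oa in aset.orfs_of(gene_a):
        for tb, ob in aset.orfs_of(gene_b):
            sa = {seg.strand for seg in oa.cds_segments}
            sb = {seg.strand for seg in ob.cds_segments}
            if sa != sb:
                continue
            map_a = overlaps.codon_offset_map(oa)
            map_b = overlaps.codon_offset_map(ob)
            if oa.cds_segments[0].seqid == ob.cds_segments[0].seqid and (
                map_a.keys() & map_b.keys()
            ):
                shared_cds = True
            add_regions(
                overlaps.multiphasic_regions(oa, ob), ta.transcript_id, tb.transcript_id
            )
    if shared_cds:
        call = overlaps.detect_cds_overlap_same_frame(gene_a, gene_b, aset)
        if call is not None:
            calls.append(call)
        return calls
    call = overlaps.classify_noncoding_overlap(gene_a, gene_b, aset, cfg)
    if call.category != "none":
        calls.append(call)
    return calls


# ---------------------------------------------------------------------------
# Classification summaries
# ---------------------------------------------------------------------------


def _transcript_classifications(
    aset: AnnotationSet, introns: list[IntronRecord]
) -> dict[str, TranscriptClassification]:
    by_tid: dict[str, list[IntronRecord]] = {}
    for rec in introns:
        for tid in rec.transcript_ids:
            by_tid.setdefault(tid, []).append(rec)
    out: dict[str, TranscriptClassification] = {}
    for tid in sorted(aset.transcripts):
        t = aset.transcripts[tid]
        cls = TranscriptClassification(transcript_id=tid, arity=cistrons.cistronic_arity(t))
        for rec in by_tid.get(tid, []):
            primary = rec.classification[0]
            if primary.startswith("noncanonical"):
                cls.noncanonical_splice = True
            if primary == "endonuclease_spliced":
                cls.endonuclease_spliced = True
        if FLAG_ENDONUCLEASE_SPLICED in t.declared_flags:
            cls.endonuclease_spliced = True
            cls.endonuclease_declared = True
        cls.trans_spliced = FLAG_TRANS_SPLICED in t.declared_flags
        for orf in t.orfs:
            if orf.start_codon_kind == "undetermined":
                cls.start_not_determined = True
            elif orf.start_codon_kind != "AUG":
                cls.non_aug_start = True
            if orf.selenocysteine_positions:
                cls.selenocysteine = True
            if orf.readthrough_positions:
                cls.readthrough = True
            if orf.frameshift is not None:
                cls.frameshift = True
            if orf.genetic_code == "invertebrate_mitochondrial":
                cls.mitochondrial_code = True
            if orf.incomplete_stop:
                cls.incomplete_stop = True
        cls.passthrough = [f for f in t.declared_flags if f in CONVENIENCE_FLAGS]
        out[tid] = cls
    return out


def _gene_classifications(
    aset: AnnotationSet,
    gene_profiles: dict[str, cistrons.CistronicProfile],
    edited_genes: set[str],
) -> dict[str, GeneClassification]:
    out: dict[str, GeneClassification] = {}
    for gid in sorted(aset.genes):
        cls = GeneClassification(gene_id=gid, arity_set=gene_profiles[gid].arity_set)
        for t in aset.transcripts_of(gid):
            if FLAG_TRANS_SPLICED in t.declared_flags:
                cls.trans_spliced = True
        for _, orf in aset.orfs_of(gid):
            if orf.start_codon_kind not in {"AUG", "undetermined"}:
                cls.non_aug_start_codons.add(orf.start_codon_kind.replace("U", "T"))
            if orf.selenocysteine_positions:
                cls.selenocysteine = True
            if orf.readthrough_positions:
                cls.readthrough = True
            if orf.frameshift is not None:
                cls.frameshift = True
            if orf.genetic_code == "invertebrate_mitochondrial":
                cls.mitochondrial = True
        cls.edited = gid in edited_genes
        out[gid] = cls
    return out


# ---------------------------------------------------------------------------
# Report emission
# ---------------------------------------------------------------------------


def report_payload(result: AuditResult) -> dict:
    """JSON-serializable audit report with stable content."""
    genes = {}
    for gid in sorted(result.aset.genes):
        profile = result.gene_profiles[gid]
        genes[gid] = {
            "arity_set": sorted(profile.arity_set),
            "exclusively_polycistronic": profile.exclusively_polycistronic,
            "so_terms": [[a.token, a.so_id] for a in result.gene_so[gid]],
        }
    transcripts = {}
    for tid in sorted(result.aset.transcripts):
        t = result.aset.transcripts[tid]
        transcripts[tid] = {
            "genes": t.gene_ids,
            "arity": len(t.orfs),
            "flags": [a.token for a in result.transcript_flags[tid]],
            "intercistronic_nt": [
                list(x) for x in result.intercistronic.get(tid, [])
            ],
        }
    introns = {
        rec.key: {
            "donor": rec.donor,
            "acceptor": rec.acceptor,
            "classification": rec.classification,
            "transcripts": sorted(rec.transcript_ids),
            "similar_alternative": result.intron_similar.get(rec.key),
        }
        for rec in result.introns
    }
    multiphasic = [
        {
            "seqid": r.interval.seqid,
            "start": r.interval.start + 1,  # report coordinates 1-based inclusive
            "end": r.interval.end,
            "length_nt": r.length_nt,
            "members": list(r.members),
            "transcripts": list(r.transcript_members),
            "cross_gene": r.cross_gene,
            "includes_stop": r.includes_stop,
            "involves_first_coding_exon": r.involves_first_coding_exon,
            "long_overlap": r.long_overlap,
            "comment": r.comment,
        }
        for r in result.multiphasic
    ]
    overlap_calls = [
        {
            "genes": list(c.genes),
            "category": c.category,
            "comment": c.comment,
            "length_nt": c.length_nt,
        }
        for c in result.overlap_calls
    ]
    junctions = [
        {
            "seqid": j.seqid,
            "start": j.start,
            "end": j.end,
            "strand": j.strand,
            "read_count": j.read_count,
            "score": j.score,
            "verdict": d.verdict,
            "nearest_intron": d.nearest_intron,
            "offset": d.offset,
        }
        for j, d in result.junction_audits
    ]
    peptides = {key: r.peptide for key, r in sorted(result.translations.items())}
    return {
        "genes": genes,
        "transcripts": transcripts,
        "introns": introns,
        "multiphasic_regions": multiphasic,
        "overlaps": overlap_calls,
        "junction_audits": junctions,
        "census": {
            row: {col: int(result.census.loc[row, col]) for col in result.census.columns}
            for row in result.census.index
        },
        "peptides": peptides,
        "editing": {
            "sites": [[s, p + 1] for s, p in result.editing_sites],
            "genes": sorted(result.edited_genes),
        },
        "counts": {
            "genes": len(result.aset.genes),
            "transcripts": len(result.aset.transcripts),
            "introns": len(result.introns),
            "multiphasic_regions": len(result.multiphasic),
            "overlap_calls": len(result.overlap_calls),
            "junctions": len(result.junction_audits),
        },
    }


def write_outputs(result: AuditResult, out_dir: str | Path) -> None:
    """Write report.json, TSV tables, and the flagged FASTA, byte-stably."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = report_payload(result)
    (out / "report.json").write_text(emit_report(payload))
    (out / "flagged.fasta").write_text(
        emit_flagged_fasta(
            result.aset, result.genome, result.translations, result.transcript_flags
        )
    )
    result.census.to_csv(out / "splice_census.tsv", sep="\t")
    _table(payload["genes"], "gene_id").to_csv(out / "genes.tsv", sep="\t", index=False)
    _table(payload["transcripts"], "transcript_id").to_csv(
        out / "transcripts.tsv", sep="\t", index=False
    )
    _table(payload["introns"], "intron").to_csv(out / "introns.tsv", sep="\t", index=False)
    pd.DataFrame(payload["multiphasic_regions"]).to_csv(
        out / "multiphasic.tsv", sep="\t", index=False
    )
    pd.DataFrame(payload["overlaps"]).to_csv(out / "overlaps.tsv", sep="\t", index=False)
    pd.DataFrame(payload["junction_audits"]).to_csv(
        out / "junction_audits.tsv", sep="\t", index=False
    )


def _table(mapping: dict, key_name: str) -> pd.DataFrame:
    rows = []
    for key in sorted(mapping):
        row = {key_name: key}
        for col, val in mapping[key].items():
            row[col] = val if not isinstance(val, (list, dict)) else repr(val)
        rows.append(row)
    return pd.DataFrame(rows)
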