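"""Deterministic toy genomes with planted exceptional gene models.

The generator writes a random-background genome, a GFF3 annotation with one
gene model per requested exception category, optional junction calls and
A-to-I editing sites, and a ground-truth manifest listing every expected
classification, flag token and peptide.  The same seed reproduces the same
bytes.  Planted ORFs are kept free of accidental in-frame stops by
rejection sampling, so expected peptides are computable at planting time.
"""

from __future__ import annotations

import dataclasses
import json
import random
from pathlib import Path
from typing import Callable, Optional

from Bio.Data import CodonTable

from . import vocab
from .model import (
    AnnotationSet,
    GeneRecord,
    GenomeSequence,
    GenomicInterval,
    OrfAnnotation,
    Frameshift,
    TranscriptModel,
    write_annotation,
    write_genome,
)
from .splices import JunctionCall, write_junctions_bed

_BASES = "ACGT"


def _code_table(table_id: int) -> dict[str, str]:
    ncbi = CodonTable.unambiguous_dna_by_id[table_id]
    table = dict(ncbi.forward_table)
    for stop in ncbi.stop_codons:
        table[stop] = "*"
    return table


_STD = _code_table(1)
_MITO = _code_table(5)
_STD_NONSTOP = sorted(c for c, aa in _STD.items() if aa != "*")
_MITO_NONSTOP = sorted(c for c, aa in _MITO.items() if aa != "*")


# ---------------------------------------------------------------------------
# Specification and container
# ---------------------------------------------------------------------------


def _default_noncanonical() -> dict[str, int]:
    pairs = {p: 1 for p in ("GT-TG", "GT-GG", "GT-CG", "GT-AT", "GT-AA", "GA-AG")}
    pairs.update({"AT-AC (U12)": 1, "AT-AC (U2)": 1, "GT-AG (U12)": 1})
    return pairs


@dataclasses.dataclass
class FixtureSpec:
    """Counts of planted exception categories (defaults: one of each)."""

    seed: int = 0
    contig_length: int = 14000
    mito_contig_length: int = 900
    mono: int = 2
    dicistronic: int = 1
    tricistronic: int = 1
    tetracistronic: int = 1
    dicistronic_overlap: int = 1  # cross-gene multiphasic on one transcript
    shared_5: int = 1
    shared_3: int = 1
    multiphasic_short: int = 1
    multiphasic_long: int = 1
    bidirectional: int = 1
    noncanonical: dict[str, int] = dataclasses.field(
        default_factory=_default_noncanonical
    )
    hac1: int = 1
    trans_splice: int = 1
    cug_start: int = 1
    sec: int = 1
    readthrough: int = 1
    double_readthrough: int = 1
    frameshift: int = 1
    mito_incomplete_stop: int = 1
    undetermined_start: int = 1
    convenience: int = 1
    editing_sites: int = 2

    @classmethod
    def empty(cls, seed: int = 0, contig_length: int = 1000) -> "FixtureSpec":
        zero = {
            f.name: 0
            for f in dataclasses.fields(cls)
            if f.name not in {"seed", "contig_length", "mito_contig_length", "noncanonical"}
        }
        return cls(
            seed=seed,
            contig_length=contig_length,
            mito_contig_length=0,
            noncanonical={},
            **zero,
        )


@dataclasses.dataclass
class Fixture:
    genome: GenomeSequence
    aset: AnnotationSet
    junctions: list[JunctionCall]
    editing_sites: list[tuple[str, int]]
    manifest: dict


# ---------------------------------------------------------------------------
# Sequence sampling helpers
# ---------------------------------------------------------------------------


def _rand_seq(rng: random.Random, n: int) -> str:
    return "".join(rng.choice(_BASES) for _ in range(n))


def _clean_cds(cds: str, stops: frozenset[str]) -> bool:
    if len(cds) % 3:
        return False
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    return all(c not in stops for c in codons[:-1]) and codons[-1] in stops


_STD_STOPS = frozenset({"TAA", "TAG", "TGA"})
_MITO_STOPS = frozenset({"TAA", "TAG"})


def _sample_segment(
    rng: random.Random,
    length: int,
    forced: dict[int, str],
    predicates: list[Callable[[str], bool]],
    max_tries: int = 50000,
) -> str:
    for _ in range(max_tries):
        chars = list(_rand_seq(rng, length))
        for pos in sorted(forced):
            text = forced[pos]
            chars[pos : pos + len(text)] = list(text)
        seq = "".join(chars)
        if len(seq) != length:
            raise ValueError("forced bases extend beyond the segment")
        if all(p(seq) for p in predicates):
            return seq
    raise RuntimeError("could not satisfy planting constraints; segment too tight")


def _orf_nt(rng: random.Random, n_codons: int, mito: bool = False) -> str:
    """ATG + (n_codons − 2) random non-stop codons + TAA."""
    pool = _MITO_NONSTOP if mito else _STD_NONSTOP
    body = "".join(rng.choice(pool) for _ in range(n_codons - 2))
    return "ATG" + body + "TAA"


def _peptide(
    cds: str,
    code: Optional[dict[str, str]] = None,
    start: str = "M",
    sec: tuple[int, ...] = (),
    readthrough: tuple[int, ...] = (),
) -> str:
    """Expected peptide for a planted effective CDS (stop included).

    ``start``: 'M' forces methionine at codon 1; None translates the first
    codon by the table (undetermined start).  ``sec``/``readthrough`` are
    1-based codon indices recoded U / X.
    """
    table = code or _STD
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    out = []
    for i, codon in enumerate(codons[:-1], start=1):
        if i == 1:
            out.append(table[codon] if start is None else "M")
        elif i in sec:
            out.append("U")
        elif i in readthrough:
            out.append("X")
        else:
            out.append(table[codon])
    return "".join(out)


# ---------------------------------------------------------------------------
# Block assembly
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class _Block:
    """One planted locus in local coordinates (offset at registration)."""

    seq: str
    transcripts: list[TranscriptModel] = dataclasses.field(default_factory=list)
    junctions: list[dict] = dataclasses.field(default_factory=list)
    intron_classes: list[tuple[int, int, str, str, list[str]]] = dataclasses.field(
        default_factory=list
    )  # (start, end, strand, pair, classification)
    similar_alt: list[tuple[tuple[int, int, str], Optional[tuple[int, int, str]]]] = (
        dataclasses.field(default_factory=list)
    )
    gene_so: dict[str, list[str]] = dataclasses.field(default_factory=dict)
    transcript_flags: dict[str, list[str]] = dataclasses.field(default_factory=dict)
    peptides: dict[str, str] = dataclasses.field(default_factory=dict)
    multiphasic: list[dict] = dataclasses.field(default_factory=list)
    overlaps: list[dict] = dataclasses.field(default_factory=list)
    intercistronic: dict[str, list[list]] = dataclasses.field(default_factory=dict)


def _mirror_block(block: _Block) -> _Block:
    """Flip a locally plus-strand block onto the minus strand."""
    L = len(block.seq)

    def flip_iv(iv: GenomicInterval) -> GenomicInterval:
        return GenomicInterval(
            iv.seqid, L - iv.end, L - iv.start, "-" if iv.strand == "+" else "+"
        )

    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    block.seq = "".join(comp[b] for b in reversed(block.seq))
    for t in block.transcripts:
        t.exons = [flip_iv(e) for e in t.exons]
        for orf in t.orfs:
            orf.cds_segments = [flip_iv(s) for s in orf.cds_segments]
    block.junctions = [
        {
            **j,
            "start": L - j["end"],
            "end": L - j["start"],
            "strand": (
                None
                if j["strand"] is None
                else ("-" if j["strand"] == "+" else "+")
            ),
        }
        for j in block.junctions
    ]
    block.intron_classes = [
        (L - e, L - s, "-" if st == "+" else "+", pair, cls)
        for s, e, st, pair, cls in block.intron_classes
    ]

    def flip_key(key):
        if key is None:
            return None
        s, e, st = key
        return (L - e, L - s, "-" if st == "+" else "+")

    block.similar_alt = [(flip_key(a), flip_key(b)) for a, b in block.similar_alt]
    return block


class _FixtureBuilder:
    def __init__(self, spec: FixtureSpec) -> None:
        self.spec = spec
        self.rng = random.Random(spec.seed)
        self.contig_parts: dict[str, list[str]] = {}
        self.cursor: dict[str, int] = {}
        self.aset = AnnotationSet()
        self.junctions: list[JunctionCall] = []
        self.expected: dict = {
            "gene_so": {},
            "transcript_flags": {},
            "peptides": {},
            "intron_classes": {},
            "similar_alternative": {},
            "multiphasic": [],
            "overlaps": [],
            "intercistronic": {},
            "junction_verdicts": [],
            "editing_genes": [],
        }
        self.entries: list[dict] = []
        self._gene_n = 0
        self._tx_n = 0
        self._artifact_intron: Optional[tuple[str, int, int, str]] = None
        self._editing_target: Optional[str] = None

    # -- identifiers --------------------------------------------------------

    def gid(self) -> str:
        self._gene_n += 1
        return f"g{self._gene_n:04d}"

    def tid(self) -> str:
        self._tx_n += 1
        return f"t{self._tx_n:04d}"

    # -- registration -------------------------------------------------------

    def _plant(self, contig: str, block: _Block, category: str) -> int:
        parts = self.contig_parts.setdefault(contig, [])
        if contig not in self.cursor:
            self.cursor[contig] = 0
        spacer = _rand_seq(self.rng, self.rng.randint(25, 45))
        parts.append(spacer)
        base = self.cursor[contig] + len(spacer)
        parts.append(block.seq)
        self.cursor[contig] = base + len(block.seq)

        def shift(iv: GenomicInterval) -> GenomicInterval:
            return GenomicInterval(contig, iv.start + base, iv.end + base, iv.strand)

        gene_spans: dict[str, list[GenomicInterval]] = {}
        for t in block.transcripts:
            t.exons = [shift(e) for e in t.exons]
            for orf in t.orfs:
                orf.cds_segments = [shift(s) for s in orf.cds_segments]
            self.aset.transcripts[t.transcript_id] = t
            for gid in t.gene_ids:
                gene_spans.setdefault(gid, []).extend(t.exons)
        for gid, exons in gene_spans.items():
            span = GenomicInterval(
                contig,
                min(e.start for e in exons),
                max(e.end for e in exons),
                exons[0].strand,
            )
            if gid not in self.aset.genes:
                self.aset.genes[gid] = GeneRecord(gene_id=gid, span=span)
            for t in block.transcripts:
                if gid in t.gene_ids:
                    if t.transcript_id not in self.aset.genes[gid].transcript_ids:
                        self.aset.genes[gid].transcript_ids.append(t.transcript_id)
        for j in block.junctions:
            call = JunctionCall(
                seqid=contig,
                start=j["start"] + base,
                end=j["end"] + base,
                strand=j["strand"],
                read_count=j["count"],
                score=j["score"],
            )
            self.junctions.append(call)
            self.expected["junction_verdicts"].append(
                {
                    "seqid": contig,
                    "start": call.start,
                    "end": call.end,
                    "strand": call.strand,
                    "read_count": call.read_count,
                    "verdict": j["verdict"],
                }
            )
        for s, e, st, pair, cls in block.intron_classes:
            key = f"{contig}:{s + base}-{e + base}:{st}"
            self.expected["intron_classes"][key] = {"pair": pair, "classification": cls}

        def global_key(local) -> Optional[str]:
            if local is None:
                return None
            s, e, st = local
            return f"{contig}:{s + base}-{e + base}:{st}"

        for intron_local, alt_local in block.similar_alt:
            self.expected["similar_alternative"][global_key(intron_local)] = global_key(
                alt_local
            )
        self.expected["gene_so"].update(block.gene_so)
        self.expected["transcript_flags"].update(block.transcript_flags)
        self.expected["peptides"].update(block.peptides)
        self.expected["multiphasic"].extend(block.multiphasic)
        self.expected["overlaps"].extend(block.overlaps)
        self.expected["intercistronic"].update(block.intercistronic)
        self.entries.append(
            {
                "category": category,
                "contig": contig,
                "start": base,
                "end": base + len(block.seq),
                "genes": sorted(
                    {g for t in block.transcripts for g in t.gene_ids}
                ),
                "transcripts": [t.transcript_id for t in block.transcripts],
            }
        )
        return base

    # -- small construction helpers ----------------------------------------

    def _single_exon_transcript(
        self,
        gid: str,
        tid: str,
        total: int,
        cds_start: int,
        cds_end: int,
        **orf_kwargs,
    ) -> TranscriptModel:
        exon = GenomicInterval("x", 0, total, "+")
        orf = OrfAnnotation(
            gene_id=gid,
            cds_segments=[GenomicInterval("x", cds_start, cds_end, "+")],
            **orf_kwargs,
        )
        return TranscriptModel(
            transcript_id=tid, gene_ids=[gid], exons=[exon], orfs=[orf]
        )

    # -- planters -----------------------------------------------------------

    def plant_mono(self, spliced: bool) -> None:
        """Unexceptional monocistronic gene; optionally two exons with a
        canonical GT-AG intron (the anchor for junction-artifact planting)."""
        gid, tid = self.gid(), self.tid()
        n_codons = self.rng.randint(20, 35)
        cds = _orf_nt(self.rng, n_codons)
        block = _Block(seq="")
        if not spliced:
            seq = _rand_seq(self.rng, 8) + cds + _rand_seq(self.rng, 8)
            block.seq = seq
            block.transcripts = [
                self._single_exon_transcript(gid, tid, len(seq), 8, 8 + len(cds))
            ]
        else:
            cut = 3 * self.rng.randint(4, n_codons - 4) + 1  # mid-codon split
            intron = "GTC" + _rand_seq(self.rng, 25) + "AG"
            e1_end = 8 + cut
            e2_start = e1_end + len(intron)
            seq = (
                _rand_seq(self.rng, 8)
                + cds[:cut]
                + intron
                + cds[cut:]
                + _rand_seq(self.rng, 8)
            )
            block.seq = seq
            exons = [
                GenomicInterval("x", 0, e1_end, "+"),
                GenomicInterval("x", e2_start, len(seq), "+"),
            ]
            orf = OrfAnnotation(
                gene_id=gid,
                cds_segments=[
                    GenomicInterval("x", 8, e1_end, "+"),
                    GenomicInterval("x", e2_start, e2_start + len(cds) - cut, "+"),
                ],
            )
            block.transcripts = [
                TranscriptModel(
                    transcript_id=tid, gene_ids=[gid], exons=exons, orfs=[orf]
                )
            ]
            block.intron_classes.append(
                (e1_end, e2_start, "+", "GT-AG", ["canonical_GT_AG"])
            )
        block.peptides[f"{tid}:{gid}"] = _peptide(cds)
        base = self._plant("ctg1", block, "mono")
        if self._editing_target is None:
            self._editing_target = gid
        if spliced and self._artifact_intron is None:
            e1_end = block.transcripts[0].exons[0].end
            e2_start = block.transcripts[0].exons[1].start
            self._artifact_intron = ("ctg1", e1_end, e2_start, "+")

    def plant_polycistronic(self, n_orfs: int) -> None:
        gids = [self.gid() for _ in range(n_orfs)]
        tid = self.tid()
        gap = 10
        parts = [_rand_seq(self.rng, 8)]
        orf_spans: list[tuple[int, int, str]] = []
        cursor = 8
        for i, gid in enumerate(gids):
            cds = _orf_nt(self.rng, self.rng.randint(12, 20))
            parts.append(cds)
            orf_spans.append((cursor, cursor + len(cds), cds))
            cursor += len(cds)
            if i < n_orfs - 1:
                parts.append(_rand_seq(self.rng, gap))
                cursor += gap
        parts.append(_rand_seq(self.rng, 8))
        seq = "".join(parts)
        exon = GenomicInterval("x", 0, len(seq), "+")
        orfs = [
            OrfAnnotation(
                gene_id=gid, cds_segments=[GenomicInterval("x", s, e, "+")]
            )
            for gid, (s, e, _) in zip(gids, orf_spans)
        ]
        t = TranscriptModel(transcript_id=tid, gene_ids=gids, exons=[exon], orfs=orfs)
        block = _Block(seq=seq, transcripts=[t])
        flag = (
            vocab.FLAG_DICISTRONIC if n_orfs == 2 else vocab.FLAG_POLYCISTRONIC
        )
        so = "SO:0000722" if n_orfs == 2 else "SO:0000690"
        block.transcript_flags[tid] = [flag]
        for gid, (_, _, cds) in zip(gids, orf_spans):
            block.gene_so[gid] = [so]
            block.peptides[f"{tid}:{gid}"] = _peptide(cds)
        block.intercistronic[tid] = [
            [gids[i], gids[i + 1], gap] for i in range(n_orfs - 1)
        ]
        category = {2: "dicistronic", 3: "tricistronic", 4: "tetracistronic"}[n_orfs]
        self._plant("ctg1", block, category)

    def plant_dicistronic_overlap(self) -> None:
        """Dicistronic transcript whose two ORFs overlap 70 nt in different
        frames (cross-gene multiphasic, long overlap)."""
        g_a, g_b = self.gid(), self.gid()
        tid = self.tid()
        utr = 8
        la, overlap, lb = 126, 70, 102
        a0 = utr
        b0 = a0 + la - overlap
        total = b0 + lb + utr
        forced = {
            a0: "ATG",
            a0 + la - 3: "TAA",
            b0: "ATG",
            b0 + lb - 3: "TAA",
        }
        preds = [
            lambda s: _clean_cds(s[a0 : a0 + la], _STD_STOPS),
            lambda s: _clean_cds(s[b0 : b0 + lb], _STD_STOPS),
        ]
        seq = _sample_segment(self.rng, total, forced, preds)
        exon = GenomicInterval("x", 0, total, "+")
        orf_a = OrfAnnotation(g_a, [GenomicInterval("x", a0, a0 + la, "+")])
        orf_b = OrfAnnotation(g_b, [GenomicInterval("x", b0, b0 + lb, "+")])
        t = TranscriptModel(tid, [g_a, g_b], [exon], [orf_a, orf_b])
        block = _Block(seq=seq, transcripts=[t])
        block.transcript_flags[tid] = [vocab.FLAG_DICISTRONIC]
        block.gene_so[g_a] = ["SO:0000722"]
        block.gene_so[g_b] = ["SO:0000722"]
        block.peptides[f"{tid}:{g_a}"] = _peptide(seq[a0 : a0 + la])
        block.peptides[f"{tid}:{g_b}"] = _peptide(seq[b0 : b0 + lb])
        block.intercistronic[tid] = [[g_a, g_b, -overlap]]
        block.multiphasic.append(
            {
                "members": sorted([g_a, g_b]),
                "length_nt": overlap,
                "comment": vocab.COMMENT_MULTIPHASIC_CROSS_GENE,
                "cross_gene": True,
                "long_overlap": True,
            }
        )
        self._plant("ctg1", block, "dicistronic_overlap")

    def plant_shared_5(self) -> None:
        """Two genes sharing an identical noncoding first exon."""
        g_a, g_b = self.gid(), self.gid()
        t_a, t_b = self.tid(), self.tid()
        cds_a = _orf_nt(self.rng, 14)
        cds_b = _orf_nt(self.rng, 16)
        e_sh = 30
        intron_a = "GTC" + _rand_seq(self.rng, 20) + "AG"
        exon2a = _rand_seq(self.rng, 6) + cds_a + _rand_seq(self.rng, 6)
        intron_b_tail = _rand_seq(self.rng, 18) + "AG"
        exon2b = _rand_seq(self.rng, 6) + cds_b + _rand_seq(self.rng, 6)
        seq = _rand_seq(self.rng, e_sh) + intron_a + exon2a + intron_b_tail + exon2b
        a2s = e_sh + len(intron_a)
        a2e = a2s + len(exon2a)
        b2s = a2e + len(intron_b_tail)
        b2e = b2s + len(exon2b)
        shared = GenomicInterval("x", 0, e_sh, "+")
        ta = TranscriptModel(
            t_a,
            [g_a],
            [shared, GenomicInterval("x", a2s, a2e, "+")],
            [OrfAnnotation(g_a, [GenomicInterval("x", a2s + 6, a2s + 6 + len(cds_a), "+")])],
        )
        tb = TranscriptModel(
            t_b,
            [g_b],
            [shared, GenomicInterval("x", b2s, b2e, "+")],
            [OrfAnnotation(g_b, [GenomicInterval("x", b2s + 6, b2s + 6 + len(cds_b), "+")])],
        )
        block = _Block(seq=seq, transcripts=[ta, tb])
        block.peptides[f"{t_a}:{g_a}"] = _peptide(cds_a)
        block.peptides[f"{t_b}:{g_b}"] = _peptide(cds_b)
        block.intron_classes.append((e_sh, a2s, "+", "GT-AG", ["canonical_GT_AG"]))
        block.intron_classes.append((e_sh, b2s, "+", "GT-AG", ["canonical_GT_AG"]))
        block.overlaps.append(
            {
                "genes": sorted([g_a, g_b]),
                "category": "shared_5_exons",
                "comment": vocab.COMMENT_SHARES_5_EXONS,
            }
        )
        self._plant("ctg1", block, "shared_5")

    def plant_shared_3(self) -> None:
        """Two genes sharing an identical noncoding last exon (3' UTR)."""
        g_a, g_b = self.gid(), self.gid()
        t_a, t_b = self.tid(), self.tid()
        cds_a = _orf_nt(self.rng, 14)
        cds_b = _orf_nt(self.rng, 12)
        exon1a = _rand_seq(self.rng, 6) + cds_a + _rand_seq(self.rng, 4)
        gap1 = "GTC" + _rand_seq(self.rng, 12)  # start of A's intron
        exon1b = _rand_seq(self.rng, 6) + cds_b + _rand_seq(self.rng, 4)
        gap2 = "GTC" + _rand_seq(self.rng, 12) + "AG"  # B's intron; shared acceptor
        e_sh = 30
        seq = exon1a + gap1 + exon1b + gap2 + _rand_seq(self.rng, e_sh)
        a1e = len(exon1a)
        b1s = a1e + len(gap1)
        b1e = b1s + len(exon1b)
        s3 = b1e + len(gap2)
        shared = GenomicInterval("x", s3, s3 + e_sh, "+")
        ta = TranscriptModel(
            t_a,
            [g_a],
            [GenomicInterval("x", 0, a1e, "+"), shared],
            [OrfAnnotation(g_a, [GenomicInterval("x", 6, 6 + len(cds_a), "+")])],
        )
        tb = TranscriptModel(
            t_b,
            [g_b],
            [GenomicInterval("x", b1s, b1e, "+"), shared],
            [OrfAnnotation(g_b, [GenomicInterval("x", b1s + 6, b1s + 6 + len(cds_b), "+")])],
        )
        block = _Block(seq=seq, transcripts=[ta, tb])
        block.peptides[f"{t_a}:{g_a}"] = _peptide(cds_a)
        block.peptides[f"{t_b}:{g_b}"] = _peptide(cds_b)
        block.intron_classes.append((a1e, s3, "+", "GT-AG", ["canonical_GT_AG"]))
        block.intron_classes.append((b1e, s3, "+", "GT-AG", ["canonical_GT_AG"]))
        block.overlaps.append(
            {
                "genes": sorted([g_a, g_b]),
                "category": "shared_3_utr",
                "comment": vocab.COMMENT_SHARES_3_UTR,
            }
        )
        self._plant("ctg1", block, "shared_3")

    def plant_multiphasic_within(self, region_nt: int) -> None:
        """One gene, two isoforms: isoform B uses an acceptor 4 nt upstream,
        shifting the frame of the next exon; the conflicting run ends at B's
        stop (region_nt long, stop included)."""
        gid = self.gid()
        t_a, t_b = self.tid(), self.tid()
        l1 = {0: 12, 1: 10, 2: 11}[(-(region_nt + 4)) % 3]
        e1 = 6 + l1
        intron_len = 20
        c = e1 + intron_len
        la2 = region_nt + [d for d in (9, 10, 11) if (l1 + region_nt + d) % 3 == 0][0]
        x_end = c + la2 + 8
        forced = {
            6: "ATG",
            e1: "GTC",
            c - 6: "AG",
            c - 2: "AG",
            c + region_nt - 3: "TAA",  # isoform B stop
            c + la2 - 3: "TAA",  # isoform A stop
        }

        def cds_a(s: str) -> str:
            return s[6:e1] + s[c : c + la2]

        def cds_b(s: str) -> str:
            return s[6:e1] + s[c - 4 : c + region_nt]

        preds = [
            lambda s: _clean_cds(cds_a(s), _STD_STOPS),
            lambda s: _clean_cds(cds_b(s), _STD_STOPS),
        ]
        seq = _sample_segment(self.rng, x_end, forced, preds)
        exon1 = GenomicInterval("x", 0, e1, "+")
        ta = TranscriptModel(
            t_a,
            [gid],
            [exon1, GenomicInterval("x", c, x_end, "+")],
            [
                OrfAnnotation(
                    gid,
                    [
                        GenomicInterval("x", 6, e1, "+"),
                        GenomicInterval("x", c, c + la2, "+"),
                    ],
                )
            ],
        )
        tb = TranscriptModel(
            t_b,
            [gid],
            [exon1, GenomicInterval("x", c - 4, x_end, "+")],
            [
                OrfAnnotation(
                    gid,
                    [
                        GenomicInterval("x", 6, e1, "+"),
                        GenomicInterval("x", c - 4, c + region_nt, "+"),
                    ],
                )
            ],
        )
        block = _Block(seq=seq, transcripts=[ta, tb])
        block.peptides[f"{t_a}:{gid}"] = _peptide(cds_a(seq))
        block.peptides[f"{t_b}:{gid}"] = _peptide(cds_b(seq))
        block.intron_classes.append((e1, c, "+", "GT-AG", ["canonical_GT_AG"]))
        block.intron_classes.append((e1, c - 4, "+", "GT-AG", ["canonical_GT_AG"]))
        short = region_nt < 40
        block.multiphasic.append(
            {
                "members": [gid, gid],
                "length_nt": region_nt,
                "comment": (
                    vocab.COMMENT_MULTIPHASIC_ALT_STOP
                    if short
                    else vocab.COMMENT_MULTIPHASIC_EXON
                ),
                "cross_gene": False,
                "long_overlap": region_nt > 63,
            }
        )
        category = "multiphasic_short" if short else "multiphasic_long"
        self._plant("ctg1", block, category)

    def plant_bidirectional(self) -> None:
        """Two genes on opposite strands with a 50-nt CDS intersection."""
        g_a, g_b = self.gid(), self.gid()
        t_a, t_b = self.tid(), self.tid()
        la, lb, overlap = 90, 120, 50
        a0 = 5
        xb = a0 + la - overlap
        total = xb + lb + 5
        forced = {
            a0: "ATG",
            a0 + la - 3: "TAA",
            xb: "TTA",  # B's stop, read TAA on the minus strand
            xb + lb - 3: "CAT",  # B's ATG on the minus strand
        }
        from .model import revcomp

        preds = [
            lambda s: _clean_cds(s[a0 : a0 + la], _STD_STOPS),
            lambda s: _clean_cds(revcomp(s[xb : xb + lb]), _STD_STOPS),
        ]
        seq = _sample_segment(self.rng, total, forced, preds)
        ta = TranscriptModel(
            t_a,
            [g_a],
            [GenomicInterval("x", 0, a0 + la + 5, "+")],
            [OrfAnnotation(g_a, [GenomicInterval("x", a0, a0 + la, "+")])],
        )
        tb = TranscriptModel(
            t_b,
            [g_b],
            [GenomicInterval("x", xb - 5, total, "-")],
            [OrfAnnotation(g_b, [GenomicInterval("x", xb, xb + lb, "-")])],
        )
        block = _Block(seq=seq, transcripts=[ta, tb])
        block.peptides[f"{t_a}:{g_a}"] = _peptide(seq[a0 : a0 + la])
        block.peptides[f"{t_b}:{g_b}"] = _peptide(revcomp(seq[xb : xb + lb]))
        block.overlaps.append(
            {
                "genes": sorted([g_a, g_b]),
                "category": "bidirectional",
                "comment": vocab.COMMENT_BIDIRECTIONAL,
                "length_nt": overlap,
            }
        )
        self._plant("ctg1", block, "bidirectional")

    def plant_noncanonical(self, kind: str, declared_convenience: bool = False) -> None:
        """Gene with an intron using the requested donor-acceptor pair,
        usually with a similar alternative canonical splice isoform and
        matching junction calls."""
        gid = self.gid()
        t_n = self.tid()
        u12 = "U12" in kind
        pair = kind.split(" ")[0]
        donor, acceptor = pair.split("-")
        canonical = pair in ("GT-AG", "GC-AG")
        donor_variant = pair in ("GA-AG", "GG-AG")
        at_ac = pair == "AT-AC"
        with_alt = not (u12 or at_ac or canonical or declared_convenience)
        minus = pair == "GT-AT"  # so unstranded callers read it as AT-AC
        l1, l2 = 9, 30
        e1 = 6 + l1
        intron_len = 30
        c = e1 + intron_len
        s = c + l2
        d = s + 6
        kind_head = donor + ("ATCC" if u12 else "C")
        forced = {e1: kind_head, c - 2: acceptor, 6: "ATG", s - 3: "TAA"}
        if with_alt:
            if donor_variant:
                forced[e1 - 6] = "GTC"  # C blocks the U12 donor consensus
            else:
                forced[c + 4] = "AG"

        def cds_main(x: str) -> str:
            return x[6:e1] + x[c:s]

        def cds_alt(x: str) -> str:
            if donor_variant:
                return x[6 : e1 - 6] + x[c:s]
            return x[6:e1] + x[c + 6 : s]

        preds = [lambda x: _clean_cds(cds_main(x), _STD_STOPS)]
        if with_alt:
            preds.append(lambda x: _clean_cds(cds_alt(x), _STD_STOPS))
        seq = _sample_segment(self.rng, d, forced, preds)
        tn = TranscriptModel(
            t_n,
            [gid],
            [GenomicInterval("x", 0, e1, "+"), GenomicInterval("x", c, d, "+")],
            [
                OrfAnnotation(
                    gid,
                    [
                        GenomicInterval("x", 6, e1, "+"),
                        GenomicInterval("x", c, s, "+"),
                    ],
                )
            ],
            declared_flags=(
                [vocab.FLAG_SEQUENCE_ERROR_OR_GAP] if declared_convenience else []
            ),
        )
        block = _Block(seq=seq, transcripts=[tn])
        block.peptides[f"{t_n}:{gid}"] = _peptide(cds_main(seq))
        if declared_convenience:
            label = ["convenience"]
            block.transcript_flags[t_n] = [vocab.FLAG_SEQUENCE_ERROR_OR_GAP]
        elif canonical:
            label = ["canonical_GT_AG" if pair == "GT-AG" else "canonical_GC_AG"]
            if u12:
                label.append("U12")
        elif at_ac:
            label = ["noncanonical_AT_AC"] + (["U12"] if u12 else [])
            block.transcript_flags[t_n] = [vocab.FLAG_NONCANONICAL_SPLICE]
        else:
            label = [f"noncanonical:{pair}"]
            block.transcript_flags[t_n] = [vocab.FLAG_NONCANONICAL_SPLICE]
        block.intron_classes.append((e1, c, "+", pair, label))
        if label[0].startswith("noncanonical"):
            block.similar_alt.append(
                ((e1, c, "+"), None if not with_alt else _alt_key(donor_variant, e1, c))
            )
        if with_alt:
            t_c = self.tid()
            if donor_variant:
                alt_exons = [
                    GenomicInterval("x", 0, e1 - 6, "+"),
                    GenomicInterval("x", c, d, "+"),
                ]
                alt_cds = [
                    GenomicInterval("x", 6, e1 - 6, "+"),
                    GenomicInterval("x", c, s, "+"),
                ]
                alt_iv = (e1 - 6, c)
            else:
                alt_exons = [
                    GenomicInterval("x", 0, e1, "+"),
                    GenomicInterval("x", c + 6, d, "+"),
                ]
                alt_cds = [
                    GenomicInterval("x", 6, e1, "+"),
                    GenomicInterval("x", c + 6, s, "+"),
                ]
                alt_iv = (e1, c + 6)
            tc = TranscriptModel(
                t_c, [gid], alt_exons, [OrfAnnotation(gid, alt_cds)]
            )
            block.transcripts.append(tc)
            block.peptides[f"{t_c}:{gid}"] = _peptide(cds_alt(seq))
            block.intron_classes.append(
                (alt_iv[0], alt_iv[1], "+", "GT-AG", ["canonical_GT_AG"])
            )
        if not canonical and not declared_convenience:
            block.junctions.append(
                {
                    "start": e1,
                    "end": c,
                    "strand": "+",
                    "count": 12,
                    "score": 60.0,
                    "verdict": "matches_annotated",
                }
            )
            if minus:
                block.junctions.append(
                    {
                        "start": e1,
                        "end": c,
                        "strand": None,
                        "count": 11,
                        "score": 55.0,
                        "verdict": "strand_flip_gt_at",
                    }
                )
        if minus:
            block = _mirror_block(block)
        self._plant("ctg1", block, f"noncanonical:{kind}" if not declared_convenience else "convenience")

    def plant_hac1(self) -> None:
        """Endonuclease-processed 23-nt CA-TG intron: the unspliced isoform
        stops early; splicing shifts the frame of the C-terminus, creating a
        short within-gene multiphasic region."""
        gid = self.gid()
        t_u, t_s = self.tid(), self.tid()
        e1 = 40
        intron = (40, 63)  # 23 nt
        s1 = 93  # unspliced CDS end
        s2 = 98  # spliced CDS end
        total = 104
        forced = {
            6: "ATG",
            90: "TAA",  # unspliced stop
            40: "CA",
            61: "TG",
            95: "TAA",  # spliced stop
        }

        def cds_u(x: str) -> str:
            return x[6:s1]

        def cds_s(x: str) -> str:
            return x[6:e1] + x[63:s2]

        preds = [
            lambda x: _clean_cds(cds_u(x), _STD_STOPS),
            lambda x: _clean_cds(cds_s(x), _STD_STOPS),
        ]
        seq = _sample_segment(self.rng, total, forced, preds)
        tu = TranscriptModel(
            t_u,
            [gid],
            [GenomicInterval("x", 0, total, "+")],
            [OrfAnnotation(gid, [GenomicInterval("x", 6, s1, "+")])],
        )
        ts = TranscriptModel(
            t_s,
            [gid],
            [GenomicInterval("x", 0, e1, "+"), GenomicInterval("x", 63, total, "+")],
            [
                OrfAnnotation(
                    gid,
                    [
                        GenomicInterval("x", 6, e1, "+"),
                        GenomicInterval("x", 63, s2, "+"),
                    ],
                )
            ],
            declared_flags=[vocab.FLAG_ENDONUCLEASE_SPLICED],
        )
        block = _Block(seq=seq, transcripts=[tu, ts])
        block.peptides[f"{t_u}:{gid}"] = _peptide(cds_u(seq))
        block.peptides[f"{t_s}:{gid}"] = _peptide(cds_s(seq))
        block.intron_classes.append((40, 63, "+", "CA-TG", ["endonuclease_spliced"]))
        block.transcript_flags[t_s] = [vocab.FLAG_ENDONUCLEASE_SPLICED]
        block.multiphasic.append(
            {
                "members": [gid, gid],
                "length_nt": s1 - 63,
                "comment": vocab.COMMENT_MULTIPHASIC_ALT_STOP,
                "cross_gene": False,
                "long_overlap": False,
            }
        )
        self._plant("ctg1", block, "hac1")

    def plant_trans_splice(self) -> None:
        """Trans-spliced transcript: coding exon on the plus strand joined
        to a noncoding 3' exon transcribed from the opposite strand."""
        gid, tid = self.gid(), self.tid()
        cds = _orf_nt(self.rng, 12)
        exon1_len = 6 + len(cds) + 8
        gap = 20
        exon2_len = 30
        total = exon1_len + gap + exon2_len
        seq = _rand_seq(self.rng, 6) + cds + _rand_seq(self.rng, total - 6 - len(cds))
        t = TranscriptModel(
            tid,
            [gid],
            [
                GenomicInterval("x", 0, exon1_len, "+"),
                GenomicInterval("x", exon1_len + gap, total, "-"),
            ],
            [OrfAnnotation(gid, [GenomicInterval("x", 6, 6 + len(cds), "+")])],
            declared_flags=[vocab.FLAG_TRANS_SPLICED],
        )
        block = _Block(seq=seq, transcripts=[t])
        block.peptides[f"{tid}:{gid}"] = _peptide(cds)
        block.gene_so[gid] = ["SO:0000459"]
        block.transcript_flags[tid] = [vocab.FLAG_TRANS_SPLICED]
        self._plant("ctg1", block, "trans_splice")

    def plant_translation_exception(self, category: str) -> None:
        """Single-exon gene with one declared translation exception."""
        gid, tid = self.gid(), self.tid()
        rng = self.rng
        orf_kwargs: dict = {}
        flags: list[str] = []
        so: list[str] = []
        mito = False
        if category == "cug_start":
            body = "".join(rng.choice(_STD_NONSTOP) for _ in range(14))
            cds = "CTG" + body + "TAA"
            orf_kwargs["start_codon_kind"] = "CTG"
            pep = _peptide(cds)
            flags = [vocab.FLAG_NON_AUG_START]
            so = ["SO:0001739", "SO:0001740"]
        elif category == "sec":
            c1, c2 = 8, 2
            cds = (
                "ATG"
                + "".join(rng.choice(_STD_NONSTOP) for _ in range(c1))
                + "TGA"
                + "".join(rng.choice(_STD_NONSTOP) for _ in range(c2))
                + "TAA"
            )
            orf_kwargs["selenocysteine_positions"] = [c1 + 2]
            pep = _peptide(cds, sec=(c1 + 2,))
            flags = [vocab.FLAG_SELENOCYSTEINE]
            so = ["SO:0000710"]
        elif category in ("readthrough", "double_readthrough"):
            c1, c2, c3 = 6, 5, 4
            stops = ["TGA"] if category == "readthrough" else ["TGA", "TAG"]
            parts = ["ATG" + "".join(rng.choice(_STD_NONSTOP) for _ in range(c1))]
            positions = []
            codon_count = 1 + c1
            for i, stop in enumerate(stops):
                parts.append(stop)
                codon_count += 1
                positions.append(codon_count)
                n = c2 if i == 0 else c3
                parts.append("".join(rng.choice(_STD_NONSTOP) for _ in range(n)))
                codon_count += n
            parts.append("TAA")
            cds = "".join(parts)
            orf_kwargs["readthrough_positions"] = positions
            pep = _peptide(cds, readthrough=tuple(positions))
            flags = [vocab.FLAG_READTHROUGH]
            so = ["SO:0000697"]
        elif category == "frameshift":
            k, m = 3, 8
            before = "ATG" + "".join(rng.choice(_STD_NONSTOP) for _ in range(k - 1))
            after = "".join(rng.choice(_STD_NONSTOP) for _ in range(m)) + "TAA"
            skipped = rng.choice("ACGT")
            cds = before + skipped + after
            orf_kwargs["frameshift"] = Frameshift(codon_index=k)
            pep = _peptide(before + after)
            flags = [vocab.FLAG_FRAMESHIFT]
            so = ["SO:0000712"]
        elif category == "mito_incomplete_stop":
            mito = True
            n = 12
            cds = "ATG" + "".join(rng.choice(_MITO_NONSTOP) for _ in range(n)) + "T"
            orf_kwargs["incomplete_stop"] = True
            orf_kwargs["genetic_code"] = "invertebrate_mitochondrial"
            pep = _peptide(cds + "AA", code=_MITO)
            flags = [vocab.FLAG_MITO_CODE, vocab.FLAG_MITO_INCOMPLETE_STOP]
            so = ["SO:0000088"]
        elif category == "undetermined_start":
            mito = True
            n = 10
            cds = "ATT" + "".join(rng.choice(_MITO_NONSTOP) for _ in range(n)) + "TAA"
            orf_kwargs["start_codon_kind"] = "undetermined"
            orf_kwargs["genetic_code"] = "invertebrate_mitochondrial"
            pep = _peptide(cds, code=_MITO, start=None)
            flags = [vocab.FLAG_MITO_CODE, vocab.FLAG_START_NOT_DETERMINED]
            so = ["SO:0000088"]
        else:
            raise ValueError(category)
        seq = _rand_seq(self.rng, 6) + cds + _rand_seq(self.rng, 6)
        block = _Block(seq=seq)
        block.transcripts = [
            self._single_exon_transcript(
                gid, tid, len(seq), 6, 6 + len(cds), **orf_kwargs
            )
        ]
        block.peptides[f"{tid}:{gid}"] = pep
        if flags:
            block.transcript_flags[tid] = flags
        if so:
            block.gene_so[gid] = so
        self._plant("mito" if mito else "ctg1", block, category)

    def plant_junction_artifacts(self) -> None:
        """Artifact-class junction calls anchored on a canonical intron:
        off-by-one, low-frequency, misaligned, and unsupported."""
        if self._artifact_intron is None:
            return
        seqid, s, e, strand = self._artifact_intron
        specs = [
            (s + 1, e + 1, strand, 9, 40.0, "off_by_one_artifact"),
            (s - 5, e - 5, strand, 1, 10.0, "low_frequency"),
            (s + 3, e + 3, strand, 8, 30.0, "misaligned_near_annotated"),
            (2, 40, None, 8, 30.0, "unsupported_noncanonical"),
        ]
        for start, end, st, count, score, verdict in specs:
            call = JunctionCall(
                seqid=seqid,
                start=start,
                end=end,
                strand=st,
                read_count=count,
                score=score,
            )
            self.junctions.append(call)
            self.expected["junction_verdicts"].append(
                {
                    "seqid": seqid,
                    "start": start,
                    "end": end,
                    "strand": st,
                    "read_count": count,
                    "verdict": verdict,
                }
            )

    # -- assembly -----------------------------------------------------------

    def build(self) -> Fixture:
        spec = self.spec
        for i in range(spec.mono):
            self.plant_mono(spliced=(i == 0))
        for _ in range(spec.dicistronic):
            self.plant_polycistronic(2)
        for _ in range(spec.tricistronic):
            self.plant_polycistronic(3)
        for _ in range(spec.tetracistronic):
            self.plant_polycistronic(4)
        for _ in range(spec.dicistronic_overlap):
            self.plant_dicistronic_overlap()
        for _ in range(spec.shared_5):
            self.plant_shared_5()
        for _ in range(spec.shared_3):
            self.plant_shared_3()
        for _ in range(spec.multiphasic_short):
            self.plant_multiphasic_within(30)
        for _ in range(spec.multiphasic_long):
            self.plant_multiphasic_within(80)
        for _ in range(spec.bidirectional):
            self.plant_bidirectional()
        for kind in sorted(spec.noncanonical):
            for _ in range(spec.noncanonical[kind]):
                self.plant_noncanonical(kind)
        for _ in range(spec.convenience):
            self.plant_noncanonical("CT-GC", declared_convenience=True)
        for _ in range(spec.hac1):
            self.plant_hac1()
        for _ in range(spec.trans_splice):
            self.plant_trans_splice()
        for category in (
            "cug_start",
            "sec",
            "readthrough",
            "double_readthrough",
            "frameshift",
            "mito_incomplete_stop",
            "undetermined_start",
        ):
            for _ in range(getattr(spec, category)):
                self.plant_translation_exception(category)
        self.plant_junction_artifacts()

        # pad contigs to their requested lengths
        records: dict[str, str] = {}
        circular: set[str] = set()
        lengths = {"ctg1": spec.contig_length, "mito": spec.mito_contig_length}
        if "ctg1" not in self.contig_parts:
            self.contig_parts["ctg1"] = []
            self.cursor["ctg1"] = 0
        for contig, parts in self.contig_parts.items():
            used = self.cursor[contig]
            target = lengths.get(contig, used)
            if used > target:
                raise ValueError(
                    f"contig {contig!r} too small for requested features: "
                    f"need {used} nt, have {target}"
                )
            records[contig] = "".join(parts) + _rand_seq(self.rng, target - used)
        if "mito" in records:
            circular.add("mito")
        genome = GenomeSequence(records=records, circular=circular)

        # A-to-I editing sites inside the first unexceptional gene
        editing_sites: list[tuple[str, int]] = []
        if spec.editing_sites and self._editing_target is not None:
            span = self.aset.genes[self._editing_target].span
            contig_seq = records[span.seqid]
            a_positions = [
                p for p in range(span.start, span.end) if contig_seq[p] == "A"
            ]
            for p in a_positions[: spec.editing_sites]:
                editing_sites.append((span.seqid, p))
            if editing_sites:
                self.expected["editing_genes"] = [self._editing_target]
                self.expected["gene_so"].setdefault(self._editing_target, []).append(
                    "SO:0000548"
                )

        for gene in self.aset.genes.values():
            gene.transcript_ids.sort()
        self.aset.validate()
        genome.validate()
        manifest = {
            "seed": spec.seed,
            "contigs": {name: len(seq) for name, seq in records.items()},
            "n_contigs": len(records),
            "entries": self.entries,
            "expected": self.expected,
        }
        return Fixture(
            genome=genome,
            aset=self.aset,
            junctions=self.junctions,
            editing_sites=editing_sites,
            manifest=manifest,
        )


def _alt_key(donor_variant: bool, e1: int, c: int) -> tuple[int, int, str]:
    return (e1 - 6, c, "+") if donor_variant else (e1, c + 6, "+")


def generate_fixture(spec: FixtureSpec) -> Fixture:
    """Generate genome + annotation + junctions + editing sites + manifest."""
    return _FixtureBuilder(spec).build()


def write_fixture(fixture: Fixture, out_dir: str | Path) -> dict[str, Path]:
    """Write genome.fa, models.gff3, junctions.bed, editing_sites.tsv and
    manifest.json; byte-identical for identical specs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": out / "genome.fa",
        "gff": out / "models.gff3",
        "junctions": out / "junctions.bed",
        "editing_sites": out / "editing_sites.tsv",
        "manifest": out / "manifest.json",
    }
    write_genome(fixture.genome, paths["genome"])
    write_annotation(fixture.aset, paths["gff"])
    write_junctions_bed(fixture.junctions, paths["junctions"])
    lines = [f"{seqid}\t{pos + 1}" for seqid, pos in fixture.editing_sites]
    paths["editing_sites"].write_text("\n".join(lines) + ("\n" if lines else ""))
    paths["manifest"].write_text(
        json.dumps(fixture.manifest, indent=2, sort_keys=True) + "\n"
    )
    return paths


# ---------------------------------------------------------------------------
# Closed-loop verification against the manifest
# ---------------------------------------------------------------------------


def verify_audit(result, manifest: dict) -> list[str]:
    """Compare an :class:`~gffaudit.pipeline.AuditResult` against a fixture
    manifest.  Returns a list of mismatch descriptions (empty = perfect
    recovery: every planted classification found, nothing unplanted)."""
    expected = manifest["expected"]
    problems: list[str] = []

    for gid in result.aset.genes:
        want = sorted(expected["gene_so"].get(gid, []))
        got = sorted(a.so_id for a in result.gene_so.get(gid, []))
        if want != got:
            problems.append(f"gene {gid}: SO terms {got} != expected {want}")

    for tid in result.aset.transcripts:
        want = sorted(expected["transcript_flags"].get(tid, []))
        got = sorted(a.token for a in result.transcript_flags.get(tid, []))
        if want != got:
            problems.append(f"transcript {tid}: flags {got} != expected {want}")

    got_peps = {k: r.peptide for k, r in result.translations.items()}
    if got_peps != expected["peptides"]:
        for key in sorted(set(got_peps) | set(expected["peptides"])):
            if got_peps.get(key) != expected["peptides"].get(key):
                problems.append(
                    f"peptide {key}: {got_peps.get(key)} != "
                    f"{expected['peptides'].get(key)}"
                )

    got_introns = {rec.key: sorted(rec.classification) for rec in result.introns}
    want_introns = {
        key: sorted(info["classification"])
        for key, info in expected["intron_classes"].items()
    }
    if got_introns != want_introns:
        for key in sorted(set(got_introns) | set(want_introns)):
            if got_introns.get(key) != want_introns.get(key):
                problems.append(
                    f"intron {key}: {got_introns.get(key)} != {want_introns.get(key)}"
                )

    for key, want_alt in expected["similar_alternative"].items():
        got_alt = result.intron_similar.get(key, "missing")
        if got_alt != want_alt:
            problems.append(f"similar splice for {key}: {got_alt} != {want_alt}")

    def multi_key(entry: dict) -> tuple:
        return (
            tuple(sorted(entry["members"])),
            entry["length_nt"],
            entry["comment"],
            entry["cross_gene"],
            entry["long_overlap"],
        )

    got_multi = sorted(
        multi_key(
            {
                "members": list(r.members),
                "length_nt": r.length_nt,
                "comment": r.comment,
                "cross_gene": r.cross_gene,
                "long_overlap": r.long_overlap,
            }
        )
        for r in result.multiphasic
    )
    want_multi = sorted(multi_key(e) for e in expected["multiphasic"])
    if got_multi != want_multi:
        problems.append(f"multiphasic regions {got_multi} != {want_multi}")

    def call_key(genes, category, comment) -> tuple:
        return (tuple(sorted(genes)), category, comment)

    got_calls = sorted(
        call_key(c.genes, c.category, c.comment) for c in result.overlap_calls
    )
    want_calls = sorted(
        call_key(e["genes"], e["category"], e["comment"])
        for e in expected["overlaps"]
    )
    if got_calls != want_calls:
        problems.append(f"overlap calls {got_calls} != {want_calls}")
    for e in expected["overlaps"]:
        if "length_nt" in e:
            match = [
                c
                for c in result.overlap_calls
                if tuple(sorted(c.genes)) == tuple(sorted(e["genes"]))
                and c.category == e["category"]
            ]
            if not match or match[0].length_nt != e["length_nt"]:
                problems.append(
                    f"overlap {e['genes']} length "
                    f"{match[0].length_nt if match else None} != {e['length_nt']}"
                )

    for tid, want in expected["intercistronic"].items():
        got = [list(x) for x in result.intercistronic.get(tid, [])]
        if got != [list(x) for x in want]:
            problems.append(f"intercistronic {tid}: {got} != {want}")

    got_verdicts = {
        (j.seqid, j.start, j.end, j.strand, j.read_count): d.verdict
        for j, d in result.junction_audits
    }
    for e in expected["junction_verdicts"]:
        key = (e["seqid"], e["start"], e["end"], e["strand"], e["read_count"])
        if got_verdicts.get(key) != e["verdict"]:
            problems.append(
                f"junction {key}: {got_verdicts.get(key)} != {e['verdict']}"
            )

    if sorted(result.edited_genes) != sorted(expected["editing_genes"]):
        problems.append(
            f"edited genes {sorted(result.edited_genes)} != "
            f"{sorted(expected['editing_genes'])}"
        )
    return problems
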