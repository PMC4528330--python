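"""Core gene-model data structures and genome/annotation I/O.

Coordinates are zero-based half-open internally; GFF3 input/output converts
at the boundary (GFF3 is 1-based inclusive).  Exons of a transcript are kept
in transcript (5'→3') order, which for minus-strand transcripts means
decreasing genomic coordinate.

GFF3 dialect
------------
Standard gene/mRNA/exon/CDS features, with three extensions needed to
represent multi-gene (dicistronic and polycistronic) transcripts and
declared exceptions:

* an mRNA encoding several genes carries a multi-valued ``Parent``
  attribute (``Parent=gA,gB``), one per encoded gene, 5'→3';
* every CDS feature carries a ``gene=<gene_id>`` attribute naming the gene
  its coding region belongs to, binding each CDS group to one gene;
* exceptions are declared as attributes: ``flags=`` on gene/mRNA lines
  (controlled transcript-flag vocabulary), and on the first CDS line of a
  group ``start_codon=<NNN|undetermined>``, ``readthrough_codons=i,j``,
  ``selenocysteine_codons=i``, ``frameshift_codon=i`` (+1 slippage after
  codon *i*), ``incomplete_stop=true`` and
  ``genetic_code=invertebrate_mitochondrial`` (codon indices 1-based).

Exons additionally carry a ``rank`` attribute giving the annotated exon
order; this is what allows a trans-spliced transcript (the one sanctioned
mixed-strand case, declared via ``trans_spliced_transcript``) to list exons
drawn from both strands in their mature-mRNA order.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Iterator, Optional

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .vocab import DECLARABLE_FLAGS, TRANSCRIPT_FLAGS

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over the A/C/G/T/N alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeError(ValueError):
    """Invalid genome sequence input."""


class AnnotationError(ValueError):
    """Invalid or inconsistent gene-model input."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True, order=True)
class GenomicInterval:
    """Zero-based half-open genomic interval on one strand."""

    seqid: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.seqid}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.seqid == other.seqid
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.seqid == other.seqid
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclasses.dataclass
class GenomeSequence:
    """Uppercase A/C/G/T/N sequences keyed by contig identifier."""

    records: dict[str, str]
    circular: set[str] = dataclasses.field(default_factory=set)

    def validate(self) -> None:
        for name, seq in self.records.items():
            if not seq:
                raise GenomeError(f"empty sequence for {name!r}")
            for pos, base in enumerate(seq):
                if base not in VALID_BASES:
                    raise GenomeError(
                        f"non-IUPAC character {base!r} in {name!r} at position {pos}"
                    )

    def fetch(self, interval: GenomicInterval) -> str:
        """Strand-aware sequence of ``interval`` (minus strand is
        reverse-complemented)."""
        try:
            contig = self.records[interval.seqid]
        except KeyError:
            raise GenomeError(f"unknown contig {interval.seqid!r}") from None
        if interval.end > len(contig):
            raise GenomeError(
                f"interval [{interval.start}, {interval.end}) extends beyond "
                f"contig {interval.seqid!r} of length {len(contig)}"
            )
        seq = contig[interval.start : interval.end]
        return revcomp(seq) if interval.strand == "-" else seq


@dataclasses.dataclass
class Frameshift:
    """+1 ribosomal frameshift after ``codon_index`` (1-based): one template
    base is skipped before translation resumes."""

    codon_index: int
    shift: int = 1

    def __post_init__(self) -> None:
        if self.shift != 1:
            raise AnnotationError(
                f"only +1 translational frameshifts are supported, got {self.shift:+d}"
            )


@dataclasses.dataclass
class OrfAnnotation:
    """One coding region (CDS group) and its declared translation exceptions.

    ``cds_segments`` are in translation (5'→3') order and include the stop
    codon.  Codon indices in the exception fields are 1-based positions in
    the effective coding sequence.
    """

    gene_id: str
    cds_segments: list[GenomicInterval]
    start_codon_kind: str = "AUG"  # "AUG", a 3-nt codon string, or "undetermined"
    readthrough_positions: list[int] = dataclasses.field(default_factory=list)
    selenocysteine_positions: list[int] = dataclasses.field(default_factory=list)
    frameshift: Optional[Frameshift] = None
    incomplete_stop: bool = False
    genetic_code: str = "standard"

    @property
    def cds_length(self) -> int:
        return sum(len(seg) for seg in self.cds_segments)

    def genomic_positions(self) -> list[tuple[str, int]]:
        """(seqid, position) of every CDS base in translation order."""
        out: list[tuple[str, int]] = []
        for seg in self.cds_segments:
            coords = range(seg.start, seg.end)
            if seg.strand == "-":
                coords = reversed(coords)
            out.extend((seg.seqid, pos) for pos in coords)
        return out

    def validate(self) -> None:
        if not self.cds_segments:
            raise AnnotationError(f"ORF for {self.gene_id!r} has no CDS segments")
        if self.start_codon_kind not in {"AUG", "undetermined"} and (
            len(self.start_codon_kind) != 3
            or set(self.start_codon_kind) - set("ACGTU")
        ):
            raise AnnotationError(
                f"invalid start codon declaration {self.start_codon_kind!r}"
            )
        rem = self.cds_length % 3
        if self.incomplete_stop:
            if rem not in (1, 2):
                raise AnnotationError(
                    f"ORF for {self.gene_id!r} declares an incomplete stop codon "
                    f"but its CDS length {self.cds_length} is a multiple of 3"
                )
        elif self.frameshift is not None:
            # A +1 slip consumes one extra template base.
            if rem != 1:
                raise AnnotationError(
                    f"ORF for {self.gene_id!r} declares a +1 frameshift; CDS "
                    f"length must be ≡ 1 mod 3, got {self.cds_length}"
                )
        elif rem != 0:
            raise AnnotationError(
                f"CDS length for {self.gene_id!r} is {self.cds_length}, "
                "not a multiple of 3"
            )
        if self.readthrough_positions != sorted(set(self.readthrough_positions)):
            raise AnnotationError(
                f"readthrough positions for {self.gene_id!r} must be strictly increasing"
            )
        if self.genetic_code not in {"standard", "invertebrate_mitochondrial"}:
            raise AnnotationError(f"unknown genetic code {self.genetic_code!r}")


@dataclasses.dataclass
class TranscriptModel:
    """A transcript: ordered exons plus one ORF per encoded gene.

    ``gene_ids`` lists the owning genes 5'→3'; more than one encodes a
    shared (dicistronic/polycistronic) transcript.  Exons must lie on one
    contig and strand except for transcripts declared trans-spliced, which
    may join exons transcribed from opposite strands.
    """

    transcript_id: str
    gene_ids: list[str]
    exons: list[GenomicInterval]
    orfs: list[OrfAnnotation] = dataclasses.field(default_factory=list)
    declared_flags: list[str] = dataclasses.field(default_factory=list)

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def seqid(self) -> str:
        return self.exons[0].seqid

    @property
    def is_trans_spliced(self) -> bool:
        return "trans_spliced_transcript" in self.declared_flags

    @property
    def is_coding(self) -> bool:
        return bool(self.orfs)

    def span(self) -> GenomicInterval:
        start = min(e.start for e in self.exons)
        end = max(e.end for e in self.exons)
        return GenomicInterval(self.exons[0].seqid, start, end, self.exons[0].strand)

    def exon_length(self) -> int:
        return sum(len(e) for e in self.exons)

    def transcript_index(self) -> dict[tuple[str, int], int]:
        """Map (seqid, genomic position) → position on the mature transcript."""
        index: dict[tuple[str, int], int] = {}
        t = 0
        for exon in self.exons:
            coords = range(exon.start, exon.end)
            if exon.strand == "-":
                coords = reversed(coords)
            for pos in coords:
                index[(exon.seqid, pos)] = t
                t += 1
        return index

    def validate(self) -> None:
        if not self.exons:
            raise AnnotationError(f"transcript {self.transcript_id!r} has no exons")
        if not self.gene_ids:
            raise AnnotationError(f"transcript {self.transcript_id!r} has no gene")
        for token in self.declared_flags:
            if token not in TRANSCRIPT_FLAGS:
                raise AnnotationError(
                    f"unknown exception token {token!r} on {self.transcript_id!r}"
                )
            if token not in DECLARABLE_FLAGS:
                raise AnnotationError(
                    f"flag {token!r} on {self.transcript_id!r} is derived by the "
                    "auditor and cannot be declared in input"
                )
        strands = {(e.seqid, e.strand) for e in self.exons}
        if len(strands) > 1 and not self.is_trans_spliced:
            raise AnnotationError(
                f"transcript {self.transcript_id!r} mixes contigs/strands but is "
                "not declared trans_spliced_transcript"
            )
        by_locus: dict[tuple[str, str], list[GenomicInterval]] = {}
        for exon in self.exons:
            by_locus.setdefault((exon.seqid, exon.strand), []).append(exon)
        for exons in by_locus.values():
            ordered = sorted(exons, key=lambda e: e.start)
            for a, b in zip(ordered, ordered[1:]):
                if a.end > b.start:
                    raise AnnotationError(
                        f"overlapping exons on transcript {self.transcript_id!r}"
                    )
        if len(self.orfs) > len(self.gene_ids):
            raise AnnotationError(
                f"transcript {self.transcript_id!r} has more ORFs than genes"
            )
        index = self.transcript_index()
        for orf in self.orfs:
            orf.validate()
            if orf.gene_id not in self.gene_ids:
                raise AnnotationError(
                    f"CDS group on {self.transcript_id!r} names gene "
                    f"{orf.gene_id!r}, which is not a parent of the transcript"
                )
            for seqid, pos in orf.genomic_positions():
                if (seqid, pos) not in index:
                    raise AnnotationError(
                        f"CDS of {orf.gene_id!r} on {self.transcript_id!r} lies "
                        f"outside the exon union (position {seqid}:{pos})"
                    )


@dataclasses.dataclass
class GeneRecord:
    gene_id: str
    span: GenomicInterval
    transcript_ids: list[str] = dataclasses.field(default_factory=list)
    declared_flags: list[str] = dataclasses.field(default_factory=list)


@dataclasses.dataclass
class IntronRecord:
    """One intron with its boundary dinucleotides read on the transcript
    strand (donor = first two intron bases, acceptor = last two)."""

    interval: GenomicInterval
    donor: str
    acceptor: str
    transcript_ids: list[str] = dataclasses.field(default_factory=list)
    classification: list[str] = dataclasses.field(default_factory=list)

    @property
    def pair(self) -> str:
        return f"{self.donor}-{self.acceptor}"

    @property
    def key(self) -> str:
        iv = self.interval
        return f"{iv.seqid}:{iv.start}-{iv.end}:{iv.strand}"


@dataclasses.dataclass
class AnnotationSet:
    """Validated collection of genes and transcripts."""

    genes: dict[str, GeneRecord] = dataclasses.field(default_factory=dict)
    transcripts: dict[str, TranscriptModel] = dataclasses.field(default_factory=dict)

    def validate(self) -> None:
        for t in self.transcripts.values():
            t.validate()
            for gid in t.gene_ids:
                if gid not in self.genes:
                    raise AnnotationError(
                        f"transcript {t.transcript_id!r} names undeclared gene {gid!r}"
                    )
        for gene in self.genes.values():
            if not gene.transcript_ids:
                raise AnnotationError(f"gene {gene.gene_id!r} has no transcript")
            for tid in gene.transcript_ids:
                if tid not in self.transcripts:
                    raise AnnotationError(
                        f"gene {gene.gene_id!r} references unknown transcript {tid!r}"
                    )

    def transcripts_of(self, gene_id: str) -> list[TranscriptModel]:
        try:
            gene = self.genes[gene_id]
        except KeyError:
            raise AnnotationError(f"unknown gene {gene_id!r}") from None
        return [self.transcripts[tid] for tid in gene.transcript_ids]

    def orfs_of(self, gene_id: str) -> list[tuple[TranscriptModel, OrfAnnotation]]:
        """Every (transcript, ORF) pair coding for ``gene_id``."""
        out = []
        for t in self.transcripts_of(gene_id):
            for orf in t.orfs:
                if orf.gene_id == gene_id:
                    out.append((t, orf))
        return out


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------


def read_genome(path: str | Path, circular: Iterable[str] = ()) -> GenomeSequence:
    """Read a FASTA genome; lowercase input is accepted and normalized.

    Contigs whose description contains the token ``circular=true`` (or that
    are named in ``circular``) are treated as circular (mitochondrion).
    """
    records: dict[str, str] = {}
    circ = set(circular)
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise GenomeError(f"duplicate sequence identifier {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
        if "circular=true" in rec.description.split():
            circ.add(rec.id)
    genome = GenomeSequence(records=records, circular=circ & set(records))
    genome.validate()
    return genome


def write_genome(genome: GenomeSequence, path: str | Path) -> None:
    recs = []
    for name in genome.records:
        desc = "circular=true" if name in genome.circular else ""
        recs.append(SeqRecord(Seq(genome.records[name]), id=name, description=desc))
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3 I/O
# ---------------------------------------------------------------------------

_ORF_ATTRS = (
    "start_codon",
    "readthrough_codons",
    "selenocysteine_codons",
    "frameshift_codon",
    "incomplete_stop",
    "genetic_code",
)


def _attr_list(feature, key: str) -> list[str]:
    return [v for v in feature.attributes.get(key, []) if v]


def read_annotation(path: str | Path) -> AnnotationSet:
    """Parse a GFF3 file in the dialect described in the module docstring."""
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except gffutils.exceptions.EmptyInputError:
        return AnnotationSet()  # header-only file: no gene models
    aset = AnnotationSet()
    for feat in db.features_of_type("gene"):
        gid = feat.id
        if gid in aset.genes:
            raise AnnotationError(f"duplicate gene identifier {gid!r}")
        span = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
        aset.genes[gid] = GeneRecord(
            gene_id=gid, span=span, declared_flags=_attr_list(feat, "flags")
        )
    for feat in db.features_of_type("mRNA"):
        tid = feat.id
        gene_ids = _attr_list(feat, "Parent")
        for gid in gene_ids:
            if gid not in aset.genes:
                raise AnnotationError(
                    f"mRNA {tid!r} names undeclared gene {gid!r} as Parent"
                )
        exon_feats = list(db.children(feat, featuretype="exon"))
        if not exon_feats:
            raise AnnotationError(f"mRNA {tid!r} has no exons")
        if all("rank" in e.attributes for e in exon_feats):
            exon_feats.sort(key=lambda e: int(e.attributes["rank"][0]))
        else:
            exon_feats.sort(
                key=lambda e: e.start, reverse=(feat.strand == "-")
            )
        exons = [
            GenomicInterval(e.seqid, e.start - 1, e.end, e.strand) for e in exon_feats
        ]
        cds_feats = sorted(db.children(feat, featuretype="CDS"), key=lambda c: c.start)
        groups: dict[str, list] = {}
        for c in cds_feats:
            owners = _attr_list(c, "gene") or gene_ids[:1]
            if len(owners) != 1:
                raise AnnotationError(
                    f"CDS on {tid!r} must name exactly one owning gene"
                )
            groups.setdefault(owners[0], []).append(c)
        transcript = TranscriptModel(
            transcript_id=tid,
            gene_ids=gene_ids,
            exons=exons,
            declared_flags=_attr_list(feat, "flags"),
        )
        index = transcript.transcript_index()
        orfs = []
        for gid, feats in groups.items():
            segs = [
                GenomicInterval(c.seqid, c.start - 1, c.end, c.strand) for c in feats
            ]
            # translation order: ascending transcript coordinate of segment start
            def _tpos(seg: GenomicInterval) -> int:
                gpos = seg.start if seg.strand == "+" else seg.end - 1
                key = (seg.seqid, gpos)
                if key not in index:
                    raise AnnotationError(
                        f"CDS of {gid!r} on {tid!r} lies outside the exon union"
                    )
                return index[key]

            segs.sort(key=_tpos)
            orf = OrfAnnotation(gene_id=gid, cds_segments=segs)
            _parse_orf_attrs(orf, feats, tid)
            orfs.append(orf)
        orfs.sort(key=lambda o: index[o.genomic_positions()[0]])
        transcript.orfs = orfs
        aset.transcripts[tid] = transcript
        for gid in gene_ids:
            aset.genes[gid].transcript_ids.append(tid)
    for gene in aset.genes.values():
        gene.transcript_ids.sort()
    aset.validate()
    return aset


def _parse_orf_attrs(orf: OrfAnnotation, cds_feats: list, tid: str) -> None:
    merged: dict[str, list[str]] = {}
    for c in cds_feats:
        for key in _ORF_ATTRS:
            vals = _attr_list(c, key)
            if vals:
                merged.setdefault(key, vals)
    if "start_codon" in merged:
        val = merged["start_codon"][0]
        orf.start_codon_kind = val if val == "undetermined" else val.upper()
    if "readthrough_codons" in merged:
        orf.readthrough_positions = sorted(int(v) for v in merged["readthrough_codons"])
    if "selenocysteine_codons" in merged:
        orf.selenocysteine_positions = sorted(
            int(v) for v in merged["selenocysteine_codons"]
        )
    if "frameshift_codon" in merged:
        orf.frameshift = Frameshift(codon_index=int(merged["frameshift_codon"][0]))
    if "incomplete_stop" in merged:
        val = merged["incomplete_stop"][0].lower()
        if val not in {"true", "false"}:
            raise AnnotationError(
                f"incomplete_stop on {tid!r} must be 'true' or 'false', got {val!r}"
            )
        orf.incomplete_stop = val == "true"
    if "genetic_code" in merged:
        orf.genetic_code = merged["genetic_code"][0]


def _gff_line(
    seqid: str,
    feature: str,
    start0: int,
    end0: int,
    strand: str,
    attrs: list[tuple[str, str]],
    phase: str = ".",
) -> str:
    attr_str = ";".join(f"{k}={v}" for k, v in attrs if v != "")
    return "\t".join(
        [seqid, "gffaudit", feature, str(start0 + 1), str(end0), ".", strand, phase, attr_str]
    )


def write_annotation(aset: AnnotationSet, path: str | Path | None = None) -> str:
    """Serialize an :class:`AnnotationSet` to GFF3 text (and optionally a file).

    The output re-reads to an identical AnnotationSet (round-trip identity).
    """
    lines = ["##gff-version 3"]
    for gid in sorted(aset.genes):
        gene = aset.genes[gid]
        attrs = [("ID", gid)]
        if gene.declared_flags:
            attrs.append(("flags", ",".join(gene.declared_flags)))
        sp = gene.span
        lines.append(_gff_line(sp.seqid, "gene", sp.start, sp.end, sp.strand, attrs))
    for tid in sorted(aset.transcripts):
        t = aset.transcripts[tid]
        sp = t.span()
        attrs = [("ID", tid), ("Parent", ",".join(t.gene_ids))]
        if t.declared_flags:
            attrs.append(("flags", ",".join(t.declared_flags)))
        lines.append(_gff_line(sp.seqid, "mRNA", sp.start, sp.end, sp.strand, attrs))
        for rank, exon in enumerate(t.exons, start=1):
            lines.append(
                _gff_line(
                    exon.seqid,
                    "exon",
                    exon.start,
                    exon.end,
                    exon.strand,
                    [("Parent", tid), ("rank", str(rank))],
                )
            )
        for orf in t.orfs:
            phase_acc = 0
            for i, seg in enumerate(orf.cds_segments):
                attrs = [("Parent", tid), ("gene", orf.gene_id)]
                if i == 0:
                    attrs.extend(_orf_attr_pairs(orf))
                phase = (3 - phase_acc % 3) % 3
                lines.append(
                    _gff_line(
                        seg.seqid,
                        "CDS",
                        seg.start,
                        seg.end,
                        seg.strand,
                        attrs,
                        phase=str(phase),
                    )
                )
                phase_acc += len(seg)
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def _orf_attr_pairs(orf: OrfAnnotation) -> list[tuple[str, str]]:
    pairs = []
    if orf.start_codon_kind != "AUG":
        pairs.append(("start_codon", orf.start_codon_kind))
    if orf.readthrough_positions:
        pairs.append(
            ("readthrough_codons", ",".join(map(str, orf.readthrough_positions)))
        )
    if orf.selenocysteine_positions:
        pairs.append(
            ("selenocysteine_codons", ",".join(map(str, orf.selenocysteine_positions)))
        )
    if orf.frameshift is not None:
        pairs.append(("frameshift_codon", str(orf.frameshift.codon_index)))
    if orf.incomplete_stop:
        pairs.append(("incomplete_stop", "true"))
    if orf.genetic_code != "standard":
        pairs.append(("genetic_code", orf.genetic_code))
    return pairs


# ---------------------------------------------------------------------------
# Sequence extraction
# ---------------------------------------------------------------------------


def spliced_sequence(t: TranscriptModel, genome: GenomeSequence) -> str:
    """Mature transcript sequence: exon sequences concatenated 5'→3', with
    minus-strand exons reverse-complemented.  Trans-spliced transcripts
    concatenate per-exon strand-aware sequences in annotated exon order."""
    return "".join(genome.fetch(exon) for exon in t.exons)


def orf_sequence(orf: OrfAnnotation, genome: GenomeSequence) -> str:
    """Annotated coding sequence (stop codon included) in translation order."""
    return "".join(genome.fetch(seg) for seg in orf.cds_segments)


def introns_of(
    t: TranscriptModel, genome: GenomeSequence
) -> list[IntronRecord]:
    """One record per adjacent same-strand exon pair, with donor/acceptor
    dinucleotides read on the transcript strand.

    Cross-strand or cross-contig gaps (trans-spliced transcripts) are not
    introns in the spliceosomal sense and are skipped.
    """
    records: list[IntronRecord] = []
    for prev, nxt in zip(t.exons, t.exons[1:]):
        if prev.seqid != nxt.seqid or prev.strand != nxt.strand:
            continue
        if prev.strand == "+":
            start, end = prev.end, nxt.start
        else:
            start, end = nxt.end, prev.start
        if end - start < 4:
            raise AnnotationError(
                f"intron of length {end - start} on {t.transcript_id!r}; "
                "introns must be at least 4 nt"
            )
        interval = GenomicInterval(prev.seqid, start, end, prev.strand)
        seq = genome.fetch(interval)
        records.append(
            IntronRecord(
                interval=interval,
                donor=seq[:2],
                acceptor=seq[-2:],
                transcript_ids=[t.transcript_id],
            )
        )
    return records


def iter_all_introns(
    aset: AnnotationSet, genome: GenomeSequence
) -> Iterator[IntronRecord]:
    """Unique introns across the annotation, transcript support merged."""
    seen: dict[str, IntronRecord] = {}
    for tid in sorted(aset.transcripts):
        t = aset.transcripts[tid]
        if len(t.exons) < 2:
            continue
        for rec in introns_of(t, genome):
            if rec.key in seen:
                seen[rec.key].transcript_ids.append(tid)
            else:
                seen[rec.key] = rec
    yield from seen.values()
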