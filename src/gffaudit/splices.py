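"""Splice-site taxonomy, U12 tagging, junction auditing, and the census.

Canonical introns use the GT-AG (primary) or GC-AG (secondary) donor-
acceptor pair.  The candidate noncanonical pairs are those differing from
GT-AG by exactly one base with the donor G invariant — eight pairs, of
which AT-AC is *not* one (its donor does not start with G); AT-AC introns
are classified separately and subtyped U12/U2 by the 5' donor consensus of
the minor spliceosome.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from itertools import product
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .config import AuditConfig
from .model import (
    AnnotationSet,
    GenomeSequence,
    GenomicInterval,
    IntronRecord,
    TranscriptModel,
    introns_of,
    iter_all_introns,
)
from .vocab import CONVENIENCE_FLAGS, FLAG_ENDONUCLEASE_SPLICED

CANONICAL_PRIMARY = "GT-AG"
CANONICAL_SECONDARY = "GC-AG"

#: Census row order: AT-AC subtypes, the eight one-base-off candidates that
#: can occur, a Total over the noncanonical rows, then U12 introns with
#: canonical termini as footer rows (already counted among the canonicals).
CENSUS_PAIR_ROWS = (
    "AT-AC (U12)",
    "AT-AC (U2)",
    "GT-TG",
    "GT-GG",
    "GT-CG",
    "GT-AT",
    "GT-AA",
    "GA-AG",
    "GG-AG",
    "GT-AC",
)
CENSUS_FOOTER_ROWS = ("GT-AG (U12)", "GC-AG (U12)")
CENSUS_COLUMNS = (
    "n_introns",
    "junction_support",
    "similar_alternative",
    "within_coding",
    "within_5utr",
    "within_lncrna",
)


def enumerate_candidate_noncanonical_pairs() -> frozenset[str]:
    """Donor-acceptor pairs one base off GT-AG with the donor G invariant,
    excluding the two canonical pairs.  Exactly eight members."""
    pairs = set()
    for second in "ACG":  # donor G fixed, second base varies (GT excluded below)
        pairs.add(f"G{second}-AG")
    for first in "CGT":
        pairs.add(f"GT-{first}G")
    for second in "ACT":
        pairs.add(f"GT-A{second}")
    pairs -= {CANONICAL_PRIMARY, CANONICAL_SECONDARY}
    assert len(pairs) == 8
    return frozenset(pairs)


CANDIDATE_NONCANONICAL_PAIRS = enumerate_candidate_noncanonical_pairs()


def classify_intron(
    intron: IntronRecord,
    declared_flags: Iterable[str] = (),
    config: Optional[AuditConfig] = None,
) -> str:
    """Primary classification label for an intron.

    Declared convenience annotations (sequence gap / strain variation)
    override everything; a CA-TG intron is endonuclease-spliced only when
    its transcript declares the HAC1-type flag; otherwise classification is
    by the donor-acceptor pair.
    """
    declared = set(declared_flags)
    if declared & CONVENIENCE_FLAGS:
        return "convenience"
    pair = intron.pair
    if pair == "CA-TG" and FLAG_ENDONUCLEASE_SPLICED in declared:
        return "endonuclease_spliced"
    if pair == CANONICAL_PRIMARY:
        return "canonical_GT_AG"
    if pair == CANONICAL_SECONDARY:
        return "canonical_GC_AG"
    if pair in CANDIDATE_NONCANONICAL_PAIRS:
        return f"noncanonical:{pair}"
    if pair == "AT-AC":
        return "noncanonical_AT_AC"
    return "other_nonconforming"


def tag_u12(
    intron: IntronRecord,
    genome: GenomeSequence,
    config: Optional[AuditConfig] = None,
) -> bool:
    """True when the intron 5' end matches the configured U12 donor
    consensus (default ``[GA]TATCC`` at the intron start)."""
    cfg = config or AuditConfig()
    if len(intron.interval) < 10:
        return False
    seq = genome.fetch(intron.interval)
    return cfg.u12_regex().match(seq) is not None


# ---------------------------------------------------------------------------
# Similar alternative splices
# ---------------------------------------------------------------------------


def _donor_coord(iv: GenomicInterval) -> int:
    return iv.start if iv.strand == "+" else iv.end


def _acceptor_coord(iv: GenomicInterval) -> int:
    return iv.end if iv.strand == "+" else iv.start


def similar_alternative_splice(
    intron: IntronRecord,
    aset: AnnotationSet,
    genome: GenomeSequence,
) -> Optional[IntronRecord]:
    """An annotated canonical intron of the same gene sharing exactly one
    boundary with ``intron`` (same donor, different acceptor, or vice
    versa), preferring the smaller boundary shift, then the upstream
    (smaller-coordinate) alternative."""
    gene_ids: set[str] = set()
    for tid in intron.transcript_ids:
        gene_ids.update(aset.transcripts[tid].gene_ids)
    candidates: list[tuple[int, int, IntronRecord]] = []
    seen: set[str] = set()
    for gid in sorted(gene_ids):
        for t in aset.transcripts_of(gid):
            if len(t.exons) < 2:
                continue
            for other in introns_of(t, genome):
                if other.key == intron.key or other.key in seen:
                    continue
                seen.add(other.key)
                if other.interval.strand != intron.interval.strand:
                    continue
                if other.interval.seqid != intron.interval.seqid:
                    continue
                if other.pair not in (CANONICAL_PRIMARY, CANONICAL_SECONDARY):
                    continue
                same_donor = _donor_coord(other.interval) == _donor_coord(
                    intron.interval
                )
                same_acceptor = _acceptor_coord(other.interval) == _acceptor_coord(
                    intron.interval
                )
                if same_donor == same_acceptor:  # must share exactly one boundary
                    continue
                if same_donor:
                    shift_at = _acceptor_coord(other.interval)
                    shift = abs(shift_at - _acceptor_coord(intron.interval))
                else:
                    shift_at = _donor_coord(other.interval)
                    shift = abs(shift_at - _donor_coord(intron.interval))
                candidates.append((shift, shift_at, other))
    if not candidates:
        return None
    candidates.sort(key=lambda c: (c[0], c[1]))
    return candidates[0][2]


# ---------------------------------------------------------------------------
# Junction auditing
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class JunctionCall:
    """One external splice-junction call (RNA-Seq)."""

    seqid: str
    start: int  # zero-based half-open intron interval
    end: int
    strand: Optional[str] = None  # None = unstranded
    read_count: int = 0
    score: float = 0.0

    @property
    def stranded(self) -> bool:
        return self.strand in {"+", "-"}


@dataclasses.dataclass
class JunctionDiagnosis:
    verdict: str
    nearest_intron: Optional[str] = None  # IntronRecord.key
    offset: int = 0  # max boundary displacement to the nearest intron


def read_junctions_bed(path: str | Path) -> list[JunctionCall]:
    """Six-column BED of junction calls, half-open intron intervals.

    Column 4 (name) carries the supporting read count, column 5 the
    confidence score, column 6 the strand ('.' for unstranded data).
    """
    calls = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track")):
            continue
        fields = line.split("\t")
        if len(fields) < 6:
            raise ValueError(f"junction BED needs 6 columns, got {len(fields)}")
        chrom, start, end, name, score, strand = fields[:6]
        calls.append(
            JunctionCall(
                seqid=chrom,
                start=int(start),
                end=int(end),
                strand=strand if strand in {"+", "-"} else None,
                read_count=int(name),
                score=float(score),
            )
        )
    return calls


def write_junctions_bed(calls: Iterable[JunctionCall], path: str | Path) -> None:
    lines = []
    for c in calls:
        lines.append(
            "\t".join(
                [
                    c.seqid,
                    str(c.start),
                    str(c.end),
                    str(c.read_count),
                    format(c.score, "g"),
                    c.strand or ".",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


class JunctionAuditor:
    """Compares junction calls against the annotated intron set."""

    def __init__(
        self,
        aset: AnnotationSet,
        genome: GenomeSequence,
        config: Optional[AuditConfig] = None,
    ) -> None:
        self.config = config or AuditConfig()
        self.genome = genome
        self.introns = list(iter_all_introns(aset, genome))
        self._by_coords: dict[tuple[str, int, int], list[IntronRecord]] = {}
        for rec in self.introns:
            iv = rec.interval
            self._by_coords.setdefault((iv.seqid, iv.start, iv.end), []).append(rec)

    def _nearest(self, j: JunctionCall) -> tuple[Optional[IntronRecord], int]:
        best: Optional[IntronRecord] = None
        best_offset = 10**9
        for rec in self.introns:
            iv = rec.interval
            if iv.seqid != j.seqid:
                continue
            offset = max(abs(iv.start - j.start), abs(iv.end - j.end))
            if offset < best_offset:
                best, best_offset = rec, offset
        return best, best_offset

    def audit(self, j: JunctionCall) -> JunctionDiagnosis:
        cfg = self.config
        exact = self._by_coords.get((j.seqid, j.start, j.end), [])
        for rec in exact:
            if not j.stranded or j.strand == rec.interval.strand:
                if not j.stranded and rec.pair == "GT-AT":
                    # unstranded callers report a minus-strand GT-AT intron
                    # as a plus-strand AT-AC splice (and vice versa)
                    return JunctionDiagnosis("strand_flip_gt_at", rec.key, 0)
                return JunctionDiagnosis("matches_annotated", rec.key, 0)
            if rec.pair == "GT-AT":
                return JunctionDiagnosis("strand_flip_gt_at", rec.key, 0)
        nearest, offset = self._nearest(j)
        if nearest is not None and offset == 1 and nearest.pair in (
            CANONICAL_PRIMARY,
            CANONICAL_SECONDARY,
        ):
            return JunctionDiagnosis("off_by_one_artifact", nearest.key, 1)
        if j.read_count < cfg.junction_min_count or j.score < cfg.junction_min_score:
            return JunctionDiagnosis(
                "low_frequency", nearest.key if nearest else None, offset
            )
        if nearest is not None and offset <= cfg.junction_window:
            return JunctionDiagnosis("misaligned_near_annotated", nearest.key, offset)
        return JunctionDiagnosis(
            "unsupported_noncanonical", nearest.key if nearest else None, offset
        )


def audit_junction(
    j: JunctionCall,
    aset: AnnotationSet,
    genome: GenomeSequence,
    config: Optional[AuditConfig] = None,
) -> JunctionDiagnosis:
    """One-shot audit of a single junction call (builds the intron index)."""
    return JunctionAuditor(aset, genome, config).audit(j)


# ---------------------------------------------------------------------------
# Census
# ---------------------------------------------------------------------------


def intron_context(t: TranscriptModel, intron: IntronRecord) -> str:
    """'lncrna' for a noncoding host; '5utr' when the intron lies entirely
    5' of the CDS; otherwise 'coding' (introns spanning a CDS boundary and
    the rare 3'-UTR introns count as coding)."""
    if not t.is_coding:
        return "lncrna"
    index = t.transcript_index()
    cds_tpos = [
        index[key] for orf in t.orfs for key in orf.genomic_positions() if key in index
    ]
    cds_min = min(cds_tpos)
    iv = intron.interval
    upstream_exon_end = iv.start if iv.strand == "+" else iv.end
    # transcript coordinate of the exonic base immediately 5' of the intron
    if iv.strand == "+":
        before = (iv.seqid, upstream_exon_end - 1)
    else:
        before = (iv.seqid, upstream_exon_end)
    tpos = index.get(before)
    if tpos is not None and tpos < cds_min:
        return "5utr"
    return "coding"


def _empty_census() -> pd.DataFrame:
    rows = list(CENSUS_PAIR_ROWS) + ["Total"] + list(CENSUS_FOOTER_ROWS)
    return pd.DataFrame(
        0, index=pd.Index(rows, name="pair"), columns=list(CENSUS_COLUMNS)
    )


def add_total_row(df: pd.DataFrame) -> pd.DataFrame:
    """Recompute the Total row as the column sums of the noncanonical pair
    rows (footer rows are already counted among the canonical introns)."""
    out = df.copy()
    out.loc["Total"] = out.loc[list(CENSUS_PAIR_ROWS)].sum()
    return out


def observed_candidate_pairs(df: pd.DataFrame) -> int:
    """How many of the eight one-base-off candidate pairs are observed."""
    count = 0
    for pair in sorted(CANDIDATE_NONCANONICAL_PAIRS):
        if pair in df.index and df.loc[pair, "n_introns"] > 0:
            count += 1
    return count


def load_reference_census() -> pd.DataFrame:
    """Published per-pair census of noncanonical splice sites in the
    FlyBase *D. melanogaster* annotation (release 6.04), without the Total
    row (recompute it with :func:`add_total_row`)."""
    with resources.files("gffaudit.data").joinpath("noncanonical_census.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", index_col="pair")
    return df.reindex(list(CENSUS_PAIR_ROWS) + ["Total"] + list(CENSUS_FOOTER_ROWS)).fillna(0).astype(int)


def splice_summary(
    aset: AnnotationSet,
    genome: GenomeSequence,
    junctions: Iterable[JunctionCall] = (),
    config: Optional[AuditConfig] = None,
) -> pd.DataFrame:
    """Census of noncanonical splice sites in an annotation set.

    Per donor-acceptor pair: intron count, count with an exactly matching
    junction call, count with a similar alternative canonical splice, and
    counts by context (coding / 5' UTR / lncRNA host).  Convenience splices
    are excluded.  The Total row sums the noncanonical pair rows; U12
    introns with canonical termini appear as footer rows.
    """
    cfg = config or AuditConfig()
    df = _empty_census()
    junction_coords: dict[tuple[str, int, int], list[Optional[str]]] = {}
    for j in junctions:
        junction_coords.setdefault((j.seqid, j.start, j.end), []).append(j.strand)

    for intron in iter_all_introns(aset, genome):
        declared: set[str] = set()
        contexts: set[str] = set()
        for tid in intron.transcript_ids:
            t = aset.transcripts[tid]
            declared.update(t.declared_flags)
            contexts.add(intron_context(t, intron))
        label = classify_intron(intron, declared, cfg)
        is_u12 = tag_u12(intron, genome, cfg)
        row: Optional[str] = None
        if label.startswith("noncanonical:"):
            row = label.split(":", 1)[1]
        elif label == "noncanonical_AT_AC":
            row = "AT-AC (U12)" if is_u12 else "AT-AC (U2)"
        elif label == "canonical_GT_AG" and is_u12:
            row = "GT-AG (U12)"
        elif label == "canonical_GC_AG" and is_u12:
            row = "GC-AG (U12)"
        if row is None:
            continue
        df.loc[row, "n_introns"] += 1
        iv = intron.interval
        strands = junction_coords.get((iv.seqid, iv.start, iv.end))
        if strands is not None and any(s is None or s == iv.strand for s in strands):
            df.loc[row, "junction_support"] += 1
        if "coding" in contexts:
            df.loc[row, "within_coding"] += 1
        elif "5utr" in contexts:
            df.loc[row, "within_5utr"] += 1
        else:
            df.loc[row, "within_lncrna"] += 1
        if row not in CENSUS_FOOTER_ROWS:
            if similar_alternative_splice(intron, aset, genome) is not None:
                df.loc[row, "similar_alternative"] += 1
    return add_total_row(df)
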