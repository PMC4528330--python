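# Methods

This note records the model behind each classifier, the tunable parameters,
the conventions chosen where annotation practice leaves the arithmetic
open, and what the synthetic fixtures do and do not demonstrate.

## Coordinates and the gene-model representation

Internally every interval is zero-based half-open on an explicit strand;
GFF3 (1-based inclusive) is converted only at the I/O boundary.  A
transcript owns an ordered exon list in mature-mRNA (5′→3′) order and one
ORF per encoded gene; the CDS includes the stop codon.  Standard GFF3
cannot bind two CDS groups of one mRNA to two distinct genes, so the
dialect adds a multi-valued `Parent` on the mRNA plus a per-CDS `gene=`
attribute.  Mixed-strand exon lists are accepted only on transcripts
explicitly declared `trans_spliced_transcript` — undeclared mixed-strand
input is treated as an error precisely because such models are so often
assumed to be mistakes.  Codon indices in exception declarations are
1-based.  One deliberate deviation from a strict "CDS length ≡ 0 mod 3"
rule: a declared +1 ribosomal frameshift consumes one extra template base,
so a contiguous annotated CDS for that case has remainder 1; validation
permits exactly that (and remainders 1–2 with a declared incomplete stop).

Circularity of the mitochondrial contig is carried as metadata only;
origin-spanning gene models are out of scope and error at sequence
extraction.

## Cistronic classification

Arity is the number of ORFs on a transcript.  Intercistronic distance is
measured on the mature transcript as *t*(first base of downstream start) −
*t*(last base of upstream stop) − 1, so an immediately abutting start
scores 0 and coding regions overlapping in different frames score negative
(an overlap of *k* nt scores −*k*).  This convention was chosen to match
the sign of curated negative distances; the endpoint arithmetic is not
otherwise standardized, so it is documented here and pinned by tests.
Small-polypeptide bins (<25 aa, 25–45 aa, >45 aa) are computed on the
predicted peptide excluding the stop, after frameshift/stop-completion
accounting.

## Overlap classification

The substrate is the codon-offset map: genomic position → (index within
the spliced CDS) mod 3.  Any base coding in two same-strand ORFs is then
*same-frame* (offsets equal) or *multiphasic* (offsets differ) — a
partition, enforced by a property test.  Maximal runs of conflicting bases
become multiphasic regions annotated with: whether the run includes either
ORF's stop codon, whether it includes a translation start (the operational
meaning of "first coding exon involvement" — without the start-codon
anchor, any single-exon isoform overlap would trivially involve a first
coding exon), and whether the two ORFs belong to different genes.

Comment assignment: cross-gene regions always receive the cross-gene
comment (the 40-nt rule reads as a within-gene rule); within a gene,
first-coding-exon involvement takes precedence, then extents shorter than
`multiphasic_short_nt` (default 40 nt, stop codon included) are flagged as
alternative translation stops, everything else as a multiphase exon.
Because the extent includes the stop codon, the 40-nt rule bounds the
encoded amino acids strictly below ⌊39/3⌋ = 13.  Extents above
`long_overlap_nt` (default 63 nt, i.e. >20 aa) are additionally marked
`long_overlap`.  Opposite-strand CDS intersections are reported as
bidirectional regions with the standardized comment.

Noncoding overlaps: a shared promoter is operationalized as an identical
5′-most exon start on the same strand (no distance threshold is published;
`shared_promoter_exact` keeps this strict).  Identical 5′-terminal exons →
"Shares 5′ exon(s)"; promoter-only sharing → "Shares 5′ UTR"; identical
3′-terminal exons → "Shares 3′ UTR"; both ends → "Complex/atypical
overlap".  A gene nested in another's intron and a 3′-UTR-over-5′-UTR
chain are recognized but deliberately unflagged (no comment), mirroring
curation practice of not treating them as unruly.

## Splice classification and junction auditing

Candidate noncanonical pairs are those one base off GT-AG with the donor G
invariant — eight pairs, reproduced in tests by exhaustive enumeration over
all 256 dinucleotide pairs.  AT-AC is *not* in this set (its donor violates
the invariant) and is classified separately, subtyped U12/U2 by the minor
spliceosome's 5′ donor consensus.  The U12 recognizer is a configurable
anchored pattern, default `[GA]TATCC` at the intron start; branch-point
matching is omitted because the 5′ consensus is the discriminative part at
the scale of this tool.  A CA-TG intron is endonuclease-spliced only when
the transcript declares the HAC1-type flag; declared convenience splices
(sequence gap, strain variation) are excluded from the census and do not
trigger the noncanonical-splice transcript flag.

"Similar alternative splice" has no published definition; here it is an
annotated canonical intron of the same gene sharing exactly one boundary
(same donor or same acceptor position, strand-aware), preferring the
smaller coordinate shift and breaking ties toward the upstream option, with
no distance cap within the gene.

Junction audits compare external calls to the annotated intron set in this
order: exact coordinate match (for an unstranded call that coincides with a
GT-AT intron the verdict is `strand_flip_gt_at`, since unstranded callers
report those as AT-AC on the opposite strand); both boundaries within 1 nt
of a canonical intron → `off_by_one_artifact`; read count below
`junction_min_count` (default 2) or score below `junction_min_score`
(default 0) → `low_frequency`; within `junction_window` (default 6 nt) of
an annotated intron → `misaligned_near_annotated`; otherwise
`unsupported_noncanonical`.  The published culling thresholds are not
numeric, so the defaults are conservative and configurable.  The census
counts *exact* junction support and reports near-misses separately;
context columns assign an intron to "within coding" when it touches the
CDS (3′-UTR introns, which the three published context columns do not
name, are folded into coding), "within 5′ UTR" when entirely upstream of
the CDS, and "lncRNA" for noncoding hosts.  The package ships the published
release 6.04 per-pair census as data; its Total row is always recomputed
from the pair rows, never stored.

## Translation engine

Genetic codes come from the NCBI tables (standard = 1, invertebrate
mitochondrial = 5) via Biopython.  A declared non-AUG start translates as
methionine, since initiation pairs the near-cognate codon with Met-tRNAi.
An undetermined start (the *mt:CoI* situation) is translated from the
annotated first codon by the code table with a recorded caveat — no
methionine is imposed, because the declaration asserts ignorance, not a
near-cognate start.  Declared readthrough stops yield `X`, declared Sec
positions yield `U` (and must be TGA); the two are distinguished purely by
declaration — no SECIS search is attempted, and readthrough extents are
taken from the annotation rather than recomputed from conservation, which
is outside this tool's scope (a `next_in_frame_stop` helper exists for
fixture construction).  A +1 frameshift skips one template base after the
declared codon; incomplete stops are completed to TAA by appended A's
(anything not ending T/TA is an error).  Translation must end at the first
undeclared in-frame stop and that stop must be the final codon; violations
raise errors naming the codon index, because they indicate an inconsistent
annotation, not a sequence to silently truncate.  Codons containing N
translate to `X`.

## Flag binding

Gene-level Sequence Ontology terms and transcript-level flag tokens are
emitted verbatim from a single vocabulary module (including the
`non-canonical_start_codon` token, whose mixed hyphen/underscore spelling
is part of the exchange format).  A CUG start receives both the generic
unconventional-start term and the CUG-specific term.  Multiphasic and
bidirectional findings are gene-model comments only; the affected
transcripts are not flagged, and no translation exception is implied.
A-to-I handling is genome-site passthrough: supplied sites tag overlapping
genes `gene_with_edited_transcript` (SO:0000548) and are listed site-level
as `modified_RNA_base_feature` (SO:0000250); edited transcript or peptide
sequences are never constructed.  Reports (JSON with sorted keys, TSV
tables) and the flagged FASTA use fixed field orders so identical inputs
produce byte-identical outputs.

## Synthetic fixtures

The generator plants one locus per requested category on a random uniform
ACGT background (default ~14 kb nuclear contig + ~0.9 kb circular
mitochondrial contig, ~40 genes), with every planted ORF kept free of
accidental in-frame stops by rejection sampling under forced bases (starts,
stops, splice dinucleotides, frame-shifting acceptors), so the expected
peptide of every ORF is computable at planting time and recorded in the
manifest.  Canonical introns are forced to a non-U12 third base so the U12
tag fires only where planted.  Alternative-splice isoforms use ±6-nt
boundary shifts: a ±1 shift cannot carry AG at both acceptor positions,
and a frame-preserving shift avoids planting unrequested multiphasic
regions.  The GT-AT locus is planted on the minus strand so that stripping
the strand from its (co-planted) junction call reproduces the AT-AC
strand-flip artifact; one off-by-one, one low-frequency, one misaligned
and one unsupported junction are planted per fixture.  Default sizes keep
a full 20-seed closed loop (generate → audit → compare to manifest) under
a second, which is the problem size the acceptance script uses.

What passing the closed loop shows: every classifier recovers exactly what
was planted, with no spurious calls, across random backgrounds.  What it
does not show: behaviour on real genomes — the fixtures have uniform base
composition, short introns without branch-point structure, no repeats
(whose spurious junction calls the auditor would only bucket as
unsupported), no alternative transcription starts, and no conservation
signal; readthrough and Sec rely on declarations, as they do in the real
exchange files.

## Known limitations

Origin-wrapping mitochondrial genes are unsupported; the 40-nt rule is
never applied to cross-gene regions; census "similar alternative" counts
depend on the one-shared-boundary definition above; junction auditing
assumes half-open BED intervals equal to intron coordinates; GFF3 input
must follow the documented dialect (GTF/GenBank are out of scope).
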