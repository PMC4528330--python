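# gffaudit

Audit genome annotations for **exceptional gene models** — the cases that
break the one-gene/one-mRNA/one-ORF assumptions most bulk-data pipelines
make.  The taxonomy follows the curation practice of the FlyBase
*Drosophila melanogaster* annotation:

* **polycistronic transcripts** — one mature mRNA encoding two or more
  separately annotated genes (di-, tri-, tetracistronic), with
  intercistronic distances measured on the mature transcript;
* **shared and overlapping gene models** — shared promoters and 5′ exons,
  shared 3′ UTRs, same-frame CDS overlaps (gene fusions), *multiphasic*
  regions (the same genomic bases translated in two reading frames on the
  same strand) and *bidirectional* regions (coding on both strands);
* **noncanonical splicing** — classification of every intron by its
  donor–acceptor dinucleotides (GT-AG, GC-AG, the eight one-base-off
  candidate pairs with invariant donor G, AT-AC), U12 minor-spliceosome
  tagging, HAC1-type endonuclease-processed introns (the *Xbp1* case),
  detection of similar alternative canonical splices, and auditing of
  RNA-Seq junction calls (exact matches, strand-flipped GT-AT/AT-AC calls,
  off-by-one artifacts, low-frequency culling);
* **trans-splicing** — declared mixed-strand transcripts à la *mod(mdg4)*;
* **translation exceptions** — non-AUG starts (translated as Met),
  selenocysteine recoding (U), stop-codon readthrough including double
  readthrough (X at suppressed stops), the single +1 ribosomal frameshift
  (*Oda*), the invertebrate mitochondrial genetic code (NCBI table 5),
  incomplete stop codons completed by polyadenylation, and undetermined
  starts;
* **A-to-I editing** — genome-site passthrough tagging only.

Detected classes are bound to Sequence Ontology terms at the gene level
(e.g. `gene_with_dicistronic_mRNA` SO:0000722) and to a controlled
transcript-flag vocabulary (e.g. `stop_codon_read_through`) emitted in
reports and FASTA headers, and peptides are derived correctly under every
declared exception.

The package is aimed at annotation curators and pipeline authors who need
to detect, validate, or propagate these cases, and it ships a deterministic
fixture generator that plants every category with a ground-truth manifest,
so the whole classifier stack is testable without external data.

## Input conventions

Genomes are plain FASTA (a `circular=true` description token marks the
mitochondrion).  Gene models are GFF3 with a small documented dialect: an
mRNA encoding several genes lists them all in `Parent=`, every CDS row
names its owning gene in a `gene=` attribute, exception declarations ride
as attributes (`flags=`, `start_codon=`, `readthrough_codons=`,
`selenocysteine_codons=`, `frameshift_codon=`, `incomplete_stop=`,
`genetic_code=`), and exons carry `rank=` so trans-spliced transcripts can
order exons from both strands.  Junction calls are 6-column BED (name =
read count, score = confidence, `.` = unstranded); editing sites are
`seqid<TAB>1-based position`.  See `src/gffaudit/model.py` for the full
dialect description.

## Worked example

```sh
gffaudit fixtures --seed 9 --out-dir fx9
gffaudit audit --genome fx9/genome.fa --gff fx9/models.gff3 \
    --junctions-bed fx9/junctions.bed --editing-sites fx9/editing_sites.tsv \
    --out-dir out9
```

The audit of this 40-gene toy annotation reports (from `out9/report.json`):

```
counts: genes 40, transcripts 42, introns 26, multiphasic_regions 4,
        overlap_calls 3, junctions 13
census Total: 8 noncanonical introns, 8 junction-supported, 6 with a
        similar alternative canonical splice, all within coding sequence
```

Among the multiphasic regions is a 70-nt cross-gene overlap on a
dicistronic transcript ("Multiphase exon postulated: this gene shares a
region of coding sequence with an overlapping gene, …", marked as a long
overlap of >20 aa) and a 30-nt within-gene region ("Alternative
translation stop created by use of multiphasic reading frames within
coding region").  A planted readthrough gene comes back as:

```
>t0038 genes=g0036 flags=stop_codon_read_through
...
t0038:g0036  gene SO term: gene_with_stop_codon_read_through (SO:0000697)
peptide: MELALREXTHSGH        # X marks the suppressed stop codon
```

`gffaudit splice-census` prints the per-pair census table (one row per
donor–acceptor pair with counts, junction support, similar-alternative and
context columns plus a Total row), `gffaudit junctions` the per-call
verdicts, and `gffaudit translate` the exception-aware protein FASTA.

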