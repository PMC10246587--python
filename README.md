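# neopept

Candidate tumor-antigen peptide generation, harmonized RNA read-support
quantification, and pMHC report assembly — across eight genomic antigen
sources, from one set of standard bioinformatics files.

## The problem

Tumor cells present peptides on MHC class I molecules that normal cells do
not. These tumor antigens are the raw material of personalized cancer
vaccines and adoptive T-cell therapies, but they arise from very different
genomic events: somatic SNVs and InDels, gene fusions, tumor-specific
splice variants (retained introns, exon skips, novel junctions), oncogenic
viruses, aberrantly expressed endogenous retrovirus (ERV) open reading
frames, and over-expressed cancer-testis/self-antigen (CTA) genes. Most
tools handle one or two of these classes; `neopept` constructs candidate
peptides from all of them, with class-specific sequence rules, and scores
every candidate with a single abundance metric so they can be prioritized
together.

`neopept` consumes the *outputs* of standard upstream tools — a reference
FASTA + GTF, per-caller somatic VCFs, a phased germline VCF, a
STAR-Fusion-style fusion table, a splice-event table, viral CDS FASTA with
RNA-called variants, ERV ORF annotations with tumor/normal count tables, a
CTA gene list, a TPM table, tumor RNA reads, and the patient's HLA
alleles. It does not run aligners, variant callers, or binding predictors;
binding prediction is a pluggable adapter (a deterministic mock ships by
default, and NetMHCpan-format output files can be parsed).

## The method

**Per-class peptide construction.**

* *SNV/InDel* — somatic variants are taken as the consensus of multiple
  callers (by default the intersection of two callers for SNVs and of
  three for InDels; union mode is available), filtered to coding
  consequences, then applied to the spliced CDS together with the phased
  heterozygous germline variants on the **same haplotype block and
  haplotype** (homozygous germline variants always apply). Missense and
  in-frame products restrict peptides to k-mer windows overlapping the
  altered residues; frameshifts translate to the first stop codon with
  everything downstream novel.
* *Fusion* — the 5' partner's CDS prefix up to the breakpoint is joined to
  the 3' partner's sequence from its breakpoint. In-frame products are
  truncated to a configurable number of residues on each side of the
  junction; frameshift products keep the upstream truncation and run to
  the first stop.
* *Splice* — retained introns append the intron to the upstream CDS and
  translate to the first stop; exon skips and novel junctions excise a
  region from the spliced CDS (frame-preserving excisions report only
  junction-spanning windows).
* *Virus / ERV / CTA-self* — the whole coding sequence (with homozygous
  variants incorporated) is translated and every k-mer window emitted.
  ERV ORFs must first pass the tumor/normal expression filter
  log2(CPM_tumor + 1) − log2(CPM_normal + 1) > 1; CTA transcripts must
  exceed a TPM percentile threshold (default 75th).

**Harmonized abundance.** Every candidate carries the exact nucleotide
subsequence that codes it. Its *read support* is the number of tumor RNA
reads containing that subsequence verbatim (either strand); fusion
peptides are scored against junction-crossing reads and spanning pairs.
Unlike TPM, this counts only the peptide-generating allele and is
comparable across all source classes.

**Report.** Candidates surviving the read-evidence filter are crossed with
the patient's HLA alleles through the predictor adapter, annotated with
affinity, stability, and agretopicity (mutant/wild-type affinity ratio,
where a wild-type counterpart exists), filtered per class (CTA/self
default: affinity < 50 nM; other classes: < 500 nM), and written as a
deterministic TSV sorted by source class, affinity, and read support.

## Worked example

Everything needed to try the tool can be generated from a seed — a toy
patient with one planted event of every antigen class and a table of the
peptides they should yield:

```sh
neopept make-fixture --seed 1 --out patient1
neopept all \
  --genome patient1/genome.fa --gtf patient1/annotation.gtf \
  --somatic-vcf mutect2=patient1/somatic_mutect2.vcf \
  --somatic-vcf strelka2=patient1/somatic_strelka2.vcf \
  --somatic-vcf abra2=patient1/somatic_abra2.vcf \
  --germline-vcf patient1/germline.vcf \
  --fusions patient1/fusions.tsv --splice-events patient1/splice_events.tsv \
  --viral-cds patient1/viral_cds.fa --viral-vcf patient1/viral_variants.vcf \
  --erv-bed patient1/erv_orfs.bed \
  --erv-counts-tumor patient1/erv_counts_tumor.tsv \
  --erv-counts-normal patient1/erv_counts_normal.tsv \
  --cta-list patient1/cta_genes.txt --tpm patient1/tpm.tsv \
  --reads patient1/reads.fastq --alleles patient1/alleles.txt \
  --config patient1/run_config.json --out run1
```

The run log reports per-stage tallies:

```
INFO neopept: snv_indel_candidates: 104
INFO neopept: fusion_candidates: 134
INFO neopept: splice_candidates: 49
INFO neopept: viral_candidates: 100
INFO neopept: erv_orfs_passing: 1
INFO neopept: erv_candidates: 42
INFO neopept: cta_candidates: 82
INFO neopept: candidates_total: 511
INFO neopept: candidates_with_read_support: 461
INFO neopept: report_rows: 922
report written: run1/report.tsv (922 rows)
```

511 candidate peptides were generated; 461 have their coding sequence
detectable in the tumor RNA reads (the 50 dropped ones belong to an
unexpressed viral CDS planted as a negative control), and each surviving
peptide appears once per HLA allele (2 alleles → 922 rows). The first
report rows look like:

```
source_class  peptide      allele       ...  affinity_nM  read_support  tpm
CTA_SELF      SRLPTEELDEL  HLA-B*07:02  ...  1.01293      1             190.0
CTA_SELF      ETKTSSRLPTE  HLA-B*07:02  ...  1.03879      1             190.0
```

The reported peptide set equals the fixture's `truth.tsv` exactly, and the
planted decoys (an ERV failing the fold-change filter, a CTA gene below
the expression percentile, the unexpressed virus, caller-private variant
artifacts) are all absent.

## Layout

```
src/neopept/
  reference.py   FASTA/GTF loading, transcript models, CDS extraction, translation
  variants.py    VCF parsing, normalization, consensus, coding effects, phasing, editing
  sources.py     per-class candidate peptide generation
  quantify.py    harmonized read support, TPM percentile, CPM, ERV fold-change filters
  report.py      predictor adapters, per-source filters, report assembly
  fixtures.py    seeded toy-patient generator with independent ground truth
  pipeline.py    end-to-end orchestration
  cli.py         `neopept` command-line interface
```

See `docs/methods.md` for modelling assumptions, parameter defaults, and
known limitations.
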