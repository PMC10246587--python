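# Methods

This note documents the models, rules, and numerical choices behind
`neopept`, what its synthetic data does and does not emulate, and the
design decisions taken where the design was genuinely open.

## Coordinate and sequence conventions

All intervals are 0-based, half-open internally. GTF (1-based inclusive)
and VCF (1-based) coordinates are converted at the parsing boundary, and
intervals in logs and reports are printed 1-based inclusive. Soft-masked
reference sequence is uppercased on load — repeat masking carries no
information for peptide generation. Translation uses the standard genetic
code (NCBI table 1) with no selenocysteine handling; codons containing N
translate to `X`; a trailing partial codon is ignored rather than
rejected, because real annotations contain CDS models whose length is not
a multiple of 3 and failing hard would block whole runs.

## Variant handling

Variant identity is the normalized `(contig, pos, ref, alt)` key:
multi-allelic records are split one variant per ALT, shared prefix/suffix
bases are trimmed, and pure indels are left-aligned against the reference.
Without normalization, equivalent indel representations from different
callers would silently break the consensus intersection. Only records with
FILTER `PASS` or `.` enter combination by default (`--keep-nonpass`
overrides); FILTER semantics differ between callers, so the conservative
default is to trust each caller's own verdict.

Consensus combination is plain set arithmetic on normalized keys:
intersection (default) or union, with per-class caller lists — two callers
for SNVs, three for InDels by default. Record-level metadata comes from
the first caller listing a key; full per-caller provenance is carried into
the report.

### Phasing

A heterozygous germline variant is incorporated into a somatic peptide
only when it shares the somatic variant's phase set *and* haplotype index
(allele left of `|` is haplotype 0, right is haplotype 1). Homozygous
germline variants are incorporated everywhere regardless of phasing. When
the somatic variant itself is unphased, heterozygous neighbors are
excluded with a warning rather than guessed onto a haplotype: a wrong
guess would fabricate a peptide the tumor does not make, which is worse
for vaccine design than missing a germline-modified variant of a peptide
it does make. When somatic and germline edits collide on the same base,
the somatic edit wins and the germline edit is dropped with a warning.

Het germline incorporation applies only to the SNV/InDel path, where the
somatic variant anchors a haplotype; the fusion, viral, ERV, and CTA paths
incorporate homozygous variants only (phasing across a fusion junction is
not attempted).

## Peptide windows and novelty

Peptides are k-mers of the mutant protein; `k_lengths` defaults to 8–11,
the MHC class I convention, and is configurable per run. Every emitted
candidate satisfies `translate(coding_nt) == peptide`, where `coding_nt`
is the in-register nucleotide slice of the mutant coding sequence — the
invariant that makes the harmonized abundance metric possible.

A residue is *novel* when the unmutated reference protein does not contain
it at the aligned position: the positional diff for substitutions and
in-frame indels, everything from the first frame-shifted codon for
frameshifts, and the junction-spanning residues for fusions and
frame-preserving splice events. Windows must overlap the novel span (for
in-frame junctions: contain residues from both sides of the junction).
Two further rules close loopholes in this definition:

* the first frame-shifted codon is identified at the *nucleotide* level
  (first position where edited and reference CDS differ), so an insertion
  landing on a codon boundary does not mark the preceding, unchanged
  residue as novel;
* a chimeric junction codon can by chance re-encode the original residue,
  making a "novel-span" window identical to a window of the unmutated
  protein. Candidates from the mutated classes (SNV/InDel/fusion/splice)
  whose peptide occurs verbatim in the relevant reference protein(s) are
  therefore dropped — they are self peptides. Because of this check (and
  of k-mer windows repeated within one protein), report rows are unique on
  (peptide, allele, source class, origin, coding sequence).

Fusion upstream truncation defaults to `max(k_lengths) − 1` residues,
the smallest length that preserves every junction-spanning window. When a
stop codon occurs before an in-frame fusion's downstream truncation point,
translation stops at the stop.

For retained introns the construct is the upstream CDS plus the intron,
translated to the first stop; downstream exons are not appended, since the
reading frame beyond the intron is undefined for prioritization purposes
once a stop has not been reached inside the intron. Splice events that do
not touch the CDS (UTR-only) yield no peptides.

## Quantification

**Read support** counts reads containing the candidate's exact coding
subsequence, on either strand (library strandedness is not assumed; a
forward-only flag exists, as does Hamming-distance-1 matching, both off by
default — the metric is exact by definition). A read counts once no matter
how many match offsets it has; paired-end mates are independent reads,
except that a fusion *spanning pair* counts once. When alignments (SAM)
are provided, only reads overlapping the candidate's genomic origin are
scanned and the pool size is reported as denominator context; with FASTQ
input the whole read set is scanned (exact 24–33-mer matches elsewhere in
a transcriptome are vanishingly unlikely at toy scale and rare at genome
scale).

**TPM percentile filter** (SNV/InDel and CTA transcripts): the threshold
is the linear-interpolation percentile of TPM over all *expressed*
(TPM > 0) features — a `population="all"` flag includes zeros — and a
transcript passes only if its TPM strictly exceeds it, so at the 100th
percentile nothing passes. Default percentile: 75.

**ERV fold-change filter**: an ORF passes iff
log2(CPM_tumor + 1) − log2(CPM_normal + 1) > 1 (strict; the boundary case
of tumor 3 CPM vs normal 1 CPM gives exactly 1 and is excluded). The log
base is fixed to 2, the convention for expression fold changes. CPM is
plain counts-per-million with the library size defaulting to the count
table's total; no TMM-style compositional normalization is applied, and
externally normalized CPM tables can be supplied instead. One normal CPM
vector is accepted; aggregating a normal cohort is left to the caller.

## pMHC features and filtering

Binding predictors are integrated only as adapters — no subprocess is
launched. The default `MockPredictor` maps (seed, peptide, allele) through
SHA-256 to a log-uniform affinity in [1, 50000] nM and a uniform stability
half-life in [0, 12] h: a pure function, so whole runs are reproducible
offline. A NetMHCpan-format output parser is provided for real
predictions. Agretopicity is the mutant/wild-type affinity ratio, computed
only where a positionally aligned wild-type peptide exists (substitutions);
frameshift, viral, ERV, and splice peptides have no wild-type counterpart
and the field is omitted, as are dissimilarity/foreignness unless an
adapter supplies them.

Report filters are per source class: the CTA/self class defaults to the
stringent affinity < 50 nM rule; all other classes default to the
community 500 nM convention, exposed in config as an explicit
interpretation rather than a reproduction claim. Optional stability floors
and a global minimum read support (default 1) complete the filter. The
report sort (source class, ascending affinity, descending read support,
then peptide and allele) and a fixed float format make the TSV
byte-deterministic.

Clonality (cancer-cell fraction) is an optional passthrough column from an
external table; no estimation is performed.

## Synthetic toy patient

The fixture generator emits, from one integer seed, every input file the
pipeline consumes plus a truth table of expected peptides. The toy genome
(default 20 genes of 90 bp CDS cycling through 1–3 exons on alternating
strands, ~5 kb total) plants one event of every class: a phased missense
SNV (with same- and opposite-haplotype germline neighbors), an in-frame
and a frameshift insertion, an in-frame and a frameshift fusion, a
retained intron, an exon skip, an expressed viral CDS with a homozygous
RNA variant, an ERV ORF passing the fold-change filter with a homozygous
germline variant, and a CTA gene above the expression percentile. Negative
controls plant the complements: caller-private variant artifacts, an
unexpressed viral CDS, an ERV failing the fold-change filter, and a CTA
gene below the percentile. Three-exon genes get a frame-preserving middle
exon so exon-skip events are codon-clean; sites for planted substitutions
are scanned for a guaranteed missense alternative.

Every expected peptide set is computed *independently* of the pipeline
code, by direct string edits, direct translation, and brute-force window
loops. Reads are error-free 50-mers tiled over each expressed tumor
sequence with a step small enough that any coding subsequence up to
3·max(k) nt lies wholly inside at least one read (alternating reads are
reverse complemented); a seeded "sampled" mode exists for stress tests,
but exact truth-table recovery is only guaranteed in tiled mode at error
rate 0. Background genes are given low expression and no reads — they
generate no candidates, so reads for them would only add runtime.

The fixture's emitted run config disables the affinity ceilings: the mock
predictor's affinities are hash values carrying no planted signal, so
filtering on them would make the reported set depend on the hash rather
than on the planted biology. The 50 nM/500 nM ceilings are exercised
separately in unit tests and in the acceptance script's filter check.

What the toy patient does **not** emulate: sequencing errors and quality
variation, expression realism (GC bias, length bias, isoform mixtures),
multi-transcript genes, UTRs and non-coding RNA, structural-variant
breakpoints outside annotated CDS, subclonal architecture, and HLA typing
ambiguity. Passing the end-to-end test therefore demonstrates the
correctness of the sequence arithmetic, filter logic, and plumbing — not
robustness to noisy real-world inputs.

## Problem sizes

The default test and acceptance problem sizes — a ~5 kb genome, ~500
candidate peptides, a few hundred reads, 1000-case randomized oracle
comparisons for the read-support counter, the window enumerator, and the
coding-effect classifier — were chosen as the smallest scales at which
every code path (both strands, all three exon counts, every event class,
every filter branch) is exercised; the whole suite runs in seconds.

## Known limitations

* Somatic variants spanning splice junctions (multi-exon REF spans) are
  skipped with a warning rather than modelled.
* In-frame fusion peptides assume the 3' partner is read in its annotated
  frame from the breakpoint; non-coding 3' breakpoints (UTR/intron) are
  skipped.
* The splice-event vocabulary is retained introns, exon skips, and
  excised novel junctions; more complex re-wirings (mutually exclusive
  exons, novel cassette exons) are not constructed.
* Binding, processing, presentation, immunogenicity, foreignness, and
  dissimilarity are adapter slots, not models; MHC class II lengths are
  out of scope.
* Read-support counting is exact substring matching; it will undercount
  when reads carry sequencing errors inside the coding subsequence.
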