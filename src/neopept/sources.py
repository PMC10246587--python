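"""Candidate peptide generation for the eight tumor-antigen source classes.

Each source class has its own sequence-construction rule:

* somatic SNV/InDel — spliced CDS edited with the somatic variant plus the
  phased germline variants on the same haplotype; missense/in-frame events
  restrict peptides to windows overlapping the altered residues, frameshifts
  translate to the first stop and every downstream residue is novel;
* fusion — 5' partner CDS prefix joined to 3' partner sequence at the
  breakpoints; in-frame products are truncated to a user-specified number of
  residues on either side of the junction, frameshift products keep the
  upstream truncation and run to the first stop;
* splice — retained introns append intron sequence to the upstream CDS and
  translate to the first stop; exon skips and novel junctions excise a
  region from the spliced CDS;
* virus / ERV / CTA-self — whole coding sequence (with homozygous variants
  incorporated) is translated and every k-mer window is a candidate, since
  there is no wild-type counterpart in the presented self proteome.

All classes funnel through :func:`enumerate_peptides`, which guarantees the
central invariant: the emitted ``coding_nt`` translates exactly to the
emitted peptide, enabling the harmonized read-support metric downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

from Bio import SeqIO

from .reference import (
    GenomeSequence,
    InputContractError,
    Interval,
    TranscriptModel,
    extract_cds,
    extract_intervals,
    format_origin,
    reverse_complement,
    translate,
)
from .variants import (
    Effect,
    Variant,
    Zygosity,
    apply_variants,
    drop_conflicting_germline,
    variant_to_cds_edit,
)

logger = logging.getLogger(__name__)


class SourceClass(str, Enum):
    SNV = "SNV"
    INDEL = "INDEL"
    FUSION = "FUSION"
    SPLICE = "SPLICE"
    VIRUS = "VIRUS"
    ERV = "ERV"
    CTA_SELF = "CTA_SELF"


@dataclass(frozen=True)
class PeptideCandidate:
    """A candidate tumor-antigen peptide and its exact coding subsequence.

    ``novel_positions`` are 0-based indices *within the peptide* of residues
    absent from the unmutated reference protein; for classes without a
    wild-type counterpart (virus, ERV, CTA/self) every residue is novel.
    ``wt_peptide`` is the positionally aligned reference window when one
    exists (substitutions only) — used for agretopicity.
    """

    peptide: str
    coding_nt: str
    source_class: SourceClass
    origin: str
    gene_id: Optional[str] = None
    transcript_id: Optional[str] = None
    novel_positions: FrozenSet[int] = frozenset()
    wt_peptide: Optional[str] = None
    origin_intervals: Tuple[Tuple[str, int, int, str], ...] = ()

    def __post_init__(self):
        if translate(self.coding_nt) != self.peptide:
            raise AssertionError(
                f"coding_nt {self.coding_nt!r} does not translate to "
                f"peptide {self.peptide!r}"
            )


@dataclass(frozen=True)
class FusionCall:
    gene5: str
    gene3: str
    breakpoint5: Tuple[str, int, str]  # (contig, 0-based pos, strand)
    breakpoint3: Tuple[str, int, str]
    transcript5: str
    transcript3: str
    frame_status: str  # "in_frame" | "frameshift"
    junction_read_count: int = 0
    spanning_frag_count: int = 0


@dataclass(frozen=True)
class SpliceEvent:
    event_type: str  # "retained_intron" | "exon_skip" | "novel_junction"
    contig: str
    strand: str
    start: int  # 0-based half-open interval of the intron/skipped/excised region
    end: int
    host_transcript_id: str


def enumerate_peptides(
    mutant_protein: str,
    mutant_cds: str,
    novel_residues: Set[int],
    k_lengths: Sequence[int],
    *,
    source_class: SourceClass,
    origin: str,
    gene_id: Optional[str] = None,
    transcript_id: Optional[str] = None,
    require_full_span: bool = False,
    wt_protein: Optional[str] = None,
    origin_intervals: Tuple[Tuple[str, int, int, str], ...] = (),
) -> List[PeptideCandidate]:
    """Slide k-mer windows over a mutant protein and emit candidates.

    A window is emitted when it overlaps at least one novel residue (or,
    with ``require_full_span``, contains *all* of them — used for in-frame
    junctions where a peptide must span both sides to be novel). The coding
    nucleotide slice is taken in register with the protein window. Windows
    containing a stop symbol are never emitted.
    """
    if len(mutant_cds) < 3 * len(mutant_protein):
        raise ValueError("mutant_cds shorter than 3x protein length")
    out: List[PeptideCandidate] = []
    for k in sorted(set(k_lengths)):
        if k < 1 or k > len(mutant_protein):
            continue
        for s in range(len(mutant_protein) - k + 1):
            window = range(s, s + k)
            if require_full_span:
                if not novel_residues <= set(window):
                    continue
            elif not any(s <= i < s + k for i in novel_residues):
                continue
            pep = mutant_protein[s : s + k]
            if "*" in pep:
                continue
            wt = None
            if wt_protein is not None and len(wt_protein) >= s + k:
                wt = wt_protein[s : s + k]
                if wt == pep or "*" in wt:
                    wt = None
            out.append(
                PeptideCandidate(
                    peptide=pep,
                    coding_nt=mutant_cds[3 * s : 3 * (s + k)],
                    source_class=source_class,
                    origin=origin,
                    gene_id=gene_id,
                    transcript_id=transcript_id,
                    novel_positions=frozenset(
                        i - s for i in novel_residues if s <= i < s + k
                    ),
                    wt_peptide=wt,
                    origin_intervals=origin_intervals,
                )
            )
    return out


def _not_in_reference(
    cands: List[PeptideCandidate], ref_proteins: Sequence[str]
) -> List[PeptideCandidate]:
    """Drop candidates whose peptide occurs verbatim in a reference protein.

    A junction or chimeric codon can by chance re-encode the original
    residue, making a "novel-span" window identical to a window of the
    unmutated protein; such peptides are self peptides and are never
    reported for the mutated source classes.
    """
    refs = [r for r in ref_proteins if r]
    return [c for c in cands if not any(c.peptide in r for r in refs)]


def _germline_cds_edits(
    transcript: TranscriptModel,
    germline: Sequence[Variant],
) -> List[Tuple[int, str, str]]:
    edits = []
    for v in germline:
        try:
            edits.append(variant_to_cds_edit(v, transcript))
        except ValueError:
            logger.warning(
                "germline variant %s:%d not applicable to CDS of %s; skipped",
                v.contig,
                v.pos + 1,
                transcript.transcript_id,
            )
    return edits


def _tx_origin_intervals(
    transcript: TranscriptModel,
) -> Tuple[Tuple[str, int, int, str], ...]:
    return tuple(
        (transcript.contig, s, e, transcript.strand)
        for s, e in transcript.cds_intervals
    )


def snv_indel_candidates(
    transcript: TranscriptModel,
    somatic_variant: Variant,
    phased_germline: Sequence[Variant],
    genome: Dict[str, GenomeSequence],
    k_lengths: Sequence[int],
) -> List[PeptideCandidate]:
    """Peptides from one somatic SNV/InDel on one transcript.

    The spliced CDS is edited with the selected germline variants and the
    somatic variant (somatic wins on overlap); the reference for novelty is
    the germline-only edited protein, so that peptides are novel with
    respect to the patient's own normal proteome.
    """
    cds = extract_cds(genome, transcript)
    try:
        somatic_edit = variant_to_cds_edit(somatic_variant, transcript)
    except ValueError:
        return []
    germ_edits = drop_conflicting_germline(
        somatic_edit, _germline_cds_edits(transcript, phased_germline)
    )
    ref_cds, _ = apply_variants(cds, germ_edits)
    mut_cds, _ = apply_variants(cds, germ_edits + [somatic_edit])

    ref_protein = translate(ref_cds, to_first_stop=True)
    mut_protein = translate(mut_cds, to_first_stop=True)
    # first nucleotide at which the somatic edit changes the sequence
    first_diff_nt = _common_prefix(ref_cds, mut_cds)
    first_diff_codon = first_diff_nt // 3
    if first_diff_codon >= len(mut_protein):
        logger.warning(
            "premature stop upstream of (or created by) somatic variant at "
            "%s:%d on %s; no peptides",
            somatic_variant.contig,
            somatic_variant.pos + 1,
            transcript.transcript_id,
        )
        return []

    delta = len(somatic_edit[2]) - len(somatic_edit[1])
    frameshift = delta % 3 != 0
    if frameshift:
        novel = set(range(first_diff_codon, len(mut_protein)))
        source = SourceClass.INDEL
        wt_prot = None
    else:
        prefix = _common_prefix(ref_protein, mut_protein)
        suffix = _common_suffix(ref_protein, mut_protein, prefix)
        novel = set(range(prefix, len(mut_protein) - suffix))
        if not novel:
            return []  # synonymous at the protein level
        source = SourceClass.SNV if somatic_variant.is_snv else SourceClass.INDEL
        wt_prot = ref_protein if len(ref_protein) == len(mut_protein) else None

    origin = (
        f"{transcript.transcript_id}|{somatic_variant.contig}:"
        f"{somatic_variant.pos + 1}{somatic_variant.ref}>{somatic_variant.alt}"
    )
    return _not_in_reference(
        enumerate_peptides(
            mut_protein,
            mut_cds,
            novel,
            k_lengths,
            source_class=source,
            origin=origin,
            gene_id=transcript.gene_id,
            transcript_id=transcript.transcript_id,
            wt_protein=wt_prot,
            origin_intervals=_tx_origin_intervals(transcript),
        ),
        [ref_protein],
    )


def _common_prefix(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


def _common_suffix(a: str, b: str, max_keep_prefix: int) -> int:
    n = 0
    while (
        n < len(a)
        and n < len(b)
        and len(a) - n > max_keep_prefix
        and len(b) - n > max_keep_prefix
        and a[len(a) - 1 - n] == b[len(b) - 1 - n]
    ):
        n += 1
    return n


def fusion_candidates(
    fusion_call: FusionCall,
    transcripts: Dict[str, TranscriptModel],
    genome: Dict[str, GenomeSequence],
    hom_germline: Sequence[Variant],
    upstream_len: int,
    k_lengths: Sequence[int],
) -> List[PeptideCandidate]:
    """Peptides spanning a fusion junction.

    The 5' partner contributes its spliced CDS up to and including the
    breakpoint base; the 3' partner contributes its coding sequence from
    its breakpoint onward. Homozygous germline variants are applied to each
    side before concatenation (het phasing across a junction is not
    attempted). In-frame products keep ``upstream_len`` residues on each
    side of the junction; frameshift products keep the upstream truncation
    and translate to the first stop.
    """
    tx5 = transcripts.get(fusion_call.transcript5)
    tx3 = transcripts.get(fusion_call.transcript3)
    if tx5 is None or tx3 is None or not tx5.is_coding or not tx3.is_coding:
        logger.warning(
            "fusion %s::%s references unknown/non-coding transcript; skipped",
            fusion_call.gene5,
            fusion_call.gene3,
        )
        return []
    _, bp5, _ = fusion_call.breakpoint5
    _, bp3, _ = fusion_call.breakpoint3
    hom = [v for v in hom_germline if v.zygosity == Zygosity.HOM]

    try:
        off5 = tx5.cds_offset_of(bp5)
        off3 = tx3.cds_offset_of(bp3)
    except ValueError:
        logger.warning(
            "fusion breakpoint outside CDS of %s/%s; skipped",
            fusion_call.transcript5,
            fusion_call.transcript3,
        )
        return []

    cds5, map5 = apply_variants(
        extract_cds(genome, tx5), _germline_cds_edits(tx5, hom)
    )
    cds3, map3 = apply_variants(
        extract_cds(genome, tx3), _germline_cds_edits(tx3, hom)
    )
    prefix = cds5[: map5[off5] + 1]
    suffix = cds3[map3[off3] :]
    concat = prefix + suffix
    j_nt = len(prefix)

    protein = translate(concat, to_first_stop=True)
    junction_codon = j_nt // 3  # first residue containing 3' bases (or fully 3')
    origin = (
        f"{fusion_call.gene5}::{fusion_call.gene3}|"
        f"{fusion_call.transcript5}:{bp5 + 1}|{fusion_call.transcript3}:{bp3 + 1}"
    )
    intervals = _tx_origin_intervals(tx5) + _tx_origin_intervals(tx3)

    if fusion_call.frame_status == "in_frame":
        if j_nt % 3 == 0:
            # junction falls on a codon boundary between residues b-1 and b
            b = junction_codon
            if len(protein) <= b:
                logger.warning(
                    "in-frame fusion %s::%s stops at/before the junction; "
                    "no peptides",
                    fusion_call.gene5,
                    fusion_call.gene3,
                )
                return []
            novel = {b - 1, b} if b > 0 else {0}
            first3 = b
            last_novel = b
        else:
            b = junction_codon  # chimeric codon is itself novel
            if len(protein) <= b:
                logger.warning(
                    "in-frame fusion %s::%s junction codon contains a stop; "
                    "no peptides",
                    fusion_call.gene5,
                    fusion_call.gene3,
                )
                return []
            novel = {b}
            first3 = b
            last_novel = b
        start = max(0, first3 - upstream_len)
        end = min(len(protein), last_novel + upstream_len + 1)
        refs = [translate(cds5, to_first_stop=True), translate(cds3, to_first_stop=True)]
        return _not_in_reference(
            enumerate_peptides(
                protein[start:end],
                concat[3 * start : 3 * end],
                {i - start for i in novel},
                k_lengths,
                source_class=SourceClass.FUSION,
                origin=origin,
                gene_id=f"{fusion_call.gene5}::{fusion_call.gene3}",
                transcript_id=f"{fusion_call.transcript5}::{fusion_call.transcript3}",
                require_full_span=True,
                origin_intervals=intervals,
            ),
            refs,
        )

    # frameshift: every residue from the junction codon onward is novel
    fc = junction_codon
    if fc >= len(protein):
        logger.warning(
            "frameshift fusion %s::%s stops before the junction; no peptides",
            fusion_call.gene5,
            fusion_call.gene3,
        )
        return []
    start = max(0, fc - upstream_len)
    truncated = protein[start:]
    novel = set(range(fc - start, len(truncated)))
    refs = [translate(cds5, to_first_stop=True), translate(cds3, to_first_stop=True)]
    return _not_in_reference(
        enumerate_peptides(
            truncated,
            concat[3 * start : 3 * (start + len(truncated))],
            novel,
            k_lengths,
            source_class=SourceClass.FUSION,
            origin=origin,
            gene_id=f"{fusion_call.gene5}::{fusion_call.gene3}",
            transcript_id=f"{fusion_call.transcript5}::{fusion_call.transcript3}",
            origin_intervals=intervals,
        ),
        refs,
    )


def splice_candidates(
    splice_event: SpliceEvent,
    transcripts: Dict[str, TranscriptModel],
    genome: Dict[str, GenomeSequence],
    k_lengths: Sequence[int],
) -> List[PeptideCandidate]:
    """Peptides from a tumor-specific splice event on its host transcript.

    Retained introns append the intron sequence after the upstream CDS and
    translate to the first stop. Exon skips and novel junctions excise the
    event region from the spliced CDS; frame-preserving excisions restrict
    peptides to junction-spanning windows, frame-breaking ones translate to
    the first stop with everything downstream novel.
    """
    tx = transcripts.get(splice_event.host_transcript_id)
    if tx is None or not tx.is_coding:
        logger.warning(
            "splice event host transcript %s unknown or non-coding; skipped",
            splice_event.host_transcript_id,
        )
        return []
    cds = extract_cds(genome, tx)
    origin = (
        f"{splice_event.event_type}|{tx.transcript_id}|"
        f"{splice_event.contig}:{splice_event.start + 1}-{splice_event.end}"
    )
    intervals = _tx_origin_intervals(tx) + (
        (splice_event.contig, splice_event.start, splice_event.end, tx.strand),
    )

    if splice_event.event_type == "retained_intron":
        intron = extract_intervals(
            genome,
            splice_event.contig,
            [(splice_event.start, splice_event.end)],
            tx.strand,
        )
        # transcriptionally-last exonic base before the intron
        donor_pos = splice_event.start - 1 if tx.strand == "+" else splice_event.end
        try:
            off = tx.cds_offset_of(donor_pos)
        except ValueError:
            logger.warning(
                "retained intron %s does not abut the CDS of %s; no peptides",
                origin,
                tx.transcript_id,
            )
            return []
        full = cds[: off + 1] + intron
        protein = translate(full, to_first_stop=True)
        first_novel = (off + 1) // 3
        if first_novel >= len(protein):
            return []
        novel = set(range(first_novel, len(protein)))
        return _not_in_reference(
            enumerate_peptides(
                protein,
                full,
                novel,
                k_lengths,
                source_class=SourceClass.SPLICE,
                origin=origin,
                gene_id=tx.gene_id,
                transcript_id=tx.transcript_id,
                origin_intervals=intervals,
            ),
            [translate(cds, to_first_stop=True)],
        )

    if splice_event.event_type in ("exon_skip", "novel_junction"):
        removed = _cds_offsets_in_region(
            tx, splice_event.start, splice_event.end
        )
        if removed is None:
            return []  # UTR-only / non-CDS event
        a, b = removed
        new_cds = cds[:a] + cds[b:]
        protein = translate(new_cds, to_first_stop=True)
        if not protein:
            return []
        if (b - a) % 3 != 0:
            first_novel = a // 3
            if first_novel >= len(protein):
                return []
            novel = set(range(first_novel, len(protein)))
            require_full = False
        elif a % 3 == 0:
            jb = a // 3
            if jb >= len(protein):
                return []
            novel = {jb - 1, jb} if jb > 0 else {0}
            require_full = True
        else:
            jb = a // 3  # chimeric junction codon
            if jb >= len(protein):
                return []
            novel = {jb}
            require_full = True
        return _not_in_reference(
            enumerate_peptides(
                protein,
                new_cds,
                novel,
                k_lengths,
                source_class=SourceClass.SPLICE,
                origin=origin,
                gene_id=tx.gene_id,
                transcript_id=tx.transcript_id,
                require_full_span=require_full,
                origin_intervals=intervals,
            ),
            [translate(cds, to_first_stop=True)],
        )

    raise InputContractError(
        f"unknown splice event type {splice_event.event_type!r}"
    )


def _cds_offsets_in_region(
    tx: TranscriptModel, start: int, end: int
) -> Optional[Tuple[int, int]]:
    """Spliced-CDS offset span [a, b) covered by a genomic region, or None."""
    offs = []
    for s, e in tx.cds_intervals:
        lo, hi = max(s, start), min(e, end)
        if lo < hi:
            offs.extend([tx.cds_offset_of(lo), tx.cds_offset_of(hi - 1)])
    offs = [o for o in offs if o >= 0]
    if not offs:
        return None
    return min(offs), max(offs) + 1


def _feature_edits(
    variants: Sequence[Variant],
    contig: str,
    start: int,
    end: int,
    strand: str,
) -> List[Tuple[int, str, str]]:
    """Convert genomic variants to edits on a single extracted interval."""
    edits = []
    for v in variants:
        if v.contig != contig or v.pos < start or v.end > end:
            continue
        if strand == "+":
            edits.append((v.pos - start, v.ref, v.alt))
        else:
            edits.append(
                (
                    end - v.end,
                    reverse_complement(v.ref),
                    reverse_complement(v.alt),
                )
            )
    return edits


def viral_candidates(
    viral_cds_fasta: str | Path | Dict[str, str],
    rna_hom_variants: Sequence[Variant],
    k_lengths: Sequence[int],
) -> List[PeptideCandidate]:
    """Peptides from expressed viral coding sequences.

    Homozygous variants called from the tumor RNA (expressed in viral CDS
    coordinates, one pseudo-contig per CDS record) are incorporated before
    translation; the whole translated protein is novel. A variant whose REF
    disagrees with the viral reference is a hard error.
    """
    if isinstance(viral_cds_fasta, dict):
        records = dict(viral_cds_fasta)
    else:
        records = {
            rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(viral_cds_fasta), "fasta")
        }
    out: List[PeptideCandidate] = []
    for cds_id in sorted(records):
        nt = records[cds_id]
        edits = [
            (v.pos, v.ref, v.alt)
            for v in rna_hom_variants
            if v.contig == cds_id and v.zygosity == Zygosity.HOM
        ]
        edited, _ = apply_variants(nt, edits)  # REF mismatch -> hard error
        protein = translate(edited, to_first_stop=True)
        if not protein:
            continue
        out.extend(
            enumerate_peptides(
                protein,
                edited,
                set(range(len(protein))),
                k_lengths,
                source_class=SourceClass.VIRUS,
                origin=f"virus:{cds_id}",
                gene_id=cds_id,
            )
        )
    return out


def erv_candidates(
    erv_orfs_passing_filter: Sequence[Tuple[str, str, int, int, str]],
    genome: Dict[str, GenomeSequence],
    hom_germline: Sequence[Variant],
    k_lengths: Sequence[int],
) -> List[PeptideCandidate]:
    """Peptides from endogenous-retrovirus ORFs that passed the
    tumor/normal fold-change filter.

    ORFs are (orf_id, contig, start, end, strand) on the host genome.
    Homozygous germline variants inside the ORF are incorporated, the ORF
    is translated to its first stop, and every window is emitted.
    """
    hom = [v for v in hom_germline if v.zygosity == Zygosity.HOM]
    out: List[PeptideCandidate] = []
    for orf_id, contig, start, end, strand in erv_orfs_passing_filter:
        if end - start < 3:
            logger.warning("ERV ORF %s shorter than one codon; skipped", orf_id)
            continue
        nt = extract_intervals(genome, contig, [(start, end)], strand)
        edited, _ = apply_variants(nt, _feature_edits(hom, contig, start, end, strand))
        protein = translate(edited, to_first_stop=True)
        if not protein:
            continue
        out.extend(
            enumerate_peptides(
                protein,
                edited,
                set(range(len(protein))),
                k_lengths,
                source_class=SourceClass.ERV,
                origin=f"erv:{orf_id}|{format_origin(contig, [(start, end)], strand)}",
                gene_id=orf_id,
                origin_intervals=((contig, start, end, strand),),
            )
        )
    return out


def cta_self_candidates(
    gene_list: Sequence[str],
    transcript_models: Sequence[TranscriptModel],
    tpm_table: Dict[str, float],
    percentile_threshold: float,
    genome: Dict[str, GenomeSequence],
    hom_germline: Sequence[Variant],
    k_lengths: Sequence[int],
) -> List[PeptideCandidate]:
    """Peptides from cancer-testis / self-antigen genes whose transcripts
    exceed the expression percentile threshold.

    The percentile is computed over all expressed transcripts in the TPM
    table (quantification module); passing transcripts get homozygous
    germline variants applied, are translated, and every window is emitted.
    """
    from .quantify import tpm_percentile_filter

    by_gene: Dict[str, List[TranscriptModel]] = {}
    for tx in transcript_models:
        by_gene.setdefault(tx.gene_id, []).append(tx)
        if tx.gene_name != tx.gene_id:
            by_gene.setdefault(tx.gene_name, []).append(tx)

    listed_tx = []
    for gene in gene_list:
        models = by_gene.get(gene)
        if not models:
            logger.warning("listed CTA/self gene %s absent from annotation", gene)
            continue
        listed_tx.extend(m for m in models if m.is_coding)

    passing = tpm_percentile_filter(
        tpm_table,
        [tx.transcript_id for tx in listed_tx],
        percentile_threshold,
    )
    hom = [v for v in hom_germline if v.zygosity == Zygosity.HOM]
    out: List[PeptideCandidate] = []
    for tx in listed_tx:
        if tx.transcript_id not in passing:
            continue
        cds = extract_cds(genome, tx)
        edited, _ = apply_variants(cds, _germline_cds_edits(tx, hom))
        protein = translate(edited, to_first_stop=True)
        if not protein:
            continue
        out.extend(
            enumerate_peptides(
                protein,
                edited,
                set(range(len(protein))),
                k_lengths,
                source_class=SourceClass.CTA_SELF,
                origin=f"cta:{tx.gene_id}|{tx.transcript_id}",
                gene_id=tx.gene_id,
                transcript_id=tx.transcript_id,
                origin_intervals=_tx_origin_intervals(tx),
            )
        )
    return out
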