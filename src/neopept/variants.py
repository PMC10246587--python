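"""Somatic/germline variant handling: VCF parsing, caller consensus,
coding-effect classification, haplotype-aware selection, and sequence editing.

Consensus semantics follow the pipeline default: SNVs are intersected across
the two SNV callers, InDels across all supplied callers; a union mode is
available. Variant identity is the normalized (contig, pos, ref, alt) key
after multi-allelic splitting and indel left-alignment, since un-normalized
equivalent representations would silently break the intersection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pysam

from .reference import (
    GenomeSequence,
    InputContractError,
    TranscriptModel,
    extract_cds,
    reverse_complement,
    translate,
)

logger = logging.getLogger(__name__)


class Origin(str, Enum):
    SOMATIC = "somatic"
    GERMLINE = "germline"


class Zygosity(str, Enum):
    HET = "het"
    HOM = "hom"
    UNKNOWN = "unknown"


class Effect(str, Enum):
    MISSENSE = "missense"
    INFRAME_INSERTION = "inframe_insertion"
    INFRAME_DELETION = "inframe_deletion"
    FRAMESHIFT = "frameshift"
    SYNONYMOUS = "synonymous"
    NON_CODING = "non_coding"
    OTHER = "other"


@dataclass(frozen=True)
class Variant:
    """A normalized variant in internal 0-based coordinates.

    ``ref``/``alt`` use the VCF anchored representation (both non-empty).
    Heterozygous phased germline variants carry ``phase_set`` and
    ``haplotype_index`` (0 = allele left of '|' in the genotype, 1 = right).
    """

    contig: str
    pos: int
    ref: str
    alt: str
    origin: Origin
    zygosity: Zygosity = Zygosity.UNKNOWN
    phase_set: Optional[str] = None
    haplotype_index: Optional[int] = None

    @property
    def key(self) -> Tuple[str, int, str, str]:
        return (self.contig, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def end(self) -> int:
        """End (exclusive) of the reference span."""
        return self.pos + len(self.ref)


@dataclass
class HaplotypeBlock:
    """Phased heterozygous variants sharing one phase set on one contig."""

    phase_set: str
    contig: str
    variants: List[Variant]


@dataclass(frozen=True)
class CodingEffect:
    effect: Effect
    transcript_id: str
    cds_pos: int


def normalize_variant(
    contig: str,
    pos: int,
    ref: str,
    alt: str,
    genome: Optional[Dict[str, GenomeSequence]] = None,
) -> Tuple[str, int, str, str]:
    """Trim shared prefix/suffix and left-align pure indels.

    Standard parsimony/left-alignment: repeatedly drop a shared terminal
    base (prepending the preceding reference base when one allele would
    empty), then drop shared leading bases. Without a genome only the
    trimming steps run.
    """
    seq = genome[contig].sequence if genome and contig in genome else None
    ref, alt = ref.upper(), alt.upper()
    changed = True
    while changed:
        changed = False
        # shared terminal base
        while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
            changed = True
        # left-shift: both end in same base but one would empty -> extend left
        if (
            seq is not None
            and ref[-1] == alt[-1]
            and (len(ref) == 1 or len(alt) == 1)
            and pos > 0
        ):
            prev = seq[pos - 1]
            ref, alt = prev + ref[:-1], prev + alt[:-1]
            pos -= 1
            changed = True
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return contig, pos, ref, alt


def parse_vcf(
    vcf_path: str | Path,
    origin: Origin | str,
    keep_nonpass: bool = False,
    genome: Optional[Dict[str, GenomeSequence]] = None,
) -> List[Variant]:
    """Parse a VCF 4.x file (plain or bgzipped) into normalized Variants.

    Multi-allelic records are split one Variant per ALT. Records failing
    FILTER (anything other than PASS or '.') are excluded unless
    ``keep_nonpass``. When a sample genotype is present, zygosity is read
    from GT; phased het genotypes ('|') populate phase_set (PS field, or
    '<contig>' when PS is absent) and haplotype_index.
    """
    path = Path(vcf_path)
    if not path.exists():
        raise InputContractError(f"VCF not found: {path}")
    origin = Origin(origin)
    out: List[Variant] = []
    seen: set = set()
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            try:
                variants = _split_record(rec, origin, keep_nonpass, genome)
            except InputContractError:
                raise
            except Exception as exc:  # malformed record
                raise InputContractError(
                    f"malformed VCF record at {path}:{rec.pos}: {exc}"
                ) from exc
            for v in variants:
                if v.key in seen:
                    continue
                seen.add(v.key)
                out.append(v)
    return out


def _split_record(rec, origin, keep_nonpass, genome) -> List[Variant]:
    filters = list(rec.filter.keys())
    if filters and filters != ["PASS"] and not keep_nonpass:
        return []
    if not rec.alts:
        return []
    sample = rec.samples[0] if rec.samples else None
    gt = sample.get("GT") if sample is not None else None
    phased = bool(sample.phased) if sample is not None else False
    ps = None
    if sample is not None and "PS" in sample and sample["PS"] is not None:
        ps = str(sample["PS"])
    out = []
    for ai, alt in enumerate(rec.alts, start=1):
        if alt is None or alt.startswith("<"):
            continue
        zyg, hap = Zygosity.UNKNOWN, None
        if gt is not None and None not in gt:
            n = sum(1 for a in gt if a == ai)
            if n == len(gt):
                zyg = Zygosity.HOM
            elif n >= 1:
                zyg = Zygosity.HET
                if phased and len(gt) == 2:
                    hap = 0 if gt[0] == ai else 1
            else:
                continue  # this alt not carried by the sample
        contig, pos, ref, alt_n = normalize_variant(
            rec.contig, rec.pos - 1, rec.ref, alt, genome
        )
        if genome is not None and contig in genome:
            span = genome[contig].sequence[pos : pos + len(ref)]
            if span != ref:
                raise InputContractError(
                    f"REF mismatch at {contig}:{pos + 1}: VCF says {ref!r}, "
                    f"genome has {span!r}"
                )
        out.append(
            Variant(
                contig=contig,
                pos=pos,
                ref=ref,
                alt=alt_n,
                origin=origin,
                zygosity=zyg,
                phase_set=(ps or contig) if hap is not None else ps,
                haplotype_index=hap,
            )
        )
    return out


def combine_callsets(
    callsets: Sequence[Tuple[str, Sequence[Variant]]],
    mode: str = "intersection",
    variant_class: str = "snv",
) -> List[Variant]:
    """Consensus combination of per-caller variant sets.

    ``intersection`` keeps keys present in every supplied callset (the
    default rule: two callers for SNVs, all three for InDels — the caller
    lists are chosen by the pipeline config); ``union`` keeps keys present
    in any. Metadata comes from the first caller listing the key. Variants
    not matching ``variant_class`` (snv vs indel) are dropped first.
    """
    if not callsets:
        raise InputContractError("combine_callsets requires at least one callset")
    if mode not in ("intersection", "union"):
        raise ValueError(f"unknown combination mode {mode!r}")

    def class_ok(v: Variant) -> bool:
        return v.is_snv if variant_class == "snv" else not v.is_snv

    keysets = []
    first_seen: Dict[Tuple, Variant] = {}
    support: Dict[Tuple, List[str]] = {}
    for name, vs in callsets:
        keys = set()
        for v in vs:
            if not class_ok(v):
                continue
            keys.add(v.key)
            first_seen.setdefault(v.key, v)
            support.setdefault(v.key, []).append(name)
        keysets.append(keys)
    if mode == "intersection":
        kept = set.intersection(*keysets)
    else:
        kept = set.union(*keysets)
    return [first_seen[k] for k in sorted(kept)]


def caller_support(
    callsets: Sequence[Tuple[str, Sequence[Variant]]]
) -> Dict[Tuple, List[str]]:
    """Map variant key -> list of caller names reporting it (provenance)."""
    out: Dict[Tuple, List[str]] = {}
    for name, vs in callsets:
        for v in vs:
            out.setdefault(v.key, []).append(name)
    return out


def classify_coding_effect(
    variant: Variant,
    transcript: TranscriptModel,
    genome: Dict[str, GenomeSequence],
) -> CodingEffect:
    """Classify a variant's coding consequence on one transcript.

    SNVs are classified by codon substitution (missense vs synonymous);
    indels by length offset modulo 3. Variants outside the CDS are
    non_coding. A REF/genome mismatch is a hard error: it signals a
    coordinate or reference mix-up upstream.
    """
    if variant.contig != transcript.contig:
        return CodingEffect(Effect.NON_CODING, transcript.transcript_id, -1)
    span = genome[variant.contig].sequence[variant.pos : variant.end]
    if span != variant.ref:
        raise InputContractError(
            f"variant REF {variant.ref!r} does not match genome {span!r} at "
            f"{variant.contig}:{variant.pos + 1}"
        )
    if not transcript.is_coding or not _ref_span_in_cds(variant, transcript):
        return CodingEffect(Effect.NON_CODING, transcript.transcript_id, -1)
    try:
        edit = variant_to_cds_edit(variant, transcript)
    except ValueError:
        return CodingEffect(Effect.OTHER, transcript.transcript_id, -1)
    offset, ref_c, alt_c = edit
    if offset < 0:
        return CodingEffect(Effect.NON_CODING, transcript.transcript_id, -1)
    if variant.is_snv:
        cds = extract_cds(genome, transcript)
        codon_i = offset // 3
        codon = cds[codon_i * 3 : codon_i * 3 + 3]
        if len(codon) < 3:
            return CodingEffect(Effect.OTHER, transcript.transcript_id, offset)
        mutated = codon[: offset % 3] + alt_c + codon[offset % 3 + 1 :]
        eff = (
            Effect.SYNONYMOUS
            if translate(codon) == translate(mutated)
            else Effect.MISSENSE
        )
        return CodingEffect(eff, transcript.transcript_id, offset)
    delta = len(alt_c) - len(ref_c)
    if delta % 3 != 0:
        eff = Effect.FRAMESHIFT
    elif delta > 0:
        eff = Effect.INFRAME_INSERTION
    else:
        eff = Effect.INFRAME_DELETION
    return CodingEffect(eff, transcript.transcript_id, offset)


def _ref_span_in_cds(variant: Variant, transcript: TranscriptModel) -> bool:
    return all(
        transcript.contains_in_cds(p) for p in range(variant.pos, variant.end)
    )


def variant_to_cds_edit(
    variant: Variant, transcript: TranscriptModel
) -> Tuple[int, str, str]:
    """Express a genomic variant as a (offset, ref, alt) edit on the spliced,
    phase-trimmed CDS of ``transcript``.

    On the minus strand the anchored representation is re-anchored at the
    genomic end of REF (which is the 5'-most transcribed base) and both
    alleles are reverse complemented, preserving insertion/deletion
    placement. The full REF span must lie inside one CDS interval.
    """
    if not _ref_span_in_cds(variant, transcript):
        raise ValueError("variant reference span not fully inside CDS")
    if transcript.strand == "+":
        offset = transcript.cds_offset_of(variant.pos)
        # REF must be contiguous in the spliced CDS
        if transcript.cds_offset_of(variant.end - 1) - offset != len(variant.ref) - 1:
            raise ValueError("variant spans a splice junction")
        return offset, variant.ref, variant.alt
    offset = transcript.cds_offset_of(variant.end - 1)
    if transcript.cds_offset_of(variant.pos) - offset != len(variant.ref) - 1:
        raise ValueError("variant spans a splice junction")
    return offset, reverse_complement(variant.ref), reverse_complement(variant.alt)


def select_phased_germline(
    somatic_variant: Variant,
    blocks: Sequence[HaplotypeBlock],
    window: Tuple[str, int, int],
    hom_germline: Sequence[Variant] = (),
) -> List[Variant]:
    """Germline variants to incorporate alongside one somatic variant.

    Returns all homozygous germline variants inside ``window`` (they sit on
    both haplotypes) plus the phased heterozygous germline variants that
    share the somatic variant's phase set AND haplotype index. Het variants
    in other blocks or on the other haplotype are excluded. If the somatic
    variant is unphased, het neighbors are conservatively excluded with a
    warning rather than guessed onto a haplotype.
    """
    contig, wstart, wend = window

    def in_window(v: Variant) -> bool:
        return v.contig == contig and v.pos < wend and v.end > wstart

    selected = [
        v for v in hom_germline if v.zygosity == Zygosity.HOM and in_window(v)
    ]
    if somatic_variant.phase_set is None or somatic_variant.haplotype_index is None:
        if any(in_window(v) for b in blocks for v in b.variants):
            logger.warning(
                "somatic variant %s:%d is unphased; het germline neighbors "
                "in window excluded",
                somatic_variant.contig,
                somatic_variant.pos + 1,
            )
        return selected
    for block in blocks:
        if block.phase_set != somatic_variant.phase_set:
            continue
        for v in block.variants:
            if (
                in_window(v)
                and v.haplotype_index == somatic_variant.haplotype_index
            ):
                selected.append(v)
    return selected


def build_haplotype_blocks(germline: Sequence[Variant]) -> List[HaplotypeBlock]:
    """Group phased het germline variants by (contig, phase_set)."""
    grouped: Dict[Tuple[str, str], List[Variant]] = {}
    for v in germline:
        if (
            v.zygosity == Zygosity.HET
            and v.phase_set is not None
            and v.haplotype_index is not None
        ):
            grouped.setdefault((v.contig, v.phase_set), []).append(v)
    return [
        HaplotypeBlock(phase_set=ps, contig=contig, variants=vs)
        for (contig, ps), vs in sorted(grouped.items())
    ]


def apply_variants(
    cds: str, variants_in_cds_coords: Sequence[Tuple[int, str, str]]
) -> Tuple[str, Dict[int, int]]:
    """Apply non-overlapping (offset, ref, alt) edits to a spliced CDS.

    Edits are applied right-to-left so earlier offsets stay valid. Returns
    the edited sequence and an offset map translating every original
    coordinate to its edited coordinate (positions inside a replaced span
    map to the span's start in the edited sequence).

    Overlapping edits and REF mismatches are hard errors.
    """
    edits = sorted(variants_in_cds_coords)
    for (o1, r1, _), (o2, r2, _) in zip(edits, edits[1:]):
        if o1 + len(r1) > o2:
            raise InputContractError(
                f"overlapping edits at offsets {o1} (ref {r1!r}) and {o2} (ref {r2!r})"
            )
    for off, ref, _alt in edits:
        if off < 0 or off + len(ref) > len(cds):
            raise InputContractError(f"edit at offset {off} exceeds sequence bounds")
        if cds[off : off + len(ref)] != ref:
            raise InputContractError(
                f"edit REF mismatch at offset {off}: expected {ref!r}, "
                f"sequence has {cds[off : off + len(ref)]!r}"
            )
    edited = cds
    for off, ref, alt in reversed(edits):
        edited = edited[:off] + alt + edited[off + len(ref) :]
    offset_map: Dict[int, int] = {}
    shift = 0  # cumulative length delta of edits fully left of pos
    ei = 0
    for pos in range(len(cds) + 1):  # +1: map the end coordinate too
        while ei < len(edits) and pos >= edits[ei][0] + len(edits[ei][1]):
            shift += len(edits[ei][2]) - len(edits[ei][1])
            ei += 1
        if ei < len(edits) and edits[ei][0] <= pos:
            # inside a replaced span: collapse to the span start
            offset_map[pos] = edits[ei][0] + shift
        else:
            offset_map[pos] = pos + shift
    return edited, offset_map


def drop_conflicting_germline(
    somatic_edit: Tuple[int, str, str],
    germline_edits: Sequence[Tuple[int, str, str]],
) -> List[Tuple[int, str, str]]:
    """Somatic wins when a germline edit overlaps it; drop with a warning."""
    so, sref, _ = somatic_edit
    kept = []
    for g in germline_edits:
        go, gref, _ = g
        if go < so + len(sref) and go + len(gref) > so:
            logger.warning(
                "germline edit at CDS offset %d overlaps somatic edit at %d; dropped",
                go,
                so,
            )
            continue
        kept.append(g)
    return kept
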