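"""Self-contained toy patient generator with known ground truth.

Emits, from a single integer seed, every input the pipeline consumes —
reference FASTA + GTF, per-pseudo-caller somatic VCFs, a phased germline
VCF, fusion and splice-event tables, viral CDS FASTA + RNA variant VCF,
ERV ORF BED + tumor/normal count tables, a CTA gene list, a TPM table,
tumor RNA reads (FASTQ), and an HLA allele list — plus a truth table of
the peptides the pipeline is expected to report.

The expected peptide set for every planted event is computed here by an
independent, straightforward construction (direct string edits, direct
translation, brute-force window loops), deliberately not reusing the
candidate-generation code paths it is meant to check.

Reads default to "tiled" mode: error-free reads tiled over every expressed
tumor sequence densely enough that any peptide-coding subsequence up to
3*max(k) nucleotides is guaranteed to appear in at least one read. A
"sampled" mode (seeded uniform sampling at a configured depth) exists for
stress testing; exact truth-table equality is only guaranteed in tiled
mode at error rate 0.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .reference import reverse_complement, translate

CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


@dataclass
class FixtureSpec:
    """Parameters of the toy patient. The seed fully determines all files."""

    seed: int = 1
    n_genes: int = 20
    gene_length_bp: int = 90  # CDS length per gene, rounded to codons
    read_length: int = 50
    depth_per_haplotype: int = 4  # sampled mode only
    k_lengths: Tuple[int, ...] = (8, 9, 10, 11)
    percentile: float = 75.0
    read_mode: str = "tiled"  # "tiled" | "sampled"
    error_rate: float = 0.0


@dataclass
class ToyGene:
    index: int
    gene_id: str
    tx_id: str
    strand: str
    cds: str  # transcription order
    exon_pieces: List[int]  # CDS split lengths, transcription order
    gene_start: int = 0
    exons: List[Tuple[int, int]] = field(default_factory=list)  # genomic order
    gpos: List[int] = field(default_factory=list)  # genomic pos per CDS base
    introns_tx: List[str] = field(default_factory=list)  # transcription order
    intron_ivs: List[Tuple[int, int]] = field(default_factory=list)  # genomic


@dataclass
class ToyReference:
    spec: FixtureSpec
    contig: str
    genome: str
    genes: List[ToyGene]
    erv_orfs: List[Tuple[str, str, int, int, str]]  # id, contig, start, end, strand
    erv_seqs: Dict[str, str]  # reading-frame order


def _random_codons(rng, n: int) -> str:
    return "".join(CODONS[i] for i in rng.integers(0, len(CODONS), n))


def _random_dna(rng, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def make_toy_reference(spec: FixtureSpec) -> ToyReference:
    """Build the toy genome and annotation.

    Genes cycle through 1, 2, and 3 exons and alternate strands; every CDS
    is a valid ATG...codons...TAA frame with no internal stop. Three-exon
    genes get a frame-preserving (length % 3 == 0) middle exon so that
    exon-skip events are codon-clean. Deterministic under the seed.
    """
    rng = np.random.default_rng(spec.seed)
    contig = "chr1"
    L = max(30, spec.gene_length_bp - spec.gene_length_bp % 3)
    parts: List[str] = []
    cursor = 0

    def emit(seq: str) -> int:
        nonlocal cursor
        parts.append(seq)
        start = cursor
        cursor += len(seq)
        return start

    genes: List[ToyGene] = []
    for i in range(spec.n_genes):
        emit(_random_dna(rng, 60))  # spacer
        cds = "ATG" + _random_codons(rng, L // 3 - 2) + "TAA"
        n_exons = (i % 3) + 1
        if n_exons == 1:
            pieces = [L]
        elif n_exons == 2:
            a = (L // 2) - (L // 2) % 3 + 1  # off codon boundary on purpose
            pieces = [a, L - a]
        else:
            mid = 3 * ((L // 3) // 3)
            a = (L - mid) // 2 + 1  # off codon boundary: chimeric skip junction
            pieces = [a, mid, L - a - mid]
        strand = "+" if i % 2 == 0 else "-"
        introns = [_random_dna(rng, 30) for _ in range(n_exons - 1)]

        # pre-mRNA in transcription order
        tx_blocks: List[Tuple[str, str]] = []  # (kind, seq)
        off = 0
        for pi, plen in enumerate(pieces):
            tx_blocks.append(("exon", cds[off : off + plen]))
            off += plen
            if pi < len(introns):
                tx_blocks.append(("intron", introns[pi]))
        pre = "".join(seq for _, seq in tx_blocks)
        block = pre if strand == "+" else reverse_complement(pre)
        gene_start = emit(block)

        gene = ToyGene(
            index=i,
            gene_id=f"GENE{i}",
            tx_id=f"TX{i}",
            strand=strand,
            cds=cds,
            exon_pieces=pieces,
            gene_start=gene_start,
            introns_tx=introns,
        )
        # map transcription-order offsets to genomic coordinates
        B = len(pre)

        def g_of(tx_off: int) -> int:
            if strand == "+":
                return gene_start + tx_off
            return gene_start + (B - 1 - tx_off)

        tx_off = 0
        for kind, seq in tx_blocks:
            s, e = g_of(tx_off), g_of(tx_off + len(seq) - 1)
            iv = (min(s, e), max(s, e) + 1)
            if kind == "exon":
                gene.exons.append(iv)
                gene.gpos.extend(g_of(tx_off + j) for j in range(len(seq)))
            else:
                gene.intron_ivs.append(iv)
            tx_off += len(seq)
        gene.exons.sort()
        gene.intron_ivs.sort()
        genes.append(gene)

    # two ERV ORFs in intergenic space
    erv_orfs: List[Tuple[str, str, int, int, str]] = []
    erv_seqs: Dict[str, str] = {}
    for j, (orf_id, strand) in enumerate([("ERV1", "+"), ("ERV2", "-")]):
        emit(_random_dna(rng, 60))
        orf = "ATG" + _random_codons(rng, 18) + "TAA"
        placed = orf if strand == "+" else reverse_complement(orf)
        start = emit(placed)
        erv_orfs.append((orf_id, contig, start, start + len(orf), strand))
        erv_seqs[orf_id] = orf
    emit(_random_dna(rng, 60))

    return ToyReference(
        spec=spec,
        contig=contig,
        genome="".join(parts),
        genes=genes,
        erv_orfs=erv_orfs,
        erv_seqs=erv_seqs,
    )


# --------------------------------------------------------------------------
# event planting


@dataclass
class PlantedFixture:
    reference: ToyReference
    files: Dict[str, str]  # filename -> text content
    truth: List[Dict[str, object]]  # source_class, peptide, coding_nt, origin,
    # reportable
    expressed_tumor_seqs: Dict[str, str]  # feature tag -> tumor nt sequence


def _brute_windows(
    protein: str,
    cds: str,
    novel: Set[int],
    ks: Sequence[int],
    require_all: bool = False,
) -> Set[Tuple[str, str]]:
    """Independent window oracle: all (peptide, coding_nt) k-mers whose
    window overlaps (or, with require_all, contains) the novel residues."""
    out = set()
    for k in ks:
        for s in range(len(protein) - k + 1):
            win = set(range(s, s + k))
            ok = novel <= win if require_all else bool(win & novel)
            pep = protein[s : s + k]
            if ok and "*" not in pep:
                out.add((pep, cds[3 * s : 3 * (s + k)]))
    return out


def _drop_self(pairs: Set[Tuple[str, str]], refs: Sequence[str]) -> Set[Tuple[str, str]]:
    """Mutated-class truth excludes peptides found verbatim in a reference
    protein (a chimeric codon can re-encode the original residue)."""
    return {(p, nt) for p, nt in pairs if not any(p in r for r in refs if r)}


def _sub(seq: str, off: int, ref: str, alt: str) -> str:
    assert seq[off : off + len(ref)] == ref
    return seq[:off] + alt + seq[off + len(ref) :]


def _gvar(gene: ToyGene, contig: str, off: int, alt_cds_base: str):
    """Genomic (pos, ref, alt) of a CDS-coordinate SNV on a toy gene."""
    pos = gene.gpos[off]
    if gene.strand == "+":
        return pos, gene.cds[off], alt_cds_base
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    return pos, comp[gene.cds[off]], comp[alt_cds_base]


def _pick_missense_alt(cds: str, off: int) -> Optional[str]:
    codon_i = off // 3
    codon = cds[codon_i * 3 : codon_i * 3 + 3]
    for b in "ACGT":
        if b == cds[off]:
            continue
        mut = codon[: off % 3] + b + codon[off % 3 + 1 :]
        if translate(mut) not in (translate(codon), "*"):
            return b
    return None


def _find_missense(cds: str, start_off: int) -> Tuple[int, str]:
    """First CDS offset >= start_off admitting a missense substitution."""
    for off in range(start_off, len(cds) - 3):
        alt = _pick_missense_alt(cds, off)
        if alt is not None:
            return off, alt
    raise AssertionError("no missense site found")


def _vcf_text(
    contigs: Sequence[Tuple[str, int]],
    records: Sequence[Tuple[str, int, str, str, str, str]],
    sample: str,
) -> str:
    """records: (contig, pos0, ref, alt, gt, ps-or-'') sorted on write."""
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c},length={ln}>" for c, ln in contigs]
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append('##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample
    )
    for contig, pos0, ref, alt, gt, ps in sorted(records):
        if ps:
            fmt, val = "GT:PS", f"{gt}:{ps}"
        else:
            fmt, val = "GT", gt
        lines.append(
            f"{contig}\t{pos0 + 1}\t.\t{ref}\t{alt}\t.\tPASS\t.\t{fmt}\t{val}"
        )
    return "\n".join(lines) + "\n"


def _fasta_text(records: Dict[str, str], width: int = 60) -> str:
    out = []
    for name, seq in records.items():
        out.append(f">{name}")
        out.extend(seq[i : i + width] for i in range(0, len(seq), width))
    return "\n".join(out) + "\n"


def _gtf_text(ref: ToyReference) -> str:
    lines = []
    for g in ref.genes:
        attrs = (
            f'gene_id "{g.gene_id}"; transcript_id "{g.tx_id}"; '
            f'gene_name "{g.gene_id}";'
        )
        # CDS offsets per exon in transcription order
        tx_exons = g.exons if g.strand == "+" else list(reversed(g.exons))
        off = 0
        frames = []
        for s, e in tx_exons:
            frames.append((3 - off % 3) % 3)
            off += e - s
        frame_by_iv = dict(zip([tuple(iv) for iv in tx_exons], frames))
        for s, e in g.exons:
            lines.append(
                f"{ref.contig}\ttoy\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}"
            )
            lines.append(
                f"{ref.contig}\ttoy\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t"
                f"{frame_by_iv[(s, e)]}\t{attrs}"
            )
    return "\n".join(lines) + "\n"


def plant_events(spec: FixtureSpec, ref: ToyReference) -> PlantedFixture:
    """Plant one event of every antigen class and compute its expected
    peptides by direct construction.

    Pseudo-caller somatic VCFs differ by caller-private false positives so
    the consensus intersection is exercised; decoy features (a CPM-failing
    ERV, a below-percentile CTA gene, an unexpressed viral CDS) are planted
    as non-reportable truth rows.
    """
    if spec.n_genes < 16:
        raise ValueError("plant_events needs n_genes >= 16")
    ks = spec.k_lengths
    g = {i: ref.genes[i] for i in range(spec.n_genes)}
    contig = ref.contig
    truth: List[Dict[str, object]] = []
    expressed: Dict[str, str] = {}

    def add_truth(source: str, pairs: Set[Tuple[str, str]], origin: str,
                  reportable: bool) -> None:
        for pep, nt in sorted(pairs):
            truth.append(
                {
                    "source_class": source,
                    "peptide": pep,
                    "coding_nt": nt,
                    "origin": origin,
                    "reportable": reportable,
                }
            )

    mutect, strelka, abra = [], [], []  # somatic VCF records
    germline = []

    # --- somatic missense SNV on GENE0 (+, 1 exon) with phased germline ---
    g0 = g[0]
    s0, alt0 = _find_missense(g0.cds, 31)
    pos0, gref0, galt0 = _gvar(g0, contig, s0, alt0)
    # het germline, same phase set + haplotype as the somatic variant
    gs_off, gs_alt = _find_missense(g0.cds, 22)
    assert gs_off < s0
    posA, grefA, galtA = _gvar(g0, contig, gs_off, gs_alt)
    # het germline, same block, OTHER haplotype: must not appear in peptides
    go_off, go_alt = _find_missense(g0.cds, s0 + 4)
    posB, grefB, galtB = _gvar(g0, contig, go_off, go_alt)
    rec0 = (contig, pos0, gref0, galt0, "0|1", "7")
    mutect.append(rec0)
    strelka.append(rec0)
    germline.append((contig, posA, grefA, galtA, "0|1", "7"))
    germline.append((contig, posB, grefB, galtB, "1|0", "7"))

    hap1 = _sub(_sub(g0.cds, gs_off, g0.cds[gs_off], gs_alt), s0, g0.cds[s0], alt0)
    hap0 = _sub(g0.cds, go_off, g0.cds[go_off], go_alt)
    ref_prot = translate(_sub(g0.cds, gs_off, g0.cds[gs_off], gs_alt),
                         to_first_stop=True)
    mut_prot = translate(hap1, to_first_stop=True)
    novel0 = {i for i, (a, b) in enumerate(zip(ref_prot, mut_prot)) if a != b}
    origin0 = f"{g0.tx_id}|{contig}:{pos0 + 1}{gref0}>{galt0}"
    add_truth(
        "SNV",
        _drop_self(_brute_windows(mut_prot, hap1, novel0, ks), [ref_prot]),
        origin0,
        True,
    )
    expressed["GENE0_hap1"] = hap1
    expressed["GENE0_hap0"] = hap0

    # --- in-frame insertion on GENE2 (+, 3 exons), all three callers ---
    g2 = g[2]
    o2 = next(
        o
        for o in range(36, 57)
        if (o + 1) % 3 == 0
        and g2.cds[o] != "T"
        and translate(g2.cds[o + 1 : o + 4]) != "D"
        and translate(g2.cds[o - 2 : o + 1]) != "D"
    )
    ins = "GAT"  # Asp
    pos2 = g2.gpos[o2]
    rec2 = (contig, pos2, g2.cds[o2], g2.cds[o2] + ins, "0/1", "")
    for cs in (mutect, strelka, abra):
        cs.append(rec2)
    mut2 = g2.cds[: o2 + 1] + ins + g2.cds[o2 + 1 :]
    prot2 = translate(mut2, to_first_stop=True)
    novel2 = {(o2 + 1) // 3}  # the inserted Asp codon
    origin2 = f"{g2.tx_id}|{contig}:{pos2 + 1}{g2.cds[o2]}>{g2.cds[o2] + ins}"
    add_truth(
        "INDEL",
        _drop_self(
            _brute_windows(prot2, mut2, novel2, ks),
            [translate(g2.cds, to_first_stop=True)],
        ),
        origin2,
        True,
    )
    expressed["GENE2_mut"] = mut2
    expressed["GENE2_wt"] = g2.cds

    # --- frameshift 1-bp insertion on GENE4 (+, 2 exons), all callers ---
    g4 = g[4]
    o4 = next(o for o in range(48, 60) if g4.cds[o] != "G")
    pos4 = g4.gpos[o4]
    rec4 = (contig, pos4, g4.cds[o4], g4.cds[o4] + "G", "0/1", "")
    for cs in (mutect, strelka, abra):
        cs.append(rec4)
    mut4 = g4.cds[: o4 + 1] + "G" + g4.cds[o4 + 1 :]
    prot4 = translate(mut4, to_first_stop=True)
    first4 = (o4 + 1) // 3  # codon of the inserted base
    novel4 = set(range(first4, len(prot4)))
    origin4 = f"{g4.tx_id}|{contig}:{pos4 + 1}{g4.cds[o4]}>{g4.cds[o4]}G"
    add_truth(
        "INDEL",
        _drop_self(
            _brute_windows(prot4, mut4, novel4, ks),
            [translate(g4.cds, to_first_stop=True)],
        ),
        origin4,
        True,
    )
    expressed["GENE4_mut"] = mut4
    expressed["GENE4_wt"] = g4.cds

    # --- caller-private false positives (must be culled by intersection) ---
    g1, g13, g14 = g[1], g[13], g[14]
    fp1_off, fp1_alt = _find_missense(g1.cds, 10)
    fp1 = _gvar(g1, contig, fp1_off, fp1_alt)
    mutect.append((contig, fp1[0], fp1[1], fp1[2], "0/1", ""))
    fp13_off, fp13_alt = _find_missense(g13.cds, 13)
    fp13 = _gvar(g13, contig, fp13_off, fp13_alt)
    strelka.append((contig, fp13[0], fp13[1], fp13[2], "0/1", ""))
    # indel in only 2 of 3 callers: excluded under the 3-caller InDel rule
    o14 = next(o for o in range(30, 45) if g14.cds[o] != "C" and g14.strand == "+")
    pos14 = g14.gpos[o14]
    rec14 = (contig, pos14, g14.cds[o14], g14.cds[o14] + "C", "0/1", "")
    mutect.append(rec14)
    strelka.append(rec14)

    # --- in-frame fusion GENE3(-) :: GENE6(+) ---
    g3, g6 = g[3], g[6]
    e5, o3 = 44, 30  # prefix of 45 nt (codon boundary), 3' native frame
    bp5 = g3.gpos[e5]
    bp3 = g6.gpos[o3]
    prefix = g3.cds[: e5 + 1]
    suffix = g6.cds[o3:]
    concat = prefix + suffix
    fus_prot = translate(concat, to_first_stop=True)
    b = len(prefix) // 3
    up = max(ks) - 1
    fstart, fend = max(0, b - up), min(len(fus_prot), b + up + 1)
    fus_origin = (
        f"{g3.gene_id}::{g6.gene_id}|{g3.tx_id}:{bp5 + 1}|{g6.tx_id}:{bp3 + 1}"
    )
    add_truth(
        "FUSION",
        _drop_self(
            _brute_windows(
                fus_prot[fstart:fend],
                concat[3 * fstart : 3 * fend],
                {b - 1 - fstart, b - fstart},
                ks,
                require_all=True,
            ),
            [
                translate(g3.cds, to_first_stop=True),
                translate(g6.cds, to_first_stop=True),
            ],
        ),
        fus_origin,
        True,
    )
    expressed["FUSION_IF"] = concat

    # --- frameshift fusion GENE5(-) :: GENE12(+) ---
    g5, g12 = g[5], g[12]
    e5b = 46  # prefix of 47 nt -> chimeric junction codon, frame broken
    bp5b = g5.gpos[e5b]
    bp3b = g12.gpos[0]
    concat_fs = g5.cds[: e5b + 1] + g12.cds
    fs_prot = translate(concat_fs, to_first_stop=True)
    fc = (e5b + 1) // 3
    fs_start = max(0, fc - up)
    fs_trunc = fs_prot[fs_start:]
    fs_origin = (
        f"{g5.gene_id}::{g12.gene_id}|{g5.tx_id}:{bp5b + 1}|{g12.tx_id}:{bp3b + 1}"
    )
    add_truth(
        "FUSION",
        _drop_self(
            _brute_windows(
                fs_trunc,
                concat_fs[3 * fs_start : 3 * (fs_start + len(fs_trunc))],
                set(range(fc - fs_start, len(fs_trunc))),
                ks,
            ),
            [
                translate(g5.cds, to_first_stop=True),
                translate(g12.cds, to_first_stop=True),
            ],
        ),
        fs_origin,
        True,
    )
    expressed["FUSION_FS"] = concat_fs

    fusion_tsv = (
        "gene5\tgene3\tbreakpoint5\tbreakpoint3\ttranscript5\ttranscript3\t"
        "frame_status\tjunction_reads\tspanning_frags\n"
        f"{g3.gene_id}\t{g6.gene_id}\t{contig}:{bp5 + 1}:{g3.strand}\t"
        f"{contig}:{bp3 + 1}:{g6.strand}\t{g3.tx_id}\t{g6.tx_id}\tin_frame\t10\t4\n"
        f"{g5.gene_id}\t{g12.gene_id}\t{contig}:{bp5b + 1}:{g5.strand}\t"
        f"{contig}:{bp3b + 1}:{g12.strand}\t{g5.tx_id}\t{g12.tx_id}\tframeshift\t8\t2\n"
    )

    # --- retained intron on GENE7 (-, 2 exons) ---
    g7 = g[7]
    ri_iv = g7.intron_ivs[0]
    intron_tx = g7.introns_tx[0]
    donor_off = g7.exon_pieces[0] - 1  # last base of exon 1 (transcription order)
    ri_nt = g7.cds[: donor_off + 1] + intron_tx
    ri_prot = translate(ri_nt, to_first_stop=True)
    ri_first = (donor_off + 1) // 3
    ri_origin = (
        f"retained_intron|{g7.tx_id}|{contig}:{ri_iv[0] + 1}-{ri_iv[1]}"
    )
    if ri_first < len(ri_prot):
        add_truth(
            "SPLICE",
            _drop_self(
                _brute_windows(
                    ri_prot, ri_nt, set(range(ri_first, len(ri_prot))), ks
                ),
                [translate(g7.cds, to_first_stop=True)],
            ),
            ri_origin,
            True,
        )
    expressed["GENE7_RI"] = g7.cds[: donor_off + 1] + intron_tx + g7.cds[donor_off + 1 :]

    # --- exon skip on GENE8 (+, 3 exons, frame-preserving middle exon) ---
    g8 = g[8]
    skip_iv = g8.exons[1]
    a8 = g8.exon_pieces[0]
    b8 = a8 + g8.exon_pieces[1]
    es_nt = g8.cds[:a8] + g8.cds[b8:]
    es_prot = translate(es_nt, to_first_stop=True)
    assert (b8 - a8) % 3 == 0 and a8 % 3 != 0  # chimeric junction codon
    es_novel = {a8 // 3}
    es_origin = f"exon_skip|{g8.tx_id}|{contig}:{skip_iv[0] + 1}-{skip_iv[1]}"
    add_truth(
        "SPLICE",
        _drop_self(
            _brute_windows(es_prot, es_nt, es_novel, ks, require_all=True),
            [translate(g8.cds, to_first_stop=True)],
        ),
        es_origin,
        True,
    )
    expressed["GENE8_ES"] = es_nt

    splice_tsv = (
        "event_type\tcontig\tstrand\tstart\tend\thost_transcript\n"
        f"retained_intron\t{contig}\t{g7.strand}\t{ri_iv[0] + 1}\t{ri_iv[1]}\t{g7.tx_id}\n"
        f"exon_skip\t{contig}\t{g8.strand}\t{skip_iv[0] + 1}\t{skip_iv[1]}\t{g8.tx_id}\n"
    )

    # --- viral CDS: virus1 expressed (with hom RNA variant), virus2 not ---
    rng = np.random.default_rng(spec.seed + 1000)
    v1 = "ATG" + _random_codons(rng, 20) + "TAA"
    v2 = "ATG" + _random_codons(rng, 20) + "TAA"
    vo, v_alt = _find_missense(v1, 12)
    v1_mut = _sub(v1, vo, v1[vo], v_alt)
    v1_prot = translate(v1_mut, to_first_stop=True)
    add_truth(
        "VIRUS",
        _brute_windows(v1_prot, v1_mut, set(range(len(v1_prot))), ks),
        "virus:virus1_cds1",
        True,
    )
    v2_prot = translate(v2, to_first_stop=True)
    add_truth(
        "VIRUS",
        _brute_windows(v2_prot, v2, set(range(len(v2_prot))), ks),
        "virus:virus2_cds1",
        False,  # no RNA reads -> fails the read-evidence filter
    )
    expressed["virus1_cds1"] = v1_mut
    viral_fasta = _fasta_text({"virus1_cds1": v1, "virus2_cds1": v2})
    viral_vcf = _vcf_text(
        [("virus1_cds1", len(v1)), ("virus2_cds1", len(v2))],
        [("virus1_cds1", vo, v1[vo], v_alt, "1/1", "")],
        "TUMOR_RNA",
    )

    # --- ERV ORFs: ERV1 passes fold change (with hom germline), ERV2 fails ---
    erv1_id, _, e1s, e1e, e1strand = ref.erv_orfs[0]
    erv1 = ref.erv_seqs[erv1_id]
    eo, e_alt = _find_missense(erv1, 10)
    # genomic representation of the ORF-frame SNV
    if e1strand == "+":
        germline.append((contig, e1s + eo, erv1[eo], e_alt, "1/1", ""))
    else:
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        germline.append(
            (contig, e1e - 1 - eo, comp[erv1[eo]], comp[e_alt], "1/1", "")
        )
    erv1_mut = _sub(erv1, eo, erv1[eo], e_alt)
    erv1_prot = translate(erv1_mut, to_first_stop=True)
    erv1_origin_iv = f"{contig}:{e1s + 1}-{e1e}({e1strand})"
    add_truth(
        "ERV",
        _brute_windows(erv1_prot, erv1_mut, set(range(len(erv1_prot))), ks),
        f"erv:{erv1_id}|{erv1_origin_iv}",
        True,
    )
    erv2_id, _, e2s, e2e, e2strand = ref.erv_orfs[1]
    erv2 = ref.erv_seqs[erv2_id]
    erv2_prot = translate(erv2, to_first_stop=True)
    add_truth(
        "ERV",
        _brute_windows(erv2_prot, erv2, set(range(len(erv2_prot))), ks),
        f"erv:{erv2_id}|{contig}:{e2s + 1}-{e2e}({e2strand})",
        False,  # fails the tumor/normal CPM fold-change filter
    )
    expressed[erv1_id] = erv1_mut
    erv_bed = (
        f"{contig}\t{e1s}\t{e1e}\t{erv1_id}\t0\t{e1strand}\n"
        f"{contig}\t{e2s}\t{e2e}\t{erv2_id}\t0\t{e2strand}\n"
    )
    erv_tumor = "orf_id\tcount\nERV1\t500\nERV2\t5\nother\t9495\n"
    erv_normal = "orf_id\tcount\nERV1\t5\nERV2\t5\nother\t9990\n"

    # --- CTA/self: GENE9 above percentile (with hom germline), GENE10 below ---
    g9, g10 = g[9], g[10]
    c_off, c_alt = _find_missense(g9.cds, 20)
    posC, grefC, galtC = _gvar(g9, contig, c_off, c_alt)
    germline.append((contig, posC, grefC, galtC, "1/1", ""))
    g9_mut = _sub(g9.cds, c_off, g9.cds[c_off], c_alt)
    g9_prot = translate(g9_mut, to_first_stop=True)
    add_truth(
        "CTA_SELF",
        _brute_windows(g9_prot, g9_mut, set(range(len(g9_prot))), ks),
        f"cta:{g9.gene_id}|{g9.tx_id}",
        True,
    )
    g10_prot = translate(g10.cds, to_first_stop=True)
    add_truth(
        "CTA_SELF",
        _brute_windows(g10_prot, g10.cds, set(range(len(g10_prot))), ks),
        f"cta:{g10.gene_id}|{g10.tx_id}",
        False,  # below the expression percentile
    )
    expressed["GENE9"] = g9_mut
    cta_list = f"{g9.gene_id}\n{g10.gene_id}\n"

    # --- TPM table: variant/CTA targets high, GENE10 low, background low ---
    tpm_rows = ["feature_id\tcount\ttpm"]
    for gene in ref.genes:
        if gene.index in (0, 2, 4, 9):
            tpm = 100.0 + 10 * gene.index
        elif gene.index == 10:
            tpm = 0.5
        else:
            tpm = 1.0 + gene.index % 5
        tpm_rows.append(f"{gene.tx_id}\t{int(tpm * 10)}\t{tpm}")
    tpm_tsv = "\n".join(tpm_rows) + "\n"

    files = {
        "genome.fa": _fasta_text({contig: ref.genome}),
        "annotation.gtf": _gtf_text(ref),
        "somatic_mutect2.vcf": _vcf_text(
            [(contig, len(ref.genome))], mutect, "TUMOR"
        ),
        "somatic_strelka2.vcf": _vcf_text(
            [(contig, len(ref.genome))], strelka, "TUMOR"
        ),
        "somatic_abra2.vcf": _vcf_text(
            [(contig, len(ref.genome))], abra, "TUMOR"
        ),
        "germline.vcf": _vcf_text([(contig, len(ref.genome))], germline, "NORMAL"),
        "fusions.tsv": fusion_tsv,
        "splice_events.tsv": splice_tsv,
        "viral_cds.fa": viral_fasta,
        "viral_variants.vcf": viral_vcf,
        "erv_orfs.bed": erv_bed,
        "erv_counts_tumor.tsv": erv_tumor,
        "erv_counts_normal.tsv": erv_normal,
        "cta_genes.txt": cta_list,
        "tpm.tsv": tpm_tsv,
        "alleles.txt": "HLA-A*02:01\nHLA-B*07:02\n",
    }
    truth_rows = ["source_class\tpeptide\tcoding_nt\torigin\treportable"]
    truth_rows += [
        f"{t['source_class']}\t{t['peptide']}\t{t['coding_nt']}\t"
        f"{t['origin']}\t{int(bool(t['reportable']))}"
        for t in truth
    ]
    files["truth.tsv"] = "\n".join(truth_rows) + "\n"
    return PlantedFixture(
        reference=ref, files=files, truth=truth, expressed_tumor_seqs=expressed
    )


def simulate_reads(planted: PlantedFixture, spec: FixtureSpec) -> str:
    """FASTQ text of tumor RNA reads over every expressed tumor sequence.

    Tiled mode walks each sequence with a step small enough that every
    subsequence of length 3*max(k) is fully contained in at least one
    read; alternating reads are emitted reverse complemented. Sampled
    mode draws seeded uniform start positions at the configured depth.
    Error-free unless ``error_rate`` is set (sampled mode only).
    """
    rl = spec.read_length
    max_nt = 3 * max(spec.k_lengths)
    reads: List[Tuple[str, str]] = []
    rng = np.random.default_rng(spec.seed + 2000)
    for tag in sorted(planted.expressed_tumor_seqs):
        seq = planted.expressed_tumor_seqs[tag]
        if len(seq) <= rl:
            starts = [0]
            eff_rl = len(seq)
        else:
            eff_rl = rl
            step = max(1, rl - max_nt)
            starts = list(range(0, len(seq) - rl + 1, step))
            if starts[-1] != len(seq) - rl:
                starts.append(len(seq) - rl)
        if spec.read_mode == "sampled":
            n = max(1, spec.depth_per_haplotype * len(seq) // max(eff_rl, 1))
            starts = sorted(
                int(x) for x in rng.integers(0, max(1, len(seq) - eff_rl + 1), n)
            )
        for i, s in enumerate(starts):
            frag = seq[s : s + eff_rl]
            if spec.error_rate > 0 and spec.read_mode == "sampled":
                frag = _mutate(frag, spec.error_rate, rng)
            if i % 2 == 1:
                frag = reverse_complement(frag)
            reads.append((f"r{spec.seed}_{tag}_{i}", frag))
    out = []
    for name, seq in reads:
        out.append(f"@{name}\n{seq}\n+\n{'I' * len(seq)}")
    return "\n".join(out) + "\n"


def _mutate(seq: str, rate: float, rng) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = "ACGT"[int(rng.integers(0, 4))]
    return "".join(out)


def generate_fixture(spec: FixtureSpec, outdir: str | Path) -> Path:
    """Write the complete toy patient into ``outdir`` and return its path.

    Also writes ``run_config.json`` with the pipeline settings the fixture
    was designed for (75th expression percentile, log2 fold-change 1,
    2-caller SNV / 3-caller InDel intersection, affinity ceilings disabled
    because the mock predictor's affinities carry no planted signal).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ref = make_toy_reference(spec)
    planted = plant_events(spec, ref)
    planted.files["reads.fastq"] = simulate_reads(planted, spec)
    planted.files["run_config.json"] = json.dumps(
        {
            "k_lengths": list(spec.k_lengths),
            "percentile": spec.percentile,
            "erv_log2fc_threshold": 1.0,
            "min_read_support": 1,
            "snv_callers": ["mutect2", "strelka2"],
            "indel_callers": ["mutect2", "strelka2", "abra2"],
            "combination_mode": "intersection",
            # mock-predictor affinities carry no planted signal, so the
            # fixture disables every affinity ceiling explicitly
            "affinity_ceilings": {
                sc: None
                for sc in (
                    "SNV", "INDEL", "FUSION", "SPLICE",
                    "VIRUS", "ERV", "CTA_SELF",
                )
            },
            "seed": spec.seed,
        },
        indent=2,
    )
    for name, content in sorted(planted.files.items()):
        (outdir / name).write_text(content)
    return outdir
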