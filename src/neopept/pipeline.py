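"""End-to-end orchestration: per-source candidate generation, harmonized
quantification, pMHC prediction, filtering, and report writing.

The CLI is a thin wrapper over :func:`run_pipeline`; every stage is also
callable on its own through the per-source source lists.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from . import quantify, report as report_mod, sources as sources_mod
from .reference import (
    InputContractError,
    build_transcript_models,
    extract_cds,
    load_genome,
)
from .report import FilterConfig, MockPredictor, assemble_report, filter_report
from .sources import FusionCall, SourceClass, SpliceEvent
from .variants import (
    Effect,
    Origin,
    Variant,
    build_haplotype_blocks,
    caller_support,
    classify_coding_effect,
    combine_callsets,
    parse_vcf,
    select_phased_germline,
)

logger = logging.getLogger(__name__)

ALL_SOURCES = ("snv-indel", "fusion", "splice", "viral", "erv", "cta")


@dataclass
class RunConfig:
    """All run inputs and tunables.

    Defaults follow the published workflow where it states them: expression
    percentile 75, ERV log2 fold-change threshold 1, CTA/self affinity
    ceiling 50 nM, SNV consensus over two callers and InDel consensus over
    three, minimum read support 1.
    """

    genome: str = ""
    gtf: str = ""
    somatic_vcfs: Dict[str, str] = field(default_factory=dict)
    germline_vcf: Optional[str] = None
    fusions: Optional[str] = None
    splice_events: Optional[str] = None
    viral_cds: Optional[str] = None
    viral_vcf: Optional[str] = None
    erv_bed: Optional[str] = None
    erv_counts_tumor: Optional[str] = None
    erv_counts_normal: Optional[str] = None
    cta_list: Optional[str] = None
    tpm: Optional[str] = None
    reads: Optional[str] = None
    bam: Optional[str] = None
    alleles: Optional[str] = None
    clonality: Optional[str] = None
    out_dir: str = "neopept_out"

    k_lengths: Tuple[int, ...] = (8, 9, 10, 11)
    percentile_threshold: float = 75.0
    erv_log2fc_threshold: float = 1.0
    min_read_support: int = 1
    snv_callers: Optional[List[str]] = None  # default: first two supplied
    indel_callers: Optional[List[str]] = None  # default: all supplied
    combination_mode: str = "intersection"
    keep_nonpass: bool = False
    upstream_len: Optional[int] = None  # default: max(k_lengths) - 1
    affinity_ceilings: Optional[Dict[str, Optional[float]]] = None
    stability_floors: Dict[str, float] = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        cfg = cls()
        for k, v in data.items():
            if hasattr(cfg, k):
                setattr(cfg, k, v)
        if isinstance(cfg.k_lengths, list):
            cfg.k_lengths = tuple(cfg.k_lengths)
        return cfg

    def filter_config(self) -> FilterConfig:
        fc = FilterConfig(min_read_support=self.min_read_support)
        if self.affinity_ceilings is not None:
            fc.affinity_ceilings = {
                SourceClass(k): (float(v) if v is not None else None)
                for k, v in self.affinity_ceilings.items()
            }
        fc.stability_floors = {
            SourceClass(k): float(v) for k, v in self.stability_floors.items()
        }
        return fc


def no_affinity_filter_config(min_read_support: int = 1) -> FilterConfig:
    """Filter settings with every affinity ceiling disabled."""
    return FilterConfig(
        affinity_ceilings={sc: None for sc in SourceClass},
        min_read_support=min_read_support,
    )


def _parse_breakpoint(text: str) -> Tuple[str, int, str]:
    parts = text.split(":")
    if len(parts) != 3:
        raise InputContractError(f"malformed breakpoint {text!r}")
    return parts[0], int(parts[1]) - 1, parts[2]


def load_fusion_table(path: str | Path) -> List[FusionCall]:
    df = pd.read_csv(path, sep="\t")
    calls = []
    for _, r in df.iterrows():
        calls.append(
            FusionCall(
                gene5=str(r["gene5"]),
                gene3=str(r["gene3"]),
                breakpoint5=_parse_breakpoint(str(r["breakpoint5"])),
                breakpoint3=_parse_breakpoint(str(r["breakpoint3"])),
                transcript5=str(r["transcript5"]),
                transcript3=str(r["transcript3"]),
                frame_status=str(r["frame_status"]),
                junction_read_count=int(r.get("junction_reads", 0)),
                spanning_frag_count=int(r.get("spanning_frags", 0)),
            )
        )
    return calls


def load_splice_table(path: str | Path) -> List[SpliceEvent]:
    df = pd.read_csv(path, sep="\t")
    events = []
    for _, r in df.iterrows():
        events.append(
            SpliceEvent(
                event_type=str(r["event_type"]),
                contig=str(r["contig"]),
                strand=str(r["strand"]),
                start=int(r["start"]) - 1,  # TSV is 1-based inclusive
                end=int(r["end"]),
                host_transcript_id=str(r["host_transcript"]),
            )
        )
    return events


def load_erv_bed(path: str | Path) -> List[Tuple[str, str, int, int, str]]:
    orfs = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track")):
            continue
        f = line.split("\t")
        if len(f) < 6:
            raise InputContractError(f"ERV BED needs 6 columns: {line!r}")
        orfs.append((f[3], f[0], int(f[1]), int(f[2]), f[5]))
    return orfs


def run_pipeline(
    config: RunConfig,
    sources: Sequence[str] = ALL_SOURCES,
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Run candidate generation for the requested source classes, quantify,
    predict, filter, and return (report DataFrame, per-stage counts)."""
    counts: Dict[str, int] = {}
    genome = load_genome(config.genome)
    models = build_transcript_models(config.gtf)
    tx_by_id = {m.transcript_id: m for m in models}
    ks = tuple(config.k_lengths)
    upstream_len = (
        config.upstream_len if config.upstream_len is not None else max(ks) - 1
    )

    germline: List[Variant] = []
    if config.germline_vcf:
        germline = parse_vcf(
            config.germline_vcf, Origin.GERMLINE, config.keep_nonpass, genome
        )
    blocks = build_haplotype_blocks(germline)
    hom_germline = [v for v in germline if v.zygosity.value == "hom"]

    tpm_table: Dict[str, float] = {}
    if config.tpm:
        expr = quantify.load_expression_table(config.tpm)
        tpm_table = expr["tpm"].to_dict()

    candidates: List[sources_mod.PeptideCandidate] = []
    provenance: Dict[str, str] = {}
    fusion_origins: set = set()

    if "snv-indel" in sources and config.somatic_vcfs:
        cands, prov = _snv_indel_stage(
            config, genome, models, blocks, hom_germline, tpm_table, ks
        )
        counts["snv_indel_candidates"] = len(cands)
        candidates.extend(cands)
        provenance.update(prov)

    if "fusion" in sources and config.fusions:
        fus = load_fusion_table(config.fusions)
        cands = []
        for call in fus:
            cands.extend(
                sources_mod.fusion_candidates(
                    call, tx_by_id, genome, hom_germline, upstream_len, ks
                )
            )
        counts["fusion_candidates"] = len(cands)
        fusion_origins = {c.origin for c in cands}
        candidates.extend(cands)

    if "splice" in sources and config.splice_events:
        cands = []
        for ev in load_splice_table(config.splice_events):
            cands.extend(
                sources_mod.splice_candidates(ev, tx_by_id, genome, ks)
            )
        counts["splice_candidates"] = len(cands)
        candidates.extend(cands)

    if "viral" in sources and config.viral_cds:
        viral_vars: List[Variant] = []
        if config.viral_vcf:
            viral_vars = parse_vcf(
                config.viral_vcf, Origin.GERMLINE, config.keep_nonpass
            )
        cands = sources_mod.viral_candidates(config.viral_cds, viral_vars, ks)
        counts["viral_candidates"] = len(cands)
        candidates.extend(cands)

    if "erv" in sources and config.erv_bed:
        orfs = load_erv_bed(config.erv_bed)
        passing = {o[0] for o in orfs}
        if config.erv_counts_tumor:
            cpm_t = quantify.compute_cpm(
                quantify.load_count_table(config.erv_counts_tumor)
            )
            cpm_n = (
                quantify.compute_cpm(
                    quantify.load_count_table(config.erv_counts_normal)
                )
                if config.erv_counts_normal
                else {}
            )
            passing &= quantify.erv_fold_change_filter(
                cpm_t, cpm_n, config.erv_log2fc_threshold
            )
        kept = [o for o in orfs if o[0] in passing]
        counts["erv_orfs_passing"] = len(kept)
        cands = sources_mod.erv_candidates(kept, genome, hom_germline, ks)
        counts["erv_candidates"] = len(cands)
        candidates.extend(cands)

    if "cta" in sources and config.cta_list:
        gene_list = [
            ln.strip()
            for ln in Path(config.cta_list).read_text().splitlines()
            if ln.strip() and not ln.startswith("#")
        ]
        cands = sources_mod.cta_self_candidates(
            gene_list,
            models,
            tpm_table,
            config.percentile_threshold,
            genome,
            hom_germline,
            ks,
        )
        counts["cta_candidates"] = len(cands)
        candidates.extend(cands)

    counts["candidates_total"] = len(candidates)

    # harmonized read support
    reads: List[quantify.Read] = []
    if config.bam:
        reads = quantify.read_sam(config.bam)
    elif config.reads:
        reads = quantify.read_fastq(config.reads)
    have_alignments = bool(config.bam)
    abundance: Dict[int, quantify.AbundanceRecord] = {}
    for i, cand in enumerate(candidates):
        if cand.origin in fusion_origins:
            # junction pool: alignment-crossing reads when alignments exist,
            # otherwise the whole read set
            pool = reads
            abundance[i] = quantify.fusion_read_support(cand.coding_nt, pool)
        else:
            abundance[i] = quantify.count_read_support(
                cand.coding_nt,
                reads,
                origin=cand.origin_intervals if have_alignments else None,
            )
    surviving_idx = [
        i
        for i in range(len(candidates))
        if abundance[i].read_support >= config.min_read_support or not reads
    ]
    survivors = [candidates[i] for i in surviving_idx]
    surv_abundance = {
        j: abundance[i] for j, i in enumerate(surviving_idx)
    }
    counts["candidates_with_read_support"] = len(survivors)

    alleles = (
        report_mod.load_alleles(config.alleles)
        if config.alleles
        else [report_mod.HlaAllele("HLA-A*02:01")]
    )
    predictor = MockPredictor(seed=config.seed)
    pmhc = report_mod.predict_pmhc(survivors, alleles, predictor)

    clonality = _load_clonality(config.clonality) if config.clonality else None
    df = assemble_report(
        survivors, pmhc, surv_abundance, tpm_table, provenance, clonality
    )
    df = filter_report(df, config.filter_config())
    counts["report_rows"] = len(df)
    return df, counts


def _snv_indel_stage(
    config: RunConfig,
    genome,
    models,
    blocks,
    hom_germline,
    tpm_table,
    ks,
):
    callsets = [
        (name, parse_vcf(path, Origin.SOMATIC, config.keep_nonpass, genome))
        for name, path in config.somatic_vcfs.items()
    ]
    names = [n for n, _ in callsets]
    snv_names = config.snv_callers or names[:2]
    indel_names = config.indel_callers or names
    by_name = dict(callsets)
    snv_sets = [(n, by_name[n]) for n in snv_names if n in by_name]
    indel_sets = [(n, by_name[n]) for n in indel_names if n in by_name]
    combined = combine_callsets(snv_sets, config.combination_mode, "snv")
    combined += combine_callsets(indel_sets, config.combination_mode, "indel")
    support = caller_support(callsets)

    coding_models = [m for m in models if m.is_coding]
    # expression percentile filter on variant-harboring transcripts
    passing_tx = None
    if tpm_table:
        passing_tx = quantify.tpm_percentile_filter(
            tpm_table,
            [m.transcript_id for m in coding_models],
            config.percentile_threshold,
        )

    cands: List[sources_mod.PeptideCandidate] = []
    prov: Dict[str, str] = {}
    for variant in combined:
        for tx in coding_models:
            if tx.contig != variant.contig or not tx.contains_in_cds(variant.pos):
                continue
            effect = classify_coding_effect(variant, tx, genome)
            if effect.effect in (Effect.NON_CODING, Effect.SYNONYMOUS, Effect.OTHER):
                continue
            if passing_tx is not None and tx.transcript_id not in passing_tx:
                logger.info(
                    "transcript %s fails the expression percentile filter",
                    tx.transcript_id,
                )
                continue
            window = (
                tx.contig,
                min(s for s, _ in tx.cds_intervals),
                max(e for _, e in tx.cds_intervals),
            )
            germ = select_phased_germline(variant, blocks, window, hom_germline)
            new = sources_mod.snv_indel_candidates(tx, variant, germ, genome, ks)
            for c in new:
                prov[c.origin] = ",".join(support.get(variant.key, []))
            cands.extend(new)
    return cands, prov


def _load_clonality(path: str | Path) -> Dict[str, float]:
    df = pd.read_csv(path, sep="\t")
    out = {}
    for _, r in df.iterrows():
        out[str(r.iloc[0])] = float(r.iloc[1])
    return out


def write_outputs(
    df: pd.DataFrame,
    counts: Dict[str, int],
    config: RunConfig,
    out_dir: str | Path,
) -> Path:
    """Write report.tsv, the effective config, and stage counts."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report_mod.write_report(df, out / "report.tsv")
    cfg = asdict(config)
    cfg["k_lengths"] = list(cfg["k_lengths"])
    (out / "effective_config.json").write_text(json.dumps(cfg, indent=2) + "\n")
    (out / "stage_counts.json").write_text(json.dumps(counts, indent=2) + "\n")
    return out / "report.tsv"
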