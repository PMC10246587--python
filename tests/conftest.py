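"""Shared fixtures: a generated toy patient and small hand-built models."""

from __future__ import annotations

from pathlib import Path

import pytest

from neopept.fixtures import FixtureSpec, generate_fixture
from neopept.pipeline import RunConfig
from neopept.reference import GenomeSequence, TranscriptModel


def make_genome(**contigs: str):
    return {name: GenomeSequence(name, seq.upper()) for name, seq in contigs.items()}


def make_transcript(
    tx_id="TX",
    gene_id="GENE",
    contig="chr1",
    strand="+",
    exons=None,
    cds=None,
    phase=0,
):
    exons = exons or []
    cds = cds if cds is not None else list(exons)
    return TranscriptModel(
        transcript_id=tx_id,
        gene_id=gene_id,
        gene_name=gene_id,
        contig=contig,
        strand=strand,
        exons=list(exons),
        cds_intervals=list(cds),
        coding_start_phase=phase,
    )


@pytest.fixture(scope="session")
def toy_fixture_dir(tmp_path_factory) -> Path:
    out = tmp_path_factory.mktemp("fixture") / "patient1"
    generate_fixture(FixtureSpec(seed=1), out)
    return out


def fixture_run_config(d: Path) -> RunConfig:
    cfg = RunConfig.from_json(d / "run_config.json")
    cfg.genome = str(d / "genome.fa")
    cfg.gtf = str(d / "annotation.gtf")
    cfg.somatic_vcfs = {
        n: str(d / f"somatic_{n}.vcf") for n in ("mutect2", "strelka2", "abra2")
    }
    cfg.germline_vcf = str(d / "germline.vcf")
    cfg.fusions = str(d / "fusions.tsv")
    cfg.splice_events = str(d / "splice_events.tsv")
    cfg.viral_cds = str(d / "viral_cds.fa")
    cfg.viral_vcf = str(d / "viral_variants.vcf")
    cfg.erv_bed = str(d / "erv_orfs.bed")
    cfg.erv_counts_tumor = str(d / "erv_counts_tumor.tsv")
    cfg.erv_counts_normal = str(d / "erv_counts_normal.tsv")
    cfg.cta_list = str(d / "cta_genes.txt")
    cfg.tpm = str(d / "tpm.tsv")
    cfg.reads = str(d / "reads.fastq")
    cfg.alleles = str(d / "alleles.txt")
    return cfg


@pytest.fixture(scope="session")
def toy_run_config(toy_fixture_dir) -> RunConfig:
    return fixture_run_config(toy_fixture_dir)
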