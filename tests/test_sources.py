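"""Per-class peptide construction rules and the window enumerator."""

import numpy as np
import pytest

from neopept.reference import InputContractError, translate
from neopept.sources import (
    FusionCall,
    SourceClass,
    SpliceEvent,
    cta_self_candidates,
    enumerate_peptides,
    erv_candidates,
    fusion_candidates,
    snv_indel_candidates,
    splice_candidates,
    viral_candidates,
)
from neopept.variants import Origin, Variant, Zygosity

from conftest import make_genome, make_transcript


def somatic(contig, pos, ref, alt, **kw):
    return Variant(contig, pos, ref, alt, Origin.SOMATIC, **kw)


def hom_germ(contig, pos, ref, alt):
    return Variant(contig, pos, ref, alt, Origin.GERMLINE, Zygosity.HOM)


PROT12 = "MAGHKLWVRTSE"
CDS12 = (
    "ATGGCTGGGCACAAGCTGTGGGTGCGGACCAGCGAG"
)


class TestEnumeratePeptides:
    def kw(self, **over):
        base = dict(source_class=SourceClass.SNV, origin="o")
        base.update(over)
        return base

    def test_single_window(self):
        out = enumerate_peptides(PROT12[:9], CDS12[:27], {4}, [9], **self.kw())
        assert len(out) == 1
        assert out[0].novel_positions == frozenset({4})

    def test_window_counts_match_brute_force(self):
        # protein length 12, k in {8, 9}, novel span {5}:
        # k=8 -> starts 0..4 all overlap 5 (5 windows); k=9 -> starts 0..3 (4)
        out = enumerate_peptides(PROT12, CDS12, {5}, [8, 9], **self.kw())
        assert len(out) == 9
        assert sum(1 for c in out if len(c.peptide) == 8) == 5

    def test_whole_protein_novel_emits_all_windows(self):
        prot10, cds30 = PROT12[:10], CDS12[:30]
        out = enumerate_peptides(
            prot10, cds30, set(range(10)), [9],
            **self.kw(source_class=SourceClass.VIRUS),
        )
        assert len(out) == 2  # 10 - 9 + 1

    def test_translation_invariant_holds(self):
        out = enumerate_peptides(PROT12, CDS12, {5}, [8, 9, 10, 11], **self.kw())
        for c in out:
            assert translate(c.coding_nt) == c.peptide

    def test_matches_brute_force_on_random_cases(self):
        """Oracle equivalence on >= 1000 randomized (protein, span, k) cases."""
        rng = np.random.default_rng(7)
        codons = [
            a + b + c
            for a in "ACGT"
            for b in "ACGT"
            for c in "ACGT"
            if a + b + c not in ("TAA", "TAG", "TGA")
        ]
        for _ in range(1000):
            n = int(rng.integers(5, 30))
            cds = "".join(codons[i] for i in rng.integers(0, len(codons), n))
            prot = translate(cds)
            lo = int(rng.integers(0, n))
            hi = int(rng.integers(lo, n)) + 1
            novel = set(range(lo, hi))
            ks = sorted(set(int(k) for k in rng.integers(2, 12, 2)))
            out = enumerate_peptides(prot, cds, novel, ks, **self.kw())
            expected = 0
            for k in ks:
                for s in range(0, n - k + 1):
                    if set(range(s, s + k)) & novel:
                        expected += 1
            assert len(out) == expected


class TestSnvIndelCandidates:
    def test_toy_missense_peptide(self):
        genome = make_genome(chr1="ATGGCTTGA")
        tx = make_transcript(exons=[(0, 9)])
        out = snv_indel_candidates(
            tx, somatic("chr1", 4, "C", "A"), [], genome, [2]
        )
        assert {(c.peptide, c.coding_nt) for c in out} == {("MD", "ATGGAT")}
        assert out[0].source_class == SourceClass.SNV
        assert out[0].wt_peptide == "MA"

    def test_frameshift_windows_fully_novel_downstream(self):
        cds = "ATGGCTAAAGCTCCCGGGTTTACCTGA"
        genome = make_genome(chr1=cds)
        tx = make_transcript(exons=[(0, len(cds))])
        # 1-bp insertion after offset 8: frame shifts from codon 3 onward
        out = snv_indel_candidates(
            tx, somatic("chr1", 8, "A", "AT"), [], genome, [3]
        )
        assert out
        mut_cds = cds[:9] + "T" + cds[9:]
        mut_prot = translate(mut_cds, to_first_stop=True)
        for c in out:
            assert c.source_class == SourceClass.INDEL
            # residues at/after the shifted codon are all flagged novel
            start = mut_prot.index(c.peptide)
            expected = {i - start for i in range(max(3, start), start + 3)}
            assert c.novel_positions == frozenset(expected)

    def test_phased_germline_lands_in_coding_nt(self):
        cds = "ATGGCTAAAGCTCCCGGGTTTACCTGA"
        genome = make_genome(chr1=cds)
        tx = make_transcript(exons=[(0, len(cds))])
        som = somatic(
            "chr1", 13, "C", "G",
            zygosity=Zygosity.HET, phase_set="7", haplotype_index=1,
        )
        germ = Variant(
            "chr1", 7, "A", "C", Origin.GERMLINE, Zygosity.HET,
            phase_set="7", haplotype_index=1,
        )
        out = snv_indel_candidates(tx, som, [germ], genome, [4])
        # edited CDS: germline A>C at 7 (codon 2 AAA->ACA) and somatic C>G at
        # 13 (codon 4 CCC->CGC); a 4-mer window spanning both must carry both
        with_both = [
            c for c in out if "ACA" in c.coding_nt and "CGC" in c.coding_nt
        ]
        assert with_both
        for c in out:
            assert translate(c.coding_nt) == c.peptide

    def test_synonymous_yields_nothing(self):
        genome = make_genome(chr1="ATGGCTTGA")
        tx = make_transcript(exons=[(0, 9)])
        out = snv_indel_candidates(tx, somatic("chr1", 5, "T", "C"), [], genome, [2])
        assert out == []

    def test_stop_gain_yields_nothing(self):
        genome = make_genome(chr1="ATGGCTAAATGA")
        tx = make_transcript(exons=[(0, 12)])
        # AAA -> TAA: the somatic variant itself creates the stop codon
        out = snv_indel_candidates(tx, somatic("chr1", 6, "A", "T"), [], genome, [2])
        assert out == []


def fusion_setup():
    # 5' gene: ATG GCT (ends mid-transcript), 3' gene: GGG TAA downstream
    genome = make_genome(chr1="ATGGCTAAATAG", chr2="CCCGGGTAA")
    tx5 = make_transcript(tx_id="T5", gene_id="G5", contig="chr1", exons=[(0, 12)])
    tx3 = make_transcript(tx_id="T3", gene_id="G3", contig="chr2", exons=[(0, 9)])
    return genome, {"T5": tx5, "T3": tx3}


class TestFusionCandidates:
    def make_call(self, bp5, bp3, frame):
        return FusionCall(
            gene5="G5", gene3="G3",
            breakpoint5=("chr1", bp5, "+"), breakpoint3=("chr2", bp3, "+"),
            transcript5="T5", transcript3="T3", frame_status=frame,
        )

    def test_in_frame_junction_protein(self):
        genome, txs = fusion_setup()
        # prefix ATGGCT + suffix GGGTAA -> MAG, junction between A and G
        out = fusion_candidates(
            self.make_call(5, 3, "in_frame"), txs, genome, [], 10, [2]
        )
        peps = {c.peptide for c in out}
        assert "AG" in peps  # spans the junction
        assert all("*" not in c.peptide for c in out)

    def test_frameshift_translates_to_first_stop(self):
        genome, txs = fusion_setup()
        genome2 = make_genome(chr1="ATGGCAAATAG", chr2="TGGGTAGCCAA")
        txs2 = {
            "T5": make_transcript(tx_id="T5", contig="chr1", exons=[(0, 11)]),
            "T3": make_transcript(tx_id="T3", contig="chr2", exons=[(0, 11)]),
        }
        # prefix ATGGC + suffix TGGGTAGCC... -> ATGGCTGGGTAGCC -> MAG (stop TAG)
        out = fusion_candidates(
            FusionCall(
                "G5", "G3", ("chr1", 4, "+"), ("chr2", 0, "+"),
                "T5", "T3", "frameshift",
            ),
            txs2, genome2, [], 10, [2, 3],
        )
        assert out
        assert {c.peptide for c in out} <= {"MA", "AG", "MAG"}
        full = max(out, key=lambda c: len(c.peptide))
        assert full.peptide == "MAG"  # terminates exactly before TAG

    def test_upstream_truncation_length_respected(self):
        genome, txs = fusion_setup()
        out = fusion_candidates(
            self.make_call(5, 3, "in_frame"), txs, genome, [], 1, [2]
        )
        # upstream_len=1: at most 1 residue kept before the junction
        assert {c.peptide for c in out} == {"AG"}

    def test_junction_stop_in_frame_yields_nothing(self):
        genome = make_genome(chr1="ATGGCTAAATAG", chr2="TAACCCGGG")
        txs = {
            "T5": make_transcript(tx_id="T5", contig="chr1", exons=[(0, 12)]),
            "T3": make_transcript(tx_id="T3", contig="chr2", exons=[(0, 9)]),
        }
        out = fusion_candidates(
            FusionCall(
                "G5", "G3", ("chr1", 5, "+"), ("chr2", 0, "+"),
                "T5", "T3", "in_frame",
            ),
            txs, genome, [], 10, [2],
        )
        assert out == []


class TestSpliceCandidates:
    def test_retained_intron_translates_intron_to_first_stop(self):
        # exon1 ATGGCT | intron GTTAGT (V then stop TAG... in frame: GTT AGT)
        genome = make_genome(chr1="ATGGCTGTTAGTAAAGGGTAA")
        tx = make_transcript(
            tx_id="H", exons=[(0, 6), (12, 21)], cds=[(0, 6), (12, 21)]
        )
        ev = SpliceEvent("retained_intron", "chr1", "+", 6, 12, "H")
        out = splice_candidates(ev, {"H": tx}, genome, [2])
        # MA + VS(GTT AGT)... translate ATGGCTGTTAGT -> M A V S, no stop
        peps = {c.peptide for c in out}
        assert "AV" in peps or "VS" in peps

    def test_retained_intron_stop_in_first_codon(self):
        genome = make_genome(chr1="ATGGCTTAAAGTAAAGGGTAA")
        tx = make_transcript(
            tx_id="H", exons=[(0, 6), (12, 21)], cds=[(0, 6), (12, 21)]
        )
        ev = SpliceEvent("retained_intron", "chr1", "+", 6, 12, "H")
        out = splice_candidates(ev, {"H": tx}, genome, [2])
        assert out == []  # intron opens with TAA: nothing novel to report

    def test_exon_skip_frame_preserved_junction_only(self):
        # three exons of 6/6/6 nt; skipping the middle one keeps frame
        genome = make_genome(chr1="ATGGCTCCCAAAGGGTTTTGA")
        tx = make_transcript(
            tx_id="H",
            exons=[(0, 6), (6, 12), (12, 21)],
            cds=[(0, 6), (6, 12), (12, 21)],
        )
        ev = SpliceEvent("exon_skip", "chr1", "+", 6, 12, "H")
        out = splice_candidates(ev, {"H": tx}, genome, [2])
        # new CDS ATGGCT+GGGTTTTGA -> M A G F *; junction between A and G
        assert {c.peptide for c in out} == {"AG"}

    def test_non_cds_event_yields_nothing(self):
        genome = make_genome(chr1="ATGGCTTGACCCCCC")
        tx = make_transcript(tx_id="H", exons=[(0, 9)])
        ev = SpliceEvent("retained_intron", "chr1", "+", 10, 14, "H")
        assert splice_candidates(ev, {"H": tx}, genome, [2]) == []


class TestViralCandidates:
    def test_whole_protein_enumerated(self):
        out = viral_candidates({"v1": "ATGAAATAA"}, [], [2])
        assert {c.peptide for c in out} == {"MK"}
        assert out[0].source_class == SourceClass.VIRUS

    def test_hom_variant_incorporated(self):
        var = hom_germ("v1", 4, "A", "G")
        out = viral_candidates({"v1": "ATGAAATAA"}, [var], [2])
        assert {c.peptide for c in out} == {"MR"}  # AAA -> AGA

    def test_ref_mismatch_is_hard_error(self):
        var = hom_germ("v1", 4, "C", "G")
        with pytest.raises(InputContractError):
            viral_candidates({"v1": "ATGAAATAA"}, [var], [2])


class TestErvCandidates:
    def test_minus_strand_orf(self):
        orf = "ATGAAACCCTAA"
        genome = make_genome(chr1="TT" + "TTAGGGTTTCAT" + "GG")  # revcomp embedded
        out = erv_candidates([("E1", "chr1", 2, 14, "-")], genome, [], [3])
        assert {c.peptide for c in out} == {"MKP"}

    def test_hom_germline_inside_orf(self):
        genome = make_genome(chr1="ATGAAACCCTAA")
        var = hom_germ("chr1", 4, "A", "G")
        out = erv_candidates([("E1", "chr1", 0, 12, "+")], genome, [var], [3])
        assert {c.peptide for c in out} == {"MRP"}

    def test_short_orf_skipped(self):
        genome = make_genome(chr1="ATGAAACCCTAA")
        assert erv_candidates([("E1", "chr1", 0, 2, "+")], genome, [], [3]) == []


class TestCtaSelfCandidates:
    genome = make_genome(chr1="ATGGCTAAACCCGGGTTTACCGATCATTGA")

    def tx(self, tx_id, gene_id):
        return make_transcript(
            tx_id=tx_id, gene_id=gene_id, exons=[(0, 30)]
        )

    def test_above_threshold_gene_emits_all_windows(self):
        models = [self.tx("T1", "CTAG1")]
        tpm = {"T1": 50.0, "X1": 1.0, "X2": 2.0, "X3": 3.0, "X4": 4.0}
        out = cta_self_candidates(
            ["CTAG1"], models, tpm, 75, self.genome, [], [9]
        )
        assert len(out) == 1  # protein length 9, k=9 -> one window
        assert out[0].source_class == SourceClass.CTA_SELF

    def test_below_threshold_gene_is_silent(self):
        models = [self.tx("T1", "CTAG1")]
        tpm = {"T1": 1.0, "X1": 10.0, "X2": 20.0, "X3": 30.0, "X4": 40.0}
        assert cta_self_candidates(
            ["CTAG1"], models, tpm, 75, self.genome, [], [9]
        ) == []

    def test_unknown_gene_warns_and_skips(self, caplog):
        out = cta_self_candidates(
            ["NOPE"], [self.tx("T1", "CTAG1")], {"T1": 9.0}, 0,
            self.genome, [], [9],
        )
        assert out == []
        assert any("absent" in r.message for r in caplog.records)


def test_mutant_peptides_are_novel_vs_reference_windows(toy_run_config):
    """Every SNV/INDEL/FUSION/SPLICE peptide is absent from the same-length
    window set of its unmutated reference protein."""
    from neopept.pipeline import run_pipeline
    from neopept.reference import (
        build_transcript_models, extract_cds, load_genome,
    )

    cfg = toy_run_config
    genome = load_genome(cfg.genome)
    models = build_transcript_models(cfg.gtf)
    ref_windows = set()
    for m in models:
        if not m.is_coding:
            continue
        prot = translate(extract_cds(genome, m), to_first_stop=True)
        for k in cfg.k_lengths:
            for s in range(len(prot) - k + 1):
                ref_windows.add(prot[s : s + k])
    df, _ = run_pipeline(cfg)
    mutated = df[df.source_class.isin(["SNV", "INDEL", "FUSION", "SPLICE"])]
    assert len(mutated) > 0
    assert not set(mutated.peptide) & ref_windows
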