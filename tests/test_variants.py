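"""VCF parsing, caller consensus, coding effects, phasing, and editing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neopept.reference import InputContractError, translate
from neopept.variants import (
    Effect,
    HaplotypeBlock,
    Origin,
    Variant,
    Zygosity,
    apply_variants,
    build_haplotype_blocks,
    classify_coding_effect,
    combine_callsets,
    normalize_variant,
    parse_vcf,
    select_phased_germline,
)

from conftest import make_genome, make_transcript

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "##contig=<ID=chr1,length=1000>\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
    '##FORMAT=<ID=PS,Number=1,Type=Integer,Description="PS">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
)


def write_vcf(tmp_path, body, name="x.vcf"):
    p = tmp_path / name
    p.write_text(VCF_HEADER + body)
    return p


def somatic(contig, pos, ref, alt, **kw):
    return Variant(contig, pos, ref, alt, Origin.SOMATIC, **kw)


class TestParseVcf:
    def test_coordinate_shift(self, tmp_path):
        p = write_vcf(tmp_path, "chr1\t5\t.\tA\tT\t.\tPASS\t.\tGT\t0/1\n")
        (v,) = parse_vcf(p, "somatic")
        assert (v.pos, v.ref, v.alt) == (4, "A", "T")
        assert v.zygosity == Zygosity.HET

    def test_multiallelic_split(self, tmp_path):
        p = write_vcf(tmp_path, "chr1\t5\t.\tA\tT,G\t.\tPASS\t.\tGT\t1/2\n")
        vs = parse_vcf(p, "somatic")
        assert {(v.pos, v.ref, v.alt) for v in vs} == {(4, "A", "T"), (4, "A", "G")}

    def test_phased_genotype_populates_haplotype(self, tmp_path):
        p = write_vcf(
            tmp_path, "chr1\t5\t.\tA\tT\t.\tPASS\t.\tGT:PS\t0|1:7\n"
        )
        (v,) = parse_vcf(p, "germline")
        assert v.phase_set == "7"
        assert v.haplotype_index == 1  # allele listed second is haplotype 1
        assert v.zygosity == Zygosity.HET

    def test_homozygous_genotype(self, tmp_path):
        p = write_vcf(tmp_path, "chr1\t5\t.\tA\tT\t.\tPASS\t.\tGT\t1/1\n")
        (v,) = parse_vcf(p, "germline")
        assert v.zygosity == Zygosity.HOM

    def test_nonpass_excluded_by_default(self, tmp_path):
        body = (
            "chr1\t5\t.\tA\tT\t.\tlowqual\t.\tGT\t0/1\n"
            "chr1\t8\t.\tC\tG\t.\tPASS\t.\tGT\t0/1\n"
        )
        p = write_vcf(tmp_path, body)
        assert len(parse_vcf(p, "somatic")) == 1
        assert len(parse_vcf(p, "somatic", keep_nonpass=True)) == 2

    def test_ref_checked_against_genome(self, tmp_path):
        p = write_vcf(tmp_path, "chr1\t2\t.\tG\tT\t.\tPASS\t.\tGT\t0/1\n")
        genome = make_genome(chr1="AAAA")
        with pytest.raises(InputContractError, match="REF mismatch"):
            parse_vcf(p, "somatic", genome=genome)


class TestNormalize:
    def test_left_alignment_of_repeat_insertion(self):
        # TA insertion in a TATA repeat shifts left to the anchor base:
        # inserting TA after offset 1, 3, 5 or 7 of GGTATATACC gives the
        # same sequence, so the leftmost (anchor G at offset 1) is canonical
        genome = make_genome(chr1="GGTATATACC")
        out = normalize_variant("chr1", 7, "A", "ATA", genome)
        assert out == ("chr1", 1, "G", "GTA")

    def test_shared_prefix_suffix_trim(self):
        assert normalize_variant("chr1", 10, "CAG", "CTG") == ("chr1", 11, "A", "T")


class TestCombineCallsets:
    v1, v2, v3, v5 = (
        somatic("chr1", 1, "A", "T"),
        somatic("chr1", 2, "C", "G"),
        somatic("chr1", 3, "G", "A"),
        somatic("chr1", 5, "T", "TAA"),
    )

    def test_intersection(self):
        out = combine_callsets(
            [("A", [self.v1, self.v2]), ("B", [self.v2, self.v3])], "intersection"
        )
        assert [v.key for v in out] == [self.v2.key]

    def test_union(self):
        out = combine_callsets(
            [("A", [self.v1, self.v2]), ("B", [self.v2, self.v3])], "union"
        )
        assert {v.key for v in out} == {self.v1.key, self.v2.key, self.v3.key}

    def test_three_caller_indel_rule(self):
        # the shared InDel survives a 3-way intersection; private ones do not
        priv = somatic("chr1", 9, "G", "GC")
        out = combine_callsets(
            [("A", [self.v5, priv]), ("B", [self.v5]), ("C", [self.v5])],
            "intersection",
            "indel",
        )
        assert [v.key for v in out] == [self.v5.key]

    def test_empty_callset_list_is_error(self):
        with pytest.raises(InputContractError):
            combine_callsets([], "intersection")

    @given(st.permutations(["A", "B", "C"]))
    @settings(deadline=None)
    def test_order_invariance_and_set_bounds(self, order):
        sets = {
            "A": [self.v1, self.v2, self.v5],
            "B": [self.v2, self.v3],
            "C": [self.v2, self.v5],
        }
        callsets = [(n, sets[n]) for n in order]
        inter = {v.key for v in combine_callsets(callsets, "intersection")}
        union = {v.key for v in combine_callsets(callsets, "union")}
        for n in order:
            keys = {v.key for v in sets[n] if v.is_snv}
            assert inter <= keys
            assert keys <= union


class TestClassifyCodingEffect:
    genome = make_genome(chr1="ATGGCTTGA")

    def tx(self):
        return make_transcript(exons=[(0, 9)])

    def test_missense(self):
        eff = classify_coding_effect(somatic("chr1", 4, "C", "A"), self.tx(), self.genome)
        assert eff.effect == Effect.MISSENSE
        assert eff.cds_pos == 4

    def test_synonymous(self):
        eff = classify_coding_effect(somatic("chr1", 5, "T", "C"), self.tx(), self.genome)
        assert eff.effect == Effect.SYNONYMOUS

    def test_two_base_deletion_is_frameshift(self):
        eff = classify_coding_effect(
            somatic("chr1", 3, "GCT", "G"), self.tx(), self.genome
        )
        assert eff.effect == Effect.FRAMESHIFT

    def test_three_base_insertion_is_inframe(self):
        eff = classify_coding_effect(
            somatic("chr1", 4, "C", "CAAA"), self.tx(), self.genome
        )
        assert eff.effect == Effect.INFRAME_INSERTION

    def test_outside_cds_is_non_coding(self):
        genome = make_genome(chr1="TTATGGCTTGA")
        tx = make_transcript(exons=[(2, 11)])
        eff = classify_coding_effect(somatic("chr1", 0, "T", "A"), tx, genome)
        assert eff.effect == Effect.NON_CODING

    def test_ref_mismatch_is_hard_error(self):
        with pytest.raises(InputContractError, match="does not match"):
            classify_coding_effect(somatic("chr1", 4, "G", "A"), self.tx(), self.genome)

    def test_agrees_with_protein_diff_oracle(self):
        """Randomized toy CDSs: classification matches a brute-force oracle
        that edits the full CDS, translates, and diffs the proteins."""
        rng = np.random.default_rng(42)
        codons = [
            a + b + c
            for a in "ACGT"
            for b in "ACGT"
            for c in "ACGT"
            if a + b + c not in ("TAA", "TAG", "TGA")
        ]
        n_checked = 0
        while n_checked < 1000:
            cds = "ATG" + "".join(
                codons[i] for i in rng.integers(0, len(codons), 8)
            ) + "TAA"
            genome = make_genome(chr1=cds)
            tx = make_transcript(exons=[(0, len(cds))])
            pos = int(rng.integers(0, len(cds) - 4))
            kind = rng.integers(0, 3)
            if kind == 0:  # SNV
                alt = "ACGT"[int(rng.integers(0, 4))]
                if alt == cds[pos]:
                    continue
                var = somatic("chr1", pos, cds[pos], alt)
                edited = cds[:pos] + alt + cds[pos + 1 :]
            elif kind == 1:  # insertion
                ins = "".join("ACGT"[i] for i in rng.integers(0, 4, rng.integers(1, 5)))
                var = somatic("chr1", pos, cds[pos], cds[pos] + ins)
                edited = cds[: pos + 1] + ins + cds[pos + 1 :]
            else:  # deletion
                dlen = int(rng.integers(1, 4))
                if pos + 1 + dlen >= len(cds):
                    continue
                var = somatic("chr1", pos, cds[pos : pos + 1 + dlen], cds[pos])
                edited = cds[: pos + 1] + cds[pos + 1 + dlen :]
            eff = classify_coding_effect(var, tx, genome).effect
            delta = len(var.alt) - len(var.ref)
            if delta == 0:
                expected = (
                    Effect.SYNONYMOUS
                    if translate(edited) == translate(cds)
                    else Effect.MISSENSE
                )
            elif delta % 3 != 0:
                expected = Effect.FRAMESHIFT
            elif delta > 0:
                expected = Effect.INFRAME_INSERTION
            else:
                expected = Effect.INFRAME_DELETION
            assert eff == expected, (cds, var)
            n_checked += 1


def germ(pos, *, zyg=Zygosity.HET, ps=None, hap=None):
    return Variant(
        "chr1", pos, "A", "T", Origin.GERMLINE, zyg, phase_set=ps, haplotype_index=hap
    )


class TestSelectPhasedGermline:
    window = ("chr1", 0, 100)

    def make_somatic(self, ps="7", hap=1):
        return Variant(
            "chr1", 50, "C", "G", Origin.SOMATIC, Zygosity.HET,
            phase_set=ps, haplotype_index=hap,
        )

    @pytest.mark.parametrize(
        "ps,hap,included",
        [
            ("7", 1, True),   # same block, same haplotype
            ("7", 0, False),  # same block, other haplotype
            ("9", 1, False),  # other block, same haplotype index
            ("9", 0, False),  # other block, other haplotype
        ],
    )
    def test_four_case_truth_table(self, ps, hap, included):
        block = HaplotypeBlock(ps, "chr1", [germ(10, ps=ps, hap=hap)])
        out = select_phased_germline(self.make_somatic(), [block], self.window)
        assert (len(out) == 1) is included

    def test_homozygous_always_included(self):
        out = select_phased_germline(
            self.make_somatic(), [], self.window, [germ(10, zyg=Zygosity.HOM)]
        )
        assert len(out) == 1

    def test_unphased_somatic_excludes_het_neighbors(self):
        block = HaplotypeBlock("7", "chr1", [germ(10, ps="7", hap=1)])
        out = select_phased_germline(
            self.make_somatic(ps=None, hap=None), [block], self.window
        )
        assert out == []

    def test_never_returns_other_haplotype(self):
        blocks = build_haplotype_blocks(
            [germ(p, ps="7", hap=p % 2) for p in range(10, 40)]
        )
        out = select_phased_germline(self.make_somatic(hap=1), blocks, self.window)
        assert all(v.haplotype_index == 1 and v.phase_set == "7" for v in out)


class TestApplyVariants:
    def test_substitution(self):
        assert apply_variants("ATGGCT", [(4, "C", "A")])[0] == "ATGGAT"

    def test_identity(self):
        assert apply_variants("ATGGCT", [])[0] == "ATGGCT"

    def test_anchored_insertion(self):
        # brute-force splice: ATG + GAA + CT
        assert apply_variants("ATGGCT", [(3, "G", "GAA")])[0] == "ATGGAACT"

    def test_overlapping_edits_error(self):
        with pytest.raises(InputContractError, match="overlap"):
            apply_variants("ATGGCT", [(2, "GG", "A"), (3, "G", "T")])

    def test_ref_mismatch_error(self):
        with pytest.raises(InputContractError, match="mismatch"):
            apply_variants("ATGGCT", [(4, "G", "A")])

    def test_offset_map_tracks_insertions(self):
        edited, omap = apply_variants("ATGGCT", [(1, "T", "TAAA")])
        assert edited == "ATAAAGGCT"
        assert omap[0] == 0 and omap[2] == 5 and omap[5] == 8

    @given(
        st.text(alphabet="ACGT", min_size=6, max_size=40),
        st.data(),
    )
    @settings(max_examples=200, deadline=None)
    def test_substitution_round_trip(self, seq, data):
        n_edits = data.draw(st.integers(1, 3))
        positions = data.draw(
            st.lists(
                st.integers(0, len(seq) - 1),
                min_size=n_edits,
                max_size=n_edits,
                unique=True,
            )
        )
        edits = [
            (p, seq[p], data.draw(st.sampled_from("ACGT"))) for p in positions
        ]
        edited, _ = apply_variants(seq, edits)
        inverse = [(p, alt, ref) for p, ref, alt in edits]
        assert apply_variants(edited, inverse)[0] == seq
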