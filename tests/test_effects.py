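"""Coding-impact classification against a hand-translatable toy gene."""

import numpy as np
import pytest

import diploscan as ds
from diploscan.effects import cds_sequence, translate
from diploscan.models import GeneModel, Variant, revcomp

# 30-bp toy CDS: ATG GCG TGG AAA CCC GGG TTT CTC GAG TAA
#                 M   A   W   K   P   G   F   L   E   *
TOY_CDS = "ATGGCGTGGAAACCCGGGTTTCTCGAGTAA"


@pytest.fixture
def toy():
    flank = "ACGTA" * 40  # 200 bp either side
    seq = flank + TOY_CDS + flank
    gene = GeneModel("toy", "c", "+", [(200, 230)], [(200, 230)])
    return gene, {"c": seq}


def _snp(pos, ref, alt):
    return Variant("c", pos, "SNP", "none", 1, ref, alt, "both", id="v")


def _del(pos, length, seq):
    return Variant("c", pos, "INDEL" if length < 40 else "SV", "DEL", length,
                   seq["c"][pos:pos + length], "", "P0", id="v")


def _ins(pos, alt):
    return Variant("c", pos, "INDEL" if len(alt) < 40 else "SV", "INS",
                   len(alt), "", alt, "P1", id="v")


class TestSnpEffects:
    def test_stop_gained_tgg_to_tga(self, toy):
        gene, seqs = toy
        # TGG codon at CDS offsets 6..8; G->A at third position gives TGA
        call = ds.classify_effect(_snp(208, "G", "A"), gene, seqs)
        assert (call.effect, call.impact) == ("stop_gained", "HIGH")

    def test_synonymous_third_position(self, toy):
        gene, seqs = toy
        # GCG codon (offsets 3..5): GCG->GCA stays alanine
        call = ds.classify_effect(_snp(205, "G", "A"), gene, seqs)
        assert (call.effect, call.impact) == ("synonymous_variant", "LOW")

    def test_missense(self, toy):
        gene, seqs = toy
        # GCG->CCG: Ala->Pro
        call = ds.classify_effect(_snp(203, "G", "C"), gene, seqs)
        assert (call.effect, call.impact) == ("missense_variant", "MODERATE")

    def test_stop_lost_in_final_codon(self, toy):
        gene, seqs = toy
        # TAA (offsets 27..29) -> CAA
        call = ds.classify_effect(_snp(227, "T", "C"), gene, seqs)
        assert (call.effect, call.impact) == ("stop_lost", "HIGH")

    def test_minus_strand_gene_translates_in_orientation(self):
        flank = "ACGTA" * 40
        seq = flank + revcomp(TOY_CDS) + flank
        gene = GeneModel("toy-", "c", "-", [(200, 230)], [(200, 230)])
        seqs = {"c": seq}
        assert cds_sequence(gene, seqs) == TOY_CDS
        # genomic base pairing with the TGG->TGA change: CDS offset 8 is
        # genomic position 200 + (30 - 1 - 8) = 221, complement G->A is C->T
        call = ds.classify_effect(_snp(221, "C", "T"), gene, seqs)
        assert call.effect == "stop_gained"


class TestIndelEffects:
    def test_four_bp_deletion_is_frameshift_high(self, toy):
        gene, seqs = toy
        call = ds.classify_effect(_del(210, 4, seqs), gene, seqs)
        assert (call.effect, call.impact) == ("frameshift_variant", "HIGH")

    def test_three_bp_deletion_is_inframe_moderate(self, toy):
        gene, seqs = toy
        call = ds.classify_effect(_del(210, 3, seqs), gene, seqs)
        assert (call.effect, call.impact) == ("inframe_deletion", "MODERATE")

    @pytest.mark.parametrize("alt,effect", [
        ("AC", "frameshift_variant"), ("ACG", "inframe_insertion")])
    def test_insertion_frame_by_length_mod_3(self, toy, alt, effect):
        gene, seqs = toy
        call = ds.classify_effect(_ins(210, alt), gene, seqs)
        assert call.effect == effect

    def test_regions_outside_cds(self, toy):
        gene, seqs = toy
        up = ds.classify_effect(_snp(100, "A", "C"), gene, seqs)
        down = ds.classify_effect(_snp(300, "A", "C"), gene, seqs)
        assert up.effect == "upstream_variant" and up.impact == "MODIFIER"
        assert down.effect == "downstream_variant"

    def test_chromosome_mismatch_is_usage_error(self, toy):
        gene, seqs = toy
        v = Variant("other", 5, "SNP", "none", 1, "A", "C", "both")
        with pytest.raises(ValueError):
            ds.classify_effect(v, gene, seqs)


class TestProteinInvariants:
    """Applying a classified variant to the CDS must change the protein the
    way the effect term promises."""

    def test_on_synthetic_genome(self, small_sim, small_called):
        _params, ref, pair, _truth = small_sim
        _blocks, variants = small_called
        calls = ds.classify_effects(
            [v for v in variants if v.var_class == "SNP"], ref.genes,
            pair.phase0)
        by_gene = {g.id: g for g in ref.genes}
        snp_by_id = {v.id: v for v in variants if v.var_class == "SNP"}
        checked = 0
        for c in calls:
            if c.region != "CDS" or c.variant_id not in snp_by_id:
                continue
            gene = by_gene[c.gene_id]
            v = snp_by_id[c.variant_id]
            p_ref = translate(cds_sequence(gene, pair.phase0))
            mutated = dict(pair.phase0)
            s = mutated[gene.chrom]
            mutated[gene.chrom] = s[:v.pos] + v.alt_allele + s[v.pos + 1:]
            p_alt = translate(cds_sequence(gene, mutated))
            if c.effect == "synonymous_variant":
                assert p_alt == p_ref
            elif c.effect == "missense_variant":
                assert sum(a != b for a, b in zip(p_ref, p_alt)) == 1
            elif c.effect == "stop_gained":
                assert p_alt.index("*") < p_ref.index("*")
            checked += 1
        assert checked >= 3


class TestPav:
    def test_containment_examples(self):
        genes = [GeneModel("in", "c", "+", [(100, 900)], [(100, 900)]),
                 GeneModel("out", "c", "+", [(100, 1100)], [(100, 1100)])]
        dele = Variant("c", 0, "SV", "DEL", 1000, "N" * 1000, "", "P0")
        assert ds.find_pav_genes(genes, [dele]) == ["in"]

    def test_matches_brute_force_on_random_instances(self, rng):
        genes = []
        for i in range(30):
            s = int(rng.integers(0, 50_000))
            e = s + int(rng.integers(200, 2000))
            genes.append(GeneModel(f"g{i}", "c", "+", [(s, e)], [(s, e)]))
        dels = []
        for i in range(10):
            s = int(rng.integers(0, 50_000))
            dels.append(Variant("c", s, "SV", "DEL",
                                int(rng.integers(40, 5000)), "", "", "P0",
                                id=f"d{i}"))
        expected = sorted(
            g.id for g in genes
            if any(d.pos <= g.start and g.end <= d.end for d in dels))
        assert sorted(ds.find_pav_genes(genes, dels)) == expected


class TestImpactSummary:
    def test_percentages(self):
        calls = [ds.EffectCall(f"v{i}", "g1", "CDS", "synonymous_variant",
                               "LOW", "SNP") for i in range(99)]
        calls.append(ds.EffectCall("v99", "g2", "CDS", "stop_gained", "HIGH",
                                   "SNP"))
        table, n_high = ds.impact_summary(calls)
        row = table[(table.var_class == "SNP") & (table.impact == "HIGH")]
        assert row["percent"].iloc[0] == 1.00
        assert n_high == 1

    def test_empty_class_omitted(self):
        calls = [ds.EffectCall("v", "g", "CDS", "missense_variant",
                               "MODERATE", "SNP")]
        table, _ = ds.impact_summary(calls)
        assert set(table.var_class) == {"SNP"}

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            ds.impact_summary([])
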