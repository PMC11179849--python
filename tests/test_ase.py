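"""ASE statistics: informative SNPs, allele counting, beta-binomial test,
FDR behaviour, clustering, and enrichment tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import diploscan as ds
from diploscan.ase import (
    InformativeSnp,
    count_alleles,
    estimate_rho,
    fisher_enrichment,
)
from diploscan.models import GeneModel, Variant


def _snp(pos, chrom="c"):
    return Variant(chrom, pos, "SNP", "none", 1, "A", "G", "both", id=f"s{pos}")


def _indel(pos, length=2, chrom="c"):
    return Variant(chrom, pos, "INDEL", "DEL", length, "N" * length, "", "P0")


GENE = GeneModel("g1", "c", "+", [(1000, 2000)], [(1000, 2000)])


class TestInformativeSnps:
    @pytest.mark.parametrize("gap,kept", [(49, False), (50, True)])
    def test_indel_distance_boundary(self, gap, kept):
        snp = _snp(1500)
        indel = _indel(1500 + gap)
        out = ds.select_informative_snps([snp], [indel], [GENE])
        assert (len(out) == 1) is kept

    def test_no_indels_keeps_all_cds_snps(self):
        snps = [_snp(p) for p in (1100, 1500, 1900, 500, 2500)]
        out = ds.select_informative_snps(snps, [], [GENE])
        assert sorted(s.pos for s in out) == [1100, 1500, 1900]

    def test_manual_toy_rule_application(self):
        snps = [_snp(p) for p in (1050, 1200, 1500, 1710, 1900)]
        indels = [_indel(1230), _indel(1760)]
        out = ds.select_informative_snps(snps, indels, [GENE])
        # 1050 ok; 1200 is 30 bp from indel edge (excluded); 1500 ok;
        # 1710 is 50 bp from 1760 (kept, boundary); 1900 is 139 bp past
        # the 1760 indel's last base (kept)
        assert sorted(s.pos for s in out) == [1050, 1500, 1710, 1900]


class TestCountAlleles:
    def _pile(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "pos", "organ",
                                           "replicate", "base", "count"])

    def test_base_splitting_and_third_allele(self):
        snps = [InformativeSnp("c", 10, "g1", "A", "G", np.inf)]
        pile = self._pile([("c", 10, "o", 1, "A", 7), ("c", 10, "o", 1, "G", 3),
                           ("c", 10, "o", 1, "T", 2)])
        rec = count_alleles(pile, snps)
        assert rec.iloc[0].count_p0 == 7 and rec.iloc[0].count_p1 == 3

    def test_gene_record_is_sum_over_snps(self):
        snps = [InformativeSnp("c", 10, "g1", "A", "G", np.inf),
                InformativeSnp("c", 20, "g1", "C", "T", np.inf)]
        pile = self._pile([("c", 10, "o", 1, "A", 7), ("c", 10, "o", 1, "G", 3),
                           ("c", 20, "o", 1, "C", 5), ("c", 20, "o", 1, "T", 5)])
        rec = count_alleles(pile, snps)
        assert rec.iloc[0].count_p0 == 12 and rec.iloc[0].count_p1 == 8

    def test_zero_coverage_site_contributes_zero(self):
        snps = [InformativeSnp("c", 10, "g1", "A", "G", np.inf)]
        pile = self._pile([("c", 99, "o", 1, "A", 4)])
        rec = count_alleles(pile, snps)
        assert rec.iloc[0].count_p0 == 0 and rec.iloc[0].count_p1 == 0


class TestAseTest:
    def test_balanced_counts_not_significant(self):
        df = pd.DataFrame([{"gene": "g", "organ": "o", "replicate": r,
                            "count_p0": 50, "count_p1": 50} for r in range(3)])
        res = ds.test_ase(df)
        assert res.p_value.iloc[0] > 0.99 and not res.is_ase.iloc[0]

    def test_skewed_counts_reduce_to_exact_binomial_at_zero_rho(self):
        df = pd.DataFrame([{"gene": "g", "organ": "o", "replicate": r,
                            "count_p0": 90, "count_p1": 10} for r in range(3)])
        res = ds.test_ase(df)
        assert res.rho.iloc[0] == 0.0
        expected = stats.binomtest(270, 300, 0.5).pvalue
        assert res.p_value.iloc[0] == pytest.approx(expected, rel=1e-9)
        assert res.p_value.iloc[0] < 1e-6

    def test_null_fdr_control(self, rng, make_counts):
        df = make_counts(rng, 1000, 100, 0.5)
        res = ds.test_ase(df)
        assert res.is_ase.sum() <= 10  # <= 1% of 1000 under the complete null

    def test_power_and_fdr_with_planted_effects(self, rng, make_counts):
        ratios = [0.8] * 100 + [0.5] * 900
        df = make_counts(rng, 1000, 200, ratios)
        res = ds.test_ase(df)
        flagged = set(res.loc[res.is_ase, "gene"])
        true_set = {f"g{i:04d}" for i in range(100)}
        sensitivity = len(flagged & true_set) / 100
        fdr = len(flagged - true_set) / max(1, len(flagged))
        assert sensitivity >= 0.9
        assert fdr <= 0.10

    def test_bh_q_values_monotone_in_p_rank(self, rng, make_counts):
        df = make_counts(rng, 200, 80, 0.55)
        res = ds.test_ase(df).sort_values("p_value")
        q = res.q_value.to_numpy()
        assert (np.diff(q) >= -1e-12).all()

    def test_zero_count_gene_flagged_untestable(self):
        df = pd.DataFrame([{"gene": "g", "organ": "o", "replicate": 1,
                            "count_p0": 0, "count_p1": 0}])
        res = ds.test_ase(df)
        assert not res.testable.iloc[0]

    def test_rho_recovers_overdispersion(self, rng):
        # beta-binomial replicates with rho = 0.05
        rho = 0.05
        a = (1 - rho) / (2 * rho)
        rows = []
        for g in range(400):
            for rep in range(3):
                n = 200
                p = rng.beta(a, a)
                x = rng.binomial(n, p)
                rows.append({"gene": f"g{g}", "organ": "o", "replicate": rep,
                             "count_p0": int(x), "count_p1": int(n - x)})
        est = estimate_rho(pd.DataFrame(rows))
        assert est == pytest.approx(rho, rel=0.3)


class TestAseFraction:
    @pytest.mark.parametrize("n_ase,n_all,expected",
                             [(579, 6182, 9.3), (0, 100, 0.0), (1, 3, 33.3)])
    def test_truncated_percentage(self, n_ase, n_all, expected):
        assert ds.ase_fraction(n_ase, n_all) == expected

    def test_guards(self):
        with pytest.raises(ValueError):
            ds.ase_fraction(1, 0)
        with pytest.raises(ValueError):
            ds.ase_fraction(5, 3)


class TestClustering:
    def _records(self, gene_props, depth=100, organs=("o1", "o2"), reps=3):
        rows = []
        for gene, props in gene_props.items():
            for organ in organs:
                for rep in range(reps):
                    x = int(round(depth * props[organ]))
                    rows.append({"gene": gene, "organ": organ,
                                 "replicate": rep, "count_p0": x,
                                 "count_p1": depth - x})
        return pd.DataFrame(rows)

    def test_read_filter_applies_to_replicate_totals(self):
        rec = pd.DataFrame(
            [{"gene": "a", "organ": "o", "replicate": 1, "count_p0": 5,
              "count_p1": 200},   # total 205 >= 10: passes
             {"gene": "b", "organ": "o", "replicate": 1, "count_p0": 3,
              "count_p1": 5}])    # total 8 < 10: fails
        out = ds.cluster_ase_profiles(None, rec, min_reads=10, k=1,
                                      ase_only=False)
        assert out.gene.tolist() == ["a"]

    def test_planted_groups_separate_at_k2(self):
        props = {}
        for i in range(10):
            props[f"p0only{i}"] = {"o1": 0.95, "o2": 0.95}
            props[f"p1only{i}"] = {"o1": 0.05, "o2": 0.05}
        out = ds.cluster_ase_profiles(None, self._records(props), k=2,
                                      ase_only=False)
        groups = out.assign(kind=out.gene.str.startswith("p0"))
        counts = groups.groupby(["kind", "cluster"]).size()
        # each planted group maps to exactly one cluster
        assert (counts.groupby("kind").size() == 1).all()

    def test_identical_profiles_zero_within_cluster_variance(self):
        props = {f"g{i}": {"o1": 0.5, "o2": 0.5} for i in range(8)}
        out = ds.cluster_ase_profiles(None, self._records(props), k=2,
                                      ase_only=False)
        for _c, grp in out.groupby("cluster"):
            assert grp.filter(like="mean_p0").var().fillna(0).sum() == 0

    def test_too_few_genes_raises(self):
        props = {"g1": {"o1": 0.5, "o2": 0.5}}
        with pytest.raises(ValueError, match="k"):
            ds.cluster_ase_profiles(None, self._records(props), k=4,
                                    ase_only=False)


class TestEnrichment:
    def test_balanced_table_p_one(self):
        res = fisher_enrichment(5, 5, 5, 5)
        assert res.p_value == pytest.approx(1.0)

    def test_reported_proportions_and_significance(self):
        # ASE genes 199/579 near an SV vs non-ASE 1569/5603
        res = fisher_enrichment(199, 380, 1569, 4034)
        assert res.percent_ase == 34.4
        assert res.percent_non_ase == 28.0
        assert res.p_value < 0.05

    def test_extreme_table_hypergeometric(self):
        res = fisher_enrichment(10, 0, 0, 10)
        assert res.p_value == pytest.approx(1.0825e-5, rel=1e-3)

    def test_gene_window_overlap(self):
        genes = [GeneModel("g1", "c", "+", [(5000, 6000)], [(5000, 6000)]),
                 GeneModel("g2", "c", "+", [(20_000, 21_000)],
                           [(20_000, 21_000)])]
        sv = Variant("c", 6500, "SV", "INS", 100, "", "N" * 100, "P1")
        res = ds.sv_ase_enrichment({"g1"}, {"g1", "g2"}, [sv], genes,
                                   window_bp=1000)
        assert res.table == ((1, 0), (0, 1))


class TestTeExpressionAssociation:
    def test_identical_groups_p_one(self):
        expr = pd.Series({f"g{i}": 1.0 for i in range(9)})
        groups = {f"g{i}": ["none", "hom", "het"][i % 3] for i in range(9)}
        out = ds.te_expression_association(expr, groups)
        assert out.loc[out.group == "hom", "p_vs_none"].iloc[0] == \
            pytest.approx(1.0)

    def test_planted_shifts_detected(self, rng):
        expr = {}
        groups = {}
        for i in range(200):
            expr[f"n{i}"] = rng.normal(5, 1)
            groups[f"n{i}"] = "none"
            expr[f"h{i}"] = rng.normal(4, 1)   # hom shifted down
            groups[f"h{i}"] = "hom"
            expr[f"e{i}"] = rng.normal(5.5, 1)  # het shifted up
            groups[f"e{i}"] = "het"
        out = ds.te_expression_association(pd.Series(expr), groups).set_index("group")
        assert out.loc["hom", "median"] < out.loc["none", "median"] \
            < out.loc["het", "median"]
        assert out.loc["hom", "p_vs_none"] < 0.05
        assert out.loc["het", "p_vs_none"] < 0.05

    def test_small_group_unavailable(self):
        expr = pd.Series({"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0, "e": 2.5})
        groups = {"a": "none", "b": "none", "c": "none", "d": "hom", "e": "hom"}
        out = ds.te_expression_association(expr, groups).set_index("group")
        assert np.isnan(out.loc["hom", "p_vs_none"])
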