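import numpy as np
import pandas as pd
import pytest

from gwasbench import benchmark
from gwasbench.errors import ConfigurationError
from gwasbench.evaluate import (EvalConfig, classify_gene_level,
                                classify_locus_level, classify_variant_level,
                                compute_f1, median_rank,
                                overlap_sensitivity_sweep, rank_methods)
from gwasbench.loci import Locus
from gwasbench.report import quadrant_assign
from gwasbench.sumstats import NominationSet

from conftest import make_sumstats, random_small_loci
from oracles import brute_classify


def variant_set(points, method="m"):
    return NominationSet(method=method, level="variant",
                         items=pd.DataFrame(points, columns=["chrom", "pos"]))


def gene_set(gene_ids=None, symbols=None, method="m"):
    items = pd.DataFrame({
        "gene_id": gene_ids if gene_ids is not None else [None] * len(symbols),
        "symbol": symbols if symbols is not None else [None] * len(gene_ids),
    })
    return NominationSet(method=method, level="gene", items=items)


class TestVariantLevel:
    def test_exact_match(self):
        res = classify_variant_level(variant_set([("1", 100)]),
                                     make_sumstats([("1", 100, 1e-9)]))
        assert (res.tp_nominated, res.fp, res.fn) == (1, 0, 0)
        assert res.sn == res.ppv == 1.0

    def test_positions_must_match_exactly(self):
        res = classify_variant_level(variant_set([("1", 100)]),
                                     make_sumstats([("1", 101, 1e-9)]))
        assert (res.tp_nominated, res.fp, res.fn) == (0, 1, 1)

    def test_counting(self):
        nominated = variant_set([("1", 1), ("1", 2), ("1", 3)])
        gold = make_sumstats([("1", 1, 1e-9), ("1", 2, 1e-9),
                              ("1", 10, 1e-9), ("1", 11, 1e-9)])
        res = classify_variant_level(nominated, gold)
        assert res.sn == 0.5 and res.ppv == pytest.approx(2 / 3)

    def test_level_mismatch_rejected(self):
        with pytest.raises(ConfigurationError):
            classify_variant_level(gene_set(gene_ids=["ENSG1"]),
                                   make_sumstats([]))


class TestLocusLevel:
    def window(self, chrom, center):
        return Locus(chrom, center - 500_000, center + 500_000, lead_pos=center)

    def test_300kb_separation_is_tp(self):
        # two ±500 kb windows with leads 300 kb apart share 700,001 bases
        res = classify_locus_level([self.window("1", 5_000_000)],
                                   [self.window("1", 5_300_000)])
        assert res.tp_nominated == 1 and res.fp == 0 and res.fn == 0

    def test_800kb_separation_is_fp_and_fn(self):
        # overlap 200,001 < 250,000
        res = classify_locus_level([self.window("1", 5_000_000)],
                                   [self.window("1", 5_800_000)])
        assert (res.tp_nominated, res.fp, res.fn) == (0, 1, 1)
        assert res.sn == 0.0 and res.ppv == 0.0

    def test_empty_nominations_sn_zero_ppv_absent(self):
        res = classify_locus_level([], [self.window("1", 5_000_000)])
        assert res.sn == 0.0 and res.ppv is None and res.f1 is None

    def test_one_nominated_locus_covering_two_gold(self):
        big = Locus("1", 1, 3_000_000)
        gold = [self.window("1", 1_000_000), self.window("1", 2_500_000)]
        res = classify_locus_level([big], gold)
        assert res.tp_nominated == 1      # once toward PPV
        assert res.gold_covered == 2      # each gold locus toward SN
        assert res.sn == 1.0 and res.ppv == 1.0

    def test_matches_base_set_oracle(self, rng):
        for _ in range(60):
            nom = [(l.chrom, l.start, l.end)
                   for l in random_small_loci(rng, int(rng.integers(0, 12)))]
            gold = [(l.chrom, l.start, l.end)
                    for l in random_small_loci(rng, int(rng.integers(1, 12)))]
            min_overlap = int(rng.integers(1, 80))
            res = classify_locus_level([Locus(*t) for t in nom],
                                       [Locus(*t) for t in gold],
                                       min_overlap=min_overlap)
            tp, fp, covered, fn = brute_classify(nom, gold, min_overlap)
            assert (res.tp_nominated, res.fp, res.gold_covered, res.fn) == \
                   (tp, fp, covered, fn)


class TestGeneLevel:
    @pytest.fixture
    def gold_genes(self):
        # 10 genes with valid p; 2 below 0.05/10
        rows = []
        for i in range(10):
            rows.append({
                "gene_id": f"ENSG{i:04d}", "symbol": f"G{i}", "chrom": "1",
                "start": 1_000_000 * (i + 1), "end": 1_000_000 * (i + 1) + 50_000,
                "pvalue": 1e-4 if i < 2 else 0.5,
            })
        df = pd.DataFrame(rows)
        df["midpoint"] = (df["start"] + df["end"]) // 2
        return df

    def test_bonferroni_gold_set_size(self, gold_genes):
        res = classify_gene_level(gene_set(gene_ids=["ENSG0000"]), gold_genes)
        # gold set = 2 significant genes; one matched
        assert res.tp_nominated == 1 and res.fn == 1

    def test_id_match(self, gold_genes):
        res = classify_gene_level(gene_set(gene_ids=["ENSG0000", "ENSG0005"]),
                                  gold_genes)
        assert (res.tp_nominated, res.fp, res.fn) == (1, 1, 1)
        assert res.ppv == 0.5 and res.sn == 0.5

    def test_symbol_mode(self, gold_genes):
        res = classify_gene_level(gene_set(symbols=["G1"]), gold_genes,
                                  EvalConfig(id_mode="symbol"))
        assert res.tp_nominated == 1

    def test_ensembl_mode_with_symbol_only_nominations_rejected(self, gold_genes):
        with pytest.raises(ConfigurationError, match="symbol"):
            classify_gene_level(gene_set(symbols=["G1"]), gold_genes)

    def test_midpoint_flank_merges_overlapping_genes(self, gold_genes):
        # two nominated genes 1 Mb apart -> midpoint windows overlap -> merged
        res = classify_gene_level(
            gene_set(gene_ids=["ENSG0000", "ENSG0001"]), gold_genes,
            EvalConfig(gene_locus_mode="midpoint_flank"))
        assert res.tp_nominated == 1  # single merged nominated locus
        assert res.gold_covered == 1  # gold side merged identically

    def test_boundaries_mode_small_overlap_threshold(self, gold_genes):
        cfg = EvalConfig(gene_locus_mode="boundaries")
        res = classify_gene_level(gene_set(gene_ids=["ENSG0000"]), gold_genes, cfg)
        assert res.tp_nominated == 1 and res.fn == 1


class TestMetricsArithmetic:
    @pytest.mark.parametrize("sn,ppv,expected", [
        (0.5, 0.5, 0.5),
        (1.0, 0.0, 0.0),
        (0.747, 0.25, 2 * 0.747 * 0.25 / (0.747 + 0.25)),
        (None, 0.5, None),
    ])
    def test_f1(self, sn, ppv, expected):
        got = compute_f1(sn, ppv)
        if expected is None:
            assert got is None
        else:
            assert got == pytest.approx(expected)

    def test_f1_bounds(self, rng):
        for _ in range(200):
            sn, ppv = rng.random(), rng.random()
            f1 = compute_f1(sn, ppv)
            assert 0 <= f1 <= 1
            assert f1 <= max(sn, ppv) + 1e-12
            assert f1 <= 2 * min(sn, ppv) + 1e-12

    @pytest.mark.parametrize("sn,ppv,quadrant", [
        (0.9, 0.9, "I"), (0.1, 0.9, "II"), (0.5, 0.5, "III"),
        (0.9, 0.1, "IV"), (0.51, 0.5, "IV"), (None, 0.9, None),
    ])
    def test_quadrants(self, sn, ppv, quadrant):
        assert quadrant_assign(sn, ppv) == quadrant


class TestRanking:
    def test_distinct_ppvs_rank_sequentially(self):
        ranks = rank_methods({"a": 0.9, "b": 0.5, "c": 0.1}, n_total=18)
        assert ranks == {"a": 1, "b": 2, "c": 3}

    def test_olympic_ties_share_lowest_rank(self):
        ranks = rank_methods({"a": 0.9, "b": 0.5, "c": 0.5, "d": 0.1})
        assert ranks["b"] == ranks["c"] == 3 and ranks["d"] == 4

    def test_absent_ppv_ranks_n_total_below_zero_ppv(self):
        ranks = rank_methods({"a": 0.0, "b": None}, n_total=18)
        assert ranks["a"] == 1 and ranks["b"] == 18

    def test_published_scz_column(self):
        ranks = benchmark.recompute_ranks("SCZ")
        assert ranks["SMR"] == 15
        assert ranks["GenoSkyline"] == 11
        assert ranks["Weighted eQTL"] == 18

    def test_published_bpd_tie(self):
        ranks = benchmark.recompute_ranks("BPD")
        assert ranks["TWAS/FUSION"] == 3 and ranks["EUGENE"] == 3

    @pytest.mark.parametrize("ranks,expected", [
        ((3, 18, 6, 4, 8), 6),
        ((6, 9, 7, 10, 9), 9),
        ((5, 5), 5),
        ((), None),
    ])
    def test_median_rank(self, ranks, expected):
        assert median_rank(list(ranks)) == expected


class TestOverlapSweep:
    def test_monotone_tp_and_endpoint_cases(self):
        nominated = [Locus("1", 4_500_000, 5_500_000),
                     Locus("1", 9_000_000, 10_000_000)]
        gold = [Locus("1", 5_300_000, 6_300_000),
                Locus("1", 9_300_000, 10_300_000)]
        table = overlap_sensitivity_sweep(nominated, gold)
        tps = list(table["tp"])
        assert tps == sorted(tps, reverse=True)
        # 800 kb-separated pair: overlap 200,001 counts at 1 b but not 250 kb
        assert table.loc[table.min_overlap == 1, "tp"].iloc[0] == 2
        assert table.loc[table.min_overlap == 250_000, "tp"].iloc[0] == 1
        # 300 kb-separated pair: overlap 700,001 fails only at 750 kb
        assert table.loc[table.min_overlap == 750_000, "tp"].iloc[0] == 0

    def test_non_positive_overlap_rejected(self):
        with pytest.raises(ConfigurationError):
            overlap_sensitivity_sweep([], [], overlaps=[0])
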