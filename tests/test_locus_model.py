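import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gwasbench.loci import (Locus, LocusConfig, define_loci,
                            exclude_overlapping, exclude_points_in_loci,
                            gene_to_locus, merge_loci, overlap_length,
                            read_loci, windows_from_points, write_loci,
                            write_loci_bed)

from conftest import make_sumstats, random_small_loci
from oracles import brute_define_loci


class TestDefineLoci:
    def test_empty_when_nothing_significant(self):
        df = make_sumstats([("1", 1_000_000, 1e-6)])
        assert define_loci(df) == []

    def test_single_variant_window(self):
        df = make_sumstats([("1", 1_000_000, 1e-9)])
        (locus,) = define_loci(df)
        assert (locus.chrom, locus.start, locus.end) == ("1", 500_000, 1_500_000)
        assert locus.lead_pos == 1_000_000 and locus.members == [1_000_000]

    def test_stepwise_two_loci(self):
        # second window opens at 2.1 Mb after the first absorbs 1.0 and 1.4 Mb
        df = make_sumstats([
            ("1", 1_000_000, 1e-10),
            ("1", 1_400_000, 1e-9),
            ("1", 2_100_000, 1e-9),
        ])
        loci = define_loci(df)
        assert [(l.start, l.end) for l in loci] == [
            (500_000, 1_500_000), (1_600_000, 2_600_000)]
        assert loci[0].members == [1_000_000, 1_400_000]
        assert loci[1].members == [2_100_000]

    def test_hla_region_collapsed(self):
        df = make_sumstats([("6", 26_000_000, 1e-12)])
        (locus,) = define_loci(df)
        assert locus.is_hla
        assert locus.start <= 25_000_000 and locus.end >= 35_000_000

    def test_hla_union_keeps_extension(self):
        # window extends past 35 Mb; union must keep the extension
        df = make_sumstats([("6", 35_400_000, 1e-12)])
        (locus,) = define_loci(df)
        assert locus.is_hla
        assert locus.end == 35_900_000 and locus.start == 25_000_000

    def test_partition_of_significant_variants(self, rng):
        rows = [("1", int(p), 10.0 ** -rng.uniform(5, 12))
                for p in rng.choice(20_000_000, size=60, replace=False)]
        df = make_sumstats(rows)
        loci = define_loci(df)
        sig_pos = sorted(df.loc[df.pvalue < 5e-8, "pos"])
        members = sorted(m for l in loci for m in l.members)
        assert members == sig_pos  # each significant variant in exactly one locus
        for a, b in zip(loci, loci[1:]):
            if a.chrom == b.chrom:
                assert overlap_length(a, b) == 0

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(st.randoms(use_true_random=False))
    def test_order_invariance(self, pyrng):
        rows = [("1" if pyrng.random() < 0.5 else "2",
                 pyrng.randrange(1, 3000),
                 10.0 ** (-pyrng.uniform(6, 10)))
                for _ in range(30)]
        df = make_sumstats(rows).drop_duplicates(subset=["chrom", "pos"])
        cfg = LocusConfig(flank=100)
        shuffled = df.sample(frac=1.0, random_state=7)
        a = define_loci(df, cfg)
        b = define_loci(shuffled, cfg)
        assert [(l.chrom, l.start, l.end, tuple(l.members)) for l in a] == \
               [(l.chrom, l.start, l.end, tuple(l.members)) for l in b]

    def test_matches_brute_force_on_random_instances(self, rng):
        cfg = LocusConfig(flank=60)
        for _ in range(50):
            n = int(rng.integers(1, 60))
            rows = [(str(rng.choice(["1", "2"])), int(rng.integers(1, 2000)),
                     10.0 ** -rng.uniform(5, 11)) for _ in range(n)]
            df = make_sumstats(rows).drop_duplicates(subset=["chrom", "pos"])
            got = sorted((l.chrom, l.start, l.end, tuple(l.members))
                         for l in define_loci(df, cfg))
            expected = brute_define_loci(df, cfg.sig_threshold, cfg.flank)
            assert got == expected

    def test_monotone_coverage_in_threshold(self, rng):
        rows = [("1", int(p), 10.0 ** -rng.uniform(5, 12))
                for p in rng.choice(30_000_000, size=80, replace=False)]
        df = make_sumstats(rows)
        covered = []
        for threshold in (1e-10, 5e-8, 1e-6):
            loci = define_loci(df, LocusConfig(sig_threshold=threshold))
            covered.append(sum(l.width for l in loci))
        assert covered == sorted(covered)


class TestWindowsFromPoints:
    def test_two_overlapping_windows_merge(self):
        points = pd.DataFrame({"chrom": ["2", "2"], "pos": [1_000_000, 1_900_000]})
        (locus,) = windows_from_points(points)
        assert (locus.start, locus.end) == (500_000, 2_400_000)

    def test_different_chromosomes_never_merge(self):
        points = pd.DataFrame({"chrom": ["1", "2"], "pos": [1_000_000, 1_000_000]})
        assert len(windows_from_points(points)) == 2

    def test_single_point_width(self):
        points = pd.DataFrame({"chrom": ["1"], "pos": [10_000_000]})
        (locus,) = windows_from_points(points)
        assert locus.width == 1_000_001

    def test_lead_from_smallest_p(self):
        points = pd.DataFrame({"chrom": ["2", "2"], "pos": [1_000_000, 1_900_000],
                               "pvalue": [1e-6, 1e-9]})
        (locus,) = windows_from_points(points)
        assert locus.lead_pos == 1_900_000 and locus.lead_p == 1e-9


class TestOverlapLength:
    def test_self_overlap_is_width(self):
        l = Locus("1", 1, 1_000_001)
        assert overlap_length(l, l) == 1_000_001

    def test_closed_interval_arithmetic(self):
        a = Locus("1", 1, 1_000_000)
        b = Locus("1", 750_001, 2_000_000)
        assert overlap_length(a, b) == 250_000

    def test_zero_across_chromosomes(self):
        assert overlap_length(Locus("1", 1, 100), Locus("2", 1, 100)) == 0

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.integers(1, 500), st.integers(1, 500), st.integers(1, 500),
           st.integers(1, 500))
    def test_symmetric_and_matches_base_sets(self, s1, w1, s2, w2):
        a, b = Locus("1", s1, s1 + w1), Locus("1", s2, s2 + w2)
        expected = len(set(range(a.start, a.end + 1)) & set(range(b.start, b.end + 1)))
        assert overlap_length(a, b) == overlap_length(b, a) == expected


class TestExclusion:
    def test_single_shared_base_removed(self):
        target = [Locus("1", 1_000_000, 2_000_000)]
        exclusion = [Locus("1", 2_000_000, 3_000_000)]
        assert exclude_overlapping(target, exclusion, min_overlap=1) == []

    def test_disjoint_identity(self):
        target = [Locus("1", 1, 10)]
        assert exclude_overlapping(target, [Locus("1", 100, 200)]) == target

    def test_counts(self):
        target = [Locus("1", 1, 100), Locus("1", 500, 600), Locus("2", 1, 100)]
        exclusion = [Locus("1", 550, 560)]
        assert len(exclude_overlapping(target, exclusion)) == 2

    def test_self_exclusion_empties(self, rng):
        loci = merge_loci(random_small_loci(rng, 10))
        assert exclude_overlapping(loci, loci, 1) == []

    def test_points_at_lead_removed(self):
        loci = [Locus("1", 500_000, 1_500_000, lead_pos=1_000_000)]
        points = pd.DataFrame({"chrom": ["1", "1"], "pos": [1_000_000, 2_100_001]})
        kept = exclude_points_in_loci(points, loci)
        assert list(kept["pos"]) == [2_100_001]

    def test_empty_loci_identity(self):
        points = pd.DataFrame({"chrom": ["1"], "pos": [5]})
        assert len(exclude_points_in_loci(points, [])) == 1


class TestGeneToLocus:
    gene = {"chrom": "1", "start": 100_000, "end": 200_000, "pvalue": 1e-7}

    def test_midpoint_flank_unclipped(self):
        locus = gene_to_locus(self.gene, mode="midpoint_flank")
        assert (locus.start, locus.end) == (-350_000, 650_000)

    def test_boundaries_mode(self):
        locus = gene_to_locus(self.gene, mode="boundaries")
        assert (locus.start, locus.end) == (100_000, 200_000)

    def test_zero_width_gene(self):
        locus = gene_to_locus({"chrom": "1", "start": 5, "end": 5},
                              mode="midpoint_flank")
        assert locus.width == 1_000_001


class TestLociIO:
    def test_tsv_round_trip(self, tmp_path):
        loci = [Locus("1", 10, 20, lead_pos=15, lead_p=1e-9),
                Locus("6", 25_000_000, 35_000_000, is_hla=True)]
        path = tmp_path / "loci.tsv"
        write_loci(loci, path)
        back = read_loci(path)
        assert [(l.chrom, l.start, l.end, l.is_hla) for l in back] == \
               [(l.chrom, l.start, l.end, l.is_hla) for l in loci]

    def test_bed_clamps_negative_starts(self, tmp_path):
        loci = [Locus("1", -350_000, 650_000)]
        path = tmp_path / "loci.bed"
        n_clamped = write_loci_bed(loci, path)
        assert n_clamped == 1
        chrom, start, end, _ = path.read_text().strip().split("\t")
        assert (chrom, start, end) == ("1", "0", "650000")
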