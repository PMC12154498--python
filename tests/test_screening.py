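"""Screening funnel: threshold boundaries, isolation, apportionment, census."""

from itertools import combinations

import pytest

from kaspanel.io import VariantRecord
from kaspanel.screening import (FilterThresholds, ScreeningError,
                                classify_variant_type, distribute_evenly,
                                flank_isolation, frequency_window, hard_filter,
                                run_screen, site_filter, variant_type_census,
                                VARIANT_TYPES)
from kaspanel.simulate import AnnotationModel, simulate_vcf


def make_snp(chrom="chr01", pos=100, ref="A", alt="G", qual=100.0, info=None,
             calls=None, depths=None):
    calls = calls if calls is not None else [(0, 1)] * 10
    depths = depths if depths is not None else [20] * len(calls)
    return VariantRecord(chrom=chrom, pos=pos, ref=ref, alts=[alt], qual=qual,
                         info=info or {}, sample_calls=calls,
                         sample_depths=depths)


class TestHardFilter:
    @pytest.mark.parametrize("info,expected,reason", [
        ({"QD": 1.9, "MQ": 50, "MQRankSum": 0, "ReadPosRankSum": 0}, False, "QD"),
        ({"QD": 2.0, "MQ": 50, "MQRankSum": 0, "ReadPosRankSum": 0}, True, None),
        ({}, True, None),  # absent annotations never fail their clause
        ({"MQ": 39.9}, False, "MQ"),
        ({"MQRankSum": -12.6}, False, "MQRankSum"),
        ({"ReadPosRankSum": -8.1}, False, "ReadPosRankSum"),
        ({"MQRankSum": -12.5, "ReadPosRankSum": -8.0}, True, None),  # boundaries
    ])
    def test_threshold_boundaries(self, info, expected, reason):
        ok, why = hard_filter(make_snp(info=info))
        assert ok is expected and why == reason

    def test_non_snp_rejected(self):
        rec = VariantRecord(chrom="chr01", pos=5, ref="AT", alts=["A"],
                            sample_calls=[(0, 0)], sample_depths=[10])
        with pytest.raises(ScreeningError):
            hard_filter(rec)


class TestSiteFilter:
    def test_low_minor_allele_count_fails(self):
        # 50 diploid samples, only 2 alt alleles in total: below MAC 3
        calls = [(0, 1)] + [(0, 1)] + [(0, 0)] * 48
        ok, why = site_filter(make_snp(calls=calls))
        assert not ok and why == "mac"

    def test_missing_fraction_boundary_inclusive(self):
        # exactly half the genotypes present: kept (vcftools --max-missing 0.5)
        calls = [(0, 1)] * 5 + [None] * 5
        ok, _ = site_filter(make_snp(calls=calls))
        assert ok

    def test_triallelic_fails(self):
        rec = VariantRecord(chrom="chr01", pos=5, ref="A", alts=["G", "T"],
                            sample_calls=[(0, 1)] * 10, sample_depths=[20] * 10)
        ok, why = site_filter(rec)
        assert not ok and why == "alleles"

    def test_all_missing(self):
        ok, why = site_filter(make_snp(calls=[None] * 10))
        assert not ok and why == "all-missing"

    @pytest.mark.parametrize("field,value,reason", [
        ("qual", 29.9, "qual"),
        ("depths", [3] * 10, "mean-dp"),
    ])
    def test_qual_and_depth(self, field, value, reason):
        kwargs = {field: value} if field != "qual" else {"qual": value}
        if field == "depths":
            kwargs = {"depths": value}
        ok, why = site_filter(make_snp(calls=[(0, 1)] * 10, **kwargs))
        assert not ok and why == reason


class TestFlankIsolation:
    def test_pair_within_flank_mutually_removed(self):
        recs = [make_snp(pos=100), make_snp(pos=150)]
        assert flank_isolation(recs, 100) == []

    def test_pair_just_outside_flank_both_kept(self):
        recs = [make_snp(pos=100), make_snp(pos=201)]
        assert len(flank_isolation(recs, 100)) == 2

    def test_boundary_distance_violates(self):
        recs = [make_snp(pos=100), make_snp(pos=200)]
        assert flank_isolation(recs, 100) == []

    def test_singleton_chromosome_kept(self):
        recs = [make_snp(chrom="chr01", pos=100), make_snp(chrom="chr02", pos=150)]
        assert len(flank_isolation(recs, 100)) == 2

    def test_unsorted_input_rejected(self):
        recs = [make_snp(pos=500), make_snp(pos=100)]
        with pytest.raises(ScreeningError, match="sorted"):
            flank_isolation(recs, 100)

    def test_non_snp_context_removes_candidates(self):
        indel = VariantRecord(chrom="chr01", pos=150, ref="AT", alts=["A"],
                              sample_calls=[(0, 1)], sample_depths=[10])
        cand = [make_snp(pos=100, calls=[(0, 1)], depths=[10])]
        assert flank_isolation(cand, 100, context=sorted(
            cand + [indel], key=lambda r: (r.chrom, r.pos))) == []


class TestFrequencyWindow:
    @pytest.mark.parametrize("n_alt_hom,expected", [
        (3, True),    # alt freq 0.30: inclusive lower bound
        (2, False),   # 0.25 (n=8 -> 0.2? computed below)
        (7, True),    # 0.70 inclusive upper
        (8, False),   # 0.80
    ])
    def test_window_bounds(self, n_alt_hom, expected):
        # 10 samples: n_alt_hom alt homozygotes, rest ref hom -> freq = n/10
        calls = [(1, 1)] * n_alt_hom + [(0, 0)] * (10 - n_alt_hom)
        rec = make_snp(calls=calls)
        kept = frequency_window([rec], (0.30, 0.70))
        assert (rec in kept) is (0.30 <= n_alt_hom / 10 <= 0.70) is expected


class TestDistributeEvenly:
    def test_uniform_quota_across_chromosomes(self):
        recs = [make_snp(chrom=f"chr{c:02d}", pos=p)
                for c in range(1, 13) for p in (1000, 5000)]
        out = distribute_evenly(recs, 12)
        per_chrom = {c: sum(r.chrom == c for r in out)
                     for c in {r.chrom for r in recs}}
        assert all(v == 1 for v in per_chrom.values())

    def test_farthest_point_matches_brute_force(self):
        positions = [1, 50, 100]
        recs = [make_snp(pos=p) for p in positions]
        out = distribute_evenly(recs, 2)
        # brute-force: the pair maximizing the minimum pairwise distance
        best = max(combinations(positions, 2), key=lambda pr: abs(pr[0] - pr[1]))
        assert sorted(r.pos for r in out) == sorted(best) == [1, 100]

    def test_identity_when_target_is_all(self):
        recs = [make_snp(pos=p) for p in (10, 500, 900)]
        assert len(distribute_evenly(recs, 3)) == 3

    def test_target_exceeding_candidates_rejected(self):
        with pytest.raises(ScreeningError):
            distribute_evenly([make_snp()], 2)

    def test_quota_within_one_of_proportionality(self):
        recs = ([make_snp(chrom="chr01", pos=p) for p in range(1000, 31000, 1000)]
                + [make_snp(chrom="chr02", pos=p) for p in range(1000, 11000, 1000)])
        out = distribute_evenly(recs, 20)
        n1 = sum(r.chrom == "chr01" for r in out)
        n2 = sum(r.chrom == "chr02" for r in out)
        assert n1 + n2 == 20
        assert abs(n1 - 20 * 30 / 40) <= 1 and abs(n2 - 20 * 10 / 40) <= 1


class TestVariantCensus:
    def test_twelve_categories(self):
        assert len(VARIANT_TYPES) == 12
        assert classify_variant_type("A", "G") == "A/G"

    def test_census_proportions(self):
        counts, props = variant_type_census([("A", "G"), ("A", "G"), ("C", "T")])
        assert counts["A/G"] == 2 and counts["C/T"] == 1
        assert props["A/G"] == pytest.approx(2 / 3)
        assert props["C/T"] == pytest.approx(1 / 3)

    def test_ref_equals_alt_rejected(self):
        with pytest.raises(ScreeningError):
            classify_variant_type("A", "A")


class TestFunnel:
    CHROMS = {f"chr{c:02d}": 2_000_000 for c in range(1, 13)}

    def test_funnel_counts_monotone_and_plants_recovered(self):
        sim = simulate_vcf(400, 20, self.CHROMS,
                           AnnotationModel(violate_fraction={"QD": 0.05,
                                                             "MQ": 0.05}),
                           clustered_fraction=0.1, seed=21)
        survivors, report = run_screen(sim.records, FilterThresholds(),
                                       n_target=96)
        counts = list(report.stage_counts.values())
        assert counts == sorted(counts, reverse=True)
        n_planted = sum(len(v) for v in sim.planted_violations.values())
        assert len(report.removals["hard_filter"]) == n_planted
        assert len(survivors) == 96
        # every survivor is isolated and mid-frequency
        for r in survivors:
            assert 0.30 <= r.alt_frequency() <= 0.70

    def test_order_independence_of_flank_isolation(self):
        sim = simulate_vcf(100, 5, self.CHROMS, AnnotationModel(),
                           clustered_fraction=0.2, seed=5)
        recs = sorted(sim.records, key=lambda r: (r.chrom, r.pos))
        import random
        shuffled = recs[:]
        random.Random(0).shuffle(shuffled)
        shuffled = sorted(shuffled, key=lambda r: (r.chrom, r.pos))
        a = {(r.chrom, r.pos) for r in flank_isolation(recs, 100)}
        b = {(r.chrom, r.pos) for r in flank_isolation(shuffled, 100)}
        assert a == b
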