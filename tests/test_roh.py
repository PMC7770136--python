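"""ROH scan tests: scoring, oracle equivalence, recovery, F_ROH, dating."""

import dataclasses

import numpy as np
import pytest

from conskit import (
    RohScanParams,
    RohSegment,
    SimConfig,
    call_segments,
    froh,
    generations_from_length,
    overlap_fractions,
    score_snps,
    simulate_cohort,
)
from conskit.io import HET, HOM_REF
from conskit.roh import cohort_froh, scan_individual

from roh_oracle import oracle_scores, oracle_segments

PARAMS = RohScanParams()


def _random_instance(rng, n_max=200):
    n = int(rng.integers(5, n_max + 1))
    pos = np.sort(rng.choice(2_000_000, size=n, replace=False)) + 1
    # mixture of homozygous stretches and noisy regions
    gt = rng.choice([0, 1, 2, -1], size=n, p=[0.55, 0.15, 0.25, 0.05]).astype(np.int8)
    if rng.random() < 0.5:  # plant a homozygous run
        a = int(rng.integers(0, n))
        b = min(n, a + int(rng.integers(10, 120)))
        gt[a:b] = rng.choice([0, 2], size=b - a)
    return pos, gt


class TestScoreSnps:
    def test_fully_homozygous_chromosome_scores_one(self):
        pos = np.arange(1, 101) * 1000
        gt = np.zeros(100, dtype=np.int8)
        assert (score_snps(pos, gt, PARAMS) == 1.0).all()

    def test_fully_heterozygous_chromosome_scores_zero(self):
        pos = np.arange(1, 101) * 1000
        gt = np.ones(100, dtype=np.int8)
        assert (score_snps(pos, gt, PARAMS) == 0.0).all()

    def test_matches_enumeration_oracle_with_one_het(self):
        pos = np.arange(1, 101) * 500
        gt = np.zeros(100, dtype=np.int8)
        gt[50] = HET
        np.testing.assert_array_equal(score_snps(pos, gt, PARAMS), oracle_scores(pos, gt, PARAMS))

    def test_unsorted_positions_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            score_snps(np.array([10, 5]), np.array([0, 0]), PARAMS)


def test_segment_calls_equal_enumeration_oracle_on_random_instances():
    rng = np.random.default_rng(90)
    params = dataclasses.replace(PARAMS, min_length_bp=10_000, min_snps_per_segment=5)
    for _ in range(50):
        pos, gt = _random_instance(rng)
        assert call_segments(pos, gt, params) == oracle_segments(pos, gt, params)


def test_no_eligible_snp_gives_no_segment():
    pos = np.arange(1, 201) * 1000
    gt = np.ones(200, dtype=np.int8)  # all het
    assert call_segments(pos, gt, PARAMS) == []


def test_planted_two_mb_tract_recovered_with_high_jaccard():
    cfg = SimConfig(
        n_samples=1,
        chromosomes=(("chr1", 10_000_000),),
        target_froh=0.2,
        roh_length_dist=("fixed", {"length_bp": 2_000_000}),
        seed=21,
    )
    table, truth = simulate_cohort(cfg)
    segments = scan_individual(table, "S01")
    (tract,) = truth.roh_tracts["S01"]
    _, t_start, t_end = tract
    hits = [s for s in segments if s.start <= t_end and s.end >= t_start]
    assert len(hits) == 1
    seg = hits[0]
    inter = min(seg.end, t_end) - max(seg.start, t_start) + 1
    union = max(seg.end, t_end) - min(seg.start, t_start) + 1
    assert inter / union >= 0.9


def test_planted_tract_below_min_length_is_not_called():
    cfg = SimConfig(
        n_samples=1,
        chromosomes=(("chr1", 5_000_000),),
        target_froh=0.01,
        roh_length_dist=("fixed", {"length_bp": 50_000}),
        seed=22,
    )
    table, truth = simulate_cohort(cfg)
    assert truth.roh_tracts["S01"]  # tracts were planted
    assert scan_individual(table, "S01") == []


def test_boundary_error_within_a_window_span():
    # tracts >= 5x min length: recovered boundaries within ~one 20-SNP window
    cfg = SimConfig(
        n_samples=2,
        chromosomes=(("chr1", 20_000_000),),
        target_froh=0.15,
        roh_length_dist=("fixed", {"length_bp": 1_500_000}),
        seed=23,
    )
    table, truth = simulate_cohort(cfg)
    window_bp = PARAMS.window_snps / cfg.snp_density  # ~20 kb expected window span
    for s in ("S01", "S02"):
        segments = scan_individual(table, s)
        for _, t_start, t_end in truth.roh_tracts[s]:
            overlapping = [g for g in segments if g.start <= t_end and g.end >= t_start]
            assert overlapping
            start = min(g.start for g in overlapping)
            end = max(g.end for g in overlapping)
            assert abs(start - t_start) <= 1.5 * window_bp
            assert abs(end - t_end) <= 1.5 * window_bp


def test_raising_het_tolerance_never_decreases_roh_bp():
    cfg = SimConfig(n_samples=1, chromosomes=(("chr1", 10_000_000),), target_froh=0.4, seed=24)
    table, _ = simulate_cohort(cfg)
    totals = []
    for max_het in (0, 1, 2, 3):
        params = dataclasses.replace(PARAMS, max_het_per_window=max_het)
        totals.append(sum(s.length for s in scan_individual(table, "S01", params)))
    assert totals == sorted(totals)


class TestFroh:
    def test_no_segments_is_zero(self):
        s = froh([], 10_000_000)
        assert s.f_roh == 0.0

    def test_five_mb_segment_on_ten_mb_genome(self):
        seg = RohSegment("chr1", 1, 5_000_000, n_snps=5000, n_het=0)
        s = froh([seg], 10_000_000)
        assert s.f_roh_pct == pytest.approx(50.0)
        assert s.f_roh_long_pct == pytest.approx(50.0)

    def test_partition_is_exact(self):
        segs = [
            RohSegment("chr1", 1, 400_000, 400, 0),
            RohSegment("chr1", 1_000_001, 2_500_000, 1500, 1),
            RohSegment("chr2", 1, 150_000, 150, 0),
        ]
        s = froh(segs, 50_000_000)
        assert s.f_roh_short + s.f_roh_long == pytest.approx(s.f_roh, abs=0)
        assert 0 <= s.f_roh_long <= s.f_roh <= 1

    def test_overlapping_segments_are_merged(self):
        segs = [RohSegment("chr1", 1, 200_000, 200, 0), RohSegment("chr1", 100_000, 300_000, 200, 0)]
        s = froh(segs, 1_000_000)
        assert s.f_roh == pytest.approx(0.3)

    @pytest.mark.parametrize("target", [0.3, 0.5, 0.7])
    def test_cohort_recovery_of_planted_froh(self, target):
        cfg = SimConfig(n_samples=4, chromosomes=(("chr1", 15_000_000),), target_froh=target, seed=31)
        table, truth = simulate_cohort(cfg)
        df, _ = cohort_froh(table)
        est = df["f_roh_pct"].mean() / 100.0
        assert est == pytest.approx(target, abs=0.05)


class TestGenerationDating:
    def test_one_centimorgan_is_fifty_generations(self):
        assert generations_from_length(1.0) == 50.0

    def test_fifty_centimorgans_is_one_generation(self):
        assert generations_from_length(50.0) == 1.0

    def test_half_centimorgan_is_one_hundred_generations(self):
        assert generations_from_length(0.5) == 100.0

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            generations_from_length(0.0)


class TestOverlapFractions:
    SEGMENTS = [
        RohSegment("chr1", 100_000, 600_000, 500, 0),  # short
        RohSegment("chr1", 2_000_000, 3_500_000, 1500, 1),  # long
        RohSegment("chr2", 1, 200_000, 200, 0),  # short
    ]

    def test_no_segments_puts_everything_outside(self):
        f = overlap_fractions([("chr1", 5)], [])
        assert f == {"short": 0.0, "long": 0.0, "outside": 1.0}

    def test_all_sites_inside_one_long_segment(self):
        sites = [("chr1", 2_000_000), ("chr1", 2_500_000), ("chr1", 3_500_000)]
        f = overlap_fractions(sites, self.SEGMENTS)
        assert f["long"] == 1.0

    def test_hand_placed_sites_match_interval_membership(self):
        # brute-force membership over 20 hand-placed sites
        sites = (
            [("chr1", p) for p in (50_000, 100_000, 300_000, 600_000, 600_001)]
            + [("chr1", p) for p in (1_999_999, 2_000_000, 3_000_000, 3_500_000, 3_500_001)]
            + [("chr2", p) for p in (1, 100, 200_000, 200_001, 999_999)]
            + [("chr3", p) for p in (1, 2, 3, 4, 5)]
        )
        f = overlap_fractions(sites, self.SEGMENTS)
        assert f["short"] == pytest.approx(6 / 20)  # 3 in chr1 short + 3 in chr2 short
        assert f["long"] == pytest.approx(3 / 20)
        assert f["outside"] == pytest.approx(11 / 20)
        assert f["short"] + f["long"] + f["outside"] == pytest.approx(1.0)
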