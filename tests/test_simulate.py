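"""Generator tests: determinism, planted structure, HWE, relationships."""

import numpy as np
import pytest

from conskit import (
    SimConfig,
    count_ibs_states,
    kinship_coefficient,
    plant_relationship,
    read_vcf,
    simulate_cohort,
    write_vcf,
)
from conskit.io import HET, HOM_ALT, HOM_REF
from conskit.simulate import ConfigError


def test_identical_seed_gives_byte_identical_vcf(tmp_path):
    cfg = SimConfig(n_samples=3, chromosomes=(("chr1", 1_000_000),), target_froh=0.3, seed=42)
    for run in ("a", "b"):
        table, _ = simulate_cohort(cfg)
        write_vcf(table, tmp_path / f"{run}.vcf")
    assert (tmp_path / "a.vcf").read_bytes() == (tmp_path / "b.vcf").read_bytes()


def test_vcf_roundtrip_reproduces_genotype_table(tmp_path):
    cfg = SimConfig(
        n_samples=4,
        chromosomes=(("chr1", 500_000), ("chr2", 300_000)),
        n_outgroups=1,
        effect_counts={"LOF": 5, "synonymous": 10},
        derived_hom_frac={"LOF": 0.2, "synonymous": 0.3},
        seed=9,
    )
    table, _ = simulate_cohort(cfg)
    write_vcf(table, tmp_path / "c.vcf")
    back = read_vcf(tmp_path / "c.vcf")
    assert back.samples == table.samples
    assert np.array_equal(back.gt, table.gt)
    assert np.array_equal(back.pos, table.pos)
    assert np.array_equal(back.dp, table.dp)
    assert list(back.ref) == list(table.ref)
    assert list(back.alt) == list(table.alt)
    np.testing.assert_allclose(
        back.info["QD"].to_numpy(), table.info["QD"].to_numpy(), rtol=1e-6
    )


def test_planted_fraction_is_exact():
    # target 0.5 of a 10-Mb chromosome -> exactly 5,000,000 bp of tract
    cfg = SimConfig(n_samples=2, chromosomes=(("chr1", 10_000_000),), target_froh=0.5, seed=1)
    _, truth = simulate_cohort(cfg)
    for s, tracts in truth.roh_tracts.items():
        total = sum(end - start + 1 for _, start, end in tracts)
        assert total == 5_000_000
        assert truth.froh_true[s] == 0.5
        # non-overlapping per individual
        by_chrom = sorted(tracts)
        for (c1, _, e1), (c2, s2, _) in zip(by_chrom, by_chrom[1:]):
            assert c1 != c2 or s2 > e1


def test_zero_theta_gives_all_homozygous_genotypes():
    cfg = SimConfig(n_samples=3, chromosomes=(("chr1", 200_000),), het_rate_theta=0.0, seed=2)
    table, _ = simulate_cohort(cfg)
    assert not np.any(table.gt == HET)


def test_realized_het_rate_matches_theta_within_three_se():
    # binomial oracle: the generator draws int(1e-3 * 1e7) = 10,000 sites with
    # per-site het probability 2p(1-p); theta/density = 0.5 forces p = 0.5.
    cfg = SimConfig(
        n_samples=1,
        chromosomes=(("chr1", 10_000_000),),
        snp_density=1e-3,
        het_rate_theta=5e-4,
        seed=1,
    )
    table, _ = simulate_cohort(cfg)
    n_sites = table.n_sites
    n_het = int(np.sum(table.gt == HET))
    expected = 0.5 * n_sites
    se = np.sqrt(n_sites * 0.5 * 0.5)
    assert abs(n_het - expected) <= 3 * se
    genome_rate = n_het / 10_000_000
    assert genome_rate == pytest.approx(5e-4, rel=3 * se / expected)


def test_hwe_holds_outside_tracts():
    # aggregate over >=1e4 sites: realized het fraction at sites binned by p
    # matches 2p(1-p) within binomial error
    cfg = SimConfig(n_samples=10, chromosomes=(("chr1", 20_000_000),), seed=5)
    table, truth = simulate_cohort(cfg)
    p = truth.site_freq_alt
    het_frac = np.mean(table.gt == HET, axis=1)
    for lo, hi in [(0.0, 0.2), (0.2, 0.4), (0.4, 0.6), (0.6, 0.8), (0.8, 1.0)]:
        sel = (p >= lo) & (p < hi)
        if sel.sum() < 500:
            continue
        expected = np.mean(2 * p[sel] * (1 - p[sel]))
        n_draws = sel.sum() * 10
        se = np.sqrt(expected * (1 - expected) / n_draws)
        assert abs(np.mean(het_frac[sel]) - expected) < 4 * se


def test_infeasible_theta_raises_named_error():
    with pytest.raises(ConfigError, match="het_rate_theta"):
        SimConfig(snp_density=1e-3, het_rate_theta=6e-4)


def test_infeasible_froh_raises_named_error():
    with pytest.raises(ConfigError, match="target_froh"):
        SimConfig(n_samples=1, chromosomes=(("chr1", 200_000),), target_froh=1.2)


def test_saturating_froh_is_placed_exactly():
    # tracts longer than the free gaps are trimmed; accounting stays exact
    cfg = SimConfig(
        n_samples=1,
        chromosomes=(("chr1", 200_000),),
        target_froh=0.9,
        roh_length_dist=("fixed", {"length_bp": 150_000}),
        snp_density=2e-3,
        het_rate_theta=5e-4,
        seed=3,
    )
    _, truth = simulate_cohort(cfg)
    assert truth.froh_true["S01"] == pytest.approx(0.9, abs=1e-9)


class TestPlantRelationship:
    def test_duplicate_is_a_copy(self):
        rng = np.random.default_rng(0)
        p = rng.beta(0.5, 0.5, 1000)
        g1, g2 = plant_relationship(p, "duplicate", seed=1)
        assert np.array_equal(g1, g2)

    def test_parent_offspring_has_zero_ibs0(self):
        rng = np.random.default_rng(0)
        p = rng.beta(0.5, 0.5, 20_000)
        g1, g2 = plant_relationship(p, "parent_offspring", seed=2)
        opposite = ((g1 == HOM_REF) & (g2 == HOM_ALT)) | ((g1 == HOM_ALT) & (g2 == HOM_REF))
        assert int(opposite.sum()) == 0

    def test_full_sib_kinship_near_quarter(self, kinship_freqs):
        g1, g2 = plant_relationship(kinship_freqs, "full_sib", seed=3)
        phi = kinship_coefficient(count_ibs_states(g1, g2))
        assert phi == pytest.approx(0.25, abs=0.03)

    def test_unknown_relation_rejected(self):
        with pytest.raises(ValueError, match="relation"):
            plant_relationship(np.array([0.5]), "cousins")


class TestInjectEffects:
    def test_zero_count_class_stays_zero(self):
        cfg = SimConfig(
            n_samples=5,
            chromosomes=(("chr1", 1_000_000),),
            n_outgroups=1,
            effect_counts={"LOF": 0, "missense": 0, "synonymous": 100},
            derived_hom_frac={"synonymous": 0.3},
            seed=4,
        )
        _, truth = simulate_cohort(cfg)
        assert (truth.planted_hom_derived["LOF"] == 0).all()
        assert (truth.load_counts["n_hom_derived_lof"] == 0).all()

    def test_planted_hom_derived_has_binomial_mean(self):
        # 40 LOF sites at derived_hom_frac 0.5 -> per-individual expectation 20
        cfg = SimConfig(
            n_samples=30,
            chromosomes=(("chr1", 2_000_000),),
            n_outgroups=1,
            effect_counts={"LOF": 40},
            derived_hom_frac={"LOF": 0.5},
            seed=11,
        )
        _, truth = simulate_cohort(cfg)
        counts = truth.planted_hom_derived["LOF"].to_numpy()
        # mean over 30 individuals of Bin(40, 0.5): SE = sqrt(40*0.25/30)
        assert np.mean(counts) == pytest.approx(20.0, abs=4 * np.sqrt(10.0 / 30.0))

    def test_too_many_effect_sites_rejected(self):
        with pytest.raises(ConfigError, match="effect sites"):
            simulate_cohort(
                SimConfig(
                    n_samples=2,
                    chromosomes=(("chr1", 100_000),),
                    effect_counts={"synonymous": 10_000},
                    seed=1,
                )
            )
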