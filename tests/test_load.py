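"""Effect classification, polarization and load-count tests."""

import numpy as np
import pandas as pd
import pytest

from conskit import (
    candidate_gene_screen,
    classify_effects,
    individual_load,
    polarize_sites,
    read_vcf,
    simulate_cohort,
    write_vcf,
)
from conskit import SimConfig
from conskit.io import GenotypeTable


def _table(gt_rows, samples, ann=None, pos=None):
    gt = np.asarray(gt_rows, dtype=np.int8).T
    n = gt.shape[0]
    info = pd.DataFrame(index=range(n))
    if ann is not None:
        info["ANN"] = ann
    return GenotypeTable(
        samples=list(samples),
        chrom=np.full(n, "chr1", dtype=object),
        pos=np.asarray(pos if pos is not None else np.arange(1, n + 1) * 100, dtype=np.int64),
        ref=np.full(n, "A", dtype=object),
        alt=np.full(n, "G", dtype=object),
        qual=np.full(n, 100.0),
        info=info,
        gt=gt,
        dp=np.full((n, len(samples)), 20, dtype=np.int32),
        chrom_lengths={"chr1": 1_000_000},
    )


class TestClassifyEffects:
    @pytest.mark.parametrize(
        "term,expected",
        [
            ("stop_gained", "LOF"),
            ("frameshift_variant", "LOF"),
            ("synonymous_variant", "synonymous"),
            ("missense_variant", "missense"),
            ("missense_variant&splice_donor_variant", "LOF"),  # severity precedence
            ("intron_variant", "other"),
        ],
    )
    def test_term_mapping_and_precedence(self, term, expected):
        table = _table([[0], [0]], ["A", "B"], ann=[f"G|{term}|HIGH|GENE1|GENE1"])
        eff = classify_effects(table)
        assert eff["effect_class"].iloc[0] == expected
        assert eff["gene_id"].iloc[0] == "GENE1"

    def test_unparseable_ann_is_other(self):
        table = _table([[0], [0]], ["A", "B"], ann=["garbage-without-pipes"])
        eff = classify_effects(table)
        assert eff["effect_class"].iloc[0] == "other"

    def test_sidecar_tsv_takes_precedence(self):
        table = _table([[0], [0]], ["A", "B"], ann=["G|synonymous_variant|LOW|GENE1|GENE1"])
        sidecar = pd.DataFrame(
            {"chrom": ["chr1"], "pos": [100], "gene_id": ["GENE9"], "effect_class": ["LOF"]}
        )
        eff = classify_effects(table, sidecar)
        assert eff["effect_class"].iloc[0] == "LOF"
        assert eff["gene_id"].iloc[0] == "GENE9"


class TestPolarizeSites:
    def _cohort(self, species_gt, outgroup_gt):
        gt_rows = species_gt + outgroup_gt
        samples = [f"S{i}" for i in range(len(species_gt))] + [f"OG{i}" for i in range(len(outgroup_gt))]
        return _table(gt_rows, samples), samples

    def test_concordant_species_major_and_outgroup(self):
        # species AF(ref)=0.9 (one het in five), outgroup hom_ref
        table, samples = self._cohort([[0], [0], [0], [0], [1]], [[0]])
        pol = polarize_sites(table, {s: "sp" for s in samples[:5]}, ["OG0"])["sp"]
        assert pol["status"].iloc[0] == "polarized"
        assert pol["ancestral"].iloc[0] == "A"
        assert pol["derived"].iloc[0] == "G"

    def test_outgroup_contradicting_species_major_is_unpolarized(self):
        table, samples = self._cohort([[0], [0], [0], [0], [1]], [[2]])
        pol = polarize_sites(table, {s: "sp" for s in samples[:5]}, ["OG0"])["sp"]
        assert pol["status"].iloc[0] == "unpolarized"

    def test_exact_half_frequency_is_unpolarized(self):
        # AF(ref) = 0.5 exactly: "above 0.5" is strict
        table, samples = self._cohort([[0], [2]], [[0]])
        pol = polarize_sites(table, {s: "sp" for s in samples[:2]}, ["OG0"])["sp"]
        assert pol["status"].iloc[0] == "unpolarized"

    def test_no_outgroup_unpolarizes_everything(self):
        table, samples = self._cohort([[0], [0], [0], [1]], [])
        pol = polarize_sites(table, {s: "sp" for s in samples}, [])["sp"]
        assert (pol["status"] == "unpolarized").all()


class TestIndividualLoad:
    def test_hom_ancestral_everywhere_counts_zero(self):
        cfg = SimConfig(
            n_samples=5,
            chromosomes=(("chr1", 1_000_000),),
            n_outgroups=2,
            effect_counts={"LOF": 10, "synonymous": 20},
            derived_hom_frac={},  # nobody homozygous-derived
            effect_het_rate=0.0,
            seed=3,
        )
        table, _ = simulate_cohort(cfg)
        eff = classify_effects(table)
        pol = polarize_sites(table, {s: "SpA" for s in cfg.sample_names()}, cfg.outgroup_names())
        loads = individual_load(table, eff, pol, {s: "SpA" for s in cfg.sample_names()}, cfg.outgroup_names())
        assert (loads["n_hom_derived_lof"] == 0).all()
        assert (loads["n_hom_derived_synonymous"] == 0).all()

    def test_hand_fixture_counts_and_ratio(self):
        # one individual: 4 hom-derived LOF in 3 genes, 100 hom-derived synonymous
        n_lof, n_syn = 4, 100
        genes = ["GENE1", "GENE1", "GENE2", "GENE3"]
        ann = [f"G|stop_gained|HIGH|{g}|{g}" for g in genes] + [
            "G|synonymous_variant|LOW|GENEs|GENEs" for _ in range(n_syn)
        ]
        # individual hom-alt (derived) everywhere; 4 reference peers keep AF(ref)>0.5
        focal = [2] * (n_lof + n_syn)
        peers = [[0] * (n_lof + n_syn) for _ in range(4)]
        table = _table([focal] + peers + [[0] * (n_lof + n_syn)], ["X", "P1", "P2", "P3", "P4", "OG"], ann=ann)
        species_of = {s: "sp" for s in ["X", "P1", "P2", "P3", "P4"]}
        eff = classify_effects(table)
        pol = polarize_sites(table, species_of, ["OG"])
        loads = individual_load(table, eff, pol, species_of, ["OG"]).set_index("sample")
        assert loads.loc["X", "n_hom_derived_lof"] == 4
        assert loads.loc["X", "n_genes_hom_lof"] == 3
        assert loads.loc["X", "ratio_lof_syn"] == pytest.approx(0.04)

    def test_zero_synonymous_denominator_is_nan(self):
        ann = ["G|stop_gained|HIGH|GENE1|GENE1"]
        table = _table([[2], [0], [0], [0]], ["X", "P1", "P2", "OG"], ann=ann)
        species_of = {"X": "sp", "P1": "sp", "P2": "sp"}
        eff = classify_effects(table)
        pol = polarize_sites(table, species_of, ["OG"])
        loads = individual_load(table, eff, pol, species_of, ["OG"]).set_index("sample")
        assert np.isnan(loads.loc["X", "ratio_lof_syn"])

    def test_matches_generator_truth_exactly(self, load_cohort):
        cfg, table, truth = load_cohort
        species_of = dict(zip(cfg.sample_names(), cfg.species_labels()))
        eff = classify_effects(table)
        pol = polarize_sites(table, species_of, cfg.outgroup_names())
        loads = individual_load(table, eff, pol, species_of, cfg.outgroup_names()).set_index("sample")
        for col in ("n_hom_derived_lof", "n_genes_hom_lof", "n_hom_derived_missense", "n_hom_derived_synonymous"):
            assert loads[col].to_dict() == truth.load_counts[col].to_dict(), col


class TestCandidateGeneScreen:
    def test_no_lof_sites_gives_empty_lists(self):
        table = _table([[0], [0], [0]], ["A", "B", "OG"], ann=["G|synonymous_variant|LOW|GENE1|GENE1"])
        species_of = {"A": "sp", "B": "sp"}
        eff = classify_effects(table)
        pol = polarize_sites(table, species_of, ["OG"])
        screen = candidate_gene_screen(table, eff, pol, species_of, outgroup_samples=["OG"])
        assert screen.get("sp", []) == []

    def test_group_private_gene_appears_only_in_that_group(self):
        # two populations of one species; only pop1's member is hom-derived
        ann = ["G|stop_gained|HIGH|GENEZ|GENEZ"]
        table = _table([[2], [0], [0], [0], [0]], ["A", "B", "C", "D", "OG"], ann=ann)
        species_of = {s: "sp" for s in "ABCD"}
        groups = {"A": "pop1", "B": "pop1", "C": "pop2", "D": "pop2"}
        eff = classify_effects(table)
        pol = polarize_sites(table, species_of, ["OG"])
        screen = candidate_gene_screen(table, eff, pol, groups, species_of=species_of, outgroup_samples=["OG"])
        assert screen.get("pop1") == ["GENEZ"]
        assert screen.get("pop2", []) == []
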