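"""Simulate two species cohorts with planted truth.

SpA emulates a larger, more diverse species (heterozygous-call rate
6.9e-4/bp outside ROH, F_ROH 0.5) carrying two consanguineous plants — a
parent-offspring pair and a technical duplicate — that the kinship stage
must find.  SpB emulates a small, highly inbred species (3.4e-4/bp outside
ROH, F_ROH 0.75).  Both carry
effect-annotated sites with known homozygous-derived load, two outgroup
genomes, 3% of sites with a deliberately corrupted QC annotation, and a
synthetic CpG-island exclusion BED.
"""

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).parent))
from common import SCRATCH, cohort_dir

from conskit import SimConfig
from conskit.simulate import write_cohort

CHROMS = (("chr1", 10_000_000), ("chr2", 8_000_000))

CONFIGS = {
    "SpA": SimConfig(
        n_samples=10,
        chromosomes=CHROMS,
        snp_density=2e-3,
        het_rate_theta=6.9e-4,
        target_froh=0.50,
        n_outgroups=2,
        effect_counts={"LOF": 60, "missense": 120, "synonymous": 200},
        derived_hom_frac={"LOF": 0.15, "missense": 0.20, "synonymous": 0.30},
        relationships=(("S09", "S10", "parent_offspring"), ("S07", "S08", "duplicate")),
        species=("SpA",) * 10,
        corrupt_qc_fraction=0.03,
        seed=1001,
    ),
    "SpB": SimConfig(
        n_samples=8,
        chromosomes=CHROMS,
        snp_density=1e-3,
        het_rate_theta=3.4e-4,
        target_froh=0.75,
        n_outgroups=2,
        effect_counts={"LOF": 60, "missense": 120, "synonymous": 200},
        derived_hom_frac={"LOF": 0.25, "missense": 0.30, "synonymous": 0.30},
        species=("SpB",) * 8,
        corrupt_qc_fraction=0.03,
        seed=1002,
    ),
}


def write_cpg_bed(path, rng):
    """~15 synthetic CpG-island-like intervals (2-5 kb) per chromosome."""
    with open(path, "w") as fh:
        for chrom, length in CHROMS:
            starts = np.sort(rng.choice(length - 5000, size=15, replace=False))
            for s in starts:
                fh.write(f"{chrom}\t{s}\t{s + int(rng.integers(2000, 5001))}\n")


def main():
    SCRATCH.mkdir(parents=True, exist_ok=True)
    write_cpg_bed(SCRATCH / "cpg_islands.bed", np.random.default_rng(555))
    for species, cfg in CONFIGS.items():
        table, truth = write_cohort(cfg, cohort_dir(species))
        print(
            f"{species}: {table.n_sites} sites x {table.n_samples} samples "
            f"({cfg.n_outgroups} outgroups), planted F_ROH "
            f"{np.mean([v for v in truth.froh_true.values() if v > 0]):.3f} "
            f"in non-related individuals, {int((truth.effect_class != '').sum())} effect sites"
        )
    print(f"cohorts written under {SCRATCH}")


if __name__ == "__main__":
    main()
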