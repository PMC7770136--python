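from pathlib import Path

import numpy as np
import pytest

from conskit import SimConfig, simulate_cohort

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def toy_vcf() -> Path:
    return DATA / "filter_toy.vcf"


@pytest.fixture(scope="session")
def toy_bed() -> Path:
    return DATA / "cpg_toy.bed"


@pytest.fixture(scope="session")
def load_cohort():
    """20-sample cohort with effect sites, outgroups and known load truth."""
    cfg = SimConfig(
        n_samples=20,
        chromosomes=(("chr1", 10_000_000),),
        n_outgroups=2,
        effect_counts={"LOF": 60, "missense": 120, "synonymous": 200},
        derived_hom_frac={"LOF": 0.2, "missense": 0.25, "synonymous": 0.3},
        seed=7,
    )
    table, truth = simulate_cohort(cfg)
    return cfg, table, truth


@pytest.fixture(scope="session")
def kinship_freqs() -> np.ndarray:
    """50k-site allele-frequency vector from the generator's default spectrum."""
    rng = np.random.default_rng(202)
    return rng.beta(3.0714, 3.0714, 50_000)
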