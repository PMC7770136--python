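"""Shared paths and loaders for the numbered analysis scripts.

The pipeline lays its large intermediates (VCFs, per-species scratch) under
``scratch/pipeline`` and its result tables under ``results/``; scripts run
in order from the repository root:

    python analysis/01_simulate_cohorts.py
    python analysis/02_filter_variants.py
    ...
"""

from pathlib import Path

import pandas as pd

from conskit.io import read_chrom_lengths, read_sample_metadata, read_vcf

REPO = Path(__file__).resolve().parents[1]
SCRATCH = REPO / "scratch" / "pipeline"
RESULTS = REPO / "results"

SPECIES = ("SpA", "SpB")


def cohort_dir(species: str) -> Path:
    return SCRATCH / species


def load_cohort(species: str, filtered: bool = False):
    """(table, metadata, chrom_lengths) for one species cohort."""
    d = cohort_dir(species)
    lengths = read_chrom_lengths(d / "chrom_lengths.tsv")
    vcf = d / ("filtered.vcf" if filtered else "cohort.vcf")
    table = read_vcf(vcf, chrom_lengths=lengths)
    meta = read_sample_metadata(d / "samples.tsv")
    return table, meta, lengths


def retained_samples(species: str) -> list[str]:
    return (cohort_dir(species) / "retained.txt").read_text().split()


def write_table(df: pd.DataFrame, name: str) -> Path:
    RESULTS.mkdir(parents=True, exist_ok=True)
    path = RESULTS / name
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path
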