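"""Apply the hard-filter cascade to both cohorts.

Removes sites failing the GATK-style annotations (QD, FS, MQ,
ReadPosRankSum, SB), low QUAL, high missingness after DP masking, low
minor-allele frequency, and sites inside the synthetic CpG-island BED;
writes the filtered VCFs and a per-rule removal tally.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import SCRATCH, SPECIES, cohort_dir, load_cohort, write_table

from conskit import FilterConfig, apply_site_filters, write_vcf
from conskit.io import read_bed


def main():
    bed = tuple(read_bed(SCRATCH / "cpg_islands.bed"))
    rows = []
    for species in SPECIES:
        table, _, lengths = load_cohort(species)
        retained, tally = apply_site_filters(table, FilterConfig(excluded_regions=bed))
        write_vcf(retained, cohort_dir(species) / "filtered.vcf")
        rows.append({"species": species, "input_sites": table.n_sites, **tally})
        print(
            f"{species}: {table.n_sites} -> {tally['retained']} sites "
            f"({table.n_sites - tally['retained']} removed; "
            f"excluded_region {tally['excluded_region']}, QC rules "
            f"{sum(tally[r] for r in ('QD', 'FS', 'MQ', 'ReadPosRankSum', 'SB', 'QUAL'))}, "
            f"missingness {tally['missingness']}, MAF {tally['allele_frequency']})"
        )
    path = write_table(pd.DataFrame(rows), "filter_tally.tsv")
    print(f"tally written to {path}")


if __name__ == "__main__":
    main()
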