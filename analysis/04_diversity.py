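"""Windowed heterozygosity and pairwise mismatch on the pruned cohorts.

He is computed per individual in non-overlapping 100-kb windows as a
percentage of the window span, and pairwise mismatch as the windowed
dosage distance between individuals of the same species.
"""

import itertools
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import SPECIES, load_cohort, retained_samples, write_table

from conskit import make_windows, pairwise_mismatch, windowed_heterozygosity


def main():
    he_rows, mm_rows = [], []
    for species in SPECIES:
        table, _, lengths = load_cohort(species, filtered=True)
        kept = retained_samples(species)
        windows = make_windows(lengths)
        _, summary = windowed_heterozygosity(table, windows, samples=kept)
        summary.insert(0, "species", species)
        he_rows.append(summary)
        pair_means = []
        for a, b in itertools.combinations(kept, 2):
            _, mean = pairwise_mismatch(table, a, b, windows)
            pair_means.append(mean)
            mm_rows.append({"species": species, "sample_a": a, "sample_b": b, "mismatch_pct": mean})
        he = summary["he_mean_pct"]
        print(
            f"{species}: He {he.mean():.4f}% (range {he.min():.4f}-{he.max():.4f}%), "
            f"mean pairwise mismatch {pd.Series(pair_means).mean():.4f}% over {len(pair_means)} pairs"
        )
    write_table(pd.concat(he_rows, ignore_index=True), "heterozygosity_summary.tsv")
    write_table(pd.DataFrame(mm_rows), "pairwise_mismatch.tsv")


if __name__ == "__main__":
    main()
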