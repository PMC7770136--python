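"""Compare the two species on He, F_ROH and load with rank-sum tests.

Merges the per-individual metrics from the previous stages and reports
group means with sd and two-sided exact Wilcoxon rank-sum p-values.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import RESULTS, write_table

from conskit import summarize_groups


def main():
    he = pd.read_csv(RESULTS / "heterozygosity_summary.tsv", sep="\t")
    roh = pd.read_csv(RESULTS / "roh_summary.tsv", sep="\t")
    load = pd.read_csv(RESULTS / "load_summary.tsv", sep="\t")
    metrics = (
        he[["species", "sample", "he_mean_pct"]]
        .merge(roh[["species", "sample", "f_roh_pct", "f_roh_long_pct"]], on=["species", "sample"])
        .merge(load[["species", "sample", "ratio_lof_syn", "ratio_mis_syn"]], on=["species", "sample"])
    )
    summary, comparisons = summarize_groups(
        metrics.drop(columns=["sample"]),
        group_col="species",
        metric_cols=["he_mean_pct", "f_roh_pct", "f_roh_long_pct", "ratio_lof_syn", "ratio_mis_syn"],
    )
    write_table(summary, "group_summary.tsv")
    write_table(comparisons, "group_comparisons.tsv")
    print("group means (sd):")
    for _, r in summary.iterrows():
        print(f"    {r['group']:>4} {r['metric']:<16} {r['mean']:.4f} ({r['sd']:.4f}), n={r['n']}")
    print("pairwise rank-sum tests:")
    for _, r in comparisons.iterrows():
        flag = " *" if r["p_value"] < 0.05 else ""
        print(f"    {r['group_a']} vs {r['group_b']} on {r['metric']}: p = {r['p_value']:.4g}{flag}")


if __name__ == "__main__":
    main()
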