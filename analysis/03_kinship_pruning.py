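"""Estimate pairwise kinship and prune consanguineous individuals.

Computes the IBS-based robust kinship coefficient for every within-species
pair on the filtered SNP set and retains only individuals whose remaining
pairs all have phi < 0 (the non-consanguineous set).  SpA carries a planted
parent-offspring pair and a duplicate; both should lose one member.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import SPECIES, cohort_dir, load_cohort, write_table

from conskit import kinship_matrix, prune_related


def main():
    rows = []
    for species in SPECIES:
        table, meta, _ = load_cohort(species, filtered=True)
        ingroup = meta.loc[~meta["is_outgroup"], "sample"].tolist()
        phi, _ = kinship_matrix(table, ingroup)
        phi.to_csv(cohort_dir(species) / "kinship_matrix.tsv", sep="\t")
        retained = prune_related(phi, groups={s: species for s in ingroup})
        (cohort_dir(species) / "retained.txt").write_text("\n".join(retained) + "\n")
        removed = sorted(set(ingroup) - set(retained))
        close = [
            (a, b, phi.loc[a, b])
            for i, a in enumerate(ingroup)
            for b in ingroup[i + 1 :]
            if phi.loc[a, b] >= 0
        ]
        rows.extend(
            {"species": species, "sample_a": a, "sample_b": b, "phi": p} for a, b, p in close
        )
        print(f"{species}: {len(ingroup)} individuals, {len(close)} pair(s) with phi >= 0 -> removed {removed or 'none'}")
        for a, b, p in close:
            print(f"    {a}-{b}: phi = {p:.4f}")
    write_table(pd.DataFrame(rows, columns=["species", "sample_a", "sample_b", "phi"]), "kinship_close_pairs.tsv")


if __name__ == "__main__":
    main()
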