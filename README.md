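# conskit

Conservation-genomics analyses on diploid cohort VCFs: SNP hard
filtering, kinship-based removal of consanguineous individuals, windowed
heterozygosity and pairwise mismatch, runs-of-homozygosity (ROH) detection
with the genomic inbreeding coefficient F_ROH, and ancestral-polarized
genetic-load statistics — plus a synthetic cohort generator that plants
ground truth for every stage.

The package is aimed at studies of small, endangered populations, where a
handful of resequenced genomes must answer three questions: how much
diversity is left (He per 100-kb window), how inbred are the individuals
(F_ROH = Σ ROH length / genome length, with long ROH > 1 Mb indicating
recent inbreeding, datable via g = 100/(2·L_cM)), and how much realized
genetic load they carry (counts of homozygous-derived loss-of-function and
missense genotypes, polarized against outgroups, relative to synonymous
ones). Because such studies rarely come with truth, `conskit.simulate`
builds multi-sample VCF cohorts with known heterozygosity, planted
autozygous tracts of known total fraction, gamete-dropped relatives
(parent-offspring, full sibs, duplicates), annotated effect sites with
known ancestral alleles, and outgroup genomes — so every estimator here is
tested by recovering what was planted.

Core statistics, in the field's notation:

- kinship: phi = (N_het,het − 2·N_IBS0) / (N_het,i + N_het,j); duplicates
  0.5, first-degree pairs 0.25, unrelated 0; individuals are pruned until
  all remaining pairs have phi < 0.
- heterozygosity: He_w = 100 × (het calls in window) / span, window 100 kb.
- ROH: 20-SNP consensus windows (≤ 1 het, ≤ 50 missing), hit fraction
  ≥ 0.05, segments ≥ 100 kb, ≥ 25 SNPs, ≥ 1 SNP/10 kb.
- load: per individual, homozygous-derived counts per effect class at
  sites where one allele has within-species frequency > 0.5 and is
  homozygous in ≥ 1 outgroup.

## Worked example

```python
from conskit import (SimConfig, simulate_cohort, make_windows,
                     windowed_heterozygosity)
from conskit.roh import cohort_froh

cfg = SimConfig(n_samples=4, chromosomes=(("chr1", 10_000_000),),
                target_froh=0.5, seed=1)
table, truth = simulate_cohort(cfg)

_, he = windowed_heterozygosity(table, make_windows({"chr1": 10_000_000}))
print(he[["sample", "he_mean_pct"]].head(2).to_string(index=False))
df, _ = cohort_froh(table)
print(df.to_string(index=False))
```

prints

```
sample  he_mean_pct
   S01      0.02219
   S02      0.02131
sample  f_roh_pct  f_roh_long_pct  n_segments
   S01   50.29596        10.31159           7
   S02   50.30147        34.65782           5
   S03   50.14577        31.37459           4
   S04   50.45967        24.46455           6
```

Each individual was simulated with half its 10-Mb genome in autozygous
tracts: the detected F_ROH comes out at 50.1–50.5% against the planted
50%, much of it in long (> 1 Mb) segments, and the windowed He (~0.022%)
is the planted outside-ROH het rate (4.3e-4/bp = 0.043%) halved by the
tracts — exactly the coupling between inbreeding and observed diversity
the statistics are designed to expose.

## The analysis

`analysis/` holds numbered drivers that run the whole pipeline on two
simulated species cohorts (a diverse, moderately inbred SpA with planted
relatives; a depauperate, highly inbred SpB), writing tables under
`results/` and large intermediates under `scratch/`:

```
python analysis/01_simulate_cohorts.py   # cohorts + truth + CpG BED
python analysis/02_filter_variants.py    # hard-filter cascade, tally
python analysis/03_kinship_pruning.py    # phi matrix, pruning
python analysis/04_diversity.py          # windowed He, pairwise mismatch
python analysis/05_roh_inbreeding.py     # ROH, F_ROH vs truth, dating
python analysis/06_genetic_load.py       # polarized load, gene screen, ROH overlap
python analysis/07_group_report.py       # group means, rank-sum tests
```

On these cohorts the pipeline removes one member of each planted related
pair (phi = 0.49 for the duplicate, 0.25 for parent-offspring), recovers
F_ROH within ~0.5 percentage points of the planted values (37.6% vs 37.5%
and 75.6% vs 75.0% cohort means), dates all long-ROH segments to < 50
generations, and finds He and F_ROH significantly different between the
species (exact rank-sum p ≈ 9e-4) while the LOF/synonymous load ratios are
not — the decoupling of recent inbreeding from realized load that
motivates this kind of analysis.

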