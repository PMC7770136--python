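# Methods

conskit implements the post-variant-calling stages of a small-population
conservation-genomics study — hard filtering, kinship pruning, windowed
diversity, runs of homozygosity (ROH), and ancestral-polarized genetic
load — together with a synthetic diploid cohort generator that plants
known truth for every stage. This note records the models, the parameter
choices that matter, and the places where a genuinely open design decision
was made.

## The synthetic cohort generator

The generator emulates the statistical structure of a multi-sample VCF
after joint genotype calling, not the sequencing process: there are no
reads, no genotype-likelihood model, and no linkage disequilibrium beyond
the planted autozygous tracts.

**Sites and frequencies.** Each chromosome receives
`round(snp_density * length)` distinct segregating positions, uniform over
the chromosome. Per-site ALT frequencies are drawn from a symmetric
Beta(a, a). Because E[2p(1-p)] = a/(2a+1) under this family, `a` is solved
from the requested per-bp heterozygous-call rate: with
r = `het_rate_theta` / `snp_density`, a = r/(1-2r). r = 1/4 recovers the
classic U-shaped Beta(0.5, 0.5); r = 1/2 degenerates to p = 0.5 at every
site (the Hardy–Weinberg maximum); r > 1/2 is rejected as infeasible.
Genotypes follow exact HWE at each site, so the expected heterozygous-call
rate per bp equals `het_rate_theta` exactly while the per-site HWE
invariant remains testable.

Defaults are `snp_density = 1e-3`/bp and `het_rate_theta = 4.3e-4`/bp.
The heterozygosity matches the scale observed in endangered primates
(He ~ 0.03–0.07%); the density is chosen so that the ratio r = 0.43 makes
the ROH scan sharply discriminative: a 20-SNP window outside a tract then
contains ~8.6 heterozygous calls in expectation and passes the ≤1-het rule
with probability ~2e-4, while windows inside tracts always pass. At low r
(≲0.25) background windows pass so often that consensus-scan ROH calling
is not meaningful at any parameterization — a property of the method, not
of this implementation.

**Autozygous tracts.** Per individual, tract lengths are drawn from a
configurable distribution (default log-normal, median 800 kb,
sigma_log 0.6 — a mixture of short and >1 Mb tracts like real inbred
genomes) and placed without overlap until the planted total equals
`round(target_froh * genome_length)` exactly, trimming the final draw.
Placement is uniform over all positions that keep a tract inside a free
gap, with gaps weighted by their number of valid offsets; a draw longer
than every remaining gap is trimmed to the largest gap. Plain rejection
sampling was rejected because it saturates near target_froh ≈ 0.6,
whereas the gap-weighted scheme realizes any target in [0, 1] with exact
accounting. Inside tracts all genotypes are homozygous (the allele is
redrawn from the site frequency), with an optional error rate for planting
stray heterozygotes.

**Relationships.** Related pairs are built by gamete dropping from the
same frequency vector: a parent transmits one of its two alleles at every
site (one allele IBD everywhere), full sibs receive one gamete from each
of two shared parents (0/1/2 IBD with probability 1/4, 1/2, 1/4),
duplicates are copies. Samples in a planted relationship receive no
autozygous tracts — forcing homozygosity on top of gamete-dropped
genotypes would corrupt the pedigree expectation — and their true F_ROH
is recorded as 0.

**Effect sites and outgroups.** A requested number of sites per class
(LOF, missense, synonymous) receives SnpEff-style `ANN` strings and gene
identifiers (consecutive blocks of 5 effect sites per gene, configurable).
The ancestral allele at effect sites is REF; each ingroup individual is
homozygous-derived with probability `derived_hom_frac[class]`,
heterozygous at a small fixed rate (0.1, suppressed inside that
individual's tracts so tracts stay homozygous), otherwise
homozygous-ancestral. Outgroup genomes are homozygous-ancestral with
probability `outgroup_ancestral_fidelity` (default 0.99) and
homozygous-derived otherwise. At neutral sites the ancestral allele is
the major allele of the drawn spectrum.

The truth tables carry two load accountings. `planted_hom_derived` is the
raw Bernoulli outcome per individual and class.  `load_counts` applies
the polarization rule exactly as realized in the emitted genotypes —
within-species ancestral frequency > 0.5 and at least one outgroup
homozygous for that allele, in whichever orientation the rule actually
fires — and is the zero-tolerance oracle for the load stage. The two
differ when drift pushes a derived allele past 0.5 or an unfaithful
outgroup breaks the homozygosity condition. A related, deliberate
property: conditioning on the focal individual being homozygous-derived
shifts the site's derived frequency upward, so classes planted at high
`derived_hom_frac` lose proportionally more sites to polarization failure;
per-individual ratios therefore sit above the naive planted expectation
even though every count matches the rule-aware truth exactly.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: linked variation and realistic LD decay,
recombination-rate variation (the 1 Mb = 1 cM conversion is exact here by
construction), genotype-likelihood uncertainty and depth-correlated
errors, population structure within a species, selection, and reference
bias. Recovery results on this generator demonstrate the correctness of
the estimators under their own assumptions, not robustness to those
complications.

## Hard filtering

A site is removed when any of these fires: QD < 2.0, FS > 60.0,
MQ < 40.0, ReadPosRankSum < −8.0, SB ≥ −1.0, QUAL < 30, missingness
> 20%, minor-allele frequency < 5%, more than one ALT allele, a
non-autosomal chromosome, or overlap with an excluded-region BED interval
(CpG islands in the motivating study). Genotypes with DP < 3 are set
missing *before* missingness and allele frequency are computed. The
removal tally attributes each site to the first firing rule in a fixed,
documented order (structural rules first, then INFO rules, then
cohort-level rules).

Two conventions were genuinely open. The SB criterion "≥ −1.0" is an
unusual direction for a strand-bias annotation; it is implemented exactly
as stated, logged loudly when it removes most sites, and overridable via
`FilterConfig.sb_max`. Missingness and allele frequency are computed over
all samples in the file: a single multi-sample VCF admits no unambiguous
per-species reading. A missing INFO annotation skips that rule for that
site (standard hard-filter practice) rather than removing the site.

## Kinship

phi = (N_het,het − 2·N_IBS0) / (N_het,i + N_het,j) over jointly
non-missing sites — the robust between-family estimator whose expectation
is 0.5 for duplicates, 0.25 for first-degree pairs, and 0 for unrelated
pairs regardless of the frequency spectrum (the IBS0 term cancels the
het–het term exactly for unrelated HWE pairs). Pairs with a zero
denominator get a NaN sentinel and carry no edge in the pruning graph.
Pruning is greedy within each species/population group: repeatedly remove
the individual in the most pairs with phi ≥ 0 (ties: lower sequencing
depth if provided, else lexicographically last id) until every remaining
pair is negative. Greedy max-degree removal is the standard minimal-removal
heuristic; the original study reports only the retention rule
(phi < 0), not an order, so any order satisfying the rule is admissible.

## Diversity

He and pairwise mismatch are computed in non-overlapping 100-kb windows
and expressed as percentages of the window span in bp — a VCF-only
numerator over a physical denominator, which is what produces per-bp
percentages on the 0.03–0.07% scale. Genome-wide values average complete
windows only (short terminal windows are computed but excluded, switchable).
The pairwise statistic defaults to the dosage distance |g_i − g_j| / 2
(identical het pairs contribute 0); the unphased expected allele-mismatch
convention (het–het contributes 0.5) is available via `convention="allele"`,
since the original in-house definition is unpublished.

## Runs of homozygosity

Windows of 20 consecutive SNPs slide along each chromosome; a window
passes with ≤ 1 heterozygous and ≤ 50 missing calls. Each SNP's hit
fraction is the passing share of the ≤ 20 windows covering it (edge SNPs
use the windows that exist; a chromosome with fewer SNPs than one window
forms a single window). Runs of SNPs with hit fraction ≥ 0.05 are trimmed
so both endpoints are homozygous non-missing calls, then gated on length
≥ 100 kb, ≥ 25 SNPs, and density ≥ 1 SNP / 10 kb. Segment coordinates are
the first/last contributing SNP positions. Note the published missing-call
tolerance (50) exceeds the window size (20), so that gate cannot fire at
the defaults; it is implemented verbatim and logged.

Two consequences of the consensus design are worth knowing. Boundaries
are window-scale, not SNP-scale: homozygous background SNPs adjacent to a
true tract are carried into the run by windows that straddle the
boundary, so per-tract boundary error is ~10–15 SNPs at the default
densities (the recovery tests bound it at 1.5 window spans; cohort-level
F_ROH bias stays well under 0.05). And the hit-fraction threshold (0.05)
with `min_snps_per_segment` (25) are the upstream tool's defaults, not
published values; both are exposed in `RohScanParams`.

F_ROH is total merged ROH length over genome length (autosome lengths
from the chromosome table), partitioned exactly into short
(100 kb–1 Mb) and long (> 1 Mb) components. A segment of genetic length L
cM dates the inbreeding loop to g = 100/(2L) generations, with physical
length standing in for genetic length at 1 Mb = 1 cM (configurable); a
1-Mb ROH thus traces to ~50 generations.

## Genetic load

Effect classes parse from `ANN` strings (severity precedence
LOF > missense > synonymous > other; LOF = stop gained/lost, start lost,
frameshift, splice acceptor/donor). Polarization is per species, with the
strict rule stated above; unpolarized sites are excluded from load counts
rather than assigned by species frequency alone. Per individual we count
homozygous-derived genotypes per class, genes with ≥ 1 homozygous-derived
LOF, and the LOF/synonymous and missense/synonymous ratios. The ratio
denominator defaults to the individual's homozygous-derived synonymous
count (the like-for-like comparison); `denominator="all_sites"` switches
to every polarized synonymous site.

## Group reporting

Group summaries report mean, sd (ddof = 1) and n per metric; pairwise
comparisons use the two-sided Wilcoxon rank-sum test, exact when both
groups have ≤ 25 untied observations, otherwise the normal approximation
with continuity correction. No multiple-testing correction is applied by
default (matching the original reporting); Benjamini–Hochberg is a flag.

## Problem sizes

The test suite and the acceptance script run the recovery analyses at
desk scale, chosen so each stage's statistical tolerance is comfortably
resolvable: F_ROH recovery on 10-sample, 30-Mb cohorts (30k sites);
kinship on 50,000 sites; heterozygosity on a 20-Mb chromosome (200
complete windows); load exactness on a 20-sample cohort with 380 effect
sites; ROH-oracle equivalence on instances of ≤ 200 SNPs. The numbered
analysis under `analysis/` uses two 18-Mb cohorts of 10 and 8 individuals.

## Known limitations

Beyond the generator's non-goals above: the filter stage consumes QC
annotations as given (it does not recompute them from reads); ROH
detection is consensus-window only (no HMM alternative); kinship offers
no within-family or structure-corrected estimators; the load stage trusts
the effect annotations and implements no deleteriousness scores. Windows,
thresholds and conversions are parameters, but their defaults are the
published parameterization and are not auto-tuned.
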