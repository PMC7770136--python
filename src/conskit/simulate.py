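"""Synthetic diploid cohorts with planted ground truth.

The generator emulates the statistical structure of a multi-species
resequencing cohort after variant calling: segregating biallelic SNVs with
a configurable site-frequency spectrum, Hardy-Weinberg genotypes outside
planted autozygous tracts, forced homozygosity inside them, gamete-dropped
related pairs, functional-effect sites with known ancestral/derived states,
and outgroup genomes fixed (with configurable fidelity) for the ancestral
allele.  Everything planted is recorded in a :class:`TruthSet` so each
downstream stage can be scored against known truth.

Genotypes follow exact HWE at each site.  The per-site ALT frequency is
drawn from a symmetric Beta(a, a); ``a`` is solved from the identity
E[2p(1-p)] = a/(2a+1) so that the expected heterozygous-call rate per bp
equals ``het_rate_theta`` given ``snp_density``.  The ratio
r = theta/density must not exceed 1/2 (r = 1/4 gives the classic U-shaped
Beta(0.5, 0.5); r = 1/2 degenerates to p = 0.5 at every site).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from conskit.io import (
    HOM_ALT,
    HOM_REF,
    HET,
    MISSING,
    GenotypeTable,
    write_chrom_lengths,
    write_json,
    write_vcf,
)

EFFECT_CLASSES = ("LOF", "missense", "synonymous")

_ANN_TERM = {"LOF": "stop_gained", "missense": "missense_variant", "synonymous": "synonymous_variant"}
_ANN_IMPACT = {"LOF": "HIGH", "missense": "MODERATE", "synonymous": "LOW"}

RELATIONS = ("parent_offspring", "full_sib", "duplicate", "unrelated")

_BASES = np.array(["A", "C", "G", "T"])


class ConfigError(ValueError):
    """Raised when a SimConfig cannot be realized."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a synthetic cohort.

    Defaults describe one species of ten diploid individuals on a single
    10-Mb autosome with ~1 segregating SNV per kb and an expected
    heterozygous-call rate of 4.3e-4 per bp (the scale observed in
    endangered primates), no autozygosity, no relatives and no outgroups.
    """

    n_samples: int = 10
    chromosomes: tuple[tuple[str, int], ...] = (("chr1", 10_000_000),)
    snp_density: float = 1e-3
    het_rate_theta: float = 4.3e-4
    target_froh: float = 0.0
    roh_length_dist: tuple[str, Mapping[str, float]] = ("lognormal", None)
    n_outgroups: int = 0
    outgroup_ancestral_fidelity: float = 0.99
    effect_counts: Mapping[str, int] = field(default_factory=dict)
    derived_hom_frac: Mapping[str, float] = field(default_factory=dict)
    relationships: tuple[tuple[str, str, str], ...] = ()
    species: tuple[str, ...] | None = None
    populations: tuple[str, ...] | None = None
    tract_het_error: float = 0.0
    missing_rate: float = 0.0
    corrupt_qc_fraction: float = 0.0
    effect_het_rate: float = 0.1
    gene_block_size: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ConfigError("n_samples must be >= 1")
        if not self.chromosomes or any(length <= 0 for _, length in self.chromosomes):
            raise ConfigError("chromosome lengths must be positive")
        if not 0.0 <= self.target_froh <= 1.0:
            raise ConfigError("target_froh must lie in [0, 1]")
        if self.snp_density <= 0:
            raise ConfigError("snp_density must be positive")
        if self.het_rate_theta < 0:
            raise ConfigError("het_rate_theta must be >= 0")
        if self.het_rate_theta > self.snp_density / 2 + 1e-12:
            raise ConfigError(
                "het_rate_theta infeasible: expected per-site heterozygosity "
                f"theta/density = {self.het_rate_theta / self.snp_density:.3f} exceeds the "
                "HWE maximum of 0.5; raise snp_density or lower het_rate_theta"
            )
        for cls, cnt in self.effect_counts.items():
            if cls not in EFFECT_CLASSES:
                raise ConfigError(f"unknown effect class {cls!r}")
            if cnt < 0:
                raise ConfigError("effect counts must be >= 0")
        for cls, frac in self.derived_hom_frac.items():
            if cls not in EFFECT_CLASSES:
                raise ConfigError(f"unknown effect class {cls!r}")
            if not 0.0 <= frac <= 1.0 - self.effect_het_rate:
                raise ConfigError(
                    f"derived_hom_frac[{cls!r}] must lie in [0, {1.0 - self.effect_het_rate}]"
                )
        names = set(self.sample_names())
        for a, b, rel in self.relationships:
            if rel not in RELATIONS:
                raise ConfigError(f"unknown relation {rel!r}; expected one of {RELATIONS}")
            if a not in names or b not in names or a == b:
                raise ConfigError(f"relationship ({a!r}, {b!r}) does not name two distinct samples")
        if self.species is not None and len(self.species) != self.n_samples:
            raise ConfigError("species labels must match n_samples")
        if self.populations is not None and len(self.populations) != self.n_samples:
            raise ConfigError("population labels must match n_samples")

    def sample_names(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_samples)]

    def outgroup_names(self) -> list[str]:
        return [f"OG{i + 1}" for i in range(self.n_outgroups)]

    def species_labels(self) -> list[str]:
        return list(self.species) if self.species is not None else ["SpA"] * self.n_samples

    def population_labels(self) -> list[str]:
        if self.populations is not None:
            return list(self.populations)
        return self.species_labels()

    @property
    def genome_length(self) -> int:
        return int(sum(length for _, length in self.chromosomes))


@dataclass
class TruthSet:
    """Everything the generator planted, for recovery tests.

    ``planted_hom_derived`` holds the raw per-individual counts of
    homozygous-derived effect genotypes as drawn.  ``load_counts`` restricts
    those counts to sites that satisfy the polarization rule as realized in
    the emitted cohort (within-species ancestral-allele frequency > 0.5 and
    at least one outgroup homozygous ancestral) and is therefore the exact
    oracle for the load stage; the two coincide whenever every effect site
    polarizes.
    """

    roh_tracts: dict[str, list[tuple[str, int, int]]]
    froh_true: dict[str, float]
    relationships: list[tuple[str, str, str]]
    ancestral: np.ndarray
    effect_class: np.ndarray
    gene_id: np.ndarray
    site_freq_alt: np.ndarray
    planted_hom_derived: pd.DataFrame
    load_counts: pd.DataFrame
    polarizable: np.ndarray | None = None

    def effects_frame(self, table: GenotypeTable) -> pd.DataFrame:
        """Sidecar effects table (chrom, pos, gene_id, class, ancestral)."""
        mask = self.effect_class != ""
        return pd.DataFrame(
            {
                "chrom": table.chrom[mask],
                "pos": table.pos[mask],
                "gene_id": self.gene_id[mask],
                "effect_class": self.effect_class[mask],
                "ancestral_allele": self.ancestral[mask],
            }
        )

    def to_json_dict(self) -> dict:
        return {
            "roh_tracts": {s: [list(t) for t in tr] for s, tr in self.roh_tracts.items()},
            "froh_true": self.froh_true,
            "relationships": [list(r) for r in self.relationships],
            "planted_hom_derived": self.planted_hom_derived.to_dict(orient="index"),
            "load_counts": self.load_counts.to_dict(orient="index"),
        }


# ---------------------------------------------------------------------------
# site layout and neutral genotypes


def _beta_param(r: float) -> float | None:
    """Solve a/(2a+1) = r for the symmetric Beta parameter; None means p==0.5."""
    if abs(r - 0.5) < 1e-9:
        return None
    return r / (1.0 - 2.0 * r)


def _draw_positions(rng: np.random.Generator, length: int, n: int) -> np.ndarray:
    """n distinct sorted 1-based positions on [1, length]."""
    if n > length:
        raise ConfigError(f"snp_density requests {n} sites on a {length}-bp chromosome")
    pos: np.ndarray = np.unique(rng.integers(1, length + 1, size=int(n * 1.1) + 16))
    while len(pos) < n:
        extra = rng.integers(1, length + 1, size=n)
        pos = np.unique(np.concatenate([pos, extra]))
    if len(pos) > n:
        pos = np.sort(rng.choice(pos, size=n, replace=False))
    return pos.astype(np.int64)


def _hwe_genotypes(rng: np.random.Generator, p_alt: np.ndarray, n_samples: int) -> np.ndarray:
    """(n_sites, n_samples) int8 dosages under exact HWE."""
    u = rng.random((len(p_alt), n_samples))
    c_hom_ref = (1.0 - p_alt) ** 2
    c_het = c_hom_ref + 2.0 * p_alt * (1.0 - p_alt)
    gt = np.zeros(u.shape, dtype=np.int8)
    gt[u >= c_hom_ref[:, None]] = HET
    gt[u >= c_het[:, None]] = HOM_ALT
    return gt


# ---------------------------------------------------------------------------
# relationships


def plant_relationship(
    freqs: np.ndarray,
    relation: str,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Gamete-drop a pair of genotype vectors with a known pedigree relation.

    ``freqs`` are per-site ALT allele frequencies.  parent_offspring shares
    exactly one allele IBD at every site; full sibs share 0/1/2 alleles with
    probability 1/4, 1/2, 1/4; duplicate is a copy; unrelated pairs are
    independent HWE draws.
    """
    if relation not in RELATIONS:
        raise ValueError(f"unknown relation {relation!r}; expected one of {RELATIONS}")
    if rng is None:
        rng = np.random.default_rng(seed)
    p = np.asarray(freqs, dtype=float)
    n = len(p)
    draw = lambda: (rng.random(n) < p).astype(np.int8)  # one gamete from the population
    if relation == "duplicate":
        g = draw() + draw()
        return g, g.copy()
    if relation == "unrelated":
        return draw() + draw(), draw() + draw()
    if relation == "parent_offspring":
        a1, a2 = draw(), draw()
        parent = a1 + a2
        transmit = np.where(rng.random(n) < 0.5, a1, a2)
        child = transmit + draw()
        return parent.astype(np.int8), child.astype(np.int8)
    # full_sib: two parents, each sib receives one random gamete from each
    a1, a2, b1, b2 = draw(), draw(), draw(), draw()
    pick = lambda x, y: np.where(rng.random(n) < 0.5, x, y)
    sib1 = pick(a1, a2) + pick(b1, b2)
    sib2 = pick(a1, a2) + pick(b1, b2)
    return sib1.astype(np.int8), sib2.astype(np.int8)


# ---------------------------------------------------------------------------
# autozygous tracts


def _draw_tract_length(rng: np.random.Generator, dist: tuple[str, Mapping[str, float] | None]) -> int:
    family, params = dist
    params = dict(params) if params else {}
    if family == "lognormal":
        median = params.get("median_bp", 8e5)
        sigma = params.get("sigma_log", 0.6)
        return max(1, int(rng.lognormal(math.log(median), sigma)))
    if family == "fixed":
        return max(1, int(params.get("length_bp", 1e6)))
    if family == "uniform":
        lo = int(params.get("min_bp", 2e5))
        hi = int(params.get("max_bp", 2e6))
        return int(rng.integers(lo, hi + 1))
    raise ConfigError(f"unknown roh_length_dist family {family!r}")


def _plant_tracts(
    rng: np.random.Generator,
    chromosomes: Sequence[tuple[str, int]],
    target_froh: float,
    dist: tuple[str, Mapping[str, float] | None],
) -> list[tuple[str, int, int]]:
    """Non-overlapping tracts totalling exactly round(target_froh * genome).

    Each drawn tract is placed uniformly over all positions that keep it
    inside a free gap (gaps weighted by their number of valid offsets); a
    tract longer than every remaining gap is trimmed to the largest gap.
    This realizes uniform non-overlapping placement for any target up to 1.
    """
    genome = sum(length for _, length in chromosomes)
    need = int(round(target_froh * genome))
    if need == 0:
        return []
    # free gaps as (chrom, start, end), 1-based inclusive
    gaps: list[tuple[str, int, int]] = [(name, 1, length) for name, length in chromosomes]
    out: list[tuple[str, int, int]] = []
    remaining = need
    while remaining > 0:
        if not gaps:
            raise ConfigError(
                f"target_froh={target_froh} infeasible: no free gap remains with "
                f"{remaining} bp of tract still to place"
            )
        largest = max(e - s + 1 for _, s, e in gaps)
        length = min(_draw_tract_length(rng, dist), remaining, largest)
        fits = [(k, e - s + 1 - length + 1) for k, (_, s, e) in enumerate(gaps) if e - s + 1 >= length]
        offsets = np.array([w for _, w in fits], dtype=float)
        k = fits[int(rng.choice(len(fits), p=offsets / offsets.sum()))][0]
        cname, g_start, g_end = gaps.pop(k)
        start = int(rng.integers(g_start, g_end - length + 2))
        end = start + length - 1
        out.append((cname, start, end))
        remaining -= length
        if start > g_start:
            gaps.append((cname, g_start, start - 1))
        if end < g_end:
            gaps.append((cname, end + 1, g_end))
    return sorted(out)


# ---------------------------------------------------------------------------
# cohort assembly


def simulate_cohort(config: SimConfig) -> tuple[GenotypeTable, TruthSet]:
    """Generate a cohort and its truth tables.  Fully determined by the seed."""
    rng = np.random.default_rng(config.seed)
    samples = config.sample_names()
    outgroups = config.outgroup_names()
    all_samples = samples + outgroups
    species = config.species_labels()

    chrom_arr: list[np.ndarray] = []
    pos_arr: list[np.ndarray] = []
    for name, length in config.chromosomes:
        n = int(round(config.snp_density * length))
        p = _draw_positions(rng, length, n)
        pos_arr.append(p)
        chrom_arr.append(np.full(n, name, dtype=object))
    chrom = np.concatenate(chrom_arr)
    pos = np.concatenate(pos_arr)
    n_sites = len(pos)

    ref_idx = rng.integers(0, 4, size=n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_sites)) % 4
    ref = _BASES[ref_idx].astype(object)
    alt = _BASES[alt_idx].astype(object)

    r = config.het_rate_theta / config.snp_density
    a = _beta_param(r)
    if a is None:
        p_alt = np.full(n_sites, 0.5)
    elif config.het_rate_theta == 0:
        p_alt = np.zeros(n_sites)
    else:
        p_alt = rng.beta(a, a, size=n_sites)

    gt = _hwe_genotypes(rng, p_alt, config.n_samples)

    # planted relationships override both members' baseline genotypes
    related: set[str] = set()
    for s_a, s_b, rel in config.relationships:
        g_a, g_b = plant_relationship(p_alt, rel, rng=rng)
        gt[:, samples.index(s_a)] = g_a
        gt[:, samples.index(s_b)] = g_b
        related.update((s_a, s_b))

    # autozygous tracts: forced homozygosity, exact bp accounting
    genome = config.genome_length
    roh_tracts: dict[str, list[tuple[str, int, int]]] = {}
    froh_true: dict[str, float] = {}
    in_tract = np.zeros((n_sites, config.n_samples), dtype=bool)
    chrom_index = {name: np.flatnonzero(chrom == name) for name, _ in config.chromosomes}
    for j, s in enumerate(samples):
        if s in related or config.target_froh == 0:
            roh_tracts[s] = []
            froh_true[s] = 0.0
            continue
        tracts = _plant_tracts(rng, config.chromosomes, config.target_froh, config.roh_length_dist)
        roh_tracts[s] = tracts
        froh_true[s] = sum(e - st + 1 for _, st, e in tracts) / genome
        for cname, st, e in tracts:
            idx = chrom_index[cname]
            lo, hi = np.searchsorted(pos[idx], [st, e + 1])
            sites = idx[lo:hi]
            hom_alt = rng.random(len(sites)) < p_alt[sites]
            gt[sites, j] = np.where(hom_alt, HOM_ALT, HOM_REF).astype(np.int8)
            if config.tract_het_error > 0:
                err = rng.random(len(sites)) < config.tract_het_error
                gt[sites[err], j] = HET
            in_tract[sites, j] = True

    # ancestral allele: the major allele under the drawn spectrum (ties -> ref)
    ancestral = np.where(p_alt > 0.5, alt, ref).astype(object)

    effect_class = np.full(n_sites, "", dtype=object)
    gene_id = np.full(n_sites, "", dtype=object)
    ann = np.full(n_sites, None, dtype=object)
    if any(config.effect_counts.values()):
        _inject_effects(
            config, rng, chrom, pos, ref, alt, gt, in_tract, ancestral, effect_class, gene_id, ann, species
        )

    # outgroups: homozygous-ancestral with the configured fidelity
    og_gt = np.zeros((n_sites, config.n_outgroups), dtype=np.int8)
    if config.n_outgroups:
        anc_is_alt = ancestral == alt
        for k in range(config.n_outgroups):
            faithful = rng.random(n_sites) < config.outgroup_ancestral_fidelity
            anc_g = np.where(anc_is_alt, HOM_ALT, HOM_REF).astype(np.int8)
            der_g = np.where(anc_is_alt, HOM_REF, HOM_ALT).astype(np.int8)
            og_gt[:, k] = np.where(faithful, anc_g, der_g)
    full_gt = np.concatenate([gt, og_gt], axis=1) if config.n_outgroups else gt

    if config.missing_rate > 0:
        miss = rng.random(full_gt.shape) < config.missing_rate
        full_gt[miss] = MISSING

    # QC annotations at pass levels, with optional corruption
    qual = np.round(rng.uniform(60, 200, n_sites), 1)
    info = pd.DataFrame(
        {
            "QD": np.round(rng.uniform(15, 35, n_sites), 2),
            "FS": np.round(rng.uniform(0.0, 5.0, n_sites), 2),
            "MQ": np.round(rng.uniform(50, 60, n_sites), 2),
            "ReadPosRankSum": np.round(rng.uniform(-2.0, 2.0, n_sites), 2),
            "SB": np.round(rng.uniform(-6.0, -2.0, n_sites), 2),
        }
    )
    dp = rng.integers(10, 41, size=full_gt.shape).astype(np.int32)
    if config.corrupt_qc_fraction > 0:
        n_bad = int(round(config.corrupt_qc_fraction * n_sites))
        bad = rng.choice(n_sites, size=n_bad, replace=False)
        rules = ("QD", "FS", "MQ", "ReadPosRankSum", "SB", "QUAL", "DP")
        choice = rng.integers(0, len(rules), size=n_bad)
        for i, c in zip(bad, choice):
            rule = rules[c]
            if rule == "QUAL":
                qual[i] = 10.0
            elif rule == "DP":
                dp[i, :] = 1
            else:
                info.loc[i, rule] = {"QD": 1.0, "FS": 80.0, "MQ": 30.0, "ReadPosRankSum": -9.0, "SB": -0.5}[rule]
    info["ANN"] = ann

    table = GenotypeTable(
        samples=all_samples,
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        qual=qual,
        info=info,
        gt=full_gt,
        dp=dp,
        chrom_lengths=dict(config.chromosomes),
    )

    truth = _build_truth(config, table, roh_tracts, froh_true, ancestral, effect_class, gene_id, p_alt, species)
    return table, truth


def _inject_effects(
    config: SimConfig,
    rng: np.random.Generator,
    chrom: np.ndarray,
    pos: np.ndarray,
    ref: np.ndarray,
    alt: np.ndarray,
    gt: np.ndarray,
    in_tract: np.ndarray,
    ancestral: np.ndarray,
    effect_class: np.ndarray,
    gene_id: np.ndarray,
    ann: np.ndarray,
    species: list[str],
) -> None:
    """Plant functional-effect sites with controlled homozygous-derived draws.

    The ancestral allele at effect sites is fixed to REF (derived = ALT);
    each individual is homozygous-derived with probability
    ``derived_hom_frac[class]``, heterozygous with rate ``effect_het_rate``
    (suppressed inside that individual's autozygous tracts, which stay
    fully homozygous), homozygous-ancestral otherwise.
    """
    total = int(sum(config.effect_counts.values()))
    n_sites = len(pos)
    if total > n_sites:
        raise ConfigError(f"requested {total} effect sites but the cohort has only {n_sites} sites")
    chosen = rng.choice(n_sites, size=total, replace=False)
    rng.shuffle(chosen)
    classes = np.concatenate(
        [np.full(int(config.effect_counts.get(c, 0)), c, dtype=object) for c in EFFECT_CLASSES]
    )
    order = np.argsort(chosen)  # genomic order for gene blocks
    chosen_sorted = chosen[order]
    classes_sorted = classes[order]
    genes = np.array(
        [f"GENE{1 + i // max(1, config.gene_block_size):04d}" for i in range(total)], dtype=object
    )
    species_arr = np.asarray(species, dtype=object)
    for site, cls, gene in zip(chosen_sorted, classes_sorted, genes):
        effect_class[site] = cls
        gene_id[site] = gene
        ancestral[site] = ref[site]
        term = _ANN_TERM[cls]
        ann[site] = f"{alt[site]}|{term}|{_ANN_IMPACT[cls]}|{gene}|{gene}"
        f = float(config.derived_hom_frac.get(cls, 0.0))
        for sp in np.unique(species_arr):
            members = np.flatnonzero(species_arr == sp)
            u = rng.random(len(members))
            g = np.full(len(members), HOM_REF, dtype=np.int8)
            g[u < f] = HOM_ALT
            het_band = (u >= f) & (u < f + config.effect_het_rate)
            g[het_band & ~in_tract[site, members]] = HET
            gt[site, members] = g


def _build_truth(
    config: SimConfig,
    table: GenotypeTable,
    roh_tracts: dict[str, list[tuple[str, int, int]]],
    froh_true: dict[str, float],
    ancestral: np.ndarray,
    effect_class: np.ndarray,
    gene_id: np.ndarray,
    p_alt: np.ndarray,
    species: list[str],
) -> TruthSet:
    samples = config.sample_names()
    n_in = config.n_samples
    gt = table.gt[:, :n_in]
    og = table.gt[:, n_in:]
    eff_idx = np.flatnonzero(effect_class != "")
    anc_is_alt = ancestral == table.alt
    der_code = np.where(anc_is_alt, HOM_REF, HOM_ALT)  # genotype code meaning hom-derived

    planted = pd.DataFrame(0, index=samples, columns=list(EFFECT_CLASSES))
    species_arr = np.asarray(species, dtype=object)
    polarizable = np.zeros(len(table.pos), dtype=bool)
    # replicate the polarization rule exactly as realized in the emitted
    # cohort: per species, an allele is ancestral iff its within-species
    # frequency exceeds 0.5 and >=1 outgroup is homozygous for it.  Drift
    # can flip the realized orientation away from the planted ancestral
    # state; the truth accounting follows the realized orientation so the
    # load stage can be held to zero tolerance.
    pol_by_species: dict[str, np.ndarray] = {}
    dercode_by_species: dict[str, np.ndarray] = {}
    if len(eff_idx):
        if og.shape[1]:
            og_hom_ref = (og[eff_idx] == HOM_REF).any(axis=1)
            og_hom_alt = (og[eff_idx] == HOM_ALT).any(axis=1)
        else:
            og_hom_ref = og_hom_alt = np.zeros(len(eff_idx), dtype=bool)
        for sp in np.unique(species_arr):
            members = np.flatnonzero(species_arr == sp)
            sub = gt[np.ix_(eff_idx, members)]
            nonmiss = (sub != MISSING).sum(axis=1)
            alt_dose = np.where(sub == MISSING, 0, sub).sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                af_alt = np.where(nonmiss > 0, alt_dose / (2.0 * nonmiss), np.nan)
            ref_anc = (1.0 - af_alt > 0.5) & og_hom_ref
            alt_anc = (af_alt > 0.5) & og_hom_alt
            pol_by_species[sp] = (nonmiss > 0) & (ref_anc | alt_anc)
            dercode_by_species[sp] = np.where(ref_anc, HOM_ALT, HOM_REF)
        polarizable[eff_idx] = np.any(
            np.vstack([pol_by_species[sp] for sp in pol_by_species]), axis=0
        )

    load = pd.DataFrame(
        0,
        index=samples,
        columns=["n_hom_derived_lof", "n_genes_hom_lof", "n_hom_derived_missense", "n_hom_derived_synonymous"],
    )
    for j, s in enumerate(samples):
        sp = species_arr[j]
        hom_der_all = gt[eff_idx, j] == der_code[eff_idx] if len(eff_idx) else np.zeros(0, dtype=bool)
        for cls in EFFECT_CLASSES:
            cls_mask = effect_class[eff_idx] == cls
            planted.loc[s, cls] = int(np.sum(hom_der_all & cls_mask))
        if len(eff_idx):
            pol = pol_by_species[sp]
            hom_der = (gt[eff_idx, j] == dercode_by_species[sp]) & pol
            lof = hom_der & (effect_class[eff_idx] == "LOF")
            load.loc[s, "n_hom_derived_lof"] = int(lof.sum())
            load.loc[s, "n_genes_hom_lof"] = int(len(set(gene_id[eff_idx[lof]])))
            load.loc[s, "n_hom_derived_missense"] = int(np.sum(hom_der & (effect_class[eff_idx] == "missense")))
            load.loc[s, "n_hom_derived_synonymous"] = int(
                np.sum(hom_der & (effect_class[eff_idx] == "synonymous"))
            )

    return TruthSet(
        roh_tracts=roh_tracts,
        froh_true=froh_true,
        relationships=list(config.relationships),
        ancestral=ancestral,
        effect_class=effect_class,
        gene_id=gene_id,
        site_freq_alt=p_alt,
        planted_hom_derived=planted,
        load_counts=load,
        polarizable=polarizable,
    )


def sample_metadata(config: SimConfig) -> pd.DataFrame:
    """Sample table with species/population labels and outgroup flags."""
    species = config.species_labels()
    populations = config.population_labels()
    rows = [
        {"sample": s, "species": sp, "population": pop, "is_outgroup": False}
        for s, sp, pop in zip(config.sample_names(), species, populations)
    ]
    rows += [
        {"sample": s, "species": "outgroup", "population": "outgroup", "is_outgroup": True}
        for s in config.outgroup_names()
    ]
    return pd.DataFrame(rows)


def write_cohort(config: SimConfig, outdir: str | Path) -> tuple[GenotypeTable, TruthSet]:
    """Simulate and write VCF, effects TSV, truth JSON and metadata tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table, truth = simulate_cohort(config)
    write_vcf(table, outdir / "cohort.vcf")
    truth.effects_frame(table).to_csv(outdir / "effects.tsv", sep="\t", index=False)
    write_json(truth.to_json_dict(), outdir / "truth.json")
    write_chrom_lengths(dict(config.chromosomes), outdir / "chrom_lengths.tsv")
    sample_metadata(config).to_csv(outdir / "samples.tsv", sep="\t", index=False)
    return table, truth
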