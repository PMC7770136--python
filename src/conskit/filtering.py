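"""Hard-filter cascade producing the analysis-ready biallelic autosomal SNP set.

The cascade applies the GATK-style site filters
``QD < 2.0 || FS > 60.0 || MQ < 40.0 || ReadPosRankSum < -8.0 || SB >= -1.0``
plus QUAL < 30, per-genotype depth masking (DP < 3 -> missing), site
missingness > 20%, minor-allele frequency < 5%, removal of multi-allelic
and non-autosomal records, and exclusion of BED regions (CpG islands).
Depth masking happens before missingness and allele frequency are computed.

A site is removed when any rule fires; the tally attributes each removed
site to the FIRST firing rule in :data:`RULE_ORDER`.  A rule whose INFO
annotation is absent is skipped for that site (standard hard-filter
practice) with a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from intervaltree import IntervalTree

from conskit.io import MISSING, GenotypeTable

logger = logging.getLogger(__name__)

#: Fixed first-firing attribution order for the removal tally.
RULE_ORDER = (
    "multiallelic",
    "non_autosome",
    "excluded_region",
    "QD",
    "FS",
    "MQ",
    "ReadPosRankSum",
    "SB",
    "QUAL",
    "missingness",
    "allele_frequency",
)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the hard-filter cascade (defaults as used for the cohort).

    ``sb_max`` is exclusive: a site is removed when SB >= sb_max, i.e. the
    printed criterion ``SB >= -1.0`` verbatim, unusual as it is (see module
    docs); override it to disable or flip the rule.
    """

    qd_min: float = 2.0
    fs_max: float = 60.0
    mq_min: float = 40.0
    rprs_min: float = -8.0
    sb_max: float = -1.0
    dp_min: int = 3
    qual_min: float = 30.0
    max_missing: float = 0.20
    min_af: float = 0.05
    autosomes: tuple[str, ...] | None = None
    excluded_regions: tuple[tuple[str, int, int], ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_missing <= 1.0:
            raise ValueError("max_missing must lie in [0, 1]")
        if not 0.0 <= self.min_af <= 0.5:
            raise ValueError("min_af must lie in [0, 0.5]")
        for v in (self.qd_min, self.fs_max, self.mq_min, self.rprs_min, self.sb_max, self.qual_min):
            if not np.isfinite(v):
                raise ValueError("thresholds must be finite")


def autosomes_from_lengths(chrom_lengths: dict[str, int]) -> tuple[str, ...]:
    """Autosome list from a chromosome table: drop X/Y-named chromosomes."""
    sex = {"x", "y", "chrx", "chry"}
    return tuple(c for c in chrom_lengths if c.lower() not in sex)


def _region_trees(regions: Sequence[tuple[str, int, int]]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end in regions:
        if end <= start:
            continue
        trees.setdefault(chrom, IntervalTree()).addi(start, end)
    return trees


def _in_regions(table: GenotypeTable, trees: dict[str, IntervalTree]) -> np.ndarray:
    hit = np.zeros(table.n_sites, dtype=bool)
    if not trees:
        return hit
    for i in range(table.n_sites):
        tree = trees.get(str(table.chrom[i]))
        if tree is not None and tree.overlaps_point(int(table.pos[i]) - 1):
            hit[i] = True
    return hit


def exclude_regions(table: GenotypeTable, bed: Sequence[tuple[str, int, int]]) -> GenotypeTable:
    """Remove sites overlapping 0-based half-open BED intervals."""
    hit = _in_regions(table, _region_trees(bed))
    return table.take_sites(~hit)


def _info_rule(table: GenotypeTable, key: str, fails) -> np.ndarray:
    """Per-site fail mask for an INFO rule; missing annotation -> skipped."""
    if key not in table.info.columns:
        logger.warning("INFO key %s absent from all sites; rule skipped", key)
        return np.zeros(table.n_sites, dtype=bool)
    vals = table.info[key].to_numpy(dtype=float)
    absent = ~np.isfinite(vals)
    if absent.any():
        logger.warning("INFO key %s absent at %d sites; rule skipped there", key, int(absent.sum()))
    fail = np.zeros(table.n_sites, dtype=bool)
    present = ~absent
    fail[present] = fails(vals[present])
    return fail


def apply_site_filters(
    table: GenotypeTable, config: FilterConfig
) -> tuple[GenotypeTable, dict[str, int]]:
    """Apply the cascade; return the retained table and the per-rule tally.

    The returned table has DP-masked genotypes (DP < dp_min set missing).
    The tally maps each rule in :data:`RULE_ORDER` to the number of sites
    it removed (first-firing attribution) plus a ``retained`` entry, so the
    tally sums to the input site count.
    """
    n = table.n_sites
    gt = table.gt.copy()
    gt[table.dp < config.dp_min] = MISSING

    nonmiss = (gt != MISSING).sum(axis=1)
    missingness = 1.0 - nonmiss / table.n_samples
    alt_dose = np.where(gt == MISSING, 0, gt).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        af_alt = np.where(nonmiss > 0, alt_dose / (2.0 * nonmiss), np.nan)
    maf = np.fmin(af_alt, 1.0 - af_alt)

    if config.autosomes is not None:
        autosomes = set(config.autosomes)
    elif table.chrom_lengths:
        autosomes = set(autosomes_from_lengths(table.chrom_lengths))
    else:
        autosomes = set(autosomes_from_lengths({c: 0 for c in dict.fromkeys(table.chrom.tolist())}))

    fails: dict[str, np.ndarray] = {
        "multiallelic": table.n_alt != 1,
        "non_autosome": ~np.isin(table.chrom.astype(str), list(autosomes)),
        "excluded_region": _in_regions(table, _region_trees(config.excluded_regions)),
        "QD": _info_rule(table, "QD", lambda v: v < config.qd_min),
        "FS": _info_rule(table, "FS", lambda v: v > config.fs_max),
        "MQ": _info_rule(table, "MQ", lambda v: v < config.mq_min),
        "ReadPosRankSum": _info_rule(table, "ReadPosRankSum", lambda v: v < config.rprs_min),
        "SB": _info_rule(table, "SB", lambda v: v >= config.sb_max),
        "QUAL": np.where(np.isfinite(table.qual), table.qual < config.qual_min, False),
        "missingness": missingness > config.max_missing,
        "allele_frequency": (nonmiss == 0) | (maf < config.min_af),
    }

    if n and fails["SB"].sum() > 0.5 * n:
        logger.warning(
            "SB >= %.1f removed %d/%d sites (>50%%); the criterion is applied verbatim — "
            "override FilterConfig.sb_max if your SB annotation uses another convention",
            config.sb_max,
            int(fails["SB"].sum()),
            n,
        )

    removed = np.zeros(n, dtype=bool)
    tally = {rule: 0 for rule in RULE_ORDER}
    for rule in RULE_ORDER:
        fire = fails[rule] & ~removed
        tally[rule] = int(fire.sum())
        removed |= fails[rule]
    tally["retained"] = int(n - removed.sum())

    masked = replace_genotypes(table, gt)
    return masked.take_sites(~removed), tally


def replace_genotypes(table: GenotypeTable, gt: np.ndarray) -> GenotypeTable:
    """Copy of the table with a new genotype matrix."""
    return GenotypeTable(
        samples=list(table.samples),
        chrom=table.chrom,
        pos=table.pos,
        ref=table.ref,
        alt=table.alt,
        qual=table.qual,
        info=table.info,
        gt=gt,
        dp=table.dp,
        n_alt=table.n_alt,
        chrom_lengths=table.chrom_lengths,
    )
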