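"""Genetic load: effect classification, ancestral polarization, load counts.

Effect classes come from SnpEff-style ``ANN`` INFO strings or a sidecar
effects table; multi-effect sites take the most severe class with
precedence LOF > missense > synonymous > other.  Alleles are polarized per
species: an allele is ancestral iff its within-species frequency exceeds
0.5 AND at least one outgroup individual is homozygous for it; all other
sites are unpolarized and excluded from load counts.  Per individual we
count homozygous-derived genotypes per class, the number of genes carrying
at least one homozygous-derived LOF, and the LOF/synonymous and
missense/synonymous ratios (homozygous-derived denominator by default; a
flag switches to the all-synonymous-sites denominator).
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from conskit.io import HET, HOM_ALT, HOM_REF, MISSING, GenotypeTable

logger = logging.getLogger(__name__)

LOF_TERMS = {
    "stop_gained",
    "stop_lost",
    "start_lost",
    "frameshift_variant",
    "splice_acceptor_variant",
    "splice_donor_variant",
}

#: Severity precedence for multi-annotation sites.
SEVERITY = ("LOF", "missense", "synonymous", "other")


def _class_of_terms(terms: Sequence[str]) -> str:
    classes = set()
    for t in terms:
        t = t.strip()
        if t in LOF_TERMS:
            classes.add("LOF")
        elif t == "missense_variant":
            classes.add("missense")
        elif t == "synonymous_variant":
            classes.add("synonymous")
        elif t:
            classes.add("other")
    for c in SEVERITY:
        if c in classes:
            return c
    return "other"


def classify_effects(
    table: GenotypeTable, effects_tsv: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-site effect classes from ANN strings or a sidecar effects table.

    Returns a DataFrame indexed like the table's sites with columns
    ``effect_class`` ("" for unannotated sites) and ``gene_id``.  The
    sidecar table (chrom, pos, gene_id, effect_class) takes precedence
    where present.
    """
    effect = np.full(table.n_sites, "", dtype=object)
    gene = np.full(table.n_sites, "", dtype=object)
    if "ANN" in table.info.columns:
        for i, raw in enumerate(table.info["ANN"]):
            if not isinstance(raw, str) or not raw:
                continue
            terms: list[str] = []
            gid = ""
            try:
                for entry in raw.split(","):
                    fields = entry.split("|")
                    terms.extend(fields[1].split("&"))
                    if len(fields) > 4 and fields[4] and not gid:
                        gid = fields[4]
                    elif len(fields) > 3 and fields[3] and not gid:
                        gid = fields[3]
            except IndexError:
                logger.warning("unparseable ANN string at %s:%d; classed 'other'", table.chrom[i], table.pos[i])
                effect[i] = "other"
                continue
            if not terms:
                logger.warning("unparseable ANN string at %s:%d; classed 'other'", table.chrom[i], table.pos[i])
                effect[i] = "other"
                continue
            effect[i] = _class_of_terms(terms)
            gene[i] = gid
    if effects_tsv is not None:
        key = {(str(c), int(p)): k for k, (c, p) in enumerate(zip(table.chrom, table.pos))}
        for _, row in effects_tsv.iterrows():
            k = key.get((str(row["chrom"]), int(row["pos"])))
            if k is None:
                continue
            effect[k] = row["effect_class"]
            gene[k] = row["gene_id"]
    return pd.DataFrame({"effect_class": effect, "gene_id": gene})


def polarize_sites(
    table: GenotypeTable,
    species_of: Mapping[str, str],
    outgroup_samples: Sequence[str],
    sites: np.ndarray | None = None,
) -> dict[str, pd.DataFrame]:
    """Ancestral/derived assignment per species.

    For each species the ancestral allele at a site is the allele with
    within-species frequency > 0.5 (over non-missing genotypes of that
    species' samples) that is also carried homozygous by at least one
    outgroup individual; sites with no such allele are unpolarized.

    Returns ``{species: DataFrame(status, ancestral, derived)}`` aligned
    with the table's sites (or the subset ``sites``).
    """
    idx = np.asarray(sites) if sites is not None else np.arange(table.n_sites)
    og_idx = [table.sample_index(s) for s in outgroup_samples]
    og = table.gt[np.ix_(idx, og_idx)] if og_idx else np.zeros((len(idx), 0), dtype=np.int8)
    og_hom_ref = (og == HOM_REF).any(axis=1)
    og_hom_alt = (og == HOM_ALT).any(axis=1)

    species_groups: dict[str, list[int]] = {}
    for s, sp in species_of.items():
        if s in outgroup_samples:
            continue
        species_groups.setdefault(sp, []).append(table.sample_index(s))

    out: dict[str, pd.DataFrame] = {}
    for sp, members in species_groups.items():
        sub = table.gt[np.ix_(idx, members)]
        nonmiss = (sub != MISSING).sum(axis=1)
        alt_dose = np.where(sub == MISSING, 0, sub).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            af_alt = np.where(nonmiss > 0, alt_dose / (2.0 * nonmiss), np.nan)
        af_ref = 1.0 - af_alt
        ref_anc = (af_ref > 0.5) & og_hom_ref
        alt_anc = (af_alt > 0.5) & og_hom_alt
        status = np.where(ref_anc | alt_anc, "polarized", "unpolarized")
        ancestral = np.where(ref_anc, table.ref[idx], np.where(alt_anc, table.alt[idx], ""))
        derived = np.where(ref_anc, table.alt[idx], np.where(alt_anc, table.ref[idx], ""))
        out[sp] = pd.DataFrame(
            {
                "site": idx,
                "status": status,
                "ancestral": ancestral,
                "derived": derived,
                "derived_is_alt": ref_anc,  # derived allele is ALT iff REF is ancestral
            }
        )
    return out


def individual_load(
    table: GenotypeTable,
    effects: pd.DataFrame,
    polarized: Mapping[str, pd.DataFrame],
    species_of: Mapping[str, str],
    outgroup_samples: Sequence[str] = (),
    denominator: str = "hom_derived",
) -> pd.DataFrame:
    """Per-individual load summary over polarized effect sites.

    ``denominator`` selects the synonymous count used in the ratios:
    ``"hom_derived"`` (the individual's homozygous-derived synonymous
    count, default) or ``"all_sites"`` (every polarized synonymous site).
    Ratios are NaN when the denominator is zero.
    """
    if denominator not in ("hom_derived", "all_sites"):
        raise ValueError("denominator must be 'hom_derived' or 'all_sites'")
    rows = []
    eff_class = effects["effect_class"].to_numpy()
    gene_id = effects["gene_id"].to_numpy()
    for s in table.samples:
        if s in outgroup_samples:
            continue
        sp = species_of.get(s)
        if sp is None or sp not in polarized:
            continue
        pol = polarized[sp]
        ok = (pol["status"] == "polarized").to_numpy()
        site = pol["site"].to_numpy()[ok]
        derived_is_alt = pol["derived_is_alt"].to_numpy()[ok]
        g = table.gt[site, table.sample_index(s)]
        hom_derived = np.where(derived_is_alt, g == HOM_ALT, g == HOM_REF)
        cls = eff_class[site]
        n_lof = int(np.sum(hom_derived & (cls == "LOF")))
        n_mis = int(np.sum(hom_derived & (cls == "missense")))
        n_syn = int(np.sum(hom_derived & (cls == "synonymous")))
        genes = set(gene_id[site[hom_derived & (cls == "LOF")]])
        genes.discard("")
        denom = n_syn if denominator == "hom_derived" else int(np.sum(cls == "synonymous"))
        if denom == 0:
            logger.warning("zero synonymous denominator for %s; ratios undefined", s)
        rows.append(
            {
                "sample": s,
                "species": sp,
                "n_hom_derived_lof": n_lof,
                "n_genes_hom_lof": len(genes),
                "n_hom_derived_missense": n_mis,
                "n_hom_derived_synonymous": n_syn,
                "ratio_lof_syn": n_lof / denom if denom else float("nan"),
                "ratio_mis_syn": n_mis / denom if denom else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def candidate_gene_screen(
    table: GenotypeTable,
    effects: pd.DataFrame,
    polarized: Mapping[str, pd.DataFrame],
    groups: Mapping[str, str],
    species_of: Mapping[str, str] | None = None,
    outgroup_samples: Sequence[str] = (),
) -> dict[str, list[str]]:
    """Per-group genes carrying >= 1 homozygous-derived LOF in any member.

    ``groups`` may be finer than species (populations); polarization is
    looked up per species via ``species_of`` (defaults to ``groups``).
    """
    species_of = species_of or groups
    out: dict[str, set[str]] = {}
    eff_class = effects["effect_class"].to_numpy()
    gene_id = effects["gene_id"].to_numpy()
    for s in table.samples:
        if s in outgroup_samples or s not in groups:
            continue
        grp = groups[s]
        pol = polarized.get(species_of.get(s, grp))
        if pol is None:
            continue
        ok = (pol["status"] == "polarized").to_numpy()
        site = pol["site"].to_numpy()[ok]
        derived_is_alt = pol["derived_is_alt"].to_numpy()[ok]
        g = table.gt[site, table.sample_index(s)]
        hom_derived = np.where(derived_is_alt, g == HOM_ALT, g == HOM_REF)
        lof = hom_derived & (eff_class[site] == "LOF")
        genes = {g for g in gene_id[site[lof]] if g}
        out.setdefault(grp, set()).update(genes)
    return {grp: sorted(genes) for grp, genes in out.items()}
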