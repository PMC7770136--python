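"""Pairwise kinship from identity-by-state counts and relatedness pruning.

The estimator is the between-family robust kinship coefficient

    phi = (N_het,het - 2 * N_IBS0) / (N_het,i + N_het,j)

computed from jointly non-missing sites: N_IBS0 counts opposite homozygotes,
N_het,het sites where both individuals are heterozygous, and N_het,i the
heterozygous sites of individual i.  Expected values: 0.5 for duplicates,
0.25 for parent-offspring and full sibs, 0 for unrelated pairs (negative
estimates indicate unrelated individuals).  Cohorts are pruned to the
non-consanguineous set by iteratively removing, within each group, the
individual involved in the most pairs at or above the threshold (default 0,
i.e. only pairs with phi < 0 are retained).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from conskit.io import HET, HOM_ALT, HOM_REF, MISSING, GenotypeTable

logger = logging.getLogger(__name__)

#: Sentinel for pairs whose kinship denominator is zero.
UNDEFINED = float("nan")


@dataclass(frozen=True)
class IbsCounts:
    """IBS-state counts over the jointly non-missing sites of a pair."""

    n_ibs0: int
    n_het_het: int
    n_het_i: int
    n_het_j: int
    n_shared: int

    def __post_init__(self) -> None:
        if min(self.n_ibs0, self.n_het_het, self.n_het_i, self.n_het_j, self.n_shared) < 0:
            raise ValueError("IBS counts must be non-negative")
        if self.n_ibs0 > self.n_shared:
            raise ValueError("n_ibs0 cannot exceed n_shared")
        if self.n_het_het > min(self.n_het_i, self.n_het_j):
            raise ValueError("n_het_het cannot exceed either individual heterozygote count")


def count_ibs_states(g_i: np.ndarray, g_j: np.ndarray) -> IbsCounts:
    """Count IBS states for two genotype vectors (0/1/2 dosage, -1 missing)."""
    g_i = np.asarray(g_i)
    g_j = np.asarray(g_j)
    if g_i.shape != g_j.shape:
        raise ValueError("genotype vectors must have equal length")
    shared = (g_i != MISSING) & (g_j != MISSING)
    n_shared = int(shared.sum())
    if n_shared == 0:
        raise ValueError("zero jointly non-missing sites; kinship undefined")
    a, b = g_i[shared], g_j[shared]
    return IbsCounts(
        n_ibs0=int(np.sum(((a == HOM_REF) & (b == HOM_ALT)) | ((a == HOM_ALT) & (b == HOM_REF)))),
        n_het_het=int(np.sum((a == HET) & (b == HET))),
        n_het_i=int(np.sum(a == HET)),
        n_het_j=int(np.sum(b == HET)),
        n_shared=n_shared,
    )


def kinship_coefficient(counts: IbsCounts) -> float:
    """phi = (N_het,het - 2 N_IBS0) / (N_het,i + N_het,j); NaN if undefined."""
    denom = counts.n_het_i + counts.n_het_j
    if denom == 0:
        logger.warning("zero heterozygote denominator; kinship undefined for this pair")
        return UNDEFINED
    return (counts.n_het_het - 2.0 * counts.n_ibs0) / denom


def kinship_matrix(
    table: GenotypeTable, samples: Sequence[str] | None = None
) -> tuple[pd.DataFrame, dict[tuple[str, str], IbsCounts]]:
    """Symmetric matrix of pairwise phi (diagonal 0.5) plus the raw counts."""
    names = list(samples) if samples is not None else list(table.samples)
    idx = [table.sample_index(s) for s in names]
    phi = pd.DataFrame(np.full((len(names), len(names)), 0.5), index=names, columns=names)
    counts: dict[tuple[str, str], IbsCounts] = {}
    for (ai, s_i), (aj, s_j) in itertools.combinations(zip(idx, names), 2):
        c = count_ibs_states(table.gt[:, ai], table.gt[:, aj])
        counts[(s_i, s_j)] = c
        v = kinship_coefficient(c)
        phi.loc[s_i, s_j] = v
        phi.loc[s_j, s_i] = v
    return phi, counts


def prune_related(
    phi: pd.DataFrame,
    groups: Mapping[str, str] | None = None,
    threshold: float = 0.0,
    depth: Mapping[str, float] | None = None,
) -> list[str]:
    """Greedy pruning to a set with all pairwise phi below the threshold.

    Within each group, while any pair satisfies phi >= threshold, the
    individual participating in the most such pairs is removed; ties are
    broken by removing the lower-sequencing-depth individual when depths
    are provided, else the lexicographically last id.  Pairs with undefined
    (NaN) kinship carry no edge and are logged.
    """
    names = list(phi.index)
    if groups is None:
        groups = {s: "all" for s in names}
    retained: list[str] = []
    for group in dict.fromkeys(groups.get(s, "all") for s in names):
        members = [s for s in names if groups.get(s, "all") == group]
        edges: dict[str, set[str]] = {s: set() for s in members}
        for s_i, s_j in itertools.combinations(members, 2):
            v = phi.loc[s_i, s_j]
            if v != v:
                logger.warning("undefined kinship for pair (%s, %s); excluded from pruning graph", s_i, s_j)
                continue
            if v >= threshold:
                edges[s_i].add(s_j)
                edges[s_j].add(s_i)
        alive = set(members)
        while True:
            deg = {s: len(edges[s] & alive) for s in alive}
            worst = max(deg.values(), default=0)
            if worst == 0:
                break
            tied = [s for s in alive if deg[s] == worst]
            if depth is not None:
                victim = min(tied, key=lambda s: (depth.get(s, float("inf")), s))
            else:
                victim = max(tied)
            alive.discard(victim)
        retained.extend(s for s in members if s in alive)
    return retained
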