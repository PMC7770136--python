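"""Windowed heterozygosity and pairwise nucleotide mismatch.

Both statistics are computed in non-overlapping windows (default 100 kb)
tiling each chromosome and expressed as percentages of the window span in
bp: He_w = 100 * (het calls in window) / span, and the pairwise mismatch
uses the per-site dosage distance d = |g_i - g_j| / 2 (opposite homozygotes
1, het vs hom 0.5, identical 0).  An unphased allele-mismatch convention
(het vs het contributes 0.5) is available via ``convention="allele"``.
Genome-wide values are means over complete windows; short terminal windows
are computed but excluded from the mean unless requested.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from conskit.io import HET, MISSING, GenotypeTable

logger = logging.getLogger(__name__)


def make_windows(chrom_lengths: Mapping[str, int], window: int = 100_000) -> pd.DataFrame:
    """Tile each chromosome with 0-based half-open windows of ``window`` bp."""
    if window <= 0:
        raise ValueError("window size must be positive")
    rows = []
    for chrom, length in chrom_lengths.items():
        starts = np.arange(0, length, window)
        ends = np.minimum(starts + window, length)
        for s, e in zip(starts, ends):
            rows.append((chrom, int(s), int(e)))
    if not rows:
        raise ValueError("no windows: empty chromosome table")
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df["span"] = df["end"] - df["start"]
    return df


def _window_of_sites(table: GenotypeTable, windows: pd.DataFrame) -> np.ndarray:
    """Index of the containing window for each site (-1 when uncovered)."""
    out = np.full(table.n_sites, -1, dtype=np.int64)
    for chrom, grp in windows.groupby("chrom", sort=False):
        on = np.flatnonzero(table.chrom == chrom)
        if not len(on):
            continue
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        pos0 = table.pos[on] - 1  # 0-based
        wi = np.searchsorted(starts, pos0, side="right") - 1
        ok = (wi >= 0) & (pos0 < ends[np.clip(wi, 0, len(ends) - 1)])
        out[on[ok]] = grp.index.to_numpy()[wi[ok]]
    return out


def _per_window(values: np.ndarray, widx: np.ndarray, windows: pd.DataFrame) -> np.ndarray:
    acc = np.zeros(len(windows))
    ok = widx >= 0
    np.add.at(acc, widx[ok], values[ok])
    return acc


def windowed_heterozygosity(
    table: GenotypeTable,
    windows: pd.DataFrame,
    samples: Sequence[str] | None = None,
    include_partial: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-window and genome-wide heterozygosity as % of window span.

    Returns ``(per_window, summary)``: per_window has one He column per
    sample alongside the window coordinates; summary has one row per sample
    with the mean and sd of He over complete windows.
    """
    names = list(samples) if samples is not None else list(table.samples)
    widx = _window_of_sites(table, windows)
    window_size = int(windows["span"].max())
    complete = (windows["span"] == window_size).to_numpy()
    per_window = windows[["chrom", "start", "end", "span"]].copy()
    rows = []
    for s in names:
        g = table.genotypes_of(s)
        het_counts = _per_window((g == HET).astype(float), widx, windows)
        he = 100.0 * het_counts / windows["span"].to_numpy()
        per_window[s] = he
        use = he if include_partial else he[complete]
        rows.append(
            {
                "sample": s,
                "he_mean_pct": float(np.mean(use)) if len(use) else float("nan"),
                "he_sd_pct": float(np.std(use, ddof=1)) if len(use) > 1 else float("nan"),
                "n_windows": int(len(use)),
            }
        )
    return per_window, pd.DataFrame(rows)


def _site_distance(g_i: np.ndarray, g_j: np.ndarray, convention: str) -> np.ndarray:
    ok = (g_i != MISSING) & (g_j != MISSING)
    gi = g_i.astype(float)
    gj = g_j.astype(float)
    if convention == "dosage":
        d = np.abs(gi - gj) / 2.0
    elif convention == "allele":
        # expected fraction of mismatching allele draws, one from each genotype
        d = (gi * (2.0 - gj) + gj * (2.0 - gi)) / 4.0
    else:
        raise ValueError(f"unknown mismatch convention {convention!r}")
    d[~ok] = 0.0
    return d


def pairwise_mismatch(
    table: GenotypeTable,
    sample_i: str,
    sample_j: str,
    windows: pd.DataFrame,
    convention: str = "dosage",
    include_partial: bool = False,
) -> tuple[pd.DataFrame, float]:
    """Per-window and mean pairwise nucleotide mismatch (% of span)."""
    if sample_i == sample_j:
        logger.warning("pairwise mismatch of %s with itself is 0 by definition", sample_i)
    g_i = table.genotypes_of(sample_i)
    g_j = table.genotypes_of(sample_j)
    d = _site_distance(g_i, g_j, convention)
    widx = _window_of_sites(table, windows)
    window_size = int(windows["span"].max())
    complete = (windows["span"] == window_size).to_numpy()
    per_window = windows[["chrom", "start", "end", "span"]].copy()
    mm = 100.0 * _per_window(d, widx, windows) / windows["span"].to_numpy()
    per_window["mismatch_pct"] = mm
    use = mm if include_partial else mm[complete]
    return per_window, float(np.mean(use)) if len(use) else float("nan")
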