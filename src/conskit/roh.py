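"""Runs of homozygosity: consensus window scan, F_ROH and ROH dating.

The scan mirrors the classic sliding-window consensus approach: windows of
``window_snps`` consecutive SNPs slide along each chromosome; a window
passes when it contains at most ``max_het_per_window`` heterozygous and
``max_missing_per_window`` missing calls.  Each SNP's hit fraction is the
share of passing windows among the windows covering it (edge SNPs use only
the windows that exist; a chromosome with fewer SNPs than a window forms a
single window).  Maximal runs of SNPs with hit fraction >= the threshold
become candidate segments, optionally trimmed so both endpoints are
homozygous non-missing calls, and are emitted when they satisfy the
minimum length, SNP count and density gates.  Segment coordinates are the
first/last contributing SNP positions (1-based inclusive).

F_ROH is total ROH length divided by genome length, partitioned into short
(100 kb - 1 Mb) and long (> 1 Mb) classes.  A segment of genetic length L
centimorgans (1 Mb ~ 1 cM here) dates the underlying inbreeding loop to
about g = 100 / (2 L) generations ago, so 1-cM segments trace back ~50
generations.

Note: the default ``max_missing_per_window`` (50) exceeds the window size
(20 SNPs), so the missing-call gate cannot fire at the defaults; it is kept
verbatim for fidelity to the published parameterization and logged once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from conskit.io import HET, MISSING, GenotypeTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RohScanParams:
    """Parameters of the consensus scan (defaults: the published settings)."""

    window_snps: int = 20
    max_het_per_window: int = 1
    max_missing_per_window: int = 50
    min_density_bp_per_snp: int = 10_000
    min_length_bp: int = 100_000
    long_threshold_bp: int = 1_000_000
    hit_fraction_threshold: float = 0.05
    min_snps_per_segment: int = 25
    trim_ends: bool = True
    cm_per_mb: float = 1.0

    def __post_init__(self) -> None:
        if min(
            self.window_snps,
            self.min_density_bp_per_snp,
            self.min_length_bp,
            self.long_threshold_bp,
            self.min_snps_per_segment,
        ) <= 0:
            raise ValueError("scan parameters must be positive")
        if self.max_het_per_window < 0 or self.max_missing_per_window < 0:
            raise ValueError("window tolerances must be >= 0")
        if self.long_threshold_bp < self.min_length_bp:
            raise ValueError("long_threshold_bp must be >= min_length_bp")
        if self.max_missing_per_window >= self.window_snps:
            logger.info(
                "max_missing_per_window (%d) >= window_snps (%d): the missing-call gate cannot fire",
                self.max_missing_per_window,
                self.window_snps,
            )


@dataclass(frozen=True)
class RohSegment:
    """A contiguous autozygous tract (1-based inclusive coordinates)."""

    chrom: str
    start: int
    end: int
    n_snps: int
    n_het: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def classify(self, long_threshold_bp: int = 1_000_000) -> str:
        return "long" if self.length > long_threshold_bp else "short"


@dataclass(frozen=True)
class InbreedingSummary:
    """Genomic inbreeding coefficient with its short/long partition."""

    f_roh: float
    f_roh_short: float
    f_roh_long: float
    segments: tuple[RohSegment, ...]

    @property
    def f_roh_pct(self) -> float:
        return 100.0 * self.f_roh

    @property
    def f_roh_long_pct(self) -> float:
        return 100.0 * self.f_roh_long


def score_snps(pos: np.ndarray, gt: np.ndarray, params: RohScanParams) -> np.ndarray:
    """Per-SNP hit fraction: share of covering windows that pass.

    ``pos`` must be sorted ascending (one chromosome); ``gt`` is the
    individual's dosage vector (0/1/2, -1 missing) at those SNPs.
    """
    pos = np.asarray(pos)
    gt = np.asarray(gt)
    if len(pos) != len(gt):
        raise ValueError("positions and genotypes must align")
    n = len(pos)
    if n == 0:
        return np.zeros(0)
    if np.any(np.diff(pos) < 0):
        raise ValueError("SNP positions must be sorted ascending within a chromosome")
    w = min(params.window_snps, n)
    het = np.cumsum(np.concatenate([[0], (gt == HET).astype(np.int64)]))
    mis = np.cumsum(np.concatenate([[0], (gt == MISSING).astype(np.int64)]))
    n_win = n - w + 1
    win_het = het[w:] - het[:-w]
    win_mis = mis[w:] - mis[:-w]
    passing = (win_het <= params.max_het_per_window) & (win_mis <= params.max_missing_per_window)
    pass_cs = np.concatenate([[0], np.cumsum(passing.astype(np.int64))])
    i = np.arange(n)
    first = np.maximum(0, i - w + 1)
    last = np.minimum(i, n_win - 1)
    cover = last - first + 1
    hits = pass_cs[last + 1] - pass_cs[first]
    return hits / cover


def call_segments(
    pos: np.ndarray, gt: np.ndarray, params: RohScanParams, chrom: str = "chr1"
) -> list[RohSegment]:
    """Candidate runs of high-hit-fraction SNPs, gated into ROH segments."""
    pos = np.asarray(pos)
    gt = np.asarray(gt)
    scores = score_snps(pos, gt, params)
    eligible = scores >= params.hit_fraction_threshold
    segments: list[RohSegment] = []
    n = len(pos)
    i = 0
    while i < n:
        if not eligible[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and eligible[j + 1]:
            j += 1
        a, b = i, j
        if params.trim_ends:
            while a <= b and gt[a] in (HET, MISSING):
                a += 1
            while b >= a and gt[b] in (HET, MISSING):
                b -= 1
        if a <= b:
            length = int(pos[b] - pos[a] + 1)
            n_snps = b - a + 1
            dense_enough = n_snps * params.min_density_bp_per_snp >= length
            if (
                length >= params.min_length_bp
                and n_snps >= params.min_snps_per_segment
                and dense_enough
            ):
                segments.append(
                    RohSegment(
                        chrom=chrom,
                        start=int(pos[a]),
                        end=int(pos[b]),
                        n_snps=n_snps,
                        n_het=int(np.sum(gt[a : b + 1] == HET)),
                    )
                )
        i = j + 1
    return segments


def scan_individual(table: GenotypeTable, sample: str, params: RohScanParams | None = None) -> list[RohSegment]:
    """ROH segments for one individual across all chromosomes of a table."""
    params = params or RohScanParams()
    g = table.genotypes_of(sample)
    segments: list[RohSegment] = []
    for chrom in dict.fromkeys(table.chrom.tolist()):
        on = np.flatnonzero(table.chrom == chrom)
        segments.extend(call_segments(table.pos[on], g[on], params, chrom=str(chrom)))
    return segments


def _merge_overlaps(segments: Sequence[RohSegment]) -> list[RohSegment]:
    merged: list[RohSegment] = []
    for seg in sorted(segments, key=lambda s: (s.chrom, s.start)):
        if merged and seg.chrom == merged[-1].chrom and seg.start <= merged[-1].end:
            logger.warning("overlapping ROH segments merged at %s:%d", seg.chrom, seg.start)
            prev = merged.pop()
            merged.append(
                RohSegment(
                    chrom=prev.chrom,
                    start=prev.start,
                    end=max(prev.end, seg.end),
                    n_snps=prev.n_snps + seg.n_snps,
                    n_het=prev.n_het + seg.n_het,
                )
            )
        else:
            merged.append(seg)
    return merged


def froh(segments: Sequence[RohSegment], genome_length_bp: int, long_threshold_bp: int = 1_000_000) -> InbreedingSummary:
    """F_ROH = total ROH length / genome length, with exact short/long split."""
    if genome_length_bp <= 0:
        raise ValueError("genome length must be positive")
    segs = _merge_overlaps(segments)
    short_bp = sum(s.length for s in segs if s.length <= long_threshold_bp)
    long_bp = sum(s.length for s in segs if s.length > long_threshold_bp)
    f_short = short_bp / genome_length_bp
    f_long = long_bp / genome_length_bp
    # f_roh defined as the sum of the partition so the bp accounting identity
    # f_roh_short + f_roh_long == f_roh holds exactly in floating point too
    return InbreedingSummary(
        f_roh=f_short + f_long,
        f_roh_short=f_short,
        f_roh_long=f_long,
        segments=tuple(segs),
    )


def cohort_froh(
    table: GenotypeTable,
    chrom_lengths: Mapping[str, int] | None = None,
    params: RohScanParams | None = None,
    samples: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, InbreedingSummary]]:
    """Per-individual F_ROH summary over the autosomes of a cohort table."""
    params = params or RohScanParams()
    lengths = dict(chrom_lengths or table.chrom_lengths or {})
    if not lengths:
        raise ValueError("chromosome lengths are required to normalize F_ROH")
    genome = sum(lengths.values())
    names = list(samples) if samples is not None else list(table.samples)
    summaries: dict[str, InbreedingSummary] = {}
    rows = []
    for s in names:
        segs = scan_individual(table, s, params)
        summary = froh(segs, genome, params.long_threshold_bp)
        summaries[s] = summary
        rows.append(
            {
                "sample": s,
                "f_roh_pct": summary.f_roh_pct,
                "f_roh_long_pct": summary.f_roh_long_pct,
                "n_segments": len(summary.segments),
            }
        )
    return pd.DataFrame(rows), summaries


def generations_from_length(length_cm):
    """Generations since the inbreeding loop: g = 100 / (2 * length_cM).

    Accepts a scalar or array of genetic lengths in centimorgans (with the
    1 Mb ~ 1 cM approximation, pass physical Mb directly).
    """
    length_cm = np.asarray(length_cm, dtype=float)
    if np.any(length_cm <= 0):
        raise ValueError("ROH genetic length must be positive")
    g = 100.0 / (2.0 * length_cm)
    return float(g) if g.ndim == 0 else g


def overlap_fractions(
    sites: Sequence[tuple[str, int]],
    segments: Sequence[RohSegment],
    long_threshold_bp: int = 1_000_000,
) -> dict[str, float]:
    """Fractions of sites inside short ROH, long ROH, and outside any ROH."""
    sites = list(sites)
    if not sites:
        return {"short": 0.0, "long": 0.0, "outside": 0.0}
    by_chrom: dict[str, list[RohSegment]] = {}
    for seg in _merge_overlaps(segments):
        by_chrom.setdefault(seg.chrom, []).append(seg)
    n_short = n_long = 0
    for chrom, pos in sites:
        for seg in by_chrom.get(chrom, ()):
            if seg.start <= pos <= seg.end:
                if seg.length > long_threshold_bp:
                    n_long += 1
                else:
                    n_short += 1
                break
    n = len(sites)
    return {
        "short": n_short / n,
        "long": n_long / n,
        "outside": (n - n_short - n_long) / n,
    }


def segments_frame(summaries: Mapping[str, InbreedingSummary], long_threshold_bp: int = 1_000_000) -> pd.DataFrame:
    """Tidy per-individual segment table (chrom, start, end, length, class)."""
    rows = []
    for sample, summary in summaries.items():
        for seg in summary.segments:
            rows.append(
                {
                    "sample": sample,
                    "chrom": seg.chrom,
                    "start": seg.start,
                    "end": seg.end,
                    "length": seg.length,
                    "n_snps": seg.n_snps,
                    "n_het": seg.n_het,
                    "class": seg.classify(long_threshold_bp),
                }
            )
    return pd.DataFrame(rows, columns=["sample", "chrom", "start", "end", "length", "n_snps", "n_het", "class"])
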