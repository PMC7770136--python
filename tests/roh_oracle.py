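"""Brute-force enumeration oracle for the ROH consensus scan.

Deliberately naive: enumerates every window and every candidate run with
plain Python loops, independent of the vectorized implementation.
"""

from conskit.io import HET, MISSING
from conskit.roh import RohScanParams, RohSegment


def oracle_scores(pos, gt, params: RohScanParams):
    n = len(pos)
    if n == 0:
        return []
    w = min(params.window_snps, n)
    starts = list(range(0, n - w + 1))
    passing = []
    for s in starts:
        window = list(gt[s : s + w])
        n_het = sum(1 for g in window if g == HET)
        n_mis = sum(1 for g in window if g == MISSING)
        passing.append(n_het <= params.max_het_per_window and n_mis <= params.max_missing_per_window)
    scores = []
    for i in range(n):
        cover = [s for s in starts if s <= i < s + w]
        hits = sum(1 for s in cover if passing[starts.index(s)])
        scores.append(hits / len(cover))
    return scores


def oracle_segments(pos, gt, params: RohScanParams, chrom="chr1"):
    scores = oracle_scores(pos, gt, params)
    n = len(pos)
    segments = []
    i = 0
    while i < n:
        if scores[i] < params.hit_fraction_threshold:
            i += 1
            continue
        j = i
        while j + 1 < n and scores[j + 1] >= params.hit_fraction_threshold:
            j += 1
        a, b = i, j
        if params.trim_ends:
            while a <= b and gt[a] in (HET, MISSING):
                a += 1
            while b >= a and gt[b] in (HET, MISSING):
                b -= 1
        if a <= b:
            length = int(pos[b]) - int(pos[a]) + 1
            n_snps = b - a + 1
            if (
                length >= params.min_length_bp
                and n_snps >= params.min_snps_per_segment
                and n_snps * params.min_density_bp_per_snp >= length
            ):
                segments.append(
                    RohSegment(
                        chrom=chrom,
                        start=int(pos[a]),
                        end=int(pos[b]),
                        n_snps=n_snps,
                        n_het=sum(1 for g in gt[a : b + 1] if g == HET),
                    )
                )
        i = j + 1
    return segments
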