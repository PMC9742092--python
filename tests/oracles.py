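"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the package's indexed/vectorised code paths: the
classification oracle is a naive scan over every gene's windows, the Fisher
oracle enumerates the hypergeometric tail with exact integer arithmetic,
and the profile/distance oracles are direct per-base / all-pairs loops.
"""

from __future__ import annotations

import math
from math import comb

import numpy as np

PRIORITY = {
    "promoter": 6,
    "tts": 5,
    "five_prime_utr_proxy": 4,
    "three_prime_utr_proxy": 3,
    "exon": 2,
    "intron": 1,
}


def gene_windows_naive(gene, cfg):
    """Labelled windows of one gene, written as plain per-strand arithmetic."""
    ivl = gene.interval
    n = ivl.end - ivl.start
    u = min(cfg.utr_proxy, n)
    wins = []
    if ivl.strand == "-":
        tss, tes = ivl.end - 1, ivl.start
        wins.append(("promoter", tss - cfg.promoter_downstream + 1,
                     tss + cfg.promoter_upstream + 1))
        wins.append(("tts", tes - cfg.tts_downstream + 1, tes + cfg.tts_upstream + 1))
        if u:
            wins.append(("five_prime_utr_proxy", ivl.end - u, ivl.end))
            wins.append(("three_prime_utr_proxy", ivl.start, ivl.start + u))
    else:
        tss, tes = ivl.start, ivl.end - 1
        wins.append(("promoter", tss - cfg.promoter_upstream,
                     tss + cfg.promoter_downstream))
        wins.append(("tts", tes - cfg.tts_upstream, tes + cfg.tts_downstream))
        if u:
            wins.append(("five_prime_utr_proxy", ivl.start, ivl.start + u))
            wins.append(("three_prime_utr_proxy", ivl.end - u, ivl.end))
    for ex in gene.exons:
        wins.append(("exon", ex.start, ex.end))
    prev = None
    for ex in gene.exons:
        if prev is not None and ex.start > prev:
            wins.append(("intron", prev, ex.start))
        prev = ex.end
    return [(lab, s, e) for lab, s, e in wins if e > s]


def classify_position_naive(genes, cfg, chrom, pos):
    """O(genes x windows) scan; returns (label, gene_id | None)."""
    best = None
    for g in genes:
        if g.interval.chrom != chrom:
            continue
        for lab, s, e in gene_windows_naive(g, cfg):
            if s <= pos < e:
                key = (-PRIORITY[lab], g.gene_id)
                if best is None or key < best[0]:
                    best = (key, lab, g.gene_id)
    if best is None:
        return "intergenic", None
    return best[1], best[2]


def nearest_gene_naive(genes, cfg, chrom, mid):
    """Min over all genes of the strand-aware midpoint-to-TSS distance,
    with distance 0 inside the gene body or its promoter/TTS windows."""
    zero_ids = []
    cands = []
    for g in genes:
        if g.interval.chrom != chrom:
            continue
        lo, hi = g.interval.start, g.interval.end
        for lab, s, e in gene_windows_naive(g, cfg):
            if lab in ("promoter", "tts"):
                lo, hi = min(lo, s), max(hi, e)
        if lo <= mid < hi:
            zero_ids.append(g.gene_id)
        if g.interval.strand == "-":
            d = (g.interval.end - 1) - mid
        else:
            d = mid - g.interval.start
        cands.append((abs(d), g.gene_id, d))
    if zero_ids:
        return min(zero_ids), 0.0
    if not cands:
        return None, math.inf
    cands.sort()
    return cands[0][1], float(cands[0][2])


def fisher_tail_enum(a: int, b: int, c: int, d: int) -> float:
    """P(X >= a) by exact hypergeometric enumeration on the table margins."""
    M, K, n = a + b + c + d, a + c, a + b
    if M == 0:
        return 1.0
    denom = comb(M, n)
    hi = min(n, K)
    return sum(comb(K, x) * comb(M - K, n - x) for x in range(a, hi + 1)) / denom


def bh_naive(pvalues):
    """Benjamini-Hochberg step-up from its textbook definition."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        q[i] = running
    return q


def metaprofile_naive(anchor_mids, track, half_window, bin_size):
    """Per-base averaging around each anchor midpoint, then per-bin means."""
    width = 2 * half_window
    acc = np.zeros(width)
    for chrom, mid in anchor_mids:
        arr = track.get(chrom)
        for off in range(width):
            pos = mid - half_window + off
            if arr is not None and 0 <= pos < len(arr):
                acc[off] += arr[pos]
    acc /= len(anchor_mids)
    nbins = width // bin_size
    return acc.reshape(nbins, bin_size).mean(axis=1)


def distance_bins_naive(chip_intervals, clip_intervals):
    """All-pairs nearest CLIP scan per ChIP interval, binned."""
    counts = {"overlap": 0, "lt_5kb": 0, "kb5_10": 0, "gt_10kb": 0}
    for ci in chip_intervals:
        gaps = []
        hit = False
        for qi in clip_intervals:
            if qi.chrom != ci.chrom:
                continue
            if ci.start < qi.end and qi.start < ci.end:
                hit = True
                break
            gaps.append(max(qi.start - ci.end, ci.start - qi.end))
        if hit:
            counts["overlap"] += 1
        elif not gaps or min(gaps) > 10000:
            counts["gt_10kb"] += 1
        elif min(gaps) > 5000:
            counts["kb5_10"] += 1
        else:
            counts["lt_5kb"] += 1
    return counts
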