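"""Integration of the filtered DEG, splicing, ChIP and CLIP layers.

This module combines the four evidence layers into:

* a per-gene classification into DEG-only / AS-only / Both / none, with the
  Both genes further split into four direction subgroups
  (1: down + inclusion up, 2: down + inclusion down,
  3: up + inclusion up, 4: up + inclusion down);
* transcriptional targets (significant DEGs owning >= 1 ChIP peak) and
  splicing targets (significant splicing events overlapped by a surviving
  CLIP peak, collapsed to genes);
* the knockdown/differentiation overlap of each layer, with concordance
  labels (same log2FC sign = concordant);
* the final co-regulated gene set: genes that are both differentiation-
  relevant transcriptional and posttranscriptional targets;
* ChIP-to-CLIP peak distance profiles and gene-set co-occupancy (Jaccard).

A gene counts as "bound" by a ChIP peak when the peak's nearest-gene
distance is 0, i.e. the peak midpoint lies in the gene body or its
promoter/TTS window; distal-enhancer linking is out of scope.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .genome import AnnotationIndex, GenomicInterval
from .tables import ASEvent, DEGRecord, Peak

log = logging.getLogger(__name__)

__all__ = [
    "GeneClassification",
    "TargetSets",
    "DistanceProfile",
    "DISTANCE_BINS",
    "classify_genes",
    "chip_bound_genes",
    "clip_bound_genes",
    "transcriptional_targets",
    "splicing_targets",
    "differentiation_overlap",
    "co_regulated_genes",
    "jaccard",
    "chip_clip_distance_profile",
]

DISTANCE_BINS = ("overlap", "lt_5kb", "kb5_10", "gt_10kb")

#: (deg_direction, as_direction) -> subgroup number
_SUBGROUP = {
    ("down", "inclusion_up"): 1,
    ("down", "inclusion_down"): 2,
    ("up", "inclusion_up"): 3,
    ("up", "inclusion_down"): 4,
}


@dataclass(frozen=True)
class GeneClassification:
    """Membership of one gene in the DEG/AS partition plus its subgroup."""

    gene_id: str
    group: str            # DEG_only | AS_only | Both | none
    subgroup: int | None  # 1-4, only for Both genes with unmixed directions
    deg_direction: str    # up | down | none
    as_direction: str     # inclusion_up | inclusion_down | mixed | none


@dataclass(frozen=True)
class TargetSets:
    """The nested target gene sets of the integration cascade."""

    transcriptional_targets: frozenset[str]
    splicing_targets: frozenset[str]
    diff_transcriptional: frozenset[str]
    diff_splicing: frozenset[str]
    co_regulated: frozenset[str]

    def __post_init__(self) -> None:
        if not self.diff_transcriptional <= self.transcriptional_targets:
            raise ValueError("diff_transcriptional must be a subset of transcriptional_targets")
        if not self.diff_splicing <= self.splicing_targets:
            raise ValueError("diff_splicing must be a subset of splicing_targets")
        if not (
            self.co_regulated <= self.diff_transcriptional
            and self.co_regulated <= self.diff_splicing
        ):
            raise ValueError("co_regulated must be contained in both parent sets")


@dataclass(frozen=True)
class DistanceProfile:
    """ChIP-to-nearest-CLIP peak distances binned into four ranges."""

    counts: dict[str, int]     # keyed by DISTANCE_BINS
    fractions: dict[str, float]


# --------------------------------------------------------------------------
# Gene classification


def classify_genes(
    deg_sig: list[DEGRecord],
    as_sig: list[ASEvent],
    universe: list[str],
) -> list[GeneClassification]:
    """Partition genes into DEG-only / AS-only / Both / none with subgroups.

    ``deg_sig`` and ``as_sig`` are the *filtered* records/events.  A gene
    carrying significant events of both dPSI signs gets as_direction
    "mixed" and no subgroup.  The counts satisfy
    |DEG_only| + |Both| = |deg genes| and |AS_only| + |Both| = |as genes|.
    """
    deg_dir: dict[str, str] = {}
    for r in deg_sig:
        deg_dir[r.gene_id] = "up" if r.log2fc > 0 else "down"
    as_signs: dict[str, set[int]] = {}
    for ev in as_sig:
        as_signs.setdefault(ev.gene_id, set()).add(1 if ev.delta_psi > 0 else -1)

    universe_set = set(universe)
    extra = (set(deg_dir) | set(as_signs)) - universe_set
    if extra:
        log.warning(
            "classify_genes: %d significant genes absent from universe (retained)",
            len(extra),
        )
    out = []
    for gid in sorted(universe_set | set(deg_dir) | set(as_signs)):
        in_deg = gid in deg_dir
        in_as = gid in as_signs
        dd = deg_dir.get(gid, "none")
        if in_as:
            signs = as_signs[gid]
            ad = "mixed" if len(signs) > 1 else (
                "inclusion_up" if 1 in signs else "inclusion_down"
            )
        else:
            ad = "none"
        if in_deg and in_as:
            group = "Both"
            sub = _SUBGROUP.get((dd, ad))
        elif in_deg:
            group, sub = "DEG_only", None
        elif in_as:
            group, sub = "AS_only", None
        else:
            group, sub = "none", None
        out.append(GeneClassification(gid, group, sub, dd, ad))
    return out


# --------------------------------------------------------------------------
# Target sets


def chip_bound_genes(chip_peaks: list[Peak], index: AnnotationIndex) -> set[str]:
    """Genes owning >= 1 ChIP peak (nearest-gene distance 0)."""
    bound: set[str] = set()
    for p in chip_peaks:
        gid, dist = index.nearest_gene(p.interval)
        if gid is not None and dist == 0:
            bound.add(gid)
    return bound


def clip_bound_genes(clip_peaks: list[Peak], index: AnnotationIndex) -> set[str]:
    """Genes owning >= 1 CLIP peak (nearest-gene distance 0)."""
    return chip_bound_genes(clip_peaks, index)


def transcriptional_targets(
    deg_sig: list[DEGRecord],
    chip_peaks: list[Peak],
    index: AnnotationIndex,
) -> set[str]:
    """Significant DEGs that are also ChIP-bound: candidate transcriptional targets."""
    if any(p.assay != "chip" for p in chip_peaks):
        raise ValueError("transcriptional_targets: expected ChIP peaks")
    deg_genes = {r.gene_id for r in deg_sig}
    return deg_genes & chip_bound_genes(chip_peaks, index)


def splicing_targets(
    as_sig_events: list[ASEvent],
    clip_peaks_sig: list[Peak],
    window: int = 0,
) -> tuple[set[str], list[ASEvent]]:
    """Genes whose significant splicing events carry a surviving CLIP peak.

    An event matches when a filtered CLIP peak overlaps its alternative
    segment extended by ``window`` bp on each side (shared bp >= 1 under
    half-open arithmetic, so mere adjacency does not match).  Returns the
    distinct gene set and the matched events.
    """
    trees: dict[str, IntervalTree] = {}
    for p in clip_peaks_sig:
        trees.setdefault(p.interval.chrom, IntervalTree()).addi(
            p.interval.start, p.interval.end
        )
    matched: list[ASEvent] = []
    for ev in as_sig_events:
        tree = trees.get(ev.event_interval.chrom)
        if tree is None:
            continue
        lo = max(0, ev.event_interval.start - window)
        hi = ev.event_interval.end + window
        if tree.overlap(lo, hi):
            matched.append(ev)
    return {ev.gene_id for ev in matched}, matched


def differentiation_overlap(kd_layer, pma_layer, mode: str):
    """Shared members of the knockdown and differentiation contrasts.

    ``mode="genes"``: both layers are filtered DEG record lists; returns
    {gene_id: "concordant" | "discordant"} for the intersection of gene
    sets, concordant meaning identical log2FC sign in both contrasts.

    ``mode="events"``: both layers are filtered splicing event lists; the
    intersection is keyed by exact (gene_id, event_type, event interval)
    match and returned as a list of the knockdown-layer events.
    """
    if mode == "genes":
        kd_fc = {r.gene_id: r.log2fc for r in kd_layer}
        pma_fc = {r.gene_id: r.log2fc for r in pma_layer}
        shared = {}
        for gid in kd_fc.keys() & pma_fc.keys():
            same = (kd_fc[gid] > 0) == (pma_fc[gid] > 0)
            shared[gid] = "concordant" if same else "discordant"
        return shared
    if mode == "events":
        def key(ev: ASEvent):
            ivl = ev.event_interval
            return (ev.gene_id, ev.event_type, ivl.chrom, ivl.start, ivl.end)

        pma_keys = {key(ev) for ev in pma_layer}
        return [ev for ev in kd_layer if key(ev) in pma_keys]
    raise ValueError(f"unknown mode {mode!r}")


def co_regulated_genes(target_sets: TargetSets) -> set[str]:
    """Exact intersection of the differentiation-restricted target sets."""
    return set(target_sets.diff_transcriptional & target_sets.diff_splicing)


def jaccard(set_a, set_b) -> float:
    """|A intersect B| / |A union B|; 0 when both sets are empty."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


# --------------------------------------------------------------------------
# Distance profile


def _gap(a: GenomicInterval, b: GenomicInterval) -> int:
    """Edge-to-edge gap in bp; 0 when the intervals intersect or are adjacent."""
    if a.start < b.end and b.start < a.end:
        return 0
    return max(b.start - a.end, a.start - b.end)


def chip_clip_distance_profile(
    chip_peaks: list[Peak],
    clip_peaks: list[Peak],
    gene_subset: set[str] | None = None,
    index: AnnotationIndex | None = None,
) -> DistanceProfile:
    """Distance from each ChIP peak to its nearest same-chromosome CLIP peak.

    Gaps are binned into {overlap, (0, 5 kb], (5, 10] kb, > 10 kb}; an
    adjacency gap of exactly 0 bp without a shared base falls in the
    (0, 5 kb] bin.  ChIP peaks with no same-chromosome CLIP peak count as
    > 10 kb.  With ``gene_subset`` both peak sets are first restricted to
    peaks assigned (distance 0) to genes in the subset, which requires an
    annotation index.
    """
    if gene_subset is not None:
        if index is None:
            raise ValueError("gene_subset restriction requires an AnnotationIndex")

        def keep(p: Peak) -> bool:
            gid, dist = index.nearest_gene(p.interval)
            return gid in gene_subset and dist == 0

        chip_peaks = [p for p in chip_peaks if keep(p)]
        clip_peaks = [p for p in clip_peaks if keep(p)]
    if not chip_peaks:
        raise ValueError("chip_clip_distance_profile: empty ChIP peak set")

    clip_by_chrom: dict[str, list[Peak]] = {}
    for p in clip_peaks:
        clip_by_chrom.setdefault(p.interval.chrom, []).append(p)

    counts = {b: 0 for b in DISTANCE_BINS}
    for cp in chip_peaks:
        candidates = clip_by_chrom.get(cp.interval.chrom, [])
        if not candidates:
            counts["gt_10kb"] += 1
            continue
        best_overlap = False
        best_gap = math.inf
        for q in candidates:
            if cp.interval.overlaps(q.interval):
                best_overlap = True
                break
            best_gap = min(best_gap, _gap(cp.interval, q.interval))
        if best_overlap:
            counts["overlap"] += 1
        elif best_gap <= 5000:
            counts["lt_5kb"] += 1
        elif best_gap <= 10000:
            counts["kb5_10"] += 1
        else:
            counts["gt_10kb"] += 1
    n = len(chip_peaks)
    fractions = {b: counts[b] / n for b in DISTANCE_BINS}
    return DistanceProfile(counts=counts, fractions=fractions)
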