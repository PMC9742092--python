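"""Gene annotation I/O and genomic region classification.

All coordinates are handled internally as 0-based half-open intervals.
GTF input (1-based inclusive) is converted on read and back on write;
BED-family formats pass through unchanged.

Every genomic position maps to exactly one region label out of a closed
vocabulary (promoter, TTS, UTR proxies, exon, intron, intergenic) given an
annotation and a window configuration.  When windows of several genes or
several classes overlap, a fixed priority resolves the tie:

    promoter > tts > five_prime_utr_proxy > three_prime_utr_proxy
             > exon > intron > intergenic

and ties between genes are broken by lexicographically smaller gene_id.
This makes classification a pure, deterministic function, so region
percentages over a peak set always sum to 100%.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "RegionConfig",
    "REGION_LABELS",
    "REGION_PRIORITY",
    "GTFParseError",
    "read_gtf",
    "write_gtf",
    "read_bed6",
    "write_bed6",
    "region_windows",
    "AnnotationIndex",
]

#: Closed region vocabulary, ordered from highest to lowest priority
#: (intergenic is the fallback for positions in no gene and no window).
REGION_LABELS = (
    "promoter",
    "tts",
    "five_prime_utr_proxy",
    "three_prime_utr_proxy",
    "exon",
    "intron",
    "intergenic",
)

REGION_PRIORITY = {
    "promoter": 6,
    "tts": 5,
    "five_prime_utr_proxy": 4,
    "three_prime_utr_proxy": 3,
    "exon": 2,
    "intron": 1,
    "intergenic": 0,
}


class GTFParseError(ValueError):
    """Raised for malformed GTF input, naming the offending line."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A scored-format-agnostic genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): need 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """floor((start + end) / 2); the anchor used for peak classification."""
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share >= 1 bp (half-open arithmetic)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """A single-transcript gene: extent, strand-aware TSS/TES and exons.

    Introns are derived as the gaps between consecutive exons.  Exons must be
    non-overlapping, sorted by start and contained in the gene interval.
    """

    gene_id: str
    gene_name: str
    interval: GenomicInterval
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        prev_end = self.interval.start
        for ex in self.exons:
            if ex.chrom != self.interval.chrom:
                raise ValueError(f"{self.gene_id}: exon on wrong chromosome")
            if ex.start < prev_end and prev_end != self.interval.start:
                raise ValueError(f"{self.gene_id}: exons overlap or are unsorted")
            if ex.start < self.interval.start or ex.end > self.interval.end:
                raise ValueError(f"{self.gene_id}: exon outside gene interval")
            prev_end = ex.end

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        """Strand-aware transcription start: 5' end of the gene."""
        if self.strand == "-":
            return self.interval.end - 1
        return self.interval.start

    @property
    def tes(self) -> int:
        """Strand-aware transcription end: 3' end of the gene."""
        if self.strand == "-":
            return self.interval.start
        return self.interval.end - 1

    def introns(self) -> tuple[GenomicInterval, ...]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(
                    GenomicInterval(self.interval.chrom, a.end, b.start, self.strand)
                )
        return tuple(out)


@dataclass(frozen=True)
class RegionConfig:
    """Window sizes (bp) for promoter/TTS regions and the UTR proxies.

    The UTR proxies are fixed-width stretches at the transcript ends used when
    the annotation lacks explicit UTR features; set ``utr_proxy=0`` to disable.
    """

    promoter_upstream: int = 1000
    promoter_downstream: int = 100
    tts_upstream: int = 100
    tts_downstream: int = 1000
    utr_proxy: int = 200

    def __post_init__(self) -> None:
        for name in (
            "promoter_upstream",
            "promoter_downstream",
            "tts_upstream",
            "tts_downstream",
            "utr_proxy",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def region_windows(
    gene: GeneModel, cfg: RegionConfig
) -> list[tuple[int, int, str]]:
    """All labelled windows of one gene as (start, end, label), clipped at 0.

    Promoter and TTS windows are strand-aware: "upstream" means 5' of the TSS
    (respectively before the TES) in the direction of transcription.  The
    half-open windows contain every position whose signed strand-aware offset
    d from the anchor satisfies -upstream <= d < downstream.
    """
    ivl = gene.interval
    out: list[tuple[int, int, str]] = []

    def anchored(anchor: int, up: int, down: int) -> tuple[int, int]:
        if gene.strand == "-":
            # d = anchor - p in [-up, down)  =>  p in (anchor - down, anchor + up]
            return anchor - down + 1, anchor + up + 1
        return anchor - up, anchor + down

    s, e = anchored(gene.tss, cfg.promoter_upstream, cfg.promoter_downstream)
    if e > s:
        out.append((max(0, s), e, "promoter"))
    s, e = anchored(gene.tes, cfg.tts_upstream, cfg.tts_downstream)
    if e > s:
        out.append((max(0, s), e, "tts"))

    if cfg.utr_proxy > 0:
        u = min(cfg.utr_proxy, ivl.length)
        if gene.strand == "-":
            out.append((ivl.end - u, ivl.end, "five_prime_utr_proxy"))
            out.append((ivl.start, ivl.start + u, "three_prime_utr_proxy"))
        else:
            out.append((ivl.start, ivl.start + u, "five_prime_utr_proxy"))
            out.append((ivl.end - u, ivl.end, "three_prime_utr_proxy"))

    for ex in gene.exons:
        out.append((ex.start, ex.end, "exon"))
    for intron in gene.introns():
        out.append((intron.start, intron.end, "intron"))
    return out


# --------------------------------------------------------------------------
# GTF / BED I/O


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(text: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(text))


def read_gtf(path: str) -> list[GeneModel]:
    """Read an Ensembl-dialect GTF into GeneModels.

    1-based inclusive coordinates are converted to 0-based half-open.  Exons
    are grouped per ``gene_id``; a ``gene`` feature line, when present, fixes
    the gene extent (otherwise it is the exon span).  Genes are returned
    sorted by (chrom, start).
    """
    gene_extent: dict[str, GenomicInterval] = {}
    gene_name: dict[str, str] = {}
    exons: dict[str, list[GenomicInterval]] = {}

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GTFParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            try:
                start = int(start_s) - 1  # 1-based inclusive -> 0-based half-open
                end = int(end_s)
            except ValueError as exc:
                raise GTFParseError(
                    f"{path}: line {lineno}: non-integer coordinate"
                ) from exc
            if end <= start:
                raise GTFParseError(
                    f"{path}: line {lineno}: empty interval after conversion "
                    f"({start_s}-{end_s})"
                )
            attributes = _parse_attributes(attrs)
            gid = attributes.get("gene_id")
            if gid is None:
                raise GTFParseError(f"{path}: line {lineno}: missing gene_id attribute")
            if "gene_name" in attributes:
                gene_name[gid] = attributes["gene_name"]
            ivl = GenomicInterval(chrom, start, end, strand if strand in "+-" else ".")
            if feature == "gene":
                gene_extent[gid] = ivl
            elif feature == "exon":
                exons.setdefault(gid, []).append(ivl)

    genes: list[GeneModel] = []
    for gid in set(gene_extent) | set(exons):
        ex = tuple(sorted(exons.get(gid, []), key=lambda i: i.start))
        if gid in gene_extent:
            extent = gene_extent[gid]
        else:
            extent = GenomicInterval(
                ex[0].chrom, ex[0].start, max(i.end for i in ex), ex[0].strand
            )
        genes.append(GeneModel(gid, gene_name.get(gid, gid), extent, ex))
    genes.sort(key=lambda g: (g.interval.chrom, g.interval.start, g.gene_id))
    return genes


def write_gtf(genes: Iterable[GeneModel], path: str) -> None:
    """Write GeneModels back to Ensembl-dialect GTF (gene + exon features)."""
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; gene_name "{g.gene_name}";'
            ivl = g.interval
            fh.write(
                f"{ivl.chrom}\tcherbp\tgene\t{ivl.start + 1}\t{ivl.end}\t.\t"
                f"{ivl.strand}\t.\t{attrs}\n"
            )
            for ex in g.exons:
                fh.write(
                    f"{ex.chrom}\tcherbp\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                    f"{ex.strand}\t.\t{attrs}\n"
                )


def read_bed6(path: str) -> list[tuple[GenomicInterval, str, float]]:
    """Read BED6 as (interval, name, score) triples; coordinates pass through."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}: line {lineno}: expected >= 6 BED columns")
            chrom, start, end, name, score, strand = fields[:6]
            out.append(
                (
                    GenomicInterval(chrom, int(start), int(end), strand),
                    name,
                    0.0 if score == "." else float(score),
                )
            )
    return out


def write_bed6(
    records: Iterable[tuple[GenomicInterval, str, float]], path: str
) -> None:
    with open(path, "w") as fh:
        for ivl, name, score in records:
            fh.write(
                f"{ivl.chrom}\t{ivl.start}\t{ivl.end}\t{name}\t{score:g}\t{ivl.strand}\n"
            )


# --------------------------------------------------------------------------
# Annotation index


class AnnotationIndex:
    """Interval index over one annotation for position/peak classification.

    Built per run (never persisted).  Classification queries an interval tree
    of all labelled gene windows; nearest-gene queries use per-chromosome
    arrays of TSS positions and "zero-distance spans" (gene body plus
    promoter and TTS windows, which form one contiguous stretch per gene).
    """

    def __init__(self, genes: Sequence[GeneModel], cfg: RegionConfig | None = None):
        self.cfg = cfg if cfg is not None else RegionConfig()
        self.genes = sorted(genes, key=lambda g: (g.interval.chrom, g.interval.start))
        self._trees: dict[str, IntervalTree] = {}
        by_chrom: dict[str, list[GeneModel]] = {}
        for g in self.genes:
            by_chrom.setdefault(g.interval.chrom, []).append(g)
        self._nearest: dict[str, dict[str, np.ndarray]] = {}
        for chrom, glist in by_chrom.items():
            tree = IntervalTree()
            span_lo, span_hi, tss, sign, ids = [], [], [], [], []
            for g in glist:
                lo, hi = g.interval.start, g.interval.end
                for s, e, label in region_windows(g, self.cfg):
                    tree.addi(s, e, (REGION_PRIORITY[label], g.gene_id, label))
                    if label in ("promoter", "tts"):
                        lo, hi = min(lo, s), max(hi, e)
                span_lo.append(lo)
                span_hi.append(hi)
                tss.append(g.tss)
                sign.append(1 if g.strand != "-" else -1)
                ids.append(g.gene_id)
            self._trees[chrom] = tree
            self._nearest[chrom] = {
                "lo": np.asarray(span_lo),
                "hi": np.asarray(span_hi),
                "tss": np.asarray(tss),
                "sign": np.asarray(sign),
                "ids": np.asarray(ids, dtype=object),
            }

    # -- classification ---------------------------------------------------

    def classify_position(self, chrom: str, pos: int) -> tuple[str, str | None]:
        """Region label and owning gene_id (None when intergenic) at one bp.

        Pure function of (annotation, config, position): overlapping windows
        resolve by region priority then lexicographic gene_id.
        """
        tree = self._trees.get(chrom)
        if tree is None:
            log.warning("classify_position: unknown chromosome %r", chrom)
            return "intergenic", None
        hits = tree.at(pos)
        if not hits:
            return "intergenic", None
        best = min(hits, key=lambda iv: (-iv.data[0], iv.data[1]))
        _prio, gene_id, label = best.data
        return label, gene_id

    def classify_peak(self, peak: GenomicInterval) -> tuple[str, str | None]:
        """Classify a peak by its midpoint, midpoint = floor((start+end)/2)."""
        return self.classify_position(peak.chrom, peak.midpoint)

    def nearest_gene(self, peak: GenomicInterval) -> tuple[str | None, float]:
        """Nearest gene to the peak midpoint and the signed distance in bp.

        Distance is 0 when the midpoint falls in a gene body or in its
        promoter/TTS window; otherwise it is the midpoint-to-TSS offset,
        negative upstream of the TSS (strand-aware).  Ties go to the
        lexicographically smaller gene_id.
        """
        arr = self._nearest.get(peak.chrom)
        if arr is None or len(arr["tss"]) == 0:
            return None, math.inf
        mid = peak.midpoint
        inside = (mid >= arr["lo"]) & (mid < arr["hi"])
        if inside.any():
            return min(arr["ids"][inside]), 0.0
        d = (mid - arr["tss"]) * arr["sign"]
        order = np.lexsort((arr["ids"], np.abs(d)))
        k = order[0]
        return arr["ids"][k], float(d[k])
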