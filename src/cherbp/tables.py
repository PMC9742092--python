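"""Readers for differential-expression, differential-splicing and peak tables,
plus the significance filters applied to each layer.

Dialects consumed:

* DESeq2-style TSV: columns gene_id, baseMean, log2FoldChange, pvalue, padj
  ("NA" allowed in pvalue/padj).
* rMATS v4 per-event-type TSV (``SE.MATS.JC.txt``-style column names); the
  per-type coordinate columns are mapped onto the alternative segment.
* narrowPeak 10-column BED: signalValue carries the IP/input fold enrichment,
  pValue the -log10 p-value.

All inequalities in the filters are strict, exactly as typeset in the rules
they implement: a row sitting on a threshold (|dPSI| = 0.05, log2FC = 0,
fold change = 4) is excluded.  Records with missing ("NA") statistics are
excluded from filtering but counted in the totals and logged.

The dPSI sign convention is PSI(condition) - PSI(control); rMATS reports
sample1 - sample2, so the caller must declare which sample is the condition
when producing the tables.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomicInterval

log = logging.getLogger(__name__)

__all__ = [
    "DEGRecord",
    "ASEvent",
    "Peak",
    "FilterThresholds",
    "SchemaError",
    "EVENT_TYPES",
    "read_deg_table",
    "read_rmats_table",
    "read_narrowpeak",
    "write_narrowpeak",
    "filter_deg",
    "filter_as",
    "filter_clip_peaks",
    "bh_fdr",
    "DEGFilterResult",
    "ASFilterResult",
]

EVENT_TYPES = ("SE", "MXE", "A3SS", "A5SS", "RI")

#: alternative-segment coordinate columns per rMATS v4 event type
_RMATS_SEGMENT_COLS = {
    "SE": ("exonStart_0base", "exonEnd"),
    "MXE": ("1stExonStart_0base", "1stExonEnd"),
    "A3SS": ("longExonStart_0base", "longExonEnd"),
    "A5SS": ("longExonStart_0base", "longExonEnd"),
    "RI": ("riExonStart_0base", "riExonEnd"),
}


class SchemaError(ValueError):
    """A required column is missing or an input file breaks its dialect."""


@dataclass(frozen=True)
class DEGRecord:
    """One row of a DESeq2-style differential-expression table."""

    gene_id: str
    base_mean: float
    log2fc: float
    pvalue: float  # NaN when the table had "NA"
    padj: float    # NaN when missing

    def __post_init__(self) -> None:
        for name in ("pvalue", "padj"):
            v = getattr(self, name)
            if not math.isnan(v) and not (0.0 <= v <= 1.0):
                raise ValueError(f"{self.gene_id}: {name}={v} outside [0, 1]")


@dataclass(frozen=True)
class ASEvent:
    """One differential alternative-splicing event (rMATS-style row).

    ``delta_psi`` is the inclusion-level difference (dPSI), signed as
    PSI(condition) - PSI(control); ``event_interval`` covers the alternative
    segment of the event.
    """

    event_id: str
    gene_id: str
    event_type: str
    event_interval: GenomicInterval
    delta_psi: float
    pvalue: float
    fdr: float

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")
        if not math.isnan(self.delta_psi) and abs(self.delta_psi) > 1.0:
            raise ValueError(f"{self.event_id}: |delta_psi| > 1")


@dataclass(frozen=True)
class Peak:
    """A scored ChIP or CLIP peak (narrowPeak row)."""

    interval: GenomicInterval
    name: str
    score: float
    fold_enrichment: float
    neg_log10_p: float
    assay: str  # "chip" | "clip"
    summit: int = -1  # offset from start; -1 = not called

    def __post_init__(self) -> None:
        if self.assay not in ("chip", "clip"):
            raise ValueError(f"assay must be 'chip' or 'clip', got {self.assay!r}")
        if self.fold_enrichment <= 0:
            raise ValueError(f"{self.name}: fold_enrichment must be > 0")
        if self.neg_log10_p < 0:
            raise ValueError(f"{self.name}: neg_log10_p must be >= 0")


@dataclass(frozen=True)
class FilterThresholds:
    """Significance thresholds for the three layers (all inequalities strict).

    Defaults: DEGs kept at p < .05 and |log2FC| > 0 (note log2(1) = 0, i.e. no
    effective fold-change cut); splicing events at |dPSI| > .05, p < .05 and
    FDR < .1; CLIP peaks at p < 1e-3 and fold change > 4.
    """

    deg_p: float = 0.05
    deg_abs_log2fc: float = 0.0
    as_abs_dpsi: float = 0.05
    as_p: float = 0.05
    as_fdr: float = 0.1
    clip_p: float = 1e-3
    clip_fc: float = 4.0

    def __post_init__(self) -> None:
        for name in ("deg_p", "as_p", "as_fdr", "clip_p"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name}={v} outside (0, 1]")
        for name in ("deg_abs_log2fc", "as_abs_dpsi", "clip_fc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


# --------------------------------------------------------------------------
# Readers


def _require_columns(df: pd.DataFrame, required: tuple[str, ...], path: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")


def read_deg_table(path: str) -> list[DEGRecord]:
    """Read a DESeq2-style TSV; "NA" statistics become NaN, row order kept."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    _require_columns(df, ("gene_id", "baseMean", "log2FoldChange", "pvalue", "padj"), path)
    return [
        DEGRecord(
            gene_id=str(r.gene_id),
            base_mean=float(r.baseMean),
            log2fc=float(r.log2FoldChange),
            pvalue=float(r.pvalue) if pd.notna(r.pvalue) else math.nan,
            padj=float(r.padj) if pd.notna(r.padj) else math.nan,
        )
        for r in df.itertuples(index=False)
    ]


def read_rmats_table(path: str, event_type: str) -> list[ASEvent]:
    """Read one rMATS v4 per-type table into ASEvents.

    The rMATS 0-based start / 1-based-exclusive end of the type's alternative
    segment (e.g. ``exonStart_0base``/``exonEnd`` for SE) is preserved as a
    half-open interval.
    """
    if event_type not in EVENT_TYPES:
        raise ValueError(f"unknown event_type {event_type!r}")
    scol, ecol = _RMATS_SEGMENT_COLS[event_type]
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    if df.empty and not set(df.columns) >= {scol, ecol}:
        # header-only file with at least the generic columns is acceptable
        pass
    _require_columns(
        df, ("GeneID", "chr", "strand", "PValue", "FDR", "IncLevelDifference"), path
    )
    if len(df) and (scol not in df.columns or ecol not in df.columns):
        raise SchemaError(f"{path}: missing {event_type} coordinate columns {scol}/{ecol}")
    out: list[ASEvent] = []
    for i, rd in enumerate(df.to_dict("records")):
        event_id = str(rd.get("ID", f"{event_type}_{i}"))
        out.append(
            ASEvent(
                event_id=f"{event_type}:{event_id}",
                gene_id=str(rd["GeneID"]),
                event_type=event_type,
                event_interval=GenomicInterval(
                    str(rd["chr"]), int(rd[scol]), int(rd[ecol]), str(rd["strand"])
                ),
                delta_psi=float(rd["IncLevelDifference"])
                if pd.notna(rd["IncLevelDifference"])
                else math.nan,
                pvalue=float(rd["PValue"]) if pd.notna(rd["PValue"]) else math.nan,
                fdr=float(rd["FDR"]) if pd.notna(rd["FDR"]) else math.nan,
            )
        )
    return out


_NARROWPEAK_COLS = (
    "chrom", "start", "end", "name", "score",
    "strand", "signalValue", "pValue", "qValue", "peak",
)


def read_narrowpeak(path: str, assay: str) -> list[Peak]:
    """Read a 10-column narrowPeak file as ChIP or CLIP peaks.

    signalValue is the IP/input fold enrichment; pValue is -log10 p.  A
    narrowPeak convention of -1 for "not available" in pValue is mapped to 0.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] != 10:
        raise SchemaError(
            f"{path}: narrowPeak requires 10 columns, found {df.shape[1]}"
        )
    df.columns = _NARROWPEAK_COLS
    peaks = []
    for r in df.itertuples(index=False):
        nlp = float(r.pValue)
        if nlp < 0:
            log.warning("%s: peak %s has pValue < 0; treated as missing", path, r.name)
            nlp = 0.0
        peaks.append(
            Peak(
                interval=GenomicInterval(str(r.chrom), int(r.start), int(r.end), str(r.strand)),
                name=str(r.name),
                score=float(r.score),
                fold_enrichment=float(r.signalValue),
                neg_log10_p=nlp,
                assay=assay,
                summit=int(r.peak),
            )
        )
    return peaks


def write_narrowpeak(peaks: list[Peak], path: str) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            ivl = p.interval
            fh.write(
                f"{ivl.chrom}\t{ivl.start}\t{ivl.end}\t{p.name}\t{p.score:g}\t"
                f"{ivl.strand}\t{p.fold_enrichment:.6g}\t{p.neg_log10_p:.6g}\t-1\t{p.summit}\n"
            )


# --------------------------------------------------------------------------
# Filters


@dataclass(frozen=True)
class DEGFilterResult:
    kept: tuple[DEGRecord, ...]
    up: tuple[DEGRecord, ...]
    down: tuple[DEGRecord, ...]
    n_total: int
    n_missing: int


@dataclass(frozen=True)
class ASFilterResult:
    kept: tuple[ASEvent, ...]
    inclusion_up: tuple[ASEvent, ...]
    inclusion_down: tuple[ASEvent, ...]
    n_total: int
    n_missing: int


def filter_deg(
    records: list[DEGRecord], thr: FilterThresholds | None = None
) -> DEGFilterResult:
    """Keep records with pvalue < deg_p and |log2FC| > deg_abs_log2fc (strict).

    The rule is applied to the raw p-value, not padj (padj is retained for
    reporting only).  Kept records are partitioned into up (log2FC > 0) and
    down (log2FC < 0) preserving input order; under strict thresholds
    log2FC = 0 can never be kept, so the partition is complete.
    """
    thr = thr or FilterThresholds()
    kept, up, down = [], [], []
    n_missing = 0
    for r in records:
        if math.isnan(r.pvalue) or math.isnan(r.log2fc):
            n_missing += 1
            continue
        if r.pvalue < thr.deg_p and abs(r.log2fc) > thr.deg_abs_log2fc:
            kept.append(r)
            (up if r.log2fc > 0 else down).append(r)
    if n_missing:
        log.info("filter_deg: %d records with NA statistics excluded", n_missing)
    return DEGFilterResult(tuple(kept), tuple(up), tuple(down), len(records), n_missing)


def filter_as(
    events: list[ASEvent], thr: FilterThresholds | None = None
) -> ASFilterResult:
    """Keep events with |dPSI| > .05, p < .05 and FDR < .1 (all strict).

    Kept events are partitioned by inclusion direction (sign of dPSI).
    """
    thr = thr or FilterThresholds()
    kept, inc_up, inc_down = [], [], []
    n_missing = 0
    for ev in events:
        if math.isnan(ev.pvalue) or math.isnan(ev.fdr) or math.isnan(ev.delta_psi):
            n_missing += 1
            continue
        if (
            abs(ev.delta_psi) > thr.as_abs_dpsi
            and ev.pvalue < thr.as_p
            and ev.fdr < thr.as_fdr
        ):
            kept.append(ev)
            (inc_up if ev.delta_psi > 0 else inc_down).append(ev)
    if n_missing:
        log.info("filter_as: %d events with NA statistics excluded", n_missing)
    return ASFilterResult(
        tuple(kept), tuple(inc_up), tuple(inc_down), len(events), n_missing
    )


def filter_clip_peaks(
    peaks: list[Peak], thr: FilterThresholds | None = None
) -> list[Peak]:
    """Keep CLIP peaks with p < clip_p and fold enrichment > clip_fc (strict).

    With the defaults this is p < 1e-3 (neg_log10_p > 3) and fold change > 4;
    a peak at exactly fold change 4 is excluded.  Passing ChIP peaks is an
    error: the rule is specific to input-normalised CLIP scores.
    """
    thr = thr or FilterThresholds()
    bad = [p.name for p in peaks if p.assay != "clip"]
    if bad:
        raise ValueError(f"filter_clip_peaks: non-CLIP peaks passed in ({bad[:3]} ...)")
    cut = -math.log10(thr.clip_p)
    return [p for p in peaks if p.neg_log10_p > cut and p.fold_enrichment > thr.clip_fc]


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values.

    Thin wrapper over scipy's BH implementation with input validation; the
    result is monotone after sorting by p and satisfies q >= p elementwise.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("bh_fdr: p-values must lie in [0, 1]")
    return stats.false_discovery_control(p, method="bh")
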