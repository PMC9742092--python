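"""Self-consistent synthetic data bundle for exercising the whole pipeline.

The generator emits every input dialect the pipeline consumes — a toy gene
annotation (GTF), ChIP and CLIP peaks (narrowPeak), coverage tracks
(bedGraph), DESeq2-style expression tables and rMATS-style splicing tables
for a knockdown and a differentiation contrast — together with a
machine-readable truth manifest of the planted targets.

Planted structure (emulating a chromatin-enriched RBP with dual DNA/RNA
activity):

* transcriptional targets: significant DEGs in the knockdown contrast whose
  promoters carry a ChIP peak (plus uniform decoy peaks elsewhere);
* splicing targets: genes with one significant splicing event whose
  alternative segment is covered by a high-fold-change CLIP peak; decoy
  CLIP peaks get a fold change below the filter cut;
* co-regulated genes: drawn from both target pools and forced to recur in
  the differentiation contrast, so the final intersection recovers exactly
  them at zero noise;
* non-targets: p-values Uniform(0,1) with zero log2FC (respectively
  |dPSI| < .05), so every null row fails its strict filter at zero noise.

p-values are planted, not computed from simulated counts: the upstream
statistical engines are out of scope, so the generator emulates their
output contract.  With ``noise_sd > 0`` effects are perturbed
multiplicatively and planted p-values degrade with the attenuated effect,
so recovery of the planted sets decreases gradually with noise.

One seed, one bundle: identical seed and config give byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field

import numpy as np

from .genome import GeneModel, GenomicInterval, RegionConfig, region_windows, write_gtf
from .tables import EVENT_TYPES, Peak, bh_fdr, write_narrowpeak

__all__ = ["SimConfig", "TruthManifest", "ConfigError", "simulate",
           "plant_chip_peaks", "plant_clip_and_events", "BUNDLE_FILES"]


class ConfigError(ValueError):
    """Invalid or infeasible simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the synthetic study.

    Defaults describe the study conditions the whole test-suite runs under:
    a 2-chromosome, 4 Mb toy genome with 500 single-transcript genes, 40
    transcriptional and 30 splicing targets of which 10 are co-regulated,
    60% of targets recurring in the differentiation contrast, log2FC effect
    2.0, dPSI effect 0.3, CLIP fold change 8 for true peaks and 2 for
    decoys, and noiseless planted statistics (targets at p <= 1e-4, nulls
    Uniform(0,1)).
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 2_000_000
    n_genes: int = 500
    exons_per_gene: tuple[int, int] = (3, 8)
    n_trans_targets: int = 40
    n_splice_targets: int = 30
    n_co_regulated: int = 10
    pma_overlap_fraction: float = 0.6
    deg_effect: float = 2.0
    dpsi_effect: float = 0.3
    clip_fc_true: float = 8.0
    clip_fc_decoy: float = 2.0
    noise_sd: float = 0.0
    n_decoy_chip: int = 200
    n_decoy_clip: int = 300
    clip_intron_fraction: float = 0.8
    n_null_events_per_type: int = 60
    n_pma_extra_deg: int = 40
    n_pma_extra_events: int = 30
    pma_clip_cover_fraction: float = 0.4
    track_background: float = 1.0
    bump_amplitude: float = 10.0
    bump_sd: float = 150.0

    def __post_init__(self) -> None:
        if self.n_co_regulated > min(self.n_trans_targets, self.n_splice_targets):
            raise ConfigError(
                "n_co_regulated must not exceed min(n_trans_targets, n_splice_targets)"
            )
        if not (0.0 <= self.pma_overlap_fraction <= 1.0):
            raise ConfigError("pma_overlap_fraction must lie in [0, 1]")
        if not (0.0 <= self.clip_intron_fraction <= 1.0):
            raise ConfigError("clip_intron_fraction must lie in [0, 1]")
        n_distinct = (
            self.n_trans_targets + self.n_splice_targets - self.n_co_regulated
        )
        if n_distinct + self.n_pma_extra_deg > self.n_genes:
            raise ConfigError("not enough genes for the requested target counts")
        per_chrom = -(-self.n_genes // self.n_chroms)
        slot = self.chrom_length // per_chrom
        if slot < 7000:
            raise ConfigError(
                "cannot place genes without overlap; increase chrom_length or "
                "decrease n_genes"
            )

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown [simulate] keys: {sorted(unknown)}")
        if "exons_per_gene" in d:
            d = dict(d, exons_per_gene=tuple(d["exons_per_gene"]))
        return cls(**d)


#: event-type sampling weights for planted significant events,
#: skewed towards cassette exons as in real splicing catalogues
_TYPE_WEIGHTS = {"SE": 0.50, "MXE": 0.10, "A3SS": 0.15, "A5SS": 0.10, "RI": 0.15}

BUNDLE_FILES = (
    "genome.gtf",
    "chrom.sizes",
    "chip_peaks.narrowPeak",
    "clip_peaks.narrowPeak",
    "h3k27ac.bedGraph",
    "polII.bedGraph",
    "deg_kd.tsv",
    "deg_pma.tsv",
    *(f"as_kd_{t}.tsv" for t in EVENT_TYPES),
    *(f"as_pma_{t}.tsv" for t in EVENT_TYPES),
    "truth.json",
)


@dataclass
class TruthManifest:
    """Planted truth: per-gene roles, per-peak and per-event flags, and the
    downstream counts expected from them by plain set algebra."""

    roles: dict[str, dict]
    peaks: list[dict]
    events: list[dict]
    expected: dict

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str) -> "TruthManifest":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


# --------------------------------------------------------------------------
# Gene placement


def _build_genes(cfg: SimConfig, rng: np.random.Generator) -> list[GeneModel]:
    per_chrom = -(-cfg.n_genes // cfg.n_chroms)
    genes: list[GeneModel] = []
    width = len(str(cfg.n_genes))
    gi = 0
    for ci in range(cfg.n_chroms):
        chrom = f"chr{ci + 1}"
        n_here = min(per_chrom, cfg.n_genes - gi)
        slot = cfg.chrom_length // n_here
        for si in range(n_here):
            gid = f"G{gi:0{width}d}"
            start = si * slot + 2500
            max_len = slot - 5000
            lo, hi = cfg.exons_per_gene
            n_ex = int(rng.integers(lo, hi + 1))
            exon_lens = rng.integers(80, 251, size=n_ex)
            intron_lens = rng.integers(100, 501, size=n_ex - 1)
            total = int(exon_lens.sum() + intron_lens.sum())
            if total > max_len:
                # shrink introns proportionally, floor 50 bp
                budget = max_len - int(exon_lens.sum())
                scale = budget / int(intron_lens.sum())
                intron_lens = np.maximum(50, (intron_lens * scale).astype(int))
            strand = "+" if rng.random() < 0.5 else "-"
            exons = []
            pos = start
            for k in range(n_ex):
                exons.append(
                    GenomicInterval(chrom, pos, pos + int(exon_lens[k]), strand)
                )
                pos += int(exon_lens[k])
                if k < n_ex - 1:
                    pos += int(intron_lens[k])
            interval = GenomicInterval(chrom, start, exons[-1].end, strand)
            genes.append(GeneModel(gid, f"GENE{gi}", interval, tuple(exons)))
            gi += 1
    return genes


def _assign_roles(
    cfg: SimConfig, genes: list[GeneModel], rng: np.random.Generator
) -> dict[str, dict]:
    gene_ids = [g.gene_id for g in genes]
    picked = rng.choice(
        len(gene_ids),
        size=cfg.n_trans_targets + cfg.n_splice_targets - cfg.n_co_regulated,
        replace=False,
    )
    co = [gene_ids[i] for i in picked[: cfg.n_co_regulated]]
    trans_only = [
        gene_ids[i]
        for i in picked[cfg.n_co_regulated : cfg.n_trans_targets]
    ]
    splice_only = [gene_ids[i] for i in picked[cfg.n_trans_targets :]]

    roles = {
        gid: {
            "trans_target": False,
            "splice_target": False,
            "co_regulated": False,
            "pma_shared_deg": False,
            "pma_shared_as": False,
            "deg_direction": "none",
            "dpsi_sign": 0,
        }
        for gid in gene_ids
    }
    for gid in co + trans_only:
        roles[gid]["trans_target"] = True
        roles[gid]["deg_direction"] = "down" if rng.random() < 0.6 else "up"
        roles[gid]["pma_shared_deg"] = bool(rng.random() < cfg.pma_overlap_fraction)
    for gid in co + splice_only:
        roles[gid]["splice_target"] = True
        roles[gid]["dpsi_sign"] = 1 if rng.random() < 0.6 else -1
        roles[gid]["pma_shared_as"] = bool(rng.random() < cfg.pma_overlap_fraction)
    for gid in co:
        roles[gid]["co_regulated"] = True
        roles[gid]["pma_shared_deg"] = True
        roles[gid]["pma_shared_as"] = True
    return roles


# --------------------------------------------------------------------------
# Peak and event planting


def plant_chip_peaks(
    genes: list[GeneModel],
    roles: dict[str, dict],
    cfg: SimConfig,
    rng: np.random.Generator,
) -> tuple[list[Peak], list[dict]]:
    """ChIP peaks: one per transcriptional-target promoter plus uniform decoys.

    Target peaks lie fully inside the strand-aware promoter window; decoy
    peaks are uniform over the genome but avoid every target promoter window.
    Returns the peaks and their per-peak truth records.
    """
    region_cfg = RegionConfig()
    by_id = {g.gene_id: g for g in genes}
    target_windows: list[tuple[str, int, int]] = []
    peaks: list[Peak] = []
    truth: list[dict] = []
    width = 200
    for gid in sorted(roles):
        if not roles[gid]["trans_target"]:
            continue
        g = by_id[gid]
        prom = [w for w in region_windows(g, region_cfg) if w[2] == "promoter"][0]
        s, e, _ = prom
        target_windows.append((g.interval.chrom, s, e))
        start = int(rng.integers(s, e - width))
        peaks.append(
            Peak(
                interval=GenomicInterval(g.interval.chrom, start, start + width, "."),
                name=f"chip_t_{gid}",
                score=1000.0,
                fold_enrichment=float(rng.uniform(5, 20)),
                neg_log10_p=float(rng.uniform(5, 20)),
                assay="chip",
            )
        )
        truth.append(
            {"name": f"chip_t_{gid}", "assay": "chip", "true": True,
             "region": "promoter", "gene": gid}
        )

    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    dwidth = 150
    planted = 0
    while planted < cfg.n_decoy_chip:
        chrom = chroms[int(rng.integers(cfg.n_chroms))]
        start = int(rng.integers(0, cfg.chrom_length - dwidth))
        mid = start + dwidth // 2
        if any(c == chrom and s <= mid < e for c, s, e in target_windows):
            continue
        name = f"chip_d_{planted}"
        peaks.append(
            Peak(
                interval=GenomicInterval(chrom, start, start + dwidth, "."),
                name=name,
                score=200.0,
                fold_enrichment=float(rng.uniform(2, 6)),
                neg_log10_p=float(rng.uniform(2, 8)),
                assay="chip",
            )
        )
        truth.append(
            {"name": name, "assay": "chip", "true": False, "region": None, "gene": None}
        )
        planted += 1
    return peaks, truth


def _event_segment(
    g: GeneModel, etype: str, rng: np.random.Generator
) -> GenomicInterval:
    """Alternative segment of a planted event, matching the reader's mapping."""
    exons = g.exons
    introns = g.introns()
    chrom, strand = g.interval.chrom, g.strand
    if etype in ("SE", "MXE"):
        k = int(rng.integers(1, len(exons) - 1))  # internal exon
        ex = exons[k]
        return GenomicInterval(chrom, ex.start, ex.end, strand)
    if etype == "RI":
        k = int(rng.integers(0, len(introns)))
        # rMATS riExon spans flanking exon - intron - flanking exon
        return GenomicInterval(chrom, exons[k].start, exons[k + 1].end, strand)
    # A5SS / A3SS: "long exon" = exon extended into the adjacent intron
    k = int(rng.integers(0, len(introns)))
    ext = min(100, introns[k].length - 10)
    return GenomicInterval(chrom, exons[k].start, exons[k].end + max(1, ext), strand)


def _noised(effect: float, noise_sd: float, rng: np.random.Generator) -> float:
    if noise_sd == 0:
        return effect
    return effect * (1.0 + float(rng.normal(0, noise_sd)))


def _planted_p(effect: float, nominal: float, rng: np.random.Generator) -> float:
    """Planted p-value <= 1e-4 at full effect, degrading as |effect| shrinks."""
    u = float(rng.uniform(4, 8))
    atten = min(1.0, abs(effect) / abs(nominal)) if nominal else 1.0
    return min(1.0, 10.0 ** (-u * atten))


def plant_clip_and_events(
    genes: list[GeneModel],
    roles: dict[str, dict],
    cfg: SimConfig,
    rng: np.random.Generator,
) -> tuple[list[Peak], list[dict], list[dict], list[dict]]:
    """Splicing events for both contrasts plus CLIP peaks (true and decoy).

    Each splicing target gets one significant knockdown event whose
    alternative segment carries a true CLIP peak (fold change clip_fc_true);
    targets flagged pma-shared repeat the identical event in the
    differentiation contrast.  Null events get |dPSI| < .05 and uniform
    p-values; decoy CLIP peaks get fold change clip_fc_decoy so the
    downstream filter removes them.  Returns (clip peaks, kd event rows,
    pma event rows, per-event truth records).
    """
    by_id = {g.gene_id: g for g in genes}
    gene_ids = [g.gene_id for g in genes]
    types = list(_TYPE_WEIGHTS)
    weights = np.array([_TYPE_WEIGHTS[t] for t in types])
    weights = weights / weights.sum()

    clip_peaks: list[Peak] = []
    kd_rows: list[dict] = []
    pma_rows: list[dict] = []
    ev_truth: list[dict] = []
    clip_i = 0

    def add_true_clip(seg: GenomicInterval) -> str:
        nonlocal clip_i
        w = min(40, seg.length - 2)
        lo = seg.start + 1
        hi = seg.end - 1 - w
        start = int(rng.integers(lo, max(lo + 1, hi + 1)))
        fc = max(0.1, _noised(cfg.clip_fc_true, cfg.noise_sd, rng))
        name = f"clip_t_{clip_i}"
        clip_i += 1
        clip_peaks.append(
            Peak(
                interval=GenomicInterval(seg.chrom, start, start + w, "."),
                name=name,
                score=500.0,
                fold_enrichment=fc,
                neg_log10_p=float(rng.uniform(4, 8)),
                assay="clip",
            )
        )
        return name

    def event_row(gene: GeneModel, etype: str, seg: GenomicInterval,
                  dpsi: float, pval: float, eid: int) -> dict:
        return {
            "ID": eid,
            "GeneID": gene.gene_id,
            "geneSymbol": gene.gene_name,
            "chr": seg.chrom,
            "strand": gene.strand,
            "type": etype,
            "seg_start": seg.start,
            "seg_end": seg.end,
            "PValue": pval,
            "IncLevelDifference": dpsi,
        }

    eid = 0
    # --- planted significant knockdown events on splicing targets
    for gid in sorted(r for r in roles if roles[r]["splice_target"]):
        g = by_id[gid]
        etype = types[int(rng.choice(len(types), p=weights))]
        seg = _event_segment(g, etype, rng)
        sign = roles[gid]["dpsi_sign"]
        dpsi = float(np.clip(_noised(sign * cfg.dpsi_effect, cfg.noise_sd, rng), -1, 1))
        pval = _planted_p(dpsi, sign * cfg.dpsi_effect, rng)
        kd_rows.append(event_row(g, etype, seg, dpsi, pval, eid))
        peak_name = add_true_clip(seg)
        if roles[gid]["pma_shared_as"]:
            dpsi_p = float(
                np.clip(_noised(sign * cfg.dpsi_effect, cfg.noise_sd, rng), -1, 1)
            )
            pma_rows.append(
                event_row(g, etype, seg, dpsi_p, _planted_p(dpsi_p, sign * cfg.dpsi_effect, rng), eid)
            )
        ev_truth.append(
            {"event_id": eid, "gene": gid, "type": etype, "contrast": "kd",
             "significant": True, "dpsi_sign": sign, "clip_covered": True,
             "clip_peak": peak_name, "pma_shared": roles[gid]["pma_shared_as"]}
        )
        eid += 1

    # --- differentiation-only significant events on unrelated genes
    non_target = [
        gid for gid in gene_ids
        if not (roles[gid]["splice_target"] or roles[gid]["trans_target"])
    ]
    extra_idx = rng.choice(len(non_target), size=cfg.n_pma_extra_events, replace=False)
    for i in extra_idx:
        g = by_id[non_target[int(i)]]
        etype = types[int(rng.choice(len(types), p=weights))]
        seg = _event_segment(g, etype, rng)
        sign = 1 if rng.random() < 0.5 else -1
        dpsi = float(np.clip(_noised(sign * cfg.dpsi_effect, cfg.noise_sd, rng), -1, 1))
        pma_rows.append(event_row(g, etype, seg, dpsi,
                                  _planted_p(dpsi, sign * cfg.dpsi_effect, rng), eid))
        covered = bool(rng.random() < cfg.pma_clip_cover_fraction)
        peak_name = add_true_clip(seg) if covered else None
        ev_truth.append(
            {"event_id": eid, "gene": g.gene_id, "type": etype, "contrast": "pma",
             "significant": True, "dpsi_sign": sign, "clip_covered": covered,
             "clip_peak": peak_name, "pma_shared": False}
        )
        eid += 1

    # --- null events, both contrasts
    def null_dpsi() -> float:
        base = float(rng.uniform(-0.045, 0.045))
        if cfg.noise_sd > 0:
            base += float(rng.normal(0, 0.05 * cfg.noise_sd))
        return float(np.clip(base, -1, 1))

    for contrast, rows in (("kd", kd_rows), ("pma", pma_rows)):
        for etype in EVENT_TYPES:
            for _ in range(cfg.n_null_events_per_type):
                g = by_id[gene_ids[int(rng.integers(len(gene_ids)))]]
                seg = _event_segment(g, etype, rng)
                dpsi = null_dpsi()
                rows.append(
                    event_row(g, etype, seg, dpsi, float(rng.uniform()), eid)
                )
                ev_truth.append(
                    {"event_id": eid, "gene": g.gene_id, "type": etype,
                     "contrast": contrast, "significant": False,
                     "dpsi_sign": 0, "clip_covered": False, "clip_peak": None,
                     "pma_shared": False}
                )
                eid += 1

    # --- decoy CLIP peaks centred in internal gene features
    for di in range(cfg.n_decoy_clip):
        g = by_id[gene_ids[int(rng.integers(len(gene_ids)))]]
        introns = g.introns()
        use_intron = rng.random() < cfg.clip_intron_fraction and len(introns) >= 2
        if use_intron:
            feat = introns[int(rng.integers(1, len(introns)))]
            region = "intron"
        else:
            feat = g.exons[int(rng.integers(1, len(g.exons) - 1))]
            region = "exon"
        w = min(40, feat.length - 2)
        center = (feat.start + feat.end) // 2
        start = max(feat.start + 1, center - w // 2)
        fc = max(0.1, _noised(cfg.clip_fc_decoy, cfg.noise_sd, rng))
        clip_peaks.append(
            Peak(
                interval=GenomicInterval(feat.chrom, start, start + w, "."),
                name=f"clip_d_{di}",
                score=100.0,
                fold_enrichment=fc,
                neg_log10_p=float(rng.uniform(0, 6)),
                assay="clip",
            )
        )
    return clip_peaks, kd_rows, pma_rows, ev_truth


# --------------------------------------------------------------------------
# Expression tables


def _deg_table(
    cfg: SimConfig,
    genes: list[GeneModel],
    roles: dict[str, dict],
    contrast: str,
    extra_sig: set[str],
    rng: np.random.Generator,
) -> list[dict]:
    rows = []
    for g in genes:
        r = roles[g.gene_id]
        sig = (
            (r["trans_target"] and contrast == "kd")
            or (r["trans_target"] and contrast == "pma" and r["pma_shared_deg"])
            or g.gene_id in extra_sig
        )
        base_mean = float(np.exp(rng.normal(5, 1)))
        if sig:
            direction = r["deg_direction"]
            if direction == "none":  # pma-extra gene
                direction = "down" if rng.random() < 0.5 else "up"
            sign = -1 if direction == "down" else 1
            lfc = _noised(sign * cfg.deg_effect, cfg.noise_sd, rng)
            pval = _planted_p(lfc, sign * cfg.deg_effect, rng)
        else:
            lfc = 0.0 if cfg.noise_sd == 0 else float(rng.normal(0, 0.3 * cfg.noise_sd))
            pval = float(rng.uniform())
        rows.append(
            {"gene_id": g.gene_id, "baseMean": base_mean,
             "log2FoldChange": lfc, "pvalue": pval}
        )
    padj = bh_fdr([r["pvalue"] for r in rows])
    for r, q in zip(rows, padj):
        r["padj"] = float(q)
    return rows


# --------------------------------------------------------------------------
# Writers


def _write_deg(rows: list[dict], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tbaseMean\tlog2FoldChange\tpvalue\tpadj\n")
        for r in rows:
            fh.write(
                f"{r['gene_id']}\t{r['baseMean']:.6g}\t{r['log2FoldChange']:.6g}\t"
                f"{r['pvalue']:.6g}\t{r['padj']:.6g}\n"
            )


_RMATS_COORD_HEADER = {
    "SE": ("exonStart_0base", "exonEnd", "upstreamES", "upstreamEE",
           "downstreamES", "downstreamEE"),
    "MXE": ("1stExonStart_0base", "1stExonEnd", "2ndExonStart_0base", "2ndExonEnd",
            "upstreamES", "upstreamEE"),
    "A3SS": ("longExonStart_0base", "longExonEnd", "shortES", "shortEE",
             "flankingES", "flankingEE"),
    "A5SS": ("longExonStart_0base", "longExonEnd", "shortES", "shortEE",
             "flankingES", "flankingEE"),
    "RI": ("riExonStart_0base", "riExonEnd", "upstreamES", "upstreamEE",
           "downstreamES", "downstreamEE"),
}


def _write_rmats(rows: list[dict], etype: str, path: str) -> None:
    coord_cols = _RMATS_COORD_HEADER[etype]
    header = ["ID", "GeneID", "geneSymbol", "chr", "strand", *coord_cols,
              "PValue", "FDR", "IncLevelDifference"]
    sub = [r for r in rows if r["type"] == etype]
    fdr = bh_fdr([r["PValue"] for r in sub]) if sub else []
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for r, q in zip(sub, fdr):
            s, e = r["seg_start"], r["seg_end"]
            # secondary coordinate columns are synthetic filler flanks
            coords = [s, e, max(0, s - 300), max(1, s - 200), e + 200, e + 300]
            fh.write(
                f"{r['ID']}\t{r['GeneID']}\t{r['geneSymbol']}\t{r['chr']}\t"
                f"{r['strand']}\t"
                + "\t".join(str(c) for c in coords)
                + f"\t{r['PValue']:.6g}\t{q:.6g}\t{r['IncLevelDifference']:.6g}\n"
            )


def _write_tracks(
    cfg: SimConfig,
    chip_peaks: list[Peak],
    chip_truth: list[dict],
    outdir: str,
) -> None:
    """Analytic coverage: flat background plus Gaussian bumps at true peaks."""
    true_names = {t["name"] for t in chip_truth if t["true"]}
    centers = [
        (p.interval.chrom, p.interval.midpoint)
        for p in chip_peaks
        if p.name in true_names
    ]
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    step = 10
    reach = int(4 * cfg.bump_sd)
    for fname, amp in (("h3k27ac.bedGraph", cfg.bump_amplitude),
                       ("polII.bedGraph", 0.8 * cfg.bump_amplitude)):
        with open(os.path.join(outdir, fname), "w") as fh:
            for chrom in chroms:
                fh.write(f"{chrom}\t0\t{cfg.chrom_length}\t{cfg.track_background:.4g}\n")
            for chrom, center in sorted(centers):
                lo = max(0, center - reach)
                hi = min(cfg.chrom_length, center + reach)
                for s in range(lo, hi, step):
                    mid = s + step // 2
                    v = cfg.track_background + amp * math.exp(
                        -((mid - center) ** 2) / (2 * cfg.bump_sd**2)
                    )
                    fh.write(f"{chrom}\t{s}\t{min(hi, s + step)}\t{v:.5g}\n")


# --------------------------------------------------------------------------
# Expected-count bookkeeping (plain set algebra over the planted flags)


def _expected(roles: dict[str, dict], cfg: SimConfig) -> dict:
    trans = {g for g, r in roles.items() if r["trans_target"]}
    splice = {g for g, r in roles.items() if r["splice_target"]}
    both = trans & splice
    diff_trans = {g for g in trans if roles[g]["pma_shared_deg"]}
    diff_splice = {g for g in splice if roles[g]["pma_shared_as"]}
    co = diff_trans & diff_splice
    subgroup_key = {("down", 1): 1, ("down", -1): 2, ("up", 1): 3, ("up", -1): 4}
    subgroups = {1: 0, 2: 0, 3: 0, 4: 0}
    for g in both:
        k = subgroup_key[(roles[g]["deg_direction"], roles[g]["dpsi_sign"])]
        subgroups[k] += 1
    return {
        "n_deg_sig_kd_genes": len(trans),
        "n_as_sig_kd_genes": len(splice),
        "n_as_sig_kd_events": len(splice),  # one planted event per target
        "groups": {
            "DEG_only": len(trans - splice),
            "AS_only": len(splice - trans),
            "Both": len(both),
        },
        "subgroups": {str(k): v for k, v in subgroups.items()},
        "transcriptional_targets": sorted(trans),
        "splicing_targets": sorted(splice),
        "diff_transcriptional": sorted(diff_trans),
        "diff_splicing": sorted(diff_splice),
        "co_regulated": sorted(co),
    }


# --------------------------------------------------------------------------
# Entry point


def simulate(cfg: SimConfig, outdir: str) -> TruthManifest:
    """Write the complete synthetic bundle to ``outdir``; return the manifest.

    The bundle contains genome.gtf, chrom.sizes, ChIP/CLIP narrowPeak files,
    two bedGraph coverage tracks, DEG tables and per-type splicing tables
    for the knockdown and differentiation contrasts, and truth.json.
    """
    os.makedirs(outdir, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    genes = _build_genes(cfg, rng)
    roles = _assign_roles(cfg, genes, rng)

    write_gtf(genes, os.path.join(outdir, "genome.gtf"))
    with open(os.path.join(outdir, "chrom.sizes"), "w") as fh:
        for i in range(cfg.n_chroms):
            fh.write(f"chr{i + 1}\t{cfg.chrom_length}\n")

    chip_peaks, chip_truth = plant_chip_peaks(genes, roles, cfg, rng)
    write_narrowpeak(chip_peaks, os.path.join(outdir, "chip_peaks.narrowPeak"))

    clip_peaks, kd_rows, pma_rows, ev_truth = plant_clip_and_events(
        genes, roles, cfg, rng
    )
    write_narrowpeak(clip_peaks, os.path.join(outdir, "clip_peaks.narrowPeak"))
    for etype in EVENT_TYPES:
        _write_rmats(kd_rows, etype, os.path.join(outdir, f"as_kd_{etype}.tsv"))
        _write_rmats(pma_rows, etype, os.path.join(outdir, f"as_pma_{etype}.tsv"))

    non_target = [
        g.gene_id for g in genes
        if not (roles[g.gene_id]["trans_target"] or roles[g.gene_id]["splice_target"])
    ]
    extra_idx = rng.choice(len(non_target), size=cfg.n_pma_extra_deg, replace=False)
    pma_extra = {non_target[int(i)] for i in extra_idx}
    _write_deg(_deg_table(cfg, genes, roles, "kd", set(), rng),
               os.path.join(outdir, "deg_kd.tsv"))
    _write_deg(_deg_table(cfg, genes, roles, "pma", pma_extra, rng),
               os.path.join(outdir, "deg_pma.tsv"))

    _write_tracks(cfg, chip_peaks, chip_truth, outdir)

    clip_truth = [
        {"name": p.name, "assay": "clip", "true": p.name.startswith("clip_t_"),
         "region": None, "gene": None}
        for p in clip_peaks
    ]
    manifest = TruthManifest(
        roles=roles,
        peaks=chip_truth + clip_truth,
        events=ev_truth,
        expected=_expected(roles, cfg),
    )
    manifest.to_json(os.path.join(outdir, "truth.json"))
    return manifest
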