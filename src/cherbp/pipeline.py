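"""End-to-end assembly of the integration report from an input bundle.

The report is a pure function of the inputs and configuration: every number
in it is produced by exactly one module operation (the assembly here only
formats, it never recomputes), and serialising it twice on the same inputs
yields byte-identical JSON.

Report keys are namespaced by the analysis they correspond to
(e.g. ``region_enrichment``, ``groups``, ``distance_profiles``) so each
section is traceable to one operation.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass

from .enrichment import (
    clip_region_enrichment,
    genome_region_composition,
    metaprofile,
    read_bedgraph,
    read_chrom_sizes,
    region_enrichment,
)
from .genome import AnnotationIndex, RegionConfig, read_gtf, write_bed6
from .integration import (
    DISTANCE_BINS,
    TargetSets,
    chip_bound_genes,
    chip_clip_distance_profile,
    classify_genes,
    clip_bound_genes,
    co_regulated_genes,
    differentiation_overlap,
    jaccard,
    splicing_targets,
    transcriptional_targets,
)
from .tables import (
    EVENT_TYPES,
    FilterThresholds,
    filter_as,
    filter_clip_peaks,
    filter_deg,
    read_deg_table,
    read_narrowpeak,
    read_rmats_table,
)

log = logging.getLogger(__name__)

__all__ = ["Bundle", "load_bundle", "run_analysis", "write_report"]


@dataclass
class Bundle:
    """Parsed inputs of one run; optional layers are None when absent."""

    genes: list
    chrom_sizes: dict
    chip_peaks: list
    clip_peaks: list | None
    deg_kd: list
    deg_pma: list | None
    as_kd: list
    as_pma: list | None
    track_paths: dict[str, str]


def load_bundle(directory: str) -> Bundle:
    """Load a bundle laid out with the generator's file names.

    ``deg_pma.tsv``, the ``as_pma_*`` tables and ``clip_peaks.narrowPeak``
    are optional; sections depending on them are skipped downstream.
    """
    def p(name: str) -> str:
        return os.path.join(directory, name)

    def opt(name: str) -> str | None:
        return p(name) if os.path.exists(p(name)) else None

    genes = read_gtf(p("genome.gtf"))
    chrom_sizes = read_chrom_sizes(p("chrom.sizes"))
    chip = read_narrowpeak(p("chip_peaks.narrowPeak"), assay="chip")
    clip = (
        read_narrowpeak(p("clip_peaks.narrowPeak"), assay="clip")
        if opt("clip_peaks.narrowPeak")
        else None
    )
    deg_kd = read_deg_table(p("deg_kd.tsv"))
    deg_pma = read_deg_table(p("deg_pma.tsv")) if opt("deg_pma.tsv") else None

    def read_as(prefix: str):
        events = []
        found = False
        for etype in EVENT_TYPES:
            path = opt(f"{prefix}_{etype}.tsv")
            if path:
                found = True
                events.extend(read_rmats_table(path, etype))
        return events if found else None

    as_kd = read_as("as_kd") or []
    as_pma = read_as("as_pma")
    tracks = {
        name: p(fname)
        for name, fname in (("h3k27ac", "h3k27ac.bedGraph"), ("polII", "polII.bedGraph"))
        if opt(fname)
    }
    return Bundle(genes, chrom_sizes, chip, clip, deg_kd, deg_pma, as_kd, as_pma, tracks)


def _enrichment_rows(results) -> list[dict]:
    return [
        {
            "region": r.region,
            "n_peaks_in": r.n_peaks_in,
            "genome_fraction": round(r.genome_fraction, 10),
            "peak_fraction": round(r.peak_fraction, 10),
            "enrichment_ratio": round(r.enrichment_ratio, 6)
            if r.enrichment_ratio != float("inf")
            else "inf",
            "pvalue": float(f"{r.pvalue:.6g}"),
        }
        for r in results
    ]


def run_analysis(
    bundle: Bundle,
    thresholds: FilterThresholds | None = None,
    region_cfg: RegionConfig | None = None,
    compute_profiles: bool = True,
) -> dict:
    """Run the full integration cascade and return the report dictionary.

    Layers absent from the bundle (CLIP peaks, differentiation contrast)
    make their sections come out as ``"empty"`` / absent; the run continues.
    With ``compute_profiles=False`` the coverage-track metaprofiles are
    skipped (they are irrelevant to target recovery).
    """
    thr = thresholds or FilterThresholds()
    cfg = region_cfg or RegionConfig()
    index = AnnotationIndex(bundle.genes, cfg)
    universe = [r.gene_id for r in bundle.deg_kd]

    # --- layer filters
    deg_kd = filter_deg(bundle.deg_kd, thr)
    as_kd = filter_as(bundle.as_kd, thr)
    clip_sig = filter_clip_peaks(bundle.clip_peaks, thr) if bundle.clip_peaks else None
    deg_pma = filter_deg(bundle.deg_pma, thr) if bundle.deg_pma is not None else None
    as_pma = filter_as(bundle.as_pma, thr) if bundle.as_pma is not None else None

    report: dict = {
        "filters": {
            "deg_kd": {"total": deg_kd.n_total, "significant": len(deg_kd.kept),
                       "up": len(deg_kd.up), "down": len(deg_kd.down)},
            "as_kd": {"total": as_kd.n_total, "significant": len(as_kd.kept),
                      "inclusion_up": len(as_kd.inclusion_up),
                      "inclusion_down": len(as_kd.inclusion_down),
                      "significant_genes": len({e.gene_id for e in as_kd.kept}),
                      "by_type": {
                          t: sum(1 for e in as_kd.kept if e.event_type == t)
                          for t in EVENT_TYPES
                      }},
            "chip_peaks": {"total": len(bundle.chip_peaks)},
        }
    }
    if clip_sig is not None:
        report["filters"]["clip_peaks"] = {
            "total": len(bundle.clip_peaks), "significant": len(clip_sig)
        }
    if deg_pma is not None:
        report["filters"]["deg_pma"] = {
            "total": deg_pma.n_total, "significant": len(deg_pma.kept),
            "up": len(deg_pma.up), "down": len(deg_pma.down),
        }
    if as_pma is not None:
        report["filters"]["as_pma"] = {
            "total": as_pma.n_total, "significant": len(as_pma.kept),
            "significant_genes": len({e.gene_id for e in as_pma.kept}),
        }

    # --- region composition / enrichment (ChIP vs genome, CLIP by region)
    composition = genome_region_composition(bundle.genes, cfg, bundle.chrom_sizes)
    report["genome_composition"] = {k: round(v, 10) for k, v in composition.items()}
    if bundle.chip_peaks:
        report["region_enrichment"] = _enrichment_rows(
            region_enrichment(bundle.chip_peaks, index, cfg, bundle.chrom_sizes)
        )
    if clip_sig:
        report["clip_region_enrichment"] = [
            {"region": r.region, "n_peaks": r.n_peaks,
             "count_fraction": round(r.count_fraction, 10),
             "mean_fold_enrichment": round(r.mean_fold_enrichment, 6),
             "mean_log2_fc": round(r.mean_log2_fc, 6)}
            for r in clip_region_enrichment(clip_sig, index, cfg)
        ]

    # --- metaprofiles around ChIP peaks
    if compute_profiles and bundle.track_paths and bundle.chip_peaks:
        report["metaprofiles"] = {}
        for name, path in sorted(bundle.track_paths.items()):
            track = read_bedgraph(path, bundle.chrom_sizes)
            prof = metaprofile(bundle.chip_peaks, track)
            report["metaprofiles"][name] = {
                "offsets": [float(o) for o in prof.offsets],
                "mean_depth": [float(f"{v:.6g}") for v in prof.mean_depth],
                "n_anchors": prof.n_anchors,
            }

    # --- gene classification (DEG-only / AS-only / Both) + subgroups
    classifications = classify_genes(list(deg_kd.kept), list(as_kd.kept), universe)
    group_counts = {g: 0 for g in ("DEG_only", "AS_only", "Both", "none")}
    subgroup_counts = {str(k): 0 for k in (1, 2, 3, 4)}
    for c in classifications:
        group_counts[c.group] += 1
        if c.subgroup is not None:
            subgroup_counts[str(c.subgroup)] += 1
    report["groups"] = group_counts
    report["subgroups"] = subgroup_counts

    # --- target sets
    trans = transcriptional_targets(list(deg_kd.kept), bundle.chip_peaks, index)
    report["transcriptional_targets"] = {"n": len(trans), "genes": sorted(trans)}

    splice_genes: set = set()
    matched_events: list = []
    if clip_sig is not None:
        splice_genes, matched_events = splicing_targets(list(as_kd.kept), clip_sig)
        report["splicing_targets"] = {
            "n": len(splice_genes),
            "genes": sorted(splice_genes),
            "n_matched_events": len(matched_events),
        }
    else:
        report["splicing_targets"] = "empty"
        log.info("CLIP layer absent: splicing sections skipped")

    # --- co-occupancy (Jaccard) and peak distance profiles per group
    bound_chip = chip_bound_genes(bundle.chip_peaks, index)
    group_of = {c.gene_id: c.group for c in classifications}
    if clip_sig is not None:
        bound_clip = clip_bound_genes(clip_sig, index)
        report["jaccard"] = {}
        report["distance_profiles"] = {}
        for gname in ("Total", "DEG_only", "AS_only", "Both"):
            if gname == "Total":
                sub_chip, sub_clip = bound_chip, bound_clip
                subset = None
            else:
                members = {g for g, grp in group_of.items() if grp == gname}
                sub_chip = bound_chip & members
                sub_clip = bound_clip & members
                subset = members
            report["jaccard"][gname] = {
                "jaccard": round(jaccard(sub_chip, sub_clip), 6),
                "n_chip_genes": len(sub_chip),
                "n_clip_genes": len(sub_clip),
                "n_co_occupied": len(sub_chip & sub_clip),
            }
            try:
                prof = chip_clip_distance_profile(
                    bundle.chip_peaks, clip_sig, gene_subset=subset, index=index
                )
                report["distance_profiles"][gname] = {
                    "counts": prof.counts,
                    "fractions": {b: round(prof.fractions[b], 6) for b in DISTANCE_BINS},
                }
            except ValueError:
                report["distance_profiles"][gname] = "empty"

    # --- differentiation overlap and the final co-regulated set
    if deg_pma is not None:
        shared = differentiation_overlap(list(deg_kd.kept), list(deg_pma.kept), "genes")
        concordant = {g for g, lab in shared.items() if lab == "concordant"}
        report["differentiation_deg_overlap"] = {
            "shared": len(shared),
            "concordant": len(concordant),
            "discordant": len(shared) - len(concordant),
        }
        diff_trans = trans & set(shared)
        report["diff_transcriptional_targets"] = {
            "n": len(diff_trans), "genes": sorted(diff_trans)
        }
    else:
        diff_trans = None
        log.info("differentiation DEG contrast absent: transcriptional cascade skipped")

    if as_pma is not None and clip_sig is not None:
        shared_events = differentiation_overlap(list(as_kd.kept), list(as_pma.kept), "events")
        shared_keys = {
            (e.gene_id, e.event_type, e.event_interval.chrom,
             e.event_interval.start, e.event_interval.end)
            for e in shared_events
        }
        diff_splice = {
            e.gene_id
            for e in matched_events
            if (e.gene_id, e.event_type, e.event_interval.chrom,
                e.event_interval.start, e.event_interval.end) in shared_keys
        }
        report["differentiation_as_overlap"] = {"shared_events": len(shared_events)}
        report["diff_splicing_targets"] = {
            "n": len(diff_splice), "genes": sorted(diff_splice)
        }
    else:
        diff_splice = None

    if diff_trans is not None and diff_splice is not None:
        ts = TargetSets(
            transcriptional_targets=frozenset(trans),
            splicing_targets=frozenset(splice_genes),
            diff_transcriptional=frozenset(diff_trans),
            diff_splicing=frozenset(diff_splice),
            co_regulated=frozenset(diff_trans & diff_splice),
        )
        co = co_regulated_genes(ts)
        report["co_regulated"] = {"n": len(co), "genes": sorted(co)}
    else:
        report["co_regulated"] = "empty"

    return report


def write_report(report: dict, outdir: str, bundle: Bundle | None = None) -> str:
    """Write report.json plus flat-text side outputs; returns the JSON path."""
    os.makedirs(outdir, exist_ok=True)
    path = os.path.join(outdir, "report.json")
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    for key in ("transcriptional_targets", "splicing_targets",
                "diff_transcriptional_targets", "diff_splicing_targets",
                "co_regulated"):
        section = report.get(key)
        if isinstance(section, dict) and "genes" in section:
            with open(os.path.join(outdir, f"{key}.txt"), "w") as fh:
                for g in section["genes"]:
                    fh.write(g + "\n")
    return path
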