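import math

import numpy as np
import pytest

from cherbp.genome import GenomicInterval
from cherbp.tables import (
    ASEvent,
    DEGRecord,
    EVENT_TYPES,
    FilterThresholds,
    Peak,
    SchemaError,
    bh_fdr,
    filter_as,
    filter_clip_peaks,
    filter_deg,
    read_deg_table,
    read_narrowpeak,
    read_rmats_table,
    write_narrowpeak,
)
from oracles import bh_naive


def mk_deg(gene, lfc, p, padj=0.5):
    return DEGRecord(gene, 100.0, lfc, p, padj)


def mk_event(eid, gene, dpsi, p, fdr, etype="SE"):
    return ASEvent(eid, gene, etype, GenomicInterval("chr1", 100, 200, "+"), dpsi, p, fdr)


def mk_clip(name, fc, nlp):
    return Peak(GenomicInterval("chr1", 0, 50), name, 0.0, fc, nlp, "clip")


class TestDEGReader:
    def test_parses_row_and_na_padj(self, tmp_path):
        p = tmp_path / "deg.tsv"
        p.write_text(
            "gene_id\tbaseMean\tlog2FoldChange\tpvalue\tpadj\n"
            "g1\t100.0\t1.5\t0.001\t0.01\n"
            "g2\t50.0\t-0.2\t0.9\tNA\n"
        )
        recs = read_deg_table(str(p))
        assert recs[0] == DEGRecord("g1", 100.0, 1.5, 0.001, 0.01)
        assert recs[1].gene_id == "g2" and math.isnan(recs[1].padj)

    def test_missing_column_names_it(self, tmp_path):
        p = tmp_path / "deg.tsv"
        p.write_text("gene_id\tbaseMean\tlog2FoldChange\tpvalue\ng1\t1\t1\t0.5\n")
        with pytest.raises(SchemaError, match="padj"):
            read_deg_table(str(p))


class TestRmatsReader:
    HEADERS = {
        "SE": "exonStart_0base\texonEnd",
        "MXE": "1stExonStart_0base\t1stExonEnd",
        "A3SS": "longExonStart_0base\tlongExonEnd",
        "A5SS": "longExonStart_0base\tlongExonEnd",
        "RI": "riExonStart_0base\triExonEnd",
    }

    @pytest.mark.parametrize("etype", EVENT_TYPES)
    def test_segment_column_mapping(self, tmp_path, etype):
        p = tmp_path / f"{etype}.tsv"
        p.write_text(
            f"ID\tGeneID\tchr\tstrand\t{self.HEADERS[etype]}\tPValue\tFDR\tIncLevelDifference\n"
            "1\tg1\tchr1\t+\t100\t200\t0.001\t0.01\t-0.3\n"
        )
        (ev,) = read_rmats_table(str(p), etype)
        assert ev.event_type == etype
        assert (ev.event_interval.start, ev.event_interval.end) == (100, 200)
        assert ev.delta_psi == -0.3 and ev.gene_id == "g1"

    def test_header_only_file(self, tmp_path):
        p = tmp_path / "se.tsv"
        p.write_text(
            "ID\tGeneID\tchr\tstrand\texonStart_0base\texonEnd\tPValue\tFDR\tIncLevelDifference\n"
        )
        assert read_rmats_table(str(p), "SE") == []

    def test_unknown_event_type(self, tmp_path):
        with pytest.raises(ValueError, match="event_type"):
            read_rmats_table(str(tmp_path / "x.tsv"), "XX")

    def test_missing_coordinate_columns(self, tmp_path):
        p = tmp_path / "se.tsv"
        p.write_text(
            "ID\tGeneID\tchr\tstrand\tPValue\tFDR\tIncLevelDifference\n"
            "1\tg1\tchr1\t+\t0.5\t0.5\t0.0\n"
        )
        with pytest.raises(SchemaError, match="coordinate"):
            read_rmats_table(str(p), "SE")

    def test_simulated_tables_match_manifest(self, default_bundle):
        outdir, cfg, manifest = default_bundle
        truth_kd_sig = [
            e for e in manifest.events if e["contrast"] == "kd" and e["significant"]
        ]
        per_type_truth = {t: 0 for t in EVENT_TYPES}
        for e in truth_kd_sig:
            per_type_truth[e["type"]] += 1
        for etype in EVENT_TYPES:
            events = read_rmats_table(f"{outdir}/as_kd_{etype}.tsv", etype)
            n_truth = per_type_truth[etype] + cfg.n_null_events_per_type
            assert len(events) == n_truth


class TestNarrowPeak:
    def test_roundtrip(self, tmp_path):
        peaks = [
            Peak(GenomicInterval("chr1", 10, 60, "."), "p1", 100.0, 8.0, 5.0, "chip", 25),
        ]
        path = tmp_path / "x.narrowPeak"
        write_narrowpeak(peaks, str(path))
        assert read_narrowpeak(str(path), "chip") == peaks

    def test_wrong_column_count(self, tmp_path):
        p = tmp_path / "bad.narrowPeak"
        p.write_text("chr1\t0\t100\tp1\t0\t.\t5.0\t3.0\t-1\n")  # 9 columns
        with pytest.raises(SchemaError, match="10 columns"):
            read_narrowpeak(str(p), "chip")


class TestFilterDEG:
    def test_zero_log2fc_excluded_even_when_significant(self):
        res = filter_deg([mk_deg("g", 0.0, 0.001)])
        assert res.kept == ()

    def test_partition_by_direction(self):
        res = filter_deg([mk_deg("a", -2.0, 0.01), mk_deg("b", 0.5, 0.02)])
        assert [r.gene_id for r in res.down] == ["a"]
        assert [r.gene_id for r in res.up] == ["b"]
        assert set(res.kept) == set(res.up) | set(res.down)

    def test_na_pvalue_counted_but_not_filtered(self):
        res = filter_deg([mk_deg("g", 2.0, math.nan)])
        assert res.kept == () and res.n_missing == 1 and res.n_total == 1

    def test_matches_bruteforce_scan(self):
        rng = np.random.default_rng(11)
        recs = [
            mk_deg(f"g{i}", float(rng.normal(0, 1.5)), float(rng.uniform()))
            for i in range(1000)
        ]
        thr = FilterThresholds()
        res = filter_deg(recs, thr)
        brute = [r for r in recs if r.pvalue < 0.05 and abs(r.log2fc) > 0.0]
        assert list(res.kept) == brute

    def test_order_independent(self):
        rng = np.random.default_rng(5)
        recs = [mk_deg(f"g{i}", float(rng.normal()), float(rng.uniform())) for i in range(200)]
        kept1 = {r.gene_id for r in filter_deg(recs).kept}
        kept2 = {r.gene_id for r in filter_deg(recs[::-1]).kept}
        assert kept1 == kept2


class TestFilterAS:
    def test_boundary_dpsi_excluded(self):
        res = filter_as([mk_event("e", "g", 0.05, 0.001, 0.01)])
        assert res.kept == ()

    def test_kept_inclusion_up(self):
        res = filter_as([mk_event("e", "g", 0.2, 0.01, 0.05)])
        assert [e.event_id for e in res.inclusion_up] == ["e"]

    def test_matches_bruteforce_scan(self):
        rng = np.random.default_rng(12)
        evs = [
            mk_event(f"e{i}", f"g{i}", float(rng.uniform(-0.5, 0.5)),
                     float(rng.uniform()), float(rng.uniform()))
            for i in range(1000)
        ]
        res = filter_as(evs)
        brute = [
            e for e in evs
            if abs(e.delta_psi) > 0.05 and e.pvalue < 0.05 and e.fdr < 0.1
        ]
        assert list(res.kept) == brute

    def test_relaxing_threshold_never_shrinks(self):
        rng = np.random.default_rng(13)
        evs = [
            mk_event(f"e{i}", f"g{i}", float(rng.uniform(-0.5, 0.5)),
                     float(rng.uniform()), float(rng.uniform()))
            for i in range(300)
        ]
        strict = {e.event_id for e in filter_as(evs, FilterThresholds()).kept}
        for relaxed in (
            FilterThresholds(as_abs_dpsi=0.01),
            FilterThresholds(as_p=0.2),
            FilterThresholds(as_fdr=0.5),
        ):
            loose = {e.event_id for e in filter_as(evs, relaxed).kept}
            assert strict <= loose


class TestFilterClip:
    def test_boundary_fold_change_excluded(self):
        assert filter_clip_peaks([mk_clip("p", 4.0, 6.0)]) == []

    def test_kept(self):
        p = mk_clip("p", 8.0, 5.0)
        assert filter_clip_peaks([p]) == [p]

    def test_chip_peaks_rejected(self):
        chip = Peak(GenomicInterval("chr1", 0, 50), "c", 0.0, 8.0, 5.0, "chip")
        with pytest.raises(ValueError, match="non-CLIP"):
            filter_clip_peaks([chip])

    def test_matches_bruteforce_scan(self):
        rng = np.random.default_rng(14)
        peaks = [
            mk_clip(f"p{i}", float(rng.uniform(0.5, 10)), float(rng.uniform(0, 8)))
            for i in range(1000)
        ]
        brute = [p for p in peaks if 10 ** -p.neg_log10_p < 1e-3 and p.fold_enrichment > 4]
        assert filter_clip_peaks(peaks) == brute


class TestBH:
    def test_small_example(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_value(self):
        assert bh_fdr([0.5]) == pytest.approx([0.5])

    def test_matches_step_up_definition(self):
        rng = np.random.default_rng(15)
        p = rng.uniform(size=200)
        assert np.allclose(bh_fdr(p), bh_naive(p))

    def test_q_at_least_p(self):
        rng = np.random.default_rng(16)
        p = rng.uniform(size=100)
        assert np.all(bh_fdr(p) >= p)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, 1.5])
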