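import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cherbp.genome import AnnotationIndex, GenomicInterval
from cherbp.integration import (
    DISTANCE_BINS,
    TargetSets,
    chip_clip_distance_profile,
    classify_genes,
    co_regulated_genes,
    differentiation_overlap,
    jaccard,
    splicing_targets,
    transcriptional_targets,
)
from cherbp.tables import ASEvent, DEGRecord, Peak
from oracles import distance_bins_naive


def deg(gene, lfc, p=0.001):
    return DEGRecord(gene, 100.0, lfc, p, p)


def event(gene, dpsi, start=100, end=None, etype="SE", chrom="chr1"):
    end = end if end is not None else start + 100
    return ASEvent(
        f"{etype}:{gene}:{start}", gene, etype,
        GenomicInterval(chrom, start, end, "+"), dpsi, 0.001, 0.01,
    )


def peak(chrom, start, end, assay="clip", fc=8.0):
    return Peak(GenomicInterval(chrom, start, end), f"{assay}{start}", 0.0, fc, 5.0, assay)


class TestClassifyGenes:
    def test_three_group_partition_with_subgroup(self):
        res = {
            c.gene_id: c
            for c in classify_genes(
                [deg("A", -2.0), deg("B", -1.0)],
                [event("B", 0.3), event("C", -0.2)],
                ["A", "B", "C", "D"],
            )
        }
        assert res["A"].group == "DEG_only" and res["A"].subgroup is None
        assert res["B"].group == "Both" and res["B"].subgroup == 1
        assert res["C"].group == "AS_only"
        assert res["D"].group == "none"

    @pytest.mark.parametrize(
        "lfc,dpsi,expected",
        [(-1, 0.3, 1), (-1, -0.3, 2), (1, 0.3, 3), (1, -0.3, 4)],
    )
    def test_subgroup_mapping(self, lfc, dpsi, expected):
        (c,) = classify_genes([deg("G", lfc)], [event("G", dpsi)], ["G"])
        assert c.subgroup == expected

    def test_mixed_inclusion_signs_have_no_subgroup(self):
        (c,) = classify_genes(
            [deg("G", -1.0)],
            [event("G", 0.3, start=100), event("G", -0.3, start=500)],
            ["G"],
        )
        assert c.as_direction == "mixed" and c.subgroup is None

    def test_disjoint_sets_give_no_both(self):
        res = classify_genes([deg("A", 1.0)], [event("B", 0.3)], ["A", "B"])
        assert all(c.group != "Both" for c in res)

    def test_partition_identities_random(self):
        rng = np.random.default_rng(21)
        universe = [f"g{i}" for i in range(100)]
        degs = [deg(g, float(rng.choice([-2, 2]))) for g in rng.choice(universe, 30, replace=False)]
        evs = [event(g, float(rng.choice([-0.3, 0.3]))) for g in rng.choice(universe, 40, replace=False)]
        res = classify_genes(degs, evs, universe)
        n = {g: 0 for g in ("DEG_only", "AS_only", "Both", "none")}
        for c in res:
            n[c.group] += 1
        assert n["DEG_only"] + n["Both"] == len({d.gene_id for d in degs})
        assert n["AS_only"] + n["Both"] == len({e.gene_id for e in evs})


class TestTargets:
    def test_promoter_peak_intersects_deg(self, toy_genes, region_cfg):
        index = AnnotationIndex(toy_genes, region_cfg)
        chip = [peak("chr1", 4400, 4600, assay="chip")]  # gplus promoter
        assert transcriptional_targets(
            [deg("gplus", -2.0), deg("gother", 1.0)], chip, index
        ) == {"gplus"}

    def test_no_peaks_no_targets(self, toy_genes, region_cfg):
        index = AnnotationIndex(toy_genes, region_cfg)
        assert transcriptional_targets([deg("gplus", 1.0)], [], index) == set()

    def test_clip_peaks_rejected_for_transcriptional(self, toy_genes, region_cfg):
        index = AnnotationIndex(toy_genes, region_cfg)
        with pytest.raises(ValueError):
            transcriptional_targets([deg("gplus", 1.0)], [peak("chr1", 0, 10)], index)

    def test_event_overlap_matches(self):
        genes, matched = splicing_targets([event("g", 0.3)], [peak("chr1", 150, 160)])
        assert genes == {"g"} and len(matched) == 1

    def test_half_open_adjacency_does_not_match(self):
        genes, matched = splicing_targets([event("g", 0.3)], [peak("chr1", 200, 300)])
        assert genes == set() and matched == []

    def test_window_extension_recovers_adjacent_peak(self):
        genes, _ = splicing_targets([event("g", 0.3)], [peak("chr1", 200, 300)], window=1)
        assert genes == {"g"}


class TestDifferentiationOverlap:
    def test_gene_mode_concordance(self):
        shared = differentiation_overlap(
            [deg("A", -1.0), deg("B", 2.0)],
            [deg("A", -0.5), deg("B", -1.0)],
            "genes",
        )
        assert shared == {"A": "concordant", "B": "discordant"}

    def test_empty_layer_empty_overlap(self):
        assert differentiation_overlap([deg("A", 1.0)], [], "genes") == {}

    def test_event_mode_requires_exact_coordinates(self):
        kd = [event("g", 0.3, start=100), event("g", 0.3, start=400)]
        pma = [event("g", -0.2, start=100), event("g", 0.3, start=401)]
        shared = differentiation_overlap(kd, pma, "events")
        assert [e.event_interval.start for e in shared] == [100]

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            differentiation_overlap([], [], "peaks")


class TestCoRegulation:
    def test_intersection(self):
        ts = TargetSets(
            transcriptional_targets=frozenset({"M", "X"}),
            splicing_targets=frozenset({"M", "Y"}),
            diff_transcriptional=frozenset({"M", "X"}),
            diff_splicing=frozenset({"M", "Y"}),
            co_regulated=frozenset({"M"}),
        )
        assert co_regulated_genes(ts) == {"M"}

    def test_subset_chain_enforced(self):
        with pytest.raises(ValueError):
            TargetSets(
                transcriptional_targets=frozenset({"A"}),
                splicing_targets=frozenset({"B"}),
                diff_transcriptional=frozenset({"Z"}),
                diff_splicing=frozenset({"B"}),
                co_regulated=frozenset(),
            )


class TestJaccard:
    def test_examples(self):
        assert jaccard({"a", "b"}, {"b", "c"}) == pytest.approx(1 / 3)
        assert jaccard({"a"}, {"a"}) == 1.0
        assert jaccard(set(), set()) == 0.0

    def test_subset_identity(self):
        a, b = {"x", "y"}, {"x", "y", "z", "w"}
        assert jaccard(a, b) == pytest.approx(len(a) / len(b))

    @settings(max_examples=200, derandomize=True)
    @given(st.sets(st.integers(0, 20)), st.sets(st.integers(0, 20)))
    def test_symmetric_bounded_and_discriminating(self, a, b):
        j = jaccard(a, b)
        assert 0.0 <= j <= 1.0
        assert j == jaccard(b, a)
        if a or b:
            assert (j == 1.0) == (a == b)


class TestDistanceProfile:
    def test_overlap_bin(self):
        prof = chip_clip_distance_profile(
            [peak("chr1", 100, 200, "chip")], [peak("chr1", 150, 250)]
        )
        assert prof.counts["overlap"] == 1

    def test_gap_7kb_in_middle_bin(self):
        prof = chip_clip_distance_profile(
            [peak("chr1", 0, 100, "chip")], [peak("chr1", 7100, 7200)]
        )
        assert prof.counts["kb5_10"] == 1

    def test_no_same_chromosome_clip_counts_far(self):
        prof = chip_clip_distance_profile(
            [peak("chr1", 0, 100, "chip")], [peak("chr2", 0, 100)]
        )
        assert prof.counts["gt_10kb"] == 1

    def test_empty_chip_set_rejected(self):
        with pytest.raises(ValueError):
            chip_clip_distance_profile([], [peak("chr1", 0, 100)])

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(30)
        chip = [peak("chr1", int(s), int(s) + 50, "chip") for s in rng.integers(0, 10**6, 40)]
        clip = [peak("chr1", int(s), int(s) + 50) for s in rng.integers(0, 10**6, 40)]
        prof = chip_clip_distance_profile(chip, clip)
        assert sum(prof.fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_matches_allpairs_oracle(self):
        rng = np.random.default_rng(31)
        chip = [
            peak(f"chr{1 + int(c)}", int(s), int(s) + 60, "chip")
            for c, s in zip(rng.integers(0, 2, 100), rng.integers(0, 300_000, 100))
        ]
        clip = [
            peak(f"chr{1 + int(c)}", int(s), int(s) + 40)
            for c, s in zip(rng.integers(0, 2, 100), rng.integers(0, 300_000, 100))
        ]
        prof = chip_clip_distance_profile(chip, clip)
        naive = distance_bins_naive(
            [p.interval for p in chip], [p.interval for p in clip]
        )
        assert prof.counts == naive

    def test_enlarging_clip_set_never_moves_peaks_farther(self):
        rng = np.random.default_rng(32)
        chip = [peak("chr1", int(s), int(s) + 50, "chip") for s in rng.integers(0, 10**6, 50)]
        clip = [peak("chr1", int(s), int(s) + 50) for s in rng.integers(0, 10**6, 30)]
        extra = clip + [peak("chr1", int(s), int(s) + 50) for s in rng.integers(0, 10**6, 30)]
        before = chip_clip_distance_profile(chip, clip).counts
        after = chip_clip_distance_profile(chip, extra).counts
        for k in range(len(DISTANCE_BINS)):
            near = DISTANCE_BINS[: k + 1]
            assert sum(after[b] for b in near) >= sum(before[b] for b in near)
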