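"""Fusion-map selection, donor fragments, windows, dedup, concordance."""

import numpy as np
import pytest

from chainmap import fusion
from chainmap.types import (
    FusionJunction,
    IntervalTrack,
    LocalSegment,
    MosaicAlignment,
    SVCall,
    Thresholds,
)


def _call(sv_type, size=None, query_id="m1", bp1=("chr1", 1e6), bp2=("chr1", 2e6)):
    return SVCall(sv_type=sv_type, query_id=query_id, ref_bp1=bp1, ref_bp2=bp2,
                  query_bp1=0, query_bp2=0, ref_gap=0, query_gap=0, size=size)


def _junc(c1, p1, c2, p2, gap, qid="m", s1="right", s2="left"):
    return FusionJunction(query_id=qid, left=(c1, float(p1), s1),
                          right=(c2, float(p2), s2), junction_gap=float(gap))


class TestSelectFusionMaps:
    def test_large_deletion_qualifies(self, th):
        sel = fusion.select_fusion_maps({"m1": [_call("deletion", 120_000)]}, th=th)
        assert sel == {"m1"}

    def test_small_insertion_does_not(self, th):
        assert fusion.select_fusion_maps({"m1": [_call("insertion", 80_000)]}, th=th) == set()

    def test_partner_of_cgr_map_included(self, th):
        calls = {"m1": [_call("inter_translocation", query_id="m1")], "m2": [], "m3": []}
        sel = fusion.select_fusion_maps(calls, pair_of={"m1": "m2", "m2": "m1"}, th=th)
        assert sel == {"m1", "m2"}

    def test_failed_calls_do_not_select(self, th):
        c = _call("inter_translocation")
        c.filters_failed.add("support")
        assert fusion.select_fusion_maps({"m1": [c]}, th=th) == set()


def _seg(ref_id, r0, r1, qid="m1", orient="+"):
    return LocalSegment(query_id=qid, ref_id=ref_id, orientation=orient,
                        pairs=[(0, 0)] * 9, q_start=1.0, q_end=2.0,
                        r_start=float(r0), r_end=float(r1), score=30.0)


class TestDonorFragments:
    def test_overlapping_segments_merge_and_count_maps(self, th):
        mosaics = [
            MosaicAlignment("m1", 1e6, [_seg("chr1", 100_000, 500_000, "m1")]),
            MosaicAlignment("m2", 1e6, [_seg("chr1", 400_000, 900_000, "m2")]),
        ]
        (frag,) = fusion.donor_fragments(mosaics, th=th)
        assert (frag.chrom, frag.start, frag.end) == ("chr1", 100_000, 900_000)
        assert frag.n_maps == 2

    def test_majority_segdup_segment_dropped(self, th):
        segdups = IntervalTrack("sd", [("chr1", 100_000, 340_000)])  # 60% of the segment
        mosaics = [MosaicAlignment("m1", 1e6, [_seg("chr1", 100_000, 500_000)])]
        assert fusion.donor_fragments(mosaics, segdups=segdups, th=th) == []

    def test_single_base_ngap_overlap_drops_segment(self, th):
        ngaps = IntervalTrack("gaps", [("chr1", 500_000, 600_000)])
        mosaics = [MosaicAlignment("m1", 1e6, [_seg("chr1", 100_000, 500_000)])]
        assert fusion.donor_fragments(mosaics, ngaps=ngaps, th=th) == []

    def test_haplomap_pair_counted_once(self, th):
        mosaics = [
            MosaicAlignment("a1", 1e6, [_seg("chr1", 100_000, 500_000, "a1")]),
            MosaicAlignment("a2", 1e6, [_seg("chr1", 120_000, 480_000, "a2")]),
        ]
        (frag,) = fusion.donor_fragments(mosaics, th=th, pair_of={"a1": "a2", "a2": "a1"})
        assert frag.n_maps == 1

    def test_merge_is_order_independent(self, th, rng):
        mosaics = []
        for i in range(12):
            s = float(rng.integers(1, 1_500_000))
            mosaics.append(MosaicAlignment(f"m{i}", 1e6,
                                           [_seg("chr2", s, s + 200_000, f"m{i}")]))
        a = fusion.donor_fragments(mosaics, th=th)
        b = fusion.donor_fragments(list(reversed(mosaics)), th=th)
        assert [(f.chrom, f.start, f.end, f.n_maps) for f in a] == \
               [(f.chrom, f.start, f.end, f.n_maps) for f in b]


class TestCoverageAndWindows:
    def test_empty_alignments_zero_track(self):
        df = fusion.coverage_profile([], {"chr1": 500_000.0})
        assert (df["depth"] == 0).all()

    def test_single_segment_spanning_three_bins(self):
        mos = MosaicAlignment("m", 1e6, [_seg("chr1", 150_000, 390_000)])
        df = fusion.coverage_profile([mos], {"chr1": 500_000.0}, bin_size=100_000.0)
        assert list(df["depth"]) == [0, 1, 1, 1, 0]

    def test_amplified_donor_mean_depth(self, th):
        mosaics = [MosaicAlignment(f"m{i}", 1e6, [_seg("chr1", 200_000, 700_000, f"m{i}")])
                   for i in range(5)]
        df = fusion.coverage_profile(mosaics, {"chr1": 1_000_000.0}, bin_size=100_000.0)
        donor = df[(df.bin_start >= 200_001) & (df.bin_end <= 700_000)]
        assert donor["depth"].mean() == pytest.approx(5.0)

    def test_window_counts_and_conservation(self, th):
        calls = [
            _call("inter_translocation", bp1=("chr1", 1_100_000), bp2=("chr2", 5_000_000)),
            _call("inter_translocation", bp1=("chr1", 1_200_000), bp2=("chr3", 1_000)),
            _call("deletion", size=5e4, bp1=("chr1", 1_900_000), bp2=("chr1", 1_950_000)),
        ]
        df = fusion.sv_windows(calls, window=1_000_000.0)
        w = df[(df.chrom == "chr1") & (df.window_start == 1_000_001)
               & (df.sv_type == "inter_translocation")]
        assert int(w["count"].iloc[0]) == 2
        assert df["count"].sum() == 2 * len(calls)  # two breakpoints per event

    def test_boundary_breakpoint_floor_division(self):
        calls = [_call("deletion", size=1e4, bp1=("chr1", 1_000_000), bp2=("chr1", 1_000_001))]
        df = fusion.sv_windows(calls, window=1_000_000.0)
        assert set(df["window_start"]) == {1.0, 1_000_001.0}


class TestDedup:
    def test_nearby_pair_with_similar_gap_merges(self, th):
        j1 = _junc("chr1", 1_000_000, "chr2", 2_000_000, 50_000)
        j2 = _junc("chr1", 1_005_000, "chr2", 2_007_000, 58_000)
        reps = fusion.dedup_fusions([j1, j2], th)
        assert len(reps) == 1

    def test_distant_breakpoints_stay_separate(self, th):
        j1 = _junc("chr1", 1_000_000, "chr2", 2_000_000, 50_000)
        j2 = _junc("chr1", 1_012_000, "chr2", 2_000_000, 50_000)
        assert len(fusion.dedup_fusions([j1, j2], th)) == 2

    def test_gap_difference_beyond_10kb_separates(self, th):
        j1 = _junc("chr1", 1_000_000, "chr2", 2_000_000, 50_000)
        j2 = _junc("chr1", 1_000_000, "chr2", 2_000_000, 61_000)
        assert len(fusion.dedup_fusions([j1, j2], th)) == 2

    def test_swapped_breakpoint_order_still_duplicates(self, th):
        j1 = _junc("chr1", 1_000_000, "chr2", 2_000_000, 50_000)
        j2 = _junc("chr2", 2_004_000, "chr1", 1_003_000, 55_000)
        assert len(fusion.dedup_fusions([j1, j2], th)) == 1

    def _random_junctions(self, rng, n=20):
        out = []
        for i in range(n):
            c1, c2 = rng.choice(["chr1", "chr2"], size=2)
            out.append(_junc(str(c1), rng.integers(0, 60_000), str(c2),
                             rng.integers(0, 60_000), rng.integers(0, 30_000), qid=f"m{i}"))
        return out

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_transitive_closure(self, seed, th):
        rng = np.random.default_rng(seed)
        juncs = self._random_junctions(rng)
        reps = fusion.dedup_fusions(juncs, th)
        clusters = {}
        for j in juncs:
            clusters.setdefault(j.cluster_id, set()).add(id(j))
        # brute force: repeated pairwise merging until fixed point
        brute = [{id(j)} for j in juncs]
        changed = True
        while changed:
            changed = False
            for i in range(len(juncs)):
                for k in range(i + 1, len(juncs)):
                    if fusion.duplicate_predicate(juncs[i], juncs[k], th):
                        gi = next(g for g in brute if id(juncs[i]) in g)
                        gk = next(g for g in brute if id(juncs[k]) in g)
                        if gi is not gk:
                            gi |= gk
                            brute.remove(gk)
                            changed = True
        assert sorted(map(sorted, clusters.values())) == sorted(map(sorted, brute))
        assert len(reps) == len(brute)

    def test_idempotent_and_identical_collapse(self, th):
        j = _junc("chr1", 1_000_000, "chr2", 2_000_000, 50_000)
        twin = _junc("chr1", 1_000_000, "chr2", 2_000_000, 50_000, qid="m2")
        reps = fusion.dedup_fusions([j, twin, j], th)
        assert len(reps) == 1
        assert len(fusion.dedup_fusions(reps, th)) == 1

    def test_representative_prefers_longest_map(self, th):
        j1 = _junc("chr1", 1_000_000, "chr2", 2_000_000, 50_000, qid="short")
        j2 = _junc("chr1", 1_001_000, "chr2", 2_001_000, 51_000, qid="long")
        (rep,) = fusion.dedup_fusions([j1, j2], th,
                                      map_lengths={"short": 1e6, "long": 2e6})
        assert rep.query_id == "long"


class TestSelectionOnSimulation:
    def test_zero_noise_selects_exactly_derivative_maps(self, small_ref, small_index, th):
        """Fusion-map selection recovers the derivative-derived consensus maps
        and never a background window."""
        from chainmap import align, simulate, svcall

        pre = simulate.liposarcoma_like(19, ref_maps=small_ref, n_derivatives=3,
                                        events_per_derivative=3, n_background=5,
                                        noise=simulate.NoiseModel.zero(),
                                        with_breakends=False)
        calls_by_map = {}
        for m in pre.consensus_maps:
            calls_by_map[m.map_id] = svcall.classify(align.mosaic(m, small_index, th), th)
        selected = fusion.select_fusion_maps(calls_by_map, th=th)
        derived = {m.map_id for m in pre.consensus_maps
                   if pre.provenance[m.map_id]["source"].startswith("der")}
        assert selected == derived


class TestConcordance:
    def test_within_100kb_both_ends(self):
        j = _junc("chr1", 1_000_000, "chr2", 2_000_000, 0)
        ext = [(("chr1", 1_050_000), ("chr2", 1_950_000))]
        assert fusion.concordance([j], ext) == [True]

    def test_one_end_beyond_tolerance(self):
        j = _junc("chr1", 1_000_000, "chr2", 2_000_000, 0)
        ext = [(("chr1", 1_150_000), ("chr2", 2_000_000))]
        assert fusion.concordance([j], ext) == [False]

    def test_order_swapped_external_pair_matches(self):
        j = _junc("chr1", 1_000_000, "chr2", 2_000_000, 0)
        ext = [(("chr2", 2_050_000), ("chr1", 950_000))]
        assert fusion.concordance([j], ext) == [True]
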