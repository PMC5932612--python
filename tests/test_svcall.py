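"""SV classification and the four filters."""

import numpy as np
import pytest

from chainmap import svcall
from chainmap.types import (
    IntervalTrack,
    LabelMap,
    LocalSegment,
    MosaicAlignment,
    SVCall,
    Thresholds,
)


def _seg(ref_id, orient, q0, q1, r0, r1, qi0=0, qi1=9):
    pairs = [(qi, 0) for qi in range(qi0, qi1 + 1)]
    return LocalSegment(query_id="q", ref_id=ref_id, orientation=orient, pairs=pairs,
                        q_start=q0, q_end=q1, r_start=r0, r_end=r1, score=30.0)


def _mosaic(segments, qlen=5e6):
    return MosaicAlignment(query_id="q", query_length=qlen, segments=segments)


class TestClassify:
    def test_single_segment_no_calls(self, th):
        assert svcall.classify(_mosaic([_seg("chr3", "+", 1, 1e6, 1, 1e6)]), th) == []

    def test_intra_translocation_beyond_5mb(self, th):
        mos = _mosaic([
            _seg("chr3", "+", 1, 1.0e6, 9.0e6, 10.0e6, 0, 9),
            _seg("chr3", "+", 1.05e6, 2.0e6, 16.2e6, 17.0e6, 10, 19),
        ], qlen=2e6)
        (call,) = svcall.classify(mos, th)
        assert call.sv_type == "intra_translocation"  # 6.2 Mb > 5 Mb

    def test_deletion_size_is_gap_difference(self, th):
        mos = _mosaic([
            _seg("chr3", "+", 1, 1.0e6, 1e6, 2.0e6, 0, 9),
            _seg("chr3", "+", 1.01e6, 2.0e6, 2.05e6, 3.0e6, 10, 19),
        ], qlen=2e6)
        (call,) = svcall.classify(mos, th)
        assert call.sv_type == "deletion"
        assert call.size == pytest.approx(40_000)  # |50,000 - 10,000|

    def test_insertion_when_query_gap_larger(self, th):
        mos = _mosaic([
            _seg("chr3", "+", 1, 1.0e6, 1e6, 2.0e6, 0, 9),
            _seg("chr3", "+", 1.2e6, 2.0e6, 2.01e6, 3.0e6, 10, 19),
        ], qlen=2e6)
        (call,) = svcall.classify(mos, th)
        assert call.sv_type == "insertion"
        assert call.size == pytest.approx(190_000)

    def test_opposite_orientation_is_inversion(self, th):
        mos = _mosaic([
            _seg("chr3", "+", 1, 1.0e6, 1e6, 2.0e6, 0, 9),
            _seg("chr3", "-", 1.01e6, 2.0e6, 2.3e6, 3.2e6, 10, 19),
        ], qlen=2e6)
        (call,) = svcall.classify(mos, th)
        assert call.sv_type == "inversion"
        assert call.size is None  # single junction: size unknown

    def test_different_chromosomes_inter(self, th):
        mos = _mosaic([
            _seg("chr3", "+", 1, 1.0e6, 1e6, 2.0e6, 0, 9),
            _seg("chr5", "+", 1.01e6, 2.0e6, 0.2e6, 1.1e6, 10, 19),
        ], qlen=2e6)
        (call,) = svcall.classify(mos, th)
        assert call.sv_type == "inter_translocation"

    def test_order_reversed_same_orientation_is_intra(self, th):
        # B upstream of A on the reference by more than the collinear slack
        mos = _mosaic([
            _seg("chr3", "+", 1, 1.0e6, 2e6, 3.0e6, 0, 9),
            _seg("chr3", "+", 1.01e6, 2.0e6, 1.0e6, 1.9e6, 10, 19),
        ], qlen=2e6)
        (call,) = svcall.classify(mos, th)
        assert call.sv_type == "intra_translocation"

    def test_simulated_derivative_types_match_truth(self, small_ref, small_index, th, rng):
        from chainmap import align, simulate

        plan, der, truth = simulate.simulate_derivative(
            small_ref, seed=33, n_events=4,
            event_weights={"inter_translocation": 0.5, "inversion": 0.25, "deletion": 0.25,
                           "intra_translocation": 0.0, "insertion": 0.0},
        )
        cons = simulate.noisy_map(der, simulate.NoiseModel.zero(), rng, "q")
        calls = svcall.classify(align.mosaic(cons, small_index, th), th)
        n_hit, n_truth = simulate.match_recall(calls, truth.svs)
        assert n_hit == n_truth == 4


class TestConfirmSupport:
    def _setup(self, n_span1, n_span2, th):
        labels = np.arange(10_000, 1_000_000, 11_000, dtype=float)
        cons = LabelMap("c", 1e6, labels)
        call = SVCall(sv_type="deletion", query_id="c", ref_bp1=("chr1", 5e5),
                      ref_bp2=("chr1", 6e5), query_bp1=labels[30], query_bp2=labels[40],
                      ref_gap=1e5, query_gap=1e5, size=5e4)
        def spans(center_idx, n):
            out = []
            for _ in range(n):
                seg = LocalSegment("m", "c", "+", [(i, i) for i in range(5)],
                                   q_start=1, q_end=2,
                                   r_start=labels[center_idx - 4], r_end=labels[center_idx + 4],
                                   score=30)
                out.append(MosaicAlignment("m", 1e6, [seg]))
            return out
        mols = spans(30, n_span1) + spans(40, n_span2)
        return call, cons, mols

    @pytest.mark.parametrize("n1,n2,passes", [(10, 10, True), (9, 10, False), (10, 9, False)])
    def test_minimum_ten_molecules_per_breakpoint(self, n1, n2, passes, th):
        call, cons, mols = self._setup(n1, n2, th)
        svcall.confirm_support(call, cons, mols, th)
        assert call.passed is passes
        assert call.support == min(n1, n2)

    def test_molecules_stopping_short_do_not_count(self, th):
        """12 molecules, 3 of which end one label inside the +/-2 window."""
        labels = np.arange(10_000, 1_000_000, 11_000, dtype=float)
        cons = LabelMap("c", 1e6, labels)
        call = SVCall(sv_type="deletion", query_id="c", ref_bp1=("chr1", 5e5),
                      ref_bp2=("chr1", 6e5), query_bp1=labels[30], query_bp2=labels[30],
                      ref_gap=1e5, query_gap=1e5, size=5e4)
        mols = []
        for k in range(12):
            hi = 31 if k < 3 else 33  # 3 molecules stop 1 label short of +2
            seg = LocalSegment("m", "c", "+", [(i, i) for i in range(5)], 1, 2,
                               labels[26], labels[hi], 30)
            mols.append(MosaicAlignment("m", 1e6, [seg]))
        svcall.confirm_support(call, cons, mols, th)
        assert call.support == 9
        assert "support" in call.filters_failed


class TestRegionFilters:
    def _del(self, chrom, lo, hi):
        return SVCall(sv_type="deletion", query_id="q", ref_bp1=(chrom, lo),
                      ref_bp2=(chrom, hi), query_bp1=0, query_bp2=0,
                      ref_gap=hi - lo, query_gap=0, size=hi - lo)

    def _transloc(self, bp1, bp2):
        return SVCall(sv_type="inter_translocation", query_id="q", ref_bp1=bp1,
                      ref_bp2=bp2, query_bp1=0, query_bp2=0,
                      ref_gap=float("nan"), query_gap=0, size=None)

    def test_single_base_ngap_overlap_excludes(self, th):
        ngaps = IntervalTrack("gaps", [("chr1", 200_000, 300_000)])
        call = self._del("chr1", 100_000, 200_000)  # touches the gap at 1 bp
        svcall.filter_regions([call], ngaps, None, th)
        assert "ngap" in call.filters_failed

    def test_segdup_below_20pct_kept(self, th):
        # breakpoint window is 20 kb wide; 3.8 kb overlap = 19%
        segdups = IntervalTrack("sd", [("chr1", 496_201, 500_000)])
        call = self._transloc(("chr1", 500_000), ("chr2", 100_000))
        svcall.filter_regions([call], None, segdups, th)
        assert call.passed

    def test_segdup_at_20pct_excluded(self, th):
        segdups = IntervalTrack("sd", [("chr1", 496_000, 500_000)])  # 4001 bp of 20001
        call = self._transloc(("chr1", 500_000), ("chr2", 100_000))
        svcall.filter_regions([call], None, segdups, th)
        assert "segdup" in call.filters_failed

    def test_randomized_overlaps_match_bruteforce(self, th):
        rng = np.random.default_rng(8)
        intervals = [("chr1", float(s), float(s + rng.integers(1_000, 80_000)))
                     for s in rng.integers(1, 2_000_000, 25)]
        track = IntervalTrack("sd", intervals)
        merged = track.by_chrom()["chr1"]

        def brute_overlap(lo, hi):
            covered = 0
            for p in range(int(lo), int(hi) + 1, 100):  # coarse grid
                if any(s <= p <= e for s, e in merged):
                    covered += 100
            return covered

        for _ in range(20):
            lo = float(rng.integers(1, 1_900_000))
            hi = lo + float(rng.integers(10_000, 100_000))
            call = self._del("chr1", lo, hi)
            svcall.filter_regions([call], None, track, th)
            frac = brute_overlap(lo, hi) / (hi - lo + 1)
            assert ("segdup" in call.filters_failed) == (frac >= 0.20) or abs(frac - 0.20) < 0.01

    def test_filter_order_invariance(self, th):
        ngaps = IntervalTrack("gaps", [("chr1", 150_000, 160_000)])
        blacklist = [(("chr1", 500_000), ("chr2", 100_000))]
        def build():
            return [
                self._del("chr1", 100_000, 155_000),
                self._del("chr1", 400_000, 400_500),
                self._transloc(("chr1", 500_000), ("chr2", 100_000)),
            ]
        a = build()
        svcall.filter_regions(a, ngaps, None, th)
        svcall.filter_size_and_blacklist(a, blacklist, th)
        b = build()
        svcall.filter_size_and_blacklist(b, blacklist, th)
        svcall.filter_regions(b, ngaps, None, th)
        assert [c.filters_failed for c in a] == [c.filters_failed for c in b]


class TestSizeAndBlacklist:
    def _indel(self, size, sv_type="insertion"):
        return SVCall(sv_type=sv_type, query_id="q", ref_bp1=("chr1", 1e5),
                      ref_bp2=("chr1", 1e5 + size), query_bp1=0, query_bp2=0,
                      ref_gap=0, query_gap=size, size=float(size))

    def test_sub_1kb_indels_removed(self, th):
        kept = svcall.filter_size_and_blacklist([self._indel(999), self._indel(1_000)], None, th)
        assert [c.passed for c in kept] == [False, True]  # "<1 kb" is strict

    def test_blacklisted_translocation_flagged_common(self, th):
        call = SVCall(sv_type="inter_translocation", query_id="q",
                      ref_bp1=("chr1", 500_000), ref_bp2=("chr2", 800_000),
                      query_bp1=0, query_bp2=0, ref_gap=float("nan"), query_gap=0, size=None)
        blacklist = [(("chr2", 805_000), ("chr1", 495_000))]  # swapped order, within 10 kb
        svcall.filter_size_and_blacklist([call], blacklist, th)
        assert "_common" in call.filters_failed

    def test_toy_seven_calls_four_survive(self, th):
        calls = [
            self._indel(500), self._indel(800, "deletion"),      # size-filtered
            self._indel(5_000), self._indel(2_000, "deletion"),  # kept
            self._indel(150_000),                                # kept
            SVCall(sv_type="inter_translocation", query_id="q",
                   ref_bp1=("chr1", 500_000), ref_bp2=("chr2", 800_000),
                   query_bp1=0, query_bp2=0, ref_gap=float("nan"), query_gap=0, size=None),
            SVCall(sv_type="inversion", query_id="q",
                   ref_bp1=("chr3", 100_000), ref_bp2=("chr3", 400_000),
                   query_bp1=0, query_bp2=0, ref_gap=3e5, query_gap=0, size=None),  # kept
        ]
        blacklist = [(("chr1", 500_000), ("chr2", 800_000))]
        svcall.filter_size_and_blacklist(calls, blacklist, th)
        assert sum(c.passed for c in calls) == 4
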