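"""Breakend graph and fusion-gap traversal, with an exhaustive path oracle."""

import numpy as np
import pytest

from chainmap import traverse
from chainmap.traverse import build_graph
from chainmap.types import BreakendCall, FusionJunction, Thresholds


def _call(cid, c1, p1, s1, c2, p2, s2, ins=0.0, q=1000.0):
    return BreakendCall(id=cid, chrom1=c1, pos1=float(p1), side1=s1,
                        chrom2=c2, pos2=float(p2), side2=s2,
                        inserted_len=float(ins), quality=q)


def brute_force_traverse(graph, fusion, th):
    """Independent exhaustive enumeration of alternating simple paths."""
    results = []
    starts = [n for n in graph.nodes
              if n[0] == fusion.left[0] and n[2] == fusion.left[2]
              and abs(n[1] - fusion.left[1]) <= th.traverse_anchor_tol]

    def junction_steps(node, used):
        for eid, (cid, u, v, ins) in enumerate(graph.junction_edges):
            if eid in used:
                continue
            if node == u:
                yield eid, cid, v, ins
            elif node == v:
                yield eid, cid, u, ins

    def segment_steps(node):
        for other in graph.nodes:
            if other[0] != node[0]:
                continue
            if node[2] == "left" and other[2] == "right" and other[1] >= node[1]:
                yield other, other[1] - node[1]
            elif node[2] == "right" and other[2] == "left" and other[1] <= node[1]:
                yield other, node[1] - other[1]

    def walk(node, used, length, ids, want_junction, depth):
        if depth > 12:
            return
        if want_junction:
            for eid, cid, nxt, ins in junction_steps(node, used):
                new_ids = ids + (cid,)
                new_len = length + ins
                if (nxt[0] == fusion.right[0] and nxt[2] == fusion.right[2]
                        and abs(nxt[1] - fusion.right[1]) <= th.traverse_anchor_tol):
                    total = new_len + abs(nxt[1] - fusion.right[1])
                    delta = abs(total - fusion.junction_gap)
                    if delta < th.traverse_len_tol:
                        results.append((delta, len(new_ids), new_ids, total))
                walk(nxt, used | {eid}, new_len, new_ids, False, depth + 1)
        else:
            for nxt, seg in segment_steps(node):
                if length + seg - fusion.junction_gap < th.traverse_len_tol:
                    walk(nxt, used, length + seg, ids, True, depth + 1)

    for s in starts:
        walk(s, set(), abs(s[1] - fusion.left[1]), (), True, 0)
    return min(results) if results else None


class TestBuildGraph:
    def test_single_call_two_nodes_one_edge(self):
        g = build_graph([_call("a", "chr1", 100, "right", "chr2", 200, "left")])
        assert len(g.nodes) == 2
        assert len(g.junction_edges) == 1

    def test_compatible_sides_make_segment_edge(self):
        calls = [
            _call("a", "chr1", 100, "right", "chr9", 5_000_000, "left"),
            _call("b", "chr9", 5_180_000, "right", "chr5", 300, "left"),
        ]
        g = build_graph(calls)
        (edge,) = g.segment_edges(max_len=1e6)
        n1, n2, length = edge
        assert length == pytest.approx(180_000)
        assert (n1[2], n2[2]) == ("left", "right")

    def test_duplicate_calls_collapse(self):
        c = _call("a", "chr1", 100, "right", "chr2", 200, "left")
        d = _call("b", "chr1", 100, "right", "chr2", 200, "left")
        assert len(build_graph([c, d, c]).junction_edges) == 1

    def test_random_graph_counts_match_hand_construction(self, rng):
        calls = []
        for i in range(15):
            c1, c2 = rng.choice(["chr1", "chr2", "chr3"], size=2)
            calls.append(_call(f"c{i}", str(c1), rng.integers(1, 10**6), "left",
                               str(c2), rng.integers(1, 10**6), "right"))
        g = build_graph(calls)
        nodes = {be for c in calls for be in c.breakends}
        assert set(g.nodes) == nodes
        assert len(g.junction_edges) == 15


class TestTraverseGap:
    def test_single_direct_call(self, th):
        fusion = FusionJunction("f", ("chr1", 1_000_000, "right"),
                                ("chr5", 2_000_000, "left"), 40_000)
        g = build_graph([_call("a", "chr1", 1_020_000, "right", "chr5", 2_010_000, "left")])
        t = traverse.traverse_gap(g, fusion, th)
        assert t.supported and t.n_junctions == 1
        assert t.path_len == pytest.approx(30_000)
        assert t.delta == pytest.approx(10_000)

    def test_two_junction_chain_with_segment(self, th):
        """Gap 300 kb; two calls bridged by a 180 kb reference walk on chr9:
        path length 20k + 180k + 10k = 210k, delta 90k -> supported."""
        fusion = FusionJunction("f", ("chr1", 1_000_000, "right"),
                                ("chr5", 2_000_000, "left"), 300_000)
        calls = [
            _call("a", "chr1", 1_020_000, "right", "chr9", 5_000_000, "left"),
            _call("b", "chr9", 5_180_000, "right", "chr5", 1_990_000, "left"),
        ]
        t = traverse.traverse_gap(build_graph(calls), fusion, th)
        assert t.supported and t.n_junctions == 2
        assert t.path_len == pytest.approx(210_000)
        assert t.delta == pytest.approx(90_000)

    def test_oversized_segment_unsupported(self, th):
        fusion = FusionJunction("f", ("chr1", 1_000_000, "right"),
                                ("chr5", 2_000_000, "left"), 300_000)
        calls = [
            _call("a", "chr1", 1_020_000, "right", "chr9", 5_000_000, "left"),
            _call("b", "chr9", 5_450_000, "right", "chr5", 1_990_000, "left"),
        ]
        t = traverse.traverse_gap(build_graph(calls), fusion, th)
        assert not t.supported  # delta 360 kb >= 100 kb

    def test_no_anchor_breakend_unsupported(self, th):
        fusion = FusionJunction("f", ("chr1", 1_000_000, "right"),
                                ("chr5", 2_000_000, "left"), 40_000)
        g = build_graph([_call("a", "chr2", 10, "right", "chr3", 20, "left")])
        t = traverse.traverse_gap(g, fusion, th)
        assert not t.supported and "anchor" in t.note

    def test_path_closest_to_optical_gap_wins(self, th):
        fusion = FusionJunction("f", ("chr1", 1_000_000, "right"),
                                ("chr5", 2_000_000, "left"), 100_000)
        calls = [
            _call("direct", "chr1", 1_000_000, "right", "chr5", 2_000_000, "left"),  # len 0
            _call("a", "chr1", 1_000_000, "right", "chr9", 5_000_000, "left"),
            _call("b", "chr9", 5_090_000, "right", "chr5", 2_000_000, "left"),  # len 90k
        ]
        t = traverse.traverse_gap(build_graph(calls), fusion, th)
        assert t.supported and t.n_junctions == 2 and t.delta == pytest.approx(10_000)

    def _random_instance(self, seed):
        """A planted (sometimes-feasible) chain plus random clutter calls."""
        rng = np.random.default_rng(seed)
        chroms = ["chr1", "chr2", "chr3", "chr4"]
        left = ("chr1", float(rng.integers(900_000, 1_100_000)), "right")
        right = ("chr2", float(rng.integers(1_900_000, 2_100_000)), "left")
        calls = []
        # chain of k junctions with compatible reference walks between them
        k = int(rng.integers(1, 5))
        node = ("chr1", left[1] + float(rng.integers(-80_000, 80_000)), "right")
        path_len = abs(node[1] - left[1])
        for i in range(k):
            if i == k - 1:
                nxt = ("chr2", right[1] + float(rng.integers(-80_000, 80_000)), "left")
            else:
                c = str(rng.choice(chroms[2:]))
                nxt = (c, float(rng.integers(100_000, 700_000)), "left")
            ins = float(rng.integers(0, 2_000))
            calls.append(_call(f"p{i:02d}", node[0], node[1], node[2],
                               nxt[0], nxt[1], nxt[2], ins=ins))
            path_len += ins
            if i == k - 1:
                path_len += abs(nxt[1] - right[1])
            else:
                seg = float(rng.integers(5_000, 150_000))
                node = (nxt[0], nxt[1] + seg, "right")
                path_len += seg
        # clutter: random calls that may or may not connect
        for i in range(int(rng.integers(2, 8))):
            c1, c2 = rng.choice(chroms, size=2)
            calls.append(_call(
                f"x{i:02d}", str(c1), rng.integers(1, 2_500_000),
                "left" if rng.random() < 0.5 else "right",
                str(c2), rng.integers(1, 2_500_000),
                "left" if rng.random() < 0.5 else "right",
                ins=float(rng.integers(0, 2_000)),
            ))
        # the measured optical gap roughly (sometimes not) matches the chain
        gap = max(path_len + float(rng.integers(-250_000, 250_000)), 0.0)
        return calls, FusionJunction("f", left, right, gap)

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_exhaustive_enumeration(self, seed, th):
        calls, fusion = self._random_instance(seed)
        g = build_graph(calls)
        got = traverse.traverse_gap(g, fusion, th)
        want = brute_force_traverse(g, fusion, th)
        if want is None:
            assert not got.supported
        else:
            assert got.supported
            assert got.delta == pytest.approx(want[0])
            assert got.n_junctions == want[1]
            path_ids = tuple(e[1] for e in got.path_edges if e[0] == "junction")
            assert path_ids == want[2]

    def test_reported_traversal_satisfies_invariants(self, th):
        for seed in range(10):
            calls, fusion = self._random_instance(seed + 100)
            t = traverse.traverse_gap(build_graph(calls), fusion, th)
            if t.supported:
                assert t.delta < th.traverse_len_tol
                assert max(t.anchor_offsets) <= th.traverse_anchor_tol
                kinds = [e[0] for e in t.path_edges]
                assert kinds[0] == kinds[-1] == "junction"
                assert all(a != b for a, b in zip(kinds, kinds[1:]))  # alternating


class TestTraverseAll:
    def test_empty_graph_zero_supported(self, th):
        fus = [FusionJunction("f", ("chr1", 1e6, "right"), ("chr5", 2e6, "left"), 1e4)]
        _, summary = traverse.traverse_all(build_graph([]), fus, th)
        assert summary["n_supported"] == 0

    def test_known_chain_length_recovered(self, small_ref, th):
        from chainmap import simulate

        pre = simulate.liposarcoma_like(
            11, ref_maps=small_ref, n_derivatives=2, events_per_derivative=3,
            n_background=0, with_breakends=True, detection=1.0, fdr=0.0,
            junction_insert_p=1.0, chain_pieces=(3, 3),
            event_weights={"inter_translocation": 1.0},
        )
        g = build_graph(pre.breakend_calls)
        fus = [FusionJunction(j.junction_id, j.left, j.right, j.gap)
               for j in pre.truth.junctions]
        trs, summary = traverse.traverse_all(g, fus, th)
        assert summary["n_supported"] == len(fus)
        assert summary["mean_junctions"] == pytest.approx(4.0)  # 3 micro-fragments -> 4

    def test_duplicated_calls_do_not_change_result(self, th):
        calls, fusion = TestTraverseGap()._random_instance(5)
        a = traverse.traverse_gap(build_graph(calls), fusion, th)
        b = traverse.traverse_gap(build_graph(calls + calls), fusion, th)
        assert (a.supported, a.n_junctions, a.path_len) == (b.supported, b.n_junctions, b.path_len)
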