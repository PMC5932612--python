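"""Fusion-map selection, donor fragments, windowed SV summaries,
fusion-junction deduplication and concordance with external fusion lists.

A *fusion map* is a consensus map carrying at least one complex genomic
rearrangement (CGR): any translocation or inversion, or an insertion/deletion
whose sample-vs-reference breakpoint distance exceeds 100 kb.  Maps whose
haplomap partner carries a CGR are included as well.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
from intervaltree import IntervalTree

from .types import (
    DonorFragment,
    FusionJunction,
    IntervalTrack,
    MosaicAlignment,
    SVCall,
    Thresholds,
)

__all__ = [
    "is_cgr",
    "select_fusion_maps",
    "fusion_junctions",
    "donor_fragments",
    "coverage_profile",
    "sv_windows",
    "dedup_fusions",
    "concordance",
]


def is_cgr(call: SVCall, th: Thresholds = Thresholds()) -> bool:
    """CGR = translocation or inversion, or indel with size > 100 kb."""
    if call.sv_type in ("inversion", "intra_translocation", "inter_translocation"):
        return True
    return call.is_indel and call.size is not None and call.size > th.cgr_indel_size


def select_fusion_maps(
    calls_by_map: Dict[str, Sequence[SVCall]],
    pair_of: Optional[Dict[str, str]] = None,
    th: Thresholds = Thresholds(),
    passing_only: bool = True,
) -> Set[str]:
    """Map ids with >= 1 CGR, plus their haplomap partners."""
    selected = {
        map_id
        for map_id, calls in calls_by_map.items()
        if any(is_cgr(c, th) and (c.passed or not passing_only) for c in calls)
    }
    if pair_of:
        partners = {pair_of[m] for m in selected if m in pair_of}
        selected |= {p for p in partners if p is not None}
    return selected


def fusion_junctions(calls: Iterable[SVCall], th: Thresholds = Thresholds()) -> List[FusionJunction]:
    """Fusion junctions (for dedup/traversal) from translocation and inversion calls."""
    out = []
    for c in calls:
        if not (c.is_translocation or c.sv_type == "inversion"):
            continue
        side1 = "right" if c.orient1 == "+" else "left"
        side2 = "left" if c.orient2 == "+" else "right"
        out.append(
            FusionJunction(
                query_id=c.query_id,
                left=(c.ref_bp1[0], c.ref_bp1[1], side1),
                right=(c.ref_bp2[0], c.ref_bp2[1], side2),
                junction_gap=max(c.query_gap, 0.0),
            )
        )
    return out


def _merge_intervals(intervals: List[Tuple[float, float]]) -> List[Tuple[float, float]]:
    merged: List[List[float]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _track_trees(track: Optional[IntervalTrack]) -> Dict[str, IntervalTree]:
    trees: Dict[str, IntervalTree] = {}
    if track is not None:
        for chrom, s, e in track.intervals:
            trees.setdefault(chrom, IntervalTree()).addi(s, e + 1)
    return trees


def _overlap_bp(trees: Dict[str, IntervalTree], chrom: str, s: float, e: float) -> float:
    tree = trees.get(chrom)
    if tree is None:
        return 0.0
    return sum(min(iv.end, e + 1) - max(iv.begin, s) for iv in tree.overlap(s, e + 1))


def donor_fragments(
    fusion_alignments: Sequence[MosaicAlignment],
    ngaps: Optional[IntervalTrack] = None,
    segdups: Optional[IntervalTrack] = None,
    th: Thresholds = Thresholds(),
    pair_of: Optional[Dict[str, str]] = None,
) -> List[DonorFragment]:
    """Merged reference intervals contributed by the fusion maps.

    Aligned segments overlapping an N-gap by any base, or a SegDup by >= 50%
    of their span, are dropped before merging.  ``n_maps`` counts distinct
    supporting maps with haplomap pairs counted once.
    """
    ngap_trees = _track_trees(ngaps)
    segdup_trees = _track_trees(segdups)

    def map_unit(map_id: str) -> str:
        if pair_of and map_id in pair_of:
            return min(map_id, pair_of[map_id])
        return map_id

    kept: Dict[str, List[Tuple[float, float, str]]] = defaultdict(list)
    for mos in fusion_alignments:
        for seg in mos.segments:
            s, e = seg.r_start, seg.r_end
            if ngap_trees and _overlap_bp(ngap_trees, seg.ref_id, s, e) >= 1.0:
                continue
            if segdup_trees:
                frac = _overlap_bp(segdup_trees, seg.ref_id, s, e) / max(e - s + 1, 1.0)
                if frac >= th.segdup_frac_donor:
                    continue
            kept[seg.ref_id].append((s, e, map_unit(mos.query_id)))
    fragments: List[DonorFragment] = []
    for chrom in sorted(kept):
        merged = _merge_intervals([(s, e) for s, e, _ in kept[chrom]])
        for s, e in merged:
            units = {u for ss, ee, u in kept[chrom] if ss <= e and ee >= s}
            fragments.append(DonorFragment(chrom=chrom, start=s, end=e, n_maps=len(units)))
    return fragments


def coverage_profile(
    fusion_alignments: Sequence[MosaicAlignment],
    chrom_lengths: Dict[str, float],
    bin_size: float = 100_000.0,
):
    """Per-bin count of fusion-map segments covering each genomic bin.

    Returns a pandas DataFrame (chrom, bin_start, bin_end, depth); the sum of
    fusion-map alignments serves as the copy-number profile.
    """
    import pandas as pd

    rows = []
    for chrom in sorted(chrom_lengths):
        n_bins = int(np.ceil(chrom_lengths[chrom] / bin_size))
        depth = np.zeros(n_bins, dtype=int)
        for mos in fusion_alignments:
            for seg in mos.segments:
                if seg.ref_id != chrom:
                    continue
                b0 = int((seg.r_start - 1) // bin_size)
                b1 = int((seg.r_end - 1) // bin_size)
                depth[b0 : b1 + 1] += 1
        for b in range(n_bins):
            rows.append((chrom, b * bin_size + 1, min((b + 1) * bin_size, chrom_lengths[chrom]), int(depth[b])))
    return pd.DataFrame(rows, columns=["chrom", "bin_start", "bin_end", "depth"])


def sv_windows(calls: Sequence[SVCall], window: float = 1_000_000.0):
    """Per-window, per-type breakpoint counts (both breakpoints of each call).

    Window index by floor division of the 1-based position.
    """
    import pandas as pd

    counts: Dict[Tuple[str, int, str], int] = defaultdict(int)
    for c in calls:
        for chrom, pos in (c.ref_bp1, c.ref_bp2):
            w = int((pos - 1) // window)
            counts[(chrom, w, c.sv_type)] += 1
    rows = [
        (chrom, w * window + 1, (w + 1) * window, sv_type, n)
        for (chrom, w, sv_type), n in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["chrom", "window_start", "window_end", "sv_type", "count"])


# ---------------------------------------------------------------------------
# deduplication and concordance


def _pairs_close(j1: FusionJunction, j2: FusionJunction, tol: float) -> bool:
    """Both breakpoint pairs within tol, tested in both pairing orders."""

    def close(a: tuple, b: tuple) -> bool:
        return a[0] == b[0] and abs(a[1] - b[1]) <= tol

    direct = close(j1.left, j2.left) and close(j1.right, j2.right)
    swapped = close(j1.left, j2.right) and close(j1.right, j2.left)
    return direct or swapped


def duplicate_predicate(j1: FusionJunction, j2: FusionJunction, th: Thresholds = Thresholds()) -> bool:
    """Two fusions are duplicates when both breakpoint pairs lie within 10 kb
    (either pairing) and their junction-gap sizes differ by <= 10 kb.

    Orientation is ignored; the compared size is the unaligned junction
    interval length (see ``gap_size_mode`` of :func:`dedup_fusions`).
    """
    return _pairs_close(j1, j2, th.dedup_tol) and abs(j1.junction_gap - j2.junction_gap) <= th.dedup_tol


def dedup_fusions(
    junctions: Sequence[FusionJunction],
    th: Thresholds = Thresholds(),
    map_lengths: Optional[Dict[str, float]] = None,
) -> List[FusionJunction]:
    """Single-linkage clustering under the duplicate predicate; one
    representative per cluster (longest supporting map, then lexicographic id).

    The pairwise predicate is not transitive, so clusters may exceed the 10 kb
    diameter; single-linkage closure makes the result order-independent.
    Idempotent: representatives re-deduplicate to themselves.
    """
    n = len(junctions)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    for i in range(n):
        for j in range(i + 1, n):
            if duplicate_predicate(junctions[i], junctions[j], th):
                union(i, j)
    clusters: Dict[int, List[int]] = defaultdict(list)
    for i in range(n):
        clusters[find(i)].append(i)

    def rep_key(idx: int):
        j = junctions[idx]
        length = map_lengths.get(j.query_id, 0.0) if map_lengths else 0.0
        return (-length, j.query_id, idx)

    reps = []
    for cid, (root, members) in enumerate(sorted(clusters.items())):
        best = min(members, key=rep_key)
        rep = junctions[best]
        rep.cluster_id = cid
        for m in members:
            junctions[m].cluster_id = cid
        reps.append(rep)
    return reps


def write_circos_files(
    junctions: Sequence[FusionJunction],
    chrom_lengths: Dict[str, float],
    links_path,
    karyotype_path,
) -> None:
    """Circos-ready plain-text link and karyotype files (rendering is left
    to Circos itself)."""
    with open(links_path, "w") as fh:
        for j in junctions:
            fh.write(f"{j.left[0]} {int(j.left[1])} {int(j.left[1])} "
                     f"{j.right[0]} {int(j.right[1])} {int(j.right[1])}\n")
    with open(karyotype_path, "w") as fh:
        for chrom in sorted(chrom_lengths):
            fh.write(f"chr - {chrom} {chrom} 0 {int(chrom_lengths[chrom])} grey\n")


def concordance(
    junctions: Sequence[FusionJunction],
    external: Sequence[tuple],
    tol: float = 100_000.0,
) -> List[bool]:
    """Whether each junction matches an external breakpoint pair.

    A junction is concordant when both of its breakpoints lie within ``tol``
    (default 100 kb) of the external pair, in either pairing order.
    """
    out = []
    for j in junctions:
        matched = False
        for (c1, p1), (c2, p2) in external:
            d_ok = (j.left[0] == c1 and abs(j.left[1] - p1) <= tol
                    and j.right[0] == c2 and abs(j.right[1] - p2) <= tol)
            s_ok = (j.left[0] == c2 and abs(j.left[1] - p2) <= tol
                    and j.right[0] == c1 and abs(j.right[1] - p1) <= tol)
            if d_ok or s_ok:
                matched = True
                break
        out.append(matched)
    return out
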