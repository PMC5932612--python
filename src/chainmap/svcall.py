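"""SV classification from mosaic alignments, plus the four post-call filters.

Classification considers each pair of query-adjacent aligned segments:

* different reference chromosomes        -> inter-chromosomal translocation
* same chromosome, separation > 5 Mb     -> intra-chromosomal translocation
* same chromosome, opposite orientation  -> inversion (one junction; a full
  inversion shows up as two calls flanking the same reference interval)
* same chromosome, same orientation, order-reversed (non-collinear)
                                         -> intra-chromosomal translocation
  (it cannot be an indel; the 5 Mb rule addresses separation, not order)
* collinear                              -> insertion if the query gap exceeds
  the reference gap, else deletion; size = |query_gap - reference_gap|

Filters only annotate ``filters_failed``; the final excluded set is the union,
so the outcome is independent of application order.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from intervaltree import IntervalTree

from .types import (
    IntervalTrack,
    LabelMap,
    MosaicAlignment,
    SVCall,
    Thresholds,
)

__all__ = [
    "classify",
    "confirm_support",
    "filter_regions",
    "filter_size_and_blacklist",
    "passing_calls",
]


def classify(mos: MosaicAlignment, th: Thresholds = Thresholds(),
             haplomap_pair_id: Optional[str] = None) -> List[SVCall]:
    """Classify one SV call per adjacent segment pair of a mosaic alignment."""
    calls: List[SVCall] = []
    segs = mos.segments
    for left, right in zip(segs, segs[1:]):
        chrom_l, pos_l, _side_l = left.junction_breakend("right")
        chrom_r, pos_r, _side_r = right.junction_breakend("left")
        query_gap = right.q_start - left.q_end
        common = dict(
            query_id=mos.query_id,
            ref_bp1=(chrom_l, pos_l),
            ref_bp2=(chrom_r, pos_r),
            query_bp1=left.q_end,
            query_bp2=right.q_start,
            query_gap=query_gap,
            orient1=left.orientation,
            orient2=right.orientation,
            haplomap_pair_id=haplomap_pair_id,
        )
        if chrom_l != chrom_r:
            calls.append(SVCall(sv_type="inter_translocation", ref_gap=float("nan"),
                                size=None, **common))
            continue
        sep = abs(pos_r - pos_l)
        if sep > th.intra_transloc_min_sep:
            calls.append(SVCall(sv_type="intra_translocation", ref_gap=sep, size=None, **common))
            continue
        if left.orientation != right.orientation:
            # single junction of an inversion; size only known when both
            # junctions flanking the reference interval are observed
            calls.append(SVCall(sv_type="inversion", ref_gap=sep, size=None, **common))
            continue
        # signed reference gap along the strand; small reversals within the
        # collinearity slack are boundary-label jitter, not rearrangement
        d = (pos_r - pos_l) if left.orientation == "+" else (pos_l - pos_r)
        if d < -th.collinear_slack:
            calls.append(SVCall(sv_type="intra_translocation", ref_gap=sep, size=None, **common))
            continue
        size = abs(query_gap - d)
        sv_type = "insertion" if query_gap > d else "deletion"
        calls.append(SVCall(sv_type=sv_type, ref_gap=d, size=size, **common))
    return calls


def pair_inversion_junctions(calls: Sequence[SVCall], th: Thresholds = Thresholds()) -> None:
    """Fill in inversion sizes where two calls flank the same reference interval.

    Two inversion junctions belong to the same event when their four reference
    breakpoints bracket one interval on one chromosome; the reported size is
    the span between the two outer breakpoints.
    """
    invs = [c for c in calls if c.sv_type == "inversion"]
    for a in invs:
        if a.size is not None:
            continue
        for b in invs:
            if b is a or b.size is not None:
                continue
            if a.ref_bp1[0] != b.ref_bp1[0]:
                continue
            pos = sorted([a.ref_bp1[1], a.ref_bp2[1], b.ref_bp1[1], b.ref_bp2[1]])
            inner = pos[2] - pos[1]
            outer = pos[3] - pos[0]
            # junctions of one inversion share the inverted interval: their
            # breakpoint pairs interleave within the padding tolerance
            if inner > 0 and outer - inner <= 2 * th.breakpoint_pad:
                a.size = b.size = outer
                break


def _mol_ref_spans(mol_alignments: Iterable[MosaicAlignment]) -> List[Tuple[float, float]]:
    spans = []
    for mos in mol_alignments:
        for seg in mos.segments:
            spans.append((seg.r_start, seg.r_end))
    return spans


def confirm_support(
    call: SVCall,
    consensus: LabelMap,
    mol_alignments: Sequence[MosaicAlignment],
    th: Thresholds = Thresholds(),
) -> SVCall:
    """Single-molecule confirmation of one call on its consensus map.

    A molecule supports a breakpoint when its alignment to the consensus map
    spans the breakpoint extended by ``support_label_slop`` labels (default 2)
    on each side.  The call fails the ``support`` filter when fewer than
    ``min_support_molecules`` (default 10) molecules span either breakpoint.
    """
    labels = consensus.labels
    spans = _mol_ref_spans(mol_alignments)
    counts = []
    for bp in (call.query_bp1, call.query_bp2):
        idx = int(np.searchsorted(labels, bp))
        idx = min(max(idx, 0), labels.size - 1)
        lo_idx = max(idx - th.support_label_slop, 0)
        hi_idx = min(idx + th.support_label_slop, labels.size - 1)
        lo, hi = labels[lo_idx], labels[hi_idx]
        counts.append(sum(1 for s, e in spans if s <= lo and e >= hi))
    call.support = int(min(counts))
    if call.support < th.min_support_molecules:
        call.filters_failed.add("support")
    return call


def _build_tree(track: IntervalTrack) -> Dict[str, IntervalTree]:
    trees: Dict[str, IntervalTree] = {}
    for chrom, start, end in track.intervals:
        trees.setdefault(chrom, IntervalTree()).addi(start, end + 1)  # half-open internally
    return trees


def _overlap_bp(trees: Dict[str, IntervalTree], chrom: str, start: float, end: float) -> float:
    tree = trees.get(chrom)
    if tree is None:
        return 0.0
    total = 0.0
    for iv in tree.overlap(start, end + 1):
        total += min(iv.end, end + 1) - max(iv.begin, start)
    return total


def _call_intervals(call: SVCall, th: Thresholds) -> List[Tuple[str, float, float]]:
    if call.is_indel:
        chrom = call.ref_bp1[0]
        lo = min(call.ref_bp1[1], call.ref_bp2[1])
        hi = max(call.ref_bp1[1], call.ref_bp2[1])
        return [(chrom, lo, hi)]
    pad = th.breakpoint_pad
    return [
        (call.ref_bp1[0], call.ref_bp1[1] - pad, call.ref_bp1[1] + pad),
        (call.ref_bp2[0], call.ref_bp2[1] - pad, call.ref_bp2[1] + pad),
    ]


def filter_regions(
    calls: Sequence[SVCall],
    ngaps: Optional[IntervalTrack],
    segdups: Optional[IntervalTrack],
    th: Thresholds = Thresholds(),
) -> List[SVCall]:
    """Annotate calls overlapping N-gaps (any base) or SegDups (>=20%).

    Indels are tested over their full reference interval; inversions and
    translocations over each breakpoint +/- 10 kb.  Either breakpoint window
    qualifying excludes the call.
    """
    ngap_trees = _build_tree(ngaps) if ngaps is not None else {}
    segdup_trees = _build_tree(segdups) if segdups is not None else {}
    for call in calls:
        for chrom, lo, hi in _call_intervals(call, th):
            if ngap_trees and _overlap_bp(ngap_trees, chrom, lo, hi) >= 1.0:
                call.filters_failed.add("ngap")
            if segdup_trees:
                frac = _overlap_bp(segdup_trees, chrom, lo, hi) / max(hi - lo + 1, 1.0)
                if frac >= th.segdup_frac_sv:
                    call.filters_failed.add("segdup")
    return list(calls)


def filter_size_and_blacklist(
    calls: Sequence[SVCall],
    blacklist: Optional[Sequence[tuple]] = None,
    th: Thresholds = Thresholds(),
) -> List[SVCall]:
    """Annotate indels < 1 kb ('size') and blacklisted translocations ('_common').

    A translocation is blacklisted when both of its breakpoints fall within
    ``dedup_tol`` (default 10 kb) of one blacklist breakpoint pair, in either
    pairing order.
    """
    blacklist = blacklist or []
    for call in calls:
        if call.is_indel and call.size is not None and call.size < th.min_indel_size:
            call.filters_failed.add("size")
        if call.is_translocation:
            for (c1, p1), (c2, p2) in blacklist:
                direct = (
                    call.ref_bp1[0] == c1 and abs(call.ref_bp1[1] - p1) <= th.dedup_tol
                    and call.ref_bp2[0] == c2 and abs(call.ref_bp2[1] - p2) <= th.dedup_tol
                )
                swapped = (
                    call.ref_bp1[0] == c2 and abs(call.ref_bp1[1] - p2) <= th.dedup_tol
                    and call.ref_bp2[0] == c1 and abs(call.ref_bp2[1] - p1) <= th.dedup_tol
                )
                if direct or swapped:
                    call.filters_failed.add("_common")
                    break
    return list(calls)


def passing_calls(calls: Iterable[SVCall]) -> List[SVCall]:
    return [c for c in calls if c.passed]


def breakpoints_track(calls: Iterable[SVCall], name: str = "sv_breakpoints") -> IntervalTrack:
    """All reference breakpoints as single-base intervals (for BED export)."""
    intervals = []
    for c in calls:
        for chrom, pos in (c.ref_bp1, c.ref_bp2):
            intervals.append((chrom, pos, pos))
    return IntervalTrack(name=name, intervals=intervals)
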