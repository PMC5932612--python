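"""Mosaic (multiple-local) alignment of query label maps to reference maps.

The aligner is a Smith-Waterman-style dynamic program over *label index*
pairs.  Pairing a query label with a reference label earns a fixed match
score; extending a chain from pair (i', j') to (i, j) pays one penalty unit
per skipped label on either map plus a sizing penalty

    ((q_gap - r_gap) / (sigma_rel * r_gap + sigma_0)) ** 2

comparing the inter-label distances spanned on each map, which models the
platform's relative sizing error.  Chains may restart anywhere (local
alignment), so a query whose label pattern jumps between distant reference
regions naturally decomposes into several high-scoring local segments; the
mosaic step then selects a maximum-score set of query-non-overlapping
segments across all reference chromosomes and both orientations.  Segments
require at least ``min_seg_labels`` paired labels (default 9, mirroring the
molecule label-count filter), which is what keeps short scrambled
fusion-junction fragments unaligned.
"""

from __future__ import annotations

from typing import List, Optional, Sequence

import numpy as np

from .types import LabelMap, LocalSegment, MosaicAlignment, Thresholds

__all__ = ["align_local", "mosaic"]


def _dp_fill(q: np.ndarray, r: np.ndarray, th: Thresholds):
    n, m = q.size, r.size
    K = th.max_skip_labels + 1
    match = th.match_score
    S = np.full((n, m), match, dtype=float)
    BI = np.full((n, m), -1, dtype=np.int32)  # predecessor row, -1 = chain start
    BJ = np.full((n, m), -1, dtype=np.int32)
    # precompute reference gaps and their sizing-error scale per step width
    r_gap = {dj: r[dj:] - r[:-dj] for dj in range(1, K + 1)}
    r_den = {dj: (th.sizing_sd_rel * r_gap[dj] + th.sizing_sd_bp) for dj in range(1, K + 1)}
    for i in range(1, n):
        best = S[i]
        for di in range(1, min(K, i) + 1):
            qg = q[i] - q[i - di]
            prev = S[i - di]
            for dj in range(1, K + 1):
                if dj > m - 1:
                    break
                pen = ((qg - r_gap[dj]) / r_den[dj]) ** 2
                cand = prev[:-dj] + match - th.skip_penalty * (di - 1 + dj - 1) - pen
                js = np.arange(dj, m)
                improve = cand > best[dj:]
                if np.any(improve):
                    idx = js[improve]
                    best[idx] = cand[improve]
                    BI[i, idx] = i - di
                    BJ[i, idx] = idx - dj
        S[i] = best
    return S, BI, BJ


def _step_cost(q: np.ndarray, r: np.ndarray, qi1: int, rj1: int, qi2: int, rj2: int,
               th: Thresholds) -> float:
    """Penalty of chaining pair (qi1, rj1) -> (qi2, rj2) (ref ascending)."""
    qg = q[qi2] - q[qi1]
    rg = r[rj2] - r[rj1]
    skips = (qi2 - qi1 - 1) + (rj2 - rj1 - 1)
    return th.skip_penalty * skips + ((qg - rg) / (th.sizing_sd_rel * rg + th.sizing_sd_bp)) ** 2


def _anchor_run(q: np.ndarray, r: np.ndarray, pairs: list, th: Thresholds) -> int:
    """Longest run of consecutively chained (no-skip), well-sized steps.

    A genuine locus produces an unbroken run of label pairs whose interval
    sizes agree; a chain assembled from lucky coincidences across a scrambled
    or unrelated region almost never does.
    """
    best = run = 0
    for (qi1, rj1), (qi2, rj2) in zip(pairs, pairs[1:]):
        if (qi2 - qi1 == 1 and rj2 - rj1 == 1
                and _step_cost(q, r, qi1, rj1, qi2, rj2, th) <= th.anchor_max_penalty):
            run += 1
            best = max(best, run)
        else:
            run = 0
    return best


def _end_trim(q: np.ndarray, r: np.ndarray, pairs: list, th: Thresholds) -> list:
    """Trim chain ends to the maximum-scoring subchain under a stern reward.

    Local alignment with a generous match reward tends to extend a few sloppy
    pairs past the true end of a segment (into a rearrangement junction or an
    unalignable region).  Re-scoring each step as ``end_trim_reward`` minus
    its chaining penalty and keeping the best contiguous subchain removes
    exactly those ends while leaving well-chained interiors untouched.
    """
    if len(pairs) < 2:
        return pairs
    values = [
        th.end_trim_reward - _step_cost(q, r, qi1, rj1, qi2, rj2, th)
        for (qi1, rj1), (qi2, rj2) in zip(pairs, pairs[1:])
    ]
    best_sum = cur_sum = 0.0
    best_range = (0, 0)  # pair index range [a, b]
    a = 0
    for k, v in enumerate(values):
        if cur_sum <= 0:
            cur_sum = v
            a = k
        else:
            cur_sum += v
        if cur_sum > best_sum:
            best_sum = cur_sum
            best_range = (a, k + 1)
    lo, hi = best_range
    return pairs[lo : hi + 1]


def _dp_segments(q: np.ndarray, r: np.ndarray, th: Thresholds, max_rounds: int = 8):
    """All disjoint high-scoring chains of monotone (query, ref) label pairs.

    Returns a list of (score, pairs) with pairs as [(qi, rj), ...] ascending.
    Chains may not share query labels; sharing *reference* labels is allowed,
    since duplicated query content genuinely re-aligns to one reference locus.
    Extraction is iterative: after the greedy pass, the DP is re-run on the
    still-unassigned query labels, so a chain whose traceback strays into an
    already-extracted chain is recovered on the next round rather than lost.
    """
    n_all, m = q.size, r.size
    if n_all == 0 or m == 0:
        return []
    assigned = np.zeros(n_all, dtype=bool)
    segments = []
    for _round in range(max_rounds):
        active = np.flatnonzero(~assigned)
        if active.size < th.min_seg_labels:
            break
        qa = q[active]
        S, BI, BJ = _dp_fill(qa, r, th)
        order = np.argsort(S, axis=None)[::-1]
        used_q = np.zeros(active.size, dtype=bool)
        flat_scores = S.ravel()
        found = 0
        for flat in order:
            if flat_scores[flat] < th.min_seg_score:
                break
            i, j = divmod(int(flat), m)
            if used_q[i]:
                continue
            pairs = []
            ci, cj = i, j
            clean = True
            while ci != -1:
                if used_q[ci]:
                    clean = False
                    break
                pairs.append((ci, cj))
                ci, cj = int(BI[ci, cj]), int(BJ[ci, cj])
            if not clean or len(pairs) < th.min_seg_labels:
                continue
            pairs.reverse()
            orig_pairs = [(int(active[qi]), rj) for qi, rj in pairs]
            orig_pairs = _end_trim(q, r, orig_pairs, th)
            if len(orig_pairs) < th.min_seg_labels:
                continue
            if len(orig_pairs) < th.anchor_exempt_pairs and _anchor_run(
                q, r, orig_pairs, th
            ) < min(th.min_anchor_pairs, len(orig_pairs) - 1):
                continue
            # exact chain score under the scoring model (restart at one match)
            score = th.match_score * len(orig_pairs) - sum(
                _step_cost(q, r, a[0], a[1], b[0], b[1], th)
                for a, b in zip(orig_pairs, orig_pairs[1:])
            )
            if score < th.min_seg_score:
                continue
            kept = set(qi for qi, _ in orig_pairs)
            for qi, _rj in pairs:
                if int(active[qi]) in kept:
                    used_q[qi] = True
            segments.append((float(score), orig_pairs))
            found += 1
        if found == 0:
            break
        assigned[active[used_q]] = True
    return segments


def align_local(
    query: LabelMap,
    ref: LabelMap,
    orientation: str = "+",
    th: Thresholds = Thresholds(),
) -> List[LocalSegment]:
    """Local alignments of ``query`` against ``ref`` in one orientation."""
    if orientation not in ("+", "-"):
        raise ValueError(f"orientation must be + or -, got {orientation!r}")
    q = query.labels
    if orientation == "-":
        q = (query.length_bp + 1.0) - q[::-1]
    raw = _dp_segments(q, ref.labels, th)
    out = []
    for score, pairs in raw:
        out.append(_chain_to_segment(query, ref, orientation, score, pairs))
    out.sort(key=lambda s: s.q_start)
    return out


def _chain_to_segment(query: LabelMap, ref: LabelMap, orientation: str,
                      score: float, pairs: list) -> LocalSegment:
    """Build a LocalSegment from a DP chain (pairs in reflected-query space
    for '-' orientation)."""
    n = query.n_labels
    if orientation == "-":
        # map back to original query indices; ref indices become descending
        pairs = [(n - 1 - qi, rj) for qi, rj in pairs]
        pairs = list(reversed(pairs))  # ascending in original query coordinate
    q_idx = [p[0] for p in pairs]
    r_idx = [p[1] for p in pairs]
    return LocalSegment(
        query_id=query.map_id,
        ref_id=ref.map_id,
        orientation=orientation,
        pairs=pairs,
        q_start=float(query.labels[min(q_idx)]),
        q_end=float(query.labels[max(q_idx)]),
        r_start=float(ref.labels[min(r_idx)]),
        r_end=float(ref.labels[max(r_idx)]),
        score=score,
    )


class ReferenceIndex:
    """All reference maps concatenated into one coordinate axis.

    Chromosomes are separated by a spacer far larger than any plausible
    inter-label distance, so no DP chain can cross a boundary (the sizing
    penalty across the spacer is astronomically large and skips are capped);
    aligning against the concatenation is then equivalent to aligning against
    every chromosome separately, at a fraction of the dispatch overhead.
    """

    SPACER = 5e7

    def __init__(self, refs: Sequence[LabelMap]):
        self.refs = list(refs)
        labels = []
        chrom_idx = []
        local_idx = []
        offset = 0.0
        for ci, ref in enumerate(self.refs):
            labels.append(ref.labels + offset)
            chrom_idx.append(np.full(ref.n_labels, ci, dtype=np.int32))
            local_idx.append(np.arange(ref.n_labels, dtype=np.int32))
            offset += ref.length_bp + self.SPACER
        self.labels = np.concatenate(labels) if labels else np.array([])
        self.chrom_idx = np.concatenate(chrom_idx) if labels else np.array([], dtype=np.int32)
        self.local_idx = np.concatenate(local_idx) if labels else np.array([], dtype=np.int32)


def _select_segments(segments: List[LocalSegment], th: Thresholds) -> List[LocalSegment]:
    """Maximum-score set of query-non-overlapping segments.

    Weighted interval scheduling over query *label index* spans; two selected
    segments may share at most 2 boundary labels (mirroring the +/-2-label
    support slop).  Deterministic tie-break: higher score, then lower ref id,
    then leftmost reference start.
    """
    if not segments:
        return []
    # deterministic candidate order: by query span, then higher score, then
    # lower ref id, then leftmost reference start
    segs = sorted(
        segments,
        key=lambda s: (s.q_idx_span[1], s.q_idx_span[0], -s.score, s.ref_id, s.r_start),
    )
    n = len(segs)
    # selection tolerates a wider overlap than the final mosaic: chains from a
    # junction region may interleave, and the surplus boundary pairs are
    # trimmed afterwards (see _trim_boundary_overlaps)
    slop = th.select_overlap_labels
    prev_idx = [0] * n  # p[k]: # of candidates compatible before segs[k]
    for k, s in enumerate(segs):
        lo = s.q_idx_span[0]
        p = 0
        for t in range(k - 1, -1, -1):
            if segs[t].q_idx_span[1] <= lo + slop - 1:
                p = t + 1
                break
        prev_idx[k] = p
    f = [0.0] * (n + 1)
    for k in range(1, n + 1):
        take = segs[k - 1].score + f[prev_idx[k - 1]]
        f[k] = max(take, f[k - 1])
    chosen = []
    k = n
    while k > 0:
        take = segs[k - 1].score + f[prev_idx[k - 1]]
        if take > f[k - 1]:
            chosen.append(segs[k - 1])
            k = prev_idx[k - 1]
        else:
            k -= 1
    chosen.reverse()
    return chosen


def _rebuild_segment(seg: LocalSegment, pairs: list, query: LabelMap, ref: LabelMap) -> LocalSegment:
    q_idx = [p[0] for p in pairs]
    r_idx = [p[1] for p in pairs]
    return LocalSegment(
        query_id=seg.query_id, ref_id=seg.ref_id, orientation=seg.orientation,
        pairs=pairs,
        q_start=float(query.labels[min(q_idx)]), q_end=float(query.labels[max(q_idx)]),
        r_start=float(ref.labels[min(r_idx)]), r_end=float(ref.labels[max(r_idx)]),
        score=seg.score,
    )


def _pair_step_cost(query: LabelMap, ref: LabelMap, seg: LocalSegment, k: int,
                    th: Thresholds) -> float:
    """Chaining penalty of the step between seg.pairs[k] and seg.pairs[k+1]."""
    (qi1, rj1), (qi2, rj2) = seg.pairs[k], seg.pairs[k + 1]
    qg = query.labels[qi2] - query.labels[qi1]
    if seg.orientation == "+":
        rg = ref.labels[rj2] - ref.labels[rj1]
    else:
        rg = ref.labels[rj1] - ref.labels[rj2]
    skips = (qi2 - qi1 - 1) + (abs(rj2 - rj1) - 1)
    return th.skip_penalty * skips + ((qg - rg) / (th.sizing_sd_rel * rg + th.sizing_sd_bp)) ** 2


def _trim_boundary_overlaps(
    query: LabelMap,
    segments: List[LocalSegment],
    ref_by_id: dict,
    th: Thresholds,
) -> List[LocalSegment]:
    """Reduce query overlap of adjacent selected segments to <= 2 labels.

    Where two segments claim the same junction-adjacent query labels, the
    surplus terminal pairs are removed from whichever side chains them more
    poorly (larger step penalty), so breakpoints settle on the register that
    genuinely fits.  Segments falling below the minimum pair count are
    dropped.
    """
    segs = sorted(segments, key=lambda s: s.q_idx_span)
    out: List[LocalSegment] = []
    for seg in segs:
        cur = seg
        while out and cur is not None:
            left = out[-1]
            lo, hi = cur.q_idx_span
            overlap = left.q_idx_span[1] - lo + 1  # shared labels (by span)
            if overlap <= th.support_label_slop:
                break
            cost_left = (_pair_step_cost(query, ref_by_id[left.ref_id], left, len(left.pairs) - 2, th)
                         if len(left.pairs) >= 2 else float("inf"))
            cost_cur = (_pair_step_cost(query, ref_by_id[cur.ref_id], cur, 0, th)
                        if len(cur.pairs) >= 2 else float("inf"))
            if cost_left > cost_cur:
                new_pairs = left.pairs[:-1]
                if len(new_pairs) < th.min_seg_labels:
                    out.pop()
                else:
                    out[-1] = _rebuild_segment(left, new_pairs, query, ref_by_id[left.ref_id])
            else:
                new_pairs = cur.pairs[1:]
                if len(new_pairs) < th.min_seg_labels:
                    cur = None
                else:
                    cur = _rebuild_segment(cur, new_pairs, query, ref_by_id[cur.ref_id])
        if cur is not None:
            out.append(cur)
    return out


def mosaic(
    query: LabelMap,
    refs: "Sequence[LabelMap] | ReferenceIndex",
    th: Thresholds = Thresholds(),
) -> MosaicAlignment:
    """Mosaic alignment of ``query`` against every reference map.

    Accepts a prebuilt :class:`ReferenceIndex` to amortize the concatenation
    across many queries.
    """
    index = refs if isinstance(refs, ReferenceIndex) else ReferenceIndex(refs)
    candidates: List[LocalSegment] = []
    for orientation in ("+", "-"):
        q = query.labels
        if orientation == "-":
            q = (query.length_bp + 1.0) - q[::-1]
        for score, pairs in _dp_segments(q, index.labels, th):
            # split defensively at chromosome boundaries (crossing chains are
            # impossible by construction of the spacer)
            groups: List[tuple] = []  # (chrom_index, [(qi, local_rj), ...])
            last_c = None
            for qi, rj in pairs:
                c = int(index.chrom_idx[rj])
                if c != last_c:
                    groups.append((c, []))
                    last_c = c
                groups[-1][1].append((qi, int(index.local_idx[rj])))
            for c, grp in groups:
                if len(grp) < th.min_seg_labels:
                    continue
                grp_score = score if len(groups) == 1 else th.match_score * len(grp)
                candidates.append(_chain_to_segment(query, index.refs[c], orientation, grp_score, grp))
    selected = _select_segments(candidates, th)
    ref_by_id = {r.map_id: r for r in index.refs}
    selected = _trim_boundary_overlaps(query, selected, ref_by_id, th)
    return MosaicAlignment(query_id=query.map_id, query_length=query.length_bp, segments=selected)
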