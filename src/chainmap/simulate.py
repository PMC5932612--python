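"""Synthetic rearranged genomes, optical maps, and matched breakend calls.

The generator emulates the statistical structure the analysis assumes:

* a multi-chromosome reference with realistic nicking-label density
  (~9 labels / 100 kb at GC 0.41 for the default motif);
* derivative chromosomes built by chained fusion of donor fragments drawn
  mostly from a few designated donor chromosomes (mirroring the concentration
  of rearrangement on a handful of chromosomes in neochromosome-bearing
  genomes), with optional scrambled micro-fragment chains (1-50 kb pieces)
  interposed at junctions -- large enough to carry short-read breakpoints but
  too label-poor to align optically;
* an optical measurement model (relative sizing error, label dropout, false
  labels, ~1 kb resolution);
* a short-read breakend call set for every true junction, with quality scores
  above/below the 500 cutoff according to a detection model whose failures
  cluster by locus, plus false calls at a configurable rate;
* a machine-readable truth set (construction plan, implied SVs, junctions).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .digest import Motif, apply_resolution, digest_sequence
from .types import BreakendCall, LabelMap, Molecule, SVCall

__all__ = [
    "NoiseModel",
    "DonorPiece",
    "InsertChain",
    "RearrangementPlan",
    "TruthSV",
    "TruthJunction",
    "TruthSet",
    "simulate_reference",
    "random_plan",
    "build_derivative",
    "simulate_derivative",
    "noisy_map",
    "sample_maps",
    "simulate_maps",
    "simulate_breakends",
    "match_recall",
    "liposarcoma_like",
    "LiposarcomaPreset",
]

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# noise / plan / truth containers


@dataclass
class NoiseModel:
    """Optical-map measurement model.

    ``sizing_sd_rel`` perturbs each inter-label interval by a Gaussian
    relative error; ``label_miss_p`` drops true labels i.i.d.;
    ``false_label_rate`` adds spurious labels as a Poisson process per bp;
    ``resolution_bp`` merges labels closer than the instrument resolution.
    """

    sizing_sd_rel: float = 0.02
    label_miss_p: float = 0.10
    false_label_rate: float = 8e-6
    resolution_bp: float = 1_000.0

    def __post_init__(self) -> None:
        if not (0 <= self.label_miss_p <= 1):
            raise ValueError("label_miss_p must be in [0, 1]")
        if self.sizing_sd_rel < 0 or self.false_label_rate < 0:
            raise ValueError("noise magnitudes must be non-negative")

    @classmethod
    def zero(cls) -> "NoiseModel":
        return cls(sizing_sd_rel=0.0, label_miss_p=0.0, false_label_rate=0.0, resolution_bp=0.0)


@dataclass(frozen=True)
class DonorPiece:
    """One reference fragment of a derivative chromosome (1-based inclusive)."""

    chrom: str
    start: float
    end: float
    orient: str = "+"

    @property
    def length(self) -> float:
        return self.end - self.start + 1

    def exit_breakend(self) -> tuple:
        return (self.chrom, self.end, "right") if self.orient == "+" else (self.chrom, self.start, "left")

    def entry_breakend(self) -> tuple:
        return (self.chrom, self.start, "left") if self.orient == "+" else (self.chrom, self.end, "right")


@dataclass(frozen=True)
class InsertChain:
    """A chain of scrambled sub-alignable micro-fragments at a junction."""

    pieces: Tuple[DonorPiece, ...]

    @property
    def length(self) -> float:
        return sum(p.length for p in self.pieces)


@dataclass
class RearrangementPlan:
    """Construction plan of one derivative chromosome."""

    derivative_id: str
    seed: int
    items: list  # alternating DonorPiece / InsertChain (never two chains adjacent)
    event_log: list = field(default_factory=list)

    @property
    def donor_pieces(self) -> List[DonorPiece]:
        return [it for it in self.items if isinstance(it, DonorPiece)]

    @property
    def total_length(self) -> float:
        return sum(it.length for it in self.items)


@dataclass
class TruthSV:
    derivative_id: str
    sv_type: str
    bp1: tuple  # (chrom, pos)
    bp2: tuple
    size: Optional[float]
    query_pos: float  # junction position on the derivative (bp)


@dataclass
class TruthJunction:
    junction_id: str
    derivative_id: str
    kind: str  # event type of the adjacency
    left: tuple  # (chrom, pos, side)
    right: tuple
    gap: float  # total micro-fragment bp between the donor ends
    chain: list  # [(breakend_a, breakend_b, inserted_len), ...]; len = n_micro + 1
    query_span: tuple  # (q_left, q_right) on the derivative


@dataclass
class TruthSet:
    svs: List[TruthSV] = field(default_factory=list)
    junctions: List[TruthJunction] = field(default_factory=list)
    plans: List[RearrangementPlan] = field(default_factory=list)
    provenance: Dict[str, dict] = field(default_factory=dict)  # map_id -> source info

    def conservation_ok(self, derivatives: Dict[str, LabelMap]) -> bool:
        for plan in self.plans:
            if plan.derivative_id in derivatives:
                if abs(plan.total_length - derivatives[plan.derivative_id].length_bp) > 0.5:
                    return False
        return True


# ---------------------------------------------------------------------------
# reference


def simulate_reference(
    seed: int,
    n_chrom: int = 20,
    chrom_len: Union[float, Sequence[float]] = 3_000_000.0,
    gc: float = 0.41,
    motif: Motif = Motif(),
    resolution_bp: float = 1_000.0,
    return_sequences: bool = True,
):
    """Random reference genome plus its in silico digest.

    Returns ``(seqs, label_maps)``; ``seqs`` is ``None`` when
    ``return_sequences`` is false.  Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    if np.isscalar(chrom_len):
        lengths = [float(chrom_len)] * n_chrom
    else:
        lengths = [float(x) for x in chrom_len]
        n_chrom = len(lengths)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seqs: Dict[str, str] = {}
    maps: List[LabelMap] = []
    for i, L in enumerate(lengths, start=1):
        name = f"chr{i:02d}"
        codes = rng.choice(4, size=int(L), p=p)
        seq = BASES[codes].tobytes().decode("ascii")
        labels = apply_resolution(digest_sequence(seq, motif), resolution_bp) if resolution_bp > 0 \
            else digest_sequence(seq, motif)
        maps.append(LabelMap(map_id=name, length_bp=float(int(L)), labels=labels, source="reference"))
        if return_sequences:
            seqs[name] = seq
    return (seqs if return_sequences else None), maps


# ---------------------------------------------------------------------------
# derivative planning


def _rand_interval(rng: np.random.Generator, chrom_len: float, frag_len: float) -> Tuple[float, float]:
    frag_len = min(frag_len, chrom_len)
    start = float(rng.integers(1, int(chrom_len - frag_len + 1) + 1))
    return start, start + frag_len - 1


def _rand_piece(rng, ref_len: Dict[str, float], chroms: Sequence[str],
                len_range: Tuple[float, float], p_invert: float) -> DonorPiece:
    chrom = str(rng.choice(list(chroms)))
    L = float(rng.uniform(*len_range))
    start, end = _rand_interval(rng, ref_len[chrom], round(L))
    orient = "-" if rng.random() < p_invert else "+"
    return DonorPiece(chrom=chrom, start=start, end=end, orient=orient)


MAX_MICRO_LABELS = 6  # pieces stay below the aligner's minimum segment size


def _micro_piece(rng, ref_labels: Dict[str, np.ndarray], ref_len: Dict[str, float],
                 L: float, chroms: list) -> DonorPiece:
    """One scrambled micro-fragment, sub-alignable by construction.

    Candidate intervals carrying enough labels to seed an optical alignment
    on their own are rejected, so junction content aligns nowhere -- the
    defining property of fusion-junction intervals.
    """
    for _ in range(50):
        chrom = str(rng.choice(chroms))
        start, end = _rand_interval(rng, ref_len[chrom], L)
        lab = ref_labels[chrom]
        n = int(np.searchsorted(lab, end, side="right") - np.searchsorted(lab, start))
        if n <= MAX_MICRO_LABELS:
            orient = "-" if rng.random() < 0.5 else "+"
            return DonorPiece(chrom, start, end, orient)
    # fall back to a shorter piece (label-dense genome)
    return _micro_piece(rng, ref_labels, ref_len, max(L / 2, 1_000.0), chroms)


def _micro_chain(rng, ref_labels: Dict[str, np.ndarray], ref_len: Dict[str, float],
                 total_len: Optional[float], n_pieces: Optional[int],
                 micro_len: Tuple[float, float]) -> InsertChain:
    """Chain of 1-50 kb scrambled pieces, by piece count or by target length."""
    pieces = []
    chroms = sorted(ref_len)
    if n_pieces is not None:
        for _ in range(int(n_pieces)):
            L = round(float(rng.uniform(*micro_len)))
            pieces.append(_micro_piece(rng, ref_labels, ref_len, L, chroms))
    else:
        acc = 0.0
        while acc < total_len:
            L = round(float(rng.uniform(*micro_len)))
            L = min(L, max(total_len - acc, 1_000.0))
            pieces.append(_micro_piece(rng, ref_labels, ref_len, L, chroms))
            acc += pieces[-1].length
    return InsertChain(pieces=tuple(pieces))


def random_plan(
    ref_maps: Sequence[LabelMap],
    seed: int,
    derivative_id: str = "der1",
    donors: Optional[Sequence[str]] = None,
    n_events: int = 4,
    frag_len: Tuple[float, float] = (250_000.0, 600_000.0),
    p_invert: float = 0.3,
    junction_insert_p: float = 0.8,
    chain_pieces: Tuple[int, int] = (2, 10),
    micro_len: Tuple[float, float] = (1_000.0, 50_000.0),
    indel_size: Tuple[float, float] = (20_000.0, 300_000.0),
    inv_sep: Tuple[float, float] = (50_000.0, 500_000.0),
    intra_sep_min: float = 5_500_000.0,
    event_weights: Optional[Dict[str, float]] = None,
) -> RearrangementPlan:
    """Draw a random chained-fusion construction plan.

    Donor fragments come from the designated donor chromosomes (default: the
    three longest, emulating the concentration of donor sequence on a few
    chromosomes); micro-fragment chains are shredded from anywhere in the
    genome so that their label patterns are unique, not repetitive.
    """
    rng = np.random.default_rng(seed)
    ref_len = {m.map_id: m.length_bp for m in ref_maps}
    ref_labels = {m.map_id: m.labels for m in ref_maps}
    if donors is None:
        donors = [m.map_id for m in sorted(ref_maps, key=lambda m: -m.length_bp)[:3]]
    donors = sorted(donors)
    weights = event_weights or {
        "inter_translocation": 0.50,
        "intra_translocation": 0.10,
        "inversion": 0.10,
        "deletion": 0.15,
        "insertion": 0.15,
    }
    kinds = sorted(weights)
    probs = np.array([weights[k] for k in kinds], dtype=float)
    probs = probs / probs.sum()

    items: list = [_rand_piece(rng, ref_len, donors, frag_len, p_invert)]
    log: list = [{"op": "anchor", "piece": dataclasses.asdict(items[0])}]

    def fallback_inter(cur: DonorPiece) -> Tuple[str, DonorPiece]:
        other = [c for c in donors if c != cur.chrom] or donors
        nxt = _rand_piece(rng, ref_len, other, frag_len, p_invert)
        return "inter_translocation", nxt

    for _ in range(n_events):
        cur: DonorPiece = items[-1]
        kind = str(rng.choice(kinds, p=probs))
        nxt: Optional[DonorPiece] = None
        chain: Optional[InsertChain] = None
        if kind == "inter_translocation":
            kind, nxt = fallback_inter(cur)
            if rng.random() < junction_insert_p:
                chain = _micro_chain(rng, ref_labels, ref_len, None,
                                     rng.integers(chain_pieces[0], chain_pieces[1] + 1), micro_len)
        elif kind == "intra_translocation":
            L = round(float(rng.uniform(*frag_len)))
            lo = intra_sep_min
            exit_pos = cur.exit_breakend()[1]
            right_room = ref_len[cur.chrom] - (exit_pos + lo) - L
            left_room = exit_pos - lo - L
            if right_room > 0:
                start = float(rng.integers(int(exit_pos + lo), int(exit_pos + lo + right_room) + 1))
                nxt = DonorPiece(cur.chrom, start, start + L - 1, "-" if rng.random() < p_invert else "+")
            elif left_room > 1:
                start = float(rng.integers(1, int(left_room) + 1))
                nxt = DonorPiece(cur.chrom, start, start + L - 1, "-" if rng.random() < p_invert else "+")
            else:
                kind, nxt = fallback_inter(cur)
            if rng.random() < junction_insert_p:
                chain = _micro_chain(rng, ref_labels, ref_len, None,
                                     rng.integers(chain_pieces[0], chain_pieces[1] + 1), micro_len)
        elif kind == "inversion":
            sep = round(float(rng.uniform(*inv_sep)))
            L = round(float(rng.uniform(*frag_len)))
            if cur.orient == "+":
                start = cur.end + sep
                cand = DonorPiece(cur.chrom, start, start + L - 1, "-")
                ok = cand.end <= ref_len[cur.chrom]
            else:
                end = cur.start - sep
                cand = DonorPiece(cur.chrom, end - L + 1, end, "+")
                ok = cand.start >= 1
            if ok:
                nxt = cand
            else:
                kind, nxt = fallback_inter(cur)
        elif kind == "deletion":
            s = round(float(rng.uniform(*indel_size)))
            L = round(float(rng.uniform(*frag_len)))
            if cur.orient == "+":
                start = cur.end + 1 + s
                cand = DonorPiece(cur.chrom, start, start + L - 1, "+")
                ok = cand.end <= ref_len[cur.chrom]
            else:
                end = cur.start - 1 - s
                cand = DonorPiece(cur.chrom, end - L + 1, end, "-")
                ok = cand.start >= 1
            if ok:
                nxt = cand
            else:
                kind, nxt = fallback_inter(cur)
        elif kind == "insertion":
            s = round(float(rng.uniform(*indel_size)))
            L = round(float(rng.uniform(*frag_len)))
            if cur.orient == "+":
                start = cur.end + 1
                cand = DonorPiece(cur.chrom, start, start + L - 1, "+")
                ok = cand.end <= ref_len[cur.chrom]
            else:
                end = cur.start - 1
                cand = DonorPiece(cur.chrom, end - L + 1, end, "-")
                ok = cand.start >= 1
            if ok:
                nxt = cand
                chain = _micro_chain(rng, ref_labels, ref_len, float(s), None, micro_len)
            else:
                kind, nxt = fallback_inter(cur)
        if chain is not None:
            items.append(chain)
        items.append(nxt)
        log.append({
            "op": kind,
            "piece": dataclasses.asdict(nxt),
            "insert_len": chain.length if chain is not None else 0.0,
            "n_micro": len(chain.pieces) if chain is not None else 0,
        })
    return RearrangementPlan(derivative_id=derivative_id, seed=seed, items=items, event_log=log)


# ---------------------------------------------------------------------------
# derivative construction + truth


def _piece_labels(piece: DonorPiece, ref_by_id: Dict[str, LabelMap], offset: float) -> np.ndarray:
    ref = ref_by_id[piece.chrom]
    lab = ref.labels
    sel = lab[(lab >= piece.start) & (lab <= piece.end)]
    if piece.orient == "+":
        out = offset + (sel - piece.start + 1)
    else:
        out = offset + (piece.end - sel + 1)
        out = out[::-1]
    return out


def build_derivative(plan: RearrangementPlan, ref_maps: Sequence[LabelMap]) -> LabelMap:
    """Replay a plan into the derivative's label map (pure function of plan)."""
    ref_by_id = {m.map_id: m for m in ref_maps}
    labels: List[np.ndarray] = []
    offset = 0.0
    for item in plan.items:
        if isinstance(item, DonorPiece):
            labels.append(_piece_labels(item, ref_by_id, offset))
            offset += item.length
        else:
            for piece in item.pieces:
                labels.append(_piece_labels(piece, ref_by_id, offset))
                offset += piece.length
    allpos = np.concatenate(labels) if labels else np.array([])
    if allpos.size:
        keep = np.concatenate(([True], np.diff(allpos) > 0))
        allpos = allpos[keep]
    return LabelMap(map_id=plan.derivative_id, length_bp=offset, labels=allpos, source="consensus")


def _plan_truth(plan: RearrangementPlan) -> Tuple[List[TruthSV], List[TruthJunction]]:
    svs: List[TruthSV] = []
    junctions: List[TruthJunction] = []
    # walk items, tracking derivative offsets
    offset = 0.0
    prev_piece: Optional[DonorPiece] = None
    prev_exit_q = 0.0
    pending_chain: Optional[InsertChain] = None
    pending_chain_q = 0.0
    event_iter = iter(plan.event_log[1:])  # skip anchor
    jidx = 0
    for item in plan.items:
        if isinstance(item, InsertChain):
            pending_chain = item
            pending_chain_q = offset
            offset += item.length
            continue
        piece: DonorPiece = item
        if prev_piece is not None:
            event = next(event_iter)
            kind = event["op"]
            gap = pending_chain.length if pending_chain is not None else 0.0
            left = prev_piece.exit_breakend()
            right = piece.entry_breakend()
            q_left = prev_exit_q
            q_right = offset
            # implied SV record
            if kind in ("deletion", "insertion"):
                if kind == "deletion":
                    size = abs(abs(right[1] - left[1]) - 1 - gap)
                else:
                    size = gap - (abs(right[1] - left[1]) - 1)
                svs.append(TruthSV(plan.derivative_id, kind, (left[0], left[1]),
                                   (right[0], right[1]), float(size), q_left))
            else:
                svs.append(TruthSV(plan.derivative_id, kind, (left[0], left[1]),
                                   (right[0], right[1]), None, q_left))
            # junction + its micro chain (traversable kinds only)
            if kind in ("inter_translocation", "intra_translocation", "inversion"):
                chain = []
                prev_be = left
                if pending_chain is not None:
                    for micro in pending_chain.pieces:
                        chain.append((prev_be, micro.entry_breakend(), 0.0))
                        prev_be = micro.exit_breakend()
                chain.append((prev_be, right, 0.0))
                junctions.append(TruthJunction(
                    junction_id=f"{plan.derivative_id}_j{jidx}",
                    derivative_id=plan.derivative_id,
                    kind=kind, left=left, right=right, gap=gap, chain=chain,
                    query_span=(q_left, q_right),
                ))
                jidx += 1
        prev_piece = piece
        offset += piece.length
        prev_exit_q = offset
        pending_chain = None
    return svs, junctions


def simulate_derivative(
    ref_maps: Sequence[LabelMap],
    seed: int,
    derivative_id: str = "der1",
    plan: Optional[RearrangementPlan] = None,
    **plan_kwargs,
) -> Tuple[RearrangementPlan, LabelMap, TruthSet]:
    """Plan (unless given) and build one derivative chromosome with truth."""
    if plan is None:
        plan = random_plan(ref_maps, seed=seed, derivative_id=derivative_id, **plan_kwargs)
    derivative = build_derivative(plan, ref_maps)
    svs, junctions = _plan_truth(plan)
    truth = TruthSet(svs=svs, junctions=junctions, plans=[plan])
    return plan, derivative, truth


# ---------------------------------------------------------------------------
# measurement


def noisy_map(
    src: LabelMap,
    noise: NoiseModel,
    rng: np.random.Generator,
    map_id: str,
    window: Optional[Tuple[float, float]] = None,
    source: str = "consensus",
    snr: Optional[float] = None,
) -> LabelMap:
    """One noisy measurement of ``src`` (optionally of a window of it)."""
    base = src if window is None else src.window(*window)
    labels = base.labels
    if noise.label_miss_p > 0 and labels.size:
        labels = labels[rng.random(labels.size) >= noise.label_miss_p]
    if noise.false_label_rate > 0:
        n_false = rng.poisson(noise.false_label_rate * base.length_bp)
        if n_false:
            false = rng.uniform(1.0, base.length_bp, size=n_false)
            labels = np.sort(np.concatenate([labels, false]))
    labels = np.unique(labels)
    length = base.length_bp
    if noise.sizing_sd_rel > 0:
        bounds = np.concatenate([[0.0], labels, [length]])
        gaps = np.diff(bounds)
        scale = np.clip(1.0 + rng.normal(0.0, noise.sizing_sd_rel, size=gaps.size), 0.05, None)
        newb = np.concatenate([[0.0], np.cumsum(gaps * scale)])
        labels = newb[1:-1]
        length = float(newb[-1])
    if noise.resolution_bp > 0:
        labels = apply_resolution(labels, noise.resolution_bp)
    labels = labels[(labels >= 1.0) & (labels <= length)]
    if source == "molecule":
        return Molecule(map_id=map_id, length_bp=length, labels=labels, source="molecule",
                        snr=snr if snr is not None else 3.5, avg_intensity=1.0)
    return LabelMap(map_id=map_id, length_bp=length, labels=labels, source=source)


def sample_maps(
    genomes: Sequence[LabelMap],
    noise: NoiseModel,
    rng: np.random.Generator,
    coverage: float,
    map_len: Tuple[float, float],
    source: str = "molecule",
    id_prefix: str = "mol",
    provenance: Optional[Dict[str, dict]] = None,
) -> List[LabelMap]:
    """Window-sample maps/molecules from genome label maps at given coverage."""
    out: List[LabelMap] = []
    counter = 0
    for g in genomes:
        mean_len = 0.5 * (map_len[0] + map_len[1])
        n = int(np.ceil(coverage * g.length_bp / mean_len))
        for _ in range(n):
            L = float(rng.uniform(*map_len))
            L = min(L, g.length_bp)
            start = float(rng.integers(1, int(g.length_bp - L + 1) + 1))
            map_id = f"{id_prefix}{counter:06d}"
            counter += 1
            m = noisy_map(g, noise, rng, map_id, window=(start, start + L - 1), source=source)
            if provenance is not None:
                provenance[map_id] = {"source": g.map_id, "window": (start, start + L - 1)}
            out.append(m)
    return out


def simulate_maps(
    genomes: Sequence[LabelMap],
    noise: NoiseModel,
    rng: np.random.Generator,
    n_replicates: int = 1,
    pair_ids: bool = False,
    id_prefix: str = "map",
    provenance: Optional[Dict[str, dict]] = None,
) -> List[LabelMap]:
    """Full-length consensus-map measurements of each genome map.

    With ``pair_ids`` and ``n_replicates=2`` the two replicates of one genome
    map model a haplomap pair and share a pair id in the provenance record.
    """
    out = []
    for g in genomes:
        for rep in range(n_replicates):
            map_id = f"{id_prefix}_{g.map_id}_{rep}"
            m = noisy_map(g, noise, rng, map_id, source="consensus")
            if provenance is not None:
                rec = {"source": g.map_id, "window": (1.0, g.length_bp)}
                if pair_ids:
                    rec["pair_id"] = f"pair_{g.map_id}"
                provenance[map_id] = rec
            out.append(m)
    return out


# ---------------------------------------------------------------------------
# breakends


def simulate_breakends(
    truth: TruthSet,
    seed: int,
    detection: float = 0.95,
    locus_detect_p: float = 0.92,
    fdr: float = 0.05,
    chrom_lengths: Optional[Dict[str, float]] = None,
    qual_detected: Tuple[float, float] = (600.0, 3000.0),
    qual_missed: Tuple[float, float] = (10.0, 490.0),
) -> List[BreakendCall]:
    """Breakend calls for every true junction, plus false calls at rate fdr.

    ``detection`` is the *marginal* probability that a junction is called with
    quality above the 500 cutoff.  Detection failures cluster by locus: each
    junction chain draws a "locus detectable" latent with probability
    ``locus_detect_p``; junctions of detectable loci are always called above
    cutoff, the rest at the conditional rate that preserves the marginal.
    """
    rng = np.random.default_rng(seed)
    pi = min(locus_detect_p, detection)
    q_bad = 1.0 if pi >= 1.0 else min(max((detection - pi) / (1.0 - pi), 0.0), 1.0)
    calls: List[BreakendCall] = []
    for junc in truth.junctions:
        locus_ok = rng.random() < pi
        for i, (be_a, be_b, ins) in enumerate(junc.chain):
            detected = locus_ok or (rng.random() < q_bad)
            quality = float(rng.uniform(*qual_detected)) if detected else float(rng.uniform(*qual_missed))
            calls.append(BreakendCall(
                id=f"{junc.junction_id}_c{i}",
                chrom1=be_a[0], pos1=be_a[1], side1=be_a[2],
                chrom2=be_b[0], pos2=be_b[1], side2=be_b[2],
                inserted_len=float(ins), quality=quality,
            ))
    if fdr > 0 and calls and chrom_lengths:
        chroms = sorted(chrom_lengths)
        n_false = rng.binomial(len(calls), fdr)
        for i in range(n_false):
            c1, c2 = rng.choice(chroms), rng.choice(chroms)
            calls.append(BreakendCall(
                id=f"false_{i}",
                chrom1=str(c1), pos1=float(rng.integers(1, int(chrom_lengths[str(c1)]))),
                side1="left" if rng.random() < 0.5 else "right",
                chrom2=str(c2), pos2=float(rng.integers(1, int(chrom_lengths[str(c2)]))),
                side2="left" if rng.random() < 0.5 else "right",
                inserted_len=0.0, quality=float(rng.uniform(*qual_detected)),
            ))
    return calls


# ---------------------------------------------------------------------------
# evaluation against truth


def match_recall(
    calls: Sequence[SVCall],
    truth_svs: Sequence[TruthSV],
    tol_bp: float = 100_000.0,  # same tolerance the concordance rule uses
    types: Optional[Sequence[str]] = None,
    min_size: Optional[float] = None,
    transloc_any: bool = True,
) -> Tuple[int, int]:
    """(n_recovered, n_truth) for truth SVs of the requested types/sizes.

    A truth SV is recovered when some call of the same type (intra/inter
    translocations interchangeable when ``transloc_any``) places both
    reference breakpoints within ``tol_bp``, in either pairing order.
    """
    def type_ok(call_type: str, truth_type: str) -> bool:
        if call_type == truth_type:
            return True
        transloc = {"intra_translocation", "inter_translocation"}
        return transloc_any and call_type in transloc and truth_type in transloc

    def bp_match(call: SVCall, t: TruthSV) -> bool:
        pairs = [
            (call.ref_bp1, call.ref_bp2),
            (call.ref_bp2, call.ref_bp1),
        ]
        for a, b in pairs:
            if (a[0] == t.bp1[0] and abs(a[1] - t.bp1[1]) <= tol_bp
                    and b[0] == t.bp2[0] and abs(b[1] - t.bp2[1]) <= tol_bp):
                return True
        return False

    selected = [
        t for t in truth_svs
        if (types is None or t.sv_type in types)
        and (min_size is None or (t.size is not None and t.size > min_size))
    ]
    n_hit = 0
    for t in selected:
        if any(type_ok(c.sv_type, t.sv_type) and bp_match(c, t) for c in calls):
            n_hit += 1
    return n_hit, len(selected)


# ---------------------------------------------------------------------------
# the liposarcoma-like preset


@dataclass
class LiposarcomaPreset:
    """All artifacts of one simulated study replicate."""

    ref_maps: List[LabelMap]
    derivatives: Dict[str, LabelMap]
    truth: TruthSet
    consensus_maps: List[LabelMap]
    provenance: Dict[str, dict]
    breakend_calls: List[BreakendCall]
    chrom_lengths: Dict[str, float]


DEFAULT_CHROM_LENGTHS = tuple(
    [8_000_000.0, 2_400_000.0, 2_400_000.0, 2_400_000.0, 2_400_000.0,
     2_400_000.0, 2_400_000.0, 2_400_000.0, 2_400_000.0, 2_400_000.0,
     2_400_000.0, 6_000_000.0, 2_400_000.0, 2_400_000.0, 5_000_000.0,
     2_400_000.0, 2_400_000.0, 2_400_000.0, 2_400_000.0, 2_400_000.0]
)  # ~59.8 Mb over 20 chromosomes; chr01/chr12/chr15 are the long donors


def liposarcoma_like(
    seed: int,
    ref_maps: Optional[Sequence[LabelMap]] = None,
    ref_seed: int = 1_234,
    n_derivatives: int = 10,
    events_per_derivative: int = 4,
    noise: Optional[NoiseModel] = None,
    pairs: bool = False,
    n_background: int = 10,
    background_len: Tuple[float, float] = (1_000_000.0, 2_000_000.0),
    with_breakends: bool = True,
    detection: float = 0.95,
    fdr: float = 0.05,
    **plan_kwargs,
) -> LiposarcomaPreset:
    """A toy highly-rearranged-genome study: ~60 Mb reference over 20
    chromosomes, derivative chromosomes fused mostly from three donor
    chromosomes, noisy consensus maps of the derivatives plus unrearranged
    background windows, and a matching breakend call set.
    """
    if noise is None:
        noise = NoiseModel()
    if ref_maps is None:
        _, ref_maps = simulate_reference(
            ref_seed, chrom_len=DEFAULT_CHROM_LENGTHS, gc=0.41, return_sequences=False
        )
    ref_maps = list(ref_maps)
    chrom_lengths = {m.map_id: m.length_bp for m in ref_maps}
    donors = [c for c in ("chr01", "chr12", "chr15") if c in chrom_lengths]
    if len(donors) < 2:  # small custom references: fall back to the longest
        donors = [m.map_id for m in sorted(ref_maps, key=lambda m: -m.length_bp)[:3]]
    rng = np.random.default_rng(seed)
    truth = TruthSet()
    derivatives: Dict[str, LabelMap] = {}
    for d in range(n_derivatives):
        plan, der, t = simulate_derivative(
            ref_maps,
            seed=int(rng.integers(0, 2**31 - 1)),
            derivative_id=f"der{d:02d}",
            donors=donors,
            n_events=events_per_derivative,
            **plan_kwargs,
        )
        derivatives[plan.derivative_id] = der
        truth.svs.extend(t.svs)
        truth.junctions.extend(t.junctions)
        truth.plans.extend(t.plans)
    provenance: Dict[str, dict] = {}
    consensus = simulate_maps(
        list(derivatives.values()), noise, rng,
        n_replicates=2 if pairs else 1, pair_ids=pairs,
        id_prefix="cmap", provenance=provenance,
    )
    if n_background:
        # draw exactly n_background unrearranged windows from random chromosomes
        background = []
        for i in range(n_background):
            g = ref_maps[int(rng.integers(0, len(ref_maps)))]
            L = float(rng.uniform(*background_len))
            L = min(L, g.length_bp)
            start = float(rng.integers(1, int(g.length_bp - L + 1) + 1))
            mid = f"bg{i:03d}"
            background.append(noisy_map(g, noise, rng, mid, window=(start, start + L - 1)))
            provenance[mid] = {"source": g.map_id, "window": (start, start + L - 1)}
        consensus = consensus + background
    truth.provenance = provenance
    calls = (
        simulate_breakends(
            truth, seed=int(rng.integers(0, 2**31 - 1)), detection=detection,
            fdr=fdr, chrom_lengths=chrom_lengths,
        )
        if with_breakends
        else []
    )
    return LiposarcomaPreset(
        ref_maps=ref_maps, derivatives=derivatives, truth=truth,
        consensus_maps=consensus, provenance=provenance,
        breakend_calls=calls, chrom_lengths=chrom_lengths,
    )
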