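"""Core domain types shared across the pipeline.

All genomic coordinates are 1-based inclusive base pairs, following the
Bionano CMAP/XMAP convention.  BED/BEDPE inputs are converted on read and
back-converted on write.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "LabelMap",
    "Molecule",
    "BreakendCall",
    "IntervalTrack",
    "Thresholds",
    "LocalSegment",
    "MosaicAlignment",
    "SVCall",
    "FusionJunction",
    "DonorFragment",
    "Traversal",
    "TestResult",
    "canonical_breakend_order",
]


@dataclass
class LabelMap:
    """Ordered fluorescent-label positions along one DNA segment.

    The segment may be a reference chromosome (in silico digest), an
    assembled consensus genome map, or a single imaged molecule.
    """

    map_id: str
    length_bp: float
    labels: np.ndarray  # 1-based bp, strictly increasing
    channel: int = 1
    source: str = "consensus"  # reference | consensus | molecule

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.length_bp <= 0:
            raise ValueError(f"map {self.map_id}: non-positive length {self.length_bp}")
        if self.labels.size:
            if np.any(np.diff(self.labels) <= 0):
                raise ValueError(f"map {self.map_id}: label positions not strictly increasing")
            if self.labels[0] < 1 or self.labels[-1] > self.length_bp:
                raise ValueError(
                    f"map {self.map_id}: labels outside [1, {self.length_bp}]"
                )

    @property
    def n_labels(self) -> int:
        return int(self.labels.size)

    def window(self, start: float, end: float, map_id: Optional[str] = None) -> "LabelMap":
        """Sub-map over the 1-based inclusive interval [start, end]."""
        if not (1 <= start <= end <= self.length_bp):
            raise ValueError(f"window [{start},{end}] outside map {self.map_id}")
        mask = (self.labels >= start) & (self.labels <= end)
        return LabelMap(
            map_id=map_id or f"{self.map_id}:{int(start)}-{int(end)}",
            length_bp=end - start + 1,
            labels=self.labels[mask] - start + 1,
            channel=self.channel,
            source=self.source,
        )


@dataclass
class Molecule(LabelMap):
    """A single imaged molecule with its label signal-to-noise ratio."""

    snr: float = 3.0
    avg_intensity: float = 1.0

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.snr <= 0:
            raise ValueError(f"molecule {self.map_id}: snr must be > 0")


def canonical_breakend_order(
    chrom1: str, pos1: float, side1: str, chrom2: str, pos2: float, side2: str
) -> tuple:
    """Return the two breakends so that (chrom1, pos1) <= (chrom2, pos2)."""
    if (chrom1, pos1) <= (chrom2, pos2):
        return chrom1, pos1, side1, chrom2, pos2, side2
    return chrom2, pos2, side2, chrom1, pos1, side1


@dataclass
class BreakendCall:
    """A short-read rearrangement junction between two breakends.

    ``side`` names which side of ``pos`` is joined to the partner breakend:
    ``right`` means the retained sequence lies at/left of ``pos`` and the
    junction continues to its right (BEDPE strand ``+``), ``left`` the mirror
    image (strand ``-``).
    """

    id: str
    chrom1: str
    pos1: float
    side1: str
    chrom2: str
    pos2: float
    side2: str
    inserted_len: float = 0.0
    quality: float = 0.0

    def __post_init__(self) -> None:
        if self.side1 not in ("left", "right") or self.side2 not in ("left", "right"):
            raise ValueError(f"breakend {self.id}: side must be left/right")
        if self.quality < 0 or self.inserted_len < 0:
            raise ValueError(f"breakend {self.id}: negative quality/inserted_len")
        (self.chrom1, self.pos1, self.side1,
         self.chrom2, self.pos2, self.side2) = canonical_breakend_order(
            self.chrom1, self.pos1, self.side1, self.chrom2, self.pos2, self.side2
        )

    @property
    def breakends(self):
        return (
            (self.chrom1, self.pos1, self.side1),
            (self.chrom2, self.pos2, self.side2),
        )


@dataclass
class IntervalTrack:
    """Named genomic intervals (1-based inclusive), e.g. N-gaps or SegDups."""

    name: str
    intervals: list  # of (chrom, start, end)

    def __post_init__(self) -> None:
        cleaned = []
        for chrom, start, end in self.intervals:
            if end < start:
                raise ValueError(f"track {self.name}: interval {chrom}:{start}-{end} has negative length")
            cleaned.append((str(chrom), float(start), float(end)))
        self.intervals = sorted(cleaned)

    def by_chrom(self) -> dict:
        out: dict = {}
        for chrom, start, end in self.intervals:
            out.setdefault(chrom, []).append((start, end))
        return out

    def total_bp(self) -> float:
        return sum(e - s + 1 for _, s, e in self.intervals)


@dataclass
class Thresholds:
    """Every numeric threshold used by the pipeline, with its default.

    Units are base pairs unless stated otherwise.
    """

    min_molecule_len: float = 150_000.0
    min_labels_per_molecule: int = 9
    min_snr: float = 2.75
    snr_strict: bool = True  # "greater 2.75" read as strict; configurable
    min_support_molecules: int = 10
    support_label_slop: int = 2  # labels
    min_indel_size: float = 1_000.0
    cgr_indel_size: float = 100_000.0
    intra_transloc_min_sep: float = 5_000_000.0
    breakpoint_pad: float = 10_000.0
    segdup_frac_sv: float = 0.20
    segdup_frac_donor: float = 0.50
    dedup_tol: float = 10_000.0
    traverse_anchor_tol: float = 100_000.0
    traverse_len_tol: float = 100_000.0
    max_traverse_junctions: int = 15
    min_breakend_quality: float = 500.0
    concordance_tol: float = 100_000.0
    window_size: float = 1_000_000.0
    # aligner scoring
    match_score: float = 3.0
    skip_penalty: float = 1.0
    sizing_sd_rel: float = 0.02
    sizing_sd_bp: float = 500.0
    min_seg_score: float = 25.0
    min_seg_labels: int = 9
    max_skip_labels: int = 4
    # segment quality/boundary handling: a chain must contain some exactly
    # chained, well-sized label pairs (anchors) to be a credible locus, and
    # junction-adjacent sloppy pairs are trimmed back to the better register
    min_anchor_pairs: int = 6
    anchor_exempt_pairs: int = 15  # long chains are credible without the run test
    anchor_max_penalty: float = 1.0
    end_trim_reward: float = 1.0
    select_overlap_labels: int = 8
    # same-chromosome adjacency: reference-order reversals smaller than this
    # (boundary-label jitter) still count as collinear
    collinear_slack: float = 50_000.0

    def __post_init__(self) -> None:
        for name in (
            "min_molecule_len", "min_snr", "min_indel_size", "cgr_indel_size",
            "intra_transloc_min_sep", "breakpoint_pad", "dedup_tol",
            "traverse_anchor_tol", "traverse_len_tol", "min_breakend_quality",
            "concordance_tol", "window_size",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be strictly positive")
        for name in ("segdup_frac_sv", "segdup_frac_donor"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"threshold {name} must be in (0, 1]")

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "Thresholds":
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        return cls(**{k: v for k, v in d.items() if k in known})


@dataclass
class LocalSegment:
    """One local alignment of a query label map to a reference label map."""

    query_id: str
    ref_id: str
    orientation: str  # + or -
    pairs: list  # of (query label idx, ref label idx), 0-based, ascending in query
    q_start: float
    q_end: float
    r_start: float
    r_end: float
    score: float
    n_pairs: int = 0

    def __post_init__(self) -> None:
        if self.orientation not in ("+", "-"):
            raise ValueError(f"segment {self.query_id}->{self.ref_id}: bad orientation {self.orientation!r}")
        if self.q_start > self.q_end or self.r_start > self.r_end:
            raise ValueError(
                f"segment {self.query_id}->{self.ref_id}: start/end must be stored ascending"
            )
        if not self.n_pairs:
            self.n_pairs = len(self.pairs)

    @property
    def q_idx_span(self) -> tuple:
        idx = [p[0] for p in self.pairs]
        return min(idx), max(idx)

    def junction_breakend(self, which: str) -> tuple:
        """Reference breakend (chrom, pos, side) at this segment's query-left
        or query-right end, oriented out of the segment."""
        if which == "right":  # junction continues past the query-right end
            if self.orientation == "+":
                return (self.ref_id, self.r_end, "right")
            return (self.ref_id, self.r_start, "left")
        else:  # junction enters at the query-left end
            if self.orientation == "+":
                return (self.ref_id, self.r_start, "left")
            return (self.ref_id, self.r_end, "right")


@dataclass
class MosaicAlignment:
    """Ordered local segments of one query map plus its unaligned complement."""

    query_id: str
    query_length: float
    segments: list  # of LocalSegment, ordered by query coordinate
    unaligned_intervals: list = field(default_factory=list)  # (q_start, q_end)

    def __post_init__(self) -> None:
        self.segments = sorted(self.segments, key=lambda s: (s.q_start, s.q_end))
        if not self.unaligned_intervals:
            self.unaligned_intervals = self._complement()

    def _complement(self) -> list:
        out = []
        pos = 1.0
        for seg in self.segments:
            if seg.q_start > pos:
                out.append((pos, seg.q_start - 1))
            pos = max(pos, seg.q_end + 1)
        if pos <= self.query_length:
            out.append((pos, self.query_length))
        return out


@dataclass
class SVCall:
    """A classified rearrangement event deduced from a mosaic alignment."""

    sv_type: str  # insertion | deletion | inversion | intra_translocation | inter_translocation
    query_id: str
    ref_bp1: tuple  # (chrom, pos)
    ref_bp2: tuple
    query_bp1: float
    query_bp2: float
    ref_gap: float
    query_gap: float
    size: Optional[float]  # |query_gap - ref_gap| for indels; None when unknown
    orient1: str = "+"
    orient2: str = "+"
    support: Optional[int] = None
    filters_failed: set = field(default_factory=set)
    haplomap_pair_id: Optional[str] = None

    @property
    def passed(self) -> bool:
        return not self.filters_failed

    @property
    def is_indel(self) -> bool:
        return self.sv_type in ("insertion", "deletion")

    @property
    def is_translocation(self) -> bool:
        return self.sv_type in ("intra_translocation", "inter_translocation")


@dataclass
class FusionJunction:
    """A fusion-map junction between two aligned donor segments."""

    query_id: str
    left: tuple  # (chrom, pos, side)
    right: tuple
    junction_gap: float  # unaligned query bp between the segments, floored at 0
    cluster_id: Optional[int] = None

    def __post_init__(self) -> None:
        if self.junction_gap < 0:
            self.junction_gap = 0.0


@dataclass
class DonorFragment:
    """A merged reference interval contributed to the rearranged genome."""

    chrom: str
    start: float
    end: float
    n_maps: int = 0


@dataclass
class Traversal:
    """A breakend-graph path explaining one optical fusion gap."""

    fusion_id: str
    supported: bool
    path_edges: list  # alternating ('junction', call_id) / ('segment', chrom, p1, p2)
    n_junctions: int
    path_len: float
    optical_gap: float
    delta: float
    anchor_offsets: tuple = (0.0, 0.0)
    note: str = ""


@dataclass
class TestResult:
    """Outcome of one statistical test."""

    statistic: float
    p_value: float
    n1: int
    n2: int
    method: str
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not np.isnan(self.p_value) and not (0 <= self.p_value <= 1):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")
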