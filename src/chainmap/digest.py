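"""In silico digestion of DNA sequence into reference label maps.

A nicking endonuclease (default Nt.BspQI, recognition GCTCTTC, nick after the
following N base: GCTCTTCN^) cuts one strand and a fluorophore is incorporated
at the nick.  Digestion therefore scans both strands for the recognition motif
and projects each nick position onto forward-strand coordinates.  The imaging
platform cannot resolve labels closer than ~1 kb, so neighbouring labels are
merged to their mean position before any downstream use.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List

import numpy as np
from Bio import SeqIO

from .types import LabelMap

__all__ = ["Motif", "digest_sequence", "apply_resolution", "digest_reference"]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DEFAULT_RESOLUTION_BP = 1_000.0


@dataclass(frozen=True)
class Motif:
    """A nicking-endonuclease recognition motif.

    ``nick_offset`` is the distance in bp from the motif 5' end to the label
    position on the strand carrying the motif (7 for GCTCTTCN^).
    """

    recognition: str = "GCTCTTC"
    nick_offset: int = 7

    def __post_init__(self) -> None:
        if not self.recognition or set(self.recognition) - set("ACGT"):
            raise ValueError(f"motif recognition must be non-empty uppercase ACGT: {self.recognition!r}")

    @property
    def revcomp(self) -> str:
        return self.recognition.translate(_COMPLEMENT)[::-1]


def _scan(seq: str, pattern: str) -> Iterable[int]:
    """Yield 0-based start positions of (possibly overlapping) matches."""
    i = seq.find(pattern)
    while i != -1:
        yield i
        i = seq.find(pattern, i + 1)


def digest_sequence(seq: str, motif: Motif = Motif()) -> np.ndarray:
    """Label positions (1-based bp, sorted) for both-strand motif matches.

    Matches whose recognition window overlaps an N base never occur because the
    exact-string scan only matches ACGT.  Nick positions falling outside the
    sequence are dropped.
    """
    seq = seq.upper()
    n = len(seq)
    k = len(motif.recognition)
    positions: List[float] = []
    for i in _scan(seq, motif.recognition):  # forward strand: motif at 1-based i+1
        pos = (i + 1) + motif.nick_offset
        if 1 <= pos <= n:
            positions.append(float(pos))
    for i in _scan(seq, motif.revcomp):  # reverse strand, projected to forward coords
        # reverse-strand motif 5' end sits at forward coordinate i+k; the nick
        # extends nick_offset bases further leftward along the reverse strand
        pos = (i + k) - motif.nick_offset
        if 1 <= pos <= n:
            positions.append(float(pos))
    return np.array(sorted(positions), dtype=float)


def apply_resolution(labels: np.ndarray, min_sep: float = DEFAULT_RESOLUTION_BP) -> np.ndarray:
    """Merge runs of labels closer than ``min_sep`` to their mean position.

    Single-linkage: consecutive gaps < min_sep chain labels into one run.  The
    operation is idempotent and order-preserving, and output gaps are all
    >= min_sep.
    """
    labels = np.asarray(labels, dtype=float)
    if labels.size < 2:
        return labels.copy()
    breaks = np.flatnonzero(np.diff(labels) >= min_sep) + 1
    runs = np.split(labels, breaks)
    return np.array([run.mean() for run in runs], dtype=float)


def digest_reference(
    fasta: "str | Path",
    motif: Motif = Motif(),
    min_sep: float = DEFAULT_RESOLUTION_BP,
) -> List[LabelMap]:
    """Digest every sequence of a FASTA file into a reference LabelMap."""
    maps: List[LabelMap] = []
    seen = set()
    for rec in SeqIO.parse(str(fasta), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence name in FASTA: {rec.id}")
        seen.add(rec.id)
        seq = str(rec.seq)
        labels = apply_resolution(digest_sequence(seq, motif), min_sep)
        maps.append(
            LabelMap(map_id=rec.id, length_bp=float(len(seq)), labels=labels, source="reference")
        )
    return maps


def digest_sequences(
    seqs: dict, motif: Motif = Motif(), min_sep: float = DEFAULT_RESOLUTION_BP
) -> List[LabelMap]:
    """Digest an in-memory {name: sequence} dict (same semantics as a FASTA)."""
    maps = []
    for name, seq in seqs.items():
        labels = apply_resolution(digest_sequence(seq, motif), min_sep)
        maps.append(LabelMap(map_id=name, length_bp=float(len(seq)), labels=labels, source="reference"))
    return maps
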