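"""Readers and writers for every on-disk artifact the pipeline touches.

Supported dialects
------------------
* CMAP  -- tab-separated label maps with a ``#``-comment header (reference
  digests and consensus maps).
* BNX   -- flat-text single molecules, format v1.2 (``0``/``1``/``QX11`` line
  triplets).  Extra quality channels are ignored, not errors.
* XMAP  -- tab-separated mosaic alignments, one row per local segment.
* BEDPE / VCF 4.2 BND -- short-read breakend calls (GRIDSS-style).
* BED   -- exclusion interval tracks (N-gaps, SegDups).
* TSV   -- breakpoint-pair lists (blacklists, external fusion lists).

Internally everything is 1-based inclusive bp; BED/BEDPE 0-based half-open
coordinates are converted on read and back-converted on write.  The strand
pair of a BEDPE row maps to breakend sides following the GRIDSS convention:
``+`` means the retained segment extends to the *left* of the position, i.e.
the junction is joined on its ``right`` side; ``-`` is the mirror image.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .types import (
    BreakendCall,
    IntervalTrack,
    LabelMap,
    LocalSegment,
    Molecule,
    MosaicAlignment,
    Thresholds,
)

log = logging.getLogger(__name__)

COORD_NOTE = "# Coordinates: 1-based inclusive bp (CMAP/XMAP convention)"

__all__ = [
    "read_label_maps",
    "write_label_maps",
    "filter_molecules",
    "read_breakends",
    "write_bedpe",
    "write_vcf_bnd",
    "read_alignments",
    "write_alignments",
    "read_bed",
    "write_bed",
    "read_breakpoint_pairs",
    "write_breakpoint_pairs",
]


# ---------------------------------------------------------------------------
# CMAP

_CMAP_COLS = [
    "CMapId", "ContigLength", "NumSites", "SiteID", "LabelChannel", "Position",
    "StdDev", "Coverage", "Occurrence",
]


def _write_cmap(maps: Sequence[LabelMap], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("# CMAP File Version:\t0.1\n")
        fh.write("# Label Channels:\t1\n")
        fh.write(COORD_NOTE + "\n")
        fh.write("#h " + "\t".join(_CMAP_COLS) + "\n")
        fh.write("#f int\tfloat\tint\tint\tint\tfloat\tfloat\tfloat\tfloat\n")
        for m in maps:
            n = m.n_labels
            for i, pos in enumerate(m.labels, start=1):
                fh.write(
                    f"{m.map_id}\t{m.length_bp:.1f}\t{n}\t{i}\t{m.channel}\t{pos:.1f}\t0.0\t1.0\t1.0\n"
                )
            fh.write(f"{m.map_id}\t{m.length_bp:.1f}\t{n}\t{n + 1}\t0\t{m.length_bp:.1f}\t0.0\t1.0\t1.0\n")


def _read_cmap(path: Path, channel: int = 1, source: str = "consensus") -> List[LabelMap]:
    by_id: dict = {}
    lengths: dict = {}
    order: List[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}: malformed CMAP data line {lineno}: {line!r}")
            try:
                map_id = parts[0]
                length = float(parts[1])
                chan = int(parts[4])
                pos = float(parts[5])
            except ValueError as exc:
                raise ValueError(f"{path}: malformed CMAP data line {lineno}: {exc}") from None
            if map_id not in by_id:
                by_id[map_id] = []
                order.append(map_id)
            lengths[map_id] = length
            if chan == channel:
                by_id[map_id].append(pos)
            # channel 0 marks the end-of-map row; other channels are dropped
    out = []
    for map_id in order:
        labels = np.array(by_id[map_id], dtype=float)
        if labels.size and np.any(np.diff(labels) <= 0):
            raise ValueError(f"{path}: non-monotone labels for map_id {map_id}")
        out.append(LabelMap(map_id=map_id, length_bp=lengths[map_id], labels=labels, source=source))
    return out


# ---------------------------------------------------------------------------
# BNX v1.2 (minimal: header + 0/1/QX11 lines; extra quality channels ignored)


def _write_bnx(mols: Sequence[Molecule], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("# BNX File Version:\t1.2\n")
        fh.write("# Label Channels:\t1\n")
        fh.write(COORD_NOTE + "\n")
        fh.write("#0h LabelChannel\tMoleculeId\tLength\tAvgIntensity\tSNR\tNumberofLabels\n")
        fh.write("#0f int\tint\tfloat\tfloat\tfloat\tint\n")
        fh.write("#1h LabelChannel\tLabelPositions[N]\n")
        fh.write("#Qh QX11\tSNR[N]\n")
        for m in mols:
            fh.write(
                f"0\t{m.map_id}\t{m.length_bp:.1f}\t{m.avg_intensity:.2f}\t{m.snr:.2f}\t{m.n_labels}\n"
            )
            positions = "\t".join(f"{p:.1f}" for p in m.labels)
            tail = f"\t{m.length_bp:.1f}" if m.n_labels else f"{m.length_bp:.1f}"
            fh.write(("1\t" + positions + tail + "\n") if m.n_labels else f"1\t{m.length_bp:.1f}\n")
            if m.n_labels:
                fh.write("QX11\t" + "\t".join(f"{m.snr:.2f}" for _ in range(m.n_labels)) + "\n")


def _read_bnx(path: Path) -> List[Molecule]:
    mols: List[Molecule] = []
    header: Optional[dict] = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("# BNX File Version"):
                    ver = line.split("\t")[-1].strip()
                    if not ver.startswith("1."):
                        raise ValueError(f"{path}: unsupported BNX version {ver!r} (header line {lineno})")
                continue
            tag = line.split("\t", 1)[0]
            if tag == "0":
                parts = line.split("\t")
                if len(parts) < 6:
                    raise ValueError(f"{path}: malformed BNX 0-line at line {lineno}")
                header = {
                    "id": parts[1],
                    "length": float(parts[2]),
                    "avg_intensity": float(parts[3]),
                    "snr": float(parts[4]),
                }
            elif tag == "1":
                if header is None:
                    raise ValueError(f"{path}: BNX 1-line before any 0-line at line {lineno}")
                vals = [float(x) for x in line.split("\t")[1:]]
                labels = np.array(vals[:-1], dtype=float)  # final value restates length
                if labels.size and np.any(np.diff(labels) <= 0):
                    raise ValueError(f"{path}: non-monotone labels for molecule {header['id']}")
                mols.append(
                    Molecule(
                        map_id=header["id"],
                        length_bp=header["length"],
                        labels=labels,
                        source="molecule",
                        snr=header["snr"],
                        avg_intensity=header["avg_intensity"],
                    )
                )
                header = None
            # QX11 and any other quality channels are ignored
    return mols


# ---------------------------------------------------------------------------
# public label-map API


def read_label_maps(path: "str | Path", dialect: str):
    """Read label maps (``cmap``) or molecules (``bnx``) from ``path``."""
    path = Path(path)
    if dialect == "cmap":
        return _read_cmap(path)
    if dialect == "bnx":
        return _read_bnx(path)
    raise ValueError(f"unknown label-map dialect {dialect!r}")


def write_label_maps(maps: Sequence[LabelMap], path: "str | Path", dialect: str) -> None:
    path = Path(path)
    if dialect == "cmap":
        _write_cmap(maps, path)
    elif dialect == "bnx":
        _write_bnx(list(maps), path)
    else:
        raise ValueError(f"unknown label-map dialect {dialect!r}")


def filter_molecules(mols: Iterable[Molecule], th: Thresholds = Thresholds()) -> List[Molecule]:
    """Molecule-level quality filter applied before assembly/alignment.

    Keeps molecules with length >= ``min_molecule_len`` (default 150 kb),
    label count >= ``min_labels_per_molecule`` (default 9) and
    SNR > ``min_snr`` (default 2.75, strict; configurable via ``snr_strict``).
    """
    def snr_ok(m: Molecule) -> bool:
        return m.snr > th.min_snr if th.snr_strict else m.snr >= th.min_snr

    return [
        m
        for m in mols
        if m.length_bp >= th.min_molecule_len
        and m.n_labels >= th.min_labels_per_molecule
        and snr_ok(m)
    ]


# ---------------------------------------------------------------------------
# breakend calls

_STRAND_TO_SIDE = {"+": "right", "-": "left"}
_SIDE_TO_STRAND = {"right": "+", "left": "-"}
_BND_RE = re.compile(r"^([ACGTN]*)([\[\]])([^\[\]:]+):(\d+)([\[\]])([ACGTN]*)$")


def _read_bedpe(path: Path) -> List[BreakendCall]:
    calls = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 10:
                raise ValueError(f"{path}: BEDPE line {lineno} lacks strand columns")
            chrom1, _s1, e1, chrom2, _s2, e2, name, score, strand1, strand2 = parts[:10]
            inserted = float(parts[10]) if len(parts) > 10 else 0.0
            calls.append(
                BreakendCall(
                    id=name if name != "." else f"bedpe_{lineno}",
                    chrom1=chrom1,
                    pos1=float(e1),  # 0-based half-open end == 1-based position
                    side1=_STRAND_TO_SIDE[strand1],
                    chrom2=chrom2,
                    pos2=float(e2),
                    side2=_STRAND_TO_SIDE[strand2],
                    inserted_len=inserted,
                    quality=float(score) if score != "." else 0.0,
                )
            )
    return calls


def write_bedpe(calls: Sequence[BreakendCall], path: "str | Path") -> None:
    with open(path, "w") as fh:
        fh.write("# BEDPE breakend calls; positions converted from 1-based inclusive internal coords\n")
        for c in calls:
            fh.write(
                "\t".join(
                    [
                        c.chrom1, str(int(c.pos1) - 1), str(int(c.pos1)),
                        c.chrom2, str(int(c.pos2) - 1), str(int(c.pos2)),
                        c.id, f"{c.quality:g}",
                        _SIDE_TO_STRAND[c.side1], _SIDE_TO_STRAND[c.side2],
                        f"{c.inserted_len:g}",
                    ]
                )
                + "\n"
            )


def _vcf_alt(pos_self: float, chrom_mate: str, pos_mate: float, side_self: str, side_mate: str,
             ins: str = "") -> str:
    mate = f"{chrom_mate}:{int(pos_mate)}"
    t = "N" + ins
    if side_self == "right":
        # retained sequence left of POS, junction continues after t
        return f"{t}[{mate}[" if side_mate == "left" else f"{t}]{mate}]"
    # junction joined before t
    return f"]{mate}]{t}" if side_mate == "right" else f"[{mate}[{t}"


def write_vcf_bnd(calls: Sequence[BreakendCall], path: "str | Path",
                  contigs: Optional[Sequence[Tuple[str, int]]] = None) -> None:
    """Write each call as a pair of VCF 4.2 BND records."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">\n')
        fh.write('##INFO=<ID=MATEID,Number=1,Type=String,Description="ID of mate breakend">\n')
        fh.write('##INFO=<ID=INSLEN,Number=1,Type=Integer,Description="Untemplated junction insertion length">\n')
        if contigs:
            for name, length in contigs:
                fh.write(f"##contig=<ID={name},length={int(length)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        rows = []
        for c in calls:
            ins = "N" * int(c.inserted_len)
            a = f"{c.id}_1"
            b = f"{c.id}_2"
            rows.append((c.chrom1, int(c.pos1), a,
                         _vcf_alt(c.pos1, c.chrom2, c.pos2, c.side1, c.side2, ins),
                         c.quality, b, int(c.inserted_len)))
            rows.append((c.chrom2, int(c.pos2), b,
                         _vcf_alt(c.pos2, c.chrom1, c.pos1, c.side2, c.side1, ins),
                         c.quality, a, int(c.inserted_len)))
        for chrom, pos, rid, alt, qual, mate, inslen in sorted(rows):
            fh.write(f"{chrom}\t{pos}\t{rid}\tN\t{alt}\t{qual:g}\t.\tSVTYPE=BND;MATEID={mate};INSLEN={inslen}\n")


def _parse_bnd_alt(alt: str, rid: str):
    m = _BND_RE.match(alt)
    if m is None:
        raise ValueError(f"unknown BND ALT grammar in record {rid}: {alt!r}")
    pre, br1, chrom, pos, br2, post = m.groups()
    if br1 != br2:
        raise ValueError(f"unknown BND ALT grammar in record {rid}: {alt!r}")
    if pre:  # t[p[ or t]p]
        side_self = "right"
        side_mate = "left" if br1 == "[" else "right"
        inserted = max(0, len(pre) - 1)
    elif post:  # ]p]t or [p[t
        side_self = "left"
        side_mate = "right" if br1 == "]" else "left"
        inserted = max(0, len(post) - 1)
    else:
        raise ValueError(f"unknown BND ALT grammar in record {rid}: {alt!r}")
    return chrom, float(pos), side_self, side_mate, float(inserted)


def _read_vcf_bnd(path: Path) -> List[BreakendCall]:
    import pysam

    calls = []
    seen: dict = {}  # record id -> breakend info, awaiting its MATEID partner
    n_anon = 0
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf.fetch() if vf.index is not None else vf:
            alts = rec.alts or ()
            if not alts or ("[" not in alts[0] and "]" not in alts[0]):
                continue
            chrom_mate, pos_mate, side_self, side_mate, inserted = _parse_bnd_alt(alts[0], rec.id or "?")
            mate_id = rec.info.get("MATEID")
            if isinstance(mate_id, tuple):
                mate_id = mate_id[0]
            rid = rec.id or f"_anon{(n_anon := n_anon + 1)}"
            info = {
                "id": rid, "mate_id": mate_id, "chrom": rec.contig, "pos": float(rec.pos),
                "side_self": side_self, "inserted": inserted,
                "qual": rec.qual if rec.qual is not None else 0.0,
            }
            partner = seen.pop(mate_id, None) if mate_id else None
            if partner is not None and partner.get("mate_id") in (rid, None):
                base_id = partner["id"].rsplit("_", 1)[0]
                calls.append(
                    BreakendCall(
                        id=base_id,
                        chrom1=partner["chrom"], pos1=partner["pos"], side1=partner["side_self"],
                        chrom2=info["chrom"], pos2=info["pos"], side2=info["side_self"],
                        inserted_len=max(inserted, partner["inserted"]),
                        quality=info["qual"],
                    )
                )
            else:
                if partner is not None:
                    seen[partner["id"]] = partner  # not actually our mate
                seen[rid] = info
    for leftover in seen.values():
        log.warning("dropping unpaired BND mate %s at %s:%d",
                    leftover["id"], leftover["chrom"], leftover["pos"])
    return calls


def read_breakends(path: "str | Path", dialect: str, th: Thresholds = Thresholds()) -> List[BreakendCall]:
    """Read breakend calls and drop records at or below the quality threshold.

    The quality comparison is strict (``quality > min_breakend_quality``,
    default 500): a call of exactly 500 is dropped.
    """
    path = Path(path)
    if dialect == "bedpe":
        calls = _read_bedpe(path)
    elif dialect == "vcf_bnd":
        calls = _read_vcf_bnd(path)
    else:
        raise ValueError(f"unknown breakend dialect {dialect!r}")
    return [c for c in calls if c.quality > th.min_breakend_quality]


# ---------------------------------------------------------------------------
# XMAP-like alignments

_XMAP_COLS = [
    "XmapEntryID", "QryContigID", "RefContigID", "QryStartPos", "QryEndPos",
    "RefStartPos", "RefEndPos", "Orientation", "Confidence", "QryLen", "Alignment",
]


def write_alignments(mosaics: Sequence[MosaicAlignment], path: "str | Path") -> None:
    with open(path, "w") as fh:
        fh.write("# XMAP-like mosaic alignments\n")
        fh.write(COORD_NOTE + "\n")
        fh.write("#h " + "\t".join(_XMAP_COLS) + "\n")
        entry = 1
        for mos in mosaics:
            for seg in mos.segments:
                pairs = "".join(f"({q},{r})" for q, r in seg.pairs)
                fh.write(
                    f"{entry}\t{mos.query_id}\t{seg.ref_id}\t{seg.q_start:.1f}\t{seg.q_end:.1f}\t"
                    f"{seg.r_start:.1f}\t{seg.r_end:.1f}\t{seg.orientation}\t{seg.score:.2f}\t"
                    f"{mos.query_length:.1f}\t{pairs}\n"
                )
                entry += 1


def read_alignments(path: "str | Path") -> List[MosaicAlignment]:
    rows_by_query: dict = {}
    qlen: dict = {}
    order: List[str] = []
    pair_re = re.compile(r"\((\d+),(\d+)\)")
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 11:
                raise ValueError(f"{path}: malformed XMAP line {lineno}")
            (_eid, qid, rid, qs, qe, rs, re_, orient, conf, qlen_s, aln) = parts[:11]
            if orient not in ("+", "-"):
                raise ValueError(f"{path}: line {lineno}: orientation must be + or -, got {orient!r}")
            if float(qs) > float(qe):
                raise ValueError(
                    f"{path}: line {lineno}: query start > end; segments are stored ascending with an orientation flag"
                )
            pairs = [(int(a), int(b)) for a, b in pair_re.findall(aln)]
            seg = LocalSegment(
                query_id=qid, ref_id=rid, orientation=orient, pairs=pairs,
                q_start=float(qs), q_end=float(qe), r_start=float(rs), r_end=float(re_),
                score=float(conf),
            )
            if qid not in rows_by_query:
                rows_by_query[qid] = []
                order.append(qid)
            rows_by_query[qid].append(seg)
            qlen[qid] = float(qlen_s)
    return [
        MosaicAlignment(query_id=qid, query_length=qlen[qid], segments=rows_by_query[qid])
        for qid in order
    ]


# ---------------------------------------------------------------------------
# BED tracks and breakpoint-pair TSVs


def read_bed(path: "str | Path", name: Optional[str] = None) -> IntervalTrack:
    """Read a BED3+ file into an IntervalTrack (converted to 1-based inclusive)."""
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            intervals.append((chrom, float(start) + 1, float(end)))
    return IntervalTrack(name=name or Path(path).stem, intervals=intervals)


def write_bed(track: IntervalTrack, path: "str | Path") -> None:
    with open(path, "w") as fh:
        for chrom, start, end in track.intervals:
            fh.write(f"{chrom}\t{int(start) - 1}\t{int(end)}\n")


def read_breakpoint_pairs(path: "str | Path") -> List[tuple]:
    """Read a TSV of breakpoint pairs: chrom1 pos1 chrom2 pos2 (1-based)."""
    pairs = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            chrom1, pos1, chrom2, pos2 = line.split("\t")[:4]
            pairs.append(((chrom1, float(pos1)), (chrom2, float(pos2))))
    return pairs


def write_breakpoint_pairs(pairs: Sequence[tuple], path: "str | Path") -> None:
    with open(path, "w") as fh:
        fh.write("#chrom1\tpos1\tchrom2\tpos2\n")
        for (c1, p1), (c2, p2) in pairs:
            fh.write(f"{c1}\t{int(p1)}\t{c2}\t{int(p2)}\n")
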