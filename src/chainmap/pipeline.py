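"""End-to-end orchestration: simulate -> align -> call -> fusion -> traverse -> stats.

Stages communicate only via the on-disk formats, so users can substitute real
optical-map (CMAP/XMAP) or short-read (BEDPE/VCF) files for any stage input.
Every run writes a manifest with SHA-256 checksums; re-running the same
configuration reproduces the artifacts byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import align as _align
from . import formats, fusion, simulate, stats, svcall, traverse
from .types import Thresholds

__all__ = ["RunConfig", "run"]


@dataclass
class RunConfig:
    """Configuration of one end-to-end run (simulation preset + thresholds)."""

    seed: int = 0
    outdir: str = "chainmap_run"
    # simulation preset
    ref_seed: int = 1234
    chrom_lengths: Optional[List[float]] = None  # None -> 20-chromosome ~60 Mb toy
    gc: float = 0.41
    n_derivatives: int = 10
    events_per_derivative: int = 4
    pairs: bool = False
    n_background: int = 10
    noise: dict = field(default_factory=lambda: dataclasses.asdict(simulate.NoiseModel()))
    detection: float = 0.95
    fdr: float = 0.05
    # molecule-support confirmation
    confirm_support: bool = False
    molecule_coverage: float = 40.0
    molecule_len: Tuple[float, float] = (180_000.0, 300_000.0)
    # optional real inputs (paths); when set, the matching stage is skipped
    ref_cmap: Optional[str] = None
    consensus_cmap: Optional[str] = None
    breakends_path: Optional[str] = None
    breakends_dialect: str = "bedpe"
    ngaps_bed: Optional[str] = None
    segdups_bed: Optional[str] = None
    blacklist_tsv: Optional[str] = None
    thresholds: dict = field(default_factory=lambda: Thresholds().to_dict())

    def to_yaml(self, path: Path) -> None:
        d = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: "str | Path") -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        if "molecule_len" in d and d["molecule_len"] is not None:
            d["molecule_len"] = tuple(d["molecule_len"])
        return cls(**d)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _sv_table(calls_by_map: Dict[str, list]) -> pd.DataFrame:
    rows = []
    for map_id in sorted(calls_by_map):
        for c in calls_by_map[map_id]:
            rows.append({
                "query_id": c.query_id,
                "sv_type": c.sv_type,
                "chrom1": c.ref_bp1[0], "pos1": c.ref_bp1[1],
                "chrom2": c.ref_bp2[0], "pos2": c.ref_bp2[1],
                "query_bp1": c.query_bp1, "query_bp2": c.query_bp2,
                "ref_gap": c.ref_gap, "query_gap": c.query_gap,
                "size": c.size if c.size is not None else "",
                "orient1": c.orient1, "orient2": c.orient2,
                "support": c.support if c.support is not None else "",
                "filters_failed": ";".join(sorted(c.filters_failed)) or "PASS",
                "haplomap_pair_id": c.haplomap_pair_id or "",
            })
    return pd.DataFrame(rows)


def run(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the summary report dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    th = Thresholds.from_dict(config.thresholds)
    noise = simulate.NoiseModel(**config.noise)
    rng = np.random.default_rng(config.seed)
    artifacts: List[Path] = []

    def emit(path: Path) -> None:
        artifacts.append(path)

    # ---- inputs: simulate or load -------------------------------------
    for name, path in (("ref_cmap", config.ref_cmap),
                       ("consensus_cmap", config.consensus_cmap),
                       ("breakends_path", config.breakends_path)):
        if path is not None and not Path(path).exists():
            raise FileNotFoundError(f"config field {name}: no such file {path}")

    preset = None
    if config.ref_cmap and config.consensus_cmap:
        ref_maps = formats.read_label_maps(config.ref_cmap, "cmap")
        consensus = formats.read_label_maps(config.consensus_cmap, "cmap")
        provenance: Dict[str, dict] = {}
        breakends = (
            formats.read_breakends(config.breakends_path, config.breakends_dialect, th)
            if config.breakends_path else []
        )
    else:
        ref_maps_in = None
        if config.chrom_lengths is not None:
            _, ref_maps_in = simulate.simulate_reference(
                config.ref_seed, chrom_len=config.chrom_lengths, gc=config.gc,
                return_sequences=False,
            )
        preset = simulate.liposarcoma_like(
            seed=config.seed,
            ref_maps=ref_maps_in,
            ref_seed=config.ref_seed,
            n_derivatives=config.n_derivatives,
            events_per_derivative=config.events_per_derivative,
            noise=noise,
            pairs=config.pairs,
            n_background=config.n_background,
            detection=config.detection,
            fdr=config.fdr,
        )
        ref_maps = preset.ref_maps
        consensus = preset.consensus_maps
        provenance = preset.provenance
        breakends = [c for c in preset.breakend_calls if c.quality > th.min_breakend_quality]
        formats.write_label_maps(ref_maps, outdir / "reference.cmap", "cmap"); emit(outdir / "reference.cmap")
        formats.write_label_maps(consensus, outdir / "consensus.cmap", "cmap"); emit(outdir / "consensus.cmap")
        formats.write_bedpe(preset.breakend_calls, outdir / "breakends.bedpe"); emit(outdir / "breakends.bedpe")
        truth_rows = [
            {"derivative_id": s.derivative_id, "sv_type": s.sv_type,
             "chrom1": s.bp1[0], "pos1": s.bp1[1], "chrom2": s.bp2[0], "pos2": s.bp2[1],
             "size": s.size if s.size is not None else "", "query_pos": s.query_pos}
            for s in preset.truth.svs
        ]
        pd.DataFrame(truth_rows).to_csv(outdir / "truth_svs.tsv", sep="\t", index=False)
        emit(outdir / "truth_svs.tsv")
        with open(outdir / "truth_junctions.json", "w") as fh:
            json.dump([dataclasses.asdict(j) for j in preset.truth.junctions], fh, indent=1, sort_keys=True)
        emit(outdir / "truth_junctions.json")

    ngaps = formats.read_bed(config.ngaps_bed, "ngaps") if config.ngaps_bed else None
    segdups = formats.read_bed(config.segdups_bed, "segdups") if config.segdups_bed else None
    blacklist = formats.read_breakpoint_pairs(config.blacklist_tsv) if config.blacklist_tsv else None

    # ---- align ---------------------------------------------------------
    mosaics = [_align.mosaic(q, ref_maps, th) for q in consensus]
    formats.write_alignments(mosaics, outdir / "alignments.xmap"); emit(outdir / "alignments.xmap")

    # ---- svcall --------------------------------------------------------
    pair_of: Dict[str, str] = {}
    by_pair: Dict[str, List[str]] = {}
    for mid, rec in provenance.items():
        pid = rec.get("pair_id")
        if pid:
            by_pair.setdefault(pid, []).append(mid)
    for pid, members in by_pair.items():
        if len(members) == 2:
            pair_of[members[0]] = members[1]
            pair_of[members[1]] = members[0]

    calls_by_map: Dict[str, list] = {}
    cmap_by_id = {m.map_id: m for m in consensus}
    for mos in mosaics:
        pid = provenance.get(mos.query_id, {}).get("pair_id")
        calls = svcall.classify(mos, th, haplomap_pair_id=pid)
        calls_by_map[mos.query_id] = calls
    all_calls = [c for calls in calls_by_map.values() for c in calls]
    svcall.pair_inversion_junctions(all_calls, th)
    svcall.filter_regions(all_calls, ngaps, segdups, th)
    svcall.filter_size_and_blacklist(all_calls, blacklist, th)

    if config.confirm_support and preset is not None:
        # molecules derive from the consensus map itself, so the anti-junk
        # anchor gate (meant for scrambled junction content) is relaxed here:
        # both maps carry measurement noise and molecule chains are short
        mol_th = dataclasses.replace(th, min_anchor_pairs=3, anchor_exempt_pairs=10)
        for mos in mosaics:
            calls = calls_by_map[mos.query_id]
            if not calls:
                continue
            cons = cmap_by_id[mos.query_id]
            mols = simulate.sample_maps(
                [cons], noise, rng, coverage=config.molecule_coverage,
                map_len=config.molecule_len, source="molecule",
                id_prefix=f"mol_{mos.query_id}_",
            )
            mols = formats.filter_molecules(mols, th)
            mol_mosaics = [_align.mosaic(m, [cons], mol_th) for m in mols]
            for c in calls:
                svcall.confirm_support(c, cons, mol_mosaics, th)

    sv_df = _sv_table(calls_by_map)
    sv_df.to_csv(outdir / "sv_calls.tsv", sep="\t", index=False); emit(outdir / "sv_calls.tsv")
    passing = svcall.passing_calls(all_calls)

    # ---- fusion --------------------------------------------------------
    fusion_ids = fusion.select_fusion_maps(calls_by_map, pair_of, th)
    fusion_mosaics = [m for m in mosaics if m.query_id in fusion_ids]
    junctions = fusion.fusion_junctions([c for c in passing if c.query_id in fusion_ids], th)
    map_lengths = {m.map_id: m.length_bp for m in consensus}
    unique_junctions = fusion.dedup_fusions(junctions, th, map_lengths)
    frags = fusion.donor_fragments(fusion_mosaics, ngaps, segdups, th, pair_of)
    pd.DataFrame([dataclasses.asdict(f) for f in frags]).to_csv(
        outdir / "donor_fragments.tsv", sep="\t", index=False); emit(outdir / "donor_fragments.tsv")
    chrom_lengths = {m.map_id: m.length_bp for m in ref_maps}
    fusion.coverage_profile(fusion_mosaics, chrom_lengths).to_csv(
        outdir / "coverage_profile.tsv", sep="\t", index=False); emit(outdir / "coverage_profile.tsv")
    fusion.sv_windows(passing, th.window_size).to_csv(
        outdir / "sv_windows.tsv", sep="\t", index=False); emit(outdir / "sv_windows.tsv")
    with open(outdir / "fusion_maps.tsv", "w") as fh:
        fh.write("#map_id\n")
        for mid in sorted(fusion_ids):
            fh.write(mid + "\n")
    emit(outdir / "fusion_maps.tsv")
    jrows = [
        {"fusion_id": f"fusion_{i:03d}", "query_id": j.query_id,
         "chrom1": j.left[0], "pos1": j.left[1], "side1": j.left[2],
         "chrom2": j.right[0], "pos2": j.right[1], "side2": j.right[2],
         "junction_gap": j.junction_gap, "cluster_id": j.cluster_id}
        for i, j in enumerate(unique_junctions)
    ]
    pd.DataFrame(jrows).to_csv(outdir / "unique_fusions.tsv", sep="\t", index=False)
    emit(outdir / "unique_fusions.tsv")
    formats.write_bed(svcall.breakpoints_track(passing), outdir / "sv_breakpoints.bed")
    emit(outdir / "sv_breakpoints.bed")
    fusion.write_circos_files(unique_junctions, chrom_lengths,
                              outdir / "circos_links.txt", outdir / "circos_karyotype.txt")
    emit(outdir / "circos_links.txt"); emit(outdir / "circos_karyotype.txt")

    # ---- traverse ------------------------------------------------------
    graph = traverse.build_graph(breakends)
    traversals, tsummary = traverse.traverse_all(graph, unique_junctions, th)
    trows = [
        {"fusion_id": t.fusion_id, "supported": t.supported, "n_junctions": t.n_junctions,
         "path_len": t.path_len, "optical_gap": t.optical_gap,
         "delta": t.delta if np.isfinite(t.delta) else "",
         "edges": ";".join(str(e) for e in t.path_edges), "note": t.note}
        for t in traversals
    ]
    pd.DataFrame(trows).to_csv(outdir / "traversals.tsv", sep="\t", index=False)
    emit(outdir / "traversals.tsv")
    traverse.write_path_dump(traversals, outdir / "traversal_paths.gfa")
    emit(outdir / "traversal_paths.gfa")

    # ---- stats ---------------------------------------------------------
    summary = stats.report(
        maps=consensus, calls=passing, fusion_map_ids=fusion_ids,
        unique_junctions=unique_junctions, traversal_summary=tsummary,
    )
    ins = [c.size for c in passing if c.sv_type == "insertion" and c.size]
    dels = [c.size for c in passing if c.sv_type == "deletion" and c.size]
    if len(ins) >= 3 and len(dels) >= 3:
        tr = stats.indel_size_test(ins, dels)
        summary["indel_size_test"] = dataclasses.asdict(tr)
    # breakpoint clustering over the donor-fragment support
    bp_by_chrom: Dict[str, list] = {}
    for j in junctions:
        for chrom, pos, _side in (j.left, j.right):
            bp_by_chrom.setdefault(chrom, []).append(pos)
    from .types import IntervalTrack

    if frags and sum(len(v) for v in bp_by_chrom.values()) >= 6:
        covered = IntervalTrack("donor_fragments", [(f.chrom, f.start, f.end) for f in frags])
        tr, qq = stats.clustering_test(bp_by_chrom, covered, seed=config.seed)
        summary["clustering_test"] = dataclasses.asdict(tr)
        pd.DataFrame(qq, columns=["observed_quantile", "null_quantile"]).to_csv(
            outdir / "clustering_qq.csv", index=False)
        emit(outdir / "clustering_qq.csv")
    with open(outdir / "report.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    emit(outdir / "report.json")

    # ---- manifest ------------------------------------------------------
    config.to_yaml(outdir / "run_config.yaml"); emit(outdir / "run_config.yaml")
    manifest = {p.name: _sha256(p) for p in sorted(set(artifacts))}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return summary
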