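"""Statistical analyses and summary reporting.

* Wilcoxon rank-sum (Mann-Whitney) with tie and continuity correction for
  comparing insertion and deletion size distributions.
* A breakpoint-clustering test: observed adjacent-breakpoint distances are
  compared against uniform placement of the same per-chromosome counts over
  the covered intervals, via the two-sample Kolmogorov-Smirnov statistic with
  a Monte-Carlo null (exchangeable by construction, hence exactly calibrated).
* Pearson correlation of per-chromosome SV proportion against chromosome
  length.
"""

from __future__ import annotations

from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .types import IntervalTrack, TestResult

__all__ = [
    "ratio",
    "percent",
    "indel_size_test",
    "ks_statistic",
    "clustering_test",
    "chrom_length_correlation",
    "report",
]


def ratio(a: float, b: float, ndigits: int = 1) -> float:
    """a/b rounded to ``ndigits`` (as printed in summary tables)."""
    return round(a / b, ndigits)


def percent(part: float, whole: float, ndigits: int = 1) -> float:
    """100*part/whole rounded to ``ndigits``."""
    return round(100.0 * part / whole, ndigits)


def indel_size_test(ins_sizes: Sequence[float], del_sizes: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon rank-sum test with continuity and tie correction.

    Null hypothesis: insertion and deletion sizes share one distribution.
    """
    x = np.asarray(list(ins_sizes), dtype=float)
    y = np.asarray(list(del_sizes), dtype=float)
    res = sps.mannwhitneyu(x, y, alternative="two-sided", use_continuity=True, method="asymptotic")
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n1=x.size,
        n2=y.size,
        method="wilcoxon_rank_sum_continuity",
    )


def ks_statistic(a: np.ndarray, b_sorted: np.ndarray) -> float:
    """Two-sample KS statistic; ``b_sorted`` must be sorted ascending."""
    a = np.sort(np.asarray(a, dtype=float))
    nb = b_sorted.size
    na = a.size
    # sup over the pooled sample points
    cdf_b_at_a = np.searchsorted(b_sorted, a, side="right") / nb
    cdf_a_at_a = (np.arange(1, na + 1)) / na
    cdf_a_at_a_left = np.arange(na) / na
    d1 = np.max(np.abs(cdf_a_at_a - cdf_b_at_a))
    d2 = np.max(np.abs(cdf_a_at_a_left - cdf_b_at_a))
    return float(max(d1, d2))


def _adjacent_distances(positions_by_chrom: Dict[str, np.ndarray]) -> np.ndarray:
    dists = []
    for chrom in sorted(positions_by_chrom):
        pos = np.sort(np.asarray(positions_by_chrom[chrom], dtype=float))
        if pos.size >= 2:
            dists.append(np.diff(pos))
    return np.concatenate(dists) if dists else np.array([])


def _uniform_placement(
    counts: Dict[str, int],
    covered_by_chrom: Dict[str, list],
    rng: np.random.Generator,
) -> Dict[str, np.ndarray]:
    """Uniformly place the per-chromosome counts over the covered intervals."""
    out = {}
    for chrom in sorted(counts):
        n = counts[chrom]
        ivs = covered_by_chrom.get(chrom)
        if not ivs or n == 0:
            out[chrom] = np.array([])
            continue
        lens = np.array([e - s + 1 for s, e in ivs], dtype=float)
        starts = np.array([s for s, _ in ivs], dtype=float)
        cum = np.concatenate([[0.0], np.cumsum(lens)])
        u = rng.uniform(0, cum[-1], size=n)
        idx = np.searchsorted(cum, u, side="right") - 1
        out[chrom] = starts[idx] + (u - cum[idx])
    return out


def clustering_test(
    breakpoints: Dict[str, Sequence[float]],
    covered: IntervalTrack,
    n_null: int = 199,
    seed: int = 0,
    pool_reps: int = 50,
    n_quantiles: int = 99,
) -> Tuple[TestResult, "np.ndarray"]:
    """Are adjacent breakpoint distances smaller than uniform placement predicts?

    The null pool is built from ``pool_reps`` uniform placements of the same
    per-chromosome breakpoint counts over ``covered``; the two-sample KS
    statistic of observed-vs-pool is ranked against ``n_null`` independent
    null replicates measured the same way, giving a Monte-Carlo p-value that
    is exactly calibrated under the null.  Returns (TestResult, QQ table with
    columns observed_quantile, null_quantile).
    """
    rng = np.random.default_rng(seed)
    obs = {str(c): np.asarray(v, dtype=float) for c, v in breakpoints.items()}
    counts = {c: v.size for c, v in obs.items()}
    cov = covered.by_chrom()
    obs_d = _adjacent_distances(obs)
    if obs_d.size == 0:
        return TestResult(np.nan, np.nan, 0, 0, "ks_clustering_mc", seed), np.empty((0, 2))
    pool = np.sort(np.concatenate([
        _adjacent_distances(_uniform_placement(counts, cov, rng)) for _ in range(pool_reps)
    ]))
    stat_obs = ks_statistic(obs_d, pool)
    null_stats = np.empty(n_null)
    for i in range(n_null):
        d = _adjacent_distances(_uniform_placement(counts, cov, rng))
        null_stats[i] = ks_statistic(d, pool)
    # KS statistics are discrete, so ties occur; breaking them with seeded
    # uniform draws keeps the Monte-Carlo p-value exactly calibrated
    u_obs = rng.random()
    u_null = rng.random(n_null)
    exceed = (null_stats > stat_obs) | ((null_stats == stat_obs) & (u_null >= u_obs))
    p = (1.0 + np.sum(exceed)) / (n_null + 1.0)
    qs = np.linspace(0, 1, n_quantiles + 2)[1:-1]
    qq = np.column_stack([np.quantile(obs_d, qs), np.quantile(pool, qs)])
    return (
        TestResult(statistic=stat_obs, p_value=float(p), n1=obs_d.size, n2=pool.size,
                   method="ks_clustering_mc", seed=seed),
        qq,
    )


def chrom_length_correlation(
    sv_counts: Dict[str, float], chrom_lengths: Dict[str, float]
) -> TestResult:
    """Pearson correlation of per-chromosome SV proportion vs chromosome length."""
    chroms = sorted(chrom_lengths)
    counts = np.array([sv_counts.get(c, 0.0) for c in chroms], dtype=float)
    lengths = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    total = counts.sum()
    if total == 0 or np.all(counts == counts[0]) or np.all(lengths == lengths[0]):
        return TestResult(np.nan, np.nan, len(chroms), len(chroms),
                          "pearson_degenerate_constant_input")
    props = counts / total
    r, p = sps.pearsonr(props, lengths)
    return TestResult(statistic=float(r), p_value=float(p), n1=len(chroms), n2=len(chroms),
                      method="pearson")


def _n50(lengths: Sequence[float]) -> float:
    lens = np.sort(np.asarray(list(lengths), dtype=float))[::-1]
    if lens.size == 0:
        return 0.0
    csum = np.cumsum(lens)
    return float(lens[np.searchsorted(csum, csum[-1] / 2.0)])


def report(
    maps=None,
    calls=None,
    fusion_map_ids=None,
    unique_junctions=None,
    traversal_summary=None,
) -> dict:
    """Assemble the run-level summary table (map N50, SV counts by type,
    fusion-map counts, traversal summary)."""
    maps = maps or []
    calls = calls or []
    by_type: Dict[str, int] = {}
    for c in calls:
        by_type[c.sv_type] = by_type.get(c.sv_type, 0) + 1
    out = {
        "n_maps": len(maps),
        "map_n50_bp": _n50([m.length_bp for m in maps]),
        "total_map_bp": float(sum(m.length_bp for m in maps)),
        "n_svs": len(calls),
        "sv_counts": dict(sorted(by_type.items())),
        "n_fusion_maps": len(fusion_map_ids) if fusion_map_ids is not None else 0,
        "n_unique_fusions": len(unique_junctions) if unique_junctions is not None else 0,
    }
    n_ins = by_type.get("insertion", 0)
    n_del = by_type.get("deletion", 0)
    if n_del:
        out["insertion_deletion_ratio"] = ratio(n_ins, n_del)
    if traversal_summary:
        out["traversal"] = dict(traversal_summary)
    return out
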