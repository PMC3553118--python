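"""Exact penalized least-squares piecewise-constant fitting (PCF).

For an ordered series y_1..y_n the segmentation S minimizes

    cost(S) = sum over segments of within-segment SSE + gamma * (|S| - 1)

subject to every segment containing at least ``min_probes`` probes (a series
shorter than ``min_probes`` becomes a single segment).  The global minimizer
is found by dynamic programming over the last breakpoint with prefix sums,
O(n^2) time and O(n) extra memory per step — exact, no pruning heuristics,
which is fine at array scale (<~5,000 probes per chromosome).

Ties in cost are broken toward fewer segments, then toward the earlier
breakpoint, so results are deterministic.
"""
from __future__ import annotations

import logging
import math

import numpy as np

from .config import PipelineConfig
from .datatypes import CopyNumberProfile, ProbeMap, Segment, SegmentedProfile

log = logging.getLogger(__name__)

# 2 * Phi^-1(3/4): scales the median absolute consecutive difference of a
# Gaussian series to its standard deviation (difference has variance 2*sd^2).
_MAD_DIFF_SCALE = math.sqrt(2.0) * 0.6744897501960817


def robust_noise_sd(values: np.ndarray, chrom: np.ndarray | None = None) -> float:
    """Robust probe-noise estimate: median |consecutive difference| rescaled.

    Differences are taken within chromosomes only (``chrom`` gives each
    probe's chromosome); NaNs are dropped first.
    """
    values = np.asarray(values, dtype=float)
    diffs: list[np.ndarray] = []
    if chrom is None:
        chrom = np.zeros(len(values), dtype=int)
    for c in np.unique(chrom):
        v = values[chrom == c]
        v = v[np.isfinite(v)]
        if len(v) >= 2:
            diffs.append(np.abs(np.diff(v)))
    if not diffs:
        return 0.0
    return float(np.median(np.concatenate(diffs)) / _MAD_DIFF_SCALE)


def pcf_segment(
    series: np.ndarray, gamma: float, min_probes: int = 3
) -> list[tuple[int, int, float]]:
    """Optimal segmentation of one ordered series.

    Returns ``[(start, stop, mean), ...]`` with half-open probe-index ranges
    covering ``0..n`` and means equal to the arithmetic mean of the member
    values.
    """
    y = np.asarray(series, dtype=float)
    n = len(y)
    if n == 0:
        raise ValueError("empty series")
    if not np.all(np.isfinite(y)):
        raise ValueError("series contains non-finite values; drop missing probes first")
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    if min_probes < 1:
        raise ValueError("min_probes must be >= 1")
    if n < min_probes:
        return [(0, n, float(y.mean()))]

    s1 = np.concatenate(([0.0], np.cumsum(y)))
    s2 = np.concatenate(([0.0], np.cumsum(y * y)))

    best = np.full(n + 1, np.inf)
    nseg = np.zeros(n + 1, dtype=np.int64)
    parent = np.full(n + 1, -1, dtype=np.int64)
    best[0] = 0.0

    idx = np.arange(n + 1)
    for j in range(min_probes, n + 1):
        # single-segment candidate (i = 0, no penalty)
        pick_i, pick_cost, pick_nseg = 0, s2[j] - s1[j] * s1[j] / j, 1
        hi = j - min_probes
        if hi >= min_probes:
            lo = min_probes
            sl = slice(lo, hi + 1)
            cost = best[sl] + (s2[j] - s2[sl]) - (s1[j] - s1[sl]) ** 2 / (j - idx[sl]) + gamma
            k = int(np.argmin(cost))  # argmin takes the earliest i among ties
            m = float(cost[k])
            if m == pick_cost:
                # tie with the single-segment candidate: fewer segments wins
                pass
            elif m < pick_cost:
                tied = np.flatnonzero(cost == m)
                if len(tied) > 1:
                    # fewer segments first, then earlier breakpoint
                    k = int(tied[np.lexsort((tied, nseg[lo + tied]))[0]])
                pick_i, pick_cost, pick_nseg = lo + k, m, int(nseg[lo + k]) + 1
        best[j] = pick_cost
        parent[j] = pick_i
        nseg[j] = pick_nseg

    bounds = [n]
    while bounds[-1] > 0:
        bounds.append(int(parent[bounds[-1]]))
    bounds.reverse()
    return [
        (a, b, float((s1[b] - s1[a]) / (b - a))) for a, b in zip(bounds[:-1], bounds[1:])
    ]


def segmentation_cost(y: np.ndarray, ranges: list[tuple[int, int, float]], gamma: float) -> float:
    """cost(S) for a given segmentation; used by tests and diagnostics."""
    y = np.asarray(y, dtype=float)
    sse = sum(float(((y[a:b] - y[a:b].mean()) ** 2).sum()) for a, b, _ in ranges)
    return sse + gamma * (len(ranges) - 1)


def _index_ranges_to_segments(
    pos: np.ndarray, ranges: list[tuple[int, int, float]], chromosome: int
) -> list[Segment]:
    """Convert probe-index ranges to bp segments.

    A segment spans from its first to its last probe; adjacent segments are
    then extended to meet at the midpoint between flanking probes, so each
    chromosome is covered gap-free and the total span does not jitter with
    breakpoint placement.
    """
    raw = [(int(pos[a]), int(pos[b - 1]), b - a, mean) for a, b, mean in ranges]
    segs: list[Segment] = []
    for k, (start, end, np_k, mean) in enumerate(raw):
        if k > 0:
            start = (raw[k - 1][1] + raw[k][0]) // 2 + 1
        if k < len(raw) - 1:
            end = (raw[k][1] + raw[k + 1][0]) // 2
        segs.append(
            Segment(chromosome=chromosome, start_bp=start, end_bp=end, n_probes=np_k, mean_log2=mean)
        )
    return segs


def segment_profile(
    profile: CopyNumberProfile, probe_map: ProbeMap, config: PipelineConfig | None = None
) -> SegmentedProfile:
    """Segment one sample chromosome by chromosome.

    Missing probes are dropped per chromosome before fitting; chromosomes
    with no finite probe are omitted with a warning.  With
    ``config.normalize_noise`` the series is divided by the sample's robust
    noise estimate before the fit (gamma then counts in noise units); means
    are always reported on the original scale.
    """
    config = config or PipelineConfig()
    values = np.asarray(profile.values, dtype=float)
    if len(values) != len(probe_map):
        raise ValueError(f"sample {profile.sample_id}: profile not aligned to probe map")

    if config.median_center:
        med = np.nanmedian(values) if np.any(np.isfinite(values)) else 0.0
        values = values - med

    scale = 1.0
    if config.normalize_noise:
        sd = robust_noise_sd(values, probe_map.chrom)
        if sd > 0:
            scale = sd

    segments: list[Segment] = []
    for c in probe_map.chromosomes:
        idx = probe_map.chrom_indices(c)
        v = values[idx]
        keep = np.isfinite(v)
        if not keep.any():
            log.warning("sample %s: chromosome %d has no finite probes; omitted",
                        profile.sample_id, c)
            continue
        v = v[keep]
        pos = probe_map.pos[idx][keep]
        ranges = pcf_segment(v / scale, config.gamma, config.min_probes_per_segment)
        ranges = [(a, b, float(v[a:b].mean())) for a, b, _ in ranges]
        segments.extend(_index_ranges_to_segments(pos, ranges, int(c)))

    return SegmentedProfile(
        sample_id=profile.sample_id,
        segments=segments,
        gamma_used=config.gamma,
        min_probes_used=config.min_probes_per_segment,
    )


def segment_cohort(
    profiles: list[CopyNumberProfile], probe_map: ProbeMap, config: PipelineConfig | None = None
) -> list[SegmentedProfile]:
    return [segment_profile(p, probe_map, config) for p in profiles]
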