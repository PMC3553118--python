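"""Cohort gain/loss frequency tracks and fixed-grid cross-cohort averages.

States are called on the *segmented* log2 means (not raw probe values): a
probe is a gain if the mean of its covering segment exceeds
``gain_threshold``, a loss if below ``loss_threshold`` (strict
inequalities), neutral otherwise.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import ProbeMap, SegmentedProfile

GAIN, NEUTRAL, LOSS = 1, 0, -1


def segmented_values(segmented: SegmentedProfile, probe_map: ProbeMap) -> np.ndarray:
    """Per-probe covering-segment mean, NaN where no segment covers a probe."""
    out = np.full(len(probe_map), np.nan)
    for seg in segmented.segments:
        idx = probe_map.chrom_indices(seg.chromosome)
        pos = probe_map.pos[idx]
        hit = (pos >= seg.start_bp) & (pos <= seg.end_bp)
        out[idx[hit]] = seg.mean_log2
    return out


def call_states(
    segmented: SegmentedProfile,
    probe_map: ProbeMap,
    gain_threshold: float,
    loss_threshold: float,
) -> np.ndarray:
    """Per-probe state in {GAIN, NEUTRAL, LOSS}; uncovered probes are NEUTRAL."""
    v = segmented_values(segmented, probe_map)
    state = np.zeros(len(probe_map), dtype=np.int8)
    with np.errstate(invalid="ignore"):
        state[v > gain_threshold] = GAIN
        state[v < loss_threshold] = LOSS
    return state


@dataclass
class FrequencyTrack:
    probe_map: ProbeMap
    gain_frequency: np.ndarray
    loss_frequency: np.ndarray
    gain_threshold: float
    loss_threshold: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "probe_id": self.probe_map.probe_id,
                "chrom": self.probe_map.chrom,
                "pos": self.probe_map.pos,
                "gain_frequency": self.gain_frequency,
                "loss_frequency": self.loss_frequency,
            }
        )


def frequency_track(
    cohort: list[SegmentedProfile],
    probe_map: ProbeMap,
    gain_threshold: float = 0.1,
    loss_threshold: float = -0.1,
) -> FrequencyTrack:
    """Fraction of samples called gain / loss at every probe.

    Samples whose segmentation does not cover a probe (e.g. the probe was
    missing in that sample) are excluded from that probe's denominator.
    """
    if not cohort:
        raise ValueError("frequency track needs at least one sample")
    n = len(probe_map)
    gains = np.zeros(n)
    losses = np.zeros(n)
    covered = np.zeros(n)
    for sp in cohort:
        v = segmented_values(sp, probe_map)
        has = np.isfinite(v)
        covered += has
        with np.errstate(invalid="ignore"):
            gains += (v > gain_threshold) & has
            losses += (v < loss_threshold) & has
    with np.errstate(invalid="ignore", divide="ignore"):
        gf = np.where(covered > 0, gains / covered, 0.0)
        lf = np.where(covered > 0, losses / covered, 0.0)
    return FrequencyTrack(probe_map, gf, lf, gain_threshold, loss_threshold)


@dataclass
class GridTrack:
    chrom: np.ndarray
    pos: np.ndarray
    mean_log2: np.ndarray  # NaN where no sample covers a locus
    n_samples: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "pos": self.pos,
                "mean_log2": self.mean_log2,
                "n_samples": self.n_samples,
            }
        )


def grid_average(cohort: list[SegmentedProfile], grid_spacing_bp: int = 1_000_000) -> GridTrack:
    """Cohort-average segmented log2 at loci on a fixed genomic grid.

    Loci are placed every ``grid_spacing_bp`` from each chromosome's first
    covered bp (cohort-wide) to its last; a locus value is the mean over
    samples of the covering segment's mean, excluding samples with no
    covering segment.
    """
    if not cohort:
        raise ValueError("grid average needs at least one sample")
    bounds: dict[int, tuple[int, int]] = {}
    for sp in cohort:
        for s in sp.segments:
            lo, hi = bounds.get(s.chromosome, (s.start_bp, s.end_bp))
            bounds[s.chromosome] = (min(lo, s.start_bp), max(hi, s.end_bp))

    chroms, loci, means, counts = [], [], [], []
    for c in sorted(bounds):
        lo, hi = bounds[c]
        grid = np.arange(lo, hi + 1, grid_spacing_bp, dtype=np.int64)
        acc = np.zeros(len(grid))
        cnt = np.zeros(len(grid))
        for sp in cohort:
            segs = sp.for_chromosome(c)
            if not segs:
                continue
            starts = np.array([s.start_bp for s in segs])
            ends = np.array([s.end_bp for s in segs])
            vals = np.array([s.mean_log2 for s in segs])
            k = np.searchsorted(starts, grid, side="right") - 1
            ok = (k >= 0) & (grid <= ends[np.clip(k, 0, None)])
            acc[ok] += vals[k[ok]]
            cnt[ok] += 1
        with np.errstate(invalid="ignore", divide="ignore"):
            m = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
        chroms.append(np.full(len(grid), c))
        loci.append(grid)
        means.append(m)
        counts.append(cnt)
    return GridTrack(
        chrom=np.concatenate(chroms),
        pos=np.concatenate(loci),
        mean_log2=np.concatenate(means),
        n_samples=np.concatenate(counts).astype(int),
    )
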