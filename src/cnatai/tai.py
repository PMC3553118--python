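"""Total Aberration Index (TAI) and cohort median-split grouping.

TAI is the length-weighted average of the absolute segment mean log2 ratios,

    TAI = sum_i L_i * |ybar_i| / sum_i L_i,

summed over all segments of all chromosomes of one sample, with L_i the
segment span in bp.  It measures the abundance and genomic size of copy
number changes: 0 for a flat diploid profile, up to max_i |ybar_i| for a
fully aberrant genome.  The denominator is the total bp span the platform's
segmented probes cover, so samples on one platform are directly comparable;
absolute values across platforms are not.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import SegmentedProfile, TAIRecord

log = logging.getLogger(__name__)


def total_aberration_index(segmented: SegmentedProfile) -> float:
    if not segmented.segments:
        raise ValueError(f"sample {segmented.sample_id}: empty segmentation")
    spans = np.array([s.span_bp for s in segmented.segments], dtype=float)
    means = np.array([s.mean_log2 for s in segmented.segments], dtype=float)
    total = spans.sum()
    if total <= 0:
        raise ValueError(f"sample {segmented.sample_id}: total segment span is 0")
    return float((spans * np.abs(means)).sum() / total)


def median_split(records: list[TAIRecord]) -> list[TAIRecord]:
    """Label each record "high" iff its TAI exceeds the cohort median.

    The median is the midpoint of the two central order statistics for even
    n; samples exactly at the median go to "low", so with even n and distinct
    values the split is exactly 50/50.
    """
    if len(records) < 2:
        raise ValueError("median split needs at least 2 samples")
    values = np.array([r.tai for r in records], dtype=float)
    med = float(np.median(values))
    if np.all(values == values[0]):
        log.warning("all TAI values identical; every sample labelled low")
    if np.any(values == med):
        log.info("TAI values tie with the cohort median; ties assigned to low")
    for r in records:
        r.group = "high" if r.tai > med else "low"
    return records


def zscore(records: list[TAIRecord]) -> list[TAIRecord]:
    """Attach the cohort z-score of TAI (SD with n-1 denominator)."""
    if len(records) < 2:
        raise ValueError("z-scores need at least 2 samples")
    values = np.array([r.tai for r in records], dtype=float)
    sd = values.std(ddof=1)
    if sd == 0:
        raise ValueError("zero TAI variance; z-scores undefined")
    mean = values.mean()
    for r in records:
        r.z = float((r.tai - mean) / sd)
    return records


def tai_table(segmented: list[SegmentedProfile]) -> pd.DataFrame:
    """Per-sample TAI with median-split group and cohort z-score."""
    records = [
        TAIRecord(sample_id=s.sample_id, tai=total_aberration_index(s)) for s in segmented
    ]
    if len(records) >= 2:
        median_split(records)
        if np.std([r.tai for r in records]) > 0:
            zscore(records)
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "tai": [r.tai for r in records],
            "group": [r.group for r in records],
            "z": [r.z for r in records],
        }
    )
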