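"""Synthetic tumour-cohort generator with known segment-level truth.

Emulates an array copy-number study: ~20k probes over chromosomes 1-23,
per-sample segmental gains/losses of log-uniform length and discrete log2
amplitude, attenuated by the sample's tumour-cell fraction through the
linear-mixture dilution

    observed_level = log2(tf * 2**level + (1 - tf)),

probe-level Gaussian noise, and clinical outcomes statistically linked to
the true Total Aberration Index: exponential survival with log-hazard
``beta_tai`` per cohort SD of true TAI, independent exponential censoring,
and platinum response through a logistic link.  Every quantity downstream
stages estimate is recorded as truth, so the whole pipeline is testable
without array downloads.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .datatypes import ClinicalRecord, CopyNumberProfile, ProbeMap

log = logging.getLogger(__name__)

# hg19-like relative chromosome sizes (1..22, X) rescaled to a 3.1 Gb genome.
_HG_LENGTHS = np.array(
    [
        249250621, 243199373, 198022430, 191154276, 180915260, 171115067,
        159138663, 146364022, 141213431, 135534747, 135006516, 133851895,
        115169878, 107349540, 102531392, 90354753, 81195210, 78077248,
        59128983, 63025520, 48129895, 51304566, 155270560,
    ],
    dtype=float,
)
DEFAULT_CHROM_LENGTHS = np.round(_HG_LENGTHS * (3.1e9 / _HG_LENGTHS.sum())).astype(np.int64)


@dataclass
class SimulationParams:
    """Study-condition knobs of the synthetic cohort.

    Defaults mirror a predominantly high-grade serous ovarian cohort profiled
    on ~20k-probe arrays: many broad aberrations per genome, single-copy
    gain/loss amplitudes (log2 +-0.58, +-1.0) plus rare homozygous deletions
    (-3.3), tumour-cell fractions 20-90%, and better survival at higher
    aberration burden (beta_tai < 0, i.e. hazard ratio < 1 per SD of TAI).
    """

    n_samples: int = 100
    n_probes: int = 20_000
    chromosome_lengths: np.ndarray = field(
        default_factory=lambda: DEFAULT_CHROM_LENGTHS.copy()
    )
    aberrations_per_sample_mean: float = 25.0
    length_range_bp: tuple[float, float] = (2e6, 2e8)  # log-uniform
    amplitude_levels: tuple[float, ...] = (0.58, -0.58, 1.0, -1.0, -3.3)
    amplitude_probs: tuple[float, ...] = (0.3, 0.3, 0.15, 0.2, 0.05)
    tumour_fraction_range: tuple[float, float] = (0.2, 0.9)
    noise_sd: float = 0.15
    beta_tai: float = -0.5  # log-hazard per cohort SD of true TAI
    baseline_hazard: float = 1.0 / 40.0  # events per month
    censor_rate: float = 0.01  # censorings per month
    chemo_logit_slope: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        self.chromosome_lengths = np.asarray(self.chromosome_lengths, dtype=np.int64)
        if len(self.chromosome_lengths) != 23:
            raise ValueError("chromosome_lengths must list 23 chromosomes")
        if self.n_samples < 1 or self.n_probes < 23:
            raise ValueError("need n_samples >= 1 and n_probes >= 23")
        if not 0 < self.tumour_fraction_range[0] <= self.tumour_fraction_range[1] <= 1:
            raise ValueError("tumour_fraction_range must lie in (0, 1]")
        if self.noise_sd < 0 or self.baseline_hazard <= 0 or self.censor_rate < 0:
            raise ValueError("rates and noise must be non-negative (hazard > 0)")
        if self.aberrations_per_sample_mean < 0:
            raise ValueError("aberration rate must be >= 0")
        if abs(sum(self.amplitude_probs) - 1) > 1e-9:
            raise ValueError("amplitude_probs must sum to 1")
        if self.length_range_bp[0] <= 0 or self.length_range_bp[0] > self.length_range_bp[1]:
            raise ValueError("invalid length_range_bp")


@dataclass
class TrueSegment:
    chromosome: int  # 1..23
    start_bp: int
    end_bp: int  # inclusive
    level: float  # clean tumour log2 level (0 = neutral)
    diluted_level: float  # after tumour-fraction mixture


@dataclass
class SampleTruth:
    sample_id: str
    tumour_fraction: float
    segments: list[TrueSegment]
    true_tai: float
    linear_predictor: float = math.nan  # beta_tai * z, filled by simulate_clinical


@dataclass
class SimulationTruth:
    samples: list[SampleTruth]
    beta_tai: float

    @property
    def true_tai(self) -> np.ndarray:
        return np.array([s.true_tai for s in self.samples])


def dilute(level: float, tumour_fraction: float) -> float:
    """Observed log2 level of a clonal aberration in an impure sample."""
    return float(np.log2(tumour_fraction * 2.0 ** level + (1.0 - tumour_fraction)))


def make_probe_map(params: SimulationParams, rng: np.random.Generator | None = None) -> ProbeMap:
    """Probes allocated to chromosomes proportionally to length, uniform
    positions, strictly increasing (ties resolved by +1 bp shifts)."""
    rng = rng or np.random.default_rng(params.seed)
    lengths = params.chromosome_lengths
    share = lengths / lengths.sum()
    alloc = np.maximum(np.floor(params.n_probes * share).astype(int), 1)
    while alloc.sum() > params.n_probes:
        alloc[np.argmax(alloc)] -= 1
    frac = params.n_probes * share - alloc
    for _ in range(params.n_probes - alloc.sum()):
        k = int(np.argmax(frac))
        alloc[k] += 1
        frac[k] = -1
    ids, chroms, poss = [], [], []
    counter = 0
    for c in range(1, 24):
        m = int(alloc[c - 1])
        pos = np.sort(rng.integers(1, lengths[c - 1] + 1, size=m))
        for i in range(1, m):
            if pos[i] <= pos[i - 1]:
                pos[i] = pos[i - 1] + 1
        chroms.append(np.full(m, c))
        poss.append(pos)
        ids.extend(f"p{counter + i:06d}" for i in range(m))
        counter += m
    return ProbeMap(
        probe_id=np.array(ids, dtype=object),
        chrom=np.concatenate(chroms),
        pos=np.concatenate(poss),
    )


_MAX_PLACEMENT_RETRIES = 200
_MAX_SAMPLE_RETRIES = 20


def _place_aberrations(
    params: SimulationParams, rng: np.random.Generator
) -> list[tuple[int, int, int, float]] | None:
    """(chrom, start, end, level) intervals, non-overlapping within chromosome."""
    k = rng.poisson(params.aberrations_per_sample_mean)
    lengths = params.chromosome_lengths
    weights = lengths / lengths.sum()
    lo, hi = np.log(params.length_range_bp[0]), np.log(params.length_range_bp[1])
    placed: list[tuple[int, int, int, float]] = []
    for _ in range(k):
        for _attempt in range(_MAX_PLACEMENT_RETRIES):
            c = int(rng.choice(23, p=weights)) + 1
            size = int(np.exp(rng.uniform(lo, hi)))
            if size >= lengths[c - 1]:
                continue
            start = int(rng.integers(1, lengths[c - 1] - size + 1))
            end = start + size - 1
            if any(cc == c and not (end < s or start > e) for cc, s, e, _ in placed):
                continue
            level = float(rng.choice(params.amplitude_levels, p=params.amplitude_probs))
            placed.append((c, start, end, level))
            break
        else:
            return None
    return placed


def _tile_chromosomes(
    intervals: list[tuple[int, int, int, float]],
    lengths: np.ndarray,
    tumour_fraction: float,
) -> list[TrueSegment]:
    """Fill neutral gaps so the truth tiles every chromosome."""
    segs: list[TrueSegment] = []
    by_chrom: dict[int, list[tuple[int, int, float]]] = {}
    for c, s, e, lv in intervals:
        by_chrom.setdefault(c, []).append((s, e, lv))
    for c in range(1, 24):
        cursor = 1
        for s, e, lv in sorted(by_chrom.get(c, [])):
            if s > cursor:
                segs.append(TrueSegment(c, cursor, s - 1, 0.0, 0.0))
            segs.append(TrueSegment(c, s, e, lv, dilute(lv, tumour_fraction)))
            cursor = e + 1
        if cursor <= lengths[c - 1]:
            segs.append(TrueSegment(c, cursor, int(lengths[c - 1]), 0.0, 0.0))
    return segs


def _tai_of_truth(segments: list[TrueSegment]) -> float:
    spans = np.array([s.end_bp - s.start_bp + 1 for s in segments], dtype=float)
    levels = np.abs([s.diluted_level for s in segments])
    return float((spans * levels).sum() / spans.sum())


def simulate_truth(params: SimulationParams, rng: np.random.Generator | None = None) -> SimulationTruth:
    """Draw per-sample true segment profiles, purity and true TAI (no probes)."""
    rng = rng or np.random.default_rng(params.seed)
    samples: list[SampleTruth] = []
    for i in range(params.n_samples):
        tf = rng.uniform(*params.tumour_fraction_range)
        for _retry in range(_MAX_SAMPLE_RETRIES):
            intervals = _place_aberrations(params, rng)
            if intervals is not None:
                break
            log.warning("sample %d: aberration placement failed; regenerating", i)
        else:
            raise RuntimeError("could not place aberrations; lower the rate or lengths")
        segs = _tile_chromosomes(intervals, params.chromosome_lengths, tf)
        samples.append(
            SampleTruth(
                sample_id=f"S{i:04d}",
                tumour_fraction=tf,
                segments=segs,
                true_tai=_tai_of_truth(segs),
            )
        )
    return SimulationTruth(samples=samples, beta_tai=params.beta_tai)


def render_profiles(
    params: SimulationParams,
    probe_map: ProbeMap,
    truth: SimulationTruth,
    rng: np.random.Generator | None = None,
) -> list[CopyNumberProfile]:
    """Materialise noisy probe-level log2 ratios from the truth segments."""
    rng = rng or np.random.default_rng(params.seed)
    profiles = []
    for st in truth.samples:
        values = np.zeros(len(probe_map))
        for c in range(1, 24):
            idx = probe_map.chrom_indices(c)
            if len(idx) == 0:
                continue
            segs = [s for s in st.segments if s.chromosome == c]
            starts = np.array([s.start_bp for s in segs])
            ends = np.array([s.end_bp for s in segs])
            lvls = np.array([s.diluted_level for s in segs])
            k = np.searchsorted(starts, probe_map.pos[idx], side="right") - 1
            k = np.clip(k, 0, len(segs) - 1)
            covered = (probe_map.pos[idx] >= starts[k]) & (probe_map.pos[idx] <= ends[k])
            vals = np.where(covered, lvls[k], 0.0)
            values[idx] = vals
        if params.noise_sd > 0:
            values = values + rng.normal(0.0, params.noise_sd, size=len(values))
        profiles.append(CopyNumberProfile(sample_id=st.sample_id, values=values))
    return profiles


def simulate_profiles(
    params: SimulationParams, probe_map: ProbeMap, rng: np.random.Generator | None = None
) -> tuple[list[CopyNumberProfile], SimulationTruth]:
    rng = rng or np.random.default_rng(params.seed)
    truth = simulate_truth(params, rng)
    return render_profiles(params, probe_map, truth, rng), truth


def simulate_clinical(
    params: SimulationParams, truth: SimulationTruth, rng: np.random.Generator | None = None
) -> list[ClinicalRecord]:
    """Outcomes linked to true TAI.

    OS ~ Exponential(baseline_hazard * exp(beta_tai * z)) with z the cohort
    z-score of true TAI; independent exponential censoring; PFS is OS scaled
    by Uniform(0.3, 1) under the same censoring time; chemo sensitivity ~
    Bernoulli(logistic(chemo_logit_slope * z)).  Age/stage/grade follow
    advanced serous ovarian cancer marginals.
    """
    rng = rng or np.random.default_rng(params.seed)
    tai = truth.true_tai
    sd = tai.std(ddof=1) if len(tai) > 1 else 0.0
    z = (tai - tai.mean()) / sd if sd > 0 else np.zeros_like(tai)
    records = []
    for st, zi in zip(truth.samples, z):
        st.linear_predictor = params.beta_tai * zi
        rate = params.baseline_hazard * math.exp(params.beta_tai * zi)
        os_true = rng.exponential(1.0 / rate)
        censor = rng.exponential(1.0 / params.censor_rate) if params.censor_rate > 0 else math.inf
        os_months = min(os_true, censor)
        os_event = int(os_true <= censor)
        pfs_true = os_true * rng.uniform(0.3, 1.0)
        pfs_months = min(pfs_true, censor)
        pfs_event = int(pfs_true <= censor)
        sensitive = rng.random() < expit(params.chemo_logit_slope * zi)
        age = float(np.clip(rng.normal(58.0, 11.0), 23.0, 81.0))
        stage = 3 if rng.random() < 0.8 else 4
        grade = int(rng.choice([1, 2, 3], p=[0.05, 0.3, 0.65]))
        records.append(
            ClinicalRecord(
                sample_id=st.sample_id,
                age=age,
                stage=stage,
                grade=grade,
                chemo_response="sensitive" if sensitive else "resistant",
                pfs_months=pfs_months,
                pfs_event=pfs_event,
                os_months=os_months,
                os_event=os_event,
            )
        )
    return records


def simulate_cohort(
    params: SimulationParams,
) -> tuple[ProbeMap, list[CopyNumberProfile], list[ClinicalRecord], SimulationTruth]:
    """Full reproducible cohort: probe map, noisy profiles, clinical, truth."""
    rng = np.random.default_rng(params.seed)
    probe_map = make_probe_map(params, rng)
    truth = simulate_truth(params, rng)
    profiles = render_profiles(params, probe_map, truth, rng)
    clinical = simulate_clinical(params, truth, rng)
    return probe_map, profiles, clinical, truth
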