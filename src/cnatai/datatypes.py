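"""Core domain containers shared by every pipeline stage.

Conventions: chromosomes are integers 1-23 with 23 encoding X (Y is never
modelled); probe positions are 1-based bp as read from input files; segment
bp spans are inclusive counts (``end_bp - start_bp + 1``).  Missing probe
values are NaN.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

MAX_CHROM = 23  # 23 encodes X


@dataclass
class ProbeMap:
    """Ordered genomic grid of measurement positions.

    Sorted by (chromosome, position); positions strictly increasing within a
    chromosome; probe ids unique.
    """

    probe_id: np.ndarray  # str
    chrom: np.ndarray  # int, 1..23
    pos: np.ndarray  # int bp, 1-based

    def __post_init__(self) -> None:
        self.probe_id = np.asarray(self.probe_id, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=np.int64)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        if not (len(self.probe_id) == len(self.chrom) == len(self.pos)):
            raise ValueError("probe_id, chrom and pos must have equal length")
        if len(self.probe_id) == 0:
            raise ValueError("ProbeMap cannot be empty")
        if len(set(self.probe_id)) != len(self.probe_id):
            raise ValueError("duplicate probe_id values")
        if self.chrom.min() < 1 or self.chrom.max() > MAX_CHROM:
            raise ValueError("chromosomes must lie in 1..23")
        if self.pos.min() < 1:
            raise ValueError("positions must be >= 1 bp")
        order = np.lexsort((self.pos, self.chrom))
        if not np.array_equal(order, np.arange(len(order))):
            raise ValueError("probes must be sorted by (chromosome, position)")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on chromosome {c}")

    def __len__(self) -> int:
        return len(self.probe_id)

    @property
    def chromosomes(self) -> np.ndarray:
        return np.unique(self.chrom)

    def chrom_indices(self, chromosome: int) -> np.ndarray:
        """Row indices of the probes on one chromosome (contiguous block)."""
        return np.flatnonzero(self.chrom == chromosome)


@dataclass
class CopyNumberProfile:
    """Per-sample log2-ratio vector aligned 1:1 to a ProbeMap (NaN = missing)."""

    sample_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.isinf(self.values)):
            raise ValueError(f"sample {self.sample_id}: infinite log2 ratios")


@dataclass
class Segment:
    """One constant-mean stretch of probes on one chromosome.

    ``span_bp`` (inclusive bp count) is the length weight L_i of the
    Total Aberration Index.
    """

    chromosome: int
    start_bp: int
    end_bp: int
    n_probes: int
    mean_log2: float

    @property
    def span_bp(self) -> int:
        return self.end_bp - self.start_bp + 1

    def __post_init__(self) -> None:
        if self.n_probes < 1:
            raise ValueError("segment must contain at least one probe")
        if self.end_bp < self.start_bp:
            raise ValueError("segment end before start")


@dataclass
class SegmentedProfile:
    """Partition of one sample's retained probes into segments."""

    sample_id: str
    segments: list[Segment]
    gamma_used: float = math.nan
    min_probes_used: int = 0

    def for_chromosome(self, chromosome: int) -> list[Segment]:
        return [s for s in self.segments if s.chromosome == chromosome]

    def __post_init__(self) -> None:
        prev: Segment | None = None
        for s in self.segments:
            if prev is not None and s.chromosome == prev.chromosome:
                if s.start_bp <= prev.end_bp:
                    raise ValueError(
                        f"sample {self.sample_id}: overlapping or unsorted segments "
                        f"on chromosome {s.chromosome}"
                    )
            prev = s


@dataclass
class TAIRecord:
    """Per-sample Total Aberration Index with cohort annotations."""

    sample_id: str
    tai: float
    group: str | None = None  # "low" / "high" after median split
    z: float | None = None  # cohort z-score (per-SD scale for Cox)


@dataclass
class ClinicalRecord:
    """One patient's clinical covariates and survival endpoints.

    ``grade`` may be None (missing); times are months; event indicators are
    0/1 with 1 = event observed.
    """

    sample_id: str
    age: float
    stage: int
    grade: int | None
    chemo_response: str  # "sensitive" | "resistant"
    pfs_months: float
    pfs_event: int
    os_months: float
    os_event: int

    VALID_STAGES = (2, 3, 4)
    VALID_GRADES = (1, 2, 3)
    VALID_RESPONSES = ("sensitive", "resistant")

    def __post_init__(self) -> None:
        if self.stage not in self.VALID_STAGES:
            raise ValueError(f"sample {self.sample_id}: unknown stage {self.stage!r}")
        if self.grade is not None and self.grade not in self.VALID_GRADES:
            raise ValueError(f"sample {self.sample_id}: unknown grade {self.grade!r}")
        if self.chemo_response not in self.VALID_RESPONSES:
            raise ValueError(
                f"sample {self.sample_id}: unknown chemo_response {self.chemo_response!r}"
            )
        if self.pfs_months < 0 or self.os_months < 0:
            raise ValueError(f"sample {self.sample_id}: negative survival time")
        if self.pfs_event not in (0, 1) or self.os_event not in (0, 1):
            raise ValueError(f"sample {self.sample_id}: event indicators must be 0/1")
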