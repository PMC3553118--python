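"""Pipeline configuration with YAML round-trip."""
from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Knobs for the segmentation / TAI / statistics pipeline.

    gamma
        Penalty per breakpoint of the piecewise-constant fit, applied to the
        noise-normalized series (see ``segmentation``).  Larger values give
        fewer segments.
    min_probes_per_segment
        Smallest number of probes a segment may contain.
    gain_threshold, loss_threshold
        Log2 cutoffs on segment means used to call per-probe gain/loss states
        for frequency tracks.
    grid_spacing_bp
        Spacing of the fixed genomic grid used for cross-cohort comparison.
    median_center
        Subtract each sample's median log2 ratio before segmentation, making
        TAI a deviation-from-diploid measure.
    normalize_noise
        Divide each sample by a robust noise estimate before segmentation so
        that one default gamma serves arrays of different noise levels.
    split_rule
        Median-split rule for TAI groups; only "above_median_high" is defined.
    """

    gamma: float = 40.0
    min_probes_per_segment: int = 3
    gain_threshold: float = 0.1
    loss_threshold: float = -0.1
    grid_spacing_bp: int = 1_000_000
    seed: int = 0
    median_center: bool = True
    normalize_noise: bool = True
    split_rule: str = "above_median_high"

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.min_probes_per_segment < 1:
            raise ValueError("min_probes_per_segment must be >= 1")
        if not (self.loss_threshold < 0 < self.gain_threshold):
            raise ValueError("thresholds must satisfy loss_threshold < 0 < gain_threshold")
        if self.grid_spacing_bp < 1:
            raise ValueError("grid_spacing_bp must be >= 1")
        if self.split_rule != "above_median_high":
            raise ValueError(f"unknown split_rule {self.split_rule!r}")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
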