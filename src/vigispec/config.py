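"""Declarative pipeline configuration with YAML round-tripping."""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """All tunables of the end-to-end pipeline, validated on construction.

    Defaults are the pipeline's canonical values: 0.5–70 Hz order-4
    band-pass, 3-SD artifact rejection, 1-s epochs, PSD over 1–65 Hz and
    the standard spectral-parameterization settings.
    """

    filter_low_hz: float = 0.5
    filter_high_hz: float = 70.0
    filter_order: int = 4
    artifact_sd: float = 3.0
    epoch_s: float = 1.0
    psd_fmin: float = 1.0
    psd_fmax: float = 65.0
    min_state_epochs: int = 30
    max_peaks: int = 6
    peak_threshold_sd: float = 2.0
    peak_width_limits: tuple[float, float] = (0.5, 12.0)
    n_boot: int = 5000
    alpha: float = 0.05
    species_mode: str = "mouse"
    human_truncate_s: float = 900.0  # human mode keeps only the first 15 min
    seed: int = 0

    def __post_init__(self) -> None:
        self.peak_width_limits = tuple(self.peak_width_limits)
        if not (0 < self.filter_low_hz < self.filter_high_hz):
            raise ValueError("filter band must satisfy 0 < low < high")
        if self.artifact_sd <= 0:
            raise ValueError("artifact_sd must be positive")
        if self.epoch_s != 1.0:
            raise ValueError("the pipeline's time quantum is the 1-s epoch")
        if not (0 < self.psd_fmin < self.psd_fmax):
            raise ValueError("psd range must satisfy 0 < fmin < fmax")
        if self.max_peaks < 0 or self.peak_threshold_sd <= 0:
            raise ValueError("invalid peak-fit settings")
        lo, hi = self.peak_width_limits
        if not (0 < lo < hi):
            raise ValueError("peak_width_limits must be increasing and positive")
        if self.n_boot < 1000 or not (0 < self.alpha < 1):
            raise ValueError("invalid stats settings")
        if self.species_mode not in ("mouse", "human"):
            raise ValueError("species_mode must be 'mouse' or 'human'")

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
        return path

    def to_dict(self) -> dict:
        d = asdict(self)
        d["peak_width_limits"] = list(self.peak_width_limits)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides)
        return cls(**data)
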