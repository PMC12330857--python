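"""Round-trippable YAML pipeline configuration."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .synthetic import StudyConfig


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run.

    Every CLI command writes a frozen copy of this (plus the tool
    version) next to its outputs.
    """

    study: StudyConfig = field(default_factory=StudyConfig)
    pipeline: str = "mcsf_wm"          # mcsf_wm | acompcor | physio | none
    # staging
    stage_center: float = 2.75
    z_thresh: float = 1.5
    epoch_volumes: int = 30
    shift_s: float = 5.0
    min_epoch_volumes: int = 30
    # windows
    window_s: float = 240.0
    overlap: float = 0.5
    k: int = 2
    restarts: int = 20
    # thresholds
    top_frac: float = 0.4
    fdr_q: float = 0.05
    # seeds
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "study" in d and isinstance(d["study"], dict):
            d["study"] = StudyConfig(**d["study"])
        return cls(**d)

    def save(self, path: Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(),
                                             sort_keys=True))

    @classmethod
    def load(cls, path: Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
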