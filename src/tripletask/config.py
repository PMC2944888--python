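"""Pipeline configuration: every tunable parameter with its documented
default, YAML/JSON round-tripping, and a content hash for provenance."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .bold import GammaParams
from .synth import NoiseModel
from .task_models import StepTimings
from .trial_sim import TrialParams

__all__ = ["PipelineConfig", "config_hash"]


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of the simulate -> predict -> synth -> analyze chain."""

    n_subjects: int = 10
    blocks: int = 10
    seed: int = 0
    timings: StepTimings = StepTimings()
    p_wrong_state: float = 0.05
    gamma: GammaParams = GammaParams()
    noise: NoiseModel = NoiseModel()
    #: peak percent signal change given to each ROI's largest condition mean
    amplitude_pct: float = 0.5
    interaction_scale: float = 1.0
    carryover: float = 0.0
    dt_s: float = 0.05
    #: trials averaged per condition for the predicted mean curves
    pred_reps: int = 3
    out_dir: str = "out"

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.blocks < 1 or self.pred_reps < 1:
            raise ValueError("n_subjects, blocks and pred_reps must be >= 1")
        if not (0.0 <= self.p_wrong_state <= 1.0):
            raise ValueError("p_wrong_state must be in [0, 1]")
        if self.amplitude_pct <= 0:
            raise ValueError("amplitude_pct must be > 0")

    def trial_params(self) -> TrialParams:
        return TrialParams(timings=self.timings, p_wrong_state=self.p_wrong_state)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @staticmethod
    def from_dict(d: dict) -> "PipelineConfig":
        d = dict(d)
        if "timings" in d and isinstance(d["timings"], dict):
            d["timings"] = StepTimings(**d["timings"])
        if "gamma" in d and isinstance(d["gamma"], dict):
            d["gamma"] = GammaParams(**d["gamma"])
        if "noise" in d and isinstance(d["noise"], dict):
            d["noise"] = NoiseModel(**d["noise"])
        unknown = set(d) - {f.name for f in dataclasses.fields(PipelineConfig)}
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return PipelineConfig(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @staticmethod
    def from_yaml(path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return PipelineConfig.from_dict(yaml.safe_load(fh) or {})

    def hash(self) -> str:
        return config_hash(self.to_dict())


def config_hash(d: dict) -> str:
    """Stable short hash of a config dict (provenance stamp on outputs)."""
    blob = json.dumps(d, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
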