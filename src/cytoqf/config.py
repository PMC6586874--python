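"""Pipeline configuration with lossless JSON round-trip.

Every threshold has a default; the only input a user must supply is the set
of channels to analyse.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .epp import EPPConfig
from .errors import ParameterError
from .qfmatch import MatchConfig

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # transform
    logicle_T: float = 262144.0
    logicle_M: float = 4.5
    logicle_A: float = 0.0
    logicle_W: float | None = None  # None -> estimated per channel
    # EPP / DBM
    max_error: float = 0.05
    min_leaf_size: int | None = None
    grid_size: int = 128
    theta: float = 0.5
    # QFMatch
    gate_multiplier: float = 4.0
    merge_combination_cap: int = 1024
    # misc
    seed: int = 0
    channels: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        if not (0 < self.max_error < 0.5):
            raise ParameterError("max_error must lie in (0, 0.5)")
        if not (0 < self.theta < 1):
            raise ParameterError("theta must lie in (0, 1)")
        if self.gate_multiplier <= 0:
            raise ParameterError("gate_multiplier must be > 0")
        if self.grid_size < 8:
            raise ParameterError("grid_size must be >= 8")

    def epp(self) -> EPPConfig:
        return EPPConfig(
            max_error=self.max_error,
            min_leaf_size=self.min_leaf_size,
            grid_size=self.grid_size,
            theta=self.theta,
        )

    def qfmatch(self) -> MatchConfig:
        return MatchConfig(
            gate_multiplier=self.gate_multiplier,
            merge_combination_cap=self.merge_combination_cap,
        )

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "PipelineConfig":
        if isinstance(source, (str, Path)) and Path(source).exists():
            data = json.loads(Path(source).read_text())
        else:
            data = json.loads(source)
        return cls(**data)
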