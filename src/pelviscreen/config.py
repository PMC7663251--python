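"""Run configuration: the processing tunables, serialized alongside results.

Defaults are the device's validated operating point: 300 ms stable window
on a 0.1 s hop, 200 Hz sampling, 13-degree mobility threshold, 1.96-SD
limits of agreement.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import yaml

from .imu_core import (
    DEFAULT_FILTER_LEN_S,
    DEFAULT_HOP_S,
    DEFAULT_SAMPLE_RATE_HZ,
    DEFAULT_WINDOW_S,
)
from .screening import HIGH_MOBILITY_THRESHOLD_DEG
from .validation_stats import DEFAULT_LOA_K

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    window_s: float = DEFAULT_WINDOW_S
    hop_s: float = DEFAULT_HOP_S
    filter_len_s: float = DEFAULT_FILTER_LEN_S
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ
    threshold_deg: float = HIGH_MOBILITY_THRESHOLD_DEG
    loa_k: float = DEFAULT_LOA_K
    fs_only: bool = False
    signed_threshold: bool = False
    invert_pitch_sign: bool = False
    unit_scale_to_g: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("window_s", "hop_s", "filter_len_s", "sample_rate_hz",
                     "threshold_deg", "loa_k", "unit_scale_to_g"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        unknown = set(data) - {f.name for f in cls.__dataclass_fields__.values()}
        if unknown:
            raise ValueError(f"unknown run-config fields: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(data or {})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
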