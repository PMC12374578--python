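"""Run configuration: one YAML file driving the whole pipeline.

All randomness flows from the single top-level ``seed``; every stage derives
its own generator from it, so identical config files give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .trap import TrapConfig

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Pipeline-wide settings with positive-threshold invariants."""

    trap: TrapConfig = field(default_factory=TrapConfig)
    # schedule
    mz_min: float = 65.0
    mz_max: float = 500.0
    segment_width: float = 20.0
    segment_overlap: float = 5.0
    # simulator
    injection_time: float = 60.0
    noise_sd: float = 0.05
    baseline_sd: float = 5.0
    detection_threshold: float = 5000.0
    # tolerances / stats thresholds
    match_tolerance: float = 0.2
    pick_half_window: float = 0.3
    p_threshold: float = 0.05
    fc_high: float = 1.5
    fc_low: float = 2.0 / 3.0
    test_fraction: float = 0.2
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "segment_width", "injection_time", "detection_threshold",
            "match_tolerance", "pick_half_window", "p_threshold", "fc_high",
            "fc_low", "test_fraction",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.segment_overlap < 0:
            raise ValueError("segment_overlap must be non-negative")
        if self.seed is None:
            raise ValueError("seed must always be set")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        trap_raw = raw.pop("trap", {})
        known = set(cls.__dataclass_fields__) - {"trap"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(trap=TrapConfig(**trap_raw), **raw)

    def to_file(self, path: str | Path) -> None:
        data = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
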