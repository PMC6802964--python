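"""Run configuration: presets, seeds, thresholds, paths.

Every stochastic step takes its seed from the configuration, and all
defaults are materialised into the run manifest so that a saved config
reproduces every output number exactly.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Self-describing configuration of one pipeline run."""

    preset: str = "myo1"
    seed: int = 1
    n_events: int = 50
    out_dir: str = "run"
    # detection
    detection_threshold_mads: float = 6.0
    min_separation_um: float = 1.0
    # trace analysis
    ramp_window_points: int = 60
    amplitude_window_s: tuple[float, float] = (5.0, 8.0)
    scission_high_frac: float = 0.5
    scission_low_frac: float = 0.2
    scission_max_drop_s: float = 0.5
    # tracking
    tracking_threshold_mads: float = 6.0
    max_displacement_um: float = 0.3
    max_gap_frames: int = 1
    min_dwell_frames: int = 2
    # calibration
    excitation_scale: float = 0.2
    overrides: dict = field(default_factory=dict)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "amplitude_window_s" in data:
            data["amplitude_window_s"] = tuple(data["amplitude_window_s"])
        return cls(**data)
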