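"""Flat run configuration shared by the command-line pipeline.

A run is parameterized by a flat, namespaced key set (``path.base_width``,
``privacy.kernel_size``, ...).  Values come from a plain ``key: value``
text file and/or command-line flags, flags winning.  Unknown keys are
rejected so a typo cannot silently fall back to a default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

from .gait import BoutConfig, EventConfig
from .path_overlap import PathConfig

# every knob, with its documented default
_DEFAULTS: dict[str, float | int | str] = {
    "seed": 0,
    "verbosity": 1,
    "path.base_width_fraction": 0.50,
    "path.top_width_fraction": 0.15,
    "path.top_y_fraction": 0.55,
    "mask.width": 200,
    "mask.height": 200,
    "gaze.radius": 30.0,
    "privacy.kernel_size": 157,
    "gait.activity_threshold": 0.4903325,  # 0.05 g, m/s^2
    "gait.window": 0.5,
    "gait.merge_gap": 0.3,
    "gait.min_duration": 3.0,
    "gait.smooth_scale": 0.05,
    "fuse.tolerance": 0.05,
    "fuse.clock_offset": 0.0,
    "fuse.attention_window": 2.0,
    "sim.n_frames": 100,
    "sim.fps": 10.0,
    "sim.width": 1088,
    "sim.height": 1080,
    "sim.hazard_in_path_prob": 0.3,
    "sim.step_mean": 0.55,
    "sim.step_std": 0.01,
    "sim.step_offset": 0.0,
    "sim.duration": 60.0,
    "sim.rest_padding": 10.0,
    "sim.fs": 100.0,
    "sim.noise_std": 0.1,
}


@dataclass
class RunConfig:
    values: dict[str, float | int | str] = field(default_factory=lambda: dict(_DEFAULTS))

    def __getitem__(self, key: str):
        return self.values[key]

    def set(self, key: str, value) -> None:
        if key not in _DEFAULTS:
            raise KeyError(f"unknown configuration key {key!r}")
        default = _DEFAULTS[key]
        self.values[key] = type(default)(value)

    def update(self, overrides: dict) -> "RunConfig":
        for k, v in overrides.items():
            if v is not None:
                self.set(k, v)
        return self

    # typed views onto module configs -------------------------------------
    def path_config(self) -> PathConfig:
        return PathConfig(
            base_width_fraction=float(self["path.base_width_fraction"]),
            top_width_fraction=float(self["path.top_width_fraction"]),
            top_y_fraction=float(self["path.top_y_fraction"]),
        )

    def mask_resolution(self) -> tuple[int, int]:
        return (int(self["mask.width"]), int(self["mask.height"]))

    def bout_config(self) -> BoutConfig:
        return BoutConfig(
            activity_threshold=float(self["gait.activity_threshold"]),
            window=float(self["gait.window"]),
            merge_gap=float(self["gait.merge_gap"]),
            min_duration=float(self["gait.min_duration"]),
        )

    def event_config(self) -> EventConfig:
        return EventConfig(smooth_scale=float(self["gait.smooth_scale"]))


def load_config(path: Union[str, Path]) -> RunConfig:
    """Parse a ``key: value`` file (``#`` comments, blank lines allowed)."""
    cfg = RunConfig()
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if ":" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key: value', got {raw!r}")
        key, value = (s.strip() for s in line.split(":", 1))
        try:
            cfg.set(key, value)
        except KeyError as exc:
            raise ValueError(f"{path}:{lineno}: {exc.args[0]}") from None
    return cfg


def default_config() -> RunConfig:
    return RunConfig()


def describe_defaults() -> str:
    return "\n".join(f"{k}: {v}" for k, v in _DEFAULTS.items())
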