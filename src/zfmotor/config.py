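"""Pipeline configuration.

Every constant of the analysis lives here with its default, so that a run
can be reproduced from the config echoed into its outputs.  Units are noted
per field; all seeds are plain integers.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import yaml

#: Class labels per plate format, in fixed (serialized) order.  The 96-well
#: format merges scoot and turn into a single "movement" class: in the small
#: wells there is too little roaming space to tell short forward scoots from
#: in-place reorienting turns.
CLASS_SETS: dict[str, tuple[str, ...]] = {
    "P24": ("stationary", "scoot", "turn", "AsLB", "VsLB"),
    "P96": ("stationary", "movement", "AsLB", "VsLB"),
}

#: Majority-vote tie-break priority (highest wins on an exact tie).  Rarer,
#: stimulus-locked classes outrank common ones so that startles are not
#: silently dropped when vote counts tie.
CLASS_PRIORITY: tuple[str, ...] = (
    "VsLB",
    "AsLB",
    "turn",
    "scoot",
    "movement",
    "stationary",
)

PLATE_FORMATS = ("P24", "P96")


@dataclass
class RunConfig:
    """All tunable parameters of the pipeline with their defaults.

    Defaults mirror the acquisition and modelling constants of the assay:
    160 fps, 40-frame (250 ms) behavior windows with stride 1, PCA retaining
    95% variance with seed 2023 and no whitening, a 90/10 stratified split,
    a 2 mm/s / 5-frame speed-bout rule, call-bouts of more than 5 frames,
    and 250 ms / 1.0 s response windows for acoustic / visual stimuli.
    """

    plate_format: str = "P24"
    fps: float = 160.0
    pixel_pitch_um: float = 37.8  # micrometres per pixel, both formats
    window_frames: int = 40  # W
    stride: int = 1

    # speed-bout rule (spontaneous movement bouts)
    speed_threshold_mm_s: float = 2.0  # 5 mm/s is a supported override
    speed_min_frames: int = 5
    # coordinate smoothing (frames) before kinematic differencing;
    # counteracts per-frame tracking jitter in speed / heading change
    kinematics_smooth_frames: int = 5

    # call-bout rule: runs must exceed this many frames (strict >)
    min_call_run: int = 5

    # PCA / random forest / clip mining
    pca_variance: float = 0.95
    pca_seed: int = 2023
    rf_trees: int = 100
    rf_seed: int = 2023
    kmeans_k: int = 9
    kmeans_seed: int = 2023
    stationary_path_mm: float = 0.5  # cluster flagged stationary below this

    # train/test split
    split_fraction: float = 0.9
    split_seed: int = 2023

    # stimulus-response windows, seconds from stimulus onset
    response_window_acoustic_s: float = 0.25
    response_window_visual_s: float = 1.0

    def __post_init__(self) -> None:
        if self.plate_format not in PLATE_FORMATS:
            raise ValueError(f"unknown plate format {self.plate_format!r}")
        if self.fps <= 0 or self.pixel_pitch_um <= 0:
            raise ValueError("fps and pixel_pitch_um must be positive")
        if self.window_frames < 2:
            raise ValueError("window_frames must be >= 2")

    @property
    def class_set(self) -> tuple[str, ...]:
        return CLASS_SETS[self.plate_format]

    @property
    def pixel_pitch_mm(self) -> float:
        return self.pixel_pitch_um / 1000.0

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must contain a mapping")
        return cls.from_dict(data)

    def replace(self, **kw: Any) -> "RunConfig":
        return dataclasses.replace(self, **kw)
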