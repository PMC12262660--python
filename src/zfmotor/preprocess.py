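"""Windowing, egocentric alignment, normalization and flattening.

The classifier's unit of input is a 40-frame (250 ms at 160 fps) behavior
window.  Each window is rigidly moved into the fish's own frame of
reference: a single rotation+translation, computed from the window's first
frame, places the body center at the origin with the center-to-snout vector
pointing "up" (the negative-y axis under image coordinates), and is applied
identically to all frames of the window.  Aligned windows are scaled by the
dataset-wide maximum absolute coordinate, shifted by the dataset mean, and
flattened frame-major to a 640-long feature vector.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .keypoint_io import PoseTrack, CENTER, SNOUT

__all__ = [
    "BehaviorWindow",
    "Normalizer",
    "make_windows",
    "window_starts",
    "egocentric_align",
    "flatten",
    "flatten_windows",
    "unflatten_windows",
    "window_time",
    "window_displacement_mm",
]

FLATTEN_ORDER = "frame-major (frame, keypoint, (y, x)); C-order reshape"


@dataclass
class BehaviorWindow:
    """A W-frame slice of a pose track, optionally egocentrically aligned."""

    start_frame: int
    coords: np.ndarray  # (W, 8, 2)
    aligned: bool = False

    @property
    def W(self) -> int:
        return self.coords.shape[0]


def window_starts(frames: int, W: int = 40, stride: int = 1) -> np.ndarray:
    """Start indices of overlapping windows: 0, stride, ... < frames - W.

    The count convention is ``frames - W`` at stride 1 (a 1,600-frame
    acquisition yields 1,560 windows); the final in-range start index is
    deliberately dropped to reproduce that published pipeline shape.
    """
    if frames <= W:
        raise ValueError(f"track has {frames} frames; need more than W={W}")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    return np.arange(0, frames - W, stride)


def make_windows(track: PoseTrack, W: int = 40, stride: int = 1) -> np.ndarray:
    """Stack overlapping windows of a track into an (n, W, 8, 2) array.

    At stride 1 this emits exactly ``frames - W`` windows, window i
    covering frames [i, i+W).
    """
    starts = window_starts(track.frames, W, stride)
    sw = np.lib.stride_tricks.sliding_window_view(track.coords, W, axis=0)
    # sliding_window_view puts the window axis last: (frames-W+1, 8, 2, W)
    return np.ascontiguousarray(np.moveaxis(sw[starts], 3, 1))


def egocentric_align(
    coords: np.ndarray, return_degenerate: bool = False
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Rigidly align window(s) to the first-frame body axis.

    Accepts a single (W, 8, 2) window or a stack (n, W, 8, 2).  For each
    window, one rotation about the first-frame center keypoint followed by
    a translation of that center to the origin is applied to every frame,
    so that the first-frame snout lands at (-d, 0) with d the center-snout
    distance (pointing "up": negative y).  Pairwise distances are exactly
    preserved.

    Windows whose first-frame heading vector has zero length cannot define
    a rotation; they are passed through center-translated only and flagged
    in the degenerate mask (returned when ``return_degenerate``).
    """
    single = coords.ndim == 3
    w = coords[None] if single else coords
    if w.ndim != 4 or w.shape[2:] != (8, 2):
        raise ValueError(f"expected (n, W, 8, 2) or (W, 8, 2), got {coords.shape}")
    center = w[:, 0, CENTER, :]  # (n, 2)
    snout = w[:, 0, SNOUT, :]
    v = snout - center  # (n, 2) in (y, x)
    norm = np.hypot(v[:, 0], v[:, 1])
    degenerate = norm < 1e-12
    # rotation angle taking v to (-d, 0): alpha = pi - atan2(vx, vy)
    alpha = np.where(degenerate, 0.0, np.pi - np.arctan2(v[:, 1], v[:, 0]))
    c, s = np.cos(alpha), np.sin(alpha)
    rot = np.empty((len(w), 2, 2))
    rot[:, 0, 0] = c
    rot[:, 0, 1] = -s
    rot[:, 1, 0] = s
    rot[:, 1, 1] = c
    shifted = w - center[:, None, None, :]
    aligned = np.einsum("nij,nwkj->nwki", rot, shifted)
    if single:
        aligned = aligned[0]
        degenerate = bool(degenerate[0])
    if return_degenerate:
        return aligned, degenerate
    return aligned


@dataclass
class Normalizer:
    """Dataset-level affine normalization, fitted once on training data.

    ``fit`` stores scale = max |coordinate| over the aligned training set
    and offset = mean of the scaled coordinates; ``apply`` returns
    x/scale - offset.  The constants are frozen into the model bundle and
    reused unchanged at inference (they differ between plate formats, the
    24-well wells being physically larger).
    """

    scale: float
    offset: float
    plate_format: str = "P24"

    @classmethod
    def fit(cls, coords: np.ndarray, plate_format: str = "P24") -> "Normalizer":
        coords = np.asarray(coords, dtype=float)
        if coords.size == 0:
            raise ValueError("cannot fit a normalizer on an empty dataset")
        scale = float(np.max(np.abs(coords)))
        if scale == 0.0:
            raise ValueError("normalizer scale is 0 (all-zero dataset)")
        offset = float(np.mean(coords / scale))
        return cls(scale=scale, offset=offset, plate_format=plate_format)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) / self.scale - self.offset

    def invert(self, normed: np.ndarray) -> np.ndarray:
        return (np.asarray(normed, dtype=float) + self.offset) * self.scale

    def to_dict(self) -> dict:
        return {
            "scale": self.scale,
            "offset": self.offset,
            "plate_format": self.plate_format,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Normalizer":
        return cls(**d)


def flatten_windows(windows: np.ndarray) -> np.ndarray:
    """Flatten aligned window(s) to feature vectors of length W*8*2.

    Element order is frame-major: (frame, keypoint, (y, x)) — a plain
    C-order reshape, recorded in the model bundle so the layout stays
    stable across versions.
    """
    w = np.asarray(windows)
    if w.ndim == 3:
        return w.reshape(-1)
    if w.ndim == 4:
        return w.reshape(w.shape[0], -1)
    raise ValueError(f"expected (n, W, 8, 2) or (W, 8, 2), got {w.shape}")


def flatten(window: BehaviorWindow) -> np.ndarray:
    """Flatten one BehaviorWindow; refuses windows not yet aligned."""
    if not window.aligned:
        raise ValueError("window must be egocentrically aligned before flattening")
    return flatten_windows(window.coords)


def unflatten_windows(features: np.ndarray, W: int) -> np.ndarray:
    """Inverse of :func:`flatten_windows` for a known window length."""
    f = np.asarray(features)
    if f.ndim == 1:
        return f.reshape(W, 8, 2)
    return f.reshape(f.shape[0], W, 8, 2)


def window_time(start_frame: int, W: int, fps: float) -> tuple[float, float]:
    """(start_s, end_s) of a window; the span is always W/fps seconds."""
    if fps <= 0:
        raise ValueError("fps must be positive")
    return start_frame / fps, (start_frame + W) / fps


def window_displacement_mm(windows: np.ndarray, pixel_pitch_um: float) -> np.ndarray:
    """Net within-window displacement of the center keypoint, millimetres.

    Used to flag stationary KMeans clusters: a window whose center ends
    about where it started is stationary regardless of tail jitter.  Net
    displacement (rather than summed path length) is robust to per-frame
    tracking noise, which would otherwise swamp the statistic.
    """
    w = np.asarray(windows)
    single = w.ndim == 3
    if single:
        w = w[None]
    disp = w[:, -1, CENTER, :] - w[:, 0, CENTER, :]
    disp_mm = np.hypot(disp[:, 0], disp[:, 1]) * pixel_pitch_um / 1000.0
    return float(disp_mm[0]) if single else disp_mm


def save_feature_matrix(
    path: str | Path,
    features: np.ndarray,
    *,
    W: int,
    stride: int,
    normalizer: Normalizer | None = None,
    starts: np.ndarray | None = None,
) -> Path:
    """Persist a feature matrix as NPZ with a JSON provenance header."""
    path = Path(path)
    header = {
        "W": W,
        "stride": stride,
        "flatten_order": FLATTEN_ORDER,
        "normalizer": normalizer.to_dict() if normalizer else None,
    }
    np.savez(
        path,
        features=features,
        starts=starts if starts is not None else np.arange(len(features)),
        header=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
    )
    return path


def load_feature_matrix(path: str | Path) -> tuple[np.ndarray, np.ndarray, dict]:
    with np.load(path) as z:
        header = json.loads(bytes(z["header"].tobytes()).decode())
        return z["features"], z["starts"], header
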