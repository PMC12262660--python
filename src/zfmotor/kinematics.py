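"""Per-frame kinematics and speed-threshold movement-bout detection.

Heading is the angle of the center-to-snout vector, measured in degrees
with 0 "up" (negative y in image coordinates) and positive angles toward
positive x.  The per-frame heading change is the wrapped absolute
difference in [0, 180]; speed is the center keypoint's frame-to-frame
displacement converted to mm/s; the tail angle is the signed deviation of
the center-to-tip vector from the body axis (0 for a straight fish).

Spontaneous movement bouts are maximal runs of frames whose speed exceeds
a threshold (2 mm/s by default) for at least 5 consecutive frames (31 ms
at 160 fps).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .keypoint_io import PoseTrack, SNOUT, CENTER, TIP

__all__ = [
    "KinematicSeries",
    "SpeedBout",
    "compute_kinematics",
    "detect_speed_bouts",
    "summarize_interval",
    "wrap_angle_deg",
]


def wrap_angle_deg(angle: np.ndarray | float) -> np.ndarray | float:
    """Wrap angle(s) into (-180, 180]."""
    return -np.mod(-np.asarray(angle, dtype=float) + 180.0, 360.0) + 180.0


@dataclass
class KinematicSeries:
    """Per-frame kinematics for one track.  Frame 0 has NaN change/speed."""

    heading_deg: np.ndarray  # (-180, 180], NaN where center == snout
    dheading_deg: np.ndarray  # wrapped |change| in [0, 180]
    speed_mm_s: np.ndarray  # center keypoint speed, >= 0
    tail_angle_deg: np.ndarray  # signed, 0 = straight body
    fps: float
    pixel_pitch_um: float

    @property
    def frames(self) -> int:
        return len(self.heading_deg)


def _vector_angle_deg(vec: np.ndarray) -> np.ndarray:
    """Angle of (y, x) vectors: 0 = up (-y), positive toward +x."""
    return np.degrees(np.arctan2(vec[..., 1], -vec[..., 0]))


def compute_kinematics(track: PoseTrack, smooth_frames: int = 1) -> KinematicSeries:
    """Derive heading, heading change, speed and tail angle from a track.

    ``smooth_frames`` > 1 applies a centered moving average to the
    coordinates before differencing — per-frame speed and heading change
    computed from raw noisy keypoints are otherwise inflated by tracking
    jitter (a linear trajectory is left exactly unchanged by the
    average).  Degenerate frames (center coincident with snout) yield NaN
    heading, which propagates into the adjacent heading-change samples
    rather than being interpolated away.
    """
    coords = track.coords
    if smooth_frames > 1:
        coords = _smooth_coords(coords, smooth_frames)
    n = track.frames
    body = coords[:, SNOUT, :] - coords[:, CENTER, :]
    tail = coords[:, TIP, :] - coords[:, CENTER, :]
    body_len = np.hypot(body[:, 0], body[:, 1])
    heading = np.where(body_len < 1e-12, np.nan, _vector_angle_deg(body))
    heading = wrap_angle_deg(heading)

    dheading = np.full(n, np.nan)
    if n > 1:
        diff = wrap_angle_deg(heading[1:] - heading[:-1])
        dheading[1:] = np.abs(diff)

    speed = np.full(n, np.nan)
    if n > 1:
        step_px = np.hypot(
            np.diff(coords[:, CENTER, 0]), np.diff(coords[:, CENTER, 1])
        )
        speed[1:] = step_px * (track.pixel_pitch_um / 1000.0) * track.fps

    tail_len = np.hypot(tail[:, 0], tail[:, 1])
    tail_angle = np.where(
        (tail_len < 1e-12) | (body_len < 1e-12),
        np.nan,
        wrap_angle_deg(_vector_angle_deg(tail) - _vector_angle_deg(body) - 180.0),
    )
    return KinematicSeries(
        heading_deg=heading,
        dheading_deg=dheading,
        speed_mm_s=speed,
        tail_angle_deg=tail_angle,
        fps=track.fps,
        pixel_pitch_um=track.pixel_pitch_um,
    )


def _smooth_coords(coords: np.ndarray, k: int) -> np.ndarray:
    """Centered moving average along time with edge shrinkage."""
    kernel = np.ones(k) / k
    n = coords.shape[0]
    norm = np.convolve(np.ones(n), kernel, mode="same")
    out = np.empty_like(coords)
    for kp in range(coords.shape[1]):
        for ax in range(2):
            out[:, kp, ax] = (
                np.convolve(coords[:, kp, ax], kernel, mode="same") / norm
            )
    return out


@dataclass
class SpeedBout:
    """A maximal supra-threshold speed run: [start_frame, end_frame)."""

    start_frame: int
    end_frame: int
    duration_s: float
    max_speed_mm_s: float
    max_dheading_deg: float

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame


def detect_speed_bouts(
    series: KinematicSeries,
    threshold_mm_s: float = 2.0,
    min_frames: int = 5,
) -> list[SpeedBout]:
    """Maximal runs with speed strictly above threshold, >= min_frames long.

    NaN speed never counts as above threshold.  Bouts are non-overlapping
    and ordered by start frame.
    """
    above = np.nan_to_num(series.speed_mm_s, nan=-np.inf) > threshold_mm_s
    bouts: list[SpeedBout] = []
    for start, end in _runs(above):
        if end - start < min_frames:
            continue
        sl = slice(start, end)
        bouts.append(
            SpeedBout(
                start_frame=start,
                end_frame=end,
                duration_s=(end - start) / series.fps,
                max_speed_mm_s=float(np.nanmax(series.speed_mm_s[sl])),
                max_dheading_deg=_nanmax_or_nan(series.dheading_deg[sl]),
            )
        )
    return bouts


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) spans of True runs in a boolean mask."""
    if len(mask) == 0:
        return []
    padded = np.concatenate(([False], mask, [False])).astype(np.int8)
    edges = np.diff(padded)
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def _nanmax_or_nan(a: np.ndarray) -> float:
    return float(np.nanmax(a)) if np.isfinite(a).any() else float("nan")


def summarize_interval(
    series: KinematicSeries, start_s: float, end_s: float
) -> tuple[float, float, float]:
    """(max |dheading|, max speed, max |tail angle|) over a time interval.

    Frames with time in [start_s, end_s) contribute; NaN samples are
    ignored.  Useful for the 200 ms pre/stimulus/post comparisons around a
    stimulus onset.
    """
    t = np.arange(series.frames) / series.fps
    sel = (t >= start_s) & (t < end_s)
    if not sel.any():
        return float("nan"), float("nan"), float("nan")
    return (
        _nanmax_or_nan(series.dheading_deg[sel]),
        _nanmax_or_nan(series.speed_mm_s[sel]),
        _nanmax_or_nan(np.abs(series.tail_angle_deg[sel])),
    )
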