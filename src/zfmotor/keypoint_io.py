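"""Reading, validating and writing keypoint pose tracks.

A pose track is one larva's time series of 8 anatomical key points along
the midline (snout to caudal tip), each an image-coordinate pair in
``(y, x)`` order, pixels, with y increasing downward.  Tracks travel in
NetCDF-4 files (one group per well, variable ``keypoints(time, point,
axis)``, attributes ``fps``, ``pixel_pitch_um``, ``plate_format``) or in
long-format CSV (``well,frame,keypoint_index,y,x``).  Stimulus metadata
rides in a JSON sidecar next to the track file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import netCDF4

from .config import PLATE_FORMATS

N_KEYPOINTS = 8
SNOUT, CENTER, TIP = 0, 2, 7  # anatomical roles of keypoint indices

__all__ = [
    "PoseTrack",
    "StimulusEvent",
    "TrialSet",
    "ValidationResult",
    "read_pose_netcdf",
    "write_pose_netcdf",
    "read_pose_csv",
    "write_pose_csv",
    "read_stimulus_json",
    "write_stimulus_json",
    "validate_track",
]


@dataclass
class PoseTrack:
    """One larva's (frames, 8, 2) keypoint series in pixels, (y, x) order."""

    coords: np.ndarray
    fps: float = 160.0
    pixel_pitch_um: float = 37.8
    plate_format: str = "P24"
    well_id: str = "A1"
    acquisition_id: str = "acq000"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 3 or self.coords.shape[1:] != (N_KEYPOINTS, 2):
            raise ValueError(
                f"coords must have shape (frames, {N_KEYPOINTS}, 2), "
                f"got {self.coords.shape}"
            )
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel_pitch_um must be positive")
        if self.plate_format not in PLATE_FORMATS:
            raise ValueError(f"unknown plate format {self.plate_format!r}")

    @property
    def frames(self) -> int:
        return self.coords.shape[0]

    @property
    def duration_s(self) -> float:
        return self.frames / self.fps


@dataclass
class StimulusEvent:
    """A single stimulus within an acquisition (tap 0.1 s, dark flash 2 s)."""

    kind: str  # tap | dark_flash | none
    onset_s: float = 5.0
    duration_s: float | None = None

    _DEFAULT_DURATION = {"tap": 0.1, "dark_flash": 2.0, "none": 0.0}

    def __post_init__(self) -> None:
        if self.kind not in self._DEFAULT_DURATION:
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        if self.duration_s is None:
            self.duration_s = self._DEFAULT_DURATION[self.kind]
        if self.onset_s < 0 or self.duration_s < 0:
            raise ValueError("stimulus onset/duration must be non-negative")


@dataclass
class TrialSet:
    """Pose tracks keyed by (well_id, acquisition_id) plus stimulus metadata."""

    tracks: dict[tuple[str, str], PoseTrack] = field(default_factory=dict)
    stimulus: dict[str, StimulusEvent] = field(default_factory=dict)
    replicate_count: int = 1

    def __post_init__(self) -> None:
        fps = {t.fps for t in self.tracks.values()}
        fmts = {t.plate_format for t in self.tracks.values()}
        if len(fps) > 1 or len(fmts) > 1:
            raise ValueError("all tracks in a TrialSet must share fps and plate_format")

    def __len__(self) -> int:
        return len(self.tracks)

    def wells(self) -> list[str]:
        return sorted({w for (w, _) in self.tracks})


@dataclass
class ValidationResult:
    """Outcome of gap-filling a track: the cleaned track, or a rejection."""

    track: PoseTrack | None
    ok: bool
    reason: str = ""


# ---------------------------------------------------------------------------
# NetCDF
# ---------------------------------------------------------------------------

def write_pose_netcdf(trialset: TrialSet, path: str | Path) -> Path:
    """Write a TrialSet to NetCDF-4, one group per well.

    All tracks must belong to a single acquisition (one file per
    acquisition).  Stimulus metadata, if present, goes to a JSON sidecar
    ``<path>.stim.json``.
    """
    path = Path(path)
    acqs = {acq for (_, acq) in trialset.tracks}
    if len(acqs) > 1:
        raise ValueError("one NetCDF file holds one acquisition; split the TrialSet")
    with netCDF4.Dataset(path, "w", format="NETCDF4") as ds:
        ds.acquisition_id = next(iter(acqs)) if acqs else ""
        ds.replicate_count = trialset.replicate_count
        for (well, _acq), track in sorted(trialset.tracks.items()):
            grp = ds.createGroup(well)
            grp.createDimension("time", track.frames)
            grp.createDimension("point", N_KEYPOINTS)
            grp.createDimension("axis", 2)
            var = grp.createVariable("keypoints", "f8", ("time", "point", "axis"))
            var[:] = track.coords
            var.axis_order = "y,x"
            grp.fps = track.fps
            grp.pixel_pitch_um = track.pixel_pitch_um
            grp.plate_format = track.plate_format
    if trialset.stimulus:
        write_stimulus_json(trialset.stimulus, _sidecar_path(path))
    return path


def read_pose_netcdf(
    path: str | Path, well_selector: Iterable[str] | None = None
) -> TrialSet:
    """Read a NetCDF pose file into a validated TrialSet.

    ``well_selector`` restricts to the given well IDs.  Raises on missing
    keypoint variables or a keypoint count other than 8.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    wanted = set(well_selector) if well_selector is not None else None
    tracks: dict[tuple[str, str], PoseTrack] = {}
    with netCDF4.Dataset(path, "r") as ds:
        acq = str(getattr(ds, "acquisition_id", "") or "acq000")
        replicate_count = int(getattr(ds, "replicate_count", 1))
        wells = list(ds.groups)
        if wanted is not None:
            missing = wanted - set(wells)
            if missing:
                raise KeyError(f"wells not in file: {sorted(missing)}")
            wells = [w for w in wells if w in wanted]
        if not wells:
            raise ValueError(f"no well groups in {path}")
        for well in wells:
            grp = ds.groups[well]
            if "keypoints" not in grp.variables:
                raise KeyError(f"well {well!r} has no 'keypoints' variable")
            var = grp.variables["keypoints"]
            coords = np.asarray(var[:], dtype=np.float64)
            if np.ma.isMaskedArray(var[:]):
                coords = np.where(np.ma.getmaskarray(var[:]), np.nan, coords)
            if coords.ndim != 3 or coords.shape[1] != N_KEYPOINTS:
                raise ValueError(
                    f"keypoint count != {N_KEYPOINTS} in well {well!r} "
                    f"(shape {coords.shape})"
                )
            tracks[(well, acq)] = PoseTrack(
                coords=coords,
                fps=float(getattr(grp, "fps", 160.0)),
                pixel_pitch_um=float(getattr(grp, "pixel_pitch_um", 37.8)),
                plate_format=str(getattr(grp, "plate_format", "P24")),
                well_id=well,
                acquisition_id=acq,
            )
    stim_path = _sidecar_path(path)
    stimulus = read_stimulus_json(stim_path) if stim_path.exists() else {}
    return TrialSet(tracks=tracks, stimulus=stimulus, replicate_count=replicate_count)


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".stim.json")


def write_stimulus_json(
    stimulus: Mapping[str, StimulusEvent], path: str | Path
) -> Path:
    path = Path(path)
    payload = {
        acq: {"kind": ev.kind, "onset_s": ev.onset_s, "duration_s": ev.duration_s}
        for acq, ev in stimulus.items()
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return path


def read_stimulus_json(path: str | Path) -> dict[str, StimulusEvent]:
    data = json.loads(Path(path).read_text())
    return {acq: StimulusEvent(**ev) for acq, ev in data.items()}


# ---------------------------------------------------------------------------
# CSV (long format: well,frame,keypoint_index,y,x)
# ---------------------------------------------------------------------------

CSV_COLUMNS = ["well", "frame", "keypoint_index", "y", "x"]


def write_pose_csv(trialset: TrialSet, path: str | Path) -> Path:
    """Write tracks as long-format CSV sorted by (well, frame, keypoint)."""
    path = Path(path)
    parts = []
    for (well, _acq), track in sorted(trialset.tracks.items()):
        n = track.frames
        frame = np.repeat(np.arange(n), N_KEYPOINTS)
        kp = np.tile(np.arange(N_KEYPOINTS), n)
        parts.append(
            pd.DataFrame(
                {
                    "well": well,
                    "frame": frame,
                    "keypoint_index": kp,
                    "y": track.coords[:, :, 0].ravel(),
                    "x": track.coords[:, :, 1].ravel(),
                }
            )
        )
    df = pd.concat(parts, ignore_index=True)
    df.sort_values(["well", "frame", "keypoint_index"], inplace=True)
    # %.17g round-trips float64 exactly
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_pose_csv(
    path: str | Path,
    fps: float = 160.0,
    pixel_pitch_um: float = 37.8,
    plate_format: str = "P24",
    acquisition_id: str = "acq000",
) -> TrialSet:
    """Read long-format CSV into a TrialSet.

    Rows may arrive in any order; frame indices per well must be the
    contiguous range 0..n-1 with all 8 keypoints per frame.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"CSV missing column(s): {missing}")
    df = df.sort_values(["well", "frame", "keypoint_index"])
    tracks: dict[tuple[str, str], PoseTrack] = {}
    for well, sub in df.groupby("well", sort=True):
        frames = np.sort(sub["frame"].unique())
        n = len(frames)
        if not np.array_equal(frames, np.arange(n)):
            raise ValueError(f"non-contiguous frame indices for well {well!r}")
        if len(sub) != n * N_KEYPOINTS:
            raise ValueError(f"well {well!r}: expected 8 keypoints per frame")
        coords = np.empty((n, N_KEYPOINTS, 2))
        coords[:, :, 0] = sub["y"].to_numpy().reshape(n, N_KEYPOINTS)
        coords[:, :, 1] = sub["x"].to_numpy().reshape(n, N_KEYPOINTS)
        tracks[(str(well), acquisition_id)] = PoseTrack(
            coords=coords,
            fps=fps,
            pixel_pitch_um=pixel_pitch_um,
            plate_format=plate_format,
            well_id=str(well),
            acquisition_id=acquisition_id,
        )
    return TrialSet(tracks=tracks)


# ---------------------------------------------------------------------------
# Validation / gap filling
# ---------------------------------------------------------------------------

def validate_track(track: PoseTrack, max_gap: int = 5) -> ValidationResult:
    """Linearly interpolate NaN runs of at most ``max_gap`` frames.

    Each keypoint/axis series is gap-filled independently; edge gaps are
    filled with the nearest valid value.  Any NaN run longer than
    ``max_gap`` rejects the track (returned as a status, not an
    exception).  Idempotent: a clean track passes through unchanged.
    """
    coords = track.coords
    if not np.isnan(coords).any():
        return ValidationResult(track=track, ok=True)
    filled = coords.copy()
    n = track.frames
    idx = np.arange(n)
    for kp in range(N_KEYPOINTS):
        for ax in range(2):
            series = filled[:, kp, ax]
            bad = np.isnan(series)
            if not bad.any():
                continue
            if bad.all():
                return ValidationResult(
                    None, False, f"keypoint {kp} axis {ax} is all-NaN"
                )
            run = _longest_nan_run(bad)
            if run > max_gap:
                return ValidationResult(
                    None,
                    False,
                    f"NaN gap of {run} frames exceeds max_gap={max_gap} "
                    f"(keypoint {kp}, axis {ax})",
                )
            series[bad] = np.interp(idx[bad], idx[~bad], series[~bad])
    return ValidationResult(track=replace(track, coords=filled), ok=True)


def _longest_nan_run(bad: np.ndarray) -> int:
    run = best = 0
    for b in bad:
        run = run + 1 if b else 0
        best = max(best, run)
    return best
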