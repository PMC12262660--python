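"""Synthetic larval-zebrafish keypoint trajectories with ground-truth labels.

The simulator emits the same data the acquisition hardware would: per-frame
(8 keypoints x (y, x)) pixel coordinates at 160 fps, with per-plate-format
Gaussian position noise, plus the per-frame behavior label that generated
them.  Five behavior classes are modelled through kinematic templates:

* ``stationary`` — drift below 0.5 mm/s, straight body;
* ``scoot``      — forward burst (default peak 8 mm/s) with a small
  tail-beat wobble, net heading change under 20 degrees;
* ``turn``       — in-place reorientation of 30-90 degrees at low speed
  (routine turn, the shortest maneuver);
* ``AsLB``       — C-start-like acoustic startle: heading flips within a
  few frames and speed bursts, both at least 5x a scoot's;
* ``VsLB``       — O-bend-like visual startle: a large, slower
  reorientation, initiated 150-500 ms after the stimulus.

The template magnitudes are simulator parameters chosen to respect the
reported orderings between classes, not claims about real fish; see the
methods note.  All randomness flows through one numpy Generator so a fixed
seed reproduces tracks bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .config import CLASS_SETS
from .keypoint_io import PoseTrack, StimulusEvent, CENTER

__all__ = [
    "BodyModel",
    "Segment",
    "BehaviorScript",
    "SimConfig",
    "CLASS_DEFAULTS",
    "DEFAULT_CORPUS_COUNTS",
    "midline_pose",
    "simulate_track",
    "make_stimulus_trial",
    "make_training_corpus",
    "merge_labels",
]

#: Per-format keypoint position noise (one standard deviation per
#: coordinate axis, micrometres) matching the measured tracking error of
#: the two plate formats.
NOISE_SIGMA_UM = {"P24": 69.59, "P96": 133.12}

#: Well radii, millimetres (24-well ~15.6 mm diameter wells, 96-well ~6.9).
WELL_RADIUS_MM = {"P24": 7.8, "P96": 3.45}

#: Default training-corpus composition per plate format (clip counts).
DEFAULT_CORPUS_COUNTS: dict[str, dict[str, int]] = {
    "P24": {"stationary": 66, "scoot": 102, "turn": 75, "AsLB": 60, "VsLB": 137},
    "P96": {"stationary": 432, "movement": 486, "AsLB": 170, "VsLB": 309},
}

#: Template parameter defaults per class.  Speeds mm/s, angles degrees,
#: times seconds.
CLASS_DEFAULTS: dict[str, dict[str, float]] = {
    "stationary": {"drift_mm_s": 0.05, "duration_s": 0.25},
    "scoot": {
        "peak_speed_mm_s": 8.0,
        "wobble_deg": 0.8,
        "tailbeat_hz": 25.0,
        "duration_s": 0.20,
    },
    "turn": {
        "total_heading_deg": 60.0,
        "peak_speed_mm_s": 3.0,
        "duration_s": 0.16,
    },
    "AsLB": {
        "total_heading_deg": 130.0,
        "peak_speed_mm_s": 45.0,
        "latency_s": 0.006,
        "duration_s": 0.18,
    },
    "VsLB": {
        "total_heading_deg": 150.0,
        "peak_speed_mm_s": 25.0,
        "latency_s": 0.30,
        "duration_s": 0.22,
    },
}

#: Per-clip randomization ranges used by :func:`make_training_corpus`.
_CORPUS_RANGES: dict[str, dict[str, tuple[float, float]]] = {
    "scoot": {"peak_speed_mm_s": (5.0, 12.0), "duration_s": (0.15, 0.24)},
    "turn": {"total_heading_deg": (30.0, 90.0), "duration_s": (0.12, 0.20)},
    "AsLB": {
        "total_heading_deg": (90.0, 140.0),
        "peak_speed_mm_s": (35.0, 60.0),
        "duration_s": (0.12, 0.18),
    },
    "VsLB": {
        "total_heading_deg": (140.0, 180.0),
        "peak_speed_mm_s": (18.0, 30.0),
        "duration_s": (0.20, 0.28),
    },
}

#: Tailward weighting of the bend profile.  The two head segments stay
#: rigid so the center->snout axis tracks the scripted heading exactly.
_BEND_WEIGHTS = np.array([0.0, 0.0, 0.35, 0.6, 0.85, 1.1, 1.3])


@dataclass
class BodyModel:
    """Midline geometry: body length and keypoint placement along the arc."""

    body_length_mm: float = 3.7
    arc_fractions: tuple[float, ...] = (0.0, 0.12, 0.30, 0.45, 0.60, 0.75, 0.88, 1.0)

    def __post_init__(self) -> None:
        af = np.asarray(self.arc_fractions, dtype=float)
        if len(af) != 8 or af[0] != 0.0 or af[-1] != 1.0 or np.any(np.diff(af) <= 0):
            raise ValueError(
                "arc_fractions must be 8 strictly increasing values from 0 to 1"
            )

    @property
    def segment_lengths_mm(self) -> np.ndarray:
        return self.body_length_mm * np.diff(np.asarray(self.arc_fractions))


@dataclass
class Segment:
    """One scripted behavior: class label, onset, duration, parameters."""

    label: str
    onset_s: float
    duration_s: float
    params: dict[str, float] = field(default_factory=dict)


@dataclass
class BehaviorScript:
    """Ordered, non-overlapping behavior segments within an acquisition."""

    segments: list[Segment] = field(default_factory=list)

    def validate(self, acquisition_s: float) -> None:
        prev_end = 0.0
        for seg in sorted(self.segments, key=lambda s: s.onset_s):
            if seg.label not in CLASS_DEFAULTS and seg.label != "movement":
                raise ValueError(f"unknown behavior class {seg.label!r}")
            if seg.onset_s < prev_end - 1e-9:
                raise ValueError("script segments overlap")
            if seg.onset_s + seg.duration_s > acquisition_s + 1e-9:
                raise ValueError("script segment exceeds acquisition length")
            prev_end = seg.onset_s + seg.duration_s


@dataclass
class SimConfig:
    """Acquisition and noise settings for the simulator."""

    plate_format: str = "P24"
    fps: float = 160.0
    acquisition_s: float = 10.0
    pixel_pitch_um: float = 37.8
    noise_sigma_um: float | None = None  # per-format default when None
    well_radius_mm: float | None = None
    seed: int = 0
    body: BodyModel = field(default_factory=BodyModel)

    def __post_init__(self) -> None:
        if self.noise_sigma_um is None:
            self.noise_sigma_um = NOISE_SIGMA_UM[self.plate_format]
        if self.well_radius_mm is None:
            self.well_radius_mm = WELL_RADIUS_MM[self.plate_format]
        if self.noise_sigma_um < 0:
            raise ValueError("noise_sigma_um must be >= 0")

    @property
    def n_frames(self) -> int:
        return int(round(self.fps * self.acquisition_s))


def _unit(heading_deg: np.ndarray) -> np.ndarray:
    """(y, x) unit vector(s) for heading: 0 = up (-y), positive toward +x."""
    rad = np.radians(np.asarray(heading_deg, dtype=float))
    return np.stack([-np.cos(rad), np.sin(rad)], axis=-1)


def midline_pose(
    position: np.ndarray,
    heading_deg: np.ndarray | float,
    bend_profile: np.ndarray,
    body: BodyModel | None = None,
) -> np.ndarray:
    """Place the 8 midline keypoints for given center position and posture.

    ``position`` is the center keypoint (index 2) in mm, ``heading_deg``
    the body-axis direction (0 = up), and ``bend_profile`` the 7 signed
    inter-segment angles in degrees (0 = straight).  The tail extends
    opposite the heading; segment i is rotated by the cumulative bend of
    segments up to i.  Batched inputs broadcast over leading axes:
    position (..., 2), heading (...), bend (..., 7) -> (..., 8, 2).
    """
    body = body or BodyModel()
    position = np.asarray(position, dtype=float)
    bend = np.asarray(bend_profile, dtype=float)
    heading = np.asarray(heading_deg, dtype=float)
    if bend.shape[-1] != 7:
        raise ValueError("bend_profile must have 7 entries (one per segment)")
    seg_angles = heading[..., None] + 180.0 + np.cumsum(bend, axis=-1)
    seg_vecs = _unit(seg_angles) * body.segment_lengths_mm[..., :, None]
    pts = np.zeros(seg_angles.shape[:-1] + (8, 2))
    pts[..., 1:, :] = np.cumsum(seg_vecs, axis=-2)
    return pts + (position - pts[..., CENTER, :])[..., None, :]


# ---------------------------------------------------------------------------
# Per-class kinematic templates
# ---------------------------------------------------------------------------
# Each template returns per-frame (speed_mm_s, signed dheading_deg,
# bend_amp_deg) arrays for a segment of m frames.

def _tmpl_stationary(m, fps, p, rng):
    speed = np.full(m, p.get("drift_mm_s", 0.05))
    return speed, np.zeros(m), np.zeros(m)


def _tmpl_scoot(m, fps, p, rng):
    tau = (np.arange(m) + 0.5) / m
    speed = p["peak_speed_mm_s"] * np.sin(np.pi * tau) ** 2
    t = np.arange(m) / fps
    phase = rng.uniform(0, 2 * np.pi)
    dhead = p["wobble_deg"] * np.sin(2 * np.pi * p["tailbeat_hz"] * t + phase)
    bend = 10.0 * np.sin(2 * np.pi * p["tailbeat_hz"] * t + phase)
    return speed, dhead, bend


def _tmpl_turn(m, fps, p, rng):
    tau = (np.arange(m) + 0.5) / m
    w = np.sin(np.pi * tau) ** 2
    sign = p.get("sign", 1.0)
    dhead = sign * p["total_heading_deg"] * w / w.sum()
    speed = p["peak_speed_mm_s"] * w
    bend = -1.8 * dhead
    return speed, dhead, bend


def _tmpl_aslb(m, fps, p, rng):
    # C-start: the heading flip is front-loaded into the first ~4 frames,
    # followed by a burst swim; both speed and per-frame heading change
    # exceed a scoot's by >= 5x.
    sign = p.get("sign", 1.0)
    dhead = np.zeros(m)
    frac = np.array([0.3, 0.4, 0.2, 0.1])
    k = min(4, m)
    dhead[:k] = sign * p["total_heading_deg"] * frac[:k] / frac[:k].sum()
    # burst swim starts with the bend and decays: speed peaks early
    tau = (np.arange(m) + 0.5) / m
    speed = p["peak_speed_mm_s"] * np.sin(np.pi * np.clip(tau * 1.8, 0.0, 1.0)) ** 2
    decay = np.exp(-np.arange(m) / max(m / 4.0, 1.0))
    bend = -sign * 55.0 * decay
    return speed, dhead, bend


def _tmpl_vslb(m, fps, p, rng):
    # O-bend: the reorientation is spread over the first ~60% of the
    # segment (slower than a C-start), with a moderate swim afterwards.
    sign = p.get("sign", 1.0)
    m1 = max(int(round(0.6 * m)), 2)
    tau1 = (np.arange(m1) + 0.5) / m1
    w = np.sin(np.pi * tau1) ** 2
    dhead = np.zeros(m)
    dhead[:m1] = sign * p["total_heading_deg"] * w / w.sum()
    # the swim follows the reorientation: speed ramps up late
    tau = (np.arange(m) + 0.5) / m
    speed = (
        p["peak_speed_mm_s"]
        * np.sin(np.pi * np.clip((tau - 0.3) / 0.7, 0.0, 1.0)) ** 2
    )
    bend = np.zeros(m)
    bend[:m1] = -sign * 65.0 * np.sin(np.pi * tau1)
    bend[m1:] = -sign * 10.0
    return speed, dhead, bend


def _posture_wander(n: int, fps: float, rng: np.random.Generator) -> np.ndarray:
    """Mean-reverting resting tail-curvature series, degrees."""
    amp = rng.uniform(4.0, 12.0)
    tau = 0.5 * fps  # frames
    out = np.empty(n)
    out[0] = rng.normal(0.0, amp)
    kick = rng.normal(0.0, amp * np.sqrt(2.0 / tau), size=n)
    for t in range(1, n):
        out[t] = out[t - 1] * (1.0 - 1.0 / tau) + kick[t]
    return out


_TEMPLATES = {
    "stationary": _tmpl_stationary,
    "scoot": _tmpl_scoot,
    "turn": _tmpl_turn,
    "AsLB": _tmpl_aslb,
    "VsLB": _tmpl_vslb,
}


def _segment_params(label: str, overrides: Mapping[str, float]) -> dict[str, float]:
    params = dict(CLASS_DEFAULTS[label])
    params.update(overrides)
    return params


def simulate_track(
    script: BehaviorScript,
    config: SimConfig,
    *,
    well_id: str = "A1",
    acquisition_id: str = "acq000",
    rng: np.random.Generator | None = None,
) -> tuple[PoseTrack, np.ndarray]:
    """Simulate one acquisition; returns the noisy track and per-frame labels.

    Frames not covered by a script segment are stationary baseline.
    Deterministic for a fixed seed (``config.seed`` unless an explicit
    ``rng`` is passed).  The trajectory reflects specularly off the well
    boundary so the fish stays in the well.
    """
    script.validate(config.acquisition_s)
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n_frames
    fps = config.fps

    speed = np.full(n, CLASS_DEFAULTS["stationary"]["drift_mm_s"])
    dhead = np.zeros(n)
    # resting larvae are never perfectly straight: slow idiosyncratic
    # tail curvature wander (mean-reverting, ~0.5 s timescale)
    bend_amp = _posture_wander(n, fps, rng)
    labels = np.full(n, "stationary", dtype="<U10")
    for seg in script.segments:
        f0 = int(round(seg.onset_s * fps))
        f1 = min(n, f0 + max(int(round(seg.duration_s * fps)), 1))
        if f1 <= f0:
            continue
        tmpl_label = seg.label
        native = seg.params.get("_native", tmpl_label)
        fn = _TEMPLATES[native if native in _TEMPLATES else tmpl_label]
        p = _segment_params(native if native in _TEMPLATES else tmpl_label, seg.params)
        s, dh, b = fn(f1 - f0, fps, p, rng)
        speed[f0:f1], dhead[f0:f1], bend_amp[f0:f1] = s, dh, b
        labels[f0:f1] = tmpl_label

    # integrate center trajectory with specular wall reflection
    radius = config.well_radius_mm - 0.5
    pos = np.empty((n, 2))
    heading = np.empty(n)
    r0 = 0.5 * radius * np.sqrt(rng.uniform())
    theta0 = rng.uniform(0, 2 * np.pi)
    pos[0] = (r0 * np.cos(theta0), r0 * np.sin(theta0))
    heading[0] = rng.uniform(-180.0, 180.0)
    for t in range(1, n):
        h = heading[t - 1] + dhead[t]
        step = (speed[t] / fps) * _unit(h)
        p = pos[t - 1] + step
        r = np.hypot(p[0], p[1])
        if r > radius:
            nrm = p / r
            p = p - 2.0 * (r - radius) * nrm
            d = _unit(h)
            d = d - 2.0 * float(d @ nrm) * nrm
            h = float(np.degrees(np.arctan2(d[1], -d[0])))
        pos[t] = p
        heading[t] = h

    bend = bend_amp[:, None] / _BEND_WEIGHTS.sum() * _BEND_WEIGHTS[None, :]
    kp_mm = midline_pose(pos, heading, bend, config.body)
    kp_mm += config.well_radius_mm  # image coordinates: well center offset

    pitch_mm = config.pixel_pitch_um / 1000.0
    kp_px = kp_mm / pitch_mm
    if config.noise_sigma_um > 0:
        sigma_px = config.noise_sigma_um / config.pixel_pitch_um
        kp_px = kp_px + rng.normal(0.0, sigma_px, size=kp_px.shape)

    track = PoseTrack(
        coords=kp_px,
        fps=fps,
        pixel_pitch_um=config.pixel_pitch_um,
        plate_format=config.plate_format,
        well_id=well_id,
        acquisition_id=acquisition_id,
    )
    return track, labels


def make_stimulus_trial(
    kind: str,
    respond: bool,
    config: SimConfig,
    *,
    well_id: str = "A1",
    acquisition_id: str = "acq000",
    rng: np.random.Generator | None = None,
) -> tuple[PoseTrack, np.ndarray, StimulusEvent]:
    """One 10 s stimulus trial with onset at 5.0 s.

    A responding fish produces an AsLB (tap) within 15 ms or a VsLB (dark
    flash) within 150-500 ms of onset; a non-responder just continues its
    baseline scoot/turn behavior with no startle-class frames anywhere.
    """
    if kind not in ("tap", "dark_flash"):
        raise ValueError(f"unknown stimulus kind {kind!r}")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    stimulus = StimulusEvent(kind=kind, onset_s=5.0)
    segments: list[Segment] = []
    # sparse baseline activity away from the stimulus window
    for window in ((0.5, 3.8), (7.0, 9.3)):
        for _ in range(rng.integers(1, 3)):
            onset = rng.uniform(*window)
            label = "scoot" if rng.uniform() < 0.6 else "turn"
            segments.append(
                Segment(label, onset, CLASS_DEFAULTS[label]["duration_s"])
            )
    if respond:
        if kind == "tap":
            latency = rng.uniform(0.0, 0.012)
            label = "AsLB"
        else:
            latency = rng.uniform(0.15, 0.45)
            label = "VsLB"
        params = {"sign": float(rng.choice([-1.0, 1.0]))}
        segments.append(
            Segment(
                label,
                stimulus.onset_s + latency,
                CLASS_DEFAULTS[label]["duration_s"],
                params,
            )
        )
    segments = _drop_overlaps(sorted(segments, key=lambda s: s.onset_s))
    track, labels = simulate_track(
        BehaviorScript(segments),
        config,
        well_id=well_id,
        acquisition_id=acquisition_id,
        rng=rng,
    )
    return track, labels, stimulus


def _drop_overlaps(segments: list[Segment]) -> list[Segment]:
    kept: list[Segment] = []
    for seg in segments:
        if kept and seg.onset_s < kept[-1].onset_s + kept[-1].duration_s:
            continue
        kept.append(seg)
    return kept


def make_training_corpus(
    class_counts: Mapping[str, int] | None = None,
    config: SimConfig | None = None,
    *,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Labeled 40-frame clips for classifier training.

    Returns (clips, labels): clips of shape (N, 40, 8, 2) in pixels with
    per-format noise, labels of length N.  Default composition is 66
    stationary / 102 scoots / 75 turns / 60 AsLB / 137 VsLB for the
    24-well format and 432 stationary / 486 movement / 170 AsLB / 309
    VsLB for the 96-well format.  Mimicking how the clip miner exports
    windows at whatever phase of a movement event the clustering catches
    them, each clip is cut from a longer simulated track at a random
    offset relative to the behavior (with at least ~100 ms of the behavior
    inside the clip so the label is unambiguous); magnitudes are
    randomized per clip, and the 96-well "movement" class mixes scoot and
    turn kinematics.
    """
    config = config or SimConfig()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    counts = dict(class_counts or DEFAULT_CORPUS_COUNTS[config.plate_format])
    valid = set(CLASS_SETS[config.plate_format])
    unknown = set(counts) - valid
    if unknown:
        raise ValueError(
            f"unknown class(es) {sorted(unknown)} for plate format "
            f"{config.plate_format}"
        )
    if any(c < 1 for c in counts.values()):
        raise ValueError("class counts must be >= 1")

    W = 40
    margin = W  # stationary lead-in before the scripted behavior
    clips, labels = [], []
    for label in sorted(counts):
        for _ in range(counts[label]):
            native = label
            if label == "movement":
                native = "scoot" if rng.uniform() < 0.6 else "turn"
            if native == "stationary":
                cfg = replace(config, acquisition_s=W / config.fps)
                track, _ = simulate_track(BehaviorScript([]), cfg, rng=rng)
                start = 0
            else:
                params: dict[str, float] = {"_native": native}
                for key, (lo, hi) in _CORPUS_RANGES[native].items():
                    params[key] = float(rng.uniform(lo, hi))
                if native in ("turn", "AsLB", "VsLB"):
                    params["sign"] = float(rng.choice([-1.0, 1.0]))
                duration = params.pop("duration_s")
                dur_frames = int(round(duration * config.fps))
                total = margin + dur_frames + W
                cfg = replace(config, acquisition_s=total / config.fps)
                script = BehaviorScript(
                    [Segment(label, margin / config.fps, duration, params)]
                )
                track, _ = simulate_track(script, cfg, rng=rng)
                # random clip phase keeping >= ~100 ms of behavior inside.
                # Startle clips must contain the behavior onset (a reviewer
                # identifies them by the initial C-/O-bend; mid-burst
                # fragments would never carry a startle label), and
                # scoot/turn clips must contain the bout's peak-speed core
                # (a low-speed tail fragment reads as stationary).
                overlap = min(dur_frames, 16)
                lo = margin - (W - overlap)
                if native in ("AsLB", "VsLB"):
                    hi = margin
                else:
                    core = margin + dur_frames // 2
                    lo = max(lo, core - W + 1)
                    hi = min(core, margin + dur_frames - overlap)
                start = int(rng.integers(lo, hi + 1))
            clips.append(track.coords[start : start + W])
            labels.append(label)
    return np.stack(clips), np.asarray(labels, dtype="<U10")


def merge_labels(labels: np.ndarray, plate_format: str) -> np.ndarray:
    """Map native simulator labels onto a plate format's class set.

    For the 96-well format, scoot and turn collapse into "movement".
    """
    labels = np.asarray(labels)
    if plate_format == "P96":
        labels = np.where(np.isin(labels, ("scoot", "turn")), "movement", labels)
    return labels.astype("<U10")
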