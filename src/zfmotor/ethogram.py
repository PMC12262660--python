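"""From per-window calls to per-frame ethograms, bouts and response rates.

With stride-1 windowing every frame is covered by up to W windows; the
per-frame motor call is the majority vote over the calls of all covering
windows, which centres calls on the time the behavior actually happens and
smooths out single-window flicker.  Maximal same-call runs longer than a
minimum run length (5 frames by default, strict) become call bouts, which
carry interval kinematics; bouts intersecting the stimulus window feed the
responder statistics (a trial responds when at least one frame carries the
elicited class within 250 ms of a tap / 1.0 s of a dark flash; a fish
responds when any of its replicate trials does).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import CLASS_PRIORITY
from .keypoint_io import StimulusEvent
from .kinematics import KinematicSeries, summarize_interval

__all__ = [
    "CallSeries",
    "CallBout",
    "ResponseTable",
    "majority_vote",
    "calls_to_bouts",
    "stimulus_bouts",
    "response_rates",
    "ethogram_report",
]

ELICITED_CLASS = {"tap": "AsLB", "dark_flash": "VsLB"}
DEFAULT_RESPONSE_WINDOW_S = {"tap": 0.25, "dark_flash": 1.0}


@dataclass
class CallSeries:
    """Per-frame labels after majority voting, plus the winning vote counts."""

    labels: np.ndarray  # (n_frames,) of str
    votes: np.ndarray  # (n_frames,) count of windows voting for the winner
    fps: float = 160.0

    @property
    def n_frames(self) -> int:
        return len(self.labels)


def _priority_order(classes: Sequence[str]) -> list[str]:
    """Classes sorted highest-priority first (ties broken alphabetically)."""
    ranked = [c for c in CLASS_PRIORITY if c in classes]
    extra = sorted(set(classes) - set(CLASS_PRIORITY))
    return ranked + extra


def majority_vote(
    window_calls: np.ndarray | Sequence[str],
    W: int,
    n_frames: int,
    fps: float = 160.0,
) -> CallSeries:
    """Per-frame mode over the calls of all windows covering each frame.

    Window i (stride 1) covers frames [i, i+W); frame t therefore collects
    the calls of windows max(0, t-W+1) .. min(n_windows-1, t).  Exact vote
    ties break by a fixed class priority (startle classes win), so the
    result is deterministic.  Trailing frames covered by no window (the
    published windowing drops the final start index) inherit the last
    covered frame's label.
    """
    calls = np.asarray(window_calls)
    n_windows = len(calls)
    if n_windows == 0:
        raise ValueError("no window calls")
    classes = _priority_order(np.unique(calls))
    class_idx = {c: i for i, c in enumerate(classes)}
    onehot = np.zeros((n_windows, len(classes)), dtype=np.int32)
    onehot[np.arange(n_windows), [class_idx[c] for c in calls]] = 1
    csum = np.zeros((n_windows + 1, len(classes)), dtype=np.int32)
    np.cumsum(onehot, axis=0, out=csum[1:])

    t = np.arange(n_frames)
    lo = np.clip(t - W + 1, 0, n_windows)
    hi = np.clip(t + 1, 0, n_windows)
    counts = csum[hi] - csum[lo]  # (n_frames, n_classes), priority-ordered
    covered = counts.sum(axis=1) > 0
    winner = counts.argmax(axis=1)  # first max => highest priority wins ties
    labels = np.array(classes, dtype="<U10")[winner]
    votes = counts[np.arange(n_frames), winner]
    if not covered.all():
        last = -1
        for i in range(n_frames):
            if covered[i]:
                last = i
            elif last >= 0:
                labels[i] = labels[last]
                votes[i] = 0
    return CallSeries(labels=labels, votes=votes, fps=fps)


@dataclass
class CallBout:
    """A maximal same-call run: [start_frame, end_frame), with kinematics."""

    label: str
    start_frame: int
    end_frame: int
    duration_s: float
    max_speed_mm_s: float = float("nan")
    max_dheading_deg: float = float("nan")

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame


def calls_to_bouts(
    series: CallSeries,
    min_run: int = 5,
    exclude: Iterable[str] = (),
    kinematics: KinematicSeries | None = None,
) -> list[CallBout]:
    """Segment the ethogram into maximal same-label runs.

    Runs must *exceed* ``min_run`` frames (strictly more than 5 by
    default — distinct from the >=5-frame speed-bout rule).  Labels in
    ``exclude`` (typically stationary) are skipped.  When a kinematic
    series is supplied, each bout is annotated with its interval maxima.
    """
    labels = series.labels
    exclude = set(exclude)
    bouts: list[CallBout] = []
    n = len(labels)
    start = 0
    for end in range(1, n + 1):
        if end == n or labels[end] != labels[start]:
            label = str(labels[start])
            if (end - start) > min_run and label not in exclude:
                bout = CallBout(
                    label=label,
                    start_frame=start,
                    end_frame=end,
                    duration_s=(end - start) / series.fps,
                )
                if kinematics is not None:
                    dh, sp, _ = summarize_interval(
                        kinematics, start / series.fps, end / series.fps
                    )
                    bout.max_dheading_deg = dh
                    bout.max_speed_mm_s = sp
                bouts.append(bout)
            start = end
    return bouts


def stimulus_bouts(
    bouts: Iterable[CallBout],
    stimulus: StimulusEvent,
    window_s: float,
    fps: float = 160.0,
) -> list[CallBout]:
    """Bouts whose span intersects [onset, onset + window_s), any overlap."""
    lo = stimulus.onset_s
    hi = stimulus.onset_s + window_s
    out = []
    for b in bouts:
        b_lo = b.start_frame / fps
        b_hi = b.end_frame / fps
        if b_lo < hi and b_hi > lo:
            out.append(b)
    return out


@dataclass
class ResponseTable:
    """Trial- and fish-level responder statistics for one stimulus kind."""

    per_trial: pd.DataFrame  # fish, trial, responsive
    per_fish: pd.DataFrame  # fish, responsive (OR over trials)
    pct_trials: float
    pct_fish: float
    kind: str


def response_rates(
    trials: Iterable[tuple[str, str, np.ndarray, StimulusEvent]],
    kind: str,
    fps: float = 160.0,
    window_s: float | None = None,
) -> ResponseTable:
    """Responder rates from per-trial frame-label series.

    ``trials`` yields (fish_id, trial_id, frame_labels, stimulus).  A trial
    is responsive when at least one frame inside [onset, onset+window_s)
    carries the elicited class (AsLB for taps, VsLB for dark flashes); a
    fish is responsive when any of its trials is.  Percentages are on the
    0-100 scale.
    """
    if kind not in ELICITED_CLASS:
        raise ValueError(f"unknown stimulus kind {kind!r}")
    elicited = ELICITED_CLASS[kind]
    window_s = DEFAULT_RESPONSE_WINDOW_S[kind] if window_s is None else window_s
    rows = []
    for fish, trial, labels, stim in trials:
        labels = np.asarray(labels)
        t = np.arange(len(labels)) / fps
        sel = (t >= stim.onset_s) & (t < stim.onset_s + window_s)
        responsive = bool((labels[sel] == elicited).any())
        rows.append({"fish": fish, "trial": trial, "responsive": responsive})
    if not rows:
        raise ValueError("no trials supplied")
    per_trial = pd.DataFrame(rows)
    per_fish = (
        per_trial.groupby("fish", sort=True)["responsive"].any().reset_index()
    )
    return ResponseTable(
        per_trial=per_trial,
        per_fish=per_fish,
        pct_trials=100.0 * per_trial["responsive"].mean(),
        pct_fish=100.0 * per_fish["responsive"].mean(),
        kind=kind,
    )


def ethogram_report(
    bouts: Iterable[CallBout],
    total_frames: int,
    fps: float = 160.0,
    stationary_label: str = "stationary",
) -> pd.DataFrame:
    """Per-class bout census: counts, proportions, durations, maxima.

    Proportions are of non-stationary bouts; ``active_time_fraction`` is
    the fraction of the recording spent inside non-stationary bouts.  The
    table is CSV-ready for downstream statistics.
    """
    bouts = list(bouts)
    rows = []
    non_stat = [b for b in bouts if b.label != stationary_label]
    n_non_stat = len(non_stat)
    active_frames = sum(b.n_frames for b in non_stat)
    by_label: dict[str, list[CallBout]] = {}
    for b in bouts:
        by_label.setdefault(b.label, []).append(b)
    for label in sorted(by_label):
        bs = by_label[label]
        durations = np.array([b.duration_s for b in bs])
        speeds = np.array([b.max_speed_mm_s for b in bs])
        dheads = np.array([b.max_dheading_deg for b in bs])
        rows.append(
            {
                "label": label,
                "n_bouts": len(bs),
                "proportion_non_stationary": (
                    len(bs) / n_non_stat
                    if (label != stationary_label and n_non_stat)
                    else np.nan
                ),
                "mean_duration_s": durations.mean(),
                "sem_duration_s": _sem(durations),
                "mean_max_speed_mm_s": _nanmean(speeds),
                "sem_max_speed_mm_s": _sem(speeds),
                "mean_max_dheading_deg": _nanmean(dheads),
                "sem_max_dheading_deg": _sem(dheads),
                "active_time_fraction": (
                    active_frames / total_frames if total_frames else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)


def _nanmean(a: np.ndarray) -> float:
    a = a[np.isfinite(a)]
    return float(a.mean()) if len(a) else float("nan")


def _sem(a: np.ndarray) -> float:
    a = a[np.isfinite(a)]
    if len(a) < 2:
        return float("nan")
    return float(a.std(ddof=1) / np.sqrt(len(a)))
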