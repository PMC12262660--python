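"""Majority voting, bout segmentation, response rates, bout census."""

from __future__ import annotations

from collections import Counter

import numpy as np
import pytest

from zfmotor.config import CLASS_PRIORITY
from zfmotor.ethogram import (
    CallBout,
    CallSeries,
    calls_to_bouts,
    ethogram_report,
    majority_vote,
    response_rates,
    stimulus_bouts,
)
from zfmotor.keypoint_io import StimulusEvent


def _rank(label: str) -> tuple:
    try:
        return (0, CLASS_PRIORITY.index(label))
    except ValueError:
        return (1, label)


def brute_force_vote(calls, W, n_frames):
    """Independent per-frame tally with the fixed priority tie-break."""
    labels = []
    for t in range(n_frames):
        votes = [calls[i] for i in range(len(calls)) if i <= t < i + W]
        if not votes:
            labels.append(labels[-1] if labels else calls[0])
            continue
        counts = Counter(votes)
        top = max(counts.values())
        winners = [c for c, n in counts.items() if n == top]
        labels.append(min(winners, key=_rank))
    return np.array(labels)


def brute_force_call_bouts(labels, min_run, exclude=()):
    bouts, start = [], 0
    n = len(labels)
    for end in range(1, n + 1):
        if end == n or labels[end] != labels[start]:
            if end - start > min_run and labels[start] not in exclude:
                bouts.append((str(labels[start]), start, end))
            start = end
    return bouts


def _series(labels, fps=160.0):
    labels = np.asarray(labels, dtype="<U10")
    return CallSeries(labels=labels, votes=np.ones(len(labels), dtype=np.int32), fps=fps)


class TestMajorityVote:
    def test_unanimous_calls(self):
        series = majority_vote(np.array(["scoot"] * 100), W=40, n_frames=140)
        assert set(series.labels) == {"scoot"}
        assert series.n_frames == 140

    def test_hand_tally_small_example(self):
        calls = np.array(["A", "A", "B", "B", "B"])
        series = majority_vote(calls, W=3, n_frames=7)
        # frame 3 is covered by windows 1,2,3 with calls A,B,B -> B
        assert series.labels[3] == "B"
        np.testing.assert_array_equal(series.labels, brute_force_vote(calls, 3, 7))

    def test_flicker_is_smoothed_out(self):
        """Window-to-window alternation never survives voting in the
        fully covered interior (frames seen by all W windows)."""
        calls = np.array(["A", "B"] * 50)
        series = majority_vote(calls, W=40, n_frames=139)
        interior = series.labels[39:100]
        isolated = [
            interior[t] != interior[t - 1] and interior[t] != interior[t + 1]
            for t in range(1, len(interior) - 1)
        ]
        assert not any(isolated)

    def test_matches_brute_force_on_random_sequences(self, rng):
        classes = np.array(["stationary", "scoot", "turn", "AsLB", "VsLB"])
        for _ in range(300):
            n_windows = int(rng.integers(1, 30))
            W = int(rng.integers(2, 10))
            calls = rng.choice(classes, size=n_windows)
            n_frames = n_windows + W - 1
            got = majority_vote(calls, W, n_frames)
            np.testing.assert_array_equal(
                got.labels, brute_force_vote(calls, W, n_frames)
            )

    def test_vote_never_adds_transitions(self, rng):
        """Voting smooths: over the fully covered interior, no more label
        transitions than the naive assignment of each window's call to
        its start frame."""
        classes = np.array(["stationary", "scoot", "AsLB"])
        W = 10
        for _ in range(200):
            calls = rng.choice(classes, size=int(rng.integers(W + 2, 60)))
            voted = majority_vote(calls, W=W, n_frames=len(calls) + W - 1).labels
            interior = voted[W - 1 : len(calls)]
            naive_trans = (calls[1:] != calls[:-1]).sum()
            voted_trans = (interior[1:] != interior[:-1]).sum()
            assert voted_trans <= naive_trans

    def test_tie_breaks_prefer_startle_classes(self):
        # two windows, W=2: frame 1 sees one vote each -> VsLB outranks scoot
        series = majority_vote(np.array(["scoot", "VsLB"]), W=2, n_frames=3)
        assert series.labels[1] == "VsLB"


class TestCallBouts:
    def test_run_of_exactly_five_is_not_a_bout(self):
        labels = ["stationary"] * 10 + ["turn"] * 5 + ["stationary"] * 10
        bouts = calls_to_bouts(_series(labels), min_run=5, exclude={"stationary"})
        assert bouts == []

    def test_run_of_six_is_a_bout(self):
        labels = ["stationary"] * 10 + ["turn"] * 6 + ["stationary"] * 10
        bouts = calls_to_bouts(_series(labels), min_run=5, exclude={"stationary"})
        assert len(bouts) == 1
        assert bouts[0].n_frames == 6
        assert bouts[0].label == "turn"
        assert bouts[0].duration_s == pytest.approx(6 / 160)

    def test_matches_brute_force_on_random_sequences(self, rng):
        classes = np.array(["stationary", "scoot", "turn"])
        for _ in range(1000):
            labels = rng.choice(classes, size=int(rng.integers(1, 50)))
            got = calls_to_bouts(_series(labels), min_run=3)
            assert [
                (b.label, b.start_frame, b.end_frame) for b in got
            ] == brute_force_call_bouts(labels, 3)


class TestStimulusBouts:
    tap = StimulusEvent(kind="tap", onset_s=5.0)

    def _bout(self, start_s, end_s, fps=160.0):
        return CallBout(
            label="AsLB",
            start_frame=int(start_s * fps),
            end_frame=int(end_s * fps),
            duration_s=end_s - start_s,
        )

    def test_overlapping_bout_included(self):
        assert stimulus_bouts([self._bout(4.9, 5.1)], self.tap, 0.25)

    def test_late_bout_excluded_from_acoustic_window(self):
        assert stimulus_bouts([self._bout(5.3, 5.5)], self.tap, 0.25) == []

    def test_boundary_overlap_with_visual_window(self):
        assert stimulus_bouts([self._bout(5.9, 6.2)], self.tap, 1.0)


class TestResponseRates:
    @staticmethod
    def _trial(fish, trial, responsive):
        labels = np.full(1600, "stationary", dtype="<U10")
        if responsive:
            labels[805:815] = "AsLB"
        return (fish, trial, labels, StimulusEvent(kind="tap", onset_s=5.0))

    def test_one_responsive_trial_of_six(self):
        trials = [self._trial("f1", f"t{i}", i == 0) for i in range(6)]
        table = response_rates(trials, "tap")
        assert table.pct_trials == pytest.approx(100 / 6)
        assert table.per_fish["responsive"].tolist() == [True]
        assert table.pct_fish == 100.0

    def test_no_elicited_frames_means_zero(self):
        trials = [self._trial(f"f{j}", "t0", False) for j in range(4)]
        table = response_rates(trials, "tap")
        assert table.pct_trials == 0.0 and table.pct_fish == 0.0

    def test_fish_level_is_or_of_trials(self, rng):
        trials = []
        resp = {}
        for j in range(8):
            r = [bool(rng.integers(0, 2)) for _ in range(6)]
            resp[f"f{j}"] = any(r)
            trials += [self._trial(f"f{j}", f"t{i}", r[i]) for i in range(6)]
        table = response_rates(trials, "tap")
        got = dict(zip(table.per_fish["fish"], table.per_fish["responsive"]))
        assert got == resp

    def test_response_outside_window_ignored(self):
        labels = np.full(1600, "stationary", dtype="<U10")
        labels[900:910] = "AsLB"  # 5.625 s: after the 250 ms window
        table = response_rates(
            [("f1", "t0", labels, StimulusEvent(kind="tap", onset_s=5.0))], "tap"
        )
        assert table.pct_fish == 0.0


class TestEthogramReport:
    def test_proportions(self):
        bouts = [
            CallBout("scoot", 0, 10, 10 / 160) for _ in range(3)
        ] + [CallBout("turn", 20, 30, 10 / 160)]
        df = ethogram_report(bouts, total_frames=160).set_index("label")
        assert df.loc["scoot", "proportion_non_stationary"] == pytest.approx(0.75)
        assert df.loc["turn", "proportion_non_stationary"] == pytest.approx(0.25)
        assert df.loc["scoot", "active_time_fraction"] == pytest.approx(40 / 160)

    def test_mean_duration_single_bout(self):
        df = ethogram_report(
            [CallBout("scoot", 0, 40, 40 / 160.0)], total_frames=1600
        )
        assert df["mean_duration_s"].iloc[0] == pytest.approx(0.25)

    def test_scripted_mixture_recovered(self, rng):
        # bout census of a synthetic mixture matches the scripted proportions
        labels, p = ["scoot", "turn"], [0.7, 0.3]
        bouts = [
            CallBout(str(rng.choice(labels, p=p)), 0, 10, 10 / 160)
            for _ in range(400)
        ]
        df = ethogram_report(bouts, total_frames=10_000).set_index("label")
        assert df.loc["scoot", "proportion_non_stationary"] == pytest.approx(
            0.7, abs=3 * np.sqrt(0.7 * 0.3 / 400)
        )
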