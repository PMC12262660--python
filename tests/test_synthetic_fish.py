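"""Simulator: midline geometry, class kinematic templates, noise calibration."""

from __future__ import annotations

import numpy as np
import pytest

from zfmotor.kinematics import compute_kinematics, summarize_interval
from zfmotor.synthetic_fish import (
    CLASS_DEFAULTS,
    BehaviorScript,
    BodyModel,
    Segment,
    SimConfig,
    make_stimulus_trial,
    make_training_corpus,
    merge_labels,
    midline_pose,
    simulate_track,
)

NOISELESS = dict(noise_sigma_um=0.0)


def chain_oracle(position, heading_deg, bend_profile, body):
    """Independent keypoint chain: explicit per-segment loop."""
    seglens = body.body_length_mm * np.diff(np.asarray(body.arc_fractions))
    pts = [np.zeros(2)]
    angle = heading_deg + 180.0
    for i in range(7):
        angle_i = heading_deg + 180.0 + sum(bend_profile[: i + 1])
        rad = np.radians(angle_i)
        step = seglens[i] * np.array([-np.cos(rad), np.sin(rad)])
        pts.append(pts[-1] + step)
    pts = np.array(pts)
    return pts + (np.asarray(position) - pts[2])


class TestMidlinePose:
    def test_straight_fish_collinear(self):
        body = BodyModel()
        pts = midline_pose(np.zeros(2), 90.0, np.zeros(7), body)
        # heading 90 = +x: all points on the y=const line, snout forwardmost
        np.testing.assert_allclose(pts[:, 0], pts[0, 0], atol=1e-12)
        gaps = np.hypot(*(pts[1:] - pts[:-1]).T)
        np.testing.assert_allclose(
            gaps, body.body_length_mm * np.diff(body.arc_fractions), atol=1e-12
        )
        assert pts[0, 1] > pts[7, 1]  # snout ahead of tail along +x

    def test_matches_chain_oracle(self, rng):
        body = BodyModel()
        for _ in range(20):
            pos = rng.uniform(-3, 3, 2)
            heading = rng.uniform(-180, 180)
            bend = rng.uniform(-40, 40, 7)
            np.testing.assert_allclose(
                midline_pose(pos, heading, bend, body),
                chain_oracle(pos, heading, bend, body),
                atol=1e-9,
            )

    def test_bend_sum_180_reverses_tail_direction(self):
        body = BodyModel()
        bend = np.full(7, 180.0 / 7)
        pts = midline_pose(np.zeros(2), 0.0, bend, body)
        oracle = chain_oracle(np.zeros(2), 0.0, bend, body)
        np.testing.assert_allclose(pts, oracle, atol=1e-9)
        # the final segment runs along the heading itself (180 + 180 = 360)
        last = pts[7] - pts[6]
        np.testing.assert_allclose(
            last / np.linalg.norm(last), [-1.0, 0.0], atol=1e-12
        )

    def test_mirrored_bend_mirrors_coordinates(self):
        body = BodyModel()
        bend = np.array([0.0, 5.0, -10.0, 20.0, 15.0, -5.0, 30.0])
        a = midline_pose(np.zeros(2), 0.0, bend, body)
        b = midline_pose(np.zeros(2), 0.0, -bend, body)
        # heading 0 is the -y axis: mirroring flips x only
        np.testing.assert_allclose(a[:, 0], b[:, 0], atol=1e-9)
        np.testing.assert_allclose(a[:, 1], -b[:, 1], atol=1e-9)

    def test_bad_bend_length_rejected(self):
        with pytest.raises(ValueError, match="7 entries"):
            midline_pose(np.zeros(2), 0.0, np.zeros(6))


class TestClassTemplates:
    """Noiseless kinematics must satisfy each class's defining inequality."""

    def test_stationary_speed_below_half_mm_s(self):
        cfg = SimConfig(seed=1, **NOISELESS)
        track, labels = simulate_track(BehaviorScript([]), cfg)
        kin = compute_kinematics(track)
        assert np.nanmax(kin.speed_mm_s) < 0.5
        assert set(labels) == {"stationary"}

    def test_scoot_peak_speed_and_small_heading_change(self):
        cfg = SimConfig(seed=2, **NOISELESS)
        script = BehaviorScript(
            [Segment("scoot", 2.0, 0.2, {"peak_speed_mm_s": 10.0})]
        )
        track, _ = simulate_track(script, cfg)
        kin = compute_kinematics(track)
        f0, f1 = int(2.0 * 160), int(2.2 * 160)
        assert np.nanmax(kin.speed_mm_s[f0:f1]) == pytest.approx(10.0, abs=1.0)
        total_turn = abs(kin.heading_deg[f1] - kin.heading_deg[f0])
        assert min(total_turn, 360 - total_turn) < 20.0

    @pytest.mark.parametrize("total", [30.0, 60.0, 90.0])
    def test_turn_heading_change_in_range(self, total):
        cfg = SimConfig(seed=3, **NOISELESS)
        script = BehaviorScript(
            [Segment("turn", 2.0, 0.16, {"total_heading_deg": total})]
        )
        track, _ = simulate_track(script, cfg)
        kin = compute_kinematics(track)
        f0, f1 = int(2.0 * 160), int(2.16 * 160)
        turned = np.abs(kin.dheading_deg[f0 : f1 + 1]).sum()
        assert 30.0 - 2 <= turned <= 90.0 + 2
        assert turned == pytest.approx(total, abs=2.0)

    def test_aslb_exceeds_scoot_by_5x(self):
        cfg = SimConfig(seed=4, **NOISELESS)
        track, _ = simulate_track(
            BehaviorScript([Segment("AsLB", 5.0, 0.18)]), cfg
        )
        kin = compute_kinematics(track)
        dh, sp, _ = summarize_interval(kin, 5.0, 5.25)
        scoot = CLASS_DEFAULTS["scoot"]
        assert dh >= 5.0 * scoot["wobble_deg"]
        assert sp >= 5.0 * scoot["peak_speed_mm_s"]

    def test_vslb_large_reorientation(self):
        cfg = SimConfig(seed=5, **NOISELESS)
        track, _ = simulate_track(
            BehaviorScript([Segment("VsLB", 5.0, 0.22)]), cfg
        )
        kin = compute_kinematics(track)
        f0, f1 = int(5.0 * 160), int(5.22 * 160)
        turned = np.abs(kin.dheading_deg[f0 : f1 + 1]).sum()
        assert turned >= 100.0


class TestSimulateTrack:
    def test_same_seed_bit_identical(self):
        cfg = SimConfig(seed=9)
        script = BehaviorScript([Segment("scoot", 1.0, 0.2)])
        a, la = simulate_track(script, cfg)
        b, lb = simulate_track(script, cfg)
        assert np.array_equal(a.coords, b.coords)
        assert np.array_equal(la, lb)

    def test_script_out_of_bounds_rejected(self):
        cfg = SimConfig(seed=1)
        with pytest.raises(ValueError, match="exceeds acquisition"):
            simulate_track(BehaviorScript([Segment("scoot", 9.9, 0.5)]), cfg)

    def test_overlapping_segments_rejected(self):
        cfg = SimConfig(seed=1)
        script = BehaviorScript(
            [Segment("scoot", 1.0, 0.3), Segment("turn", 1.1, 0.2)]
        )
        with pytest.raises(ValueError, match="overlap"):
            simulate_track(script, cfg)

    def test_fish_stays_in_well(self):
        cfg = SimConfig(seed=6, **NOISELESS)
        script = BehaviorScript(
            [Segment("scoot", 0.5 + i, 0.3, {"peak_speed_mm_s": 30.0})
             for i in range(9)]
        )
        track, _ = simulate_track(script, cfg)
        center_mm = track.coords[:, 2, :] * cfg.pixel_pitch_um / 1000.0
        r = np.hypot(*(center_mm - cfg.well_radius_mm).T)
        assert r.max() <= cfg.well_radius_mm + 1e-6

    def test_noise_rms_calibrated(self):
        """sigma = 70 um noise shows up as ~70 um RMS per coordinate."""
        clean_cfg = SimConfig(seed=7, noise_sigma_um=0.0)
        noisy_cfg = SimConfig(seed=7, noise_sigma_um=70.0)
        clean, _ = simulate_track(BehaviorScript([]), clean_cfg)
        noisy, _ = simulate_track(BehaviorScript([]), noisy_cfg)
        dev_um = (noisy.coords - clean.coords) * clean_cfg.pixel_pitch_um
        assert dev_um.size >= 10_000
        rms = np.sqrt(np.mean(dev_um**2))
        assert rms == pytest.approx(70.0, abs=5.0)


class TestStimulusTrials:
    def test_tap_responder_has_aslb_in_window(self):
        cfg = SimConfig(seed=8)
        track, labels, ev = make_stimulus_trial("tap", True, cfg)
        assert ev.kind == "tap" and ev.onset_s == 5.0
        window = labels[int(5.0 * 160) : int(5.25 * 160)]
        assert "AsLB" in window

    def test_dark_flash_responder_has_vslb_in_window(self):
        cfg = SimConfig(seed=8)
        track, labels, ev = make_stimulus_trial("dark_flash", True, cfg)
        assert ev.duration_s == 2.0
        window = labels[int(5.0 * 160) : int(6.0 * 160)]
        assert "VsLB" in window

    def test_non_responder_has_no_startle_labels(self):
        cfg = SimConfig(seed=8)
        _, labels, _ = make_stimulus_trial("tap", False, cfg)
        assert "AsLB" not in labels and "VsLB" not in labels


class TestTrainingCorpus:
    def test_default_p24_corpus_size(self, p24_corpus):
        clips, labels = p24_corpus
        assert len(clips) == 440  # 66 + 102 + 75 + 60 + 137
        assert clips.shape[1:] == (40, 8, 2)
        counts = dict(zip(*np.unique(labels, return_counts=True)))
        assert counts == {
            "stationary": 66, "scoot": 102, "turn": 75, "AsLB": 60, "VsLB": 137
        }

    def test_default_p96_corpus_size(self, p96_corpus):
        clips, labels = p96_corpus
        assert len(clips) == 1397  # 432 + 486 + 170 + 309
        counts = dict(zip(*np.unique(labels, return_counts=True)))
        assert counts == {
            "stationary": 432, "movement": 486, "AsLB": 170, "VsLB": 309
        }

    def test_explicit_counts(self):
        cfg = SimConfig(seed=12)
        clips, labels = make_training_corpus({"scoot": 3}, cfg)
        assert len(clips) == 3 and set(labels) == {"scoot"}

    def test_unknown_class_for_format_rejected(self):
        with pytest.raises(ValueError, match="unknown class"):
            make_training_corpus({"scoot": 3}, SimConfig(plate_format="P96"))

    def test_merge_labels_collapses_movement(self):
        labels = np.array(["scoot", "turn", "AsLB", "stationary"])
        merged = merge_labels(labels, "P96")
        assert list(merged) == ["movement", "movement", "AsLB", "stationary"]
        assert list(merge_labels(labels, "P24")) == list(labels)
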