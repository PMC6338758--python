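"""Synthetic assay generator: determinism, geometry, ground-truth consistency."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from flycourt.angle import AngleClass, classify, measure_deviation
from flycourt.detect import extract_blobs
from flycourt.synth import (
    DEFAULT_OFFSPRING_PROBS,
    ArenaSpec,
    ClassProbabilities,
    SimConfig,
    make_landmarks,
    make_outcome_table,
    simulate_assay,
)


class TestArenaAndConfig:
    def test_arena_invariants(self):
        with pytest.raises(ValueError):
            ArenaSpec(diameter_mm=-1)
        with pytest.raises(ValueError):
            ArenaSpec(pixels_per_mm=2)
        with pytest.raises(ValueError):
            ArenaSpec(frame_interval_s=0)

    def test_scripted_event_outside_recording_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            SimConfig(duration_s=100, scripted_events=(("copulation", 50.0, 150.0),))

    def test_overlapping_scripted_events_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            SimConfig(
                duration_s=500,
                scripted_events=(("following", 0.0, 100.0), ("copulation", 50.0, 200.0)),
            )


class TestSimulateAssay:
    def test_scripted_copulation_passes_through_to_log(self, scripted_assay):
        _, _, log, _ = scripted_assay
        cop = log.events("copulation")
        assert len(cop) == 1
        assert (float(cop["start_s"].iloc[0]), float(cop["end_s"].iloc[0])) == (100.0, 250.0)
        assert int(cop["truncated"].iloc[0]) == 0

    def test_same_seed_bit_identical(self, scripted_assay):
        cfg, rec, log, _ = scripted_assay
        rec2, log2 = simulate_assay(cfg)
        assert np.array_equal(rec.frames, rec2.frames)
        assert log.df.equals(log2.df)

    def test_different_seed_differs(self, scripted_assay):
        cfg, rec, _, _ = scripted_assay
        rec3, _ = simulate_assay(dataclasses.replace(cfg, seed=cfg.seed + 1))
        assert not np.array_equal(rec.frames, rec3.frames)

    def test_frame_count_and_timestamps(self, small_arena):
        cfg = SimConfig(arena=small_arena, duration_s=200.0, seed=0, scripted_events=())
        rec, _ = simulate_assay(cfg)
        assert len(rec) == 41  # floor(200/5) + 1
        assert rec.timestamps_s[0] == 0.0 and rec.timestamps_s[-1] == 200.0

    def test_no_copulation_masks_disjoint_when_agents_apart(self, small_arena):
        """Whenever the two agents are more than one body length apart, their
        rendered masks are disjoint (geometric-overlap oracle on the agent
        trajectory); without copulation, avoidance keeps them apart always."""
        cfg = SimConfig(
            arena=small_arena, duration_s=400.0, seed=5, scripted_events=(), noise_sigma=0.0
        )
        rec, _ = simulate_assay(cfg)
        tr = rec.trajectory
        sep = np.hypot(tr["female_x"] - tr["male_x"], tr["female_y"] - tr["male_y"])
        assert (sep > cfg.fly_length_mm).all()
        for k, frame in enumerate(rec.frames):
            assert extract_blobs(frame < 128, min_area_px=9).component_count == 2, k

    def test_copulation_frames_form_single_component(self, scripted_assay):
        cfg, _, _, gt_masks = scripted_assay
        ts = np.arange(len(gt_masks)) * cfg.arena.frame_interval_s
        during = (ts >= 100.0) & (ts < 250.0)
        for mask in gt_masks[during]:
            assert extract_blobs(mask, min_area_px=9).component_count == 1

    def test_ground_truth_consistency_of_merged_frames(self, scripted_assay):
        """The set of frames where the silhouettes merge equals the scripted
        copulation interval to within one frame interval."""
        cfg, _, _, gt_masks = scripted_assay
        ts = np.arange(len(gt_masks)) * cfg.arena.frame_interval_s
        merged = np.array(
            [extract_blobs(m, min_area_px=9).component_count == 1 for m in gt_masks]
        )
        on = ts[merged]
        assert abs(on.min() - 100.0) <= cfg.arena.frame_interval_s
        assert abs((on.max() + cfg.arena.frame_interval_s) - 250.0) <= cfg.arena.frame_interval_s
        # merged frames are one contiguous run
        idx = np.flatnonzero(merged)
        assert np.all(np.diff(idx) == 1)

    def test_every_fly_pixel_inside_arena_disk(self, scripted_assay):
        cfg, _, _, gt_masks = scripted_assay
        ppm = cfg.arena.pixels_per_mm
        r_mm = cfg.arena.diameter_mm / 2
        for mask in gt_masks[::7]:
            ys, xs = np.nonzero(mask)
            d = np.hypot((xs + 0.5) / ppm - r_mm, (ys + 0.5) / ppm - r_mm)
            assert d.max() <= r_mm + 1e-9

    def test_truncated_copulation_flagged(self, small_arena):
        cfg = SimConfig(
            arena=small_arena, duration_s=300.0, seed=2,
            scripted_events=(("copulation", 200.0, 300.0),),
        )
        _, log = simulate_assay(cfg)
        cop = log.events("copulation")
        assert int(cop["truncated"].iloc[0]) == 1

    def test_sampled_mode_copulates_at_most_once(self, small_arena):
        for seed in range(6):
            cfg = SimConfig(
                arena=small_arena, duration_s=1200.0, seed=seed, copulation_prob=0.8
            )
            _, log = simulate_assay(cfg)
            assert len(log.events("copulation")) <= 1


class TestMakeLandmarks:
    def test_zero_deviation_axis_parallel_to_midline(self):
        lm = make_landmarks(0.0, 0.0, seed=4)
        assert measure_deviation(lm) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("dev", [45.0, -45.0, 180.0, -135.0, 22.0])
    def test_noise_free_landmarks_measure_true_angle(self, dev):
        lm = make_landmarks(dev, 0.0, seed=9)
        assert measure_deviation(lm) == pytest.approx(dev, abs=1e-9)

    def test_noise_is_zero_mean_with_stated_spread(self):
        devs = np.array(
            [measure_deviation(make_landmarks(30.0, 5.0, seed=s)) for s in range(400)]
        )
        err = devs - 30.0
        assert abs(err.mean()) < 5.0 / np.sqrt(400) * 4
        assert err.std() == pytest.approx(5.0, rel=0.25)

    def test_out_of_range_true_angle_rejected(self):
        with pytest.raises(ValueError):
            make_landmarks(-180.0, 0.0, seed=0)

    def test_deterministic_in_seed(self):
        assert make_landmarks(10, 2, seed=7) == make_landmarks(10, 2, seed=7)


class TestMakeOutcomeTable:
    def _uniform_probs(self, p: float) -> ClassProbabilities:
        return ClassProbabilities(
            offspring={"wild_type": {cls: p for cls in AngleClass}}
        )

    def test_degenerate_probability_one(self):
        table = make_outcome_table(self._uniform_probs(1.0), 10, seed=0)
        assert (table["offspring"] == 1).all() and (table["copulated"] == 1).all()
        assert len(table) == 80

    def test_degenerate_probability_zero(self):
        table = make_outcome_table(self._uniform_probs(0.0), 10, seed=0)
        assert (table["offspring"] == 0).all()

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            self._uniform_probs(1.5)
        with pytest.raises(ValueError):
            ClassProbabilities(
                offspring={"g": {AngleClass.DEG_0: 0.8}},
                copulation={"g": {AngleClass.DEG_0: 0.5}},
            )

    def test_no_offspring_without_copulation(self):
        probs = ClassProbabilities(
            offspring=DEFAULT_OFFSPRING_PROBS,
            copulation={
                g: {c: min(1.0, p + 0.2) for c, p in m.items()}
                for g, m in DEFAULT_OFFSPRING_PROBS.items()
            },
        )
        table = make_outcome_table(probs, 50, seed=3)
        assert not ((table["offspring"] == 1) & (table["copulated"] == 0)).any()

    def test_binomial_recovery_pooled_over_seeds(self):
        """Empirical per-class rates pooled over many seeds recover the input
        probabilities within 3 binomial standard errors (sampling-theory oracle)."""
        probs = ClassProbabilities(offspring={"wild_type": DEFAULT_OFFSPRING_PROBS["wild_type"]})
        n, reps = 60, 30
        tallies = None
        for seed in range(reps):
            t = make_outcome_table(probs, n, seed=seed)
            agg = t.groupby("angle_class")["offspring"].sum()
            tallies = agg if tallies is None else tallies + agg
        for cls, p in DEFAULT_OFFSPRING_PROBS["wild_type"].items():
            total = n * reps
            se = np.sqrt(p * (1 - p) / total)
            assert abs(tallies[cls.value] / total - p) <= max(3 * se, 1e-12)

    def test_measured_angles_classify_into_their_class(self):
        table = make_outcome_table(ClassProbabilities.defaults(), 5, seed=1)
        for _, row in table.iterrows():
            assert classify(row["measured_angle_deg"]).value == row["angle_class"]

    def test_per_day_series(self):
        probs = ClassProbabilities(
            offspring={"wild_type": {AngleClass.DEG_0: 1.0}},
            per_day={1: 0.8, 2: 0.9, 3: 1.0, 4: 1.0},
        )
        table = make_outcome_table(probs, 20, seed=0)
        days = table[table["angle_class"] == "normal"]["mating_days"]
        assert sorted(days.unique()) == [1, 2, 3, 4]

    def test_deterministic_in_seed(self):
        t1 = make_outcome_table(ClassProbabilities.defaults(), 15, seed=42)
        t2 = make_outcome_table(ClassProbabilities.defaults(), 15, seed=42)
        pd.testing.assert_frame_equal(t1, t2)
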