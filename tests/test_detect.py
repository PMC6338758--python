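"""Frame sampling, binarization, blob extraction and the copulation caller."""

import numpy as np
import pytest

from flycourt.detect import (
    AssayRecording,
    BlobSummary,
    binarize,
    build_volume,
    call_copulation,
    detect_assay,
    extract_blobs,
    sample_frames,
)


def _recording(duration_s: float, fps: float = 1.0) -> AssayRecording:
    n = int(duration_s * fps) + 1
    frames = np.full((n, 8, 8), 200, dtype=np.uint8)
    return AssayRecording(frames=frames, timestamps_s=np.arange(n) / fps)


class TestSampleFrames:
    def test_hour_at_1fps_sampled_every_10s_gives_361(self):
        assert len(sample_frames(_recording(3600), 10.0)) == 361

    def test_interval_equal_native_is_identity(self):
        rec = _recording(50)
        out = sample_frames(rec, 1.0)
        assert np.array_equal(out.timestamps_s, rec.timestamps_s)

    def test_short_recording_arithmetic_sequence(self):
        out = sample_frames(_recording(65), 10.0)
        assert np.array_equal(out.timestamps_s, np.arange(0, 61, 10))

    def test_empty_recording_rejected(self):
        rec = AssayRecording(frames=np.zeros((0, 4, 4), np.uint8), timestamps_s=np.array([]))
        with pytest.raises(ValueError):
            sample_frames(rec, 10.0)

    def test_interval_finer_than_native_rejected(self):
        with pytest.raises(ValueError):
            sample_frames(_recording(60), 0.5)


class TestBinarize:
    def test_two_level_image_recovers_exact_ellipses(self):
        img = np.full((40, 40), 200, dtype=np.uint8)
        img[5:10, 5:15] = 40
        img[25:30, 20:30] = 40
        assert np.array_equal(binarize(img), img == 40)

    def test_noisy_frame_recovers_99_percent(self, scripted_assay):
        _, rec, _, gt_masks = scripted_assay
        worst = min(
            (binarize(f) & g).sum() / g.sum() for f, g in zip(rec.frames, gt_masks)
        )
        assert worst >= 0.99

    def test_constant_frame_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="constant"):
            mask = binarize(np.full((10, 10), 128, dtype=np.uint8))
        assert not mask.any()

    def test_fixed_threshold(self):
        img = np.full((10, 10), 200, dtype=np.uint8)
        img[0, 0] = 50
        assert binarize(img, threshold=100).sum() == 1


class TestExtractBlobs:
    def test_two_disjoint_ellipses(self):
        mask = np.zeros((40, 40), bool)
        mask[5:10, 5:15] = True
        mask[25:30, 20:30] = True
        assert extract_blobs(mask).component_count == 2

    def test_overlapping_region_is_one_component(self):
        mask = np.zeros((40, 40), bool)
        mask[5:15, 5:15] = True
        mask[10:20, 10:20] = True
        assert extract_blobs(mask).component_count == 1

    def test_diagonal_touch_merges_with_8_connectivity(self):
        mask = np.zeros((4, 4), bool)
        mask[0:2, 0:2] = True
        mask[2:4, 2:4] = True
        assert extract_blobs(mask).component_count == 1

    def test_speck_rejection(self):
        mask = np.zeros((40, 40), bool)
        mask[5:10, 5:15] = True     # 50 px
        mask[25:30, 20:30] = True   # 50 px
        mask[35, 35:38] = True      # 3-px speck
        blobs = extract_blobs(mask, min_area_px=20)
        assert blobs.component_count == 2
        assert blobs.areas == (50, 50)

    def test_areas_sorted_descending_with_centroids(self):
        mask = np.zeros((40, 40), bool)
        mask[0:2, 0:5] = True   # 10 px
        mask[20:25, 20:30] = True  # 50 px
        blobs = extract_blobs(mask)
        assert blobs.areas == (50, 10)
        assert len(blobs.centroids) == 2


def _series(merged_flags, interval=10.0, fly_area=200):
    """Blob series: merged samples show one double blob, others two singles."""
    out = []
    for i, m in enumerate(merged_flags):
        if m:
            out.append(BlobSummary(i * interval, (2 * fly_area,), ((5.0, 5.0),)))
        else:
            out.append(
                BlobSummary(i * interval, (fly_area, fly_area), ((2.0, 2.0), (8.0, 8.0)))
            )
    return out


class TestCallCopulation:
    def test_seven_consecutive_merged_samples_span_70s_called(self):
        flags = [False] * 3 + [True] * 7 + [False] * 3
        call = call_copulation(_series(flags), single_fly_area_px=200)
        assert call.success
        (s, e, tr) = call.intervals[0]
        assert (s, e, tr) == (30.0, 100.0, False)

    def test_five_merged_samples_span_50s_not_called(self):
        flags = [False] * 3 + [True] * 5 + [False] * 3
        call = call_copulation(_series(flags), single_fly_area_px=200)
        assert not call.success and call.intervals == ()

    def test_six_merged_samples_span_60s_fails_strict_rule(self):
        flags = [False] * 3 + [True] * 6 + [False] * 3
        call = call_copulation(_series(flags), single_fly_area_px=200)
        assert not call.success

    def test_single_gap_breaks_run_by_default(self):
        flags = [False] + [True] * 5 + [False] + [True] * 5 + [False]
        call = call_copulation(_series(flags), single_fly_area_px=200)
        assert not call.success

    def test_allow_gap_samples_bridges_run(self):
        flags = [False] + [True] * 5 + [False] + [True] * 5 + [False]
        call = call_copulation(_series(flags), single_fly_area_px=200, allow_gap_samples=1)
        assert call.success
        assert call.intervals[0][:2] == (10.0, 120.0)

    def test_run_reaching_final_sample_is_truncated(self):
        flags = [False] * 2 + [True] * 8
        call = call_copulation(_series(flags), single_fly_area_px=200)
        assert call.intervals[0][2] is True
        assert call.success  # span 80 s > 60 s

    def test_short_truncated_run_reported_but_not_success(self):
        flags = [False] * 8 + [True] * 2
        call = call_copulation(_series(flags), single_fly_area_px=200)
        assert len(call.intervals) == 1 and call.intervals[0][2] is True
        assert not call.success

    def test_merge_requires_area_not_just_count(self):
        # one fly-sized component only (other fly lost): not merged
        series = [BlobSummary(i * 10.0, (200,), ((5.0, 5.0),)) for i in range(12)]
        call = call_copulation(series, single_fly_area_px=200)
        assert not call.success

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            call_copulation([], single_fly_area_px=200)

    def test_extending_a_run_never_removes_the_interval(self):
        base = [False] * 2 + [True] * 7 + [False] * 4
        call0 = call_copulation(_series(base), single_fly_area_px=200)
        for extra in range(1, 4):
            flags = [False] * 2 + [True] * (7 + extra) + [False] * 4
            call = call_copulation(_series(flags), single_fly_area_px=200)
            assert len(call.intervals) >= len(call0.intervals)
            assert call.success

    def test_raising_min_duration_never_adds_intervals(self):
        flags = [False] + [True] * 7 + [False] * 2 + [True] * 9 + [False]
        prev = None
        for dur in (30.0, 60.0, 80.0, 200.0):
            n = len(call_copulation(_series(flags),
                                    min_duration_s=dur, single_fly_area_px=200).intervals)
            if prev is not None:
                assert n <= prev
            prev = n


class TestBuildVolume:
    def _masks(self, n=5):
        rng = np.random.default_rng(0)
        return [rng.random((6, 6)) > 0.5 for _ in range(n)]

    def test_depth_equals_mask_count(self):
        vol = build_volume(self._masks(361), np.arange(361) * 10.0)
        assert len(vol) == 361

    def test_lookup_round_trip(self):
        masks = self._masks()
        vol = build_volume(masks, np.arange(5) * 10.0)
        for k in range(5):
            assert np.array_equal(vol.lookup(k * 10.0), masks[k])

    def test_mismatched_dimensions_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            build_volume([np.zeros((4, 4), bool), np.zeros((5, 5), bool)], [0.0, 10.0])

    def test_tiff_round_trip_bit_identical(self, tmp_path):
        from flycourt.detect import SpaceTimeVolume

        vol = build_volume(self._masks(8), np.arange(8) * 10.0)
        path = tmp_path / "vol.tif"
        vol.write_tiff(path)
        back = SpaceTimeVolume.read_tiff(path)
        assert np.array_equal(back.masks, vol.masks)
        assert np.array_equal(back.timestamps_s, vol.timestamps_s)


class TestEndToEnd:
    def test_scripted_assay_detected_within_one_sampling_interval(self, scripted_assay):
        _, rec, _, _ = scripted_assay
        call, volume = detect_assay(rec)
        assert call.success and len(call.intervals) == 1
        s, e, truncated = call.intervals[0]
        assert not truncated
        assert abs(s - 100.0) <= 10.0 and abs(e - 250.0) <= 10.0
        assert len(volume) == 61  # 600 s sampled every 10 s
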