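import numpy as np
import pytest
from skimage import measure

from oracles import naive_grow_region, random_small_frame
from thermoroi import (
    SearchWindow,
    SegmentationParams,
    ThermalFrame,
    ThermalSequence,
    grow_region,
    segment_sequence,
    select_seed,
    select_tolerance,
    threshold_segment,
)
from thermoroi.exceptions import MissingFrameWarning, SegmentationError, ShapeError


def frame_of(vals):
    return ThermalFrame(np.asarray(vals, dtype=float))


class TestSelectSeed:
    def test_unique_maximum(self):
        vals = np.full((5, 5), 33.0)
        vals[2, 3] = 36.0
        assert select_seed(frame_of(vals), SearchWindow(0, 5, 0, 5)) == (2, 3)

    def test_tie_breaks_row_major(self):
        vals = np.full((4, 4), 35.0)
        assert select_seed(frame_of(vals), SearchWindow(0, 4, 0, 4)) == (0, 0)
        assert select_seed(frame_of(vals), SearchWindow(1, 4, 2, 4)) == (1, 2)

    def test_global_maximum_outside_window_is_ignored(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            vals = 30.0 + 10.0 * rng.random((8, 9))
            win = SearchWindow(2, 6, 3, 8)
            r, c = select_seed(frame_of(vals), win)
            assert win.contains(r, c)
            # exhaustive-scan reference over the window only
            sub = vals[2:6, 3:8]
            assert vals[r, c] == sub.max()

    def test_all_invalid_window_raises(self):
        vals = np.full((4, 4), 33.0)
        vals[0:2, 0:2] = np.nan
        with pytest.raises(SegmentationError):
            select_seed(frame_of(vals), SearchWindow(0, 2, 0, 2))


class TestGrowRegion:
    def test_uniform_frame_is_fully_admitted(self):
        """On a uniform 3x3 frame delta stays 0, so T_t = 0 admits all pixels."""
        params = SegmentationParams(t_t=0.0, seed_region_radius=0, max_region_fraction=1.0)
        region = grow_region(frame_of(np.full((3, 3), 34.0)), (1, 1), params)
        assert region.pixel_count == 9
        assert region.mean_temperature == pytest.approx(34.0)

    def test_plateau_is_recovered_exactly(self, plateau_frame_5x5):
        params = SegmentationParams(t_t=1.0, seed_region_radius=0, max_region_fraction=1.0)
        region = grow_region(frame_of(plateau_frame_5x5), (1, 1), params)
        assert region.pixels == {(r, c) for r in (1, 2, 3) for c in (1, 2, 3)}
        assert region.mean_temperature == pytest.approx(37.0)
        # from-scratch oracle replays the same min-delta admissions
        assert region.pixels == naive_grow_region(
            plateau_frame_5x5, (1, 1), 1.0, seed_region_radius=0, max_region_fraction=1.0
        )

    def test_single_step_rejection(self):
        """Seed at 37.0 with a sole 36.8 neighbour: delta 0.2 > T_t 0.1."""
        params = SegmentationParams(t_t=0.1, seed_region_radius=0, max_region_fraction=1.0)
        region = grow_region(frame_of([[37.0, 36.8]]), (0, 0), params)
        assert region.pixels == {(0, 0)}

    def test_seed_outside_frame_raises(self):
        with pytest.raises(SegmentationError):
            grow_region(frame_of(np.full((3, 3), 33.0)), (5, 5), SegmentationParams(t_t=1.0))

    def test_size_cap_limits_growth(self):
        params = SegmentationParams(t_t=5.0, seed_region_radius=0, max_region_fraction=0.25)
        region = grow_region(frame_of(np.full((4, 4), 34.0)), (0, 0), params)
        assert region.pixel_count == 4  # floor(0.25 * 16)

    def test_matches_from_scratch_oracle_on_random_small_frames(self):
        """Incremental frontier/mean bookkeeping agrees pixel-for-pixel with a
        reference that recomputes everything from scratch each iteration."""
        rng = np.random.default_rng(2024)
        for _ in range(300):
            vals = random_small_frame(rng)
            finite = np.argwhere(np.isfinite(vals))
            if finite.size == 0:
                continue
            seed = tuple(finite[rng.integers(len(finite))])
            t_t = float(rng.choice([0.0, 0.1, 0.3, 0.5, 1.0, 3.0]))
            rad = int(rng.integers(0, 3))
            seed_tol = None if rng.random() < 0.5 else float(rng.uniform(0, 2))
            params = SegmentationParams(
                t_t=t_t,
                seed_region_radius=rad,
                seed_tolerance=seed_tol,
                max_region_fraction=1.0,
            )
            got = grow_region(frame_of(vals), seed, params).pixels
            want = naive_grow_region(
                vals, seed, t_t, rad, max_region_fraction=1.0, seed_tolerance=seed_tol
            )
            assert got == want

    def test_region_grows_monotonically_with_tolerance(self):
        rng = np.random.default_rng(77)
        for _ in range(60):
            vals = random_small_frame(rng)
            finite = np.argwhere(np.isfinite(vals))
            if finite.size == 0:
                continue
            seed = tuple(finite[rng.integers(len(finite))])
            tolerances = sorted(rng.uniform(0.0, 3.0, size=3))
            prev = None
            for t_t in tolerances:
                params = SegmentationParams(
                    t_t=float(t_t), seed_region_radius=1, max_region_fraction=1.0
                )
                region = grow_region(frame_of(vals), seed, params).pixels
                if prev is not None:
                    assert prev <= region
                prev = region

    def test_output_is_one_8_connected_component_containing_seed(self):
        rng = np.random.default_rng(13)
        for _ in range(60):
            vals = random_small_frame(rng)
            finite = np.argwhere(np.isfinite(vals))
            if finite.size == 0:
                continue
            seed = tuple(finite[rng.integers(len(finite))])
            params = SegmentationParams(
                t_t=float(rng.uniform(0, 2)), seed_region_radius=1, max_region_fraction=1.0
            )
            region = grow_region(frame_of(vals), seed, params)
            assert seed in region.pixels
            labels = measure.label(region.mask(), connectivity=2)
            assert labels.max() == 1

    def test_region_mean_matches_member_mean(self):
        rng = np.random.default_rng(99)
        vals = 30 + 5 * rng.random((6, 6))
        region = grow_region(
            frame_of(vals), (3, 3), SegmentationParams(t_t=2.0, max_region_fraction=1.0)
        )
        member_mean = np.mean([vals[p] for p in region.pixels])
        assert region.mean_temperature == pytest.approx(member_mean, abs=1e-9)


class TestThresholdBaseline:
    def test_top_quartile_median_threshold(self):
        vals = np.arange(1, 17, dtype=float).reshape(4, 4)
        mask, threshold = threshold_segment(frame_of(vals), SearchWindow(0, 4, 0, 4))
        assert threshold == 14.5  # median of {13, 14, 15, 16}
        assert set(map(tuple, np.argwhere(mask))) == {(3, 2), (3, 3)}

    def test_uniform_window_selects_everything(self):
        vals = np.full((3, 4), 33.0)
        mask, _ = threshold_segment(frame_of(vals), SearchWindow(0, 3, 0, 4))
        assert mask.sum() == 12

    def test_too_few_pixels_raises(self):
        with pytest.raises(SegmentationError):
            threshold_segment(frame_of([[33.0, 34.0]]), SearchWindow(0, 1, 0, 2))

    def test_baseline_scatters_where_srg_stays_closed(self):
        """Two equally hot plateaus in one window: thresholding selects both
        (disconnected clusters) while region growing returns one closed ROI."""
        vals = np.full((9, 15), 33.0)
        vals[3:6, 2:5] = 37.0
        vals[3:6, 10:13] = 37.0
        frame = frame_of(vals)
        window = SearchWindow(0, 9, 0, 15)
        mask, _ = threshold_segment(frame, window)
        assert measure.label(mask, connectivity=2).max() >= 2
        seed = select_seed(frame, window)
        region = grow_region(
            frame, seed, SegmentationParams(t_t=1.0, seed_region_radius=0), window=window
        )
        assert measure.label(region.mask(), connectivity=2).max() == 1
        assert region.pixel_count == 9


class TestSequenceSegmentation:
    @staticmethod
    def _seq(frames):
        return ThermalSequence([ThermalFrame(v, i) for i, v in enumerate(frames)])

    def test_constant_sequence_average_equals_single_frame(self, plateau_frame_5x5):
        seq = self._seq([plateau_frame_5x5] * 10)
        params = SegmentationParams(t_t=1.0, seed_region_radius=0)
        res = segment_sequence(seq, SearchWindow(0, 5, 0, 5), params)
        assert res.mean_pixel_count == 9
        assert res.mean_roi_temperature_c == pytest.approx(37.0)

    def test_averages_are_arithmetic_means(self):
        """ROIs of 100 and 120 pixels average to a mean count of 110."""
        f1 = np.full((20, 20), 30.0)
        f1[0:10, 0:10] = 37.0  # 100-pixel plateau
        f2 = np.full((20, 20), 30.0)
        f2[0:10, 0:12] = 37.0  # 120-pixel plateau
        seq = self._seq([f1, f2])
        params = SegmentationParams(
            t_t=1.0, seed_region_radius=0, max_region_fraction=0.5
        )
        res = segment_sequence(seq, SearchWindow(0, 20, 0, 20), params)
        assert [f.pixel_count for f in res.frames] == [100, 120]
        assert res.mean_pixel_count == 110.0

    def test_unsegmentable_frame_warns_and_is_excluded(self, plateau_frame_5x5):
        bad = np.full((5, 5), np.nan)
        seq = self._seq([plateau_frame_5x5, bad, plateau_frame_5x5])
        params = SegmentationParams(t_t=1.0, seed_region_radius=0)
        with pytest.warns(MissingFrameWarning):
            res = segment_sequence(seq, SearchWindow(0, 5, 0, 5), params)
        assert res.frames[1] is None
        assert res.n_frames_processed == 2
        assert res.mean_pixel_count == 9


class TestToleranceScan:
    def test_plateau_scene_yields_stable_tolerance(self, plateau_frame_5x5):
        frame = frame_of(plateau_frame_5x5)
        window = SearchWindow(0, 5, 0, 5)
        t = select_tolerance(
            frame, window, grid=np.arange(0.1, 3.1, 0.1), seed_region_radius=0,
            max_region_fraction=1.0,
        )
        region = grow_region(
            frame,
            select_seed(frame, window),
            SegmentationParams(t_t=t, seed_region_radius=0, max_region_fraction=1.0),
        )
        assert region.pixel_count == 9


class TestWindowValidation:
    def test_empty_window_rejected(self):
        with pytest.raises(ShapeError):
            SearchWindow(3, 3, 0, 5)

    def test_window_must_fit_frame(self):
        with pytest.raises(ShapeError):
            select_seed(frame_of(np.full((4, 4), 33.0)), SearchWindow(0, 6, 0, 4))
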