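"""Walking-path geometry and the mask-based overlap engine."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import pixel_box_mask, pixel_disc_mask, pixel_path_mask
from gaitcontext import (
    BoundingBox,
    Circle,
    Detection,
    FrameRecord,
    GazeSample,
    PathConfig,
    attention_on_hazards,
    build_walking_path,
    detect_overlaps,
    rasterize,
    summarize_frame,
)
from gaitcontext.path_overlap import FrameContext


class TestWalkingPath:
    def test_default_base_is_middle_half(self):
        path = build_walking_path(1000, 800)
        assert path.bottom_left == (250.0, 800.0)
        assert path.bottom_right == (750.0, 800.0)

    @pytest.mark.parametrize("w,h", [(1920, 1080), (1088, 1080), (640, 480), (333, 777)])
    def test_base_width_ratio_half_for_any_frame(self, w, h):
        path = build_walking_path(w, h)
        assert path.base_width == round(0.5 * w)
        # centred and symmetric about the vertical midline
        assert path.bottom_left[0] + path.bottom_right[0] == pytest.approx(w)
        assert path.top_left[0] + path.top_right[0] == pytest.approx(w)

    def test_degenerate_rectangle(self):
        cfg = PathConfig(base_width_fraction=1.0, top_width_fraction=1.0, top_y_fraction=0.0)
        path = build_walking_path(640, 480, cfg)
        assert path.vertices == ((0.0, 480.0), (640.0, 480.0), (640.0, 0.0), (0.0, 0.0))

    def test_top_wider_than_base_rejected(self):
        with pytest.raises(ValueError):
            PathConfig(base_width_fraction=0.3, top_width_fraction=0.5)

    def test_bottom_edge_on_last_row(self):
        path = build_walking_path(1088, 1080)
        assert path.bottom_y == 1080.0
        assert path.top_y == round(0.55 * 1080)


class TestRasterize:
    def test_full_frame_box_saturates(self):
        mask = rasterize(BoundingBox(0, 0, 640, 480), 640, 480)
        assert mask.grid.all()
        assert mask.grid.shape == (200, 200)

    def test_box_outside_frame_is_empty(self):
        mask = rasterize(BoundingBox(700, 10, 800, 50), 640, 480)
        assert not mask.grid.any()

    def test_box_cells_match_brute_force_footprint(self, rng):
        """Each cell is set iff its pixel footprint intersects the box."""
        W, H, res = 640, 480, (200, 200)
        sx, sy = W / res[0], H / res[1]
        for _ in range(25):
            x0, y0 = rng.uniform(0, W - 30), rng.uniform(0, H - 30)
            box = BoundingBox(x0, y0, x0 + rng.uniform(5, 200), y0 + rng.uniform(5, 200))
            mask = rasterize(box, W, H, res)
            for row, col in [(int(rng.integers(res[1])), int(rng.integers(res[0]))) for _ in range(60)]:
                fx0, fx1 = col * sx, (col + 1) * sx
                fy0, fy1 = row * sy, (row + 1) * sy
                hits = (
                    min(fx1, min(box.x_max, W)) - max(fx0, box.x_min) > 0
                    and min(fy1, min(box.y_max, H)) - max(fy0, box.y_min) > 0
                )
                assert bool(mask.grid[row, col]) == hits

    def test_circle_cells_match_brute_force(self, rng):
        W = H = 400
        mask = rasterize(Circle((200.0, 150.0), 40.0), W, H, (100, 100))
        sx = sy = 4.0
        cols = np.arange(100) * sx
        rows = np.arange(100) * sy
        dx = np.maximum.reduce([cols - 200.0, 200.0 - (cols + sx), np.zeros(100)])
        dy = np.maximum.reduce([rows - 150.0, 150.0 - (rows + sy), np.zeros(100)])
        expected = (dx[None, :] ** 2 + dy[:, None] ** 2) < 1600.0
        assert np.array_equal(mask.grid.astype(bool), expected)

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            Circle((10.0, 10.0), 0.0)

    @given(
        x0=st.integers(0, 600), y0=st.integers(0, 440),
        w=st.integers(5, 40), h=st.integers(5, 40),
        grow=st.integers(1, 50),
    )
    @settings(max_examples=40, deadline=None)
    def test_growing_a_box_never_unsets_cells(self, x0, y0, w, h, grow):
        """Outward rounding makes masks monotone in the box: a larger box
        can only add cells, so in_path can never flip true -> false."""
        small = rasterize(BoundingBox(x0, y0, x0 + w, y0 + h), 640, 480)
        big = rasterize(
            BoundingBox(max(x0 - grow, 0), max(y0 - grow, 0), x0 + w + grow, y0 + h + grow),
            640, 480,
        )
        assert not np.any(small.grid & ~big.grid)


def _frame(width, height, detections, gaze=None, index=0, ts=0.0):
    return FrameRecord(index=index, timestamp=ts, width=width, height=height,
                       detections=detections, gaze=gaze)


class TestDetectOverlaps:
    def test_disjoint_box_is_false_false(self, taxonomy):
        # box in the far top-left corner, gaze in the top-right corner
        frame = _frame(
            1000, 1000,
            [Detection("Chair", BoundingBox(0, 0, 100, 100))],
            GazeSample(0.0, 900.0, 50.0),
        )
        path = build_walking_path(1000, 1000)
        (v,) = detect_overlaps(frame, path)
        assert (v.in_path, v.gazed) == (False, False)

    def test_contained_gaze_and_path_straddle_is_true_true(self):
        frame = _frame(
            1000, 1000,
            [Detection("Chair", BoundingBox(400, 850, 600, 1000))],
            GazeSample(0.0, 500.0, 900.0),
        )
        path = build_walking_path(1000, 1000)
        (v,) = detect_overlaps(frame, path)
        assert (v.in_path, v.gazed) == (True, True)

    def test_missing_or_invalid_gaze_means_not_gazed(self):
        box = Detection("Chair", BoundingBox(400, 850, 600, 1000))
        path = build_walking_path(1000, 1000)
        for gaze in (None, GazeSample(0.0, 500.0, 900.0, valid=False)):
            (v,) = detect_overlaps(_frame(1000, 1000, [box], gaze), path)
            assert v.in_path and not v.gazed

    def test_empty_detections_empty_verdicts(self):
        path = build_walking_path(640, 480)
        assert detect_overlaps(_frame(640, 480, []), path) == []

    def test_order_invariance(self, rng):
        dets = []
        for _ in range(6):
            x, y = rng.uniform(0, 600), rng.uniform(0, 440)
            dets.append(Detection("Chair", BoundingBox(x, y, x + 30, y + 30)))
        path = build_walking_path(640, 480)
        gaze = GazeSample(0.0, 320.0, 400.0)
        fwd = detect_overlaps(_frame(640, 480, dets, gaze), path)
        rev = detect_overlaps(_frame(640, 480, dets[::-1], gaze), path)
        fwd_map = {id(v.detection): (v.in_path, v.gazed) for v in fwd}
        rev_map = {id(v.detection): (v.in_path, v.gazed) for v in rev}
        assert fwd_map == rev_map

    def test_native_resolution_equals_pixel_oracle(self, rng):
        """At mask resolution == frame resolution the engine reproduces
        the per-pixel oracle verdict exactly."""
        W, H = 160, 120
        path = build_walking_path(W, H)
        path_px = pixel_path_mask(W, H)
        gaze = GazeSample(0.0, 80.0, 90.0)
        gaze_px = pixel_disc_mask(80.0, 90.0, 30.0, W, H)
        for _ in range(50):
            x0 = float(rng.integers(0, W - 10))
            y0 = float(rng.integers(0, H - 10))
            box = BoundingBox(x0, y0, x0 + float(rng.integers(4, 60)), y0 + float(rng.integers(4, 60)))
            frame = _frame(W, H, [Detection("Chair", box)], gaze)
            (v,) = detect_overlaps(frame, path, mask_resolution=(W, H))
            box_px = pixel_box_mask(box.x_min, box.y_min, box.x_max, box.y_max, W, H)
            assert v.in_path == bool((box_px & path_px).any())
            assert v.gazed == bool((box_px & gaze_px).any())


class TestFrameSummary:
    def test_no_detections_no_hazard(self, taxonomy):
        ctx = summarize_frame([], taxonomy)
        assert not ctx.hazard_in_path

    def test_in_path_kerb_raises_hazard(self, taxonomy):
        frame = _frame(1000, 1000, [Detection("Raised kerb", BoundingBox(400, 900, 600, 1000))])
        path = build_walking_path(1000, 1000)
        ctx = summarize_frame(detect_overlaps(frame, path), taxonomy)
        assert ctx.hazard_in_path

    def test_context_only_class_in_path_is_not_hazard(self, taxonomy):
        frame = _frame(1000, 1000, [Detection("Bed", BoundingBox(400, 900, 600, 1000))])
        path = build_walking_path(1000, 1000)
        verdicts = detect_overlaps(frame, path)
        assert verdicts[0].in_path
        assert not summarize_frame(verdicts, taxonomy).hazard_in_path

    def test_unknown_class_rejected(self, taxonomy):
        from gaitcontext.path_overlap import OverlapVerdict

        verdict = OverlapVerdict(Detection("Spoon", BoundingBox(0, 0, 10, 10)), True, False)
        with pytest.raises(KeyError):
            summarize_frame([verdict], taxonomy)


def _ctx(t, hazard, gazed):
    return FrameContext(frame_index=int(t * 10), timestamp=t, verdicts=[],
                        hazard_in_path=hazard, gaze_on_path=False, hazard_gazed=gazed)


class TestAttentionOnHazards:
    def test_hazard_never_gazed_is_zero(self):
        contexts = [_ctx(t / 10, True, False) for t in range(10)]
        windows = attention_on_hazards(contexts, window=1.0)
        assert [f for _, f in windows] == [0.0]

    def test_hazard_always_gazed_is_one(self):
        contexts = [_ctx(t / 10, True, True) for t in range(10)]
        assert [f for _, f in attention_on_hazards(contexts, 1.0)] == [1.0]

    def test_alternating_gaze_is_half(self):
        contexts = [_ctx(t / 10, True, t % 2 == 0) for t in range(10)]
        assert [f for _, f in attention_on_hazards(contexts, 1.0)] == [0.5]

    def test_no_hazard_window_is_undefined(self):
        contexts = [_ctx(0.0, False, False), _ctx(1.5, True, True)]
        fractions = [f for _, f in attention_on_hazards(contexts, 1.0)]
        assert fractions == [None, 1.0]

    def test_nonpositive_window_rejected(self):
        with pytest.raises(ValueError):
            attention_on_hazards([_ctx(0.0, True, False)], 0.0)
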