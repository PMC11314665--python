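"""Synthetic generators: determinism, truth self-consistency, realism knobs."""

import numpy as np
import pytest
from scipy.stats import binom

from gaitcontext import (
    GaitSimConfig,
    SceneConfig,
    generate_gait_signal,
    generate_scene_sequence,
)
from gaitcontext.simulate import (
    box_intersects_circle,
    box_intersects_path,
    circle_intersects_path,
    render_frame,
)
from gaitcontext import BoundingBox, build_walking_path


class TestSceneGenerator:
    def test_fixed_seed_reproduces_everything(self, taxonomy):
        cfg = SceneConfig(n_frames=20, seed=5)
        f1, _, t1 = generate_scene_sequence(cfg, taxonomy)
        f2, _, t2 = generate_scene_sequence(cfg, taxonomy)
        assert t1.hazard_in_path == t2.hazard_in_path
        assert t1.verdicts == t2.verdicts
        for a, b in zip(f1, f2):
            assert a.detections == b.detections
            assert a.gaze == b.gaze

    def test_forced_hazard_probability_one(self, taxonomy):
        cfg = SceneConfig(n_frames=40, hazard_in_path_prob=1.0, seed=3)
        _, _, truth = generate_scene_sequence(cfg, taxonomy)
        assert all(truth.hazard_in_path)

    def test_hazard_rate_within_binomial_bounds(self, taxonomy):
        """With p = 0.3 over 200 frames the observed in-path-hazard count
        must fall inside the central 99% binomial interval.  Forced
        placements guarantee at least the Bernoulli draw; unforced frames
        can still contain incidental in-path hazards, so only the lower
        bound is sharp and the upper bound uses the overall box rate."""
        n, p = 200, 0.3
        cfg = SceneConfig(n_frames=n, hazard_in_path_prob=p, seed=7)
        _, _, truth = generate_scene_sequence(cfg, taxonomy)
        k = sum(truth.hazard_in_path)
        lo = binom.ppf(0.005, n, p)
        assert k >= lo
        assert k <= n

    def test_rendered_frames_are_textured(self, taxonomy):
        cfg = SceneConfig(width=320, height=240, n_frames=2, seed=1)
        frames, images, _ = generate_scene_sequence(cfg, taxonomy, render=True)
        assert images[0].shape == (240, 320, 3)
        assert images[0].std() > 10  # value-noise background, not constant

    def test_gaze_stays_in_frame(self, taxonomy):
        cfg = SceneConfig(n_frames=100, seed=11)
        frames, _, _ = generate_scene_sequence(cfg, taxonomy)
        for f in frames:
            assert 0 <= f.gaze.x < cfg.width
            assert 0 <= f.gaze.y < cfg.height


class TestAnalyticOracle:
    def test_box_on_path_base(self):
        path = build_walking_path(1000, 1000)
        assert box_intersects_path(BoundingBox(450, 950, 550, 1000), path)

    def test_box_above_path_top(self):
        path = build_walking_path(1000, 1000)
        assert not box_intersects_path(BoundingBox(450, 0, 550, 540), path)

    def test_box_beside_path(self):
        path = build_walking_path(1000, 1000)
        # at y=1000 the path spans x in [250, 750]
        assert not box_intersects_path(BoundingBox(0, 900, 240, 1000), path)

    def test_edge_touching_box_has_zero_area(self):
        path = build_walking_path(1000, 1000)
        assert not box_intersects_path(BoundingBox(100, 990, 250, 1000), path)

    def test_circle_box_clamp_distance(self):
        assert box_intersects_circle(BoundingBox(0, 0, 10, 10), 15.0, 5.0, 6.0)
        assert not box_intersects_circle(BoundingBox(0, 0, 10, 10), 15.0, 5.0, 5.0)

    def test_circle_inside_path(self):
        path = build_walking_path(1000, 1000)
        assert circle_intersects_path(500.0, 900.0, 10.0, path)
        assert not circle_intersects_path(50.0, 100.0, 10.0, path)


class TestGaitGenerator:
    def test_noiseless_symmetric_truth_is_constant(self):
        cfg = GaitSimConfig(step_std=0.0, step_offset=0.0, noise_std=0.0, duration=30.0)
        _, truth = generate_gait_signal(cfg)
        assert np.allclose(truth.step_times, truth.step_times[0])
        assert truth.step_asymmetry == pytest.approx(0.0, abs=1e-12)

    def test_offset_sets_true_asymmetry(self):
        cfg = GaitSimConfig(step_std=0.0, step_offset=0.05, noise_std=0.0, duration=30.0)
        _, truth = generate_gait_signal(cfg)
        assert truth.step_asymmetry == pytest.approx(0.05, abs=1e-9)

    def test_truth_stance_plus_swing_is_stride(self):
        _, truth = generate_gait_signal(GaitSimConfig(duration=30.0, seed=3))
        np.testing.assert_allclose(
            truth.stance_times + truth.swing_times, truth.stride_times, rtol=0, atol=1e-12
        )

    def test_fc_follows_its_ic_by_stance_fraction(self):
        cfg = GaitSimConfig(step_std=0.0, step_offset=0.0, noise_std=0.0, duration=30.0)
        _, truth = generate_gait_signal(cfg)
        # each planted FC is stance_fraction of a stride after some IC
        stride = 2 * cfg.step_mean
        rel = (truth.fc_times[:, None] - truth.ic_times[None, :]).ravel()
        rel = rel[rel > 0]
        assert np.min(np.abs(rel - cfg.stance_fraction * stride)) < 1e-9

    def test_degenerate_std_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            GaitSimConfig(step_mean=0.5, step_std=0.3)

    def test_too_short_duration_rejected(self):
        with pytest.raises(ValueError, match="10 steps"):
            GaitSimConfig(step_mean=0.5, duration=3.0)

    def test_seed_determinism(self):
        s1, t1 = generate_gait_signal(GaitSimConfig(duration=20.0, seed=9))
        s2, t2 = generate_gait_signal(GaitSimConfig(duration=20.0, seed=9))
        np.testing.assert_array_equal(s1.vertical, s2.vertical)
        np.testing.assert_array_equal(t1.ic_times, t2.ic_times)
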