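"""Gait analysis: bout segmentation, event detection, temporal stats."""

import numpy as np
import pytest

from gaitcontext import (
    AccelSignal,
    BoutConfig,
    GaitEvents,
    GaitSimConfig,
    WalkingBout,
    compute_temporal_stats,
    detect_bouts,
    detect_gait_events,
    generate_gait_signal,
)
from gaitcontext.gait import G, estimate_step_frequency


def _still_signal(duration=30.0, fs=100.0, noise=0.005 * G, seed=0):
    rng = np.random.default_rng(seed)
    n = int(duration * fs)
    t = np.arange(n) / fs
    return AccelSignal(
        t,
        G + rng.normal(0, noise, n),
        rng.normal(0, noise, n),
        rng.normal(0, noise, n),
    )


class TestAccelSignal:
    def test_non_uniform_sampling_rejected(self):
        t = np.array([0.0, 0.01, 0.03, 0.04])
        z = np.zeros(4)
        with pytest.raises(ValueError, match="non-uniform"):
            AccelSignal(t, z, z, z)

    def test_channel_length_mismatch_rejected(self):
        t = np.arange(5) / 100
        with pytest.raises(ValueError, match="length"):
            AccelSignal(t, np.zeros(5), np.zeros(4), np.zeros(5))


class TestDetectBouts:
    def test_still_signal_has_no_bouts(self):
        assert detect_bouts(_still_signal()) == []

    def test_walk_flanked_by_rest_is_one_bout(self):
        cfg = GaitSimConfig(duration=60.0, rest_padding=10.0, seed=4)
        signal, truth = generate_gait_signal(cfg)
        bouts = detect_bouts(signal)
        assert len(bouts) == 1
        assert bouts[0].start == pytest.approx(truth.bout_start, abs=0.5)
        assert bouts[0].end == pytest.approx(truth.bout_end, abs=0.5)

    def test_short_gap_merged(self):
        """Two active periods separated by less than merge_gap fuse."""
        fs = 100.0
        rng = np.random.default_rng(1)
        t = np.arange(int(20 * fs)) / fs
        v = G + rng.normal(0, 0.01, t.size)
        burst = 2.0 * np.sin(2 * np.pi * 2.0 * t)
        active = ((t > 2) & (t < 9)) | ((t > 10) & (t < 17))
        v[active] += burst[active]
        signal = AccelSignal(t, v, np.zeros(t.size), np.zeros(t.size))
        assert len(detect_bouts(signal, BoutConfig(merge_gap=1.5))) == 1
        assert len(detect_bouts(signal, BoutConfig(merge_gap=0.3))) == 2

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError, match="1 s"):
            detect_bouts(_still_signal(duration=0.5))


class TestDetectGaitEvents:
    def test_constant_signal_yields_no_events(self):
        n = 1000
        t = np.arange(n) / 100.0
        signal = AccelSignal(t, np.full(n, G), np.zeros(n), np.zeros(n))
        events = detect_gait_events(signal)
        assert events.ic_times.size == 0 and events.fc_times.size == 0

    def test_planted_ics_recovered_within_30ms(self):
        signal, truth = generate_gait_signal(GaitSimConfig(duration=60.0, seed=2))
        events = detect_gait_events(signal)
        errors = np.abs(truth.ic_times[:, None] - events.ic_times[None, :]).min(axis=1)
        assert (errors <= 0.03).mean() >= 0.95

    def test_step_count_matches_truth_within_one(self):
        signal, truth = generate_gait_signal(GaitSimConfig(duration=60.0, seed=9))
        events = detect_gait_events(signal)
        assert abs(events.ic_times.size - truth.ic_times.size) <= 1

    def test_fc_between_consecutive_ics(self):
        """Validated events alternate: exactly one toe-off per step."""
        signal, _ = generate_gait_signal(GaitSimConfig(duration=60.0, seed=5))
        ev = detect_gait_events(signal)
        for a, b in zip(ev.ic_times, ev.ic_times[1:]):
            assert ((ev.fc_times > a) & (ev.fc_times < b)).sum() == 1

    def test_short_bout_rejected(self):
        signal, _ = generate_gait_signal(GaitSimConfig(duration=60.0, seed=2))
        with pytest.raises(ValueError, match="too short"):
            detect_gait_events(signal, WalkingBout(0.0, 0.8))

    def test_spectral_step_frequency(self):
        signal, truth = generate_gait_signal(GaitSimConfig(step_mean=0.5, duration=60.0, seed=3))
        f = estimate_step_frequency(signal.vertical, signal.fs)
        assert f == pytest.approx(2.0, abs=0.1)


class TestTemporalStats:
    def test_hand_worked_example(self):
        """ICs every 0.5 s, FCs 0.7 s after the corresponding IC."""
        events = GaitEvents(
            ic_times=np.array([0.0, 0.5, 1.0, 1.5, 2.0]),
            fc_times=np.array([0.7, 1.2, 1.7]),
        )
        s = compute_temporal_stats(events)
        assert s.step_mean == pytest.approx(0.5)
        assert s.stance_mean == pytest.approx(0.7)
        assert s.swing_mean == pytest.approx(0.3)
        for v in (s.step_std, s.stance_std, s.swing_std,
                  s.step_asymmetry, s.stance_asymmetry, s.swing_asymmetry):
            assert v == pytest.approx(0.0, abs=1e-12)

    def test_alternating_steps_give_asymmetry(self):
        """Steps alternating 0.5/0.6 s: mean 0.55, asymmetry 0.1."""
        ic = np.concatenate([[0.0], np.cumsum([0.5, 0.6] * 10)])
        fc = ic[1:] + 0.2
        s = compute_temporal_stats(GaitEvents(ic, fc))
        assert s.step_mean == pytest.approx(0.55)
        assert s.step_asymmetry == pytest.approx(0.1)

    def test_stance_plus_swing_equals_stride_exactly(self):
        signal, _ = generate_gait_signal(GaitSimConfig(duration=60.0, step_offset=0.05, seed=8))
        s = compute_temporal_stats(detect_gait_events(signal))
        np.testing.assert_array_equal(
            s.series["stance"] + s.series["swing"], s.series["stride"]
        )

    def test_symmetric_periodic_input_zero_std_and_asymmetry(self):
        ic = np.arange(20) * 0.55
        fc = ic[1:] + 0.13
        s = compute_temporal_stats(GaitEvents(ic, fc))
        assert s.step_std == pytest.approx(0.0, abs=1e-12)
        assert s.step_asymmetry == pytest.approx(0.0, abs=1e-12)
        assert s.stance_asymmetry == pytest.approx(0.0, abs=1e-12)

    def test_mean_step_is_half_mean_stride_for_symmetric_gait(self):
        ic = np.arange(30) * 0.55
        fc = ic[1:] + 0.13
        s = compute_temporal_stats(GaitEvents(ic, fc))
        assert s.step_mean == pytest.approx(s.series["stride"].mean() / 2, abs=1e-9)

    def test_time_shift_invariance(self):
        ic = np.concatenate([[0.0], np.cumsum([0.5, 0.6] * 10)])
        fc = ic[1:] + 0.2
        a = compute_temporal_stats(GaitEvents(ic, fc)).as_row()
        b = compute_temporal_stats(GaitEvents(ic + 1000.0, fc + 1000.0)).as_row()
        for k in a:
            assert a[k] == pytest.approx(b[k], abs=1e-9)

    def test_too_few_events_rejected(self):
        with pytest.raises(ValueError, match=">= 4"):
            compute_temporal_stats(GaitEvents(np.array([0.0, 0.5, 1.0]), np.array([0.7])))


class TestParameterRecovery:
    @pytest.mark.parametrize("mean", [0.45, 0.6, 0.8])
    def test_step_mean_recovered_within_10ms(self, mean):
        cfg = GaitSimConfig(step_mean=mean, step_std=0.02, duration=45.0, fs=100.0, seed=13)
        signal, truth = generate_gait_signal(cfg)
        s = compute_temporal_stats(detect_gait_events(signal))
        assert s.step_mean == pytest.approx(truth.step_mean, abs=0.01)
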