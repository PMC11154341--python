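import numpy as np
import pytest

from pairflow.errors import GeometryError, ParameterError
from pairflow.infotheory import half_decay_time, peak_summary, tlmi_curve
from pairflow.synthetic_data import (
    DoorEvent,
    FishPairParams,
    GroundTruth,
    door_passage_counts,
    generate_pair,
)
from pairflow.trajectory_io import channel_state, discretize_x


class TestGeneratorBasics:
    def test_fixed_seed_is_bit_identical(self):
        p = FishPairParams(mode="following", duration=60.0, seed=11)
        pair_a, _ = generate_pair(p)
        pair_b, _ = generate_pair(p)
        for f in ("x0", "y0", "x1", "y1"):
            np.testing.assert_array_equal(getattr(pair_a, f), getattr(pair_b, f))

    @pytest.mark.parametrize("mode", ["following", "anticipatory", "independent"])
    def test_positions_inside_tank(self, mode):
        pair, _ = generate_pair(FishPairParams(mode=mode, duration=60.0, seed=2))
        for x in (pair.x0, pair.x1):
            assert x.min() >= 0.0 and x.max() <= pair.x_span_mm
        for y in (pair.y0, pair.y1):
            assert y.min() >= 0.0 and y.max() <= 140.0

    def test_invalid_mode_rejected(self):
        with pytest.raises(ParameterError):
            FishPairParams(mode="chaotic")

    def test_empty_door_list_rejected(self):
        with pytest.raises(GeometryError):
            FishPairParams(door_x_mm=())


class TestDoorEvents:
    def test_transitions_only_near_doors(self, following_pair):
        pair, _ = generate_pair(
            FishPairParams(mode="following", duration=300.0, seed=5)
        )
        params = FishPairParams(mode="following")
        for x, y in ((pair.x0, pair.y0), (pair.x1, pair.y1)):
            states = channel_state(y, pair.wall_y_mm).symbols
            flips = np.flatnonzero(np.diff(states) != 0) + 1
            for i in flips:
                dist = min(abs(x[i] - d) for d in pair.door_x_mm)
                assert dist <= params.door_radius_mm + 1e-9

    def test_leader_always_crosses_first(self, following_pair):
        _, truth = following_pair
        # every follower passage is preceded by a leader passage into
        # the channel the follower is moving to
        leader_channel = None
        for ev in truth.door_events:
            if ev.agent == 0:
                leader_channel = ev.new_channel
            else:
                assert leader_channel == ev.new_channel

    def test_event_counts_match_channel_transitions(self, following_pair):
        pair, truth = following_pair
        n_flips = sum(
            int(np.sum(np.diff(channel_state(y, pair.wall_y_mm).symbols) != 0))
            for y in (pair.y0, pair.y1)
        )
        assert len(truth.door_events) == n_flips
        counts = door_passage_counts(truth, len(pair.door_x_mm))
        assert counts.sum() == n_flips

    def test_counts_by_door(self):
        gt = GroundTruth(
            leader_label="fish0",
            mode="following",
            door_events=[DoorEvent(1.0, 0, 0, 1), DoorEvent(2.0, 1, 0, 1),
                         DoorEvent(3.0, 0, 0, 0)],
        )
        np.testing.assert_array_equal(door_passage_counts(gt, 3), [3, 0, 0])

    def test_no_events_gives_zero_counts(self):
        gt = GroundTruth(leader_label=None, mode="independent", door_events=[])
        np.testing.assert_array_equal(door_passage_counts(gt, 3), [0, 0, 0])


class TestStatisticalEnvelope:
    """The generator's defaults must land in the empirical ranges of real
    recordings: sub-second x memory, seconds-scale channel decisions."""

    @staticmethod
    def x_summary(pair, max_lag_s=3.0):
        dt = pair.time_step_s
        a = discretize_x(pair.x0, 2, pair.x_span_mm, dt)
        b = discretize_x(pair.x1, 2, pair.x_span_mm, dt)
        return peak_summary(
            tlmi_curve(a, b, max_lag_s),
            tlmi_curve(a, a, max_lag_s),
            tlmi_curve(b, b, max_lag_s),
        )

    @staticmethod
    def y_peak_lag(pair, max_lag_s=25.0):
        dt = pair.time_step_s
        a = channel_state(pair.y0, pair.wall_y_mm, dt)
        b = channel_state(pair.y1, pair.wall_y_mm, dt)
        curve = tlmi_curve(a, b, max_lag_s)
        return float(curve.lag_s[np.argmax(curve.values_bits)])

    @pytest.mark.parametrize("seed", range(5))
    def test_following_mode_envelope(self, seed):
        pair, _ = generate_pair(FishPairParams(mode="following", seed=seed))
        ps = self.x_summary(pair)
        assert 0.3 <= ps.half_decay_s <= 1.5
        assert ps.normalized_height >= 0.10
        assert ps.peak_lag_s < 0  # leader is agent 0
        assert -12.0 <= self.y_peak_lag(pair) <= -0.3

    def test_independent_mode_is_uncoupled(self):
        pair, truth = generate_pair(FishPairParams(mode="independent", seed=1))
        assert self.x_summary(pair).normalized_height < 0.05
        assert truth.leader_label is None
        assert not truth.door_events

    def test_anticipatory_mode_has_opposite_lag_signs(self):
        pair, _ = generate_pair(FishPairParams(mode="anticipatory", seed=1))
        assert self.x_summary(pair).peak_lag_s > 0  # follower leads in x
        assert self.y_peak_lag(pair) < 0  # but still trails through doors
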