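"""Temporal scaling function and scaled focal loss."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scrubsight.objective import (
    FrameSupervision,
    LossError,
    LossParams,
    focal_loss,
    frame_supervision,
    scale,
    sequence_loss,
    sequence_loss_graph,
)
from scrubsight.timelines import LEFT, RIGHT, FrameTrack, Interval, SurgeryTimeline, sample_frames
from scrubsight.vocab import IDLE, LabelVocabulary
from scrubsight.windowing import (
    AnticipationEvent,
    Span,
    WindowParams,
    WindowSchedule,
    build_window_schedule,
)


def event(rest=(79.0, 89.0), pred=(89.0, 96.0), target=2, trocar=LEFT):
    return AnticipationEvent(
        trocar=trocar, t0=95.0, target=target, resting=Span(*rest), prediction=Span(*pred)
    )


class TestScale:
    def test_prediction_window_endpoints(self):
        params = LossParams(beta=0.4)
        ev = event()
        assert scale(89.0, ev, params) == pytest.approx(1.0)  # w_p start
        assert scale(96.0, ev, params) == pytest.approx(0.4)  # w_p end

    def test_prediction_window_midpoint(self):
        params = LossParams(beta=0.4)
        ev = event(pred=(89.0, 96.0))
        mid = (89.0 + 96.0) / 2
        assert scale(mid, ev, params) == pytest.approx(0.4 + 0.25 * 0.6)

    def test_resting_window_endpoints(self):
        params = LossParams(beta=0.4)
        ev = event()
        assert scale(79.0, ev, params) == pytest.approx(0.4)  # w_r start
        # w_r end coincides with w_p start where scale is 1: continuity
        assert scale(89.0 - 1e-9, ev, params) == pytest.approx(1.0, abs=1e-6)

    def test_disregard_weight(self):
        params = LossParams(mu=0.1)
        assert scale(10.0, event(), params) == 0.1
        assert scale(10.0, None, params) == 0.1

    def test_zero_width_window_rejected(self):
        ev = event(pred=(89.0, 89.0), rest=(79.0, 89.0))
        with pytest.raises(LossError):
            scale(89.0, ev, LossParams())

    @settings(max_examples=100, derandomize=True)
    @given(
        t=st.floats(0, 130, allow_nan=False),
        beta=st.floats(0, 1, allow_nan=False),
        mu=st.floats(0, 2, allow_nan=False),
    )
    def test_weight_bounded_by_beta_one_and_mu(self, t, beta, mu):
        params = LossParams(beta=beta, mu=mu)
        w = scale(t, event(), params)
        rest, pred = event().resting, event().prediction
        if rest.start <= t <= pred.end:
            assert beta - 1e-9 <= w <= 1 + 1e-9
        else:
            assert w == mu

    def test_invalid_params_rejected(self):
        with pytest.raises(LossError):
            LossParams(beta=1.5)
        with pytest.raises(LossError):
            LossParams(mu=-0.1)


class TestFocalLoss:
    def test_perfect_prediction_is_zero(self):
        assert focal_loss(np.array([0.0, 1.0, 0.0]), 1, gamma=2) == 0.0

    def test_half_probability_gamma_two(self):
        value = focal_loss(np.array([0.5, 0.5]), 0, gamma=2)
        assert value == pytest.approx(0.25 * np.log(2))

    def test_gamma_zero_reduces_to_cross_entropy(self):
        value = focal_loss(np.array([0.5, 0.5]), 0, gamma=0)
        assert value == pytest.approx(np.log(2))

    def test_zero_probability_clamped(self):
        value = focal_loss(np.array([0.0, 1.0]), 0, gamma=2)
        assert np.isfinite(value) and value > 20  # -log(1e-12) scale

    def test_decreasing_in_target_probability(self):
        ps = np.linspace(0.05, 0.95, 10)
        losses = [focal_loss(np.array([p, 1 - p]), 0, gamma=2) for p in ps]
        assert np.all(np.diff(losses) < 0)


def tiny_setup(vocab):
    """A 130-frame surgery with one left-trocar change (w_p=[89,96), w_r=[79,89))."""
    tl = SurgeryTimeline(
        video_id="v",
        duration=130.0,
        phase_intervals=[Interval(0, 130, vocab.phases[0])],
        instrument_intervals=[
            Interval(5, 95, "grasper", LEFT),
            Interval(100, 120, "irrigator", LEFT),
        ],
    )
    track = sample_frames(tl, vocab)
    schedule = build_window_schedule(track, tl, WindowParams(), vocab)
    return tl, track, schedule


def uniform_outputs(T, vocab, stages=1):
    c = vocab.n_anticipation_classes
    return [
        {
            "left": np.full((T, c), 1.0 / c),
            "right": np.full((T, c), 1.0 / c),
            "phase": np.full((T, vocab.n_phases), 1.0 / vocab.n_phases),
        }
        for _ in range(stages)
    ]


class TestSequenceLoss:
    def test_perfect_predictions_zero_loss(self, vocab):
        _, track, schedule = tiny_setup(vocab)
        T = track.n_frames
        labels = schedule.frame_labels(T)
        c = vocab.n_anticipation_classes
        stage = {}
        for trocar, key in ((LEFT, "left"), (RIGHT, "right")):
            _, target = labels[trocar]
            dist = np.zeros((T, c))
            dist[np.arange(T), np.where(target < 0, IDLE, target)] = 1.0
            stage[key] = dist
        phase = np.zeros((T, vocab.n_phases))
        phase[np.arange(T), np.where(track.phase < 0, 0, track.phase)] = 1.0
        stage["phase"] = phase
        assert sequence_loss([stage], schedule, track, LossParams()) == pytest.approx(0.0)

    def test_identical_stages_average_to_single_stage(self, vocab):
        _, track, schedule = tiny_setup(vocab)
        T = track.n_frames
        stage = uniform_outputs(T, vocab)[0]
        params = LossParams()
        single = sequence_loss([stage], schedule, track, params)
        tripled = sequence_loss([stage, stage, stage], schedule, track, params)
        assert tripled == pytest.approx(single)

    def test_against_per_frame_brute_force(self, vocab, rng):
        """Independent accumulation: loop over frames applying scale * FL."""
        _, track, schedule = tiny_setup(vocab)
        T = track.n_frames
        c = vocab.n_anticipation_classes
        params = LossParams(beta=0.3, mu=0.2, phase_loss_weight=0.7)
        stage = {}
        for key in ("left", "right"):
            raw = rng.random((T, c))
            stage[key] = raw / raw.sum(axis=1, keepdims=True)
        raw = rng.random((T, vocab.n_phases))
        stage["phase"] = raw / raw.sum(axis=1, keepdims=True)

        labels = schedule.frame_labels(T)
        expected = 0.0
        for t in range(T):
            for trocar, key in ((LEFT, "left"), (RIGHT, "right")):
                kind, target = labels[trocar]
                ev = next(
                    (
                        e
                        for e in schedule.events[trocar]
                        if e.resting.start <= t < e.prediction.end
                    ),
                    None,
                )
                tgt = target[t] if target[t] >= 0 else IDLE
                if ev is not None and ev.prediction.start <= t:
                    gamma, w = params.gamma_pred, scale(t, ev, params)
                elif ev is not None:
                    gamma, w = params.gamma_rest, scale(t, ev, params)
                else:
                    gamma, w = params.gamma_disregard, params.mu
                expected += w * focal_loss(stage[key][t], tgt, gamma)
            if track.phase[t] >= 0:
                expected += params.phase_loss_weight * focal_loss(
                    stage["phase"][t], track.phase[t], 2.0
                )
        expected /= T
        assert sequence_loss([stage], schedule, track, params) == pytest.approx(expected)

    def test_monotone_in_target_probability(self, vocab):
        _, track, schedule = tiny_setup(vocab)
        T = track.n_frames
        params = LossParams()
        stage = uniform_outputs(T, vocab)[0]
        base = sequence_loss([stage], schedule, track, params)
        improved = {k: v.copy() for k, v in stage.items()}
        # raise idle probability on a disregard frame (its supervised target)
        improved["left"][0] = np.r_[0.9, np.full(12, 0.1 / 12)]
        assert sequence_loss([improved], schedule, track, params) < base

    def test_graph_path_matches_numpy_path(self, vocab, rng):
        _, track, schedule = tiny_setup(vocab)
        T = track.n_frames
        params = LossParams(beta=0.35, mu=0.15)
        stages_np = []
        for _ in range(2):
            stage = {}
            for key in ("left", "right"):
                raw = rng.random((T, vocab.n_anticipation_classes))
                stage[key] = raw / raw.sum(axis=1, keepdims=True)
            raw = rng.random((T, vocab.n_phases))
            stage["phase"] = raw / raw.sum(axis=1, keepdims=True)
            stages_np.append(stage)
        from scrubsight import autodiff as ad

        sup = frame_supervision(schedule, T, params)
        graph_stages = [
            {k: ad.Tensor(v) for k, v in stage.items()} for stage in stages_np
        ]
        graph_value = float(
            sequence_loss_graph(graph_stages, sup, track.phase, params).data
        )
        assert graph_value == pytest.approx(
            sequence_loss(stages_np, schedule, track, params), rel=1e-10
        )

    def test_frame_count_mismatch_rejected(self, vocab):
        _, track, schedule = tiny_setup(vocab)
        stage = uniform_outputs(50, vocab)[0]
        with pytest.raises(LossError, match="frames"):
            sequence_loss([stage], schedule, track, LossParams())
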