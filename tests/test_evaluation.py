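"""Sequence evaluation: first-prediction scan, embedded confusion, metrics.

The brute-force oracle used here re-derives per-class metrics from raw
frame predictions with explicit loops (no shared code with the package's
counting path).
"""

import numpy as np
import pytest

from scrubsight.evaluation import (
    EvaluationError,
    PREDICTION,
    RESTING,
    SequenceOutcome,
    aggregate,
    confusion_from_outcomes,
    evaluate_videos,
    first_prediction_per_sequence,
    idle_baseline_heads,
    metrics_from_confusion,
    occlude_features,
)
from scrubsight.timelines import LEFT, RIGHT
from scrubsight.vocab import IDLE
from scrubsight.windowing import AnticipationEvent, Span, WindowSchedule
import pandas as pd


def make_schedule(events_left=(), events_right=()):
    schedule = WindowSchedule()
    schedule.events[LEFT] = list(events_left)
    schedule.events[RIGHT] = list(events_right)
    return schedule


def ev(rest, pred, target, trocar=LEFT):
    return AnticipationEvent(
        trocar=trocar, t0=pred[1] - 1.0, target=target, resting=Span(*rest), prediction=Span(*pred)
    )


class TestFirstPrediction:
    def test_always_idle_has_no_record(self):
        schedule = make_schedule([ev((10, 20), (20, 27), target=3)])
        preds = {LEFT: np.zeros(40, dtype=int), RIGHT: np.zeros(40, dtype=int)}
        (outcome,) = first_prediction_per_sequence(preds, schedule)
        assert outcome.window is None and outcome.predicted is None
        assert outcome.label == 3

    def test_correct_at_first_prediction_frame(self):
        schedule = make_schedule([ev((10, 20), (20, 27), target=3)])
        left = np.zeros(40, dtype=int)
        left[20] = 3
        (outcome,) = first_prediction_per_sequence(
            {LEFT: left, RIGHT: np.zeros(40, dtype=int)}, schedule
        )
        assert outcome.window == PREDICTION
        assert outcome.predicted == 3
        assert outcome.offset_s == pytest.approx(0.0)

    def test_first_non_idle_in_resting_window_wins(self):
        schedule = make_schedule([ev((10, 20), (20, 27), target=3)])
        left = np.zeros(40, dtype=int)
        left[12] = 5  # wrong class at the 3rd resting frame
        left[21] = 3  # later correct prediction is ignored
        (outcome,) = first_prediction_per_sequence(
            {LEFT: left, RIGHT: np.zeros(40, dtype=int)}, schedule
        )
        assert outcome.window == RESTING
        assert outcome.predicted == 5
        assert outcome.offset_s == pytest.approx(12 - 20)

    def test_disregard_frames_never_scanned(self):
        schedule = make_schedule([ev((10, 20), (20, 27), target=3)])
        left = np.zeros(40, dtype=int)
        left[5] = 7  # before the resting window: disregard
        left[30] = 7  # after the prediction window: disregard
        (outcome,) = first_prediction_per_sequence(
            {LEFT: left, RIGHT: np.zeros(40, dtype=int)}, schedule
        )
        assert outcome.predicted is None


class TestConfusion:
    def test_all_correct_in_prediction_window(self):
        outcomes = [
            SequenceOutcome(LEFT, 2, PREDICTION, 2, 0.0),
            SequenceOutcome(LEFT, 2, PREDICTION, 2, 1.0),
            SequenceOutcome(LEFT, 4, PREDICTION, 4, 0.0),
        ]
        conf = confusion_from_outcomes(outcomes, classes=[1, 2, 3, 4])
        assert conf.counts.loc[2, "tp_wp"] == 2
        assert conf.counts.loc[4, "tp_wp"] == 1
        assert conf.pooled("fp").sum() == 0 and conf.pooled("fn").sum() == 0

    def test_wrong_class_in_resting_window(self):
        outcomes = [SequenceOutcome(LEFT, 1, RESTING, 2, -3.0)]
        conf = confusion_from_outcomes(outcomes, classes=[1, 2, 3])
        assert conf.counts.loc[2, "fp_wr"] == 1
        assert conf.counts.loc[1, "fn_wr"] == 1
        assert conf.counts.loc[3, "tn_wr"] == 1

    def test_miss_is_prediction_compartment_fn(self):
        conf = confusion_from_outcomes([SequenceOutcome(LEFT, 1)], classes=[1, 2])
        assert conf.counts.loc[1, "fn_wp"] == 1
        assert conf.counts.loc[2, "tn_wp"] == 1

    def test_count_conservation(self, rng):
        classes = [1, 2, 3, 4, 5]
        for _ in range(30):
            outcomes = []
            for _ in range(rng.integers(1, 20)):
                label = int(rng.choice(classes))
                if rng.random() < 0.3:
                    outcomes.append(SequenceOutcome(LEFT, label))
                else:
                    outcomes.append(
                        SequenceOutcome(
                            LEFT,
                            label,
                            RESTING if rng.random() < 0.5 else PREDICTION,
                            int(rng.choice(classes)),
                            float(rng.normal()),
                        )
                    )
            conf = confusion_from_outcomes(outcomes, classes)
            totals = sum(conf.pooled(kind) for kind in ("tp", "fp", "fn", "tn"))
            assert np.all(totals.to_numpy() == len(outcomes))

    def test_unknown_class_rejected(self):
        with pytest.raises(EvaluationError, match="outside"):
            confusion_from_outcomes([SequenceOutcome(LEFT, 9)], classes=[1, 2])


class TestMetrics:
    def test_pooled_worked_example(self):
        # TP_wp=3, TP_wr=1, FP_wp=1, FN pooled=2, TN pooled=10
        conf = confusion_from_outcomes([SequenceOutcome(LEFT, 1)], classes=[1])
        conf.counts.loc[1] = 0
        conf.counts.loc[1, ["tp_wp", "tp_wr", "fp_wp", "fn_wp", "tn_wp"]] = [3, 1, 1, 2, 10]
        m = metrics_from_confusion(conf).loc[1]
        assert m["precision"] == pytest.approx(4 / 5)
        assert m["recall"] == pytest.approx(4 / 6)
        assert m["f1"] == pytest.approx(8 / 11)
        assert m["accuracy"] == pytest.approx(14 / 17)

    def test_perfect_class(self):
        outcomes = [SequenceOutcome(LEFT, 1, PREDICTION, 1, 0.0)] * 3
        m = metrics_from_confusion(confusion_from_outcomes(outcomes, [1])).loc[1]
        assert all(m[k] == 1.0 for k in ("precision", "recall", "accuracy", "f1"))

    def test_degenerate_class_conventions(self):
        outcomes = [SequenceOutcome(LEFT, 1, PREDICTION, 1, 0.0)]
        m = metrics_from_confusion(confusion_from_outcomes(outcomes, [1, 2]))
        assert m.loc[2, "precision"] == 0.0
        assert m.loc[2, "recall"] == 0.0
        assert m.loc[2, "f1"] == 0.0
        assert m.loc[2, "accuracy"] == 1.0  # only TNs

    def test_f1_is_harmonic_mean_when_defined(self, rng):
        classes = [1, 2, 3]
        outcomes = []
        for _ in range(40):
            label = int(rng.choice(classes))
            pred = int(rng.choice(classes))
            outcomes.append(SequenceOutcome(LEFT, label, PREDICTION, pred, 0.0))
        m = metrics_from_confusion(confusion_from_outcomes(outcomes, classes))
        for _, row in m.iterrows():
            p, r = row["precision"], row["recall"]
            if p + r > 0:
                assert row["f1"] == pytest.approx(2 * p * r / (p + r))


class TestAggregate:
    def table(self, values, supports):
        return pd.DataFrame(
            {
                "precision": values,
                "recall": values,
                "accuracy": values,
                "f1": values,
                "support": supports,
            }
        )

    def test_single_class_weighted_equals_macro(self):
        report = aggregate([self.table([0.8], [4])])
        assert report.weighted["f1"]["mean"] == pytest.approx(0.8)
        assert report.macro["f1"]["mean"] == pytest.approx(0.8)

    def test_equal_supports_weighted_is_arithmetic_mean(self):
        report = aggregate([self.table([1.0, 0.5], [2, 2])])
        assert report.weighted["f1"]["mean"] == pytest.approx(0.75)

    def test_support_weighting(self):
        report = aggregate([self.table([1.0, 0.0], [3, 1])])
        assert report.weighted["f1"]["mean"] == pytest.approx(0.75)
        assert report.macro["f1"]["mean"] == pytest.approx(0.5)

    def test_zero_support_class_excluded(self):
        report = aggregate([self.table([1.0, 0.3], [5, 0])])
        assert report.weighted["f1"]["mean"] == pytest.approx(1.0)

    def test_sd_over_videos(self):
        report = aggregate([self.table([1.0], [1]), self.table([0.0], [1])])
        assert report.weighted["f1"]["mean"] == pytest.approx(0.5)
        assert report.weighted["f1"]["sd"] == pytest.approx(0.5)


def brute_force_metrics(frame_preds, events, classes, T):
    """Oracle: explicit per-sequence scan and direct formula evaluation."""
    records = []
    for event in events:
        rest_frames = [t for t in range(T) if event.resting.start <= t < event.resting.end]
        pred_frames = [t for t in range(T) if event.prediction.start <= t < event.prediction.end]
        first = None
        for t in rest_frames + pred_frames:
            if frame_preds[t] != 0:
                first = ("wr" if t in rest_frames else "wp", frame_preds[t])
                break
        records.append((event.target, first))
    result = {}
    for k in classes:
        tp = {"wp": 0, "wr": 0}
        fp = {"wp": 0, "wr": 0}
        fn = {"wp": 0, "wr": 0}
        tn = {"wp": 0, "wr": 0}
        for label, first in records:
            if first is None:
                if label == k:
                    fn["wp"] += 1
                else:
                    tn["wp"] += 1
            else:
                w, pred = first
                if label == k and pred == k:
                    tp[w] += 1
                elif pred == k:
                    fp[w] += 1
                elif label == k:
                    fn[w] += 1
                else:
                    tn[w] += 1
        TP = tp["wp"] + tp["wr"]
        FP = fp["wp"] + fp["wr"]
        FN = fn["wp"] + fn["wr"]
        TN = tn["wp"] + tn["wr"]
        result[k] = {
            "precision": TP / (TP + FP) if TP + FP else 0.0,
            "recall": TP / (TP + FN) if TP + FN else 0.0,
            "accuracy": (TP + TN) / (TP + TN + FP + FN) if TP + TN + FP + FN else 1.0,
            "f1": 2 * TP / (2 * TP + FP + FN) if 2 * TP + FP + FN else 0.0,
        }
    return result


def random_instance(rng, max_sequences=20, max_classes=5):
    n_classes = int(rng.integers(1, max_classes + 1))
    classes = list(range(1, n_classes + 1))
    n_events = int(rng.integers(1, max_sequences + 1))
    events, t = [], 0
    for _ in range(n_events):
        rest_len = int(rng.integers(1, 5))
        pred_len = int(rng.integers(1, 5))
        start = t + int(rng.integers(0, 3))
        events.append(
            ev(
                (start, start + rest_len),
                (start + rest_len, start + rest_len + pred_len),
                int(rng.choice(classes)),
            )
        )
        t = start + rest_len + pred_len
    T = t + 2
    frame_preds = rng.choice(n_classes + 1, size=T, p=None)
    return frame_preds, events, classes, T


class TestBruteForceAgreement:
    def test_randomized_instances_match_oracle(self, rng):
        for _ in range(100):
            frame_preds, events, classes, T = random_instance(rng)
            schedule = make_schedule(events)
            outcomes = first_prediction_per_sequence(
                {LEFT: frame_preds, RIGHT: np.zeros(T, dtype=int)}, schedule
            )
            ours = metrics_from_confusion(confusion_from_outcomes(outcomes, classes))
            oracle = brute_force_metrics(frame_preds, events, classes, T)
            for k in classes:
                for metric, value in oracle[k].items():
                    assert ours.loc[k, metric] == pytest.approx(value), (k, metric)


class TestEndToEndHelpers:
    def test_idle_baseline_recall_zero(self, vocab):
        schedule = make_schedule([ev((10, 20), (20, 27), target=2)])
        heads = idle_baseline_heads(40, vocab)
        report = evaluate_videos([(heads, schedule)], vocab)
        assert report.weighted["recall"]["mean"] == 0.0

    def test_perfect_predictor_scores_one(self, vocab):
        schedule = make_schedule([ev((10, 20), (20, 27), target=2)])
        heads = idle_baseline_heads(40, vocab)
        heads["left"] = heads["left"].copy()
        heads["left"][20] = 0.0
        heads["left"][20, 2] = 1.0
        report = evaluate_videos([(heads, schedule)], vocab)
        for metric in ("precision", "recall", "accuracy", "f1"):
            assert report.weighted[metric]["mean"] == 1.0

    def test_occlude_unknown_block_rejected(self, vocab):
        from scrubsight.features import BlockLayout

        layout = BlockLayout.for_vocab(vocab, c_s=5)
        with pytest.raises(EvaluationError, match="unknown feature block"):
            occlude_features(np.zeros((3, layout.total_len)), layout, "X")

    def test_occluding_block_zeroes_exactly_that_slice(self, vocab, rng):
        from scrubsight.features import BlockLayout

        layout = BlockLayout.for_vocab(vocab, c_s=5)
        F = rng.random((4, layout.total_len))
        out = occlude_features(F, layout, "D")
        slices = layout.slices()
        assert not out[:, slices["D"]].any()
        assert np.array_equal(out[:, slices["V"]], F[:, slices["V"]])
        assert np.array_equal(out[:, slices["S"]], F[:, slices["S"]])
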