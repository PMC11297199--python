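"""Sequence-based evaluation with embedded confusion matrices.

Each resting window followed by its prediction window is one *sequence*
whose label is the prediction-window target.  Scanning the sequence's
frames in order (resting first, then prediction; disregard frames are
never scanned), the first frame whose predicted class is not idle yields
the sequence's single counted prediction, together with the window it
occurred in and its offset relative to the prediction-window start.

Per class the TP/FP/FN/TN counts are kept in two compartments — the
prediction-window and the resting-window confusion matrix; the four
metrics pool both compartments:

    precision = (TP_wp + TP_wr) / ((TP_wp + TP_wr) + (FP_wp + FP_wr))
    recall    = (TP_wp + TP_wr) / ((TP_wp + TP_wr) + (FN_wp + FN_wr))
    accuracy  = (TP + TN) / (TP + TN + FP + FN)        (both compartments)
    F1        = 2 TP / (2 TP + FP + FN)                (both compartments)

A sequence with no non-idle prediction is a miss: FN in the prediction
compartment for its label class.  Metrics are computed per class
(instrument x trocar) and per video, then averaged over classes weighted
by support, then averaged over videos (reported as mean +/- sd); macro
(unweighted) means are reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .timelines import TROCARS
from .vocab import IDLE, LabelVocabulary
from .windowing import WindowParams, WindowSchedule, build_window_schedule

RESTING = "resting"
PREDICTION = "prediction"


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class SequenceOutcome:
    """First-prediction record of one resting+prediction sequence."""

    trocar: str
    label: int  # anticipation-space class of the prediction window
    window: str | None = None  # RESTING / PREDICTION, None when no prediction
    predicted: int | None = None
    offset_s: float | None = None  # relative to the prediction-window start


def first_prediction_per_sequence(
    predictions: dict[str, np.ndarray], schedule: WindowSchedule
) -> list[SequenceOutcome]:
    """Scan each event's resting then prediction frames for the first non-idle.

    ``predictions`` maps trocar to a per-frame predicted anticipation class.
    Disregard frames are skipped entirely; they never produce the first
    prediction.
    """
    outcomes = []
    for trocar in TROCARS:
        pred = np.asarray(predictions[trocar])
        T = len(pred)
        for ev in schedule.events[trocar]:
            if ev.prediction.end > T + 1.0:
                raise EvaluationError(
                    f"schedule event at t0={ev.t0} exceeds the {T}-frame prediction track"
                )
            frames = np.concatenate([ev.resting.frames(T), ev.prediction.frames(T)])
            n_rest = len(ev.resting.frames(T))
            record = None
            for j, t in enumerate(frames):
                if pred[t] != IDLE:
                    record = (
                        RESTING if j < n_rest else PREDICTION,
                        int(pred[t]),
                        float(t - ev.prediction.start),
                    )
                    break
            if record is None:
                outcomes.append(SequenceOutcome(trocar, ev.target))
            else:
                outcomes.append(SequenceOutcome(trocar, ev.target, *record))
    return outcomes


@dataclass
class EmbeddedConfusion:
    """Per-class one-vs-rest counts split into the two window compartments."""

    classes: list[int]
    counts: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.counts is None:
            cols = [
                f"{kind}_{comp}" for kind in ("tp", "fp", "fn", "tn") for comp in ("wp", "wr")
            ]
            self.counts = pd.DataFrame(0, index=list(self.classes), columns=cols, dtype=np.int64)

    def add(self, kind: str, compartment: str, cls: int) -> None:
        self.counts.loc[cls, f"{kind}_{compartment}"] += 1

    def pooled(self, kind: str) -> pd.Series:
        return self.counts[f"{kind}_wp"] + self.counts[f"{kind}_wr"]


def confusion_from_outcomes(
    outcomes: list[SequenceOutcome], classes: list[int]
) -> EmbeddedConfusion:
    """One-vs-rest embedded confusion counts over sequences.

    Assignment rule per sequence with label ``c``: no record -> FN for
    ``c`` in the prediction compartment; a record in window ``w`` with
    predicted ``p == c`` -> TP in compartment ``w``; ``p != c`` -> FP for
    ``p`` and FN for ``c`` in ``w``.  All classes not involved receive TN
    in that sequence's compartment (prediction when there is no record).
    Per class, TP+FP+FN+TN summed over both compartments equals the number
    of sequences.
    """
    class_set = set(classes)
    conf = EmbeddedConfusion(classes=list(classes))
    for seq in outcomes:
        if seq.label not in class_set:
            raise EvaluationError(f"sequence label {seq.label} outside the class set")
        if seq.predicted is not None and seq.predicted not in class_set:
            raise EvaluationError(f"predicted class {seq.predicted} outside the class set")
        comp = "wp" if seq.window in (None, PREDICTION) else "wr"
        involved = {seq.label}
        if seq.predicted is None:
            conf.add("fn", comp, seq.label)
        elif seq.predicted == seq.label:
            conf.add("tp", comp, seq.label)
        else:
            conf.add("fp", comp, seq.predicted)
            conf.add("fn", comp, seq.label)
            involved.add(seq.predicted)
        for cls in class_set - involved:
            conf.add("tn", comp, cls)
    return conf


def metrics_from_confusion(conf: EmbeddedConfusion) -> pd.DataFrame:
    """Per-class precision/recall/accuracy/F1 with pooled compartments.

    0/0 convention: precision, recall and F1 are 0 when their denominator
    vanishes; accuracy of a class with no sequences at all is 1.
    """
    tp, fp = conf.pooled("tp").astype(float), conf.pooled("fp").astype(float)
    fn, tn = conf.pooled("fn").astype(float), conf.pooled("tn").astype(float)

    def safe(num, den):
        return np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)

    total = tp + fp + fn + tn
    return pd.DataFrame(
        {
            "precision": safe(tp, tp + fp),
            "recall": safe(tp, tp + fn),
            "accuracy": np.where(total > 0, (tp + tn) / np.where(total > 0, total, 1.0), 1.0),
            "f1": safe(2 * tp, 2 * tp + fp + fn),
            "support": (tp + fn).astype(np.int64),
        },
        index=conf.counts.index,
    )


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

@dataclass
class MetricReport:
    """Per-class and aggregated anticipation metrics.

    ``weighted`` and ``macro`` map each metric to its mean and standard
    deviation over videos; ``per_video`` keeps the class-level tables;
    ``confusions`` carries the multiclass label x predicted counts per
    trocar summed over videos; ``offsets`` the first-prediction offset
    diagnostics per class.
    """

    per_video: list[pd.DataFrame]
    weighted: dict[str, dict[str, float]]
    macro: dict[str, dict[str, float]]
    confusions: dict[str, pd.DataFrame] = field(default_factory=dict)
    offsets: pd.DataFrame | None = None

    def summary(self) -> str:
        lines = [
            "sequence-based anticipation metrics (mean +/- sd over videos)",
            f"  videos evaluated: {len(self.per_video)}",
            "  weighted: "
            + "  ".join(
                f"{k}={v['mean']:.4f}+/-{v['sd']:.4f}" for k, v in self.weighted.items()
            ),
            "  macro:    "
            + "  ".join(f"{k}={v['mean']:.4f}+/-{v['sd']:.4f}" for k, v in self.macro.items()),
        ]
        return "\n".join(lines)

    def to_json(self) -> dict:
        return {
            "weighted": self.weighted,
            "macro": self.macro,
            "per_video": [t.reset_index().to_dict(orient="records") for t in self.per_video],
        }


METRICS = ("precision", "recall", "accuracy", "f1")


def aggregate(per_video: list[pd.DataFrame]) -> MetricReport:
    """Support-weighted and macro means per video, then mean +/- sd over videos.

    Classes with zero support in a video are excluded from that video's
    averages; a video with no supported class at all is skipped.
    """
    if not per_video:
        raise EvaluationError("no per-video metric tables to aggregate")
    weighted_rows, macro_rows = [], []
    for table in per_video:
        sup = table["support"].to_numpy(dtype=float)
        if sup.sum() <= 0:
            continue
        mask = sup > 0
        w = sup[mask] / sup[mask].sum()
        weighted_rows.append(
            {m: float(np.sum(w * table.loc[mask, m].to_numpy())) for m in METRICS}
        )
        macro_rows.append({m: float(table.loc[mask, m].mean()) for m in METRICS})
    if not weighted_rows:
        raise EvaluationError("all videos have zero total support")

    def stats(rows):
        frame = pd.DataFrame(rows)
        return {
            m: {"mean": float(frame[m].mean()), "sd": float(frame[m].std(ddof=0))}
            for m in METRICS
        }

    return MetricReport(per_video=per_video, weighted=stats(weighted_rows), macro=stats(macro_rows))


# ---------------------------------------------------------------------------
# end-to-end evaluation helpers
# ---------------------------------------------------------------------------

def _class_key(vocab: LabelVocabulary, trocar: str, cls: int) -> str:
    return f"{trocar}:{vocab.anticipation_names()[cls]}"


def predictions_from_heads(heads: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Per-frame predicted anticipation class (argmax) per trocar."""
    return {t: np.argmax(heads[t], axis=1) for t in TROCARS}


def evaluate_videos(
    items: list[tuple[dict[str, np.ndarray], WindowSchedule]],
    vocab: LabelVocabulary,
    compatibility: np.ndarray | None = None,
) -> MetricReport:
    """Evaluate per-video final-stage head outputs against their schedules.

    ``compatibility`` optionally applies the informed phase-compatibility
    reweighting to the instrument heads before the argmax.
    """
    from .informed import reweight_distributions  # local import: avoid cycle

    classes = list(range(1, vocab.n_anticipation_classes))
    tables = []
    offset_rows = []
    confusions = {
        t: pd.DataFrame(
            0,
            index=[_class_key(vocab, t, c) for c in classes],
            columns=[_class_key(vocab, t, c) for c in classes] + ["none"],
            dtype=np.int64,
        )
        for t in TROCARS
    }
    for heads, schedule in items:
        if compatibility is not None:
            heads = dict(heads)
            for trocar in TROCARS:
                heads[trocar] = reweight_distributions(
                    heads[trocar], heads["phase"], compatibility
                )
        outcomes = first_prediction_per_sequence(predictions_from_heads(heads), schedule)
        video_rows = []
        for trocar in TROCARS:
            sub = [o for o in outcomes if o.trocar == trocar]
            conf = confusion_from_outcomes(sub, classes)
            table = metrics_from_confusion(conf)
            table.index = [_class_key(vocab, trocar, c) for c in table.index]
            video_rows.append(table)
            for o in sub:
                pred_key = (
                    _class_key(vocab, trocar, o.predicted) if o.predicted is not None else "none"
                )
                confusions[trocar].loc[_class_key(vocab, trocar, o.label), pred_key] += 1
                if o.offset_s is not None:
                    offset_rows.append(
                        {
                            "class": _class_key(vocab, trocar, o.label),
                            "window": o.window,
                            "offset_s": o.offset_s,
                        }
                    )
        tables.append(pd.concat(video_rows))
    report = aggregate(tables)
    report.confusions = confusions
    if offset_rows:
        frame = pd.DataFrame(offset_rows)
        report.offsets = frame.groupby("class")["offset_s"].agg(["mean", "median", "count"])
    return report


def evaluate_model(
    net,
    dataset,
    split: str = "test",
    window_params: WindowParams | None = None,
    compatibility: np.ndarray | None = None,
    occlude_block: str | None = None,
) -> MetricReport:
    """Forward a dataset split through a trained network and score it."""
    window_params = window_params or WindowParams()
    vocab = dataset.vocab
    items = []
    for video in dataset.split_videos(split):
        features = video.features
        if occlude_block is not None:
            features = occlude_features(features, dataset.layout, occlude_block)
        schedule = build_window_schedule(video.track, video.timeline, window_params, vocab)
        items.append((net.forward(features).final, schedule))
    return evaluate_videos(items, vocab, compatibility=compatibility)


def occlude_features(features: np.ndarray, layout, block: str) -> np.ndarray:
    """Zero-fill one feature block (V, D or S) at inference time."""
    slices = layout.slices()
    if block not in slices:
        raise EvaluationError(f"unknown feature block {block!r}; expected one of {list(slices)}")
    out = np.array(features, copy=True)
    out[:, slices[block]] = 0.0
    return out


def occlusion_ablation(
    net,
    dataset,
    block: str,
    split: str = "test",
    window_params: WindowParams | None = None,
    baseline: float | None = None,
) -> float:
    """Drop in weighted F1 (-Delta wAF1) when one feature block is occluded.

    Evaluates the unperturbed baseline (unless supplied), re-evaluates with
    the chosen block zero-filled, and returns ``baseline - occluded``.
    """
    if baseline is None:
        baseline = evaluate_model(net, dataset, split, window_params).weighted["f1"]["mean"]
    occluded = evaluate_model(
        net, dataset, split, window_params, occlude_block=block
    ).weighted["f1"]["mean"]
    return float(baseline - occluded)


def idle_baseline_heads(T: int, vocab: LabelVocabulary) -> dict[str, np.ndarray]:
    """The always-idle predictor: all probability mass on idle at every frame."""
    instr = np.zeros((T, vocab.n_anticipation_classes))
    instr[:, IDLE] = 1.0
    phase = np.full((T, vocab.n_phases), 1.0 / max(vocab.n_phases, 1))
    return {"left": instr.copy(), "right": instr.copy(), "phase": phase}
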