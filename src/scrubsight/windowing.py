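"""Resting / prediction / disregard windows and per-frame anticipation labels.

An instrument change on a trocar is anchored at the last-use time ``t0`` of
the outgoing instrument.  The robot must commit to the next instrument by
``t_pred = t0 - delta`` (handover lead); with the acceptable threshold
``tau`` and the post-extraction shift ``sigma`` the prediction window is

    w_p = [t0 - delta - tau,  t0 + sigma)

so that with delta = tau = 3 s and sigma = 1 s it spans [t0-6, t0+1).  The
shift extends the window *end* past t0 (not a translation of both ends):
only this reading reproduces that range.  A resting window w_r of duration
``rho`` immediately precedes w_p; there the model must output idle to keep
the robot still.  Every remaining frame is a disregard frame w_d.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .timelines import LEFT, RIGHT, TROCARS, FrameTrack, Interval, SurgeryTimeline
from .vocab import IDLE, LabelVocabulary

logger = logging.getLogger(__name__)

# window-kind codes in per-frame tracks
DISREGARD = 0
REST = 1
PRED = 2

NO_TARGET = -1
"""Target code of disregard frames (no supervised anticipation target)."""


class WindowError(ValueError):
    pass


@dataclass(frozen=True)
class WindowParams:
    """Timing parameters of the anticipation task, all in seconds.

    delta : robot preparation lead before extraction.
    tau   : acceptable threshold around the prediction time.
    sigma : shift of the window end past extraction, letting the model see
            the instrument disappear.
    rho   : resting-window duration (not fixed by the task itself; default
            10 s, comparable to the 7 s default prediction window).
    """

    delta: float = 3.0
    tau: float = 3.0
    sigma: float = 1.0
    rho: float = 10.0

    def __post_init__(self):
        if self.delta < 0 or self.tau < 0 or self.sigma < 0:
            raise WindowError("delta, tau and sigma must be >= 0")
        if self.rho <= 0:
            raise WindowError("rho must be > 0")


@dataclass
class Span:
    """Half-open [start, end) span in seconds; may be empty after truncation."""

    start: float
    end: float

    @property
    def width(self) -> float:
        return self.end - self.start

    @property
    def empty(self) -> bool:
        return self.end <= self.start

    def frames(self, T: int) -> np.ndarray:
        lo = max(int(np.ceil(self.start)), 0)
        hi = min(int(np.ceil(self.end)), T)
        return np.arange(lo, max(hi, lo))


@dataclass
class AnticipationEvent:
    """One instrument change: resting window followed by prediction window."""

    trocar: str
    t0: float
    target: int  # anticipation-space index of the next instrument (never idle)
    resting: Span
    prediction: Span

    def __post_init__(self):
        if self.target == IDLE:
            raise WindowError("event target must not be the idle class")


def compute_prediction_window(t0: float, params: WindowParams) -> Span:
    """The raw (unclipped) prediction window ``[t0 - delta - tau, t0 + sigma)``."""
    return Span(t0 - params.delta - params.tau, t0 + params.sigma)


@dataclass
class WindowSchedule:
    """Time-ordered anticipation events per trocar plus derived frame tracks."""

    events: dict[str, list[AnticipationEvent]] = field(
        default_factory=lambda: {LEFT: [], RIGHT: []}
    )

    def frame_labels(self, T: int) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per trocar ``(window_kind, target)`` arrays of length ``T``.

        Prediction frames carry the event target, resting frames idle,
        disregard frames :data:`NO_TARGET`.
        """
        out = {}
        for trocar in TROCARS:
            kind = np.full(T, DISREGARD, dtype=np.int64)
            target = np.full(T, NO_TARGET, dtype=np.int64)
            for ev in self.events[trocar]:
                rf = ev.resting.frames(T)
                pf = ev.prediction.frames(T)
                kind[rf] = REST
                target[rf] = IDLE
                kind[pf] = PRED
                target[pf] = ev.target
            out[trocar] = (kind, target)
        return out

    def to_frame(self, vocab: LabelVocabulary) -> pd.DataFrame:
        rows = []
        for trocar in TROCARS:
            for i, ev in enumerate(self.events[trocar]):
                rows.append(
                    {
                        "trocar": trocar,
                        "event_id": i,
                        "t0_s": ev.t0,
                        "target": vocab.anticipation_names()[ev.target],
                        "rest_start": ev.resting.start,
                        "rest_end": ev.resting.end,
                        "pred_start": ev.prediction.start,
                        "pred_end": ev.prediction.end,
                    }
                )
        return pd.DataFrame(rows)


def build_window_schedule(
    track: FrameTrack,
    timeline: SurgeryTimeline,
    params: WindowParams,
    vocab: LabelVocabulary,
) -> WindowSchedule:
    """Derive anticipation events from per-trocar instrument-use intervals.

    One event per instrument change: ``t0`` is the end of the outgoing
    instrument's interval, the target is the next instrument inserted into
    the same trocar.  The final extraction (no successor) yields no event,
    and neither does the first insertion of a surgery.  Windows are clipped
    to ``[0, duration]`` and truncated so that windows of one trocar never
    overlap: a resting window yields to the preceding prediction window,
    and when two prediction windows collide the later event wins.
    """
    if track.n_frames != timeline.n_frames:
        raise WindowError(
            f"frame track length {track.n_frames} does not match timeline "
            f"({timeline.n_frames} frames)"
        )
    schedule = WindowSchedule()
    for trocar in TROCARS:
        intervals = timeline.instruments_for(trocar)
        events: list[AnticipationEvent] = []
        for outgoing, incoming in zip(intervals, intervals[1:]):
            t0 = outgoing.end
            pred = compute_prediction_window(t0, params)
            pred.start = max(pred.start, 0.0)
            pred.end = min(pred.end, timeline.duration)
            rest = Span(pred.start - params.rho, pred.start)
            rest.start = max(rest.start, 0.0)
            if events:
                prev = events[-1]
                # resting window yields to the preceding prediction window;
                # if the prediction windows themselves collide, later wins.
                rest.start = min(max(rest.start, prev.prediction.end), rest.end)
                prev.prediction.end = min(prev.prediction.end, rest.start)
            events.append(
                AnticipationEvent(
                    trocar=trocar,
                    t0=t0,
                    target=vocab.anticipation_index(incoming.label),
                    resting=rest,
                    prediction=pred,
                )
            )
        kept = []
        for ev in events:
            if ev.prediction.empty:
                logger.warning(
                    "dropping %s-trocar event at t0=%.1f: prediction window empty "
                    "after clipping/truncation",
                    ev.trocar,
                    ev.t0,
                )
                continue
            kept.append(ev)
        schedule.events[trocar] = kept
    return schedule


def frame_labels(schedule: WindowSchedule, T: int) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Convenience wrapper around :meth:`WindowSchedule.frame_labels`."""
    return schedule.frame_labels(T)
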