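"""The temporally-scaled multiclass focal loss.

Per supervised frame the loss is ``scale(t) * FL(p, y, gamma)`` with the
multiclass focal loss ``FL = -(1 - p_y)^gamma * log(p_y)``.  The scaling
function rises quadratically towards the *start* of the prediction window
(weight 1 there, ``beta`` at its end) and mirrors this over the resting
window (``beta`` at its start, 1 at its end), so the model is pushed
hardest exactly where a timely robot trigger is decided; disregard frames
get the constant weight ``mu`` with target idle.  The focusing parameter
is ``gamma = 2`` inside resting/prediction windows and ``1`` in the
disregard window.  The total loss averages over refinement stages and sums
over the two trocar heads; the phase head contributes an unscaled focal
term.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .timelines import TROCARS, FrameTrack
from .vocab import IDLE
from .windowing import DISREGARD, PRED, REST, AnticipationEvent, WindowSchedule

logger = logging.getLogger(__name__)


class LossError(ValueError):
    pass


@dataclass(frozen=True)
class LossParams:
    """Hyperparameters of the scaled focal loss.

    beta  : floor of the quadratic temporal scaling, in [0, 1].
    mu    : constant weight of disregard frames (>= 0).
    gamma_pred / gamma_rest / gamma_disregard : focusing parameters.
    phase_loss_weight : weight of the (unscaled) phase-head focal loss.
    eps   : probability clamp before the logarithm.
    """

    beta: float = 0.25
    mu: float = 0.1
    gamma_pred: float = 2.0
    gamma_rest: float = 2.0
    gamma_disregard: float = 1.0
    phase_loss_weight: float = 1.0
    eps: float = 1e-12

    def __post_init__(self):
        if not 0.0 <= self.beta <= 1.0:
            raise LossError(f"beta must lie in [0, 1], got {self.beta}")
        if self.mu < 0:
            raise LossError(f"mu must be >= 0, got {self.mu}")
        for g in (self.gamma_pred, self.gamma_rest, self.gamma_disregard):
            if g < 0:
                raise LossError(f"focusing parameters must be >= 0, got {g}")


def scale(t: float, event: AnticipationEvent | None, params: LossParams) -> float:
    """Temporal loss weight of frame time ``t``.

    Inside the event's prediction window the weight falls quadratically
    from 1 (window start) to ``beta`` (window end); inside the resting
    window it rises from ``beta`` (start) to 1 (end); everywhere else
    (``event is None`` or ``t`` outside both windows) it is ``mu``.
    """
    if event is not None:
        wp, wr = event.prediction, event.resting
        if wp.start <= t < wp.end or t == wp.end:
            if wp.width <= 0:
                raise LossError("prediction window has zero width")
            return params.beta + ((t - wp.end) / wp.width) ** 2 * (1 - params.beta)
        if wr.start <= t < wr.end or (t == wr.start and wr.width > 0):
            if wr.width <= 0:
                raise LossError("resting window has zero width")
            return params.beta + ((wr.start - t) / wr.width) ** 2 * (1 - params.beta)
    return params.mu


def focal_loss(dist: np.ndarray, target: int, gamma: float, eps: float = 1e-12) -> float:
    """Multiclass focal loss ``-(1 - p_y)^gamma * log(p_y)`` for one frame."""
    dist = np.asarray(dist, dtype=np.float64)
    if not np.isclose(dist.sum(), 1.0, atol=1e-5):
        raise LossError(f"distribution sums to {dist.sum()}, expected 1")
    p = float(dist[target])
    if p <= 0.0:
        logger.warning("clamping zero target probability to eps=%g", eps)
    p = max(p, eps)
    return -((1.0 - p) ** gamma) * np.log(p)


@dataclass
class FrameSupervision:
    """Per-frame target / weight / focusing arrays for one trocar head."""

    target: np.ndarray  # (T,) anticipation-class index (idle on rest+disregard)
    weight: np.ndarray  # (T,) scale(t)
    gamma: np.ndarray  # (T,)


def frame_supervision(
    schedule: WindowSchedule, T: int, params: LossParams
) -> dict[str, FrameSupervision]:
    """Vectorized per-frame supervision derived from a window schedule.

    Disregard frames supervise towards idle at weight ``mu``; resting and
    prediction frames get the quadratic Eq.-style weights evaluated at
    integer frame times.
    """
    out = {}
    labels = schedule.frame_labels(T)
    for trocar in TROCARS:
        kind, target_track = labels[trocar]
        target = np.where(target_track < 0, IDLE, target_track)
        weight = np.full(T, params.mu, dtype=np.float64)
        gamma = np.full(T, params.gamma_disregard, dtype=np.float64)
        for ev in schedule.events[trocar]:
            for span, kind_code, g in (
                (ev.resting, REST, params.gamma_rest),
                (ev.prediction, PRED, params.gamma_pred),
            ):
                frames = span.frames(T)
                if len(frames) == 0:
                    continue
                if span.width <= 0:
                    raise LossError("zero-width window with labelled frames")
                t = frames.astype(np.float64)
                if kind_code is PRED:
                    q = ((t - span.end) / span.width) ** 2
                else:
                    q = ((span.start - t) / span.width) ** 2
                weight[frames] = params.beta + q * (1 - params.beta)
                gamma[frames] = g
        # frames re-labelled by window kinds must agree with the event fill
        assert np.all((kind != DISREGARD) | (weight == params.mu))
        out[trocar] = FrameSupervision(target=target, weight=weight, gamma=gamma)
    return out


def _head_loss_np(probs: np.ndarray, sup: FrameSupervision, eps: float) -> np.ndarray:
    p = np.maximum(probs[np.arange(len(sup.target)), sup.target], eps)
    return sup.weight * (1.0 - p) ** sup.gamma * (-np.log(p))


def sequence_loss(
    outputs: list[dict[str, np.ndarray]],
    schedule: WindowSchedule,
    track: FrameTrack,
    params: LossParams,
) -> float:
    """Aggregate loss of multi-stage outputs against a window schedule.

    ``outputs`` is one dict per refinement stage with keys ``"left"``,
    ``"right"`` (frame distributions over idle + instruments) and
    ``"phase"``.  Per stage the per-frame losses of the two trocar heads
    are summed, the phase head adds an unscaled focal term (masked where no
    phase is annotated), frames are averaged, and stages are averaged.
    """
    if not outputs:
        raise LossError("no stage outputs")
    T = track.n_frames
    for m, stage in enumerate(outputs):
        for key in ("left", "right", "phase"):
            if len(stage[key]) != T:
                raise LossError(f"stage {m} head {key!r} has {len(stage[key])} frames, expected {T}")
    sup = frame_supervision(schedule, T, params)
    phase_mask = track.phase >= 0
    total = 0.0
    for stage in outputs:
        per_frame = np.zeros(T, dtype=np.float64)
        for trocar in TROCARS:
            per_frame += _head_loss_np(stage[trocar], sup[trocar], params.eps)
        if params.phase_loss_weight > 0 and phase_mask.any():
            probs = stage["phase"]
            idx = np.where(phase_mask)[0]
            p = np.maximum(probs[idx, track.phase[idx]], params.eps)
            phase_l = np.zeros(T, dtype=np.float64)
            phase_l[idx] = (1.0 - p) ** 2 * (-np.log(p))
            per_frame += params.phase_loss_weight * phase_l
        total += per_frame.mean()
    return float(total / len(outputs))


def sequence_loss_graph(
    stage_heads: list[dict[str, "ad.Tensor"]],
    sup: dict[str, FrameSupervision],
    phase_track: np.ndarray,
    params: LossParams,
) -> "ad.Tensor":
    """Autodiff twin of :func:`sequence_loss` used during training.

    Consumes probability tensors (post-softmax) per stage and returns the
    scalar loss tensor; numerically identical to the NumPy path.
    """
    M = len(stage_heads)
    T = len(phase_track)
    phase_mask = phase_track >= 0
    phase_target = np.where(phase_mask, phase_track, 0)
    terms = []
    for heads in stage_heads:
        frame_sum = None
        for trocar in TROCARS:
            s = sup[trocar]
            p = ad.clamp_min(ad.gather_rows(heads[trocar], s.target), params.eps)
            fl = ad.mul(ad.power(ad.add(ad.mul(p, -1.0), 1.0), s.gamma), ad.mul(ad.log(p), -1.0))
            term = ad.mul(fl, s.weight)
            frame_sum = term if frame_sum is None else ad.add(frame_sum, term)
        if params.phase_loss_weight > 0 and phase_mask.any():
            p = ad.clamp_min(ad.gather_rows(heads["phase"], phase_target), params.eps)
            fl = ad.mul(ad.power(ad.add(ad.mul(p, -1.0), 1.0), 2.0), ad.mul(ad.log(p), -1.0))
            term = ad.mul(fl, params.phase_loss_weight * phase_mask.astype(np.float64))
            frame_sum = ad.add(frame_sum, term)
        terms.append(ad.mean(frame_sum))
    total = terms[0]
    for t in terms[1:]:
        total = ad.add(total, t)
    return ad.mul(total, 1.0 / M)
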