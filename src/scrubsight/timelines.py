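"""Data model and I/O for annotated surgery timelines.

A :class:`SurgeryTimeline` holds phase, action and per-trocar instrument-use
intervals in continuous seconds.  Frame sampling follows the 1 fps
sub-sampling convention of laparoscopic workflow datasets: frame ``i`` sits
at integer second ``t = i`` and carries the label of any interval with
``start <= t < end`` (half-open membership).

The on-disk dialect is JSON (one object per video); a CSV dialect with one
interval per row is accepted for import.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .vocab import LabelVocabulary

LEFT = "left"
RIGHT = "right"
NO_TROCAR = "none"
TROCARS = (LEFT, RIGHT)

NONE_IDX = -1
"""Frame-track sentinel for 'no label active at this frame'."""


class TimelineFormatError(ValueError):
    """File does not parse as the documented timeline dialect."""


class TimelineValidationError(ValueError):
    """A timeline violates a structural invariant."""


@dataclass(frozen=True)
class Interval:
    """A labelled time span ``[start, end)`` in seconds."""

    start: float
    end: float
    label: str
    trocar: str = NO_TROCAR

    def __post_init__(self):
        if not (self.start < self.end):
            raise TimelineValidationError(
                f"interval must satisfy start < end, got [{self.start}, {self.end}) "
                f"for label {self.label!r}"
            )
        if self.start < 0:
            raise TimelineValidationError(f"interval start must be >= 0, got {self.start}")
        if self.trocar not in (LEFT, RIGHT, NO_TROCAR):
            raise TimelineValidationError(f"unknown trocar {self.trocar!r}")

    @property
    def duration(self) -> float:
        return self.end - self.start

    def contains(self, t: float) -> bool:
        return self.start <= t < self.end


def _check_disjoint(intervals: list[Interval], what: str) -> None:
    ordered = sorted(intervals, key=lambda iv: iv.start)
    for a, b in zip(ordered, ordered[1:]):
        if b.start < a.end:
            raise TimelineValidationError(
                f"overlapping {what} intervals: "
                f"[{a.start}, {a.end}) {a.label!r} and [{b.start}, {b.end}) {b.label!r}"
            )


@dataclass
class SurgeryTimeline:
    """Per-video annotations: phases, actions and per-trocar instrument use."""

    video_id: str
    duration: float
    fps_source: float = 1.0
    phase_intervals: list[Interval] = field(default_factory=list)
    action_intervals: list[Interval] = field(default_factory=list)
    instrument_intervals: list[Interval] = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.duration < 0:
            raise TimelineValidationError(f"duration must be >= 0, got {self.duration}")
        for iv in self.phase_intervals + self.action_intervals:
            if iv.trocar != NO_TROCAR:
                raise TimelineValidationError(
                    f"phase/action interval {iv.label!r} must have trocar='none'"
                )
        for iv in self.instrument_intervals:
            if iv.trocar not in TROCARS:
                raise TimelineValidationError(
                    f"instrument interval {iv.label!r} must name a working trocar"
                )
        for iv in self.phase_intervals + self.action_intervals + self.instrument_intervals:
            if iv.end > self.duration + 1e-9:
                raise TimelineValidationError(
                    f"interval [{iv.start}, {iv.end}) {iv.label!r} exceeds duration "
                    f"{self.duration}"
                )
        _check_disjoint(self.phase_intervals, "phase")
        for trocar in TROCARS:
            _check_disjoint(
                [iv for iv in self.instrument_intervals if iv.trocar == trocar],
                f"{trocar}-trocar instrument",
            )

    def instruments_for(self, trocar: str) -> list[Interval]:
        """Instrument-use intervals of one trocar, time ordered."""
        return sorted(
            (iv for iv in self.instrument_intervals if iv.trocar == trocar),
            key=lambda iv: iv.start,
        )

    @property
    def n_frames(self) -> int:
        return int(np.floor(self.duration))


@dataclass
class FrameTrack:
    """Per-frame label indices at 1 fps; ``NONE_IDX`` marks unlabeled frames."""

    phase: np.ndarray
    action: np.ndarray
    instr_left: np.ndarray
    instr_right: np.ndarray

    def __post_init__(self):
        lengths = {len(self.phase), len(self.action), len(self.instr_left), len(self.instr_right)}
        if len(lengths) != 1:
            raise TimelineValidationError(f"frame arrays have mismatched lengths {lengths}")

    @property
    def n_frames(self) -> int:
        return len(self.phase)

    def to_frame(self, vocab: LabelVocabulary) -> pd.DataFrame:
        """Human-readable export: one row per frame with label names."""

        def names(idx: np.ndarray, table: tuple[str, ...]) -> list[str]:
            return [table[i] if i >= 0 else "" for i in idx]

        return pd.DataFrame(
            {
                "frame": np.arange(self.n_frames),
                "phase": names(self.phase, vocab.phases),
                "action": names(self.action, vocab.actions),
                "instr_left": names(self.instr_left, vocab.instruments),
                "instr_right": names(self.instr_right, vocab.instruments),
            }
        )


# ---------------------------------------------------------------------------
# frame sampling
# ---------------------------------------------------------------------------

def _rasterize(intervals: list[Interval], index_of, T: int) -> np.ndarray:
    out = np.full(T, NONE_IDX, dtype=np.int64)
    for iv in intervals:
        lo = int(np.ceil(iv.start))
        hi = int(np.ceil(iv.end))  # frame t labelled iff start <= t < end
        out[max(lo, 0) : min(hi, T)] = index_of(iv.label)
    return out


def sample_frames(timeline: SurgeryTimeline, vocab: LabelVocabulary) -> FrameTrack:
    """Sub-sample a timeline to 1 fps.

    Frame ``i`` (at integer second ``t = i``) carries the label of the
    interval containing ``t`` under half-open membership; frames outside all
    intervals carry ``NONE_IDX``.
    """
    T = timeline.n_frames
    return FrameTrack(
        phase=_rasterize(timeline.phase_intervals, vocab.phase_index, T),
        action=_rasterize(timeline.action_intervals, vocab.action_index, T),
        instr_left=_rasterize(timeline.instruments_for(LEFT), vocab.instrument_index, T),
        instr_right=_rasterize(timeline.instruments_for(RIGHT), vocab.instrument_index, T),
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_KIND_KEYS = ("phases", "actions", "instruments")


def _interval_to_obj(iv: Interval) -> dict:
    obj = {"label": iv.label, "start_s": iv.start, "end_s": iv.end}
    if iv.trocar != NO_TROCAR:
        obj["trocar"] = iv.trocar
    return obj


def save_timeline(timeline: SurgeryTimeline, path: str | Path) -> None:
    """Write a timeline as the documented JSON dialect (UTF-8)."""
    timeline.validate()
    payload = {
        "video_id": timeline.video_id,
        "duration_s": timeline.duration,
        "fps_source": timeline.fps_source,
        "phases": [_interval_to_obj(iv) for iv in timeline.phase_intervals],
        "actions": [_interval_to_obj(iv) for iv in timeline.action_intervals],
        "instruments": [_interval_to_obj(iv) for iv in timeline.instrument_intervals],
    }
    Path(path).write_text(json.dumps(payload, ensure_ascii=False, indent=1), encoding="utf-8")


def _parse_interval(obj: dict, kind: str, where: str) -> Interval:
    try:
        trocar = obj.get("trocar", NO_TROCAR)
        return Interval(
            start=float(obj["start_s"]),
            end=float(obj["end_s"]),
            label=str(obj["label"]),
            trocar=trocar,
        )
    except KeyError as exc:
        raise TimelineFormatError(f"{where}: missing field {exc} in {kind} entry {obj!r}") from exc


def _validate_labels(timeline: SurgeryTimeline, vocab: LabelVocabulary) -> None:
    for iv in timeline.phase_intervals:
        if iv.label not in vocab.phases:
            raise TimelineValidationError(f"unknown phase label {iv.label!r}")
    for iv in timeline.action_intervals:
        if iv.label not in vocab.actions:
            raise TimelineValidationError(f"unknown action label {iv.label!r}")
    for iv in timeline.instrument_intervals:
        if iv.label not in vocab.instruments:
            raise TimelineValidationError(f"unknown instrument label {iv.label!r}")


def load_timeline(path: str | Path, vocab: LabelVocabulary | None = None) -> SurgeryTimeline:
    """Load and validate a timeline from the JSON or CSV dialect.

    When a vocabulary is given, every interval label must be a member of it.
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return _load_timeline_csv(path, vocab)
    try:
        payload = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise TimelineFormatError(f"{path}: not valid JSON ({exc})") from exc
    for key in ("video_id", "duration_s"):
        if key not in payload:
            raise TimelineFormatError(f"{path}: missing top-level key {key!r}")
    kinds = {
        kind: [_parse_interval(o, kind, str(path)) for o in payload.get(kind, [])]
        for kind in _KIND_KEYS
    }
    timeline = SurgeryTimeline(
        video_id=str(payload["video_id"]),
        duration=float(payload["duration_s"]),
        fps_source=float(payload.get("fps_source", 1.0)),
        phase_intervals=kinds["phases"],
        action_intervals=kinds["actions"],
        instrument_intervals=kinds["instruments"],
    )
    if vocab is not None:
        _validate_labels(timeline, vocab)
    return timeline


def _load_timeline_csv(path: Path, vocab: LabelVocabulary | None) -> SurgeryTimeline:
    """CSV import: columns kind,label,start_s,end_s,trocar (one interval per row).

    The video id defaults to the file stem; duration to the latest interval end.
    """
    try:
        table = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise TimelineFormatError(f"{path}: cannot parse CSV ({exc})") from exc
    required = {"kind", "label", "start_s", "end_s"}
    if not required.issubset(table.columns):
        raise TimelineFormatError(f"{path}: CSV must have columns {sorted(required)}")
    kinds: dict[str, list[Interval]] = {"phase": [], "action": [], "instrument": []}
    for row in table.itertuples(index=False):
        kind = str(row.kind)
        if kind not in kinds:
            raise TimelineFormatError(f"{path}: unknown interval kind {kind!r}")
        trocar = getattr(row, "trocar", NO_TROCAR)
        if pd.isna(trocar) or trocar == "":
            trocar = NO_TROCAR
        kinds[kind].append(
            Interval(float(row.start_s), float(row.end_s), str(row.label), str(trocar))
        )
    all_ivs = kinds["phase"] + kinds["action"] + kinds["instrument"]
    duration = max((iv.end for iv in all_ivs), default=0.0)
    timeline = SurgeryTimeline(
        video_id=path.stem,
        duration=float(duration),
        phase_intervals=kinds["phase"],
        action_intervals=kinds["action"],
        instrument_intervals=kinds["instrument"],
    )
    if vocab is not None:
        _validate_labels(timeline, vocab)
    return timeline
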