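"""Informed post-processing with an instrument-phase compatibility prior.

A binary matrix ``B`` (phases x anticipation classes, idle at column 0)
encodes which instruments are naturally used in which phases of a surgery.
At each frame the instrument distribution ``i`` is reweighted by the
phase-marginalised compatibility

    g_k = sum_alpha p_alpha * B[alpha, k],     a'_k = i_k * g_k / sum(i * g)

where ``p`` is the frame's phase distribution.  With a one-hot phase this
zeroes exactly the incompatible instruments; with ``B`` all ones it is the
identity.  Idle is compatible with every phase by construction, so the
resting-window behaviour is never vetoed.  The reweighting is applied at
inference only, to the final refinement stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .timelines import TROCARS, SurgeryTimeline
from .vocab import IDLE, LabelVocabulary


class CompatibilityError(ValueError):
    pass


@dataclass
class CompatibilityMatrix:
    """Binary phase x (idle + instrument) compatibility matrix."""

    B: np.ndarray
    vocab: LabelVocabulary

    def __post_init__(self):
        self.B = np.asarray(self.B)
        expected = (self.vocab.n_phases, self.vocab.n_anticipation_classes)
        if self.B.shape != expected:
            raise CompatibilityError(f"B must have shape {expected}, got {self.B.shape}")
        if not np.all(np.isin(self.B, (0, 1))):
            raise CompatibilityError("B entries must be 0 or 1")
        if not np.all(self.B[:, IDLE] == 1):
            raise CompatibilityError("the idle column of B must be all ones")
        if np.any(self.B.sum(axis=1) < 1):
            raise CompatibilityError("every phase must allow at least one class")

    @classmethod
    def all_ones(cls, vocab: LabelVocabulary) -> "CompatibilityMatrix":
        return cls(np.ones((vocab.n_phases, vocab.n_anticipation_classes), dtype=np.int64), vocab)

    def to_csv(self, path: str | Path) -> None:
        frame = pd.DataFrame(
            self.B, index=list(self.vocab.phases), columns=list(self.vocab.anticipation_names())
        )
        frame.to_csv(path, index_label="phase")

    @classmethod
    def from_csv(cls, path: str | Path, vocab: LabelVocabulary) -> "CompatibilityMatrix":
        frame = pd.read_csv(path, index_col="phase")
        if list(frame.index) != list(vocab.phases) or list(frame.columns) != list(
            vocab.anticipation_names()
        ):
            raise CompatibilityError("CSV header does not match the vocabulary")
        return cls(frame.to_numpy(), vocab)


def reweight_frame(
    instrument_dist: np.ndarray, phase_dist: np.ndarray, B: CompatibilityMatrix | np.ndarray
) -> np.ndarray:
    """Reweight one frame's instrument distribution by phase compatibility.

    Falls back to the unmodified distribution when the reweighted mass is
    zero (e.g. a one-hot phase that vetoes every predicted class).
    """
    B = B.B if isinstance(B, CompatibilityMatrix) else np.asarray(B)
    i = np.asarray(instrument_dist, dtype=np.float64)
    p = np.asarray(phase_dist, dtype=np.float64)
    if i.shape[0] != B.shape[1] or p.shape[0] != B.shape[0]:
        raise CompatibilityError(
            f"shape mismatch: i has {i.shape[0]} classes, p has {p.shape[0]} phases, "
            f"B is {B.shape}"
        )
    g = p @ B
    a = i * g
    s = a.sum()
    if s <= 0:
        return i.copy()
    return a / s


def reweight_distributions(
    instrument: np.ndarray, phase: np.ndarray, B: CompatibilityMatrix | np.ndarray
) -> np.ndarray:
    """Vectorized :func:`reweight_frame` over a (T, classes) sequence."""
    B = B.B if isinstance(B, CompatibilityMatrix) else np.asarray(B)
    i = np.asarray(instrument, dtype=np.float64)
    p = np.asarray(phase, dtype=np.float64)
    g = p @ B
    a = i * g
    s = a.sum(axis=1, keepdims=True)
    fallback = s[:, 0] <= 0
    out = np.where(s > 0, a / np.where(s > 0, s, 1.0), i)
    if fallback.any():
        out[fallback] = i[fallback]
    return out


@dataclass
class InformedOutput:
    """Final-stage outputs after compatibility reweighting."""

    left: np.ndarray
    right: np.ndarray
    phase: np.ndarray

    def heads(self) -> dict[str, np.ndarray]:
        return {"left": self.left, "right": self.right, "phase": self.phase}


def apply_informed(outputs, B: CompatibilityMatrix | np.ndarray) -> InformedOutput:
    """Reweight the final stage's instrument heads with its phase head."""
    final = outputs.final if hasattr(outputs, "final") else outputs
    phase = final["phase"]
    return InformedOutput(
        left=reweight_distributions(final["left"], phase, B),
        right=reweight_distributions(final["right"], phase, B),
        phase=np.asarray(phase, dtype=np.float64),
    )


def estimate_compatibility(
    timelines: list[SurgeryTimeline], vocab: LabelVocabulary
) -> CompatibilityMatrix:
    """Derive a usage-based B: instrument allowed in a phase iff ever used there.

    The idle column is forced to 1.  Adding timelines can only turn zeros
    into ones (monotone union).
    """
    if not timelines:
        raise CompatibilityError("need at least one timeline to estimate compatibility")
    B = np.zeros((vocab.n_phases, vocab.n_anticipation_classes), dtype=np.int64)
    B[:, IDLE] = 1
    for tl in timelines:
        for trocar in TROCARS:
            for iv in tl.instruments_for(trocar):
                k = vocab.anticipation_index(iv.label)
                for ph in tl.phase_intervals:
                    if ph.start < iv.end and iv.start < ph.end:
                        B[vocab.phase_index(ph.label), k] = 1
    return CompatibilityMatrix(B, vocab)
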