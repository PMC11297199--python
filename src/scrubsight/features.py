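"""Per-frame feature vectors: visual (V), detection (D) and segmentation (S).

The single-frame backbones themselves (a frame-wise CNN classifier, a
detector, a segmenter) are outside this package; what is defined here is
their output contract and the assembly of the concatenated frame feature
vector F = V ‖ D ‖ S consumed by the temporal model.

Block sizes:

* V: 2048 image-embedding values plus ``c_v`` class probabilities
  (instruments + phases + actions; 34 by default), i.e. |V| = 2082.
* D: 6 values per instrument-class slot — class indicator, box x, y, w, h
  in normalized image coordinates, and the box size s = w*h.
* S: 9 values per segmentation-class slot — eccentricity, extent,
  orientation, perimeter, solidity of the largest region, region count,
  area proportion of the frame, and the relative x/y centroid position.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Protocol

import numpy as np
from skimage.measure import label as sk_label
from skimage.measure import regionprops

from .vocab import LabelVocabulary

EMBEDDING_DIM = 2048
DETECTION_SLOT = 6
SEGMENTATION_SLOT = 9


class FeatureDimensionError(ValueError):
    pass


@dataclass
class VisualFeatures:
    """Frame embedding plus class probabilities of the single-frame model."""

    embedding: np.ndarray  # (2048,)
    class_probs: np.ndarray  # (c_v,) in [0, 1]

    def __post_init__(self):
        self.embedding = np.asarray(self.embedding, dtype=np.float32)
        self.class_probs = np.asarray(self.class_probs, dtype=np.float32)
        if self.embedding.shape != (EMBEDDING_DIM,):
            raise FeatureDimensionError(
                f"visual embedding must have shape ({EMBEDDING_DIM},), "
                f"got {self.embedding.shape}"
            )
        if np.any(self.class_probs < -1e-6) or np.any(self.class_probs > 1 + 1e-6):
            raise FeatureDimensionError("class probabilities must lie in [0, 1]")

    @property
    def vector(self) -> np.ndarray:
        return np.concatenate([self.embedding, self.class_probs])


@dataclass
class DetectionFeatures:
    """One 6-value slot per instrument class; empty slots are zero-filled."""

    slots: np.ndarray  # (c_i, 6)

    def __post_init__(self):
        self.slots = np.asarray(self.slots, dtype=np.float32)
        if self.slots.ndim != 2 or self.slots.shape[1] != DETECTION_SLOT:
            raise FeatureDimensionError(
                f"detection slots must have shape (c_i, {DETECTION_SLOT}), got {self.slots.shape}"
            )

    @property
    def vector(self) -> np.ndarray:
        return self.slots.reshape(-1)


@dataclass
class SegmentationFeatures:
    """One 9-value shape-descriptor slot per segmentation class."""

    slots: np.ndarray  # (c_s, 9)

    def __post_init__(self):
        self.slots = np.asarray(self.slots, dtype=np.float32)
        if self.slots.ndim != 2 or self.slots.shape[1] != SEGMENTATION_SLOT:
            raise FeatureDimensionError(
                f"segmentation slots must have shape (c_s, {SEGMENTATION_SLOT}), "
                f"got {self.slots.shape}"
            )

    @property
    def vector(self) -> np.ndarray:
        return self.slots.reshape(-1)


@dataclass(frozen=True)
class BlockLayout:
    """Offsets of the V, D, S blocks inside a concatenated frame vector."""

    c_v: int
    c_i: int
    c_s: int

    @property
    def visual_len(self) -> int:
        return EMBEDDING_DIM + self.c_v

    @property
    def detection_len(self) -> int:
        return DETECTION_SLOT * self.c_i

    @property
    def segmentation_len(self) -> int:
        return SEGMENTATION_SLOT * self.c_s

    @property
    def total_len(self) -> int:
        return self.visual_len + self.detection_len + self.segmentation_len

    def slices(self) -> dict[str, slice]:
        v = self.visual_len
        d = v + self.detection_len
        return {
            "V": slice(0, v),
            "D": slice(v, d),
            "S": slice(d, d + self.segmentation_len),
        }

    @classmethod
    def for_vocab(cls, vocab: LabelVocabulary, c_s: int) -> "BlockLayout":
        c_v = vocab.n_instruments + vocab.n_phases + vocab.n_actions
        return cls(c_v=c_v, c_i=vocab.n_instruments, c_s=c_s)


@dataclass
class FrameFeatureVector:
    """Ordered concatenation V ‖ D ‖ S with recorded block boundaries."""

    vector: np.ndarray
    layout: BlockLayout

    def block(self, name: str) -> np.ndarray:
        return self.vector[self.layout.slices()[name]]


def assemble_frame_features(
    v: VisualFeatures, d: DetectionFeatures, s: SegmentationFeatures
) -> FrameFeatureVector:
    """Concatenate the three blocks, recording their offsets."""
    layout = BlockLayout(c_v=len(v.class_probs), c_i=len(d.slots), c_s=len(s.slots))
    vector = np.concatenate([v.vector, d.vector, s.vector]).astype(np.float32)
    if vector.shape[0] != layout.total_len:  # pragma: no cover - defensive
        raise FeatureDimensionError("assembled vector length does not match layout")
    return FrameFeatureVector(vector=vector, layout=layout)


# ---------------------------------------------------------------------------
# mask shape descriptors
# ---------------------------------------------------------------------------

def shape_descriptors(mask: np.ndarray) -> np.ndarray:
    """Nine shape statistics of a binary class mask.

    Returns ``(eccentricity, extent, orientation, perimeter, solidity,
    region_count, area_proportion, rel_x, rel_y)`` where the first five
    describe the largest connected region, ``region_count`` counts all
    regions, ``area_proportion`` is total foreground area over frame area
    and ``rel_x``/``rel_y`` are the largest region's centroid normalized by
    image width/height.  An empty mask yields the all-zero vector.
    """
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise FeatureDimensionError(f"mask must be 2-D, got shape {mask.shape}")
    uniq = np.unique(mask)
    if not np.all(np.isin(uniq, (0, 1))):
        raise FeatureDimensionError(f"mask must be binary, found values {uniq}")
    if mask.sum() == 0:
        return np.zeros(SEGMENTATION_SLOT, dtype=np.float64)
    h, w = mask.shape
    labelled = sk_label(mask.astype(np.uint8), connectivity=2)
    regions = regionprops(labelled)
    largest = max(regions, key=lambda r: r.area)
    total_area = int(mask.sum())
    cy, cx = largest.centroid  # (row, col)
    return np.array(
        [
            largest.eccentricity,
            largest.extent,
            largest.orientation,
            largest.perimeter,
            largest.solidity,
            float(len(regions)),
            total_area / (h * w),
            cx / w,
            cy / h,
        ],
        dtype=np.float64,
    )


# ---------------------------------------------------------------------------
# extractor plug-in contract
# ---------------------------------------------------------------------------

FrameTriple = tuple[VisualFeatures, DetectionFeatures, SegmentationFeatures]


class FeatureExtractor(Protocol):
    """Anything that maps a frame stream to one (V, D, S) triple per frame."""

    def __call__(self, frames: Iterable) -> list[FrameTriple]: ...


class ExtractorContractError(RuntimeError):
    pass


def run_extractor(extractor: Callable, frames: list) -> list[FrameTriple]:
    """Invoke an extractor and enforce the one-triple-per-frame contract."""
    try:
        triples = extractor(frames)
    except Exception as exc:
        raise ExtractorContractError(f"extractor failed: {exc}") from exc
    triples = list(triples)
    if len(triples) != len(frames):
        raise ExtractorContractError(
            f"extractor returned {len(triples)} triples for {len(frames)} frames"
        )
    for i, triple in enumerate(triples):
        if len(triple) != 3:
            raise ExtractorContractError(f"frame {i}: expected a (V, D, S) triple")
    return triples


def stack_features(triples: list[FrameTriple]) -> tuple[np.ndarray, BlockLayout]:
    """Stack per-frame triples into a (T, |F|) matrix with a shared layout."""
    if not triples:
        raise FeatureDimensionError("cannot stack an empty feature sequence")
    frames = [assemble_frame_features(*t) for t in triples]
    layout = frames[0].layout
    for i, f in enumerate(frames):
        if f.layout != layout:
            raise FeatureDimensionError(f"frame {i}: block layout differs from frame 0")
    return np.stack([f.vector for f in frames]), layout
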