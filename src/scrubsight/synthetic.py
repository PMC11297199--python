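"""Synthetic surgery simulator: timelines and feature streams.

The generator emulates the statistical structure of annotated laparoscopic
cholecystectomies that the anticipation task assumes: ~30-minute surgeries
of 11 ordered phases, a left working trocar whose instrument changes about
4 times per surgery (mainly at phase transitions) and a right working
trocar changing about 20 times (within phases), with every instrument
placement drawn from a phase-compatibility design matrix.

Feature emission stands in for the single-frame CNN/detector backbones.
The visual embedding carries class-conditional signatures of the current
left/right instrument and phase plus, within ``cue_lead_s`` seconds before
each extraction, an additive *cue* signature identifying the NEXT
instrument of that trocar — the minimal mechanism that makes anticipation
(rather than mere recognition) learnable.  The cue lives in the V block
only; D and S encode the currently present instruments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import truncnorm

from .features import (
    DETECTION_SLOT,
    EMBEDDING_DIM,
    SEGMENTATION_SLOT,
    BlockLayout,
    DetectionFeatures,
    FrameTriple,
    SegmentationFeatures,
    VisualFeatures,
)
from .timelines import LEFT, RIGHT, TROCARS, FrameTrack, Interval, SurgeryTimeline, sample_frames
from .vocab import LabelVocabulary

DEFAULT_PHASE_MEANS = (120.0, 90.0, 200.0, 260.0, 180.0, 150.0, 220.0, 160.0, 140.0, 160.0, 120.0)

DEFAULT_SEGMENTATION_CLASSES = (
    "liver",
    "gallbladder",
    "omentum",
    "instrument_tip",
    "instrument_shaft",
)


class SimulationError(ValueError):
    pass


def _default_right_specifics(n_phases: int) -> tuple[tuple[str, ...], ...]:
    """Two rotating phase-specific right-trocar instruments per phase."""
    pool = (
        "clipper",
        "scissors",
        "drain",
        "retrieval_bag",
        "instrument_09",
        "instrument_10",
        "instrument_11",
        "instrument_12",
    )
    return tuple(
        (pool[(2 * p) % len(pool)], pool[(2 * p + 1) % len(pool)]) for p in range(n_phases)
    )


@dataclass(frozen=True)
class SimulatorConfig:
    """Study conditions of the synthetic cohort.

    Change-count defaults follow the cohort statistics the task targets
    (left 4.13 ± 0.78, right 20.0 ± 3.0 changes per surgery); phase-plan
    means sum to 1800 s so surgeries last about 30 minutes.
    ``compat_margin_s`` makes an instrument compatible with every phase it
    may be *anticipated* in, not only used in: the instrument of an
    interval must be allowed in all phases overlapping
    ``[insertion - compat_margin_s, end]``.
    """

    vocab: LabelVocabulary = field(default_factory=LabelVocabulary)
    phase_means: tuple[float, ...] = DEFAULT_PHASE_MEANS
    phase_sd_frac: float = 0.25
    left_pool: tuple[str, ...] = ("grasper", "irrigator", "biopsy_forceps")
    right_universal: tuple[str, ...] = ("coagulation_suction_tube",)
    right_specifics: tuple[tuple[str, ...], ...] | None = None
    left_changes_mean: float = 4.13
    left_changes_sd: float = 0.78
    right_changes_mean: float = 20.0
    right_changes_sd: float = 3.0
    handover_gap_s: float = 5.0
    min_right_gap_s: float = 25.0
    cue_lead_s: float = 6.0
    cue_tail_s: float = 2.0
    cue_strength: float = 1.0
    noise_sd: float = 0.05
    compat_margin_s: float = 15.0
    segmentation_classes: tuple[str, ...] = DEFAULT_SEGMENTATION_CLASSES
    seed: int = 0

    def __post_init__(self):
        if len(self.phase_means) != self.vocab.n_phases:
            raise SimulationError(
                f"phase plan has {len(self.phase_means)} entries for "
                f"{self.vocab.n_phases} phases"
            )
        if not self.phase_means:
            raise SimulationError("phase plan must be non-empty")
        if self.cue_lead_s <= 0:
            raise SimulationError("cue_lead_s must be > 0")
        if self.left_changes_mean <= 0 or self.right_changes_mean < 0:
            raise SimulationError("expected change counts must be positive")
        for name in self.left_pool + self.right_universal:
            if name not in self.vocab.instruments:
                raise SimulationError(f"unknown instrument {name!r} in simulator pools")

    # -- derived ---------------------------------------------------------
    def right_allowed(self) -> list[set[str]]:
        """Allowed right-trocar instruments per phase (universal + specifics)."""
        specifics = self.right_specifics
        if specifics is None:
            specifics = _default_right_specifics(self.vocab.n_phases)
            specifics = tuple(
                tuple(n for n in names if n in self.vocab.instruments) for names in specifics
            )
        return [
            set(self.right_universal) | set(specifics[p] if p < len(specifics) else ())
            for p in range(self.vocab.n_phases)
        ]

    def ground_truth_compatibility(self) -> np.ndarray:
        """Binary phase x (idle + instrument) design matrix of the generator."""
        vocab = self.vocab
        B = np.zeros((vocab.n_phases, vocab.n_anticipation_classes), dtype=np.int64)
        B[:, 0] = 1  # idle compatible with every phase
        for p, allowed in enumerate(self.right_allowed()):
            for name in set(self.left_pool) | allowed:
                B[p, vocab.anticipation_index(name)] = 1
        return B

    def layout(self) -> BlockLayout:
        return BlockLayout.for_vocab(self.vocab, c_s=len(self.segmentation_classes))


# ---------------------------------------------------------------------------
# timeline simulation
# ---------------------------------------------------------------------------

def _phase_durations(config: SimulatorConfig, rng: np.random.Generator) -> np.ndarray:
    means = np.asarray(config.phase_means, dtype=np.float64)
    sds = np.maximum(config.phase_sd_frac * means, 1e-6)
    lo, hi = 0.3 * means, 2.5 * means
    a, b = (lo - means) / sds, (hi - means) / sds
    return truncnorm.rvs(a, b, loc=means, scale=sds, random_state=rng)


def _spaced_times(
    rng: np.random.Generator, n: int, lo: float, hi: float, min_gap: float
) -> np.ndarray:
    """n sorted change times in [lo, hi] separated by at least min_gap."""
    if n <= 0:
        return np.zeros(0)
    if hi - lo < (n - 1) * min_gap:
        # plan is too dense for the surgery length; fall back to even spacing
        return np.linspace(lo, hi, n)
    for _ in range(200):
        times = np.sort(rng.uniform(lo, hi, size=n))
        if n == 1 or np.min(np.diff(times)) >= min_gap:
            return times
    # deterministic fallback: evenly spaced with a small jitter
    base = np.linspace(lo, hi, n)
    slack = min((hi - lo) / max(n, 1) - min_gap, min_gap) / 2
    return base + rng.uniform(-max(slack, 0.0), max(slack, 0.0), size=n)


def _phases_overlapping(boundaries: np.ndarray, start: float, end: float) -> list[int]:
    """Indices of phases whose span intersects [start, end]."""
    out = []
    for p in range(len(boundaries) - 1):
        if boundaries[p] < end and start < boundaries[p + 1]:
            out.append(p)
    return out


def simulate_timeline(config: SimulatorConfig, seed: int) -> SurgeryTimeline:
    """Simulate one annotated surgery.

    Phases follow the plan order with truncated-normal durations; the left
    instrument changes at a sampled subset of phase transitions, the right
    instrument at uniformly spread times within the surgery; every
    placement respects the generator's phase-compatibility design.
    """
    rng = np.random.default_rng(seed)
    vocab = config.vocab
    durations = _phase_durations(config, rng)
    boundaries = np.concatenate([[0.0], np.cumsum(durations)])
    duration = float(boundaries[-1])
    gap = config.handover_gap_s

    phase_ivs = [
        Interval(float(boundaries[p]), float(boundaries[p + 1]), vocab.phases[p])
        for p in range(vocab.n_phases)
    ]
    action_ivs = [
        Interval(iv.start, iv.end, vocab.actions[p % vocab.n_actions])
        for p, iv in enumerate(phase_ivs)
    ]

    instrument_ivs: list[Interval] = []

    # -- left trocar: changes at phase transitions -----------------------
    n_transitions = vocab.n_phases - 1
    k_left = int(np.clip(np.rint(rng.normal(config.left_changes_mean, config.left_changes_sd)),
                         0, n_transitions))
    if len(config.left_pool) < 2:
        k_left = 0 if len(config.left_pool) <= 1 else k_left
    chosen = np.sort(rng.choice(n_transitions, size=k_left, replace=False)) if k_left else []
    seg_bounds = [0.0] + [float(boundaries[i + 1]) for i in chosen] + [duration]
    prev = None
    for j in range(len(seg_bounds) - 1):
        start = seg_bounds[j] + (gap if j > 0 else min(5.0, max(duration / 10, 0.1)))
        end = seg_bounds[j + 1] if j < len(seg_bounds) - 2 else max(duration - 2.0, start + 0.5)
        end = min(end, duration)
        if end <= start:
            continue
        options = [n for n in config.left_pool if n != prev] or list(config.left_pool)
        name = str(rng.choice(sorted(options)))
        instrument_ivs.append(Interval(start, end, name, LEFT))
        prev = name

    # -- right trocar: changes within phases -----------------------------
    k_right = int(np.clip(np.rint(rng.normal(config.right_changes_mean, config.right_changes_sd)),
                          0, 60))
    lo, hi = min(40.0, duration * 0.1), duration - min(30.0, duration * 0.1)
    changes = _spaced_times(rng, k_right, lo, hi, config.min_right_gap_s) if hi > lo else np.zeros(0)
    allowed = config.right_allowed()
    ends = list(changes) + [max(duration - 2.0, 0.0)]
    ins = min(8.0, max(duration / 10, 0.1))
    prev = None
    for end in ends:
        if end <= ins:
            continue
        spanned = _phases_overlapping(boundaries, ins - config.compat_margin_s, end)
        candidates: set[str] = set.intersection(*(allowed[p] for p in spanned)) if spanned else set()
        pool = sorted(candidates - {prev}) or sorted(candidates) or sorted(
            set(config.right_universal) - {prev}
        ) or sorted(config.right_universal)
        name = str(rng.choice(pool))
        instrument_ivs.append(Interval(float(ins), float(end), name, RIGHT))
        prev = name
        ins = float(end) + gap

    return SurgeryTimeline(
        video_id=f"synthetic_{seed:08d}",
        duration=duration,
        fps_source=1.0,
        phase_intervals=phase_ivs,
        action_intervals=action_ivs,
        instrument_intervals=instrument_ivs,
    )


# ---------------------------------------------------------------------------
# feature emission
# ---------------------------------------------------------------------------

def _unit_rows(rng: np.random.Generator, n: int, dim: int) -> np.ndarray:
    rows = rng.standard_normal((n, dim))
    return (rows / np.linalg.norm(rows, axis=1, keepdims=True)).astype(np.float32)


@dataclass
class _SignatureBank:
    """Fixed class-conditional directions in embedding space (per config seed)."""

    left: np.ndarray
    right: np.ndarray
    phase: np.ndarray
    cue_left: np.ndarray
    cue_right: np.ndarray

    @classmethod
    def for_config(cls, config: SimulatorConfig) -> "_SignatureBank":
        rng = np.random.default_rng(config.seed + 987_654_321)
        c_i, c_p = config.vocab.n_instruments, config.vocab.n_phases
        return cls(
            left=_unit_rows(rng, c_i, EMBEDDING_DIM),
            right=_unit_rows(rng, c_i, EMBEDDING_DIM),
            phase=_unit_rows(rng, c_p, EMBEDDING_DIM),
            cue_left=_unit_rows(rng, c_i, EMBEDDING_DIM),
            cue_right=_unit_rows(rng, c_i, EMBEDDING_DIM),
        )


def _cue_track(timeline: SurgeryTimeline, config: SimulatorConfig, trocar: str, T: int) -> np.ndarray:
    """Per-frame instrument index (vocab space) of the upcoming change, or -1."""
    out = np.full(T, -1, dtype=np.int64)
    intervals = timeline.instruments_for(trocar)
    for outgoing, incoming in zip(intervals, intervals[1:]):
        t0 = outgoing.end
        lo = max(int(np.ceil(t0 - config.cue_lead_s)), 0)
        hi = min(int(np.ceil(t0 + config.cue_tail_s)), T)
        out[lo:hi] = config.vocab.instrument_index(incoming.label)
    return out


_ORGAN_BASE = np.array(
    [
        # ecc, extent, orient, perimeter, solidity, count, area, relx, rely
        [0.72, 0.55, 0.30, 140.0, 0.92, 1.0, 0.22, 0.45, 0.35],
        [0.85, 0.50, -0.40, 95.0, 0.88, 1.0, 0.10, 0.55, 0.45],
        [0.60, 0.45, 0.90, 160.0, 0.80, 2.0, 0.15, 0.40, 0.65],
    ]
)
_TIP_BASE = np.array([0.95, 0.40, 0.50, 60.0, 0.85, 1.0, 0.02, 0.50, 0.50])
_SHAFT_BASE = np.array([0.99, 0.35, 0.60, 180.0, 0.75, 1.0, 0.05, 0.50, 0.60])
_PROPORTION_COLS = (1, 4, 6, 7, 8)  # extent, solidity, area proportion, rel x, rel y


def emit_feature_arrays(
    timeline: SurgeryTimeline, config: SimulatorConfig, seed: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Emit stacked per-frame features: V (T, 2082), D (T, c_i, 6), S (T, c_s, 9).

    Deterministic per ``(config, seed)``; with ``noise_sd = 0`` and
    ``cue_strength = 0`` the output is an exact function of the current
    frame labels.
    """
    vocab = config.vocab
    track = sample_frames(timeline, vocab)
    T = track.n_frames
    rng = np.random.default_rng(seed)
    bank = _SignatureBank.for_config(config)
    c_i, c_p, c_a = vocab.n_instruments, vocab.n_phases, vocab.n_actions
    c_s = len(config.segmentation_classes)
    sd = config.noise_sd

    # -- embedding -------------------------------------------------------
    emb = np.zeros((T, EMBEDDING_DIM), dtype=np.float32)
    left_present = track.instr_left >= 0
    right_present = track.instr_right >= 0
    phase_present = track.phase >= 0
    emb[left_present] += 0.5 * bank.left[track.instr_left[left_present]]
    emb[right_present] += 0.5 * bank.right[track.instr_right[right_present]]
    emb[phase_present] += 0.5 * bank.phase[track.phase[phase_present]]
    if config.cue_strength != 0.0:
        for trocar, cues in ((LEFT, bank.cue_left), (RIGHT, bank.cue_right)):
            cue = _cue_track(timeline, config, trocar, T)
            has = cue >= 0
            emb[has] += np.float32(config.cue_strength) * cues[cue[has]]
    if sd > 0:
        emb += sd * rng.standard_normal((T, EMBEDDING_DIM)).astype(np.float32)

    # -- class probabilities --------------------------------------------
    probs = np.zeros((T, c_i + c_p + c_a), dtype=np.float32)
    rows = np.arange(T)
    probs[rows[left_present], track.instr_left[left_present]] = 0.8
    probs[rows[right_present], track.instr_right[right_present]] = 0.8
    probs[rows[phase_present], c_i + track.phase[phase_present]] = 0.9
    action_present = track.action >= 0
    probs[rows[action_present], c_i + c_p + track.action[action_present]] = 0.9
    if sd > 0:
        probs += sd * rng.standard_normal(probs.shape).astype(np.float32)
    np.clip(probs, 0.0, 1.0, out=probs)
    V = np.concatenate([emb, probs], axis=1)

    # -- detection block -------------------------------------------------
    D = np.zeros((T, c_i, DETECTION_SLOT), dtype=np.float32)
    for present, instr, bx in (
        (left_present, track.instr_left, 0.30),
        (right_present, track.instr_right, 0.70),
    ):
        idx = rows[present]
        cls = instr[present]
        n = len(idx)
        jitter = sd * rng.standard_normal((n, 4)).astype(np.float32) if sd > 0 else 0.0
        box = np.tile(np.array([bx, 0.52, 0.18, 0.25], dtype=np.float32), (n, 1)) + jitter
        box[:, :2] = np.clip(box[:, :2], 0.0, 1.0)
        box[:, 2:] = np.clip(box[:, 2:], 0.02, 0.60)
        D[idx, cls, 0] = 1.0
        D[idx, cls, 1:5] = box
        D[idx, cls, 5] = box[:, 2] * box[:, 3]  # s = w * h, exact

    # -- segmentation block ---------------------------------------------
    S = np.zeros((T, c_s, SEGMENTATION_SLOT), dtype=np.float32)
    n_organs = min(3, c_s)
    for k in range(n_organs):
        S[:, k, :] = _ORGAN_BASE[k]
    any_instr = left_present | right_present
    if c_s > 3:
        S[any_instr, 3, :] = _TIP_BASE
        S[any_instr, 3, 5] = left_present[any_instr] + right_present[any_instr]
    if c_s > 4:
        S[any_instr, 4, :] = _SHAFT_BASE
        S[any_instr, 4, 5] = left_present[any_instr] + right_present[any_instr]
    if sd > 0:
        active = S[:, :, 3] > 0  # perimeter > 0 marks an occupied slot
        noise = sd * rng.standard_normal(S.shape).astype(np.float32)
        noise[:, :, 3] *= 20.0  # perimeter lives on a pixel scale
        S += noise * active[:, :, None]
    S[:, :, _PROPORTION_COLS] = np.clip(S[:, :, _PROPORTION_COLS], 0.0, 1.0)

    return V, D, S


def emit_features(
    timeline: SurgeryTimeline, config: SimulatorConfig, seed: int
) -> list[FrameTriple]:
    """Per-frame (V, D, S) triples satisfying the extractor contract."""
    V, D, S = emit_feature_arrays(timeline, config, seed)
    return [
        (
            VisualFeatures(V[t, :EMBEDDING_DIM], V[t, EMBEDDING_DIM:]),
            DetectionFeatures(D[t]),
            SegmentationFeatures(S[t]),
        )
        for t in range(len(V))
    ]


class SyntheticExtractor:
    """Reference :class:`~scrubsight.features.FeatureExtractor` implementation.

    Treats each incoming frame as a frame *index* into a pre-simulated
    timeline and returns the corresponding synthetic (V, D, S) triples.
    """

    def __init__(self, timeline: SurgeryTimeline, config: SimulatorConfig, seed: int = 0):
        self._triples = emit_features(timeline, config, seed)

    def __call__(self, frames) -> list[FrameTriple]:
        return [self._triples[int(i)] for i in frames]


# ---------------------------------------------------------------------------
# datasets
# ---------------------------------------------------------------------------

@dataclass
class SimulatedVideo:
    video_id: str
    timeline: SurgeryTimeline
    track: FrameTrack
    V: np.ndarray
    D: np.ndarray  # (T, c_i, 6)
    S: np.ndarray  # (T, c_s, 9)
    layout: BlockLayout

    @property
    def features(self) -> np.ndarray:
        """Concatenated frame feature matrix F = V ‖ D ‖ S, shape (T, |F|)."""
        T = len(self.V)
        return np.concatenate(
            [self.V, self.D.reshape(T, -1), self.S.reshape(T, -1)], axis=1
        ).astype(np.float32)

    @property
    def n_frames(self) -> int:
        return len(self.V)


@dataclass
class SyntheticDataset:
    videos: list[SimulatedVideo]
    splits: dict[str, list[int]]
    compatibility: np.ndarray  # ground-truth B, (c_p, c_i + 1)
    config: SimulatorConfig

    def split_videos(self, split: str) -> list[SimulatedVideo]:
        return [self.videos[i] for i in self.splits[split]]

    @property
    def vocab(self) -> LabelVocabulary:
        return self.config.vocab

    @property
    def layout(self) -> BlockLayout:
        return self.config.layout()


def simulate_video(config: SimulatorConfig, seed: int) -> SimulatedVideo:
    timeline = simulate_timeline(config, seed)
    V, D, S = emit_feature_arrays(timeline, config, seed + 1)
    return SimulatedVideo(
        video_id=timeline.video_id,
        timeline=timeline,
        track=sample_frames(timeline, config.vocab),
        V=V,
        D=D,
        S=S,
        layout=config.layout(),
    )


def make_dataset(
    config: SimulatorConfig,
    n_videos: int,
    split: tuple[float, float, float] = (0.68, 0.16, 0.16),
    seed: int = 0,
) -> SyntheticDataset:
    """Simulate ``n_videos`` surgeries and split them train/val/test.

    The default 68/16/16 proportions give 34/8/8 videos at ``n_videos=50``.
    """
    if abs(sum(split) - 1.0) > 1e-9:
        raise SimulationError(f"split proportions must sum to 1, got {split}")
    n_train = int(round(n_videos * split[0]))
    n_val = int(round(n_videos * split[1]))
    n_test = n_videos - n_train - n_val
    counts = {"train": n_train, "val": n_val, "test": n_test}
    for name, (count, prop) in zip(counts, zip(counts.values(), split)):
        if count < 0 or (prop > 0 and count == 0):
            raise SimulationError(
                f"n_videos={n_videos} too small for split {split} ({name} would get {count})"
            )
    rng = np.random.default_rng(seed)
    video_seeds = rng.integers(0, 2**31 - 1, size=n_videos)
    videos = [simulate_video(config, int(s)) for s in video_seeds]
    perm = rng.permutation(n_videos)
    splits = {
        "train": sorted(int(i) for i in perm[:n_train]),
        "val": sorted(int(i) for i in perm[n_train : n_train + n_val]),
        "test": sorted(int(i) for i in perm[n_train + n_val :]),
    }
    return SyntheticDataset(
        videos=videos,
        splits=splits,
        compatibility=config.ground_truth_compatibility(),
        config=config,
    )


def short_config(**overrides) -> SimulatorConfig:
    """A scaled-down configuration (~6-minute surgeries) for quick experiments."""
    means = tuple(m / 5.0 for m in DEFAULT_PHASE_MEANS)
    defaults = dict(
        phase_means=means,
        left_changes_mean=3.0,
        left_changes_sd=0.7,
        right_changes_mean=8.0,
        right_changes_sd=1.5,
        min_right_gap_s=25.0,
    )
    defaults.update(overrides)
    return SimulatorConfig(**defaults)
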