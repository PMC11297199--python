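"""Causal multi-stage temporal anticipation networks.

Two backbones map a frame-feature sequence (T, |F|) to per-frame class
distributions for three heads — next-instrument left trocar, next-
instrument right trocar (both over idle + instruments) and surgical phase:

* ``causal-tcn``: a causalized multi-stage temporal convolutional network —
  dilated temporal convolutions (dilation doubling per layer) with
  left-only padding and residual 1x1 mixing.
* ``causal-ltcontext``: dilated causal convolutions interleaved with
  windowed local self-attention and strided long-term context attention,
  both with future positions masked out.

Every stage beyond the first consumes the previous stage's concatenated
head distributions (refinement), optionally concatenated with the raw
features.  All heads exist at every stage and enter the per-stage loss.

Training follows full-video batches (batch size = video length) with Adam
and a linear learning-rate warm-up; the returned weights are those of the
epoch with the best validation weighted F1.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from . import autodiff as ad
from .objective import LossParams, frame_supervision, sequence_loss_graph
from .timelines import LEFT, RIGHT, TROCARS
from .vocab import LabelVocabulary
from .windowing import WindowParams, WindowSchedule, build_window_schedule

logger = logging.getLogger(__name__)

BACKBONES = ("causal-tcn", "causal-ltcontext")

#: training defaults of the full-scale reference setup: Adam, initial
#: learning rate 5e-5, 550 epochs with 70 warm-up epochs, one video per batch
FULL_SCALE_TRAINING = {"lr": 5e-5, "epochs": 550, "warmup_epochs": 70}


class ModelConfigError(ValueError):
    pass


class TrainingDivergedError(RuntimeError):
    pass


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    The full-scale reference uses ``stages=1`` and ``layers=8``; the
    desk-scale default here keeps one stage with 4 layers and hidden width
    32, which a single CPU trains in minutes.
    """

    backbone: str = "causal-tcn"
    stages: int = 1
    layers: int = 4
    hidden: int = 32
    kernel_size: int = 3
    local_window: int = 16
    lt_stride: int = 8
    dropout: float = 0.0
    stage_feature_passthrough: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.backbone not in BACKBONES:
            raise ModelConfigError(f"backbone must be one of {BACKBONES}, got {self.backbone!r}")
        if self.stages < 1 or self.layers < 1:
            raise ModelConfigError("stages and layers must both be >= 1")


@dataclass
class StageOutputs:
    """Per-stage, per-frame head distributions (probabilities, rows sum to 1)."""

    stages: list[dict[str, np.ndarray]]

    def __len__(self) -> int:
        return len(self.stages)

    @property
    def final(self) -> dict[str, np.ndarray]:
        return self.stages[-1]


# ---------------------------------------------------------------------------
# parameter initialisation
# ---------------------------------------------------------------------------

def _he(rng: np.random.Generator, *shape) -> np.ndarray:
    fan_in = int(np.prod(shape[:-1])) or 1
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class TemporalAnticipationNet:
    """A multi-stage causal network with three output heads per stage."""

    def __init__(
        self,
        config: ModelConfig,
        feature_dim: int,
        n_anticipation: int,
        n_phases: int,
    ):
        self.config = config
        self.feature_dim = feature_dim
        self.n_anticipation = n_anticipation
        self.n_phases = n_phases
        self.params: dict[str, ad.Tensor] = {}
        # per-dimension input standardization (fitted on the training split)
        self.norm_mean = np.zeros(feature_dim, dtype=np.float32)
        self.norm_sd = np.ones(feature_dim, dtype=np.float32)
        rng = np.random.default_rng(config.seed)
        head_dim = 2 * n_anticipation + n_phases
        for m in range(config.stages):
            in_dim = feature_dim if m == 0 else head_dim
            if m > 0 and config.stage_feature_passthrough:
                in_dim += feature_dim
            self._init_stage(m, in_dim, rng)

    # -- parameters ------------------------------------------------------
    def _add(self, name: str, value: np.ndarray) -> None:
        self.params[name] = ad.Tensor(value, requires_grad=True)

    def _init_stage(self, m: int, in_dim: int, rng: np.random.Generator) -> None:
        cfg = self.config
        H, K = cfg.hidden, cfg.kernel_size
        self._add(f"s{m}.in.w", _he(rng, in_dim, H))
        self._add(f"s{m}.in.b", np.zeros(H, dtype=np.float32))
        for l in range(cfg.layers):
            self._add(f"s{m}.l{l}.conv.w", _he(rng, K, H, H))
            self._add(f"s{m}.l{l}.conv.b", np.zeros(H, dtype=np.float32))
            self._add(f"s{m}.l{l}.mix.w", _he(rng, H, H))
            self._add(f"s{m}.l{l}.mix.b", np.zeros(H, dtype=np.float32))
            if cfg.backbone == "causal-ltcontext":
                for att in ("loc", "ltc"):
                    for proj in ("q", "k", "v"):
                        self._add(f"s{m}.l{l}.{att}.{proj}.w", _he(rng, H, H))
                    # zero-initialised output projection: the attention branch
                    # starts as the identity and is grown in by the optimiser
                    self._add(f"s{m}.l{l}.{att}.out.w", np.zeros((H, H), dtype=np.float32))
                    self._add(f"s{m}.l{l}.{att}.out.b", np.zeros(H, dtype=np.float32))
        for head, dim in (
            ("left", self.n_anticipation),
            ("right", self.n_anticipation),
            ("phase", self.n_phases),
        ):
            self._add(f"s{m}.head.{head}.w", _he(rng, H, dim))
            self._add(f"s{m}.head.{head}.b", np.zeros(dim, dtype=np.float32))

    def parameters(self) -> list[ad.Tensor]:
        return list(self.params.values())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in self.params.items():
            v.data = np.asarray(state[k], dtype=v.data.dtype)

    # -- attention masks -------------------------------------------------
    _mask_cache: dict[tuple, np.ndarray] = {}

    @classmethod
    def _local_mask(cls, T: int, window: int) -> np.ndarray:
        key = ("loc", T, window)
        if key not in cls._mask_cache:
            t = np.arange(T)
            allowed = (t[None, :] <= t[:, None]) & (t[:, None] - t[None, :] < window)
            cls._mask_cache[key] = np.where(allowed, 0.0, -np.inf).astype(np.float32)
        return cls._mask_cache[key]

    @classmethod
    def _strided_mask(cls, T: int, stride: int) -> np.ndarray:
        key = ("ltc", T, stride)
        if key not in cls._mask_cache:
            t = np.arange(T)
            causal = t[None, :] <= t[:, None]
            strided = (t[None, :] % stride == 0) | (t[None, :] == t[:, None])
            cls._mask_cache[key] = np.where(causal & strided, 0.0, -np.inf).astype(np.float32)
        return cls._mask_cache[key]

    # -- forward ---------------------------------------------------------
    def _attention(self, h: ad.Tensor, m: int, l: int, att: str, mask: np.ndarray) -> ad.Tensor:
        p = self.params
        pre = f"s{m}.l{l}.{att}"
        q = ad.matmul(h, p[f"{pre}.q.w"])
        k = ad.matmul(h, p[f"{pre}.k.w"])
        v = ad.matmul(h, p[f"{pre}.v.w"])
        scores = ad.mul(ad.matmul(q, ad.transpose(k)), 1.0 / np.sqrt(self.config.hidden))
        attn = ad.softmax(ad.add(scores, mask), axis=-1)
        ctx = ad.matmul(attn, v)
        return ad.add(ad.matmul(ctx, p[f"{pre}.out.w"]), p[f"{pre}.out.b"])

    def _stage_forward(self, m: int, x: ad.Tensor) -> dict[str, ad.Tensor]:
        cfg = self.config
        p = self.params
        T = x.data.shape[0]
        h = ad.add(ad.matmul(x, p[f"s{m}.in.w"]), p[f"s{m}.in.b"])
        for l in range(cfg.layers):
            dilation = 2**l
            z = ad.relu(
                ad.causal_conv1d(
                    h, p[f"s{m}.l{l}.conv.w"], p[f"s{m}.l{l}.conv.b"], dilation=dilation
                )
            )
            if cfg.backbone == "causal-ltcontext":
                z = ad.add(z, self._attention(z, m, l, "loc", self._local_mask(T, cfg.local_window)))
                z = ad.add(z, self._attention(z, m, l, "ltc", self._strided_mask(T, cfg.lt_stride)))
            z = ad.add(ad.matmul(z, p[f"s{m}.l{l}.mix.w"]), p[f"s{m}.l{l}.mix.b"])
            h = ad.add(h, z)  # residual refinement
        heads = {}
        for head in ("left", "right", "phase"):
            logits = ad.add(ad.matmul(h, p[f"s{m}.head.{head}.w"]), p[f"s{m}.head.{head}.b"])
            heads[head] = ad.softmax(logits, axis=-1)
        return heads

    def set_normalizer(self, mean: np.ndarray, sd: np.ndarray) -> None:
        self.norm_mean = np.asarray(mean, dtype=np.float32)
        self.norm_sd = np.maximum(np.asarray(sd, dtype=np.float32), 1e-6)

    def forward_graph(self, features: np.ndarray) -> list[dict[str, ad.Tensor]]:
        """Forward pass returning autodiff tensors (one head dict per stage)."""
        features = (np.asarray(features, dtype=np.float32) - self.norm_mean) / self.norm_sd
        x = ad.Tensor(features)
        stages = []
        for m in range(self.config.stages):
            if m == 0:
                inp = x
            else:
                prev = stages[-1]
                parts = [prev["left"], prev["right"], prev["phase"]]
                if self.config.stage_feature_passthrough:
                    parts.append(x)
                inp = ad.concat(parts, axis=-1)
            stages.append(self._stage_forward(m, inp))
        return stages

    def forward(self, features: np.ndarray) -> StageOutputs:
        """Inference forward pass: per-stage head probability arrays.

        Causal by construction: outputs at frame ``t`` depend only on
        features at frames ``<= t``.
        """
        features = np.asarray(features, dtype=np.float32)
        if features.ndim != 2 or features.shape[1] != self.feature_dim:
            raise ModelConfigError(
                f"expected features of shape (T, {self.feature_dim}), got {features.shape}"
            )
        if features.shape[0] == 0:
            empty = {
                "left": np.zeros((0, self.n_anticipation)),
                "right": np.zeros((0, self.n_anticipation)),
                "phase": np.zeros((0, self.n_phases)),
            }
            return StageOutputs([dict(empty) for _ in range(self.config.stages)])
        graphs = self.forward_graph(features)
        return StageOutputs(
            [{k: np.asarray(v.data, dtype=np.float64) for k, v in g.items()} for g in graphs]
        )


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings; defaults are the desk-scale configuration."""

    epochs: int = 50
    lr: float = 3e-3
    warmup_epochs: int = 5
    weight_decay: float = 1e-3
    input_noise_sd: float = 0.5  # augmentation noise on standardized features
    window_params: WindowParams = field(default_factory=WindowParams)
    val_every: int = 5
    seed: int = 0

    @classmethod
    def full_scale(cls, **overrides) -> "TrainConfig":
        """The reference full-scale setup (lr 5e-5, 550 epochs, 70 warm-up)."""
        kwargs = dict(FULL_SCALE_TRAINING)
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass
class _PreparedVideo:
    video_id: str
    features: np.ndarray
    schedule: WindowSchedule
    sup: dict
    phase_track: np.ndarray


def _prepare(videos, vocab: LabelVocabulary, wp: WindowParams, lp: LossParams):
    prepared = []
    for v in videos:
        schedule = build_window_schedule(v.track, v.timeline, wp, vocab)
        prepared.append(
            _PreparedVideo(
                video_id=v.video_id,
                features=v.features,
                schedule=schedule,
                sup=frame_supervision(schedule, v.n_frames, lp),
                phase_track=v.track.phase,
            )
        )
    return prepared


def fit(
    dataset,
    model_config: ModelConfig,
    loss_params: LossParams | None = None,
    train_config: TrainConfig | None = None,
    resume_state: dict | None = None,
) -> tuple[TemporalAnticipationNet, pd.DataFrame]:
    """Train a temporal anticipation network on a synthetic dataset.

    One optimisation step per video per epoch (full-video batches).  The
    returned network carries the weights of the epoch with the best
    validation weighted F1 (sequence-based); when the validation split is
    empty, the final weights are kept.  Deterministic given the seeds in
    ``model_config`` and ``train_config``.
    """
    from .evaluation import evaluate_videos  # local import: avoid cycle

    loss_params = loss_params or LossParams()
    train_config = train_config or TrainConfig()
    vocab = dataset.vocab
    train_videos = dataset.split_videos("train")
    if not train_videos:
        raise ModelConfigError("training split is empty")
    val_videos = dataset.split_videos("val")
    wp = train_config.window_params

    train_prep = _prepare(train_videos, vocab, wp, loss_params)
    val_prep = _prepare(val_videos, vocab, wp, loss_params)

    feature_dim = train_prep[0].features.shape[1]
    net = TemporalAnticipationNet(
        model_config,
        feature_dim=feature_dim,
        n_anticipation=vocab.n_anticipation_classes,
        n_phases=vocab.n_phases,
    )
    stacked = np.concatenate([pv.features for pv in train_prep], axis=0)
    net.set_normalizer(stacked.mean(axis=0), stacked.std(axis=0))
    del stacked
    opt = ad.Adam(net.parameters(), lr=train_config.lr, weight_decay=train_config.weight_decay)
    start_epoch = 0
    if resume_state is not None:
        net.load_state_dict(resume_state["weights"])
        start_epoch = int(resume_state.get("epoch", 0))
    rng = np.random.default_rng(train_config.seed)

    log_rows = []
    best = {"wf1": -np.inf, "state": net.state_dict(), "epoch": -1}
    for epoch in range(start_epoch, train_config.epochs):
        lr_scale = min(1.0, (epoch + 1) / max(train_config.warmup_epochs, 1))
        order = rng.permutation(len(train_prep))
        epoch_loss = 0.0
        for idx in order:
            pv = train_prep[idx]
            opt.zero_grad()
            feats = pv.features
            if train_config.input_noise_sd > 0:
                feats = feats + (
                    train_config.input_noise_sd
                    * net.norm_sd
                    * rng.standard_normal(feats.shape, dtype=np.float32)
                )
            stages = net.forward_graph(feats)
            loss = sequence_loss_graph(stages, pv.sup, pv.phase_track, loss_params)
            value = float(loss.data)
            if not np.isfinite(value):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}, video {pv.video_id}"
                )
            loss.backward()
            opt.step(lr_scale=lr_scale)
            epoch_loss += value
        epoch_loss /= len(train_prep)

        val_wf1 = np.nan
        is_val_epoch = val_prep and (
            (epoch + 1) % train_config.val_every == 0 or epoch == train_config.epochs - 1
        )
        if is_val_epoch:
            report = evaluate_videos(
                [(net.forward(pv.features).final, pv.schedule) for pv in val_prep], vocab
            )
            val_wf1 = report.weighted["f1"]["mean"]
            if val_wf1 > best["wf1"]:
                best = {"wf1": val_wf1, "state": net.state_dict(), "epoch": epoch}
        log_rows.append({"epoch": epoch, "train_loss": epoch_loss, "val_wf1": val_wf1})
        logger.info("epoch %d: loss %.4f val_wf1 %s", epoch, epoch_loss, val_wf1)

    if val_prep and best["epoch"] >= 0:
        net.load_state_dict(best["state"])
    return net, pd.DataFrame(log_rows)


# ---------------------------------------------------------------------------
# streaming inference
# ---------------------------------------------------------------------------

def streaming_infer(
    feature_stream: Iterable[np.ndarray], net: TemporalAnticipationNet
) -> Iterator[dict[str, np.ndarray]]:
    """Online per-frame inference, prefix-consistent with batch ``forward``.

    Each yielded dict holds the final-stage head distributions of the
    newest frame, computed from the feature prefix observed so far.  The
    implementation re-runs the causal forward pass on the growing prefix,
    trading compute for exact prefix consistency.
    """
    buffer: list[np.ndarray] = []
    for frame in feature_stream:
        buffer.append(np.asarray(frame, dtype=np.float32))
        out = net.forward(np.stack(buffer)).final
        yield {k: v[-1] for k, v in out.items()}


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

class CheckpointError(RuntimeError):
    pass


def save_checkpoint(
    path: str | Path,
    net: TemporalAnticipationNet,
    vocab: LabelVocabulary,
    extra: dict | None = None,
) -> None:
    """Serialize weights + architecture config + vocabulary hash (.npz)."""
    meta = {
        "model_config": asdict(net.config),
        "feature_dim": net.feature_dim,
        "n_anticipation": net.n_anticipation,
        "n_phases": net.n_phases,
        "vocab_hash": vocab.hash(),
        "extra": extra or {},
    }
    arrays = {f"param::{k}": v for k, v in net.state_dict().items()}
    arrays["norm::mean"] = net.norm_mean
    arrays["norm::sd"] = net.norm_sd
    np.savez(Path(path), __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path, vocab: LabelVocabulary) -> TemporalAnticipationNet:
    """Load a checkpoint, refusing on a vocabulary mismatch."""
    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta["vocab_hash"] != vocab.hash():
            raise CheckpointError(
                "checkpoint was trained with a different label vocabulary "
                f"(hash {meta['vocab_hash']} != {vocab.hash()})"
            )
        net = TemporalAnticipationNet(
            ModelConfig(**meta["model_config"]),
            feature_dim=int(meta["feature_dim"]),
            n_anticipation=int(meta["n_anticipation"]),
            n_phases=int(meta["n_phases"]),
        )
        net.load_state_dict(
            {k[len("param::") :]: data[k] for k in data.files if k.startswith("param::")}
        )
        if "norm::mean" in data.files:
            net.set_normalizer(data["norm::mean"], data["norm::sd"])
    return net
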