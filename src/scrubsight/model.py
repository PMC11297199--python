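"""High-level modelling interface: a Model fitted to data yields Results.

`InstrumentAnticipationModel` bundles a (synthetic or loaded) dataset with
the architecture, loss and window parameters; ``fit()`` trains the causal
temporal network and returns an :class:`InstrumentAnticipationResults`
carrying the learned weights, the training log and evaluation /
simulation / plotting methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluation import (
    MetricReport,
    evaluate_model,
    idle_baseline_heads,
    occlusion_ablation,
)
from .informed import CompatibilityMatrix, estimate_compatibility
from .objective import LossParams
from .synthetic import SimulatorConfig, SyntheticDataset, make_dataset
from .temporal import (
    ModelConfig,
    StageOutputs,
    TemporalAnticipationNet,
    TrainConfig,
    fit as _fit,
    load_checkpoint,
    save_checkpoint,
)
from .windowing import WindowParams


class InstrumentAnticipationModel:
    """Instrument-anticipation model over per-frame feature sequences.

    Parameters
    ----------
    dataset : SyntheticDataset
        Videos with features, timelines and train/val/test splits.
    model_config, loss_params, window_params : optional
        Architecture, objective and task-timing settings; defaults follow
        the package's desk-scale configuration.
    """

    def __init__(
        self,
        dataset: SyntheticDataset,
        model_config: ModelConfig | None = None,
        loss_params: LossParams | None = None,
        window_params: WindowParams | None = None,
    ):
        self.dataset = dataset
        self.model_config = model_config or ModelConfig()
        self.loss_params = loss_params or LossParams()
        self.window_params = window_params or WindowParams()

    @classmethod
    def from_simulator(
        cls,
        sim_config: SimulatorConfig | None = None,
        n_videos: int = 13,
        split: tuple[float, float, float] = (10 / 13, 0.0, 3 / 13),
        seed: int = 0,
        **kwargs,
    ) -> "InstrumentAnticipationModel":
        """Build a model over a freshly simulated cohort."""
        config = sim_config or SimulatorConfig()
        return cls(make_dataset(config, n_videos, split=split, seed=seed), **kwargs)

    def fit(
        self, train_config: TrainConfig | None = None, resume_state: dict | None = None
    ) -> "InstrumentAnticipationResults":
        train_config = train_config or TrainConfig(window_params=self.window_params)
        net, log = _fit(
            self.dataset,
            self.model_config,
            loss_params=self.loss_params,
            train_config=train_config,
            resume_state=resume_state,
        )
        return InstrumentAnticipationResults(self, net, log, train_config)


@dataclass
class InstrumentAnticipationResults:
    """Fitted anticipation model: weights, training log and diagnostics."""

    model: InstrumentAnticipationModel
    net: TemporalAnticipationNet
    log: pd.DataFrame
    train_config: TrainConfig
    _baseline_cache: dict = field(default_factory=dict, repr=False)

    # -- prediction ------------------------------------------------------
    def predict(self, features: np.ndarray) -> StageOutputs:
        """Per-stage head distributions for a feature sequence."""
        return self.net.forward(features)

    # -- evaluation ------------------------------------------------------
    def evaluate(
        self,
        split: str = "test",
        informed: bool | CompatibilityMatrix | np.ndarray = False,
        occlude_block: str | None = None,
    ) -> MetricReport:
        """Sequence-based metric report on a dataset split.

        ``informed=True`` uses the dataset's ground-truth compatibility
        matrix; a :class:`CompatibilityMatrix` (or raw binary array) may be
        passed instead.
        """
        if informed is True:
            compatibility = self.model.dataset.compatibility
        elif informed is False:
            compatibility = None
        elif isinstance(informed, CompatibilityMatrix):
            compatibility = informed.B
        else:
            compatibility = np.asarray(informed)
        return evaluate_model(
            self.net,
            self.model.dataset,
            split=split,
            window_params=self.model.window_params,
            compatibility=compatibility,
            occlude_block=occlude_block,
        )

    def occlusion_ablation(self, block: str, split: str = "test") -> float:
        """-Delta wAF1 when the given feature block (V/D/S) is zeroed."""
        key = split
        if key not in self._baseline_cache:
            self._baseline_cache[key] = self.evaluate(split).weighted["f1"]["mean"]
        return occlusion_ablation(
            self.net,
            self.model.dataset,
            block,
            split=split,
            window_params=self.model.window_params,
            baseline=self._baseline_cache[key],
        )

    def estimated_compatibility(self, split: str = "train") -> CompatibilityMatrix:
        """Usage-derived compatibility matrix from the split's timelines."""
        videos = self.model.dataset.split_videos(split)
        return estimate_compatibility([v.timeline for v in videos], self.model.dataset.vocab)

    # -- reporting -------------------------------------------------------
    def summary(self, split: str = "test") -> str:
        report = self.evaluate(split)
        cfg = self.net.config
        lines = [
            "Instrument anticipation results",
            "=" * 31,
            f"backbone: {cfg.backbone}  stages: {cfg.stages}  layers: {cfg.layers}  "
            f"hidden: {cfg.hidden}",
            f"epochs trained: {len(self.log)}  final train loss: "
            f"{self.log['train_loss'].iloc[-1]:.4f}" if len(self.log) else "no training log",
            f"evaluation split: {split}",
            report.summary(),
        ]
        return "\n".join(lines)

    def plot_training(self, ax=None):
        """Training-loss and validation-wAF1 curves."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.log["epoch"], self.log["train_loss"], label="train loss")
        ax.set_xlabel("epoch")
        ax.set_ylabel("loss")
        val = self.log.dropna(subset=["val_wf1"])
        if len(val):
            twin = ax.twinx()
            twin.plot(val["epoch"], val["val_wf1"], color="C1", label="val wAF1")
            twin.set_ylabel("validation wAF1")
        ax.legend(loc="upper right")
        return ax

    # -- baselines -------------------------------------------------------
    def idle_baseline(self, split: str = "test") -> MetricReport:
        """Score of the always-idle predictor on the split's schedules."""
        from .evaluation import evaluate_videos
        from .windowing import build_window_schedule

        dataset = self.model.dataset
        items = []
        for video in dataset.split_videos(split):
            schedule = build_window_schedule(
                video.track, video.timeline, self.model.window_params, dataset.vocab
            )
            items.append((idle_baseline_heads(video.n_frames, dataset.vocab), schedule))
        return evaluate_videos(items, dataset.vocab)

    # -- persistence -----------------------------------------------------
    def save(self, path: str | Path) -> None:
        save_checkpoint(path, self.net, self.model.dataset.vocab)

    @classmethod
    def load(
        cls, path: str | Path, model: InstrumentAnticipationModel
    ) -> "InstrumentAnticipationResults":
        net = load_checkpoint(path, model.dataset.vocab)
        empty_log = pd.DataFrame(columns=["epoch", "train_loss", "val_wf1"])
        return cls(model, net, empty_log, TrainConfig(window_params=model.window_params))
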