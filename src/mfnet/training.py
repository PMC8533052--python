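"""Supervised training, evaluation and the k-fold cross-validation harness.

Training follows the published recipe: Adam with learning rate 5e-4 and
weight decay 1e-4, batch size 4, 50 epochs, optimising the joint
Dice + BCE loss.  There is no learning-rate schedule and no augmentation by
default; both can be injected via ``epoch_hook``/``augment`` if needed.
Model selection takes the epoch with the best validation Dice score.

Everything is seeded: weight initialisation from ``config.seed``, shuffling
from a generator derived from it, so two runs with the same configuration
produce identical losses and weights.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from . import autodiff as F
from .autodiff import no_grad
from .backbone import MFNet, NetworkConfig
from .data_io import REAL_LABEL, UNLABELED, FoldSplit, OCTSample, make_folds, preprocess
from .losses_metrics import (MetricsReport, joint_loss_per_sample,
                             segmentation_metrics)
from .nn import Adam


@dataclass
class TrainConfig:
    lr: float = 5e-4
    weight_decay: float = 1e-4
    batch_size: int = 4
    epochs: int = 50
    seed: int = 0
    device: str = "cpu"
    network: NetworkConfig = field(default_factory=NetworkConfig)
    threshold: float = 0.5

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("lr must be > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")

    @classmethod
    def from_config_dict(cls, cfg: dict) -> "TrainConfig":
        model = cfg.get("model", {})
        optim = cfg.get("optim", {})
        return cls(lr=optim.get("lr", 5e-4),
                   weight_decay=optim.get("weight_decay", 1e-4),
                   batch_size=optim.get("batch_size", 4),
                   epochs=optim.get("epochs", 50),
                   seed=cfg.get("seed", 0),
                   network=NetworkConfig(
                       base_channels=model.get("base_channels", 64),
                       use_mad=model.get("use_mad", True),
                       use_sda=model.get("use_sda", True),
                       input_size=tuple(model.get("input_size", (256, 256)))))


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_dsc: list[float] = field(default_factory=list)
    best_epoch: int = -1
    checkpoint_path: str | None = None


@dataclass
class Checkpoint:
    state: dict[str, np.ndarray]
    network: NetworkConfig

    def build(self) -> MFNet:
        net = MFNet(self.network)
        net.load_state_dict(self.state)
        return net


# ---------------------------------------------------------------------------
# batching helpers
# ---------------------------------------------------------------------------

def _sized(samples: Sequence[OCTSample], size: tuple[int, int]
           ) -> list[OCTSample]:
    return [preprocess(s, size) for s in samples]


def _stack(samples: Sequence[OCTSample]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([s.image for s in samples])[:, None].astype(np.float32)
    y = np.stack([s.mask for s in samples])[:, None].astype(np.float32)
    return x, y


def predict_batch(model: MFNet, samples: Sequence[OCTSample],
                  batch_size: int = 8) -> np.ndarray:
    """Probability maps (N, H, W) for preprocessed samples, eval mode."""
    if not samples:
        h, w = model.config.input_size
        return np.zeros((0, h, w), dtype=np.float32)
    was_training = model.training
    model.eval()
    outs = []
    try:
        with no_grad():
            for i in range(0, len(samples), batch_size):
                chunk = samples[i:i + batch_size]
                x = np.stack([s.image for s in chunk])[:, None].astype(np.float32)
                outs.append(model(x).data[:, 0])
    finally:
        if was_training:
            model.train()
    return np.concatenate(outs)


# ---------------------------------------------------------------------------
# supervised training
# ---------------------------------------------------------------------------

def train_supervised(config: TrainConfig,
                     train_samples: Sequence[OCTSample],
                     val_samples: Sequence[OCTSample],
                     loss_weights: Callable[[Sequence[OCTSample]], np.ndarray] | None = None,
                     initial_state: dict[str, np.ndarray] | None = None,
                     epoch_hook: Callable[[int, float, float], None] | None = None,
                     ) -> tuple[Checkpoint, TrainHistory]:
    """Train MF-Net on labelled samples; returns best-val-DSC checkpoint.

    ``loss_weights`` maps a batch to per-sample loss weights (used by the
    semi-supervised retraining); by default every sample weighs 1/batch.
    ``initial_state`` warm-starts the weights.
    """
    for s in train_samples:
        if s.provenance == UNLABELED or s.mask is None:
            raise ValueError(f"unlabeled sample {s.id!r} in training set")
        if loss_weights is None and s.provenance != REAL_LABEL:
            raise ValueError(
                f"sample {s.id!r} has provenance {s.provenance!r}; supervised "
                "training expects real labels")

    size = config.network.input_size
    train = _sized(train_samples, size)
    val = _sized(val_samples, size)

    model = MFNet(config.network, seed=config.seed)
    if initial_state is not None:
        model.load_state_dict(initial_state)
    opt = Adam(model.parameters(), lr=config.lr,
               weight_decay=config.weight_decay)
    shuffle_rng = np.random.default_rng(config.seed + 1)

    history = TrainHistory()
    best_dsc, best_state = -1.0, model.state_dict()
    for epoch in range(config.epochs):
        model.train()
        order = shuffle_rng.permutation(len(train))
        total, count = 0.0, 0
        for start in range(0, len(train), config.batch_size):
            batch = [train[i] for i in order[start:start + config.batch_size]]
            x, y = _stack(batch)
            opt.zero_grad()
            per_sample = joint_loss_per_sample(model(x), y)
            if loss_weights is None:
                w = np.full(len(batch), 1.0 / len(batch), dtype=np.float64)
            else:
                w = np.asarray(loss_weights(batch), dtype=np.float64)
            loss = F.tsum(F.mul(per_sample, w))
            loss.backward()
            opt.step()
            total += float((per_sample.data * w).sum()) * len(batch)
            count += len(batch)
        mean_loss = total / count
        val_dsc = evaluate_model(model, val, threshold=config.threshold).mean_dsc \
            if val else float("nan")
        history.train_loss.append(mean_loss)
        history.val_dsc.append(val_dsc)
        if val and val_dsc > best_dsc:
            best_dsc, best_state = val_dsc, model.state_dict()
            history.best_epoch = epoch
        if epoch_hook is not None:
            epoch_hook(epoch, mean_loss, val_dsc)
    if not val:  # no validation set: keep final weights
        best_state = model.state_dict()
        history.best_epoch = config.epochs - 1
    return Checkpoint(state=best_state, network=config.network), history


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def evaluate_model(model_or_checkpoint,
                   samples: Sequence[OCTSample],
                   threshold: float = 0.5,
                   fold_id: int | None = None,
                   csv_path=None) -> MetricsReport:
    """Per-image (DSC, SEN, JSC) and mean +/- SD for labelled samples."""
    model = (model_or_checkpoint.build()
             if isinstance(model_or_checkpoint, Checkpoint)
             else model_or_checkpoint)
    samples = _sized(samples, model.config.input_size)
    for s in samples:
        if s.mask is None:
            raise ValueError(f"sample {s.id!r} has no mask; cannot evaluate")
    probs = predict_batch(model, samples)
    per_image = [segmentation_metrics(p, s.mask, threshold)
                 for p, s in zip(probs, samples)]
    report = MetricsReport(per_image=per_image, fold_id=fold_id)
    if csv_path is not None:
        with open(csv_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["id", "dsc", "sen", "jsc"])
            for s, (d, se, j) in zip(samples, per_image):
                writer.writerow([s.id, f"{d:.4f}", f"{se:.4f}", f"{j:.4f}"])
    return report


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def cross_validate(config: TrainConfig, dataset: Sequence[OCTSample],
                   k: int = 4, out_dir=None,
                   folds: FoldSplit | None = None) -> list[MetricsReport]:
    """k-fold cross-validation: train on k-1 folds, evaluate on the held-out one.

    Returns one MetricsReport per fold; with ``out_dir`` also writes one
    per-image CSV per fold plus a summary CSV of per-fold means (the input
    to paired significance tests).
    """
    if k > len(dataset):
        raise ValueError(f"k={k} exceeds dataset size {len(dataset)}")
    by_id = {s.id: s for s in dataset}
    if folds is None:
        folds = make_folds(list(by_id), k=k, seed=config.seed)
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    reports = []
    for fold in range(1, k + 1):
        train = [by_id[i] for i in folds.train_ids(fold)]
        test = [by_id[i] for i in folds.fold_ids(fold)]
        ckpt, _ = train_supervised(config, train, test)
        csv_path = out_dir / f"fold{fold}_per_image.csv" if out_dir else None
        reports.append(evaluate_model(ckpt, test, threshold=config.threshold,
                                      fold_id=fold, csv_path=csv_path))
    if out_dir is not None:
        with open(out_dir / "folds_summary.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["fold", "dsc", "sen", "jsc"])
            for r in reports:
                writer.writerow([r.fold_id] + [f"{m:.4f}" for m in r.mean])
    return reports
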