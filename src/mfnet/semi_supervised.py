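"""Pseudo-label semi-supervised training (SemiMF-Net).

Three steps:

1. *Pretrain* MF-Net on the available labelled scans.
2. *Pseudo-label*: run the pretrained model over the unlabelled scans and
   binarise the probability maps at a threshold (0.5 by default, no
   confidence filtering), attaching the results as pseudo-masks.
3. *Retrain* on the pooled set under the objective

       L = L_Pseudo + beta * L_Real,        beta = 1.0 by default,

   where each component is the joint Dice + BCE loss of that provenance's
   samples.  Loss accounting is per sample over the whole batch (each
   component sums its samples' losses and divides by the total batch size),
   so at beta = 1 the pooled objective is exactly the uniform mean joint
   loss over all samples.

Retraining warm-starts from the pretrained weights by default; pass
``warm_start=False`` to retrain from scratch.  A single pseudo-labelling
round is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .data_io import PSEUDO_LABEL, REAL_LABEL, UNLABELED, OCTSample, preprocess
from .training import Checkpoint, TrainConfig, predict_batch, train_supervised


@dataclass
class PseudoSet:
    samples: list[OCTSample]
    source_checkpoint: str
    threshold: float


def generate_pseudo_labels(checkpoint: Checkpoint,
                           unlabeled: Sequence[OCTSample],
                           threshold: float = 0.5) -> PseudoSet:
    """Binarise model predictions on unlabelled scans into pseudo-masks.

    Every input sample must be unlabelled; the output has one pseudo-labelled
    sample per input, masks predicted at the network input size.
    """
    for s in unlabeled:
        if s.provenance != UNLABELED or s.mask is not None:
            raise ValueError(
                f"sample {s.id!r} is not unlabeled (provenance "
                f"{s.provenance!r}); refusing to overwrite its label")
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    model = checkpoint.build()
    sized = [preprocess(s, model.config.input_size) for s in unlabeled]
    probs = predict_batch(model, sized)
    out = []
    for s, p in zip(sized, probs):
        mask = (p > threshold).astype(np.uint8)
        out.append(OCTSample(image=s.image, mask=mask, id=s.id,
                             provenance=PSEUDO_LABEL))
    return PseudoSet(samples=out, source_checkpoint="pretrained-mfnet",
                     threshold=threshold)


def semi_objective(loss_pseudo_batch: float, loss_real_batch: float,
                   beta: float = 1.0) -> float:
    """The mixed-batch objective L_Pseudo + beta * L_Real."""
    if beta < 0:
        raise ValueError("beta must be >= 0")
    return loss_pseudo_batch + beta * loss_real_batch


def _provenance_weights(beta: float):
    """Per-sample batch weights realising the semi objective.

    Each provenance component is (sum of its per-sample losses) / batch_size;
    real-labelled samples additionally carry the factor beta.
    """
    def weights(batch: Sequence[OCTSample]) -> np.ndarray:
        w = np.array([beta if s.provenance == REAL_LABEL else 1.0
                      for s in batch], dtype=np.float64)
        return w / len(batch)
    return weights


def train_semi(config: TrainConfig,
               labeled: Sequence[OCTSample],
               unlabeled: Sequence[OCTSample],
               val_samples: Sequence[OCTSample] | None = None,
               beta: float = 1.0,
               pseudo_threshold: float = 0.5,
               warm_start: bool = True,
               ) -> tuple[Checkpoint, dict]:
    """Full three-step pipeline; returns the retrained checkpoint.

    With no unlabelled data the procedure degenerates to two supervised
    phases on the labelled set.  Batches in step 3 are drawn from the pooled
    set without provenance balancing.
    """
    if not labeled:
        raise ValueError("train_semi requires a non-empty labeled set")
    if beta < 0:
        raise ValueError("beta must be >= 0")
    val = list(val_samples) if val_samples is not None else list(labeled)

    pre_ckpt, pre_hist = train_supervised(config, labeled, val)
    pseudo = generate_pseudo_labels(pre_ckpt, unlabeled,
                                    threshold=pseudo_threshold)
    pooled = list(labeled) + pseudo.samples
    retrain_config = replace(config, seed=config.seed)
    semi_ckpt, semi_hist = train_supervised(
        retrain_config, pooled, val,
        loss_weights=_provenance_weights(beta),
        initial_state=pre_ckpt.state if warm_start else None)
    return semi_ckpt, {"pretrain": pre_hist, "retrain": semi_hist,
                       "pretrain_checkpoint": pre_ckpt}
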