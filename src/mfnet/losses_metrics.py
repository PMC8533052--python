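"""Training objective and evaluation metrics for binary lesion segmentation.

The training objective is the unweighted sum of a smoothed Dice loss and a
mean-reduced binary cross-entropy:

    L = L_Dice + L_BCE
    L_Dice = 1 - (2 |X.Y| + eps) / (|X| + |Y| + eps),     eps = 1e-6
    L_BCE  = -mean( Y log X + (1 - Y) log(1 - X) )

Evaluation uses pixel confusion counts at a fixed binarisation threshold:

    DSC = 2 TP / (FP + 2 TP + FN),  SEN = TP / (TP + FN),
    JSC = TP / (FP + TP + FN),      all reported in percent.

When a metric's denominator is zero it is 100 if both masks are empty (the
prediction is vacuously perfect) and 0 otherwise.  Fold-level comparisons
use a two-sided paired t-test on per-fold metric vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import autodiff as F
from .autodiff import Tensor

DICE_EPS = 1e-6
BCE_CLAMP = 1e-7


def _pair(x, y) -> tuple[Tensor, Tensor]:
    x, y = F.astensor(x), F.astensor(y)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: prediction {x.shape} vs target {y.shape}")
    return x, y


def _maybe_float(out: Tensor, was_tensor: bool):
    return out if was_tensor else out.item()


# ---------------------------------------------------------------------------
# losses (differentiable when given Tensors)
# ---------------------------------------------------------------------------

def dice_loss(x, y, eps: float = DICE_EPS):
    """Smoothed Dice loss over the whole array; in [0, 1]."""
    was_tensor = isinstance(x, Tensor)
    x, y = _pair(x, y)
    inter = F.tsum(F.mul(x, y))
    denom = F.add(F.tsum(x), F.tsum(y))
    out = 1.0 - F.div(2.0 * inter + eps, denom + eps)
    return _maybe_float(out, was_tensor)


def bce_loss(x, y, clamp: float = BCE_CLAMP):
    """Binary cross-entropy, mean over pixels; predictions clamped away from {0,1}."""
    was_tensor = isinstance(x, Tensor)
    x, y = _pair(x, y)
    xc = F.clip(x, clamp, 1.0 - clamp)
    term = F.add(F.mul(y, F.log(xc)), F.mul(1.0 - y, F.log(1.0 - xc)))
    return _maybe_float(-F.tmean(term), was_tensor)


def joint_loss(x, y):
    """The training objective: Dice loss + BCE, unweighted."""
    was_tensor = isinstance(x, Tensor)
    out = F.add(dice_loss(F.astensor(x), y), bce_loss(F.astensor(x), y))
    return _maybe_float(out, was_tensor)


def joint_loss_per_sample(x, y) -> Tensor:
    """Per-sample Dice + BCE for a batch (N, ...); returns a length-N Tensor."""
    x, y = _pair(x, y)
    n = x.shape[0]
    npix = int(np.prod(x.shape[1:]))
    inter = F.sum_per_sample(F.mul(x, y))
    denom = F.add(F.sum_per_sample(x), F.sum_per_sample(y))
    dice = 1.0 - F.div(2.0 * inter + DICE_EPS, denom + DICE_EPS)
    xc = F.clip(x, BCE_CLAMP, 1.0 - BCE_CLAMP)
    term = F.add(F.mul(y, F.log(xc)), F.mul(1.0 - y, F.log(1.0 - xc)))
    bce = F.div(-F.sum_per_sample(term), float(npix))
    return F.add(dice, bce)


# ---------------------------------------------------------------------------
# confusion counts and metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _check_binary(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must be strictly binary")
    return arr.astype(bool)


def confusion_counts(pred, gt) -> ConfusionCounts:
    """Exact pixel confusion counts between two binary masks."""
    p = _check_binary(pred, "pred")
    g = _check_binary(gt, "gt")
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs gt {g.shape}")
    tp = int(np.count_nonzero(p & g))
    fp = int(np.count_nonzero(p & ~g))
    fn = int(np.count_nonzero(~p & g))
    return ConfusionCounts(tp, fp, fn, p.size - tp - fp - fn)


def _safe_ratio(num: float, den: float, both_empty: bool) -> float:
    if den == 0:
        return 100.0 if both_empty else 0.0
    return 100.0 * num / den


def metrics_from_counts(c: ConfusionCounts) -> tuple[float, float, float]:
    """(DSC, SEN, JSC) in percent from confusion counts."""
    both_empty = c.tp + c.fp + c.fn == 0
    dsc = _safe_ratio(2 * c.tp, c.fp + 2 * c.tp + c.fn, both_empty)
    sen = _safe_ratio(c.tp, c.tp + c.fn, both_empty)
    jsc = _safe_ratio(c.tp, c.fp + c.tp + c.fn, both_empty)
    return dsc, sen, jsc


def segmentation_metrics(prob, gt, threshold: float = 0.5
                         ) -> tuple[float, float, float]:
    """Binarise a probability map and return (DSC, SEN, JSC) in percent."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    prob = np.asarray(prob, dtype=np.float64)
    pred = (prob > threshold).astype(np.uint8)
    return metrics_from_counts(confusion_counts(pred, gt))


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    """Per-image (DSC, SEN, JSC) plus mean +/- sample SD, for one fold."""

    per_image: list[tuple[float, float, float]]
    fold_id: int | None = None
    mean: tuple[float, float, float] = field(init=False)
    sd: tuple[float, float, float] = field(init=False)

    def __post_init__(self):
        arr = np.asarray(self.per_image, dtype=np.float64)
        self.mean = tuple(arr.mean(axis=0))
        self.sd = tuple(arr.std(axis=0, ddof=1) if len(arr) > 1
                        else np.zeros(3))

    @property
    def mean_dsc(self) -> float:
        return self.mean[0]


def aggregate_mean_sd(values) -> tuple[float, float]:
    """Mean and sample SD (ddof=1), the convention used for fold summaries."""
    arr = np.asarray(values, dtype=np.float64)
    return float(arr.mean()), float(arr.std(ddof=1)) if arr.size > 1 else 0.0


# ---------------------------------------------------------------------------
# statistical significance
# ---------------------------------------------------------------------------

def paired_ttest(a, b) -> float:
    """Two-sided paired t-test p-value between matched metric vectors.

    Conventions for degenerate inputs: identical vectors give p = 1.0; a
    constant nonzero difference (zero variance, infinite t) gives the
    smallest positive float.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired_ttest expects two equal-length 1-D vectors")
    if a.size < 2:
        raise ValueError("paired_ttest requires n >= 2")
    d = a - b
    if np.all(d == 0):
        return 1.0
    if np.std(d, ddof=1) == 0:
        return float(np.finfo(np.float64).tiny)
    return float(stats.ttest_rel(a, b).pvalue)
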