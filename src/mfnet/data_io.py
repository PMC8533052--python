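"""Image/mask IO, preprocessing, fold splitting and overlay rendering.

Samples are grayscale OCT B-scans in [0, 1] with optional binary lesion
masks.  Masks live on disk as 8-bit PNGs with values {0, 255} and are
binarised at 128 when read.  Cross-validation folds follow the scheme in
which the first k-1 folds each receive floor(N/k) samples and the last fold
the remainder, so 1,522 samples split 4 ways as (380, 380, 380, 382).

Library functions here are pure (no hidden state); only the CLI and the
explicit ``save_*``/``load_*`` helpers touch the filesystem.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml
from skimage.transform import resize as _sk_resize

from .backbone import NetworkConfig

REAL_LABEL = "real_label"
PSEUDO_LABEL = "pseudo_label"
UNLABELED = "unlabeled"
PROVENANCES = (REAL_LABEL, PSEUDO_LABEL, UNLABELED)

MASK_THRESHOLD = 128  # on the 0..255 scale


@dataclass
class OCTSample:
    """One B-scan: image in [0,1], optional binary mask, id, label provenance."""

    image: np.ndarray
    mask: np.ndarray | None
    id: str
    provenance: str = REAL_LABEL

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=np.float32)
        if self.image.ndim != 2:
            raise ValueError(f"sample {self.id}: image must be 2-D")
        if self.provenance not in PROVENANCES:
            raise ValueError(f"sample {self.id}: unknown provenance "
                             f"{self.provenance!r}")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=np.uint8)
            if self.mask.shape != self.image.shape:
                raise ValueError(
                    f"sample {self.id}: mask dims {self.mask.shape} do not "
                    f"match image dims {self.image.shape}")
            if not np.isin(self.mask, (0, 1)).all():
                raise ValueError(f"sample {self.id}: mask must be binary")

    @property
    def labeled(self) -> bool:
        return self.mask is not None


# ---------------------------------------------------------------------------
# reading and writing
# ---------------------------------------------------------------------------

def _to_unit_gray(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 3:  # RGB(A) -> luminance
        arr = arr[..., :3] @ np.array([0.299, 0.587, 0.114])
    arr = arr.astype(np.float64)
    if arr.max() > 1.0:
        scale = 65535.0 if arr.max() > 255 else 255.0
        arr = arr / scale
    return np.clip(arr, 0.0, 1.0).astype(np.float32)


def load_sample(image_path, mask_path=None, sample_id: str | None = None,
                provenance: str | None = None) -> OCTSample:
    """Read an image (PNG/JPEG/TIFF) and optional mask PNG into an OCTSample."""
    image_path = Path(image_path)
    image = _to_unit_gray(iio.imread(image_path))
    mask = None
    if mask_path is not None:
        mask = load_mask(mask_path)
        if mask.shape != image.shape:
            raise ValueError(
                f"mask dims {mask.shape} do not match image dims {image.shape} "
                f"({image_path.name})")
    if provenance is None:
        provenance = REAL_LABEL if mask is not None else UNLABELED
    return OCTSample(image=image, mask=mask,
                     id=sample_id or image_path.stem, provenance=provenance)


def load_mask(path) -> np.ndarray:
    """Read a mask PNG; any pixel >= 128 (0..255 scale) counts as lesion."""
    raw = iio.imread(path)
    if raw.ndim == 3:
        raw = raw[..., 0]
    if raw.dtype.kind == "f" and raw.max() <= 1.0:
        raw = raw * 255.0
    return (raw >= MASK_THRESHOLD).astype(np.uint8)


def save_mask(mask: np.ndarray, path) -> None:
    """Write a binary mask as an 8-bit {0, 255} PNG."""
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("save_mask expects a strictly binary mask")
    iio.imwrite(Path(path), (mask.astype(np.uint8) * 255))


def save_image(image: np.ndarray, path) -> None:
    """Write a [0,1] grayscale image as 8-bit PNG."""
    arr = np.clip(np.asarray(image, dtype=np.float64), 0, 1)
    iio.imwrite(Path(path), np.round(arr * 255).astype(np.uint8))


def save_probability(prob: np.ndarray, path) -> None:
    """Write a probability map as float32 TIFF."""
    iio.imwrite(Path(path), np.asarray(prob, dtype=np.float32).squeeze())


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def preprocess(sample: OCTSample, target_size: tuple[int, int] = (256, 256)
               ) -> OCTSample:
    """Resize to the network input size: bilinear image, nearest mask.

    Idempotent: a sample already at ``target_size`` is returned unchanged
    (modulo a copy), so masks stay strictly binary through repeated calls.
    """
    th, tw = target_size
    for axis, size in (("height", th), ("width", tw)):
        if size % 16:
            raise ValueError(f"target {axis} {size} is not divisible by 16")
    if sample.image.shape == (th, tw):
        return replace(sample)
    image = _sk_resize(sample.image, (th, tw), order=1, mode="edge",
                       anti_aliasing=False, preserve_range=True
                       ).astype(np.float32)
    mask = None
    if sample.mask is not None:
        mask = _sk_resize(sample.mask, (th, tw), order=0, mode="edge",
                          anti_aliasing=False, preserve_range=True
                          ).astype(np.uint8)
    return OCTSample(image=np.clip(image, 0, 1), mask=mask,
                     id=sample.id, provenance=sample.provenance)


# ---------------------------------------------------------------------------
# cross-validation folds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldSplit:
    """Assignment of sample ids to folds 1..k (last fold takes the remainder)."""

    assignments: dict[str, int]
    k: int

    def fold_ids(self, fold: int) -> list[str]:
        return [i for i, f in self.assignments.items() if f == fold]

    def train_ids(self, fold: int) -> list[str]:
        return [i for i, f in self.assignments.items() if f != fold]

    def sizes(self) -> tuple[int, ...]:
        return tuple(len(self.fold_ids(f)) for f in range(1, self.k + 1))


def make_folds(ids, k: int = 4, seed: int = 0) -> FoldSplit:
    """Shuffle ids with ``seed`` and deal floor(N/k) to folds 1..k-1, rest to k."""
    ids = list(ids)
    if not ids:
        raise ValueError("make_folds: empty id list")
    if k < 2:
        raise ValueError("make_folds: k must be >= 2")
    if len(ids) < k:
        raise ValueError(f"make_folds: {len(ids)} ids cannot fill {k} folds")
    if len(set(ids)) != len(ids):
        raise ValueError("make_folds: duplicate ids")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    base = len(ids) // k
    assignments: dict[str, int] = {}
    pos = 0
    for fold in range(1, k):
        for sid in order[pos:pos + base]:
            assignments[sid] = fold
        pos += base
    for sid in order[pos:]:
        assignments[sid] = k
    return FoldSplit(assignments=assignments, k=k)


# ---------------------------------------------------------------------------
# overlay rendering
# ---------------------------------------------------------------------------

_YELLOW = (255, 255, 0)   # true positive
_RED = (255, 0, 0)        # false positive
_BLUE = (0, 0, 255)       # false negative


def render_overlay(pred: np.ndarray, gt: np.ndarray, image: np.ndarray
                   ) -> np.ndarray:
    """RGB overlay: TP yellow, FP red, FN blue, TN grayscale passthrough."""
    pred = np.asarray(pred).astype(bool)
    gt = np.asarray(gt).astype(bool)
    image = np.asarray(image, dtype=np.float64)
    if not (pred.shape == gt.shape == image.shape):
        raise ValueError(
            f"shape mismatch: pred {pred.shape}, gt {gt.shape}, "
            f"image {image.shape}")
    gray = np.round(np.clip(image, 0, 1) * 255).astype(np.uint8)
    out = np.repeat(gray[..., None], 3, axis=-1)
    out[pred & gt] = _YELLOW
    out[pred & ~gt] = _RED
    out[~pred & gt] = _BLUE
    return out


# ---------------------------------------------------------------------------
# configuration and checkpoints
# ---------------------------------------------------------------------------

DEFAULT_CONFIG = {
    "model": {"base_channels": 64, "use_mad": True, "use_sda": True,
              "input_size": [256, 256]},
    "optim": {"lr": 0.0005, "weight_decay": 0.0001, "batch_size": 4,
              "epochs": 50},
    "semi": {"beta": 1.0, "pseudo_threshold": 0.5},
    "seed": 0,
}


def load_yaml_config(path=None) -> dict:
    """Read a YAML config, filling unspecified keys from the defaults."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for section, values in user.items():
            if isinstance(values, dict):
                cfg.setdefault(section, {}).update(values)
            else:
                cfg[section] = values
    return cfg


def save_checkpoint(path, state: dict[str, np.ndarray],
                    network: NetworkConfig) -> None:
    meta = json.dumps(network.to_dict())
    np.savez(path, __config__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **state)


def load_checkpoint(path) -> tuple[dict[str, np.ndarray], NetworkConfig]:
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["__config__"]).decode())
        state = {k: npz[k] for k in npz.files if k != "__config__"}
    return state, NetworkConfig.from_dict(meta)
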