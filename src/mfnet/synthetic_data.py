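"""Seeded generator of OCT-like B-scans with ground-truth lesion masks.

Real CNV B-scans are hard to segment because of blurred lesion boundaries,
large shape variability and multiplicative speckle noise.  The generator
emulates exactly those properties so the whole pipeline — supervised
training, evaluation, pseudo-labelling — runs without any external dataset:

* smooth curved horizontal intensity bands mimic the retinal layers;
* one simply-connected, irregular, hyperreflective lesion (a random radial
  polygon with low-order Fourier boundary perturbations) straddles the band
  region, composited with a Gaussian-blurred edge so its boundary is soft;
* multiplicative gamma speckle (mean 1, variance = ``speckle_strength``)
  corrupts the image, the standard model for coherent-imaging noise.

The returned mask is the exact pre-blur polygon raster.  Everything is
driven by a single integer seed, so images and masks are bit-reproducible.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import polygon as _draw_polygon
from skimage.measure import label as _cc_label

from .data_io import OCTSample, REAL_LABEL, save_image, save_mask

_MAX_ATTEMPTS = 80


@dataclass(frozen=True)
class SynthParams:
    image_size: tuple[int, int] = (128, 128)
    n_layers: int = 6
    lesion_area_frac: tuple[float, float] = (0.03, 0.12)
    speckle_strength: float = 0.15
    blur_sigma: float = 1.5
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.lesion_area_frac
        if not lo < hi:
            raise ValueError("lesion_area_frac must satisfy min < max")
        for name in ("speckle_strength", "blur_sigma"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0")
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")


def _band_background(params: SynthParams, rng: np.random.Generator
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Curved layered background; returns (image, top_curve, bottom_curve)."""
    h, w = params.image_size
    xx = np.linspace(0, 2 * np.pi, w)
    amp = h * rng.uniform(0.02, 0.06)
    phase = rng.uniform(0, 2 * np.pi)
    top = h * rng.uniform(0.18, 0.28) + amp * np.sin(xx + phase)
    thickness = h * rng.uniform(0.38, 0.5)
    bottom = top + thickness
    intensities = rng.uniform(0.15, 0.6, size=params.n_layers)
    # a brighter band near the top mimics the hyperreflective RNFL/RPE bands
    intensities[0] = rng.uniform(0.5, 0.65)
    intensities[-1] = rng.uniform(0.5, 0.65)

    yy = np.arange(h, dtype=np.float64)[:, None]
    rel = (yy - top[None, :]) / thickness
    img = np.full((h, w), 0.05)                     # vitreous above
    below = rel >= 1.0
    img[below] = 0.16                               # choroid/sclera below
    in_band = (rel >= 0.0) & (rel < 1.0)
    band_idx = np.clip((rel * params.n_layers).astype(int), 0,
                       params.n_layers - 1)
    img[in_band] = intensities[band_idx[in_band]]
    return img, top, bottom


def _lesion_mask(params: SynthParams, rng: np.random.Generator,
                 top: np.ndarray, bottom: np.ndarray) -> np.ndarray | None:
    """One simply-connected irregular polygon inside the band region."""
    h, w = params.image_size
    lo, hi = params.lesion_area_frac
    target = rng.uniform(lo, hi) * h * w
    aspect = rng.uniform(1.2, 2.2)                  # CNV tends to be wide
    r0 = np.sqrt(target / np.pi)
    rx, ry = r0 * np.sqrt(aspect), r0 / np.sqrt(aspect)

    cx = rng.uniform(0.25 * w, 0.75 * w)
    band_mid = 0.5 * (top[int(cx)] + bottom[int(cx)])
    cy = rng.uniform(band_mid, min(bottom[int(cx)], h - ry - 2))

    theta = np.linspace(0, 2 * np.pi, 48, endpoint=False)
    perturb = np.zeros_like(theta)
    for m in range(2, 6):
        perturb += rng.uniform(0, 0.15) * np.cos(m * theta + rng.uniform(0, 2 * np.pi))
    rr = 1.0 + perturb
    ys = cy + ry * rr * np.sin(theta)
    xs = cx + rx * rr * np.cos(theta)
    if ys.min() < 0 or ys.max() > h - 1 or xs.min() < 0 or xs.max() > w - 1:
        return None
    mask = np.zeros((h, w), dtype=np.uint8)
    pr, pc = _draw_polygon(ys, xs, shape=(h, w))
    mask[pr, pc] = 1

    frac = mask.sum() / (h * w)
    if not lo <= frac <= hi:
        return None
    if _cc_label(mask, connectivity=2).max() != 1:
        return None
    return mask


def synth_bscan(params: SynthParams) -> OCTSample:
    """Generate one OCT-like B-scan plus its exact lesion mask.

    Lesion candidates are rejection-sampled until the area fraction lands in
    ``lesion_area_frac`` and the mask is a single 8-connected component.
    """
    rng = np.random.default_rng(params.seed)
    img, top, bottom = _band_background(params, rng)

    mask = None
    for _ in range(_MAX_ATTEMPTS):
        mask = _lesion_mask(params, rng, top, bottom)
        if mask is not None:
            break
    if mask is None:
        raise ValueError(
            f"lesion_area_frac {params.lesion_area_frac} infeasible for "
            f"image size {params.image_size}")

    lesion_intensity = rng.uniform(0.8, 0.95)
    soft = mask.astype(np.float64)
    if params.blur_sigma > 0:
        soft = gaussian_filter(soft, params.blur_sigma)
    img = img * (1.0 - soft) + lesion_intensity * soft

    if params.speckle_strength > 0:
        shape = 1.0 / params.speckle_strength
        img = img * rng.gamma(shape, 1.0 / shape, size=img.shape)

    img = np.clip(img, 0.0, 1.0).astype(np.float32)
    return OCTSample(image=img, mask=mask, id=f"synth_{params.seed:06d}",
                     provenance=REAL_LABEL)


def synth_samples(n: int, params: SynthParams) -> list[OCTSample]:
    """n in-memory samples with consecutive seeds starting at ``params.seed``."""
    return [synth_bscan(replace(params, seed=params.seed + i)) for i in range(n)]


def synth_dataset(n: int, params: SynthParams, out_dir) -> Path:
    """Write n image/mask PNG pairs and a manifest CSV; returns manifest path.

    Regenerating with identical parameters reproduces identical files.
    """
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "image", "mask", "lesion_area", "seed"])
        for i in range(n):
            sample = synth_bscan(replace(params, seed=params.seed + i))
            img_path = out_dir / "images" / f"{sample.id}.png"
            mask_path = out_dir / "masks" / f"{sample.id}.png"
            save_image(sample.image, img_path)
            save_mask(sample.mask, mask_path)
            writer.writerow([sample.id, img_path.name, mask_path.name,
                             int(sample.mask.sum()), params.seed + i])
    return manifest


def load_synth_dataset(out_dir) -> list[OCTSample]:
    """Read a dataset previously written by :func:`synth_dataset`."""
    from .data_io import load_sample

    out_dir = Path(out_dir)
    samples = []
    with open(out_dir / "manifest.csv") as fh:
        for row in csv.DictReader(fh):
            samples.append(load_sample(out_dir / "images" / row["image"],
                                       out_dir / "masks" / row["mask"],
                                       sample_id=row["id"]))
    return samples


def otsu_baseline(sample: OCTSample, blur_sigma: float = 1.0) -> np.ndarray:
    """Trivial thresholding baseline: Otsu on the Gaussian-blurred image."""
    from skimage.filters import threshold_otsu

    img = gaussian_filter(sample.image.astype(np.float64), blur_sigma)
    return (img > threshold_otsu(img)).astype(np.uint8)
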