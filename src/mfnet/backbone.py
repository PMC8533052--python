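"""MF-Net: encoder-decoder segmentation network for CNV in retinal OCT B-scans.

The backbone is a U-shaped encoder-decoder *without* same-level skip
connections.  Four encoder stages (two 3x3 conv + batch-norm + ReLU layers,
then 2x2 max pooling) halve the resolution and double the channel width at
every stage, so stage k produces ``base_channels * 2**(k-1)`` channels at
1/2^k of the input resolution.  The deepest features pass through the MAD
module (when enabled) and three decoder stages (bilinear x2 upsampling, 3x3
conv + batch-norm + ReLU) walk back up; the two shallow skip paths are
reconstructed by SDA modules (when enabled).  A head upsamples the final x2,
applies a 1x1 convolution and a sigmoid, giving a per-pixel lesion
probability map the size of the input.

Ablation switches ``use_mad``/``use_sda`` realise the four architectural
variants (plain backbone, +MAD, +SDA, full network) used in the ablation
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as F
from .autodiff import Tensor, no_grad
from .mad import MAD
from .nn import Conv2d, ConvBNReLU, Module
from .sda import SDA

N_STAGES = 4
_DOWN_FACTOR = 2 ** N_STAGES  # input dims must be divisible by this


@dataclass
class NetworkConfig:
    """Architecture hyper-parameters and ablation switches."""

    in_channels: int = 1
    base_channels: int = 64
    use_mad: bool = True
    use_sda: bool = True
    input_size: tuple[int, int] = (256, 256)
    pretrained_encoder: str | None = None  # optional .npz with encoder weights

    def __post_init__(self):
        self.input_size = tuple(self.input_size)
        if self.base_channels % 4:
            raise ValueError("base_channels must be divisible by 4")
        _check_divisible(*self.input_size)

    def to_dict(self) -> dict:
        return {"in_channels": self.in_channels,
                "base_channels": self.base_channels,
                "use_mad": self.use_mad, "use_sda": self.use_sda,
                "input_size": list(self.input_size),
                "pretrained_encoder": self.pretrained_encoder}

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        return cls(**{**d, "input_size": tuple(d.get("input_size", (256, 256)))})


def _check_divisible(h: int, w: int) -> None:
    for axis, size in (("height", h), ("width", w)):
        if size % _DOWN_FACTOR:
            raise ValueError(
                f"input {axis} {size} is not divisible by {_DOWN_FACTOR}")


class _EncoderStage(Module):
    def __init__(self, in_ch: int, out_ch: int, rng):
        super().__init__()
        self.conv1 = ConvBNReLU(in_ch, out_ch, rng)
        self.conv2 = ConvBNReLU(out_ch, out_ch, rng)

    def forward(self, x):
        return F.maxpool2x2(self.conv2(self.conv1(x)))


class _DecoderStage(Module):
    def __init__(self, in_ch: int, out_ch: int, rng):
        super().__init__()
        self.conv = ConvBNReLU(in_ch, out_ch, rng)

    def forward(self, x):
        return self.conv(F.upsample2x(x))


class MFNet(Module):
    """Full segmentation network; see the module docstring for the wiring."""

    def __init__(self, config: NetworkConfig | None = None, seed: int = 0):
        super().__init__()
        self.config = config or NetworkConfig()
        cfg = self.config
        rng = np.random.default_rng(seed)
        b = cfg.base_channels
        widths = [b * 2 ** k for k in range(N_STAGES)]          # E1..E4 channels
        ins = [cfg.in_channels] + widths[:-1]
        self.encoders = [_EncoderStage(i, o, rng) for i, o in zip(ins, widths)]
        if cfg.use_mad:
            self.mad = MAD(widths[3], rng)
        self.decoder3 = _DecoderStage(widths[3], widths[2], rng)
        self.decoder2 = _DecoderStage(widths[2], widths[1], rng)
        self.decoder1 = _DecoderStage(widths[1], widths[0], rng)
        if cfg.use_sda:
            self.sda1 = SDA(widths[2], widths[1], rng)
            self.sda2 = SDA(widths[1], widths[0], rng)
        self.head_conv = Conv2d(widths[0], 1, 1, rng)
        if cfg.pretrained_encoder:
            self._load_encoder_weights(cfg.pretrained_encoder)

    def _load_encoder_weights(self, path: str) -> None:
        with np.load(path) as npz:
            state = {k: npz[k] for k in npz.files}
        own = {name: p for name, p in self.named_parameters()
               if name.startswith("encoders.")}
        for name, p in own.items():
            if name not in state or state[name].shape != p.data.shape:
                raise ValueError(f"pretrained encoder missing/mismatched: {name}")
            p.data = state[name].astype(p.data.dtype)

    # -- forward ----------------------------------------------------------
    def encode(self, image) -> list[Tensor]:
        """Run the encoder path; returns [E1, E2, E3, E4]."""
        x = F.astensor(image)
        if x.ndim == 3:
            x = F.reshape(x, (1, *x.shape))
        _check_divisible(x.shape[2], x.shape[3])
        feats = []
        for enc in self.encoders:
            x = enc(x)
            feats.append(x)
        return feats

    def forward(self, image) -> Tensor:
        e1, e2, e3, e4 = self.encode(image)
        top = self.mad(e4) if self.config.use_mad else e4
        d3 = self.decoder3(top)
        d2 = self.decoder2(d3)
        s1 = self.sda1(d3, e2, d2) if self.config.use_sda else d2
        d1 = self.decoder1(s1)
        s2 = self.sda2(s1, e1, d1) if self.config.use_sda else d1
        return F.sigmoid(self.head_conv(F.upsample2x(s2)))

    def predict(self, image: np.ndarray) -> np.ndarray:
        """Inference on one image (1,H,W) or (H,W); returns (1,H,W) probabilities."""
        arr = np.asarray(image, dtype=np.float32)
        if arr.ndim == 2:
            arr = arr[None]
        was_training = self.training
        self.eval()
        try:
            with no_grad():
                out = self.forward(arr[None])
        finally:
            if was_training:
                self.train()
        return out.data[0]


def mf_net_forward(image, config: NetworkConfig | None = None, *,
                   seed: int = 0, model: MFNet | None = None) -> np.ndarray:
    """One forward pass through MF-Net, returning a probability map (1,H,W).

    Builds a freshly initialised model from ``config``/``seed`` unless an
    existing ``model`` is supplied.
    """
    net = model if model is not None else MFNet(config, seed=seed)
    return net.predict(np.asarray(image, dtype=np.float32))
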