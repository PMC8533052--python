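"""Semantics-details aggregation module (SDA).

A reconstructed skip connection: instead of copying encoder features across
to the decoder, the shallow encoder detail E is multiplicatively gated by
upsampled deeper semantics F before being added to the decoder stream D:

    S = conv3x3(upsample_x2(F)) * E + D

The 3x3 convolution squeezes F's channel count down to E's; there is no
normalisation or activation inside the module, so the zero-gate (E = 0 gives
S = D) and unit-gate (conv output = 1 gives S = E + D) identities hold
exactly.  The network uses two instances: SDA 1 takes the Decoder-3 output
and (E2, D2); SDA 2 takes the SDA-1 output and (E1, D1).  No skip paths
exist from the two deepest encoder stages.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as F
from .nn import Conv2d, Module


class SDA(Module):
    def __init__(self, f_channels: int, e_channels: int, rng: np.random.Generator):
        super().__init__()
        self.squeeze = Conv2d(f_channels, e_channels, 3, rng)

    def forward(self, f, e, d):
        f, e, d = F.astensor(f), F.astensor(e), F.astensor(d)
        if e.shape != d.shape:
            raise ValueError(
                f"SDA: encoder {e.shape} and decoder {d.shape} shapes differ")
        if (f.shape[2] * 2, f.shape[3] * 2) != (e.shape[2], e.shape[3]):
            raise ValueError(
                f"SDA: source spatial dims {f.shape[2:]} must be half of "
                f"encoder dims {e.shape[2:]}")
        gate = self.squeeze(F.upsample2x(f))
        return F.add(F.mul(gate, e), d)


def wire_sda_chain(sda1: SDA, sda2: SDA, decoder3_out, e2, d2, e1, d1):
    """Chain the two SDA instances: S1 from (Dec3, E2, D2); S2 from (S1, E1, D1).

    Returns (S1, S2).  S1 feeds Decoder 1 in the full network; S2 feeds the
    segmentation head.
    """
    s1 = sda1(decoder3_out, e2, d2)
    s2 = sda2(s1, e1, d1)
    return s1, s2
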