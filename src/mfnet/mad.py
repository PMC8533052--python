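"""Multi-scale adaptive-aware deformation module (MAD).

Inserted after the deepest encoder stage, MAD aggregates context at several
dilation scales, fuses the scales with a deformable convolution, and then
re-weights the fused map with two global attention branches before an
adaptive residual:

1. *Parallel dilated branches*: four 1x1 squeezes (c -> c/4) each followed by
   a 3x3 convolution with dilation rate 2k-1 (1, 3, 5, 7); the branch
   outputs are concatenated back to c channels.
2. *Deformable fusion*: a 3x3 deformable convolution whose sampling offsets
   are predicted from the input (zero-initialised, so it starts as a plain
   convolution).
3. *Dual global attention*: a spatial gate S (1 x h x w) from per-position
   channel max/mean, and a channel gate C (c x 1 x 1) from global max/mean
   pooling; both end in a sigmoid.
4. *Adaptive residual*: O = B + conv(lambda*B.S + gamma*B.C) with scalar
   learnable weights lambda and gamma, both initialised to 1.0.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as F
from .nn import Conv2d, DeformConv2d, Linear, Module, Parameter

DILATION_RATES = (1, 3, 5, 7)


class MAD(Module):
    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        if channels % 4:
            raise ValueError(
                f"MAD requires channels divisible by 4, got {channels}")
        branch = channels // 4
        self.squeezes = [Conv2d(channels, branch, 1, rng) for _ in DILATION_RATES]
        self.dilated = [Conv2d(branch, branch, 3, rng, dilation=r)
                        for r in DILATION_RATES]
        self.deform = DeformConv2d(channels, channels, rng)
        self.spatial_conv = Conv2d(2, 1, 7, rng)
        self.channel_conv = Conv2d(2 * channels, channels, 1, rng)
        self.channel_fc = Linear(channels, channels, rng)
        self.residual_conv = Conv2d(channels, channels, 3, rng)
        self.lambda_param = Parameter(np.float32(1.0))
        self.gamma_param = Parameter(np.float32(1.0))
        self.channels = channels

    # -- the four stages, exposed individually for inspection/testing ------
    def parallel_dilated_branches(self, x):
        """Four (1x1 squeeze, 3x3 dilated) branches, concatenated to c channels."""
        outs = [dil(sq(x)) for sq, dil in zip(self.squeezes, self.dilated)]
        return F.concat_channels(outs)

    def deformable_fusion(self, x):
        """3x3 deformable convolution producing the fused map B."""
        return self.deform(x)

    def spatial_attention(self, b):
        """S = sigmoid(conv7x7(concat(max_c B, mean_c B))), shape (N,1,h,w)."""
        s1 = F.channel_max(b)
        s2 = F.channel_mean(b)
        return F.sigmoid(self.spatial_conv(F.concat_channels([s1, s2])))

    def channel_attention(self, b):
        """C = sigmoid(FC(conv1x1(concat(gmax B, gmean B)))), shape (N,c,1,1)."""
        c1 = F.global_max(b)
        c2 = F.global_mean(b)
        squeezed = self.channel_conv(F.concat_channels([c1, c2]))
        n = squeezed.shape[0]
        flat = F.reshape(squeezed, (n, self.channels))
        return F.reshape(F.sigmoid(self.channel_fc(flat)),
                         (n, self.channels, 1, 1))

    def adaptive_residual(self, b, s, c):
        """O = B + conv(lambda*(B.S) + gamma*(B.C)); gates broadcast over B."""
        spatial = F.mul(F.mul(self.lambda_param, b), s)
        channel = F.mul(F.mul(self.gamma_param, b), c)
        return F.add(b, self.residual_conv(F.add(spatial, channel)))

    def forward(self, x):
        b = self.deformable_fusion(self.parallel_dilated_branches(x))
        s = self.spatial_attention(b)
        c = self.channel_attention(b)
        return self.adaptive_residual(b, s, c)
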