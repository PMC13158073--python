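"""The four bespoke feature-map blocks of the dual-branch segmentation net.

* :class:`ECRB` — efficient context refinement block: 1x1 conv -> 3x3 dilated
  conv -> 3x3 conv, each with BN+ReLU.  The dilated middle stage enlarges the
  receptive field at constant spatial size and parameter count.
* :class:`AGFRB` — attention-guided feature refinement block: a max-pool
  saliency path, a 1x1 -> depthwise -> ECA path and an identity path, summed
  elementwise and refined by a 3x3 conv.
* :class:`ECA` — efficient channel attention: global average pool -> adaptive
  1-D conv over the channel descriptor -> sigmoid -> per-channel reweighting.
* :class:`LRM` — lightweight reinforcement module: L cascaded layers, each
  computing DWConv(x) + PWConv(x) + x.  The branch convolutions are bare
  (bias, no normalization, no activation) so that the residual identity is
  exact: with zero weights each layer is the identity map.

All blocks preserve spatial extent (stride-1 convs, same padding).
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from . import nn


def eca_kernel_size(channels: int, gamma: int = 2, b: int = 1) -> int:
    """Adaptive 1-D kernel extent for efficient channel attention.

    Nearest odd integer to ``log2(channels)/gamma + b/gamma`` (ties resolved
    toward the smaller odd value), clamped to at least 1.
    """
    if channels < 1:
        raise ValueError(f"channels must be >= 1, got {channels}")
    t = np.log2(channels) / gamma + b / gamma
    lo = 2 * int(np.floor((t - 1) / 2)) + 1  # largest odd <= t (or just below)
    hi = lo + 2
    k = lo if (t - lo) <= (hi - t) else hi
    return max(k, 1)


class ECA(nn.Module):
    """Efficient channel attention gate.

    The spatial mean of each channel forms a length-C descriptor, convolved by
    a single odd-length 1-D kernel (adaptive extent unless ``kernel_size`` is
    given), squashed by a sigmoid into per-channel weights in (0, 1) that
    multiply the input.  No spatial mixing occurs.
    """

    def __init__(self, rng, channels: int, gamma: int = 2, b: int = 1,
                 kernel_size: int | None = None):
        super().__init__()
        k = eca_kernel_size(channels, gamma, b) if kernel_size is None else kernel_size
        if k % 2 == 0:
            raise ValueError(f"ECA kernel length must be odd, got {k}")
        self.kernel_size = k
        self.channels = channels
        self.weight = ad.Tensor(
            nn.kaiming_uniform(rng, (k,), k), requires_grad=True
        )
        self.bias = ad.Tensor(np.zeros((), dtype=nn.DTYPE), requires_grad=True)

    def gate(self, x):
        """Per-channel attention weights of shape [B, C, 1, 1], in (0, 1)."""
        s = x.mean(axis=(2, 3)) if isinstance(x, ad.Tensor) else ad.Tensor(
            x.mean(axis=(2, 3))
        )
        y = ad.conv1d_channels(s, self.weight, self.bias)
        w = ad.sigmoid(y)
        b, c = w.shape
        return w.reshape(b, c, 1, 1)

    def forward(self, x):
        return x * self.gate(x)


class ECRB(nn.Module):
    """Efficient context refinement block (main-encoder stage)."""

    def __init__(self, rng, in_channels: int, out_channels: int,
                 dilation: int = 2):
        super().__init__()
        self.reduce = nn.ConvBNReLU(rng, in_channels, out_channels, 1)
        self.context = nn.ConvBNReLU(rng, out_channels, out_channels, 3,
                                     dilation=dilation)
        self.refine = nn.ConvBNReLU(rng, out_channels, out_channels, 3)

    def forward(self, x):
        return self.refine(self.context(self.reduce(x)))


class AGFRB(nn.Module):
    """Attention-guided feature refinement block (auxiliary-encoder stage)."""

    def __init__(self, rng, in_channels: int, out_channels: int,
                 eca_gamma: int = 2, eca_b: int = 1,
                 eca_kernel: int | None = None):
        super().__init__()
        # upper path: saliency pooling then channel re-encoding
        self.upper_conv = nn.ConvBNReLU(rng, in_channels, out_channels, 1)
        # lower path: 1x1 re-encode -> depthwise spatial modelling -> ECA gate
        self.lower_reduce = nn.ConvBNReLU(rng, in_channels, out_channels, 1)
        self.lower_dw = nn.ConvBNReLU(rng, out_channels, out_channels, 3,
                                      groups=out_channels)
        self.eca = ECA(rng, out_channels, eca_gamma, eca_b, eca_kernel)
        # identity path: projected only on a channel mismatch
        if in_channels != out_channels:
            self.project = nn.Sequential(
                nn.Conv2d(rng, in_channels, out_channels, 1, bias=False),
                nn.BatchNorm2d(out_channels),
            )
        else:
            self.project = nn.Identity()
        self.refine = nn.ConvBNReLU(rng, out_channels, out_channels, 3)

    def fuse(self, x):
        """Elementwise sum of the three aligned paths (pre-refinement map)."""
        upper = self.upper_conv(ad.max_pool_same(x, 3))
        lower = self.eca(self.lower_dw(self.lower_reduce(x)))
        return upper + lower + self.project(x)

    def forward(self, x):
        return self.refine(self.fuse(x))


class LRM(nn.Module):
    """Lightweight reinforcement module (bottleneck reinforcement).

    ``layers`` cascaded stages; each stage sums a k x k depthwise conv, a 1x1
    pointwise conv and the residual shortcut of its input.
    """

    def __init__(self, rng, channels: int, layers: int = 2, kernel: int = 3):
        super().__init__()
        if layers < 1:
            raise ValueError(f"LRM needs at least one layer, got {layers}")
        if kernel % 2 == 0:
            raise ValueError(f"LRM depthwise kernel must be odd, got {kernel}")
        self.n_layers = layers
        self.kernel = kernel
        self.dw = nn.Sequential(*[
            nn.Conv2d(rng, channels, channels, kernel, groups=channels)
            for _ in range(layers)
        ])
        self.pw = nn.Sequential(*[
            nn.Conv2d(rng, channels, channels, 1) for _ in range(layers)
        ])

    def forward(self, x):
        for dw, pw in zip(self.dw.layers, self.pw.layers):
            x = dw(x) + pw(x) + x
        return x


class DoubleConv(nn.Module):
    """Two consecutive 3x3 conv+BN+ReLU layers — the plain U-Net stage."""

    def __init__(self, rng, in_channels: int, out_channels: int):
        super().__init__()
        self.conv1 = nn.ConvBNReLU(rng, in_channels, out_channels, 3)
        self.conv2 = nn.ConvBNReLU(rng, out_channels, out_channels, 3)

    def forward(self, x):
        return self.conv2(self.conv1(x))
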