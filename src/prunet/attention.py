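"""Convolutional block attention: channel gate, spatial gate, composition.

Given a feature map F of shape (N, C, H, W), the channel gate produces
Mc in (0,1)^(N,C,1,1) by pushing the global-average-pooled and
global-max-pooled channel descriptors through one shared two-layer
perceptron (C -> C/r -> C, no biases), summing the two outputs and applying
a sigmoid. The channel-refined map is F' = Mc * F. The spatial gate then
produces Ms in (0,1)^(N,1,H,W) by convolving the concatenated channel-mean
and channel-max maps of F' with a single k x k kernel (odd k, same padding,
one bias) and applying a sigmoid; the output is F'' = Ms * F'. Both gates
are multiplicative and strictly inside (0,1), so on non-negative
activations attention can only attenuate.
"""

from __future__ import annotations

import logging

import numpy as np

from . import nn
from .nn import Tensor

logger = logging.getLogger(__name__)

_CLAMP_WARNED: set[tuple[int, int]] = set()


def _as_feature_tensor(x) -> Tensor:
    t = x if isinstance(x, Tensor) else Tensor(x)
    if t.ndim == 3:  # single sample C,H,W
        t = Tensor(t.data[None]) if not isinstance(x, Tensor) else t
    if t.ndim != 4:
        raise ValueError(f"expected a (N,C,H,W) feature map, got shape {t.shape}")
    if t.data.size == 0:
        raise ValueError("empty feature map")
    return t


class ChannelAttention(nn.Module):
    """Per-channel gate from pooled descriptors through a shared MLP."""

    def __init__(self, channels: int, reduction: int = 16, rng=None):
        super().__init__()
        if channels < 1:
            raise ValueError("channels must be positive")
        self.channels = channels
        self.reduction = reduction
        hidden = channels // reduction
        if hidden < 1 or channels % reduction:
            hidden = max(hidden, 1)
            if (channels, reduction) not in _CLAMP_WARNED:
                _CLAMP_WARNED.add((channels, reduction))
                logger.warning(
                    "channel attention: C=%d not divisible by r=%d; hidden "
                    "width clamped to %d", channels, reduction, hidden)
        self.hidden = hidden
        # shared two-layer perceptron, realised as 1x1 convs without biases
        self.fc1 = nn.Conv2d(channels, hidden, kernel_size=1, bias=False, rng=rng)
        self.fc2 = nn.Conv2d(hidden, channels, kernel_size=1, bias=False, rng=rng)

    def forward(self, x) -> Tensor:
        x = _as_feature_tensor(x)
        avg = nn.global_avg_pool(x)
        mx = nn.global_max_pool(x)
        score = nn.add(
            self.fc2(nn.relu(self.fc1(avg))),
            self.fc2(nn.relu(self.fc1(mx))),
        )
        return nn.sigmoid(score)  # (N,C,1,1)


class SpatialAttention(nn.Module):
    """Per-pixel gate from channel-pooled maps through one k x k conv."""

    def __init__(self, kernel_size: int = 7, rng=None):
        super().__init__()
        if kernel_size % 2 == 0:
            raise ValueError(f"spatial attention kernel must be odd, got {kernel_size}")
        self.kernel_size = kernel_size
        self.conv = nn.Conv2d(2, 1, kernel_size=kernel_size, bias=True, rng=rng)

    def forward(self, x) -> Tensor:
        x = _as_feature_tensor(x)
        pooled = nn.concat([nn.channel_mean(x), nn.channel_max(x)], axis=1)
        return nn.sigmoid(self.conv(pooled))  # (N,1,H,W)


class CBAM(nn.Module):
    """Channel-then-spatial attention; preserves the feature-map shape."""

    def __init__(self, channels: int, reduction: int = 16, kernel_size: int = 7,
                 rng=None):
        super().__init__()
        self.channel_gate = ChannelAttention(channels, reduction, rng=rng)
        self.spatial_gate = SpatialAttention(kernel_size, rng=rng)

    def forward(self, x) -> Tensor:
        x = _as_feature_tensor(x)
        mc = self.channel_gate(x)
        refined = nn.mul(x, mc)
        ms = self.spatial_gate(refined)
        return nn.mul(refined, ms)


# -- functional conveniences (NumPy in, NumPy out) --------------------------

def channel_attention(feature_map: np.ndarray, reduction: int = 16,
                      seed: int = 0) -> np.ndarray:
    """Channel map Mc of a freshly He-initialised gate (single sample ok)."""
    fm = np.asarray(feature_map)
    single = fm.ndim == 3
    gate = ChannelAttention(fm.shape[-3], reduction,
                            rng=np.random.default_rng(seed))
    with nn.no_grad():
        out = gate(fm[None] if single else fm).data
    return out[0] if single else out


def spatial_attention(feature_map: np.ndarray, kernel_size: int = 7,
                      seed: int = 0) -> np.ndarray:
    """Spatial map Ms of a freshly He-initialised gate."""
    fm = np.asarray(feature_map)
    single = fm.ndim == 3
    gate = SpatialAttention(kernel_size, rng=np.random.default_rng(seed))
    with nn.no_grad():
        out = gate(fm[None] if single else fm).data
    return out[0] if single else out


def apply_cbam(feature_map: np.ndarray, reduction: int = 16,
               kernel_size: int = 7, seed: int = 0) -> np.ndarray:
    """F'' for a freshly He-initialised CBAM block."""
    fm = np.asarray(feature_map)
    single = fm.ndim == 3
    block = CBAM(fm.shape[-3], reduction, kernel_size,
                 rng=np.random.default_rng(seed))
    with nn.no_grad():
        out = block(fm[None] if single else fm).data
    return out[0] if single else out
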