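"""Skip-connection topologies for the encoder-decoder family.

A topology maps each decoder level i (1 = full resolution, N = bottleneck)
to an ordered list of sources. Each source names an encoder or decoder
level, the rescaling it needs to reach decoder i's resolution, and the
branch transform applied to it:

``S``  same-scale encoder: conv + BN + ReLU;
``M``  shallower encoder: max-pool down, then the transform;
``U``  deeper decoder: upsample, then the transform.

Three topologies are supported. The classic UNet wires decoder i to the
same-level encoder and the next-deeper decoder. UNet 3+ wires decoder i to
*all* shallower/same-level encoders and *all* deeper decoders (full-scale
skip connections). The pruned variant keeps, of those, only the same-level
encoder, the next-deeper decoder and the encoder two levels shallower —
dropping the adjacent sources whose contribution is nearly redundant —
except at the top level, which instead collects the decoders at levels
2..N-2. Level N has no decoder block: the bottleneck encoder output is used
directly wherever decoder N is named as a source.
"""

from __future__ import annotations

from typing import NamedTuple

from .config import VARIANTS, UnknownVariantError


class SkipSource(NamedTuple):
    """One input branch of a decoder block.

    ``scale`` is a signed power-of-two exponent: a source at level j feeding
    decoder i carries scale = j - i, positive when the source is coarser and
    must be upsampled by 2**(j-i), negative when it is finer and must be
    max-pooled down by 2**(i-j).
    """

    role: str        # "encoder" | "decoder"
    level: int       # 1-based level of the source
    scale: int       # signed exponent, factor = 2**|scale|
    transform: str   # "S" | "M" | "U"


def build_skip_topology(variant: str, n_levels: int) -> dict[int, list[SkipSource]]:
    """Return {decoder level i: ordered sources} for i in 1..n_levels-1."""
    if variant not in VARIANTS:
        raise UnknownVariantError(
            f"unknown variant {variant!r}; expected one of {VARIANTS}")
    if n_levels < 3:
        raise ValueError(f"n_levels must be >= 3, got {n_levels}")
    n = n_levels
    topo: dict[int, list[SkipSource]] = {}
    for i in range(1, n):
        if variant == "unet":
            topo[i] = [
                SkipSource("encoder", i, 0, "S"),
                SkipSource("decoder", i + 1, 1, "U"),
            ]
        elif variant == "unet3plus":
            sources = [SkipSource("encoder", j, j - i, "M") for j in range(1, i)]
            sources.append(SkipSource("encoder", i, 0, "S"))
            sources += [SkipSource("decoder", k, k - i, "U") for k in range(i + 1, n + 1)]
            topo[i] = sources
        else:  # unet3plus_pruned
            if i == 1:
                sources = [SkipSource("encoder", 1, 0, "S")]
                sources += [SkipSource("decoder", k, k - 1, "U") for k in range(2, n - 1)]
            else:
                sources = []
                if i - 2 >= 1:
                    sources.append(SkipSource("encoder", i - 2, -2, "M"))
                sources.append(SkipSource("encoder", i, 0, "S"))
                sources.append(SkipSource("decoder", i + 1, 1, "U"))
            topo[i] = sources
    return topo


def n_branches(topology: dict[int, list[SkipSource]]) -> dict[int, int]:
    """Number of fused branches per decoder level."""
    return {i: len(srcs) for i, srcs in topology.items()}
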