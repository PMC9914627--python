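"""Declarative model configuration.

``ArchConfig`` names one member of the model family (which skip topology,
which encoder widths, attention on or off). ``ConventionSet`` pins down the
block-level degrees of freedom that a topology alone does not determine —
conv biases, batch norm in the rescale branches, the upsampling operator,
the fusion-width rule and the classic-decoder composition. Every reported
parameter count is meaningful only relative to a convention set, so the set
serialises alongside any count.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import yaml

logger = logging.getLogger(__name__)

VARIANTS = ("unet", "unet3plus", "unet3plus_pruned")


class UnknownVariantError(ValueError):
    """Raised for a variant name outside the supported family."""


@dataclass(frozen=True)
class ConventionSet:
    """Architectural choices shared by every variant.

    conv_bias
        Bias terms on the 3x3/branch convolutions (the batch norm that
        follows makes them redundant, hence default off).
    encoder_convs_per_block
        Number of conv+BN+ReLU stages per encoder level.
    upsample_mode
        Upsampling operator of the classic decoder: ``bilinear``
        interpolation, or ``transposed`` (a learned 2x2 stride-2 convolution
        that halves the channels). The full-scale family's branch
        upsampling is always bilinear.
    fusion_out_rule
        Output width of the decoder fusion convolution: ``per_branch``
        (branch width x number of branches, the full-scale family's
        published rule) or ``branch_width`` (a fixed narrow fusion).
    classic_up_reduce
        Channel-reduction conv applied after upsampling in the classic
        decoder: ``none``, ``conv2`` (2x2) or ``conv3`` (3x3); with
        ``transposed`` upsampling the transposed conv itself halves the
        channels and this field is ignored.
    batchnorm_in_branches
        Batch norm inside the per-source rescale-transform branches
        (default off: the calibrated best-fit set; the fusion conv that
        follows every branch concatenation always carries batch norm).
    final_head
        Fixed, descriptive: 1x1 conv with bias for the classic decoder,
        3x3 conv with bias for the full-scale family, sigmoid output.
    """

    conv_bias: bool = False
    encoder_convs_per_block: int = 2
    upsample_mode: str = "bilinear"
    fusion_out_rule: str = "per_branch"
    classic_up_reduce: str = "none"
    batchnorm_in_branches: bool = False
    final_head: str = "1x1 conv + bias (classic) / 3x3 conv + bias (full-scale), sigmoid"

    def __post_init__(self):
        if self.upsample_mode not in ("bilinear", "transposed"):
            raise ValueError(f"unknown upsample_mode {self.upsample_mode!r}")
        if self.fusion_out_rule not in ("per_branch", "branch_width"):
            raise ValueError(f"unknown fusion_out_rule {self.fusion_out_rule!r}")
        if self.classic_up_reduce not in ("none", "conv2", "conv3"):
            raise ValueError(f"unknown classic_up_reduce {self.classic_up_reduce!r}")
        if self.encoder_convs_per_block < 1:
            raise ValueError("encoder_convs_per_block must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ConventionSet":
        return cls(**d)


@dataclass(frozen=True)
class ArchConfig:
    """One model variant: topology, widths and attention flag."""

    variant: str = "unet3plus_pruned"
    attention: bool = False
    encoder_widths: tuple = (64, 128, 256, 512, 1024)
    in_channels: int = 3
    out_channels: int = 1
    branch_width: int | None = None
    cbam_reduction: int = 16
    cbam_kernel: int = 7
    conventions: ConventionSet = field(default_factory=ConventionSet)

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise UnknownVariantError(
                f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        widths = tuple(int(w) for w in self.encoder_widths)
        object.__setattr__(self, "encoder_widths", widths)
        if len(widths) < 3:
            raise ValueError("encoder_widths needs at least 3 levels")
        if any(w <= 0 for w in widths) or any(b >= a for b, a in zip(widths, widths[1:])):
            raise ValueError("encoder_widths must be positive and strictly increasing")
        if self.in_channels < 1 or self.out_channels < 1:
            raise ValueError("in_channels and out_channels must be positive")
        if self.branch_width is None:
            object.__setattr__(self, "branch_width", widths[0])
        if self.branch_width <= 0:
            raise ValueError("branch_width must be positive")
        if self.attention and self.variant != "unet3plus_pruned":
            logger.warning(
                "attention=True with variant=%s: supported, but the attention "
                "module is designed for the pruned decoder", self.variant)

    @property
    def n_levels(self) -> int:
        return len(self.encoder_widths)

    # -- (de)serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["encoder_widths"] = list(self.encoder_widths)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ArchConfig":
        d = dict(d)
        if "conventions" in d and isinstance(d["conventions"], dict):
            d["conventions"] = ConventionSet.from_dict(d["conventions"])
        if "encoder_widths" in d:
            d["encoder_widths"] = tuple(d["encoder_widths"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ArchConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
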