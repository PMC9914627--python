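"""Assembly of the segmentation model family and parameter accounting.

All three topologies share one encoder (``encoder_convs_per_block`` stages
of 3x3 conv + BN + ReLU per level, max-pool 2 between levels). The
full-scale and pruned variants share one decoder-block design: every source
listed by the skip topology is rescaled to the decoder's resolution,
projected to ``branch_width`` channels by a 3x3 conv (+BN+ReLU per the
convention set), the branches are concatenated, fused by a 3x3 conv + BN,
optionally refined by CBAM, and passed through a ReLU. The classic UNet
decoder upsamples, optionally reduces channels, concatenates the same-level
encoder map, and applies two 3x3 conv+BN+ReLU stages. A 1-channel sigmoid
head yields per-pixel foreground probabilities.

The bottleneck encoder output doubles as "decoder N": no block is built at
level N and any topology source naming decoder N reads the encoder feature
directly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import nn
from .config import ArchConfig, ConventionSet
from .nn import Tensor
from .topology import SkipSource, build_skip_topology


class ConvBNReLU(nn.Module):
    def __init__(self, cin, cout, kernel=3, bias=False, bn=True, relu=True, rng=None):
        super().__init__()
        self.conv = nn.Conv2d(cin, cout, kernel, bias=bias, rng=rng)
        self.bn = nn.BatchNorm2d(cout) if bn else None
        self.relu = relu

    def forward(self, x):
        x = self.conv(x)
        if self.bn is not None:
            x = self.bn(x)
        return nn.relu(x) if self.relu else x


class EncoderBlock(nn.Module):
    def __init__(self, cin, cout, conventions: ConventionSet, rng=None):
        super().__init__()
        stages = []
        for s in range(conventions.encoder_convs_per_block):
            stages.append(ConvBNReLU(cin if s == 0 else cout, cout,
                                     bias=conventions.conv_bias, rng=rng))
        self.stages = nn.ModuleList(stages)

    def forward(self, x):
        for stage in self.stages:
            x = stage(x)
        return x


class BranchTransform(nn.Module):
    """Rescale one skip source and project it to the branch width."""

    def __init__(self, source: SkipSource, src_channels: int, branch_width: int,
                 conventions: ConventionSet, rng=None):
        super().__init__()
        self.source = source
        factor = 2 ** abs(source.scale)
        resample: nn.Module
        conv_in = src_channels
        if source.transform == "M":
            resample = nn.MaxPool2d(factor)
        elif source.transform == "U":
            # branch upsampling is always bilinear; the learned-transposed
            # option only concerns the classic decoder
            resample = nn.Upsample(factor)
        else:  # "S"
            resample = nn.Identity()
        self.resample = resample
        self.proj = ConvBNReLU(conv_in, branch_width, bias=conventions.conv_bias,
                               bn=conventions.batchnorm_in_branches, rng=rng)

    def forward(self, x):
        return self.proj(self.resample(x))


class DecoderBlock(nn.Module):
    """Branch transforms -> concat -> fusion conv + BN -> [CBAM] -> ReLU."""

    def __init__(self, sources: list[SkipSource], src_channels: list[int],
                 config: ArchConfig, rng=None, rng_attn=None):
        super().__init__()
        conv = config.conventions
        bw = config.branch_width
        self.branches = nn.ModuleList([
            BranchTransform(src, ch, bw, conv, rng=rng)
            for src, ch in zip(sources, src_channels)
        ])
        self.fusion_in_channels = bw * len(sources)
        if conv.fusion_out_rule == "per_branch":
            self.out_channels = self.fusion_in_channels
        else:
            self.out_channels = bw
        self.fusion = ConvBNReLU(self.fusion_in_channels, self.out_channels,
                                 bias=conv.conv_bias, bn=True, relu=False, rng=rng)
        if config.attention:
            from .attention import CBAM
            self.cbam = CBAM(self.out_channels, config.cbam_reduction,
                             config.cbam_kernel, rng=rng_attn)
        else:
            self.cbam = None

    def forward(self, inputs: list[Tensor]) -> Tensor:
        fused = self.fusion(nn.concat(
            [branch(x) for branch, x in zip(self.branches, inputs)], axis=1))
        if self.cbam is not None:
            fused = self.cbam(fused)
        return nn.relu(fused)


class ClassicUp(nn.Module):
    """Classic UNet decoder stage: upsample [+reduce], concat skip, double conv."""

    def __init__(self, cin_deep, cin_skip, cout, conventions: ConventionSet, rng=None):
        super().__init__()
        conv = conventions
        self.reduce = None
        up_out = cin_deep
        if conv.upsample_mode == "transposed":
            self.up = nn.ConvTranspose2x2(cin_deep, cin_deep // 2,
                                          bias=conv.conv_bias, rng=rng)
            up_out = cin_deep // 2
        else:
            self.up = nn.Upsample(2)
            if conv.classic_up_reduce != "none":
                k = 2 if conv.classic_up_reduce == "conv2" else 3
                self.reduce = ConvBNReLU(cin_deep, cin_deep // 2, kernel=k,
                                         bias=conv.conv_bias, rng=rng)
                up_out = cin_deep // 2
        cat = up_out + cin_skip
        self.conv1 = ConvBNReLU(cat, cout, bias=conv.conv_bias, rng=rng)
        self.conv2 = ConvBNReLU(cout, cout, bias=conv.conv_bias, rng=rng)
        self.out_channels = cout

    def forward(self, deep, skip):
        x = self.up(deep)
        if self.reduce is not None:
            x = self.reduce(x)
        x = nn.concat([skip, x], axis=1)
        return self.conv2(self.conv1(x))


class SegmentationNet(nn.Module):
    """One assembled variant of the encoder-decoder family."""

    def __init__(self, config: ArchConfig, seed: int = 0, init: str = "he"):
        super().__init__()
        self.config = config
        widths = config.encoder_widths
        n = config.n_levels
        if init == "he":
            ss = np.random.SeedSequence(seed)
            s_main, s_attn = ss.spawn(2)
            rng = np.random.default_rng(s_main)
            rng_attn = np.random.default_rng(s_attn)
        elif init == "zeros":
            rng = rng_attn = None
        else:
            raise ValueError(f"unknown init {init!r}")

        self.topology = build_skip_topology(config.variant, n)

        # encoder
        enc = []
        cin = config.in_channels
        for w in widths:
            enc.append(EncoderBlock(cin, w, config.conventions, rng=rng))
            cin = w
        self.encoder = nn.ModuleList(enc)
        self.pool = nn.MaxPool2d(2)

        # decoder channel bookkeeping; decoder N is the bottleneck itself
        de_ch = {n: widths[-1]}

        def source_channels(src: SkipSource) -> int:
            if src.role == "encoder":
                return widths[src.level - 1]
            return de_ch[src.level]

        decoders: dict[int, nn.Module] = {}
        if config.variant == "unet":
            for i in range(n - 1, 0, -1):
                block = ClassicUp(de_ch[i + 1], widths[i - 1], widths[i - 1],
                                  config.conventions, rng=rng)
                de_ch[i] = block.out_channels
                decoders[i] = block
        else:
            for i in range(n - 1, 0, -1):
                sources = self.topology[i]
                block = DecoderBlock(sources, [source_channels(s) for s in sources],
                                     config, rng=rng, rng_attn=rng_attn)
                de_ch[i] = block.out_channels
                decoders[i] = block
        for i, block in decoders.items():
            setattr(self, f"de{i}", block)
        self._decoder_levels = sorted(decoders)
        self.decoder_channels = dict(de_ch)

        head_kernel = 1 if config.variant == "unet" else 3
        self.head = nn.Conv2d(de_ch[1], config.out_channels, head_kernel,
                              bias=True, rng=rng)

    # -- forward -----------------------------------------------------------
    def decoder_block(self, level: int) -> nn.Module:
        return getattr(self, f"de{level}")

    def forward(self, x) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(x)
        if x.ndim != 4:
            raise ValueError(f"expected (N,C,H,W) input, got shape {x.shape}")
        n_lv = self.config.n_levels
        _, c, h, w = x.shape
        if c != self.config.in_channels:
            raise ValueError(
                f"expected {self.config.in_channels} input channels, got {c}")
        divisor = 2 ** (n_lv - 1)
        if h % divisor or w % divisor:
            raise ValueError(
                f"input height and width must be divisible by {divisor} "
                f"for {n_lv} levels; got {(h, w)}")

        feats: dict[tuple[str, int], Tensor] = {}
        cur = x
        for i, block in enumerate(self.encoder, start=1):
            if i > 1:
                cur = self.pool(cur)
            cur = block(cur)
            feats[("encoder", i)] = cur
        feats[("decoder", n_lv)] = feats[("encoder", n_lv)]  # bottleneck reuse

        if self.config.variant == "unet":
            for i in range(n_lv - 1, 0, -1):
                block = self.decoder_block(i)
                feats[("decoder", i)] = block(
                    feats[("decoder", i + 1)], feats[("encoder", i)])
        else:
            for i in range(n_lv - 1, 0, -1):
                block = self.decoder_block(i)
                inputs = [feats[(s.role, s.level)] for s in self.topology[i]]
                feats[("decoder", i)] = block(inputs)

        return nn.sigmoid(self.head(feats[("decoder", 1)]))

    def predict_proba(self, x) -> np.ndarray:
        """Probability maps as a NumPy array, without building a graph."""
        was_training = self.training
        self.eval()
        with nn.no_grad():
            out = self.forward(x).data
        if was_training:
            self.train()
        return out


def assemble_model(config: ArchConfig, seed: int = 0, init: str = "he") -> SegmentationNet:
    """Build a trainable model from a config (deterministic given the seed)."""
    return SegmentationNet(config, seed=seed, init=init)


def count_parameters(model: nn.Module) -> int:
    """Exact number of trainable scalars."""
    return model.num_parameters()


def params_millions(model_or_count) -> float:
    """Count in millions, rounded to two decimals (the reporting unit)."""
    count = model_or_count if isinstance(model_or_count, (int, np.integer)) \
        else count_parameters(model_or_count)
    return round(count / 1e6, 2)


def parameter_breakdown(model: nn.Module) -> dict[str, int]:
    """Split the count into conv weights, biases and norm parameters."""
    out = {"conv_weight": 0, "bias": 0, "norm": 0}
    for name, p in model.named_parameters():
        leaf = name.rsplit(".", 1)[-1]
        if leaf == "weight":
            out["conv_weight"] += p.data.size
        elif leaf == "bias":
            out["bias"] += p.data.size
        else:  # gamma/beta
            out["norm"] += p.data.size
    return out


def model_summary(model: SegmentationNet, size: int = 64) -> pd.DataFrame:
    """Per-layer table (name, type, output shape, parameter count).

    Runs a single dummy forward pass to trace output shapes; ``size`` must
    satisfy the model's divisibility constraint.
    """
    dummy = np.zeros((1, model.config.in_channels, size, size),
                     dtype=nn.default_dtype())
    was_training = model.training
    model.eval()
    with nn.no_grad():
        model.forward(dummy)
    if was_training:
        model.train()
    rows = []
    for name, mod in model.named_modules():
        if not name or mod._params == {}:
            continue
        own = sum(p.data.size for p in mod._params.values())
        rows.append({
            "layer": name,
            "type": type(mod).__name__,
            "output_shape": str(getattr(mod, "_out_shape", None)),
            "n_params": own,
        })
    df = pd.DataFrame(rows)
    df.loc[len(df)] = {"layer": "TOTAL", "type": "", "output_shape": "",
                       "n_params": count_parameters(model)}
    return df
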