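"""Model assembly, forward contracts and parameter accounting."""

import numpy as np
import pytest
import yaml

from prunet import nn
from prunet.attention import CBAM
from prunet.calibration import convention_space, count_for
from prunet.config import ArchConfig, ConventionSet
from prunet.models import (
    assemble_model,
    count_parameters,
    model_summary,
    parameter_breakdown,
    params_millions,
)


class TestParameterCounting:
    def test_single_conv_bn_closed_form(self):
        """3x3 conv 1->1 with bias (10) plus batch norm over 1 channel (2)."""
        class Tiny(nn.Module):
            def __init__(self):
                super().__init__()
                self.conv = nn.Conv2d(1, 1, 3, bias=True)
                self.bn = nn.BatchNorm2d(1)

        assert Tiny().num_parameters() == 12

    def test_cbam_closed_form_at_64_channels(self):
        """Shared MLP 64->4->4->64 without biases plus a 7x7 conv on the
        2-channel pooled map with one bias: 2*(64*4) + (7*7*2 + 1) = 611."""
        assert CBAM(64, reduction=16, kernel_size=7).num_parameters() == 611

    def test_millions_reporting_rounds_to_two_decimals(self):
        assert params_millions(21_653_377) == 21.65

    def test_breakdown_partitions_total(self):
        model = assemble_model(ArchConfig(variant="unet3plus_pruned",
                                          encoder_widths=(8, 16, 32)),
                               init="zeros")
        parts = parameter_breakdown(model)
        assert sum(parts.values()) == count_parameters(model)


class TestAssembly:
    def test_pruned_decoder_fuses_three_branches(self, small_widths):
        model = assemble_model(ArchConfig(variant="unet3plus_pruned",
                                          encoder_widths=small_widths),
                               init="zeros")
        assert model.decoder_block(3).fusion_in_channels == 3 * model.config.branch_width

    def test_no_decoder_block_at_bottleneck_level(self, small_widths):
        model = assemble_model(ArchConfig(variant="unet3plus_pruned",
                                          encoder_widths=small_widths),
                               init="zeros")
        assert model._decoder_levels == [1, 2, 3, 4]
        assert not hasattr(model, "de5")

    def test_attention_insertion_preserves_backbone_weights(self):
        """Same seed with and without CBAM: every shared parameter is
        bitwise identical; only the attention blocks are new."""
        widths = (8, 16, 32, 64)
        plain = assemble_model(ArchConfig(variant="unet3plus_pruned",
                                          encoder_widths=widths), seed=3)
        attn = assemble_model(ArchConfig(variant="unet3plus_pruned",
                                         encoder_widths=widths,
                                         attention=True), seed=3)
        sd_plain = {k: v for k, v in plain.state_dict().items()
                    if k.startswith("param:")}
        sd_attn = {k: v for k, v in attn.state_dict().items()
                   if k.startswith("param:")}
        extra = set(sd_attn) - set(sd_plain)
        assert extra and all("cbam" in k for k in extra)
        for k, v in sd_plain.items():
            assert np.array_equal(v, sd_attn[k]), k

    def test_config_yaml_round_trip(self, tmp_path):
        cfg = ArchConfig(variant="unet3plus", encoder_widths=(8, 16, 32, 64),
                         attention=False, branch_width=8,
                         conventions=ConventionSet(conv_bias=True))
        path = tmp_path / "arch.yaml"
        cfg.to_yaml(path)
        assert ArchConfig.from_yaml(path) == cfg
        assert yaml.safe_load(path.read_text())["conventions"]["conv_bias"] is True

    def test_summary_totals_match_count(self):
        cfg = ArchConfig(variant="unet3plus_pruned", attention=True,
                         encoder_widths=(8, 16, 32))
        model = assemble_model(cfg, init="zeros")
        df = model_summary(model, size=16)
        total_row = df[df["layer"] == "TOTAL"]["n_params"].iloc[0]
        assert total_row == count_parameters(model)
        assert df["n_params"].iloc[:-1].sum() == total_row

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            ArchConfig(encoder_widths=(8, 16))          # too few levels
        with pytest.raises(ValueError):
            ArchConfig(encoder_widths=(16, 8, 32))      # not increasing


@pytest.fixture(scope="module")
def model():
    cfg = ArchConfig(variant="unet3plus_pruned", attention=True,
                     encoder_widths=(8, 16, 32, 64, 128))
    return assemble_model(cfg, seed=0)


class TestForward:

    def test_output_shape_and_open_interval_range(self, model):
        x = np.random.default_rng(0).random((2, 3, 64, 64), dtype=np.float32)
        out = model.predict_proba(x)
        assert out.shape == (2, 1, 64, 64)
        assert (out > 0).all() and (out < 1).all()

    def test_indivisible_input_rejected_naming_divisor(self, model):
        x = np.zeros((1, 3, 100, 100), dtype=np.float32)
        with pytest.raises(ValueError, match="16"):
            model.predict_proba(x)

    def test_determinism_same_seed_same_output(self):
        cfg = ArchConfig(variant="unet3plus_pruned", encoder_widths=(8, 16, 32))
        x = np.random.default_rng(1).random((2, 3, 16, 16), dtype=np.float32)
        outs = [assemble_model(cfg, seed=9).predict_proba(x) for _ in range(2)]
        assert np.array_equal(outs[0], outs[1])

    def test_batch_permutation_equivariance(self, model):
        x = np.random.default_rng(2).random((4, 3, 32, 32), dtype=np.float32)
        perm = np.array([2, 0, 3, 1])
        out = model.predict_proba(x)
        out_perm = model.predict_proba(x[perm])
        assert np.allclose(out[perm], out_perm, atol=1e-6)

    @pytest.mark.parametrize("variant", ["unet", "unet3plus"])
    def test_other_variants_forward(self, variant):
        cfg = ArchConfig(variant=variant, encoder_widths=(8, 16, 32))
        model = assemble_model(cfg, seed=0)
        out = model.predict_proba(np.zeros((1, 3, 16, 16), dtype=np.float32))
        assert out.shape == (1, 1, 16, 16)


class TestCountInvariants:
    WIDTH_SETS = [(8, 16, 32, 64, 128), (16, 32, 64, 128, 256),
                  (64, 128, 256, 512, 1024)]

    @pytest.mark.parametrize("widths", WIDTH_SETS)
    def test_pruning_strictly_orders_counts(self, widths):
        cs = ConventionSet()
        pruned = count_for("unet3plus_pruned", widths, False, cs)
        full = count_for("unet3plus", widths, False, cs)
        classic = count_for("unet", widths, False, cs)
        assert pruned < full < classic

    def test_ordering_holds_across_convention_space(self):
        """Pruned < full-scale < classic for every documented convention."""
        widths = (8, 16, 32, 64, 128)
        for cs in convention_space():
            pruned = count_for("unet3plus_pruned", widths, False, cs)
            full = count_for("unet3plus", widths, False, cs)
            classic = count_for("unet", widths, False, cs)
            assert pruned < full < classic, cs

    def test_cbam_adds_less_than_half_percent_at_full_widths(self):
        cs = ConventionSet()
        widths = (64, 128, 256, 512, 1024)
        base = count_for("unet3plus_pruned", widths, False, cs)
        attn = count_for("unet3plus_pruned", widths, True, cs)
        assert base < attn
        assert (attn - base) / base < 0.005

    def test_doubling_widths_quadruples_conv_weights(self):
        """Conv-weight count scales ~4x when widths double (slightly less,
        because the image-input channels stay fixed)."""
        cfg1 = ArchConfig(variant="unet3plus_pruned",
                          encoder_widths=(8, 16, 32, 64, 128))
        cfg2 = ArchConfig(variant="unet3plus_pruned",
                          encoder_widths=(16, 32, 64, 128, 256))
        w1 = parameter_breakdown(assemble_model(cfg1, init="zeros"))["conv_weight"]
        w2 = parameter_breakdown(assemble_model(cfg2, init="zeros"))["conv_weight"]
        assert 3.5 <= w2 / w1 <= 4.0
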