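"""Architecture: shapes, residual identity, tie-breaks, and accounting."""

import numpy as np
import pytest

from breathnet.resnet1d import (
    ArchitectureConfig,
    build_model,
    count_flops,
    count_parameters,
    count_weighted_layers,
    downsample_half,
    forward,
    layer_account,
    load_checkpoint,
    save_checkpoint,
)

from conftest import closed_form_counts

rng = np.random.default_rng(0)


class TestConfig:
    def test_bad_variant(self):
        with pytest.raises(ValueError):
            ArchitectureConfig(variant="stage1_k7")

    def test_length_divisibility(self):
        with pytest.raises(ValueError, match="multiple of 8"):
            ArchitectureConfig(input_length=60)
        ArchitectureConfig(variant="ds", input_length=36)  # /4 suffices

    def test_round_trip_dict(self):
        cfg = ArchitectureConfig(variant="stage1_k3", input_channels=2)
        assert ArchitectureConfig.from_dict(cfg.to_dict()) == cfg


class TestWeightedLayerCounts:
    @pytest.mark.parametrize("variant,blocks,expected", [
        ("stage1_k5", 12, 113),
        ("stage1_k3", 12, 113),
        ("ds", 12, 110),     # 113 minus the three front-stage convolutions
        ("stage1_k5", 1, 14),  # 1 + 3 + 9 + 1
    ])
    def test_counts(self, variant, blocks, expected):
        length = 32 if variant == "ds" else 64
        cfg = ArchitectureConfig(variant=variant, blocks_per_stage=blocks,
                                 input_length=length)
        assert count_weighted_layers(cfg) == expected


class TestShapes:
    def test_stage_lengths_64_32_32_16_8_and_pooled_256(self):
        """Temporal lengths through the stages match the published table."""
        model = build_model(ArchitectureConfig(), seed=0)
        x = rng.normal(size=(2, 1, 64)).astype(np.float32)
        h = model.stem.forward(x)
        assert h.shape[2] == 64
        lengths = {}
        for stage, unit in model.units:
            h = unit.forward(h)
            lengths[stage] = h.shape[2]
        assert lengths == {"stage1": 32, "stage2": 32, "stage3": 16,
                           "stage4": 8}
        pooled = model.pool.forward(model.final_relu.forward(
            model.final_bn.forward(h)))
        assert pooled.shape == (2, 256)

    def test_ds_variant_runs_on_halved_input(self):
        model = build_model(ArchitectureConfig(variant="ds", input_length=32),
                            seed=0)
        x = rng.normal(size=(3, 1, 64)).astype(np.float32)
        logits = forward(model, downsample_half(x))
        assert logits.shape == (3, 3)

    def test_batch_of_n_gives_n_by_3_logits(self, toy_arch):
        model = build_model(toy_arch, seed=0)
        x = rng.normal(size=(7, 1, 64)).astype(np.float32)
        logits = forward(model, x)
        assert logits.shape == (7, 3)
        assert np.all(np.isfinite(logits))

    def test_two_channel_input(self):
        model = build_model(ArchitectureConfig(input_channels=2,
                                               blocks_per_stage=1), seed=0)
        assert forward(model, rng.normal(size=(2, 2, 64)).astype(
            np.float32)).shape == (2, 3)

    def test_shape_mismatch_raises(self, toy_arch):
        model = build_model(toy_arch, seed=0)
        with pytest.raises(ValueError):
            forward(model, rng.normal(size=(2, 1, 32)).astype(np.float32))


class TestResidualIdentity:
    def test_zeroed_final_conv_makes_identity_unit_transparent(self):
        """With F forced to zero, x_{l+1} = x_l exactly for identity units."""
        model = build_model(ArchitectureConfig(blocks_per_stage=2), seed=0)
        units = [u for _, u in model.units if u.proj is None]
        assert units
        for unit in units:
            unit.conv3.weight.value[...] = 0.0
            x = rng.normal(size=(2, unit.bn1.channels, 16)).astype(np.float32)
            np.testing.assert_array_equal(unit.forward(x), x)

    def test_zeroed_classifier_ties_break_to_class_zero(self, toy_arch):
        model = build_model(toy_arch, seed=0)
        model.fc.weight.value[...] = 0.0
        model.fc.bias.value[...] = 0.0
        preds = model.predict(rng.normal(size=(5, 1, 64)).astype(np.float32))
        np.testing.assert_array_equal(preds, 0)


class TestDeterminismAndInference:
    def test_seeded_build_identical_weights(self):
        a = build_model(ArchitectureConfig(blocks_per_stage=2), seed=9)
        b = build_model(ArchitectureConfig(blocks_per_stage=2), seed=9)
        for pa, pb in zip(a.params(), b.params()):
            np.testing.assert_array_equal(pa.value, pb.value)
        c = build_model(ArchitectureConfig(blocks_per_stage=2), seed=10)
        assert any(not np.array_equal(pa.value, pc.value)
                   for pa, pc in zip(a.params(), c.params()))

    def test_inference_deterministic(self, toy_arch):
        model = build_model(toy_arch, seed=0)
        x = rng.normal(size=(4, 1, 64)).astype(np.float32)
        np.testing.assert_array_equal(forward(model, x), forward(model, x))

    def test_checkpoint_round_trip(self, toy_arch, tmp_path):
        model = build_model(toy_arch, seed=3)
        x = rng.normal(size=(4, 1, 64)).astype(np.float32)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(model, path)
        restored = load_checkpoint(path)
        assert restored.config == model.config
        np.testing.assert_array_equal(forward(restored, x), forward(model, x))


class TestAccounting:
    @pytest.mark.parametrize("variant,blocks,channels,length", [
        ("stage1_k5", 12, 1, 64),
        ("stage1_k3", 12, 2, 64),
        ("ds", 12, 1, 32),
        ("stage1_k5", 1, 1, 64),
    ])
    def test_counts_match_independent_closed_form_ledger(
            self, variant, blocks, channels, length):
        cfg = ArchitectureConfig(variant=variant, blocks_per_stage=blocks,
                                 input_channels=channels, input_length=length)
        model = build_model(cfg, seed=0)
        account = layer_account(model)
        expected = closed_form_counts(variant, blocks, channels, length)
        assert account.parameter_count == expected["main_path_params"]
        assert account.total_parameter_count == expected["total_params"]
        assert account.flop_count == expected["flops"]
        assert count_parameters(model) == expected["total_params"]
        assert count_parameters(model, include_projections=False) \
            == expected["main_path_params"]
        assert count_flops(model) == expected["flops"]

    def test_headline_figures(self):
        """The published budget: 113 layers, 0.7 M parameters, 15 M FLOPs."""
        model = build_model(ArchitectureConfig(), seed=0)
        account = layer_account(model)
        assert account.weighted_layer_count == 113
        assert round(account.parameter_count / 1e6, 1) == 0.7
        assert round(account.flop_count / 1e6) == 15

    def test_component_examples(self):
        """Stem conv: 80 params, 10240 FLOPs at length 64; classifier:
        771 params, 1536 FLOPs."""
        model = build_model(ArchitectureConfig(), seed=0)
        account = layer_account(model)
        stage0 = account.per_stage[0]
        assert stage0["parameters"] == 80
        assert stage0["flops"] == 2 * 5 * 1 * 16 * 64 == 10240
        head = account.per_stage[-1]
        assert model.fc.weight.size + model.fc.bias.size == 256 * 3 + 3 == 771
        assert head["flops"] == 2 * 256 * 3 == 1536

    def test_totals_equal_breakdown_sum(self):
        account = layer_account(build_model(ArchitectureConfig(
            blocks_per_stage=2), seed=0))
        assert account.flop_count == sum(r["flops"] for r in account.per_stage)
        assert account.parameter_count == sum(
            r["parameters"] for r in account.per_stage)
        assert all(r["flops"] >= 0 for r in account.per_stage)

    def test_render_mentions_megafigures(self):
        text = layer_account(build_model(ArchitectureConfig(), seed=0)).render()
        assert "0.7 M" in text and "15.0 M" in text


class TestDownsample:
    def test_subsample_every_second(self):
        x = np.arange(8.0).reshape(1, 1, 8)
        np.testing.assert_array_equal(downsample_half(x)[0, 0], [0, 2, 4, 6])

    def test_average_pairs(self):
        x = np.arange(8.0).reshape(1, 1, 8)
        np.testing.assert_array_equal(
            downsample_half(x, "average")[0, 0], [0.5, 2.5, 4.5, 6.5])

    def test_odd_length_rejected(self):
        with pytest.raises(ValueError):
            downsample_half(np.zeros((1, 1, 7)))
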