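"""Cost model: shape inference, FLOPs/parameter formulas, brute-force oracle."""

import pytest

from nar.errors import ShapeError
from nar.cost import (conv_flops, cost_report, count_params, dense_flops,
                      infer_shapes)
from nar.ir import (BlockSpec, LayerSpec, NetworkSpec, StageSpec, TensorShape)
from nar.reduce import ScalingCoefficients, compound_reduce, input_reduce


def conv(filters, kernel, stride=1, padding="same", bias=True):
    return LayerSpec(kind="conv", kernel=(kernel, kernel), filters=filters,
                     stride=(stride, stride), padding=padding, bias=bias)


def micro_net(layers, side=10, channels=3, n_classes=2):
    """Wrap a few layers into a minimal valid network for the walker."""
    return NetworkSpec(
        name="micro", input=TensorShape(side, side, channels),
        stem=[LayerSpec(kind="input"), *layers],
        stages=[],
        head=[LayerSpec(kind="global_pool"),
              LayerSpec(kind="dense", filters=n_classes, bias=True)],
        n_classes=n_classes)


class TestShapeInference:
    def test_same_padding_ceil_division(self):
        shapes = dict(infer_shapes(micro_net([conv(64, 7, stride=2)], side=240)))
        assert shapes["stem.conv0"] == TensorShape(120, 120, 64)

    def test_same_padding_odd_input(self):
        shapes = dict(infer_shapes(micro_net([conv(8, 3, stride=2)], side=209)))
        assert shapes["stem.conv0"] == TensorShape(105, 105, 8)

    def test_valid_padding(self):
        shapes = dict(infer_shapes(micro_net(
            [conv(8, 3, stride=2, padding="valid")], side=240)))
        assert shapes["stem.conv0"] == TensorShape(119, 119, 8)

    def test_activation_preserves_shape(self):
        shapes = dict(infer_shapes(micro_net(
            [conv(8, 3), LayerSpec(kind="activation")])))
        assert shapes["stem.activation0"] == shapes["stem.conv0"]

    def test_resnet_stage_output_sides(self, resnet240):
        shapes = infer_shapes(resnet240)
        last_per_stage = {}
        for lid, shape in shapes:
            stage = lid.split(".")[0]
            last_per_stage[stage] = shape
        assert [last_per_stage[f"stage{i}"].height for i in (1, 2, 3, 4)] == \
            [60, 30, 15, 8]

    def test_concat_mismatch_names_the_layer(self):
        branch = LayerSpec(kind="branch", branches=[
            [conv(4, 3, stride=2)], [conv(4, 3, stride=1)]], merge="concat")
        with pytest.raises(ShapeError, match="branch"):
            infer_shapes(micro_net([branch]))

    def test_collapsed_extent_is_an_error(self):
        with pytest.raises(ShapeError):
            infer_shapes(micro_net([conv(4, 9, padding="valid")], side=5))


class TestFlopsFormulas:
    def test_stem_conv_flops_by_hand(self):
        # 2 * 3 * 49 * 14400 * 64, the 7x7/2 stem on a 240 input
        layer = conv(64, 7, stride=2)
        flops = conv_flops(layer, TensorShape(240, 240, 3),
                           TensorShape(120, 120, 64))
        assert flops == 270_950_400

    def test_pointwise_conv_flops(self):
        layer = conv(8, 1)
        assert conv_flops(layer, TensorShape(10, 10, 3),
                          TensorShape(10, 10, 8)) == 4_800

    def test_unit_conv(self):
        layer = conv(1, 1)
        assert conv_flops(layer, TensorShape(1, 1, 1),
                          TensorShape(1, 1, 1)) == 2

    def test_dense_flops(self):
        assert dense_flops(2048, 2) == 8_192
        assert dense_flops(1, 1) == 2


class TestParamFormulas:
    def test_dense_with_bias(self):
        net = micro_net([])
        net.head[-1] = LayerSpec(kind="dense", filters=2, bias=True)
        net.input = TensorShape(1, 1, 2048)
        assert count_params(net) == 2048 * 2 + 2

    def test_batchnorm_counts_moving_statistics(self):
        net = micro_net([LayerSpec(kind="batchnorm")], side=4, channels=16)
        dense = 16 * 2 + 2
        assert count_params(net) - dense == 4 * 16

    def test_bias_flag_controls_conv_params(self):
        with_bias = micro_net([conv(8, 3, bias=True)])
        without = micro_net([conv(8, 3, bias=False)])
        assert count_params(with_bias) - count_params(without) == 8


class TestBruteForceOracle:
    """Literal-loop enumeration of MACs and weights on a tiny network."""

    LAYERS = [conv(4, 3, stride=2, bias=True),
              conv(6, 1, bias=False),
              conv(3, 3, stride=1, padding="valid", bias=True)]

    @staticmethod
    def loop_conv_cost(cin, k, hout, wout, cout, bias):
        flops = 0
        weights = 0
        for _ in range(k * k * cin * cout):
            weights += 1
        if bias:
            weights += cout
        for _ in range(hout * wout):
            for _ in range(cout):
                for _ in range(cin * k * k):
                    flops += 2          # one multiply + one accumulate
        return flops, weights

    def test_conv_flops_and_params_match_enumeration(self):
        net = micro_net(self.LAYERS, side=9)
        report = cost_report(net)
        by_id = {r.layer_id: r for r in report.per_layer}
        # independent shape bookkeeping: 9 -> 5 (same,s2) -> 5 (1x1) -> 3 (valid)
        specs = [(3, 3, 5, 5, 4, True),    # cin, k, hout, wout, cout, bias
                 (4, 1, 5, 5, 6, False),
                 (6, 3, 3, 3, 3, True)]
        for i, spec in enumerate(specs):
            flops, weights = self.loop_conv_cost(*spec)
            rec = by_id[f"stem.conv{i}"]
            assert rec.flops == flops
            assert rec.params == weights

    def test_report_totals_equal_per_layer_sums(self, resnet240):
        report = cost_report(resnet240)
        assert report.total_flops == sum(r.flops for r in report.per_layer)
        assert report.total_params == sum(r.params for r in report.per_layer)


class TestReports:
    def test_only_conv_and_dense_carry_flops(self, resnet240):
        for rec in cost_report(resnet240).per_layer:
            if rec.kind not in ("conv", "dense"):
                assert rec.flops == 0

    def test_all_templates_cost_positive(self, resnet240, inception240):
        for net in (resnet240, inception240):
            rep = cost_report(net)
            assert rep.total_flops > 0
            assert rep.total_params > 0

    @pytest.mark.parametrize("phi", [1, 2, 3])
    def test_reduction_strictly_cheaper(self, phi, resnet240):
        base = cost_report(resnet240)
        red = cost_report(compound_reduce(resnet240,
                                          ScalingCoefficients(phi=phi)))
        assert red.total_flops < base.total_flops
        assert red.total_params < base.total_params

    def test_input_reduction_keeps_params(self, resnet240):
        base = cost_report(resnet240)
        for phi in (1, 2, 3):
            red = cost_report(input_reduce(resnet240,
                                           ScalingCoefficients(phi=phi)))
            assert red.total_params == base.total_params

    def test_gflops_rounding(self):
        from nar.cost import CostReport
        assert CostReport([], 9_607_217_152, 0).gflops == 9.61
        assert CostReport([], 2_955_000_000, 0).gflops == 2.96
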