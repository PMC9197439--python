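"""Compound reduction: factors, rounding, transforms, budget selection.

The rounding oracle freezes every unambiguous reduced repeat/width/input
cell of the published reduction of ResNet-50 V2 under (alpha, beta,
gamma) = (1.2, 1.1, 1.15); the stage-2 width pair at phi=1/2, whose
printed values are inconsistent with the scaling arithmetic (they appear
swapped), is excluded.
"""

import warnings

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nar.cost import cost_report
from nar.errors import BudgetError, SpecError
from nar.ir import serialize
from nar.reduce import (PHI_MAX, ScalingCoefficients, check_constraint,
                        choose_phi_for_budget, compound_reduce, input_reduce,
                        reduction_factors, scale_count, theoretical_ratio)


def coeff(phi):
    return ScalingCoefficients(phi=phi)


class TestFactors:
    def test_phi_zero_is_identity(self):
        assert reduction_factors(coeff(0)) == (1.0, 1.0, 1.0)

    def test_phi_one_direct_arithmetic(self):
        d, w, r = reduction_factors(coeff(1))
        assert d == pytest.approx(1 / 1.2)
        assert w == pytest.approx(1 / 1.1)
        assert r == pytest.approx(1 / 1.15)

    def test_phi_two_width(self):
        _, w, _ = reduction_factors(coeff(2))
        assert w == pytest.approx(1.1 ** -2)

    def test_invalid_coefficients_rejected(self):
        with pytest.raises(SpecError):
            ScalingCoefficients(alpha=1.0)
        with pytest.raises(SpecError):
            ScalingCoefficients(phi=-1)


class TestScaleCount:
    # (original, factor, expected) — frozen from the published reduction
    # tables; stage-2 widths at phi=1/2 excluded (printed pair is swapped).
    TABLE_CELLS = [
        # input resolution, gamma = 1.15
        (240, 1.15 ** -1, 209), (240, 1.15 ** -2, 181), (240, 1.15 ** -3, 158),
        (240, 1.15 ** -4, 137), (240, 1.15 ** -5, 119), (240, 1.15 ** -6, 104),
        # block repeats, alpha = 1.2
        (3, 1.2 ** -1, 2), (4, 1.2 ** -1, 3), (6, 1.2 ** -1, 5),
        (3, 1.2 ** -2, 2), (4, 1.2 ** -2, 3), (6, 1.2 ** -2, 4),
        (3, 1.2 ** -3, 2), (4, 1.2 ** -3, 2), (6, 1.2 ** -3, 3),
        # stage widths, beta = 1.1
        (64, 1.1 ** -1, 58), (256, 1.1 ** -1, 233), (512, 1.1 ** -1, 465),
        (64, 1.1 ** -2, 53), (256, 1.1 ** -2, 212), (512, 1.1 ** -2, 423),
        (64, 1.1 ** -3, 48), (128, 1.1 ** -3, 96), (256, 1.1 ** -3, 192),
        (512, 1.1 ** -3, 385),
    ]

    @pytest.mark.parametrize("n,factor,expected", TABLE_CELLS)
    def test_published_cells(self, n, factor, expected):
        assert scale_count(n, factor) == expected

    def test_tie_resolves_to_even(self):
        # 3 * 1.2**-1 == 2.5 exactly: half-to-even gives 2, not 3
        assert scale_count(3, 1.2 ** -1) == 2
        assert scale_count(5, 0.5) == 2
        assert scale_count(7, 0.5) == 4

    def test_clamps_to_one(self):
        assert scale_count(1, 0.5) == 1
        assert scale_count(2, 0.1) == 1

    @given(n=st.integers(1, 4096),
           factor=st.floats(0.05, 1.0, allow_nan=False))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_result_bounds_and_monotonicity(self, n, factor):
        out = scale_count(n, factor)
        assert 1 <= out <= n
        assert abs(out - n * factor) <= 0.5 + 1e-6 or out == 1
        # non-decreasing in n for fixed factor
        assert out <= scale_count(n + 1, factor)


class TestCompoundReduce:
    def test_phi1_stage_repeats(self, resnet240):
        red = compound_reduce(resnet240, coeff(1))
        assert [s.repeats for s in red.stages] == [2, 3, 5, 2]
        assert red.input.height == 209

    def test_phi3_stage4_width(self, resnet240):
        red = compound_reduce(resnet240, coeff(3))
        assert red.stages[3].base_width == 385
        widths = [c.filters for c in red.stages[3].block.scalable_convs()]
        assert widths == [385, 385, 1540]

    def test_phi_zero_is_bit_identical_after_serialization(
            self, resnet240, inception240):
        for net in (resnet240, inception240):
            assert serialize(compound_reduce(net, coeff(0))) == serialize(net)

    def test_original_is_not_modified(self, resnet240):
        before = serialize(resnet240)
        compound_reduce(resnet240, coeff(3))
        assert serialize(resnet240) == before

    def test_stem_and_classifier_are_untouched(self, resnet240):
        red = compound_reduce(resnet240, coeff(3))
        stem_conv = next(l for l in red.stem if l.kind == "conv")
        assert stem_conv.filters == 64
        assert red.n_classes == resnet240.n_classes
        assert red.input.channels == 3
        for stage, orig in zip(red.stages, resnet240.stages):
            assert stage.block.width_ratios == orig.block.width_ratios

    def test_warns_beyond_phi_three(self, resnet240):
        with pytest.warns(UserWarning, match="sequential"):
            compound_reduce(resnet240, coeff(4))

    @pytest.mark.parametrize("template", ["resnet", "inception"])
    def test_cost_monotone_in_phi(self, template, resnet240, inception240):
        net = resnet240 if template == "resnet" else inception240
        flops, params = [], []
        for phi in range(PHI_MAX + 1):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rep = cost_report(compound_reduce(net, coeff(phi)))
            flops.append(rep.total_flops)
            params.append(rep.total_params)
        assert flops == sorted(flops, reverse=True)
        assert params == sorted(params, reverse=True)


class TestInputReduce:
    def test_phi1_only_input_changes(self, resnet240):
        red = input_reduce(resnet240, coeff(1))
        assert (red.input.height, red.input.width) == (209, 209)
        assert [s.repeats for s in red.stages] == [3, 4, 6, 3]
        assert [s.base_width for s in red.stages] == [64, 128, 256, 512]

    def test_phi_zero_identity(self, resnet240):
        assert serialize(input_reduce(resnet240, coeff(0))) == \
            serialize(resnet240)

    def test_phi6_input_104(self, resnet240):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert input_reduce(resnet240, coeff(6)).input.height == 104

    def test_below_minimum_is_rejected(self):
        from nar.templates import resnet50v2_template
        small = resnet50v2_template(36, 2)
        with pytest.raises(SpecError, match="minimum"):
            input_reduce(small, coeff(2))

    def test_params_invariant_flops_drop(self, resnet240):
        base = cost_report(resnet240)
        red = cost_report(input_reduce(resnet240, coeff(2)))
        assert red.total_params == base.total_params
        assert red.total_flops < base.total_flops


class TestConstraintAndTheory:
    def test_default_triple(self):
        value, ok = check_constraint(ScalingCoefficients())
        assert value == pytest.approx(1.9203, abs=1e-4)
        assert ok

    def test_exact_two(self):
        value, ok = check_constraint(ScalingCoefficients(2.0, 1.0 + 1e-12,
                                                         1.0 + 1e-12))
        assert value == pytest.approx(2.0)
        assert ok

    def test_far_from_two_flagged(self):
        _, ok = check_constraint(
            ScalingCoefficients(1.01, 1.01, 1.01))
        assert not ok

    @pytest.mark.parametrize("phi,expected", [(0, 1.0), (1, 0.5), (3, 0.125)])
    def test_theoretical_ratio(self, phi, expected):
        assert theoretical_ratio(phi) == expected

    @pytest.mark.parametrize("phi", [1, 2, 3, 4, 5, 6])
    def test_continuous_scaling_law(self, phi):
        """d * w^2 * r^2 equals (alpha beta^2 gamma^2)^-phi exactly and
        tracks 2^-phi within 5% per unit of phi."""
        c = coeff(phi)
        d, w, r = reduction_factors(c)
        product = d * w * w * r * r
        assert product == pytest.approx(c.constraint_value ** -phi, rel=1e-9)
        per_unit = (product / theoretical_ratio(phi)) ** (1 / phi)
        assert abs(per_unit - 1.0) < 0.05


class TestBudgetSelection:
    def test_generous_budget_gives_zero(self, resnet240):
        budget = cost_report(resnet240).total_flops + 1
        assert choose_phi_for_budget(resnet240, ScalingCoefficients(),
                                     budget) == 0

    def test_matches_enumeration_oracle(self, resnet240):
        # independent oracle: enumerate phi and compare computed costs
        costs = {}
        for phi in range(PHI_MAX + 1):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                costs[phi] = cost_report(
                    compound_reduce(resnet240, coeff(phi))).total_flops
        budget = 3.0e9
        expected = min(p for p, f in costs.items() if f <= budget)
        assert expected == 2
        assert choose_phi_for_budget(resnet240, ScalingCoefficients(),
                                     budget) == expected

    def test_unattainable_budget_fails_listing_cost(self, resnet240):
        with pytest.raises(BudgetError, match="phi=6"):
            choose_phi_for_budget(resnet240, ScalingCoefficients(), 1.0)
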