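"""Compound network reduction and the input-reduction baseline.

The compound transform shrinks a network's depth, width and input
resolution together.  Given coefficients ``alpha, beta, gamma > 1`` and an
exponent ``phi >= 0``, the reduction factors are

    d = alpha ** -phi      (depth: block repeats per stage)
    w = beta  ** -phi      (width: stage base channel counts)
    r = gamma ** -phi      (resolution: input side)

subject to ``alpha * beta**2 * gamma**2 ~ 2``, so each unit of ``phi``
roughly halves the FLOPs of the network (cost scales as ``d * w**2 *
r**2``).  The default coefficients (1.2, 1.1, 1.15) give a constraint
value of 1.9203, hence an exact continuous per-unit ratio of 1.9203x.

All integer quantities are rescaled with round-half-to-even and clamped to
a minimum of 1, so stages, downsampling blocks and transitions never
disappear.  Width ratios inside a block (e.g. the 1:1:4 bottleneck
expansion) are preserved exactly: the stage base width is rounded first
and per-layer widths are recomputed from the rounded base.
"""

from __future__ import annotations

import copy
import math
import warnings
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_EVEN
from fractions import Fraction
from typing import Optional

from .errors import BudgetError, SpecError
from .ir import BlockSpec, NetworkSpec, TensorShape, validate

#: coefficients reported to give the best accuracy/efficiency trade-off
DEFAULT_ALPHA = 1.2
DEFAULT_BETA = 1.1
DEFAULT_GAMMA = 1.15

#: largest exponent the selection loop explores
PHI_MAX = 6


@dataclass(frozen=True)
class ScalingCoefficients:
    """Compound-scaling coefficients ``(alpha, beta, gamma)`` and exponent ``phi``."""

    alpha: float = DEFAULT_ALPHA
    beta: float = DEFAULT_BETA
    gamma: float = DEFAULT_GAMMA
    phi: float = 0.0

    def __post_init__(self):
        for name in ("alpha", "beta", "gamma"):
            if getattr(self, name) <= 1.0:
                raise SpecError(f"{name} must be > 1, got {getattr(self, name)}")
        if self.phi < 0:
            raise SpecError(f"phi must be non-negative, got {self.phi}")

    @property
    def constraint_value(self) -> float:
        """``alpha * beta**2 * gamma**2`` — should be close to 2."""
        return self.alpha * self.beta ** 2 * self.gamma ** 2

    def at_phi(self, phi: float) -> "ScalingCoefficients":
        return ScalingCoefficients(self.alpha, self.beta, self.gamma, phi)


@dataclass
class ReductionRequest:
    """Either a fixed ``phi`` or a FLOPs budget drives the reduction."""

    coefficients: ScalingCoefficients = field(default_factory=ScalingCoefficients)
    flops_budget: Optional[float] = None
    memory_budget: Optional[float] = None
    mode: str = "compound"  # or "input_only"

    def __post_init__(self):
        if self.mode not in ("compound", "input_only"):
            raise SpecError(f"mode must be 'compound' or 'input_only', got {self.mode!r}")
        if self.flops_budget is not None and self.coefficients.phi:
            raise SpecError("give either phi or a FLOPs budget, not both")


def reduction_factors(c: ScalingCoefficients) -> tuple[float, float, float]:
    """Return ``(d, w, r) = (alpha**-phi, beta**-phi, gamma**-phi)``."""
    return c.alpha ** -c.phi, c.beta ** -c.phi, c.gamma ** -c.phi


def scale_count(n: int, factor: float) -> int:
    """Rescale an integer quantity: round ``n * factor`` half-to-even, clamp to 1.

    The product is quantized to 9 decimal places before rounding so that
    exact ties (e.g. ``3 * 1.2**-1 == 2.5``) are not perturbed by binary
    floating-point representation error.
    """
    if n < 1:
        raise SpecError(f"count must be >= 1, got {n}")
    if not 0 < factor <= 1:
        raise SpecError(f"factor must be in (0, 1], got {factor}")
    exact = Decimal(repr(float(n) * float(factor))).quantize(Decimal("1e-9"))
    return max(1, int(exact.to_integral_value(rounding=ROUND_HALF_EVEN)))


def _round_ratio(base: int, ratio: Fraction) -> int:
    """Half-to-even rounding of ``base * ratio`` in exact rational arithmetic."""
    value = Fraction(base) * ratio
    floor = value.numerator // value.denominator
    frac = value - floor
    if frac > Fraction(1, 2) or (frac == Fraction(1, 2) and floor % 2 == 1):
        floor += 1
    return max(1, floor)


def theoretical_ratio(phi: float) -> float:
    """Expected FLOPs reduction ``2**-phi`` before integer rounding."""
    if phi < 0:
        raise SpecError(f"phi must be non-negative, got {phi}")
    return 2.0 ** -phi


def check_constraint(c: ScalingCoefficients, tol: float = 0.1) -> tuple[float, bool]:
    """Evaluate ``alpha * beta**2 * gamma**2`` and whether it is within ``tol`` of 2.

    The default coefficient triple gives 1.9203, which passes; the check is
    advisory (a warning, not a rejection) because a constraint value below
    2 simply means each unit of ``phi`` reduces cost slightly less than 2x.
    """
    value = c.constraint_value
    ok = abs(value - 2.0) <= tol
    return value, ok


def _scale_block_widths(block: BlockSpec, new_base: int) -> None:
    convs = list(block.scalable_convs())
    if not block.width_ratios:
        return
    for conv, ratio in zip(convs, block.width_ratios):
        conv.filters = _round_ratio(new_base, ratio)
    if block.projection is not None and block.projection_ratio is not None:
        block.projection.filters = _round_ratio(new_base, block.projection_ratio)


def _check_valid(net: NetworkSpec) -> None:
    issues = validate(net)
    if issues:
        raise SpecError("invalid network: " + "; ".join(issues))


def _warn_phi(net: NetworkSpec, phi: float) -> None:
    if phi > 3:
        warnings.warn(
            f"phi={phi} is beyond the range where the reduced {net.name} "
            "retains its block structure; stages collapse toward single "
            "repeats and the result approaches a plain sequential model",
            stacklevel=3)


def compound_reduce(net: NetworkSpec, c: ScalingCoefficients) -> NetworkSpec:
    """Return a new network with depth, width and resolution scaled down.

    Every depth-scalable stage's repeat count is rescaled by ``d``, every
    stage base width by ``w`` (per-layer widths recomputed from the exact
    ratios), and the input height/width by ``r``.  Stem, head,
    non-scalable layers and channel count are untouched; the original
    network is not modified.
    """
    _check_valid(net)
    _warn_phi(net, c.phi)
    d, w, r = reduction_factors(c)
    out = copy.deepcopy(net)

    side_h = max(scale_count(net.input.height, r), net.min_input_side)
    side_w = max(scale_count(net.input.width, r), net.min_input_side)
    if (side_h, side_w) != (scale_count(net.input.height, r),
                            scale_count(net.input.width, r)):
        warnings.warn(f"reduced input clamped to the template minimum "
                      f"{net.min_input_side}", stacklevel=2)
    out.input = TensorShape(side_h, side_w, net.input.channels)

    for stage in out.stages:
        if stage.depth_scalable:
            stage.repeats = scale_count(stage.repeats, d)
        stage.base_width = scale_count(stage.base_width, w)
        for block in (stage.entry_block, stage.block, stage.transition):
            if block is not None:
                _scale_block_widths(block, stage.base_width)
    if c.phi:
        out.name = f"{net.name}-nar{c.phi:g}"
    return out


def input_reduce(net: NetworkSpec, c: ScalingCoefficients) -> NetworkSpec:
    """Baseline: scale only the input resolution, leave the architecture alone."""
    _check_valid(net)
    _warn_phi(net, c.phi)
    _, _, r = reduction_factors(c)
    side_h = scale_count(net.input.height, r)
    side_w = scale_count(net.input.width, r)
    if min(side_h, side_w) < net.min_input_side:
        raise SpecError(
            f"reduced input {side_h}x{side_w} is below the network minimum "
            f"of {net.min_input_side}")
    out = copy.deepcopy(net)
    out.input = TensorShape(side_h, side_w, net.input.channels)
    if c.phi:
        out.name = f"{net.name}-ir{c.phi:g}"
    return out


def reduce(net: NetworkSpec, request: ReductionRequest) -> NetworkSpec:
    """Apply a :class:`ReductionRequest` (phi- or budget-driven, either mode)."""
    c = request.coefficients
    if request.flops_budget is not None:
        phi = choose_phi_for_budget(net, c, request.flops_budget)
        c = c.at_phi(phi)
    if request.mode == "input_only":
        return input_reduce(net, c)
    return compound_reduce(net, c)


def choose_phi_for_budget(net: NetworkSpec, c: ScalingCoefficients,
                          flops_budget: float, phi_max: int = PHI_MAX) -> int:
    """Smallest integer ``phi`` whose compound reduction fits the FLOPs budget."""
    from .cost import cost_report  # deferred to avoid an import cycle

    if flops_budget <= 0:
        raise SpecError(f"budget must be positive, got {flops_budget}")
    last = None
    for phi in range(phi_max + 1):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reduced = compound_reduce(net, c.at_phi(phi))
        last = cost_report(reduced).total_flops
        if last <= flops_budget:
            return phi
    raise BudgetError(
        f"budget {flops_budget:.3g} FLOPs unattainable: cost at "
        f"phi={phi_max} is still {last:.4g} FLOPs")
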