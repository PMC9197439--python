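"""Shape inference and analytic FLOPs / parameter accounting.

FLOPs are counted as two operations per multiply-accumulate, over
convolutional and dense layers only:

    F_conv  = 2 * C_in * K_h * K_w * H_out * W_out * C_out
    F_dense = 2 * N_in * N_out

Batchnorm, pooling, activations and shortcut additions contribute zero
FLOPs.  Parameters count every stored weight: conv kernels (plus bias
where the layer carries one), batchnorm scale/shift/moving-mean/
moving-variance (4 per channel), and dense weights plus bias.

``same`` padding uses ceiling division for the output extent, ``valid``
uses ``floor((n - k) / s) + 1``; both follow the conventions of the major
frameworks and keep shapes defined for inputs that are not multiples of
32 (209, 181, 157, ...).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

from .errors import ShapeError
from .ir import BlockSpec, LayerSpec, NetworkSpec, TensorShape


def _ceil_div(n: int, s: int) -> int:
    return -(-n // s)


def _spatial(side: int, kernel: int, stride: int, padding: str, lid: str) -> int:
    if padding == "same":
        out = _ceil_div(side, stride)
    else:
        out = (side - kernel) // stride + 1
    if out < 1:
        raise ShapeError(lid, f"spatial extent collapsed (in {side}, kernel "
                              f"{kernel}, stride {stride}, {padding})")
    return out


def conv_out_shape(layer: LayerSpec, in_shape: TensorShape, lid: str,
                   filters: int) -> TensorShape:
    kh, kw = layer.kernel
    sh, sw = layer.stride
    h = _spatial(in_shape.height, kh, sh, layer.padding, lid)
    w = _spatial(in_shape.width, kw, sw, layer.padding, lid)
    return TensorShape(h, w, filters)


def conv_flops(layer: LayerSpec, in_shape: TensorShape, out_shape: TensorShape) -> int:
    """2 * C_in * K_h * K_w * H_out * W_out * C_out for one convolution."""
    kh, kw = layer.kernel
    if in_shape.channels < 1 or kh < 1 or kw < 1:
        raise ShapeError("conv", "zero channel or kernel extent")
    return (2 * in_shape.channels * kh * kw
            * out_shape.height * out_shape.width * out_shape.channels)


def dense_flops(in_size: int, out_size: int) -> int:
    """2 * N_in * N_out for one fully-connected layer."""
    return 2 * in_size * out_size


@dataclass
class LayerCost:
    layer_id: str
    kind: str
    out_shape: TensorShape
    flops: int
    params: int


@dataclass
class CostReport:
    per_layer: list[LayerCost]
    total_flops: int
    total_params: int

    @property
    def gflops(self) -> float:
        """Total FLOPs / 1e9, rounded half-up to two decimals."""
        scaled = Decimal(self.total_flops) * Decimal("1e-9")
        return float(scaled.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


class _Walker:
    """Single traversal computing shapes, FLOPs and parameters together."""

    def __init__(self):
        self.records: list[LayerCost] = []

    # -- layer sequences ---------------------------------------------------

    def seq(self, layers: list[LayerSpec], shape: TensorShape, prefix: str,
            carrier: TensorShape | None = None) -> TensorShape:
        counts: dict[str, int] = {}
        for layer in layers:
            n = counts.get(layer.kind, 0)
            counts[layer.kind] = n + 1
            lid = f"{prefix}.{layer.kind}{n}"
            shape = self.layer(layer, shape, lid, carrier)
        return shape

    def layer(self, layer: LayerSpec, shape: TensorShape, lid: str,
              carrier: TensorShape | None) -> TensorShape:
        kind = layer.kind
        if kind == "input":
            self.records.append(LayerCost(lid, kind, shape, 0, 0))
            return shape
        if kind == "conv":
            filters = layer.filters
            if layer.match_channels:
                if carrier is None:
                    raise ShapeError(lid, "match_channels conv outside a block")
                filters = carrier.channels
            out = conv_out_shape(layer, shape, lid, filters)
            flops = conv_flops(layer, shape, out)
            kh, kw = layer.kernel
            params = kh * kw * shape.channels * filters + (filters if layer.bias else 0)
            self.records.append(LayerCost(lid, kind, out, flops, params))
            return out
        if kind == "dense":
            in_size = shape.size
            out = TensorShape(1, 1, layer.filters)
            flops = dense_flops(in_size, layer.filters)
            params = in_size * layer.filters + (layer.filters if layer.bias else 0)
            self.records.append(LayerCost(lid, kind, out, flops, params))
            return out
        if kind == "batchnorm":
            self.records.append(LayerCost(lid, kind, shape, 0, 4 * shape.channels))
            return shape
        if kind in ("activation", "flatten", "add", "concat"):
            out = (TensorShape(1, 1, shape.size) if kind == "flatten" else shape)
            self.records.append(LayerCost(lid, kind, out, 0, 0))
            return out
        if kind in ("pool_max", "pool_avg"):
            kh, kw = layer.kernel
            sh, sw = layer.stride
            out = TensorShape(_spatial(shape.height, kh, sh, layer.padding, lid),
                              _spatial(shape.width, kw, sw, layer.padding, lid),
                              shape.channels)
            self.records.append(LayerCost(lid, kind, out, 0, 0))
            return out
        if kind == "global_pool":
            out = TensorShape(1, 1, shape.channels)
            self.records.append(LayerCost(lid, kind, out, 0, 0))
            return out
        if kind == "branch":
            outs = [self.seq(br, shape, f"{lid}.b{i}", carrier)
                    for i, br in enumerate(layer.branches)]
            if layer.merge == "concat":
                h, w = outs[0].height, outs[0].width
                for i, o in enumerate(outs[1:], start=1):
                    if (o.height, o.width) != (h, w):
                        raise ShapeError(lid, f"concat branch {i} spatial "
                                              f"{o.height}x{o.width} != {h}x{w}")
                out = TensorShape(h, w, sum(o.channels for o in outs))
            else:
                for i, o in enumerate(outs[1:], start=1):
                    if o != outs[0]:
                        raise ShapeError(lid, f"add branch {i} shape {o} != {outs[0]}")
                out = outs[0]
            self.records.append(LayerCost(lid, kind, out, 0, 0))
            return out
        raise ShapeError(lid, f"unknown layer kind {kind!r}")

    # -- blocks and stages -------------------------------------------------

    def block(self, block: BlockSpec, shape: TensorShape, prefix: str) -> TensorShape:
        carrier = shape
        out = self.seq(block.layers, shape, prefix, carrier=carrier)
        if block.shortcut == "projection":
            proj = self.layer(block.projection, carrier, f"{prefix}.projection",
                              carrier)
            if proj != out:
                raise ShapeError(prefix, f"projection shape {proj} != main path {out}")
        elif block.shortcut == "identity":
            if carrier != out:
                raise ShapeError(prefix, f"identity shortcut: input {carrier} "
                                         f"!= main path {out}")
        if block.post:
            out = self.seq(block.post, out, f"{prefix}.post")
        return out

    def network(self, net: NetworkSpec) -> TensorShape:
        shape = net.input
        shape = self.seq(net.stem, shape, "stem")
        for stage in net.stages:
            for r in range(stage.repeats):
                blk = (stage.entry_block
                       if r == 0 and stage.entry_block is not None else stage.block)
                shape = self.block(blk, shape, f"{stage.name}.r{r}")
            if stage.transition is not None:
                shape = self.block(stage.transition, shape, f"{stage.name}.transition")
        return self.seq(net.head, shape, "head")


def infer_shapes(net: NetworkSpec) -> list[tuple[str, TensorShape]]:
    """Propagate tensor shapes through every layer of ``net``.

    Returns ``(layer_id, out_shape)`` pairs in execution order.  Raises
    :class:`~nar.errors.ShapeError` naming the offending layer on a merge
    mismatch or a collapsed spatial extent.
    """
    walker = _Walker()
    walker.network(net)
    return [(rec.layer_id, rec.out_shape) for rec in walker.records]


def count_params(net: NetworkSpec) -> int:
    """Total stored parameters (trainable plus batchnorm moving statistics)."""
    walker = _Walker()
    walker.network(net)
    return sum(rec.params for rec in walker.records)


def cost_report(net: NetworkSpec) -> CostReport:
    """Per-layer and total FLOPs / parameters with inferred shapes."""
    walker = _Walker()
    walker.network(net)
    return CostReport(
        per_layer=walker.records,
        total_flops=sum(r.flops for r in walker.records),
        total_params=sum(r.params for r in walker.records),
    )
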