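"""Built-in architecture templates.

Two networks widely used for histopathology patch classification:

* :func:`resnet50v2_template` — pre-activation bottleneck ResNet-50.
* :func:`inception_v4_template` — the residual Inception network
  (Inception-ResNet-v2 topology) as shipped by Keras-style ports.

Both are expressed in the stage grammar of :mod:`nar.ir` with exact
rational width ratios, so compound reduction preserves their block
geometry.
"""

from __future__ import annotations

from fractions import Fraction

from .errors import SpecError
from .ir import BlockSpec, LayerSpec, NetworkSpec, StageSpec, TensorShape

TEMPLATES = ("resnet50v2", "inceptionv4")


def _conv(filters, kernel, stride=1, padding="same", bias=True,
          width_scalable=True, match_channels=False) -> LayerSpec:
    return LayerSpec(kind="conv", kernel=(kernel, kernel) if isinstance(kernel, int) else kernel,
                     filters=filters, stride=(stride, stride) if isinstance(stride, int) else stride,
                     padding=padding, bias=bias, width_scalable=width_scalable,
                     match_channels=match_channels)


def _bn() -> LayerSpec:
    return LayerSpec(kind="batchnorm")


def _act() -> LayerSpec:
    return LayerSpec(kind="activation")


def _pool(kind, kernel, stride, padding="same") -> LayerSpec:
    return LayerSpec(kind=kind, kernel=(kernel, kernel), stride=(stride, stride),
                     padding=padding)


# ---------------------------------------------------------------------------
# ResNet50 V2

def _bottleneck(base: int, stride: int, projection: bool) -> BlockSpec:
    """Pre-activation bottleneck: BN-ReLU-1x1 / BN-ReLU-3x3 / BN-ReLU-1x1(x4).

    The inner 1x1 and 3x3 convolutions are bias-free (their batchnorm
    absorbs the shift); the expanding 1x1 and the projection carry biases.
    The projection taps the pre-activated input, and in downsampling blocks
    the stride sits on the 3x3 conv and the projection.
    """
    layers = [
        _bn(), _act(),
        _conv(base, 1, bias=False),
        _bn(), _act(),
        _conv(base, 3, stride=stride, bias=False),
        _bn(), _act(),
        _conv(4 * base, 1, bias=True),
    ]
    ratios = [Fraction(1), Fraction(1), Fraction(4)]
    if projection:
        return BlockSpec(
            name="bottleneck_proj", layers=layers, shortcut="projection",
            width_ratios=ratios,
            projection=_conv(4 * base, 1, stride=stride, bias=True),
            projection_ratio=Fraction(4),
            projection_from_preact=True,
        )
    return BlockSpec(name="bottleneck", layers=layers, shortcut="identity",
                     width_ratios=ratios)


def resnet50v2_template(input_side: int, n_classes: int = 2) -> NetworkSpec:
    """Pre-activation (V2) ResNet-50 with a dense classifier head.

    Stem: 7x7/2 conv with 64 filters plus a 3x3/2 max pool.  Four stages of
    bottleneck blocks with base widths 64/128/256/512 (1:1:4 expansion) and
    repeats 3/4/6/3; stages 2-4 downsample in their first block, where the
    stride sits on the 3x3 conv and the projection shortcut.  Head: final
    batchnorm + ReLU, global average pool, dense ``n_classes`` output.

    ``input_side`` must allow the five stride-2 reductions, i.e. be at
    least 32 pixels.
    """
    if n_classes < 2:
        raise SpecError(f"n_classes must be >= 2, got {n_classes}")
    if input_side < 32:
        raise SpecError(
            f"input side {input_side} is below the minimum of 32 needed for "
            "the network's 5 stride-2 downsamplings")
    stem = [
        LayerSpec(kind="input"),
        _conv(64, 7, stride=2, bias=True, width_scalable=False),
        _pool("pool_max", 3, 2),
    ]
    stages = []
    for i, (base, repeats) in enumerate(
            zip((64, 128, 256, 512), (3, 4, 6, 3)), start=1):
        stride = 1 if i == 1 else 2
        stages.append(StageSpec(
            name=f"stage{i}",
            entry_block=_bottleneck(base, stride=stride, projection=True),
            block=_bottleneck(base, stride=1, projection=False),
            repeats=repeats,
            base_width=base,
            depth_scalable=True,
        ))
    head = [
        _bn(), _act(),
        LayerSpec(kind="global_pool"),
        LayerSpec(kind="dense", filters=n_classes, bias=True, width_scalable=False),
    ]
    return NetworkSpec(
        name="resnet50v2",
        input=TensorShape(input_side, input_side, 3),
        stem=stem, stages=stages, head=head, n_classes=n_classes,
        min_input_side=32,
    )


# ---------------------------------------------------------------------------
# residual Inception ("Inception V4" as used in Keras-based pipelines)

def _cb(filters, kernel, stride=1, padding="same", width_scalable=True) -> list[LayerSpec]:
    """conv + batchnorm + ReLU triple (bias-free conv)."""
    return [_conv(filters, kernel, stride=stride, padding=padding, bias=False,
                  width_scalable=width_scalable), _bn(), _act()]


def _branchcat(*branches: list[LayerSpec]) -> LayerSpec:
    return LayerSpec(kind="branch", branches=list(branches), merge="concat")


def _residual_inception_block(name: str, base: int, branch_widths, kernels,
                              scale: float) -> BlockSpec:
    """Branches -> concat -> 1x1 carrier-matching conv, residual add, ReLU.

    ``branch_widths``/``kernels`` give per-branch conv widths and kernel
    shapes.  The closing 1x1 conv restores whatever channel count the
    residual carrier has (``match_channels``), so the block stays valid
    under any width scaling of the surrounding stages.
    """
    branches = []
    ratios = []
    for widths, ks in zip(branch_widths, kernels):
        seq: list[LayerSpec] = []
        for w, k in zip(widths, ks):
            seq += _cb(w, k)
            ratios.append(Fraction(w, base))
        branches.append(seq)
    layers = [
        _branchcat(*branches),
        # linear 1x1 projection back to the carrier width (bias, no BN)
        _conv(None, 1, bias=True, width_scalable=False, match_channels=True),
    ]
    return BlockSpec(name=name, layers=layers, shortcut="identity",
                     width_ratios=ratios, residual_scale=scale,
                     post=[_act()])


def inception_v4_template(input_side: int, n_classes: int = 2) -> NetworkSpec:
    """Residual Inception network (Inception-ResNet-v2 topology).

    This is the "Inception V4" of Keras-based histopathology pipelines:
    a six-conv stem with an Inception-style mixed block, then three
    depth-scalable stages of residual Inception blocks — 10x block35
    (35x35 grid), 20x block17 (17x17) and 10x block8 (8x8) at carrier
    widths 320/1088/2080 — joined by two non-scalable reduction blocks,
    closed by a 1x1 conv to 1536 features, global pooling and a dense
    classifier.  Strided convolutions and pools use valid padding, as in
    the reference implementation.
    """
    if n_classes < 2:
        raise SpecError(f"n_classes must be >= 2, got {n_classes}")
    if input_side < 96:
        raise SpecError(
            f"input side {input_side} is below the minimum of 96 needed for "
            "the stem's valid-padded reductions")
    stem = [
        LayerSpec(kind="input"),
        *_cb(32, 3, stride=2, padding="valid", width_scalable=False),
        *_cb(32, 3, padding="valid", width_scalable=False),
        *_cb(64, 3, width_scalable=False),
        _pool("pool_max", 3, 2, padding="valid"),
        *_cb(80, 1, padding="valid", width_scalable=False),
        *_cb(192, 3, padding="valid", width_scalable=False),
        _pool("pool_max", 3, 2, padding="valid"),
        # mixed block: 96 + 64 + 96 + 64 = 320-channel carrier
        _branchcat(
            _cb(96, 1, width_scalable=False),
            [*_cb(48, 1, width_scalable=False), *_cb(64, 5, width_scalable=False)],
            [*_cb(64, 1, width_scalable=False), *_cb(96, 3, width_scalable=False),
             *_cb(96, 3, width_scalable=False)],
            [_pool("pool_avg", 3, 1), *_cb(64, 1, width_scalable=False)],
        ),
    ]

    block35 = _residual_inception_block(
        "block35", 320,
        branch_widths=[(32,), (32, 32), (32, 48, 64)],
        kernels=[(1,), (1, 3), (1, 3, 3)],
        scale=0.17)
    reduction_a = BlockSpec(
        name="reduction_a",
        layers=[_branchcat(
            [_pool("pool_max", 3, 2, padding="valid")],
            _cb(384, 3, stride=2, padding="valid"),
            [*_cb(256, 1), *_cb(256, 3), *_cb(384, 3, stride=2, padding="valid")],
        )],
        width_ratios=[Fraction(384, 320), Fraction(256, 320), Fraction(256, 320),
                      Fraction(384, 320)],
    )
    block17 = _residual_inception_block(
        "block17", 1088,
        branch_widths=[(192,), (128, 160, 192)],
        kernels=[(1,), (1, (1, 7), (7, 1))],
        scale=0.10)
    reduction_b = BlockSpec(
        name="reduction_b",
        layers=[_branchcat(
            [_pool("pool_max", 3, 2, padding="valid")],
            [*_cb(256, 1), *_cb(384, 3, stride=2, padding="valid")],
            [*_cb(256, 1), *_cb(288, 3, stride=2, padding="valid")],
            [*_cb(256, 1), *_cb(288, 3), *_cb(320, 3, stride=2, padding="valid")],
        )],
        width_ratios=[Fraction(w, 1088) for w in (256, 384, 256, 288, 256, 288, 320)],
    )
    block8 = _residual_inception_block(
        "block8", 2080,
        branch_widths=[(192,), (192, 224, 256)],
        kernels=[(1,), (1, (1, 3), (3, 1))],
        scale=0.20)

    stages = [
        StageSpec(name="block35", block=block35, repeats=10, base_width=320,
                  depth_scalable=True, transition=reduction_a),
        StageSpec(name="block17", block=block17, repeats=20, base_width=1088,
                  depth_scalable=True, transition=reduction_b),
        StageSpec(name="block8", block=block8, repeats=10, base_width=2080,
                  depth_scalable=True),
    ]
    head = [
        *_cb(1536, 1, width_scalable=False),
        LayerSpec(kind="global_pool"),
        LayerSpec(kind="dense", filters=n_classes, bias=True, width_scalable=False),
    ]
    return NetworkSpec(
        name="inceptionv4",
        input=TensorShape(input_side, input_side, 3),
        stem=stem, stages=stages, head=head, n_classes=n_classes,
        min_input_side=96,
    )


def toy_cnn_template(input_side: int, n_classes: int = 2,
                     widths: tuple[int, ...] = (8, 16, 32)) -> NetworkSpec:
    """Small 3-conv network for desk-scale experiments and tests.

    conv-BN-ReLU-maxpool stacks at the given widths, global average pool,
    dense classifier.  Downsamples once per stack, so the minimum input
    side is ``2 ** len(widths)``.
    """
    if n_classes < 2:
        raise SpecError(f"n_classes must be >= 2, got {n_classes}")
    min_side = 2 ** len(widths)
    if input_side < min_side:
        raise SpecError(f"input side {input_side} below minimum {min_side}")
    stages = []
    for i, w in enumerate(widths, start=1):
        stages.append(StageSpec(
            name=f"stack{i}",
            block=BlockSpec(name="conv_pool", layers=[
                _conv(w, 3, bias=False),
                _bn(), _act(),
                _pool("pool_max", 2, 2),
            ], width_ratios=[Fraction(1)]),
            repeats=1, base_width=w, depth_scalable=False,
        ))
    return NetworkSpec(
        name="toy_cnn",
        input=TensorShape(input_side, input_side, 3),
        stem=[LayerSpec(kind="input")],
        stages=stages,
        head=[LayerSpec(kind="global_pool"),
              LayerSpec(kind="dense", filters=n_classes, bias=True,
                        width_scalable=False)],
        n_classes=n_classes,
        min_input_side=min_side,
    )


def get_template(name: str, input_side: int, n_classes: int = 2) -> NetworkSpec:
    """Resolve a template by name (``resnet50v2`` or ``inceptionv4``)."""
    if name == "resnet50v2":
        return resnet50v2_template(input_side, n_classes)
    if name == "inceptionv4":
        return inception_v4_template(input_side, n_classes)
    raise SpecError(f"unknown template {name!r}; choose from {TEMPLATES}")
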