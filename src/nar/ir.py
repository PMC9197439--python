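"""Framework-neutral intermediate representation of block-based CNNs.

A network is described declaratively as ``stem -> stages -> head``.  Each
stage repeats a block a configurable number of times; the first repeat may
use a distinct *entry* block (projection shortcut, downsampling stride) and
a stage may end in a one-shot *transition* block (reduction).  Channel
widths inside a stage are expressed as exact rational ratios of the stage's
``base_width`` so that compound width scaling preserves the block geometry
(for example the 1:1:4 bottleneck expansion).

The representation is deliberately a grammar, not a general computational
graph: sequences, branches merged by concatenation or addition, and
residual shortcuts are the only control structures.  That is enough to
express the two built-in templates (see :mod:`nar.templates`) and every
compound-reduced variant of them, while keeping shape inference, cost
accounting and serialization simple and lossless.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from fractions import Fraction
from typing import Iterator, Optional

from .errors import ParseError, SpecError

LAYER_KINDS = {
    "input", "conv", "dense", "batchnorm", "activation",
    "pool_max", "pool_avg", "global_pool", "add", "concat",
    "flatten", "branch",
}

#: layer kinds that never carry weights
NON_PARAMETRIC = {
    "input", "activation", "pool_max", "pool_avg", "global_pool",
    "add", "concat", "flatten", "branch",
}


@dataclass(frozen=True)
class TensorShape:
    """Spatial height/width plus channel count of an activation tensor."""

    height: int
    width: int
    channels: int

    def __post_init__(self):
        if min(self.height, self.width, self.channels) < 1:
            raise SpecError(f"tensor dimensions must be positive, got {self}")

    @property
    def size(self) -> int:
        return self.height * self.width * self.channels


@dataclass
class LayerSpec:
    """One layer of the network grammar.

    ``filters`` is the output channel count for conv/dense layers.  A conv
    with ``match_channels=True`` takes its output width from the residual
    carrier of the enclosing block at build time (used by residual
    Inception blocks, whose 1x1 "up" projection must restore the carrier
    width); such a layer is never width-scaled directly.
    ``width_scalable=False`` pins a conv's width under compound scaling
    (stem convolutions, head feature convolutions).
    """

    kind: str
    kernel: Optional[tuple[int, int]] = None
    filters: Optional[int] = None
    stride: tuple[int, int] = (1, 1)
    padding: str = "same"
    bias: bool = True
    width_scalable: bool = True
    match_channels: bool = False
    branches: Optional[list[list["LayerSpec"]]] = None
    merge: str = "concat"

    def __post_init__(self):
        if isinstance(self.kernel, list):
            self.kernel = tuple(self.kernel)
        if isinstance(self.stride, list):
            self.stride = tuple(self.stride)


@dataclass
class BlockSpec:
    """A reusable residual/branching unit.

    ``layers`` is the main path.  ``shortcut`` selects how the block input
    is merged back in: ``none`` (plain sequence), ``identity`` (added
    unchanged) or ``projection`` (passed through ``projection``, a 1x1 conv,
    before the add).  ``width_ratios`` lists, in traversal order, the width
    of every width-scalable conv of the main path as an exact fraction of
    the owning stage's base width; ``projection_ratio`` does the same for
    the projection conv.  ``residual_scale`` multiplies the main path before
    the addition (residual Inception blocks damp their branches); ``post``
    runs after the merge (e.g. a closing activation).
    """

    name: str
    layers: list[LayerSpec]
    shortcut: str = "none"
    width_ratios: list[Fraction] = field(default_factory=list)
    projection: Optional[LayerSpec] = None
    projection_ratio: Optional[Fraction] = None
    projection_from_preact: bool = False
    residual_scale: float = 1.0
    post: list[LayerSpec] = field(default_factory=list)

    def scalable_convs(self) -> Iterator[LayerSpec]:
        """Width-scalable convs of the main path, in width_ratios order."""
        yield from _scalable_convs(self.layers)


def _scalable_convs(layers: list[LayerSpec]) -> Iterator[LayerSpec]:
    for layer in layers:
        if layer.kind == "branch":
            for branch in layer.branches or []:
                yield from _scalable_convs(branch)
        elif layer.kind == "conv" and layer.width_scalable and not layer.match_channels:
            yield layer


@dataclass
class StageSpec:
    """A repeated block, optionally with an entry variant and a transition.

    ``repeats`` counts every repeat including the entry block.  Depth
    scaling applies only when ``depth_scalable``; the entry block and the
    transition always survive (the minimum repeat count is 1), so the
    network never loses a downsampling step.
    """

    name: str
    block: BlockSpec
    repeats: int
    base_width: int
    depth_scalable: bool = True
    entry_block: Optional[BlockSpec] = None
    transition: Optional[BlockSpec] = None


@dataclass
class NetworkSpec:
    """Declarative description of a block-based CNN."""

    name: str
    input: TensorShape
    stem: list[LayerSpec]
    stages: list[StageSpec]
    head: list[LayerSpec]
    n_classes: int
    min_input_side: int = 32

    def blocks(self) -> Iterator[tuple[str, BlockSpec]]:
        for stage in self.stages:
            if stage.entry_block is not None:
                yield stage.name, stage.entry_block
            yield stage.name, stage.block
            if stage.transition is not None:
                yield stage.name, stage.transition


# ---------------------------------------------------------------------------
# serialization (JSON, lossless)

_FORMAT = "nar-network/1"


def _frac_to_str(f: Fraction) -> str:
    return f"{f.numerator}/{f.denominator}"


def _frac_from_str(s: str, loc: str) -> Fraction:
    try:
        num, _, den = s.partition("/")
        return Fraction(int(num), int(den or "1"))
    except (ValueError, ZeroDivisionError) as exc:
        raise ParseError(loc, f"bad ratio {s!r}") from exc


def _layer_to_dict(layer: LayerSpec) -> dict:
    d = {"kind": layer.kind, "stride": list(layer.stride), "padding": layer.padding,
         "bias": layer.bias, "width_scalable": layer.width_scalable,
         "match_channels": layer.match_channels, "merge": layer.merge}
    if layer.kernel is not None:
        d["kernel"] = list(layer.kernel)
    if layer.filters is not None:
        d["filters"] = layer.filters
    if layer.branches is not None:
        d["branches"] = [[_layer_to_dict(sub) for sub in br] for br in layer.branches]
    return d


def _layer_from_dict(d: dict, loc: str) -> LayerSpec:
    if not isinstance(d, dict) or "kind" not in d:
        raise ParseError(loc, "layer must be an object with a 'kind'")
    kind = d["kind"]
    if kind not in LAYER_KINDS:
        raise ParseError(loc, f"unknown layer kind {kind!r}")
    branches = None
    if d.get("branches") is not None:
        branches = [
            [_layer_from_dict(sub, f"{loc}.branches[{i}][{j}]")
             for j, sub in enumerate(br)]
            for i, br in enumerate(d["branches"])
        ]
    return LayerSpec(
        kind=kind,
        kernel=tuple(d["kernel"]) if d.get("kernel") is not None else None,
        filters=d.get("filters"),
        stride=tuple(d.get("stride", (1, 1))),
        padding=d.get("padding", "same"),
        bias=d.get("bias", True),
        width_scalable=d.get("width_scalable", True),
        match_channels=d.get("match_channels", False),
        branches=branches,
        merge=d.get("merge", "concat"),
    )


def _block_to_dict(block: BlockSpec) -> dict:
    d = {
        "name": block.name,
        "layers": [_layer_to_dict(l) for l in block.layers],
        "shortcut": block.shortcut,
        "width_ratios": [_frac_to_str(r) for r in block.width_ratios],
        "projection_from_preact": block.projection_from_preact,
        "residual_scale": block.residual_scale,
        "post": [_layer_to_dict(l) for l in block.post],
    }
    if block.projection is not None:
        d["projection"] = _layer_to_dict(block.projection)
    if block.projection_ratio is not None:
        d["projection_ratio"] = _frac_to_str(block.projection_ratio)
    return d


def _block_from_dict(d: dict, loc: str) -> BlockSpec:
    if not isinstance(d, dict) or "layers" not in d:
        raise ParseError(loc, "block must be an object with 'layers'")
    return BlockSpec(
        name=d.get("name", "block"),
        layers=[_layer_from_dict(l, f"{loc}.layers[{i}]")
                for i, l in enumerate(d["layers"])],
        shortcut=d.get("shortcut", "none"),
        width_ratios=[_frac_from_str(r, f"{loc}.width_ratios[{i}]")
                      for i, r in enumerate(d.get("width_ratios", []))],
        projection=(_layer_from_dict(d["projection"], f"{loc}.projection")
                    if d.get("projection") is not None else None),
        projection_ratio=(_frac_from_str(d["projection_ratio"], f"{loc}.projection_ratio")
                          if d.get("projection_ratio") is not None else None),
        projection_from_preact=d.get("projection_from_preact", False),
        residual_scale=d.get("residual_scale", 1.0),
        post=[_layer_from_dict(l, f"{loc}.post[{i}]")
              for i, l in enumerate(d.get("post", []))],
    )


def serialize(net: NetworkSpec) -> str:
    """Render a network as a JSON document; lossless round-trip."""
    doc = {
        "format": _FORMAT,
        "name": net.name,
        "input": asdict(net.input),
        "n_classes": net.n_classes,
        "min_input_side": net.min_input_side,
        "stem": [_layer_to_dict(l) for l in net.stem],
        "stages": [
            {
                "name": s.name,
                "repeats": s.repeats,
                "base_width": s.base_width,
                "depth_scalable": s.depth_scalable,
                "block": _block_to_dict(s.block),
                **({"entry_block": _block_to_dict(s.entry_block)}
                   if s.entry_block is not None else {}),
                **({"transition": _block_to_dict(s.transition)}
                   if s.transition is not None else {}),
            }
            for s in net.stages
        ],
        "head": [_layer_to_dict(l) for l in net.head],
    }
    return json.dumps(doc, indent=1)


def deserialize(text: str) -> NetworkSpec:
    """Parse a JSON network document produced by :func:`serialize`."""
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ParseError(f"line {exc.lineno}, col {exc.colno}", exc.msg) from exc
    if not isinstance(doc, dict):
        raise ParseError("document", "top level must be an object")
    for key in ("name", "input", "stem", "stages", "head", "n_classes"):
        if key not in doc:
            raise ParseError("document", f"missing required key {key!r}")
    inp = doc["input"]
    try:
        shape = TensorShape(inp["height"], inp["width"], inp["channels"])
    except (TypeError, KeyError) as exc:
        raise ParseError("input", "input must carry height/width/channels") from exc
    stages = []
    for i, s in enumerate(doc["stages"]):
        loc = f"stages[{i}]"
        if "block" not in s or "repeats" not in s:
            raise ParseError(loc, "stage needs 'block' and 'repeats'")
        stages.append(StageSpec(
            name=s.get("name", f"stage{i + 1}"),
            block=_block_from_dict(s["block"], f"{loc}.block"),
            repeats=int(s["repeats"]),
            base_width=int(s["base_width"]),
            depth_scalable=s.get("depth_scalable", True),
            entry_block=(_block_from_dict(s["entry_block"], f"{loc}.entry_block")
                         if s.get("entry_block") is not None else None),
            transition=(_block_from_dict(s["transition"], f"{loc}.transition")
                        if s.get("transition") is not None else None),
        ))
    return NetworkSpec(
        name=doc["name"],
        input=shape,
        stem=[_layer_from_dict(l, f"stem[{i}]") for i, l in enumerate(doc["stem"])],
        stages=stages,
        head=[_layer_from_dict(l, f"head[{i}]") for i, l in enumerate(doc["head"])],
        n_classes=int(doc["n_classes"]),
        min_input_side=int(doc.get("min_input_side", 32)),
    )


# ---------------------------------------------------------------------------
# validation

def _validate_layers(layers: list[LayerSpec], loc: str, issues: list[str]) -> None:
    for i, layer in enumerate(layers):
        lid = f"{loc}[{i}]({layer.kind})"
        if layer.kind not in LAYER_KINDS:
            issues.append(f"{lid}: unknown kind")
            continue
        if layer.kind in ("conv", "pool_max", "pool_avg"):
            if layer.kernel is None or min(layer.kernel) < 1:
                issues.append(f"{lid}: kernel must be positive")
        if min(layer.stride) < 1:
            issues.append(f"{lid}: stride must be positive")
        if layer.padding not in ("same", "valid"):
            issues.append(f"{lid}: padding must be 'same' or 'valid'")
        if layer.kind in ("conv", "dense"):
            if not layer.match_channels and (layer.filters is None or layer.filters < 1):
                issues.append(f"{lid}: filters must be positive")
        elif layer.filters is not None:
            issues.append(f"{lid}: non-parametric kind carries filters")
        if layer.kind == "branch":
            if not layer.branches:
                issues.append(f"{lid}: branch without sub-paths")
            else:
                for j, br in enumerate(layer.branches):
                    _validate_layers(br, f"{lid}.branches[{j}]", issues)
            if layer.merge not in ("concat", "add"):
                issues.append(f"{lid}: merge must be 'concat' or 'add'")


def _validate_block(block: BlockSpec, loc: str, issues: list[str]) -> None:
    _validate_layers(block.layers, f"{loc}.layers", issues)
    _validate_layers(block.post, f"{loc}.post", issues)
    if block.shortcut not in ("none", "identity", "projection"):
        issues.append(f"{loc}: unknown shortcut {block.shortcut!r}")
    if block.shortcut == "projection" and block.projection is None:
        issues.append(f"{loc}: projection shortcut without a projection conv")
    n_scalable = sum(1 for _ in block.scalable_convs())
    if block.width_ratios and len(block.width_ratios) != n_scalable:
        issues.append(
            f"{loc}: width_ratios has {len(block.width_ratios)} entries "
            f"for {n_scalable} width-scalable convs")


def validate(net: NetworkSpec) -> list[str]:
    """Check every structural invariant; empty list means the network is sound.

    Issues are returned as data rather than raised so that callers can
    report all of them at once.  The final check runs shape inference end
    to end, which catches merge mismatches and collapsed spatial extents.
    """
    issues: list[str] = []
    n_inputs = sum(1 for l in net.stem if l.kind == "input")
    if n_inputs != 1:
        issues.append(f"stem: expected exactly one input layer, found {n_inputs}")
    if net.n_classes < 2:
        issues.append("n_classes must be at least 2")
    dense = [l for l in net.head if l.kind == "dense"]
    if not dense:
        issues.append("head: missing dense classifier")
    elif dense[-1].filters != net.n_classes:
        issues.append(
            f"head: classifier outputs {dense[-1].filters}, expected {net.n_classes}")
    _validate_layers(net.stem, "stem", issues)
    _validate_layers(net.head, "head", issues)
    for stage in net.stages:
        if stage.repeats < 1:
            issues.append(f"stage {stage.name}: repeats must be >= 1, got {stage.repeats}")
        if stage.base_width < 1:
            issues.append(f"stage {stage.name}: base_width must be >= 1")
        _validate_block(stage.block, f"stage {stage.name}.block", issues)
        if stage.entry_block is not None:
            _validate_block(stage.entry_block, f"stage {stage.name}.entry", issues)
        if stage.transition is not None:
            _validate_block(stage.transition, f"stage {stage.name}.transition", issues)
    if not issues:
        from .cost import infer_shapes  # deferred: cost depends on ir
        try:
            infer_shapes(net)
        except (SpecError, ValueError) as exc:
            issues.append(f"shape inference: {exc}")
    return issues
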