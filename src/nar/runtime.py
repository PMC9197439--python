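"""Materialize a :class:`~nar.ir.NetworkSpec` into a trainable model.

This is a small, deterministic, pure-NumPy training backend: NHWC
tensors, im2col convolutions, batch normalization with moving statistics,
max/average pooling, residual blocks with optional damping, softmax
cross-entropy, and Adam with decoupled weight decay.  It exists so that
every architecture the reduction transform can produce is executable and
its stored parameter count can be checked against the analytic
:func:`nar.cost.count_params` — the two code paths share nothing but the
spec.

The backend is sized for patch-classification at desk scale (tens of
thousands of small patches); it is not a GPU framework.  Determinism is
exact for a fixed seed because all randomness flows through a single
``numpy.random.Generator`` and execution is single-threaded NumPy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from .errors import SpecError
from .ir import BlockSpec, LayerSpec, NetworkSpec


# ---------------------------------------------------------------------------
# parameters and layers

class Param:
    """A learnable or stored array; ``decay`` marks weight-decay targets."""

    __slots__ = ("value", "grad", "decay", "trainable")

    def __init__(self, value: np.ndarray, decay: bool = False, trainable: bool = True):
        self.value = value
        self.grad = np.zeros_like(value)
        self.decay = decay
        self.trainable = trainable


def _pad_amounts(n: int, k: int, s: int, padding: str) -> tuple[int, int, int]:
    """Return (out, pad_before, pad_after) for one spatial axis."""
    if padding == "same":
        out = -(-n // s)
        total = max((out - 1) * s + k - n, 0)
        before = total // 2
        return out, before, total - before
    out = (n - k) // s + 1
    if out < 1:
        raise SpecError(f"spatial extent collapsed: n={n}, kernel={k}, stride={s}")
    return out, 0, 0


def _im2col(xp: np.ndarray, kh: int, kw: int, sh: int, sw: int,
            oh: int, ow: int) -> np.ndarray:
    n, _, _, c = xp.shape
    cols = np.empty((n, oh, ow, kh, kw, c), dtype=xp.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, :, i, j, :] = xp[:, i:i + sh * oh:sh, j:j + sw * ow:sw, :]
    return cols


def _col2im(dcols: np.ndarray, xp_shape, kh, kw, sh, sw, oh, ow) -> np.ndarray:
    dxp = np.zeros(xp_shape, dtype=dcols.dtype)
    for i in range(kh):
        for j in range(kw):
            dxp[:, i:i + sh * oh:sh, j:j + sw * ow:sw, :] += dcols[:, :, :, i, j, :]
    return dxp


class _Node:
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> Iterable[Param]:
        return ()


class Conv2D(_Node):
    def __init__(self, rng, cin, cout, kernel, stride, padding, bias):
        kh, kw = kernel
        fan_in = kh * kw * cin
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                  (kh, kw, cin, cout)).astype(np.float32), decay=True)
        self.b = Param(np.zeros(cout, dtype=np.float32)) if bias else None
        self.kernel, self.stride, self.padding = (kh, kw), stride, padding

    def forward(self, x, training):
        kh, kw = self.kernel
        sh, sw = self.stride
        n, h, w, c = x.shape
        oh, pt, pb = _pad_amounts(h, kh, sh, self.padding)
        ow, pl, pr = _pad_amounts(w, kw, sw, self.padding)
        xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
        cols = _im2col(xp, kh, kw, sh, sw, oh, ow)
        flat = cols.reshape(n * oh * ow, kh * kw * c)
        cout = self.W.value.shape[-1]
        y = flat @ self.W.value.reshape(-1, cout)
        if self.b is not None:
            y += self.b.value
        self._cache = (flat, xp.shape, (n, h, w, c), (oh, ow), (pt, pl))
        return y.reshape(n, oh, ow, cout)

    def backward(self, dy):
        kh, kw = self.kernel
        sh, sw = self.stride
        flat, xp_shape, x_shape, (oh, ow), (pt, pl) = self._cache
        n, h, w, c = x_shape
        cout = self.W.value.shape[-1]
        dyf = dy.reshape(-1, cout)
        self.W.grad += (flat.T @ dyf).reshape(self.W.value.shape)
        if self.b is not None:
            self.b.grad += dyf.sum(axis=0)
        dcols = (dyf @ self.W.value.reshape(-1, cout).T).reshape(
            n, oh, ow, kh, kw, c)
        dxp = _col2im(dcols, xp_shape, kh, kw, sh, sw, oh, ow)
        return dxp[:, pt:pt + h, pl:pl + w, :]

    def params(self):
        return (self.W, self.b) if self.b is not None else (self.W,)


class Dense(_Node):
    def __init__(self, rng, cin, cout, bias):
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / cin),
                                  (cin, cout)).astype(np.float32), decay=True)
        self.b = Param(np.zeros(cout, dtype=np.float32)) if bias else None

    def forward(self, x, training):
        if x.ndim > 2:
            x = x.reshape(x.shape[0], -1)
        self._x = x
        y = x @ self.W.value
        if self.b is not None:
            y += self.b.value
        return y

    def backward(self, dy):
        self.W.grad += self._x.T @ dy
        if self.b is not None:
            self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value.T

    def params(self):
        return (self.W, self.b) if self.b is not None else (self.W,)


class BatchNorm(_Node):
    def __init__(self, channels, momentum=0.99, eps=1e-3):
        self.gamma = Param(np.ones(channels, dtype=np.float32))
        self.beta = Param(np.zeros(channels, dtype=np.float32))
        self.moving_mean = Param(np.zeros(channels, dtype=np.float32),
                                 trainable=False)
        self.moving_var = Param(np.ones(channels, dtype=np.float32),
                                trainable=False)
        self.momentum, self.eps = momentum, eps

    def forward(self, x, training):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.moving_mean.value = m * self.moving_mean.value + (1 - m) * mean
            self.moving_var.value = m * self.moving_var.value + (1 - m) * var
        else:
            mean, var = self.moving_mean.value, self.moving_var.value
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv, axes, training, x.shape)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, dy):
        xhat, inv, axes, training, shape = self._cache
        self.gamma.grad += (dy * xhat).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)
        dxhat = dy * self.gamma.value
        if not training:
            return dxhat * inv
        m = np.prod([shape[a] for a in axes])
        return (inv / m) * (m * dxhat - dxhat.sum(axis=axes)
                            - xhat * (dxhat * xhat).sum(axis=axes))

    def params(self):
        return (self.gamma, self.beta, self.moving_mean, self.moving_var)


class ReLU(_Node):
    def forward(self, x, training):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Pool(_Node):
    def __init__(self, mode, kernel, stride, padding):
        self.mode, self.kernel, self.stride, self.padding = mode, kernel, stride, padding

    def forward(self, x, training):
        kh, kw = self.kernel
        sh, sw = self.stride
        n, h, w, c = x.shape
        oh, pt, pb = _pad_amounts(h, kh, sh, self.padding)
        ow, pl, pr = _pad_amounts(w, kw, sw, self.padding)
        fill = -np.inf if self.mode == "max" else 0.0
        xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)),
                    constant_values=fill)
        cols = _im2col(xp, kh, kw, sh, sw, oh, ow).reshape(n, oh, ow, kh * kw, c)
        if self.mode == "max":
            idx = cols.argmax(axis=3)
            y = np.take_along_axis(cols, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]
            self._cache = (idx, xp.shape, (h, w), (oh, ow), (pt, pl))
        else:
            y = cols.mean(axis=3)
            self._cache = (None, xp.shape, (h, w), (oh, ow), (pt, pl))
        return y

    def backward(self, dy):
        kh, kw = self.kernel
        sh, sw = self.stride
        idx, xp_shape, (h, w), (oh, ow), (pt, pl) = self._cache
        n, _, _, c = xp_shape
        dcols = np.zeros((n, oh, ow, kh * kw, c), dtype=dy.dtype)
        if self.mode == "max":
            np.put_along_axis(dcols, idx[:, :, :, None, :], dy[:, :, :, None, :],
                              axis=3)
        else:
            dcols += (dy / (kh * kw))[:, :, :, None, :]
        dxp = _col2im(dcols.reshape(n, oh, ow, kh, kw, c), xp_shape,
                      kh, kw, sh, sw, oh, ow)
        return dxp[:, pt:pt + h, pl:pl + w, :]


class GlobalAvgPool(_Node):
    def forward(self, x, training):
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dy):
        n, h, w, c = self._shape
        return np.broadcast_to(dy[:, None, None, :] / (h * w),
                               self._shape).copy()


class Flatten(_Node):
    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Sequence(_Node):
    def __init__(self, nodes):
        self.nodes = list(nodes)

    def forward(self, x, training):
        for node in self.nodes:
            x = node.forward(x, training)
        return x

    def backward(self, dy):
        for node in reversed(self.nodes):
            dy = node.backward(dy)
        return dy

    def params(self):
        for node in self.nodes:
            yield from node.params()


class Branch(_Node):
    def __init__(self, paths, merge):
        self.paths = [Sequence(p) for p in paths]
        self.merge = merge

    def forward(self, x, training):
        outs = [p.forward(x, training) for p in self.paths]
        self._channels = [o.shape[-1] for o in outs]
        if self.merge == "concat":
            return np.concatenate(outs, axis=-1)
        return np.sum(outs, axis=0)

    def backward(self, dy):
        if self.merge == "concat":
            splits = np.cumsum(self._channels)[:-1]
            parts = np.split(dy, splits, axis=-1)
        else:
            parts = [dy] * len(self.paths)
        dx = None
        for path, part in zip(self.paths, parts):
            g = path.backward(part)
            dx = g if dx is None else dx + g
        return dx

    def params(self):
        for p in self.paths:
            yield from p.params()


class ResidualBlock(_Node):
    """Main path plus identity/projection shortcut, with optional damping.

    When the projection taps the pre-activation (V2 convention), ``pre``
    holds the leading batchnorm+ReLU pair and both the main path and the
    projection consume its output.
    """

    def __init__(self, pre, main, shortcut, projection, scale, post):
        self.pre = pre
        self.main = main
        self.shortcut = shortcut
        self.projection = projection
        self.scale = scale
        self.post = post

    def forward(self, x, training):
        t = self.pre.forward(x, training) if self.pre is not None else x
        y = self.main.forward(t, training)
        if self.shortcut == "projection":
            s = self.projection.forward(t, training)
        elif self.shortcut == "identity":
            s = x
        else:
            return self.post.forward(y, training)
        out = s + self.scale * y
        return self.post.forward(out, training)

    def backward(self, dy):
        dy = self.post.backward(dy)
        if self.shortcut == "none":
            d = self.main.backward(dy)
            return self.pre.backward(d) if self.pre is not None else d
        dmain = self.main.backward(self.scale * dy)
        if self.shortcut == "projection":
            dt = dmain + self.projection.backward(dy)
            return self.pre.backward(dt) if self.pre is not None else dt
        # identity: shortcut taps the raw input
        dx = self.pre.backward(dmain) if self.pre is not None else dmain
        return dx + dy

    def params(self):
        for part in (self.pre, self.main, self.projection, self.post):
            if part is not None:
                yield from part.params()


# ---------------------------------------------------------------------------
# compilation

def _build_layer(layer: LayerSpec, cin: int, carrier: Optional[int],
                 rng) -> tuple[_Node, int]:
    kind = layer.kind
    if kind == "conv":
        cout = carrier if layer.match_channels else layer.filters
        if cout is None:
            raise SpecError("conv without filters outside a block")
        return Conv2D(rng, cin, cout, layer.kernel, layer.stride,
                      layer.padding, layer.bias), cout
    if kind == "dense":
        return Dense(rng, cin, layer.filters, layer.bias), layer.filters
    if kind == "batchnorm":
        return BatchNorm(cin), cin
    if kind == "activation":
        return ReLU(), cin
    if kind in ("pool_max", "pool_avg"):
        return Pool(kind[5:], layer.kernel, layer.stride, layer.padding), cin
    if kind == "global_pool":
        return GlobalAvgPool(), cin
    if kind == "flatten":
        return Flatten(), cin
    if kind == "branch":
        paths, channels = [], []
        for br in layer.branches:
            nodes, c = _build_seq(br, cin, carrier, rng)
            paths.append(nodes)
            channels.append(c)
        cout = sum(channels) if layer.merge == "concat" else channels[0]
        return Branch(paths, layer.merge), cout
    raise SpecError(f"layer kind {kind!r} is not executable")


def _build_seq(layers: Sequence[LayerSpec], cin: int, carrier: Optional[int],
               rng) -> tuple[list[_Node], int]:
    nodes = []
    for layer in layers:
        if layer.kind == "input":
            continue
        node, cin = _build_layer(layer, cin, carrier, rng)
        nodes.append(node)
    return nodes, cin


def _build_block(block: BlockSpec, cin: int, rng) -> tuple[ResidualBlock, int]:
    layers = block.layers
    pre = None
    if block.shortcut == "projection" and block.projection_from_preact:
        # split the leading batchnorm+activation pair off as the shared tap
        split = 0
        while split < len(layers) and layers[split].kind in ("batchnorm", "activation"):
            split += 1
        pre_nodes, _ = _build_seq(layers[:split], cin, cin, rng)
        pre = Sequence(pre_nodes)
        layers = layers[split:]
    main_nodes, cout = _build_seq(layers, cin, cin, rng)
    projection = None
    if block.shortcut == "projection":
        projection, pout = _build_layer(block.projection, cin, cin, rng)
        if pout != cout:
            raise SpecError(f"block {block.name}: projection width {pout} != "
                            f"main path width {cout}")
    elif block.shortcut == "identity" and cout != cin:
        raise SpecError(f"block {block.name}: identity shortcut over a width "
                        f"change {cin} -> {cout}")
    post_nodes, cout = _build_seq(block.post, cout, None, rng)
    return ResidualBlock(pre, Sequence(main_nodes), block.shortcut, projection,
                         block.residual_scale, Sequence(post_nodes)), cout


class Model:
    """Executable network compiled from a :class:`~nar.ir.NetworkSpec`."""

    def __init__(self, net: NetworkSpec, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.spec = net
        self.input_side = (net.input.height, net.input.width)
        self.n_classes = net.n_classes
        nodes, cin = _build_seq(net.stem, net.input.channels, None, rng)
        for stage in net.stages:
            for r in range(stage.repeats):
                blk = (stage.entry_block
                       if r == 0 and stage.entry_block is not None else stage.block)
                node, cin = _build_block(blk, cin, rng)
                nodes.append(node)
            if stage.transition is not None:
                node, cin = _build_block(stage.transition, cin, rng)
                nodes.append(node)
        head_nodes, _ = _build_seq(net.head, cin, None, rng)
        self.graph = Sequence(nodes + head_nodes)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.graph.forward(x.astype(np.float32, copy=False), training)

    def parameters(self) -> list[Param]:
        return list(self.graph.params())

    def param_count(self) -> int:
        """Stored scalars, including batchnorm moving statistics."""
        return int(sum(p.value.size for p in self.parameters()))

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Class probabilities, evaluation mode, batched."""
        outs = []
        for i in range(0, len(x), batch_size):
            logits = self.forward(x[i:i + batch_size], training=False)
            outs.append(_softmax(logits))
        return np.concatenate(outs, axis=0)


def materialize(net: NetworkSpec, seed: int = 0) -> Model:
    """Compile a spec into a trainable model.

    The model's :meth:`Model.param_count` equals the analytic
    :func:`nar.cost.count_params` for every valid spec — the contract that
    keeps the cost model honest.
    """
    return Model(net, seed=seed)


# ---------------------------------------------------------------------------
# training

@dataclass
class TrainConfig:
    """Training protocol: Adam, lr 5e-4, decoupled weight decay 5e-4, 50 epochs."""

    epochs: int = 50
    optimizer: str = "adam"
    learning_rate: float = 5e-4
    weight_decay: float = 5e-4
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise SpecError("epochs and batch_size must be positive")
        if self.learning_rate <= 0 or self.weight_decay < 0:
            raise SpecError("rates must be positive")


class AdamW:
    """Adam with decoupled weight decay applied to conv/dense kernels only."""

    def __init__(self, params: list[Param], lr: float, weight_decay: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = [p for p in params if p.trainable]
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1 - self.b1) * (p.grad - m)
            v += (1 - self.b2) * (p.grad * p.grad - v)
            update = (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            if p.decay:
                update = update + self.wd * p.value
            p.value -= self.lr * update


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def train(model: Model, dataset: tuple[np.ndarray, np.ndarray],
          cfg: TrainConfig) -> tuple[Model, list[float]]:
    """Fit ``model`` on ``(images, labels)``; returns the model and loss history.

    Images are NHWC float arrays already resized to the model input;
    labels are integer class indices.  The shape check happens before any
    optimizer state is created, so a mismatched dataset fails fast.
    """
    x, y = dataset
    x = np.asarray(x, dtype=np.float32)
    y = np.asarray(y, dtype=np.int64)
    if x.shape[1:3] != model.input_side:
        raise SpecError(
            f"dataset patches are {x.shape[1]}x{x.shape[2]} but the model "
            f"expects {model.input_side[0]}x{model.input_side[1]}")
    if len(x) != len(y):
        raise SpecError("images and labels differ in length")
    opt = AdamW(model.parameters(), cfg.learning_rate, cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed)
    history = []
    n = len(x)
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        total, seen = 0.0, 0
        for i in range(0, n, cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            xb, yb = x[idx], y[idx]
            model.zero_grad()
            logits = model.forward(xb, training=True)
            probs = _softmax(logits)
            loss = -np.mean(np.log(probs[np.arange(len(yb)), yb] + 1e-12))
            dlogits = probs
            dlogits[np.arange(len(yb)), yb] -= 1.0
            model.graph.backward(dlogits / len(yb))
            opt.step()
            total += loss * len(yb)
            seen += len(yb)
        history.append(total / seen)
    return model, history


# ---------------------------------------------------------------------------
# evaluation

@dataclass
class EvalResult:
    """Per-run AUC values and their mean."""

    auc_runs: list[float]
    auc_mean: float
    n_runs: int = 3


def evaluate_auc(scores, labels, n_runs: Optional[int] = None) -> EvalResult:
    """Rank-based ROC AUC, averaged over runs.

    ``scores`` is either a single 1-D array of positive-class
    probabilities or a sequence of such arrays (one per training run);
    ``labels`` holds the matching binary ground truth.  Raises when only
    one class is present, where the AUC is undefined.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        scores = scores[None, :]
    labels = np.asarray(labels)
    if labels.ndim == 1:
        labels = np.broadcast_to(labels, scores.shape)
    if scores.shape != labels.shape:
        raise SpecError(f"scores {scores.shape} and labels {labels.shape} differ")
    if n_runs is not None and n_runs != scores.shape[0]:
        raise SpecError(f"expected {n_runs} runs, got {scores.shape[0]}")
    aucs = []
    for s, l in zip(scores, labels):
        if len(np.unique(l)) < 2:
            raise SpecError("AUC undefined: labels contain a single class")
        aucs.append(float(roc_auc_score(l, s)))
    return EvalResult(auc_runs=aucs, auc_mean=float(np.mean(aucs)),
                      n_runs=len(aucs))
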