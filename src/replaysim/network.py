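"""Layered convolutional classifier with named replay cut points.

This module implements a VGG-style stack of 3x3 convolution blocks, each
terminated by a 2x2 max-pool, followed by a fully connected head with
dropout and a softmax output.  The pooling layer ending each block is a
named *cut point* (``pool_1`` .. ``pool_5``): the network can be truncated
there, activations can be read out there, and offline replay can inject
activation patterns there.

Everything is plain NumPy (float32): im2col convolutions, hand-written
backpropagation, and an Adam optimizer.  The network is small enough that
CPU matrix products carry desk-scale experiments in minutes, while the
``vgg16`` preset reproduces the full-scale architecture exactly (including
its parameter count) for structural checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "ArchitectureSpec",
    "OptimizerConfig",
    "EvalReport",
    "LayeredClassifier",
    "TruncatedHead",
    "Adam",
    "build_model",
    "count_parameters",
    "train_epoch",
    "evaluate",
    "evaluate_arrays",
    "activations_at",
    "truncate_at",
    "weight_fingerprint",
]

DTYPE = np.float32


# ---------------------------------------------------------------------------
# Architecture description
# ---------------------------------------------------------------------------

#: (n_conv_layers, n_filters) per block; every block ends in one 2x2 max-pool.
VGG16_BLOCKS: tuple[tuple[int, int], ...] = ((2, 64), (2, 128), (3, 256), (3, 512), (3, 512))
MINI_BLOCKS: tuple[tuple[int, int], ...] = ((1, 8), (1, 16), (1, 32), (2, 64), (2, 64))


@dataclass(frozen=True)
class ArchitectureSpec:
    """Structural description of the classifier.

    ``blocks`` is an ordered list of ``(n_conv_layers, n_filters)`` pairs;
    each block uses 3x3 same-padded ReLU convolutions and is closed by a
    single 2x2 max-pool, which is the block's legal replay cut point.
    ``head`` lists fully connected widths, each followed by dropout at
    ``dropout_rate``.
    """

    input_shape: tuple[int, int, int] = (64, 64, 3)
    blocks: tuple[tuple[int, int], ...] = MINI_BLOCKS
    head: tuple[int, ...] = (128, 128)
    n_outputs: int = 10
    dropout_rate: float = 0.5
    preset: str = "mini"

    @staticmethod
    def mini(n_outputs: int = 10, input_shape: tuple[int, int, int] = (64, 64, 3)) -> "ArchitectureSpec":
        return ArchitectureSpec(input_shape=input_shape, blocks=MINI_BLOCKS,
                                head=(128, 128), n_outputs=n_outputs, preset="mini")

    @staticmethod
    def vgg16(n_outputs: int = 1000) -> "ArchitectureSpec":
        return ArchitectureSpec(input_shape=(224, 224, 3), blocks=VGG16_BLOCKS,
                                head=(4096, 4096), n_outputs=n_outputs, preset="vgg16")

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def cut_point_names(self) -> list[str]:
        return [f"pool_{i + 1}" for i in range(self.n_blocks)]

    def validate(self) -> None:
        h, w, c = self.input_shape
        if c != 3:
            raise ValueError("input_shape must be (H, W, 3)")
        side = min(h, w)
        if side < 2 ** self.n_blocks:
            raise ValueError(
                f"input side {side} too small for {self.n_blocks} pooling stages")
        if not self.blocks:
            raise ValueError("at least one convolutional block is required")
        if self.n_outputs < 1:
            raise ValueError("n_outputs must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass(frozen=True)
class OptimizerConfig:
    """Adam + categorical cross-entropy training configuration."""

    learning_rate: float = 3e-4
    batch_size: int = 36
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-7

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class EvalReport:
    """Per-class and overall accuracy of one evaluation pass."""

    overall_accuracy: float
    per_class_accuracy: np.ndarray
    per_class_correct: np.ndarray
    per_class_total: np.ndarray
    split: str
    predictions: np.ndarray
    labels: np.ndarray


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------


class Layer:
    """Minimal layer interface: forward / backward plus named parameters."""

    params: dict[str, np.ndarray]
    grads: dict[str, np.ndarray]

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def n_params(self) -> int:
        return sum(int(p.size) for p in self.params.values())


class Conv2D(Layer):
    """3x3 same-padded convolution with fused ReLU, NHWC layout."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        fan_in = 9 * c_in
        limit = np.sqrt(6.0 / fan_in)
        self.params["W"] = rng.uniform(-limit, limit, size=(3, 3, c_in, c_out)).astype(DTYPE)
        self.params["b"] = np.zeros(c_out, dtype=DTYPE)
        self._cols: np.ndarray | None = None
        self._relu_mask: np.ndarray | None = None
        self._in_shape: tuple[int, ...] | None = None

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        win = sliding_window_view(xp, (3, 3), axis=(1, 2))  # (n, h, w, c, 3, 3)
        cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(n * h * w, 9 * c)
        return np.ascontiguousarray(cols, dtype=DTYPE)

    def forward(self, x, train=False, rng=None):
        n, h, w, c = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {c}")
        cols = self._im2col(x)
        wmat = self.params["W"].reshape(9 * self.c_in, self.c_out)
        z = cols @ wmat + self.params["b"]
        out = np.maximum(z, 0.0, out=z).reshape(n, h, w, self.c_out)
        if train:
            self._cols = cols
            self._relu_mask = out > 0
            self._in_shape = (n, h, w, c)
        return out

    def backward(self, grad):
        assert self._cols is not None and self._in_shape is not None
        n, h, w, c = self._in_shape
        g = np.asarray((grad * self._relu_mask).reshape(n * h * w, self.c_out), dtype=DTYPE)
        wmat = self.params["W"].reshape(9 * self.c_in, self.c_out)
        self.grads["W"] = (self._cols.T @ g).reshape(3, 3, self.c_in, self.c_out)
        self.grads["b"] = g.sum(axis=0)
        dcols = (g @ wmat.T).reshape(n, h, w, 3, 3, c)
        dxp = np.zeros((n, h + 2, w + 2, c), dtype=DTYPE)
        for i in range(3):
            for j in range(3):
                dxp[:, i:i + h, j:j + w, :] += dcols[:, :, :, i, j, :]
        self._cols = None
        self._relu_mask = None
        return dxp[:, 1:-1, 1:-1, :]


class MaxPool2(Layer):
    """2x2 max pooling with stride 2 (spatial sides must be even).

    The backward pass routes gradient to every input equal to the window
    maximum.  Exact ties only occur at zero here (a ReLU convolution always
    precedes the pool), and those units carry no gradient anyway because
    the upstream ReLU mask is closed.
    """

    def __init__(self) -> None:
        super().__init__()
        self._mask: np.ndarray | None = None
        self._in_shape: tuple[int, ...] | None = None

    def forward(self, x, train=False, rng=None):
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError("MaxPool2 requires even spatial sides")
        rows = np.maximum(x[:, 0::2], x[:, 1::2])
        out = np.maximum(rows[:, :, 0::2], rows[:, :, 1::2])
        if train:
            up = np.repeat(np.repeat(out, 2, axis=1), 2, axis=2)
            self._mask = x == up
            self._in_shape = (n, h, w, c)
        return out

    def backward(self, grad):
        assert self._mask is not None and self._in_shape is not None
        gup = np.repeat(np.repeat(np.asarray(grad, dtype=DTYPE), 2, axis=1), 2, axis=2)
        dx = gup * self._mask
        self._mask = None
        return dx


class Flatten(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._in_shape: tuple[int, ...] | None = None

    def forward(self, x, train=False, rng=None):
        if train:
            self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        assert self._in_shape is not None
        return grad.reshape(self._in_shape)


class Dense(Layer):
    """Fully connected layer, optionally with fused ReLU."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 relu: bool = True):
        super().__init__()
        self.n_in, self.n_out, self.relu = n_in, n_out, relu
        if relu:
            limit = np.sqrt(6.0 / n_in)          # He-uniform
        else:
            limit = np.sqrt(6.0 / (n_in + n_out))  # Glorot-uniform for logits
        self.params["W"] = rng.uniform(-limit, limit, size=(n_in, n_out)).astype(DTYPE)
        self.params["b"] = np.zeros(n_out, dtype=DTYPE)
        self._x: np.ndarray | None = None
        self._relu_mask: np.ndarray | None = None

    def forward(self, x, train=False, rng=None):
        z = x @ self.params["W"] + self.params["b"]
        if self.relu:
            out = np.maximum(z, 0.0, out=z)
        else:
            out = z
        if train:
            self._x = x
            self._relu_mask = out > 0 if self.relu else None
        return out

    def backward(self, grad):
        assert self._x is not None
        g = np.asarray(grad * self._relu_mask if self.relu else grad, dtype=DTYPE)
        self.grads["W"] = self._x.T @ g
        self.grads["b"] = g.sum(axis=0)
        dx = g @ self.params["W"].T
        self._x = None
        self._relu_mask = None
        return dx


class Dropout(Layer):
    """Inverted dropout: active only when ``train`` and an rng is supplied."""

    def __init__(self, rate: float):
        super().__init__()
        self.rate = rate
        self._mask: np.ndarray | None = None

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("dropout in training mode needs an rng")
        keep = 1.0 - self.rate
        mask = (rng.random(x.shape) < keep).astype(DTYPE) / keep
        self._mask = mask
        return x * mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------


class LayeredClassifier:
    """A built network: ordered layers plus named pooling cut points."""

    def __init__(self, spec: ArchitectureSpec, layers: list[Layer],
                 cut_points: dict[str, int]):
        self.spec = spec
        self.layers = layers
        self.cut_points = cut_points
        self._optimizer: "Adam | None" = None
        self._optimizer_lr: float | None = None

    # -- forward passes ----------------------------------------------------
    def forward_logits(self, x: np.ndarray, train: bool = False,
                       rng: np.random.Generator | None = None) -> np.ndarray:
        h = np.asarray(x, dtype=DTYPE)
        for layer in self.layers:
            h = layer.forward(h, train=train, rng=rng)
        return h

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """Class probabilities (softmax over the final logits)."""
        return softmax(self.forward_logits(x, train=train, rng=rng))

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        g = dlogits
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    # -- cut-point helpers -------------------------------------------------
    def cut_index(self, cut_point: str) -> int:
        if cut_point not in self.cut_points:
            raise ValueError(
                f"unknown cut point {cut_point!r}; legal: {sorted(self.cut_points)}")
        return self.cut_points[cut_point]

    def cut_shape(self, cut_point: str) -> tuple[int, int, int]:
        """(h, w, c) of the activation map emitted at ``cut_point``."""
        h, w, _ = self.spec.input_shape
        k = int(cut_point.split("_")[1])
        return h // 2 ** k, w // 2 ** k, self.spec.blocks[k - 1][1]

    def conv_layers(self) -> list[Layer]:
        flat = next(i for i, l in enumerate(self.layers) if isinstance(l, Flatten))
        return self.layers[:flat]

    def head_layers(self) -> list[Layer]:
        flat = next(i for i, l in enumerate(self.layers) if isinstance(l, Flatten))
        return self.layers[flat:]


def build_model(spec: ArchitectureSpec, init_seed: int,
                pretrained_base: "LayeredClassifier | None" = None) -> LayeredClassifier:
    """Build a classifier; head layers are freshly initialized from ``init_seed``.

    If ``pretrained_base`` is given, its convolutional-block weights are
    copied in (shapes must match); the fully connected head is always newly
    initialized, mirroring transfer of a pretrained base to a new task.
    """
    spec.validate()
    ss = np.random.SeedSequence(init_seed)
    rng = np.random.default_rng(ss)

    layers: list[Layer] = []
    cut_points: dict[str, int] = {}
    c_in = spec.input_shape[2]
    for b, (n_conv, n_filt) in enumerate(spec.blocks, start=1):
        for _ in range(n_conv):
            layers.append(Conv2D(c_in, n_filt, rng))
            c_in = n_filt
        layers.append(MaxPool2())
        cut_points[f"pool_{b}"] = len(layers) - 1
    layers.append(Flatten())
    h, w, _ = spec.input_shape
    n_in = (h // 2 ** spec.n_blocks) * (w // 2 ** spec.n_blocks) * c_in
    for width in spec.head:
        layers.append(Dense(n_in, width, rng, relu=True))
        layers.append(Dropout(spec.dropout_rate))
        n_in = width
    layers.append(Dense(n_in, spec.n_outputs, rng, relu=False))

    model = LayeredClassifier(spec, layers, cut_points)
    if pretrained_base is not None:
        src = pretrained_base.conv_layers()
        dst = model.conv_layers()
        if len(src) != len(dst):
            raise ValueError("pretrained base has a different block structure")
        for ls, ld in zip(src, dst):
            for name, p in ls.params.items():
                if p.shape != ld.params[name].shape:
                    raise ValueError(
                        f"pretrained weight shape {p.shape} does not match {ld.params[name].shape}")
                ld.params[name] = p.copy()
    return model


def count_parameters(model: "LayeredClassifier | ArchitectureSpec") -> int:
    """Exact number of trainable scalars (weights + biases)."""
    if isinstance(model, ArchitectureSpec):
        spec = model
        total = 0
        c_in = spec.input_shape[2]
        for n_conv, n_filt in spec.blocks:
            for _ in range(n_conv):
                total += 9 * c_in * n_filt + n_filt
                c_in = n_filt
        h, w, _ = spec.input_shape
        n_in = (h // 2 ** spec.n_blocks) * (w // 2 ** spec.n_blocks) * c_in
        for width in (*spec.head, spec.n_outputs):
            total += n_in * width + width
            n_in = width
        return total
    return sum(layer.n_params() for layer in model.layers)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def weight_fingerprint(layers: Sequence[Layer]) -> tuple[bytes, ...]:
    """Byte-exact snapshot of all parameters, for frozenness assertions."""
    return tuple(p.tobytes() for l in layers for p in l.params.values())


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------


class Adam:
    """Adam over the parameters of a fixed list of layers."""

    def __init__(self, layers: Sequence[Layer], cfg: OptimizerConfig):
        self.layers = list(layers)
        self.cfg = cfg
        self.t = 0
        self._m = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]
        self._v = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]

    def step(self) -> None:
        c = self.cfg
        if c.learning_rate == 0.0:
            return
        self.t += 1
        bc1 = 1.0 - c.beta1 ** self.t
        bc2 = 1.0 - c.beta2 ** self.t
        for li, layer in enumerate(self.layers):
            for name, p in layer.params.items():
                g = layer.grads.get(name)
                if g is None:
                    continue
                m = self._m[li][name]
                v = self._v[li][name]
                m *= c.beta1
                m += (1 - c.beta1) * g
                v *= c.beta2
                v += (1 - c.beta2) * (g * g)
                p -= (c.learning_rate * (m / bc1) / (np.sqrt(v / bc2) + c.epsilon)).astype(p.dtype)


# ---------------------------------------------------------------------------
# Training and evaluation
# ---------------------------------------------------------------------------


def _cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(probs[np.arange(len(y)), y], 1e-12, 1.0)
    return float(-np.mean(np.log(p)))


def _preprocess(x: np.ndarray, channel_means: np.ndarray | None) -> np.ndarray:
    x = np.asarray(x, dtype=DTYPE)
    if channel_means is not None:
        x = x - np.asarray(channel_means, dtype=DTYPE)
    return x


def train_epoch(model: LayeredClassifier, X: np.ndarray, y: np.ndarray,
                opt: OptimizerConfig, rng: np.random.Generator,
                augment: Callable[[np.ndarray, np.random.Generator], np.ndarray] | None = None,
                channel_means: np.ndarray | None = None,
                collect_augmented: bool = False) -> float:
    """One shuffled pass over (X, y); returns the mean batch loss.

    ``augment`` receives the whole image batch plus the epoch rng and
    returns the augmented batch.  With ``collect_augmented`` the augmented
    images of this epoch are kept on ``model.last_augmented`` (in dataset
    order), so a replay phase can capture activations of exactly the views
    the network trained on.

    The final partial batch is kept.  The model's Adam state persists
    across epochs; it is reset if the learning rate changes.
    """
    n = len(X)
    if n == 0:
        raise ValueError("training split is empty")
    if model._optimizer is None or model._optimizer_lr != opt.learning_rate:
        model._optimizer = Adam(model.layers, opt)
        model._optimizer_lr = opt.learning_rate
    order = rng.permutation(n)
    losses = []
    collected = np.empty_like(X) if collect_augmented else None
    for start in range(0, n, opt.batch_size):
        idx = order[start:start + opt.batch_size]
        xb = X[idx]
        if augment is not None:
            xb = augment(xb, rng)
        if collected is not None:
            collected[idx] = xb
        xb = _preprocess(xb, channel_means)
        yb = y[idx]
        probs = model.forward(xb, train=True, rng=rng)
        losses.append(_cross_entropy(probs, yb))
        dlogits = probs.copy()
        dlogits[np.arange(len(yb)), yb] -= 1.0
        dlogits /= len(yb)
        model.backward(dlogits.astype(DTYPE))
        model._optimizer.step()
    model.last_batch_losses = losses
    model.last_augmented = collected
    return float(np.mean(losses))


def evaluate_arrays(model: LayeredClassifier, X: np.ndarray, y: np.ndarray,
                    split: str = "test", channel_means: np.ndarray | None = None,
                    batch_size: int = 256) -> EvalReport:
    """Deterministic evaluation (dropout off, no augmentation)."""
    if len(X) == 0:
        raise ValueError("evaluation split is empty")
    preds = np.empty(len(X), dtype=np.int64)
    for start in range(0, len(X), batch_size):
        xb = _preprocess(X[start:start + batch_size], channel_means)
        preds[start:start + batch_size] = model.forward(xb).argmax(axis=1)
    n_classes = model.spec.n_outputs
    total = np.bincount(y, minlength=n_classes)
    correct = np.bincount(y[preds == y], minlength=n_classes)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_class = np.where(total > 0, correct / np.maximum(total, 1), np.nan)
    return EvalReport(
        overall_accuracy=float(correct.sum() / total.sum()),
        per_class_accuracy=per_class,
        per_class_correct=correct,
        per_class_total=total,
        split=split,
        predictions=preds,
        labels=np.asarray(y),
    )


def evaluate(model: LayeredClassifier, data, split: str = "test",
             batch_size: int = 256) -> EvalReport:
    """Evaluate on one split of a :class:`~replaysim.synthetic.DatasetBundle`."""
    X, y = data.arrays(split)
    return evaluate_arrays(model, X, y, split=split,
                           channel_means=data.channel_means, batch_size=batch_size)


def activations_at(model: LayeredClassifier, cut_point: str, X: np.ndarray,
                   channel_means: np.ndarray | None = None,
                   batch_size: int = 144) -> np.ndarray:
    """Activation maps at a pooling cut point (eval mode, deterministic)."""
    stop = model.cut_index(cut_point)
    outs = []
    for start in range(0, len(X), batch_size):
        h = _preprocess(X[start:start + batch_size], channel_means)
        for layer in model.layers[:stop + 1]:
            h = layer.forward(h)
        outs.append(h)
    return np.concatenate(outs, axis=0)


class TruncatedHead:
    """The part of a classifier after a cut point, sharing the parent's weights.

    Training the head updates the parent model in place (the layer objects
    are shared); layers at or before the cut are untouched by construction.
    A fresh Adam state is created per head, mirroring the nightly
    disconnect/reattach of the replay procedure.
    """

    def __init__(self, parent: LayeredClassifier, cut_point: str):
        stop = parent.cut_index(cut_point)
        self.parent = parent
        self.cut_point = cut_point
        self.layers = parent.layers[stop + 1:]
        self.input_shape = parent.cut_shape(cut_point)
        self._optimizer: Adam | None = None
        self._optimizer_cfg: OptimizerConfig | None = None

    def forward(self, acts: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        h = np.asarray(acts, dtype=DTYPE)
        if h.shape[1:] != self.input_shape:
            raise ValueError(
                f"head expects activations of shape {self.input_shape}, got {h.shape[1:]}")
        for layer in self.layers:
            h = layer.forward(h, train=train, rng=rng)
        return softmax(h)

    def predict(self, acts: np.ndarray, batch_size: int = 64) -> np.ndarray:
        preds = []
        for start in range(0, len(acts), batch_size):
            preds.append(self.forward(acts[start:start + batch_size]).argmax(axis=1))
        return np.concatenate(preds)

    def train_epoch(self, acts: np.ndarray, y: np.ndarray, opt: OptimizerConfig,
                    rng: np.random.Generator) -> float:
        """One shuffled epoch on activation/label pairs; returns mean loss."""
        n = len(acts)
        if n == 0:
            raise ValueError("replay batch is empty")
        if self._optimizer is None or self._optimizer_cfg != opt:
            self._optimizer = Adam(self.layers, opt)
            self._optimizer_cfg = opt
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, opt.batch_size):
            idx = order[start:start + opt.batch_size]
            probs = self.forward(acts[idx], train=True, rng=rng)
            yb = y[idx]
            losses.append(_cross_entropy(probs, yb))
            dlogits = probs.copy()
            dlogits[np.arange(len(yb)), yb] -= 1.0
            dlogits /= len(yb)
            g = dlogits.astype(DTYPE)
            for layer in reversed(self.layers):
                g = layer.backward(g)
            self._optimizer.step()
        return float(np.mean(losses))


def truncate_at(model: LayeredClassifier, cut_point: str) -> TruncatedHead:
    """Disconnect the network after ``cut_point``; weights remain shared."""
    return TruncatedHead(model, cut_point)


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------


def save_model(model: LayeredClassifier, path) -> None:
    """Write a checkpoint archive: the architecture as JSON plus all arrays."""
    import json

    spec = model.spec
    meta = {
        "input_shape": list(spec.input_shape),
        "blocks": [list(b) for b in spec.blocks],
        "head": list(spec.head),
        "n_outputs": spec.n_outputs,
        "dropout_rate": spec.dropout_rate,
        "preset": spec.preset,
    }
    arrays = {f"layer{i:03d}_{name}": p
              for i, layer in enumerate(model.layers)
              for name, p in layer.params.items()}
    np.savez(path, spec_json=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_model(path) -> LayeredClassifier:
    """Load a checkpoint written by :func:`save_model`; validates shapes."""
    import json

    with np.load(path) as blob:
        meta = json.loads(bytes(blob["spec_json"]).decode())
        spec = ArchitectureSpec(
            input_shape=tuple(meta["input_shape"]),
            blocks=tuple(tuple(b) for b in meta["blocks"]),
            head=tuple(meta["head"]), n_outputs=meta["n_outputs"],
            dropout_rate=meta["dropout_rate"], preset=meta["preset"])
        model = build_model(spec, init_seed=0)
        for i, layer in enumerate(model.layers):
            for name in layer.params:
                key = f"layer{i:03d}_{name}"
                if key not in blob:
                    raise ValueError(f"checkpoint is missing array {key}")
                arr = blob[key]
                if arr.shape != layer.params[name].shape:
                    raise ValueError(
                        f"checkpoint array {key} has shape {arr.shape}, "
                        f"expected {layer.params[name].shape}")
                layer.params[name] = arr
    return model
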