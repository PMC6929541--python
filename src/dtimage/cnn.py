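"""The convolutional classifier: a small LeNet-style network in NumPy.

Topology (one layer deeper than LeNet-5 in conv/pool count): three 3x3
same-padded convolution blocks, each optionally batch-normalised and ReLU
activated, with 2x2 max pooling after the first two blocks; the feature
maps are flattened into a fully connected stage (hidden layer, dropout,
then a two-neuron softmax output whose class order is fixed as
(negative, positive)).  Each layer computes pool(f(V_{l-1} * W_l + b_l)).

Training minimises two-class cross-entropy by mini-batch stochastic
gradient descent with momentum at a configurable learning rate (default
0.001).  Everything stochastic — weight initialisation, batch shuffling,
dropout — is driven by one seeded generator, so a (seed, data) pair
reproduces identical weights.  Convolutions are evaluated as matrix
products over im2col patch matrices; gradients are exact (verified by
finite differences in the test suite).  Batch normalisation keeps running
moments for inference; dropout is the inverted variant and is disabled at
inference, so scoring is deterministic.

A non-finite training loss (e.g. from a deliberately huge learning rate)
aborts with a diagnostic rather than silently producing NaN weights.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import asdict, dataclass, field
from io import BytesIO

import numpy as np

CHECKPOINT_FORMAT_VERSION = 1
CLASS_ORDER = ("negative", "positive")


class GeometryError(ValueError):
    """Raised when the layer stack cannot process the declared image side."""


class TrainingError(ValueError):
    """Raised for unusable training inputs (e.g. a single class)."""


class TrainingDivergedError(RuntimeError):
    """Raised when the loss becomes non-finite during training."""


@dataclass
class ModelConfig:
    """Hyper-parameters of the convolutional classifier.

    Only the topology class (three conv blocks, two pooling stages, one
    fully connected stage), the 0.001 learning rate and batch
    normalisation-on are fixed by the method; filter counts, kernel size,
    hidden width, dropout, batch size and iteration budget are this
    package's documented defaults and are all overridable.
    """

    conv_filters: tuple[int, int, int] = (32, 64, 128)
    kernel_size: int = 3
    activation: str = "relu"
    batch_norm: bool = True
    dropout_rate: float = 0.5
    fc_units: int = 128
    learning_rate: float = 0.001
    momentum: float = 0.9
    optimizer: str = "sgd"  # "sgd" (momentum) or "adam"
    batch_size: int = 128
    max_iterations: int = 5000
    log_every: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if len(self.conv_filters) != 3:
            raise ValueError("topology requires exactly three convolution blocks")
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd (same padding)")
        if self.optimizer not in ("sgd", "adam"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["conv_filters"] = list(self.conv_filters)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["conv_filters"] = tuple(d["conv_filters"])
        return cls(**d)


# ---------------------------------------------------------------------------
# layer primitives


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, H, W, C) channels-last -> (B*H*W, C*k*k) patch matrix, same padding."""
    pad = k // 2
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    windows = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
    b, h, w, c, _, _ = windows.shape
    # window dims are appended last: (B, H, W, C, k, k) -> rows are (C, k, k)
    return windows.reshape(b * h * w, c * k * k)


def _col2im(cols: np.ndarray, shape: tuple, k: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter-add patches back to an image."""
    b, h, w, c = shape
    pad = k // 2
    out = np.zeros((b, h + 2 * pad, w + 2 * pad, c), dtype=cols.dtype)
    cols = cols.reshape(b, h, w, c, k, k)
    for i in range(k):
        for j in range(k):
            out[:, i : i + h, j : j + w, :] += cols[:, :, :, :, i, j]
    return out[:, pad : pad + h, pad : pad + w, :]


class _Conv:
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 input_grad: bool = True):
        fan_in = c_in * k * k
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU stacks
        self.w = (rng.standard_normal((fan_in, c_out)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.k = k
        self.input_grad = input_grad  # the first layer never needs dx
        self.params = ["w", "b"]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        self._cols = _im2col(x, self.k)
        b, h, w, _ = x.shape
        y = self._cols @ self.w + self.b
        return y.reshape(b, h, w, -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, h, w, f = dy.shape
        dy2 = dy.reshape(b * h * w, f)
        self.dw = self._cols.T @ dy2
        self.db = dy2.sum(axis=0)
        if not self.input_grad:
            return None
        dcols = dy2 @ self.w.T
        return _col2im(dcols, self._shape, self.k)


class _BatchNorm:
    """Per-channel batch normalisation with running moments for inference."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self.params = ["gamma", "beta"]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        # channels-last: the channel axis is always the last one
        axes = (0, 1, 2) if x.ndim == 4 else (0,)
        shape = (-1,)
        m = x.size // x.shape[-1]
        flat = x.reshape(m, x.shape[-1])
        if training:
            mean = flat.mean(axis=0)
            centred = flat - mean
            var = np.einsum("ij,ij->j", centred, centred) / m
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean = self.running_mean
            var = self.running_var
            centred = flat - mean
        self._std = np.sqrt(var + self.eps)
        centred /= self._std
        self._xhat = centred  # (m, C)
        self._out_shape = x.shape
        y = centred * self.gamma
        y += self.beta
        return y.reshape(x.shape)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c = dy.shape[-1]
        m = dy.size // c
        dy2 = dy.reshape(m, c)
        self.dgamma = np.einsum("ij,ij->j", dy2, self._xhat)
        self.dbeta = dy2.sum(axis=0)
        g = dy2 * self.gamma
        gmean = g.mean(axis=0)
        proj = np.einsum("ij,ij->j", g, self._xhat) / m
        g -= gmean
        g -= self._xhat * proj
        g /= self._std
        return g.reshape(self._out_shape)


class _ReLU:
    params: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class _MaxPool2:
    """2x2 max pooling, stride 2; odd trailing rows/columns are cropped."""

    params: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        self._in_shape = x.shape
        xc = np.ascontiguousarray(x[:, : h2 * 2, : w2 * 2, :]).reshape(b, h2, 2, w2, 2, c)
        out = xc.max(axis=(2, 4))
        # gradient routed to maxima; exact ties (measure-zero on real
        # activations) receive the gradient in full at each tied site
        self._mask = xc == out[:, :, None, :, None, :]
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, h, w, c = self._in_shape
        h2, w2 = h // 2, w // 2
        dx = np.zeros(self._in_shape, dtype=dy.dtype)
        spread = self._mask * dy[:, :, None, :, None, :]
        dx[:, : h2 * 2, : w2 * 2, :] = spread.reshape(b, h2 * 2, w2 * 2, c)
        return dx


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.w = (rng.standard_normal((n_in, n_out)) * scale).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.params = ["w", "b"]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dw = self._x.T @ dy
        self.db = dy.sum(axis=0)
        return dy @ self.w.T


# ---------------------------------------------------------------------------
# the network


class ConvNet:
    """Three conv blocks, two pools, FC hidden layer, dropout, softmax pair."""

    def __init__(self, config: ModelConfig, image_side: int):
        self.config = config
        self.image_side = image_side
        self.rng = np.random.default_rng(config.seed)
        f1, f2, f3 = config.conv_filters
        k = config.kernel_size
        side = image_side
        plan = [side]
        for _ in range(2):  # two pooling stages
            side = side // 2
            plan.append(side)
        if plan[-1] < 1:
            raise GeometryError(
                f"image side {image_side} collapses below 1x1 under two 2x2 "
                f"pooling stages (per-stage sides: {plan})"
            )
        self.map_plan = plan
        rng = self.rng
        self.conv1, self.conv2, self.conv3 = (
            _Conv(1, f1, k, rng, input_grad=False),
            _Conv(f1, f2, k, rng),
            _Conv(f2, f3, k, rng),
        )
        self.bn = (
            [_BatchNorm(f1), _BatchNorm(f2), _BatchNorm(f3)] if config.batch_norm else None
        )
        self.pool1, self.pool2 = _MaxPool2(), _MaxPool2()
        self.relu = [_ReLU() for _ in range(4)]
        flat = f3 * plan[-1] * plan[-1]
        self.fc1 = _Dense(flat, config.fc_units, rng)
        self.fc2 = _Dense(config.fc_units, 2, rng)
        self._layers_with_params = [self.conv1, self.conv2, self.conv3, self.fc1, self.fc2]
        if self.bn:
            self._layers_with_params += self.bn
        self._velocity = {
            (id(l), p): np.zeros_like(getattr(l, p))
            for l in self._layers_with_params
            for p in l.params
        }
        self._adam_m = {k: np.zeros_like(v) for k, v in self._velocity.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self._velocity.items()}
        self._adam_t = 0

    # -- forward / backward --------------------------------------------------

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Logits for a (B, side, side) or (B, side, side, 1) batch."""
        if x.ndim == 3:
            x = x[..., None]
        if x.shape[1] != self.image_side:
            raise GeometryError(
                f"input side {x.shape[1]} does not match model side {self.image_side}"
            )
        h = self.conv1.forward(x)
        if self.bn:
            h = self.bn[0].forward(h, training)
        h = self.relu[0].forward(h)
        h = self.pool1.forward(h)
        h = self.conv2.forward(h)
        if self.bn:
            h = self.bn[1].forward(h, training)
        h = self.relu[1].forward(h)
        h = self.pool2.forward(h)
        h = self.conv3.forward(h)
        if self.bn:
            h = self.bn[2].forward(h, training)
        h = self.relu[2].forward(h)
        self._flat_shape = h.shape
        h = h.reshape(h.shape[0], -1)
        h = self.relu[3].forward(self.fc1.forward(h))
        if training and self.config.dropout_rate > 0:
            keep = 1.0 - self.config.dropout_rate
            self._drop_mask = (self.rng.random(h.shape) < keep) / keep
            h = h * self._drop_mask
        else:
            self._drop_mask = None
        return self.fc2.forward(h)

    def backward(self, dlogits: np.ndarray) -> None:
        g = self.fc2.backward(dlogits)
        if self._drop_mask is not None:
            g = g * self._drop_mask
        g = self.fc1.backward(self.relu[3].backward(g))
        g = g.reshape(self._flat_shape)
        g = self.relu[2].backward(g)
        if self.bn:
            g = self.bn[2].backward(g)
        g = self.conv3.backward(g)
        g = self.pool2.backward(g)
        g = self.relu[1].backward(g)
        if self.bn:
            g = self.bn[1].backward(g)
        g = self.conv2.backward(g)
        g = self.pool1.backward(g)
        g = self.relu[0].backward(g)
        if self.bn:
            g = self.bn[0].backward(g)
        self.conv1.backward(g)

    def sgd_step(self) -> None:
        lr = self.config.learning_rate
        if self.config.optimizer == "adam":
            b1, b2, eps = 0.9, 0.999, 1e-8
            self._adam_t += 1
            t = self._adam_t
            for layer in self._layers_with_params:
                for p in layer.params:
                    g = getattr(layer, "d" + p).astype(np.float32)
                    key = (id(layer), p)
                    m, v = self._adam_m[key], self._adam_v[key]
                    m *= b1
                    m += (1 - b1) * g
                    v *= b2
                    v += (1 - b2) * g * g
                    mhat = m / (1 - b1**t)
                    vhat = v / (1 - b2**t)
                    getattr(layer, p)[...] -= lr * mhat / (np.sqrt(vhat) + eps)
            return
        mu = self.config.momentum
        for layer in self._layers_with_params:
            for p in layer.params:
                v = self._velocity[(id(layer), p)]
                v *= mu
                v -= lr * getattr(layer, "d" + p).astype(np.float32)
                getattr(layer, p)[...] += v

    # -- parameter (de)serialisation ------------------------------------------

    def state_arrays(self) -> dict[str, np.ndarray]:
        state = {}
        names = ["conv1", "conv2", "conv3", "fc1", "fc2"]
        for name in names:
            layer = getattr(self, name)
            for p in layer.params:
                state[f"{name}.{p}"] = getattr(layer, p)
        if self.bn:
            for i, bn in enumerate(self.bn):
                for p in ("gamma", "beta", "running_mean", "running_var"):
                    state[f"bn{i}.{p}"] = getattr(bn, p)
        return state

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for key, arr in state.items():
            name, p = key.split(".")
            layer = self.bn[int(name[2:])] if name.startswith("bn") else getattr(self, name)
            getattr(layer, p)[...] = arr


def _softmax_xent(logits: np.ndarray, labels: np.ndarray):
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    eps = 1e-12
    loss = -np.log(probs[np.arange(len(labels)), labels] + eps).mean()
    dlogits = probs.copy()
    dlogits[np.arange(len(labels)), labels] -= 1.0
    return float(loss), dlogits / len(labels), probs


@dataclass
class TrainedModel:
    """A trained classifier: config, network weights and training trace."""

    config: ModelConfig
    net: ConvNet
    training_log: list = field(default_factory=list)  # (iteration, loss)
    class_order: tuple = CLASS_ORDER

    def score(self, images: np.ndarray, batch_size: int = 512) -> np.ndarray:
        """Positive-class probability per image, deterministic (eval mode)."""
        images = np.asarray(images, dtype=np.float32)
        if images.ndim == 2:
            images = images[None]
        if images.shape[-1] != self.net.image_side:
            raise GeometryError(
                f"image side {images.shape[-1]} does not match trained side "
                f"{self.net.image_side}"
            )
        out = np.empty(len(images))
        for start in range(0, len(images), batch_size):
            chunk = images[start : start + batch_size]
            logits = self.net.forward(chunk, training=False)
            z = logits - logits.max(axis=1, keepdims=True)
            ez = np.exp(z)
            out[start : start + len(chunk)] = (ez[:, 1] / ez.sum(axis=1))
        return out

    def save(self, path) -> None:
        """Single-file checkpoint: config + weights + class order + version."""
        buf = BytesIO()
        np.savez(buf, **self.net.state_arrays())
        meta = {
            "format_version": CHECKPOINT_FORMAT_VERSION,
            "config": self.config.to_dict(),
            "image_side": self.net.image_side,
            "class_order": list(self.class_order),
            "training_log": self.training_log,
        }
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("meta.json", json.dumps(meta))
            zf.writestr("weights.npz", buf.getvalue())

    @classmethod
    def load(cls, path) -> "TrainedModel":
        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("meta.json"))
            if meta["format_version"] != CHECKPOINT_FORMAT_VERSION:
                raise ValueError(
                    f"checkpoint format {meta['format_version']} not supported "
                    f"(expected {CHECKPOINT_FORMAT_VERSION})"
                )
            with zf.open("weights.npz") as fh:
                state = dict(np.load(BytesIO(fh.read())))
        config = ModelConfig.from_dict(meta["config"])
        net = ConvNet(config, meta["image_side"])
        net.load_state(state)
        return cls(
            config=config,
            net=net,
            training_log=[tuple(e) for e in meta["training_log"]],
            class_order=tuple(meta["class_order"]),
        )


def build_model(config: ModelConfig, image_side: int) -> ConvNet:
    """Construct the untrained network, validating the pooling geometry."""
    return ConvNet(config, image_side)


def train(
    net: ConvNet,
    images: np.ndarray,
    labels: np.ndarray,
    config: ModelConfig | None = None,
) -> TrainedModel:
    """Mini-batch SGD training on (N, side, side) images with 0/1 labels."""
    config = config or net.config
    images = np.asarray(images, dtype=np.float32)
    labels = np.asarray(labels, dtype=np.int64)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise TrainingError(f"training set contains a single class: {classes.tolist()}")
    n = len(images)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(101,)))
    order = rng.permutation(n)
    cursor = 0
    log: list[tuple[int, float]] = []
    for it in range(1, config.max_iterations + 1):
        if cursor + config.batch_size > n:
            order = rng.permutation(n)
            cursor = 0
        idx = order[cursor : cursor + config.batch_size]
        cursor += config.batch_size
        logits = net.forward(images[idx], training=True)
        loss, dlogits, _ = _softmax_xent(logits, labels[idx])
        if not np.isfinite(loss):
            raise TrainingDivergedError(
                f"loss became non-finite at iteration {it} "
                f"(learning_rate={config.learning_rate}); reduce the learning "
                "rate or enable batch normalisation"
            )
        net.backward(dlogits.astype(np.float32))
        net.sgd_step()
        if it % config.log_every == 0 or it == 1 or it == config.max_iterations:
            log.append((it, loss))
    return TrainedModel(config=config, net=net, training_log=log)


def write_training_log(model: TrainedModel, path) -> None:
    with open(path, "w") as fh:
        fh.write("iteration,loss\n")
        for it, loss in model.training_log:
            fh.write(f"{it},{loss}\n")
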