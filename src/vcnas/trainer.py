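"""Realize a network structure as a trainable model and train it.

The training protocol is deliberately rigid, because the point of the
surrounding search is to compare *structures* under identical conditions:
Adam at a constant learning rate of 0.001 with no weight decay, softmax
cross-entropy loss, a fixed minibatch size, validation after every epoch,
and early stopping once the validation error has not reached a new minimum
for ``patience`` consecutive epochs.  The per-epoch validation error curve
— and its minimum, the ranking score — is the trial's entire output.

Models are built directly from :class:`~vcnas.arch_space.NetworkStructure`
with ReLU activations after every conv and hidden dense layer (the
capacity bound used for enumeration assumes piecewise-linear activations),
and no activation on the output layer: softmax lives in the loss.  The
forward and backward passes are plain NumPy; convolutions use same padding
at stride 1, pooling uses stride equal to its window with same padding.
Everything is seeded and deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .arch_space import (
    CONV,
    DENSE,
    MAXPOOL,
    OUTPUT,
    NetworkStructure,
    TopologyError,
    encode_structure,
)
from .data_io import DatasetBundle

__all__ = [
    "TrainConfig",
    "TrialResult",
    "iterations_per_epoch",
    "early_stop_decision",
    "train_model",
    "evaluate_error",
]


@dataclass(frozen=True)
class TrainConfig:
    """Fixed training protocol parameters.

    ``learning_rate`` 0.001 and ``patience`` 5 are the protocol constants;
    ``max_epochs`` is only a safety cap on top of early stopping.
    """

    batch_size: int = 100
    learning_rate: float = 0.001
    patience: int = 5
    max_epochs: int = 200
    seed: int = 0
    optimizer: str = "adam"
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.patience < 1:
            raise ValueError("patience must be at least 1")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be positive")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")


@dataclass
class TrialResult:
    """Outcome of training one network once: the validation error curve."""

    structure_encoding: str
    val_error_curve: list[float]
    best_epoch: int
    best_val_error: float
    stopped_early: bool
    seed: int
    failed: bool = False

    def to_record(self) -> dict:
        return {
            "structure_encoding": self.structure_encoding,
            "val_error_curve": self.val_error_curve,
            "best_epoch": self.best_epoch,
            "best_val_error": self.best_val_error,
            "stopped_early": self.stopped_early,
            "seed": self.seed,
            "failed": self.failed,
        }

    @classmethod
    def from_record(cls, rec: dict) -> "TrialResult":
        return cls(
            rec["structure_encoding"],
            list(rec["val_error_curve"]),
            rec["best_epoch"],
            rec["best_val_error"],
            rec["stopped_early"],
            rec["seed"],
            rec.get("failed", False),
        )


def iterations_per_epoch(train_n: int, batch_size: int) -> int:
    """Gradient steps per epoch: ``ceil(train_n / batch_size)``.

    The last partial minibatch is kept; the study's configurations all
    divide evenly (800/100 -> 8, 400/100 -> 4, 60/10 -> 6, 4000/100 -> 40,
    2500/100 -> 25).
    """
    if train_n < 1 or batch_size < 1:
        raise ValueError("train_n and batch_size must be positive")
    return math.ceil(train_n / batch_size)


def early_stop_decision(curve: list[float], patience: int) -> tuple[bool, int]:
    """Early-stopping check on a validation error curve.

    Returns ``(stop, best_epoch)`` with 1-based ``best_epoch`` at the first
    epoch attaining the curve minimum (ties resolve to the earliest epoch).
    Training stops when the last ``patience`` epochs produced no new strict
    minimum, i.e. when ``len(curve) - best_epoch >= patience``.
    """
    if not curve:
        raise ValueError("curve must be non-empty")
    best_epoch = int(np.argmin(curve)) + 1
    return (len(curve) - best_epoch >= patience), best_epoch


# ---------------------------------------------------------------------------
# layers


class _Conv:
    def __init__(self, k: int, cin: int, cout: int, rng: np.random.Generator):
        self.k = k
        scale = math.sqrt(2.0 / (k * k * cin))  # He init for ReLU nets
        self.W = rng.normal(0.0, scale, size=(k, k, cin, cout))
        self.b = np.zeros(cout)

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        k = self.k
        pl, pr = (k - 1) // 2, k // 2
        xp = np.pad(x, ((0, 0), (pl, pr), (pl, pr), (0, 0)))
        n, h, w, _ = x.shape
        y = np.empty((n, h, w, self.W.shape[3]))
        y[:] = self.b
        for di in range(k):
            for dj in range(k):
                y += np.tensordot(
                    xp[:, di : di + h, dj : dj + w, :], self.W[di, dj], axes=1
                )
        if train:
            self._xp, self._hw = xp, (h, w)
        return y

    def backward(self, dy: np.ndarray):
        k, (h, w) = self.k, self._hw
        xp = self._xp
        dW = np.empty_like(self.W)
        dxp = np.zeros_like(xp)
        for di in range(k):
            for dj in range(k):
                patch = xp[:, di : di + h, dj : dj + w, :]
                dW[di, dj] = np.tensordot(patch, dy, axes=([0, 1, 2], [0, 1, 2]))
                dxp[:, di : di + h, dj : dj + w, :] += np.tensordot(
                    dy, self.W[di, dj], axes=([3], [1])
                )
        db = dy.sum(axis=(0, 1, 2))
        pl = (k - 1) // 2
        self._xp = None
        dx = dxp[:, pl : pl + h, pl : pl + w, :]
        return dx, [dW, db]


class _MaxPool:
    def __init__(self, k: int):
        self.k = k

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        k = self.k
        n, h, w, c = x.shape
        ho, wo = math.ceil(h / k), math.ceil(w / k)
        xp = np.pad(
            x,
            ((0, 0), (0, ho * k - h), (0, wo * k - w), (0, 0)),
            constant_values=-np.inf,
        )
        windows = xp.reshape(n, ho, k, wo, k, c).transpose(0, 1, 3, 5, 2, 4)
        flat = windows.reshape(n, ho, wo, c, k * k)
        arg = flat.argmax(axis=-1)
        y = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
        if train:
            self._arg, self._inshape = arg, (n, h, w, c)
        return y

    def backward(self, dy: np.ndarray):
        k = self.k
        n, h, w, c = self._inshape
        ho, wo = dy.shape[1], dy.shape[2]
        flat = np.zeros((n, ho, wo, c, k * k))
        np.put_along_axis(flat, self._arg[..., None], dy[..., None], axis=-1)
        dxp = flat.reshape(n, ho, wo, c, k, k).transpose(0, 1, 4, 2, 5, 3)
        dxp = dxp.reshape(n, ho * k, wo * k, c)
        self._arg = None
        return dxp[:, :h, :w, :], []


class _Dense:
    def __init__(self, din: int, dout: int, rng: np.random.Generator):
        scale = math.sqrt(2.0 / din)
        self.W = rng.normal(0.0, scale, size=(din, dout))
        self.b = np.zeros(dout)

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        flat = x.reshape(len(x), -1)
        if train:
            self._x = flat
            self._inshape = x.shape
        return flat @ self.W + self.b

    def backward(self, dy: np.ndarray):
        dW = self._x.T @ dy
        db = dy.sum(axis=0)
        dx = (dy @ self.W.T).reshape(self._inshape)
        self._x = None
        return dx, [dW, db]


class _ReLU:
    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dy: np.ndarray):
        dx = dy * self._mask
        self._mask = None
        return dx, []


class _Model:
    """A structure realized as a sequence of NumPy layers."""

    def __init__(self, structure: NetworkStructure, rng: np.random.Generator):
        shape = structure.input_shape
        h, c = shape.height, shape.channels
        flat = None
        self.layers: list = []
        for spec in structure.layers:
            if spec.kind == CONV:
                self.layers.append(_Conv(spec.size, c, spec.width, rng))
                self.layers.append(_ReLU())
                c = spec.width
            elif spec.kind == MAXPOOL:
                self.layers.append(_MaxPool(spec.size))
                h = math.ceil(h / spec.size)
            else:
                din = flat if flat is not None else h * h * c
                self.layers.append(_Dense(din, spec.width, rng))
                if spec.kind == DENSE:
                    self.layers.append(_ReLU())
                flat = spec.width

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dlogits: np.ndarray) -> list[np.ndarray]:
        grads: list[np.ndarray] = []
        d = dlogits
        for layer in reversed(self.layers):
            d, g = layer.backward(d)
            grads = g + grads
        return grads

    def predict(self, images: np.ndarray, batch: int = 256) -> np.ndarray:
        out = []
        for i in range(0, len(images), batch):
            out.append(self.forward(images[i : i + batch]).argmax(axis=1))
        return np.concatenate(out) if out else np.empty(0, dtype=int)


class _Adam:
    def __init__(self, params: list[np.ndarray], config: TrainConfig):
        self.lr = config.learning_rate
        self.b1, self.b2, self.eps = config.adam_beta1, config.adam_beta2, config.adam_eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _softmax_xent_grad(logits: np.ndarray, labels: np.ndarray):
    z = logits - logits.max(axis=1, keepdims=True)
    expz = np.exp(z)
    p = expz / expz.sum(axis=1, keepdims=True)
    n = len(labels)
    loss = -np.mean(np.log(p[np.arange(n), labels] + 1e-300))
    dlogits = p
    dlogits[np.arange(n), labels] -= 1.0
    return loss, dlogits / n


def evaluate_error(model: _Model, bundle: DatasetBundle) -> float:
    """Classification error fraction of ``model`` on ``bundle``."""
    pred = model.predict(bundle.images)
    return float(np.mean(pred != bundle.labels))


def train_model(
    structure: NetworkStructure,
    train: DatasetBundle,
    val: DatasetBundle,
    config: TrainConfig,
) -> TrialResult:
    """Train one network under the fixed protocol; return its trial result.

    The model is validated after every epoch; training stops per
    :func:`early_stop_decision` or at ``config.max_epochs``.  A diverged
    trial (non-finite loss) is recorded as failed with error 1.0 rather
    than raising.
    """
    h, w, c = train.image_shape
    shape = structure.input_shape
    if (shape.height, shape.width, shape.channels) != (h, w, c):
        raise TopologyError(
            f"structure expects {shape.height}x{shape.width}x{shape.channels} "
            f"input but data is {h}x{w}x{c}"
        )
    if structure.n_classes != train.n_classes:
        raise TopologyError(
            f"structure has {structure.n_classes} outputs but data has "
            f"{train.n_classes} classes"
        )

    rng = np.random.default_rng(config.seed)
    model = _Model(structure, rng)
    params = model.parameters()
    opt = _Adam(params, config)
    encoding = encode_structure(structure, include_widths=True)

    curve: list[float] = []
    stopped_early = False
    for _epoch in range(config.max_epochs):
        order = rng.permutation(len(train))
        diverged = False
        for i in range(0, len(order), config.batch_size):
            idx = order[i : i + config.batch_size]
            logits = model.forward(train.images[idx], train=True)
            loss, dlogits = _softmax_xent_grad(logits, train.labels[idx])
            if not np.isfinite(loss):
                diverged = True
                break
            grads = model.backward(dlogits)
            opt.step(params, grads)
        if diverged:
            curve.append(1.0)
            best_epoch = int(np.argmin(curve)) + 1
            return TrialResult(
                encoding, curve, best_epoch, float(min(curve)), True, config.seed,
                failed=True,
            )
        curve.append(evaluate_error(model, val))
        stop, best_epoch = early_stop_decision(curve, config.patience)
        if stop:
            stopped_early = True
            break
    best_epoch = int(np.argmin(curve)) + 1
    return TrialResult(
        encoding, curve, best_epoch, float(min(curve)), stopped_early, config.seed
    )
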