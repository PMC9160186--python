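"""Compact convolutional classifier for 125 x W SSVEP spectrograms.

Architecture: an 8-filter 5x5 convolution with ReLU, max pooling, dropout;
a 16-filter 3x3 convolution, max pooling, dropout; a 256-unit dense layer
with dropout; and a 3-node softmax output, one node per stimulus frequency
(class order fixed as ascending frequency). Trained with Adam on the
cross-entropy loss, learning rate 0.001, batch size 64, dropout rate 0.5,
for a fixed 100 epochs.

The network is implemented directly on numpy (im2col convolutions, manual
backpropagation), which keeps training deterministic under a fixed seed and
fast at these image sizes. Convolutions use "same" padding and pooling
windows shrink to 2x1 once the time axis is a single column, so every input
width from 1 to 5 columns is supported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .spectro import N_BINS, Spectrogram

__all__ = [
    "ArchitectureSpec",
    "TrainConfig",
    "SoftmaxTriple",
    "softmax",
    "build_model",
    "SsvepCnn",
]

DEFAULT_CLASS_LABELS = (8.0, 11.0, 14.0)
_MAX_WIDTH = 5


def softmax(z: np.ndarray) -> np.ndarray:
    """Normalized exponential, stable under constant shifts of the input."""
    z = np.asarray(z, dtype=float)
    if z.shape[-1] < 2:
        raise ValueError("softmax needs at least two classes")
    if not np.all(np.isfinite(z)):
        raise ValueError("softmax input must be finite")
    shifted = z - np.max(z, axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / np.sum(e, axis=-1, keepdims=True)


@dataclass(frozen=True)
class ArchitectureSpec:
    """Layer sizing of the spectrogram CNN (filter counts fixed at 8 and 16)."""

    conv1_filters: int = 8
    conv1_kernel: tuple[int, int] = (5, 5)
    conv2_filters: int = 16
    conv2_kernel: tuple[int, int] = (3, 3)
    dense_units: int = 256
    n_classes: int = 3
    pool: tuple[int, int] = (2, 2)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings; the stopping criterion is the epoch count alone."""

    learning_rate: float = 1e-3
    batch_size: int = 64
    dropout: float = 0.5
    max_epochs: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size <= 0 or self.max_epochs <= 0:
            raise ValueError("learning rate, batch size and epochs must be positive")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout rate must lie in [0, 1)")


@dataclass(frozen=True)
class SoftmaxTriple:
    """Class-probability vector from the 3-node softmax output layer."""

    probs: np.ndarray
    class_labels: tuple[float, ...] = DEFAULT_CLASS_LABELS

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (len(self.class_labels),):
            raise ValueError(
                f"expected {len(self.class_labels)} probabilities, got shape {p.shape}"
            )
        if abs(float(p.sum()) - 1.0) > 1e-6:
            raise ValueError("softmax probabilities must sum to 1 within 1e-6")

    @property
    def predicted_index(self) -> int:
        """Argmax class index; ties break toward the lowest index."""
        return int(np.argmax(self.probs))

    @property
    def predicted_freq(self) -> float:
        return self.class_labels[self.predicted_index]


# ---------------------------------------------------------------------------
# layers (internal): each caches what backward needs; single-threaded use


class _Conv2DSame:
    def __init__(self, rng, kh, kw, cin, cout):
        self.kh, self.kw, self.cin, self.cout = kh, kw, cin, cout
        scale = np.sqrt(2.0 / (kh * kw * cin))  # He init for ReLU stacks
        self.W = rng.normal(0.0, scale, (kh, kw, cin, cout)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        n, h, w, _ = x.shape
        ph, pw = self.kh // 2, self.kw // 2
        xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
        # (N, H, W, C, kh, kw) -> (N, H, W, kh*kw*C), matching W.reshape order
        cols = sliding_window_view(xp, (self.kh, self.kw), axis=(1, 2))
        cols = np.ascontiguousarray(cols.transpose(0, 1, 2, 4, 5, 3)).reshape(
            n, h, w, self.kh * self.kw * self.cin
        )
        self._cols, self._xshape = cols, x.shape
        wmat = self.W.reshape(-1, self.cout)
        return cols @ wmat + self.b

    def backward(self, g):
        n, h, w, _ = self._xshape
        ph, pw = self.kh // 2, self.kw // 2
        k = self.kh * self.kw * self.cin
        wmat = self.W.reshape(-1, self.cout)
        self.dW = (self._cols.reshape(-1, k).T @ g.reshape(-1, self.cout)).reshape(
            self.W.shape
        )
        self.db = g.sum(axis=(0, 1, 2))
        dcols = (g @ wmat.T).reshape(n, h, w, self.kh, self.kw, self.cin)
        dxp = np.zeros((n, h + 2 * ph, w + 2 * pw, self.cin), dtype=g.dtype)
        for i in range(self.kh):
            for j in range(self.kw):
                dxp[:, i : i + h, j : j + w, :] += dcols[:, :, :, i, j, :]
        self._cols = None
        return dxp[:, ph : ph + h, pw : pw + w, :]

    @property
    def grads(self):
        return [self.dW, self.db]


class _ReLU:
    params: list = []
    grads: list = []

    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask


class _MaxPool:
    """Non-overlapping max pooling; trailing rows/columns beyond a full
    window are cropped (and receive zero gradient)."""

    params: list = []
    grads: list = []

    def __init__(self, ph, pw):
        self.ph, self.pw = ph, pw

    def forward(self, x):
        n, h, w, c = x.shape
        h2, w2 = h // self.ph, w // self.pw
        crop = x[:, : h2 * self.ph, : w2 * self.pw, :]
        blocks = crop.reshape(n, h2, self.ph, w2, self.pw, c)
        blocks = blocks.transpose(0, 1, 3, 5, 2, 4).reshape(
            n, h2, w2, c, self.ph * self.pw
        )
        self._idx = np.argmax(blocks, axis=-1)
        self._xshape = x.shape
        return np.take_along_axis(blocks, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, g):
        n, h, w, c = self._xshape
        h2, w2 = h // self.ph, w // self.pw
        dblocks = np.zeros(
            (n, h2, w2, c, self.ph * self.pw), dtype=g.dtype
        )
        np.put_along_axis(dblocks, self._idx[..., None], g[..., None], axis=-1)
        dcrop = dblocks.reshape(n, h2, w2, c, self.ph, self.pw).transpose(
            0, 1, 4, 2, 5, 3
        ).reshape(n, h2 * self.ph, w2 * self.pw, c)
        dx = np.zeros(self._xshape, dtype=g.dtype)
        dx[:, : h2 * self.ph, : w2 * self.pw, :] = dcrop
        return dx


class _Dropout:
    params: list = []
    grads: list = []

    def __init__(self, rate):
        self.rate = rate

    def forward(self, x, rng=None):
        if rng is None or self.rate == 0.0:  # inference mode
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask


class _Flatten:
    params: list = []
    grads: list = []

    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


class _Dense:
    def __init__(self, rng, n_in, n_out):
        scale = np.sqrt(2.0 / n_in)
        self.W = rng.normal(0.0, scale, (n_in, n_out)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, g):
        self.dW = self._x.T @ g
        self.db = g.sum(axis=0)
        self._x = None
        return g @ self.W.T

    @property
    def grads(self):
        return [self.dW, self.db]


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2**self.t) / (1 - self.b1**self.t)
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= lr_t * m / (np.sqrt(v) + self.eps)


# ---------------------------------------------------------------------------


class SsvepCnn:
    """The spectrogram classifier, built for a fixed input width.

    Parameters
    ----------
    spec : ArchitectureSpec
        Layer sizing (defaults match the reference architecture).
    input_width : int
        Spectrogram width W in columns (window length in seconds), 1..5.
    seed : int
        Seed for weight initialization, batch shuffling and dropout; two
        models built with the same seed start from identical parameters.
    """

    def __init__(
        self,
        spec: ArchitectureSpec | None = None,
        input_width: int = 5,
        seed: int = 0,
        class_labels: tuple[float, ...] = DEFAULT_CLASS_LABELS,
    ):
        spec = spec or ArchitectureSpec()
        if not (1 <= input_width <= _MAX_WIDTH):
            raise ValueError(f"input_width must be in 1..{_MAX_WIDTH}, got {input_width}")
        if spec.n_classes != len(class_labels):
            raise ValueError("n_classes must match the class label count")
        self.spec = spec
        self.input_width = int(input_width)
        self.seed = int(seed)
        self.class_labels = tuple(class_labels)
        self.rng = np.random.default_rng(seed)
        self._fitted = False

        ph, pw = spec.pool
        w = input_width
        self.conv1 = _Conv2DSame(self.rng, *spec.conv1_kernel, 1, spec.conv1_filters)
        self.pool1 = _MaxPool(ph, pw if w >= pw else 1)
        w = w // self.pool1.pw
        self.conv2 = _Conv2DSame(
            self.rng, *spec.conv2_kernel, spec.conv1_filters, spec.conv2_filters
        )
        self.pool2 = _MaxPool(ph, pw if w >= pw else 1)
        w = w // self.pool2.pw
        h = (N_BINS // ph) // ph
        flat = h * w * spec.conv2_filters
        self.drop1 = _Dropout(0.5)
        self.drop2 = _Dropout(0.5)
        self.drop3 = _Dropout(0.5)
        self.dense1 = _Dense(self.rng, flat, spec.dense_units)
        self.relu1, self.relu2, self.relu3 = _ReLU(), _ReLU(), _ReLU()
        self.flatten = _Flatten()
        self.dense2 = _Dense(self.rng, spec.dense_units, spec.n_classes)
        self._layers = [
            self.conv1, self.relu1, self.pool1, self.drop1,
            self.conv2, self.relu2, self.pool2, self.drop2,
            self.flatten, self.dense1, self.relu3, self.drop3,
            self.dense2,
        ]

    @property
    def n_parameters(self) -> int:
        return sum(p.size for layer in self._layers for p in layer.params)

    # -- forward / backward --------------------------------------------------

    def _forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        rng = self.rng if train else None
        out = x
        for layer in self._layers:
            if isinstance(layer, _Dropout):
                out = layer.forward(out, rng)
            else:
                out = layer.forward(out)
        return out  # logits

    def _backward(self, g: np.ndarray) -> None:
        for layer in reversed(self._layers):
            g = layer.backward(g)

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[..., None]
        if x.ndim != 4 or x.shape[1] != N_BINS or x.shape[2] != self.input_width:
            raise ValueError(
                f"expected images of shape ({N_BINS}, {self.input_width}), "
                f"got {x.shape[1:]}"
            )
        return x

    # -- training ------------------------------------------------------------

    def fit(
        self,
        images: np.ndarray,
        labels: np.ndarray,
        cfg: TrainConfig | None = None,
        validation: tuple[np.ndarray, np.ndarray] | None = None,
    ) -> pd.DataFrame:
        """Train for exactly ``cfg.max_epochs`` epochs; returns the loss history.

        ``images`` is (N, 125, W) or (N, 125, W, 1); ``labels`` are class
        indices 0..n_classes-1. The history has one row per epoch with the
        mean minibatch training loss and, when a validation set is given,
        evaluation-mode validation loss and accuracy.
        """
        cfg = cfg or TrainConfig(seed=self.seed)
        x = self._check_input(images)
        y = np.asarray(labels, dtype=int)
        if x.shape[0] == 0:
            raise ValueError("training set is empty")
        if y.shape != (x.shape[0],):
            raise ValueError("labels must be one class index per image")
        present = np.unique(y)
        missing = sorted(set(range(self.spec.n_classes)) - set(present.tolist()))
        if missing:
            raise ValueError(
                f"classes {missing} absent from training labels; every output "
                "node needs at least one example"
            )
        for d in (self.drop1, self.drop2, self.drop3):
            d.rate = cfg.dropout
        params = [p for layer in self._layers for p in layer.params]
        opt = _Adam(params, cfg.learning_rate)
        onehot = np.eye(self.spec.n_classes, dtype=np.float32)[y]
        rows = []
        for epoch in range(cfg.max_epochs):
            order = self.rng.permutation(x.shape[0])
            losses = []
            for start in range(0, x.shape[0], cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                logits = self._forward(x[idx], train=True)
                p = softmax(logits)
                eps = 1e-12
                losses.append(
                    float(-np.mean(np.sum(onehot[idx] * np.log(p + eps), axis=1)))
                )
                self._backward((p - onehot[idx]).astype(np.float32) / idx.size)
                opt.step(params, [g for layer in self._layers for g in layer.grads])
            row = {"epoch": epoch, "train_loss": float(np.mean(losses))}
            if validation is not None:
                xv, yv = validation
                pv = self.predict_proba(xv)
                yv = np.asarray(yv, dtype=int)
                row["val_loss"] = float(
                    -np.mean(np.log(pv[np.arange(len(yv)), yv] + 1e-12))
                )
                row["val_accuracy"] = float(np.mean(pv.argmax(axis=1) == yv))
            rows.append(row)
        self._fitted = True
        self.history = pd.DataFrame(rows)
        return self.history

    # -- inference -----------------------------------------------------------

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        """Softmax probabilities, (N, n_classes), computed in inference mode."""
        x = self._check_input(images)
        return softmax(self._forward(x, train=False))

    def predict(self, images: np.ndarray) -> np.ndarray:
        """Class indices; argmax with ties broken toward the lowest index."""
        return self.predict_proba(images).argmax(axis=1)

    def predict_softmax(self, image: Spectrogram | np.ndarray) -> SoftmaxTriple:
        """Classify one spectrogram, returning the full softmax triple."""
        values = image.values if isinstance(image, Spectrogram) else np.asarray(image)
        p = self.predict_proba(values[None, ...])[0]
        return SoftmaxTriple(probs=p, class_labels=self.class_labels)

    # -- persistence ----------------------------------------------------------

    def save(self, path) -> None:
        arrays = {}
        for li, layer in enumerate(self._layers):
            for pi, p in enumerate(layer.params):
                arrays[f"layer{li}_param{pi}"] = p
        np.savez(
            path,
            input_width=self.input_width,
            seed=self.seed,
            class_labels=np.asarray(self.class_labels),
            **arrays,
        )

    @classmethod
    def load(cls, path) -> "SsvepCnn":
        with np.load(path) as data:
            model = cls(
                input_width=int(data["input_width"]),
                seed=int(data["seed"]),
                class_labels=tuple(float(f) for f in data["class_labels"]),
            )
            for li, layer in enumerate(model._layers):
                for pi, p in enumerate(layer.params):
                    p[...] = data[f"layer{li}_param{pi}"]
        model._fitted = True
        return model


def build_model(
    spec: ArchitectureSpec | None = None, input_width: int = 5, seed: int = 0
) -> SsvepCnn:
    """Construct an untrained classifier for the given spectrogram width."""
    return SsvepCnn(spec=spec, input_width=input_width, seed=seed)
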