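"""Convolutional multi-label classifier for 46-dimensional propensity features.

The network treats a feature vector as a 1-channel, length-46 signal and
applies four convolution blocks (conv -> ReLU -> max-pool) followed by a
single fully connected layer with sigmoid outputs, one per modification
type.  Training minimizes the mean binary cross-entropy over samples and
labels with the Adam optimizer; prediction thresholds each probability at
0.5 (boundary inclusive).

Implemented directly on numpy with explicit backpropagation; all randomness
(weight init, batch order) flows from a single seed, so training is
bit-reproducible on a fixed platform.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
import numpy as np

from .sampling import SampleSet

N_INPUT = 46
N_LABELS = 4
EPS = 1e-7


@dataclass
class ClassifierConfig:
    """Hyperparameters; layer counts are fixed (4 conv blocks + 1 dense)."""

    channels: tuple[int, int, int, int] = (16, 32, 64, 128)
    kernel: int = 3
    padding: int = 1
    pool: int = 2
    learning_rate: float = 1e-3
    epochs: int = 100
    batch_size: int = 64
    seed: int = 0
    threshold: float = 0.5

    def __post_init__(self) -> None:
        self.channels = tuple(self.channels)
        if len(self.channels) != 4:
            raise ValueError("exactly 4 convolution blocks are required")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")


# ---------------------------------------------------------------------------
# layer primitives
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kernel: int, padding: int) -> np.ndarray:
    """(B, C, L) -> (B, C, kernel, L_out) sliding windows."""
    if padding:
        x = np.pad(x, ((0, 0), (0, 0), (padding, padding)))
    l_out = x.shape[2] - kernel + 1
    return np.stack([x[:, :, i:i + l_out] for i in range(kernel)], axis=2)


def _conv_forward(x, w, b, padding):
    cols = _im2col(x, w.shape[2], padding)
    y = np.einsum("oci,bcil->bol", w, cols, optimize=True) + b[None, :, None]
    return y, cols


def _conv_backward(dy, cols, w, x_len, padding):
    dw = np.einsum("bol,bcil->oci", dy, cols, optimize=True)
    db = dy.sum(axis=(0, 2))
    dcols = np.einsum("oci,bol->bcil", w, dy, optimize=True)
    b_, c, k, l_out = dcols.shape
    dxp = np.zeros((b_, c, x_len + 2 * padding))
    for i in range(k):
        dxp[:, :, i:i + l_out] += dcols[:, :, i, :]
    dx = dxp[:, :, padding:padding + x_len] if padding else dxp
    return dx, dw, db


def _maxpool_forward(x, width):
    l_out = x.shape[2] // width  # trailing remainder dropped
    xr = x[:, :, :l_out * width].reshape(*x.shape[:2], l_out, width)
    idx = xr.argmax(axis=3)
    y = np.take_along_axis(xr, idx[..., None], axis=3)[..., 0]
    return y, idx


def _maxpool_backward(dy, idx, width, x_len):
    b, c, l_out = dy.shape
    dxr = np.zeros((b, c, l_out, width))
    np.put_along_axis(dxr, idx[..., None], dy[..., None], axis=3)
    dx = np.zeros((b, c, x_len))
    dx[:, :, :l_out * width] = dxr.reshape(b, c, l_out * width)
    return dx


def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_loss(predicted: np.ndarray, target: np.ndarray) -> float:
    """Mean binary cross-entropy over samples and labels.

    Probabilities at exactly 0 or 1 are clamped to [1e-7, 1 - 1e-7].
    """
    p = np.clip(np.asarray(predicted, dtype=float), EPS, 1.0 - EPS)
    y = np.asarray(target, dtype=float)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {y.shape}")
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def predict_labels(probabilities: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binary flags: 1 iff probability >= threshold (boundary inclusive)."""
    return (np.asarray(probabilities) >= threshold).astype(int)


# ---------------------------------------------------------------------------
# the classifier
# ---------------------------------------------------------------------------

class TrainedClassifier:
    """Weight container with forward pass; built by :func:`train` or loaded."""

    def __init__(self, config: ClassifierConfig, params: dict[str, np.ndarray]):
        self.config = config
        self.params = params
        self.training_log: list[float] = []
        self.initial_loss: float | None = None

    # -- construction ------------------------------------------------------
    @classmethod
    def initialize(cls, config: ClassifierConfig) -> "TrainedClassifier":
        """He-normal conv weights; the output layer starts at zero, so an
        untrained network outputs exactly 0.5 for every label."""
        rng = np.random.default_rng(config.seed)
        params: dict[str, np.ndarray] = {}
        c_in, length = 1, N_INPUT
        for i, c_out in enumerate(config.channels):
            fan_in = c_in * config.kernel
            params[f"w{i}"] = rng.normal(
                0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, config.kernel)
            )
            params[f"b{i}"] = np.zeros(c_out)
            length = (length + 2 * config.padding - config.kernel + 1) // config.pool
            c_in = c_out
        if length < 1:
            raise ValueError("input too short for 4 pooling stages")
        params["w_fc"] = np.zeros((N_LABELS, c_in * length))
        params["b_fc"] = np.zeros(N_LABELS)
        return cls(config, params)

    # -- forward / backward ------------------------------------------------
    def _forward_full(self, x: np.ndarray):
        """Forward pass keeping intermediates for backprop."""
        cfg = self.config
        cache = []
        h = x
        for i in range(4):
            z, cols = _conv_forward(h, self.params[f"w{i}"], self.params[f"b{i}"], cfg.padding)
            a = np.maximum(z, 0.0)
            p, idx = _maxpool_forward(a, cfg.pool)
            cache.append((h.shape[2], cols, z, a.shape[2], idx))
            h = p
        flat = h.reshape(h.shape[0], -1)
        logits = flat @ self.params["w_fc"].T + self.params["b_fc"]
        probs = _sigmoid(logits)
        return probs, (cache, h.shape, flat)

    def forward(self, features: np.ndarray) -> np.ndarray:
        """Probabilities in (0,1)^4 for one feature vector or a batch."""
        x = np.asarray(features, dtype=float)
        single = x.ndim == 1
        if single:
            x = x[None, :]
        if x.shape[1] != N_INPUT:
            raise ValueError(f"expected {N_INPUT} features, got {x.shape[1]}")
        probs, _ = self._forward_full(x[:, None, :])
        return probs[0] if single else probs

    def _backward(self, dlogits: np.ndarray, aux) -> dict[str, np.ndarray]:
        cfg = self.config
        cache, h_shape, flat = aux
        grads = {
            "w_fc": dlogits.T @ flat,
            "b_fc": dlogits.sum(axis=0),
        }
        dh = (dlogits @ self.params["w_fc"]).reshape(h_shape)
        for i in range(3, -1, -1):
            x_len, cols, z, a_len, idx = cache[i]
            da = _maxpool_backward(dh, idx, cfg.pool, a_len)
            dz = da * (z > 0)
            dh, grads[f"w{i}"], grads[f"b{i}"] = _conv_backward(
                dz, cols, self.params[f"w{i}"], x_len, cfg.padding
            )
        return grads

    def predict(self, features: np.ndarray) -> np.ndarray:
        return predict_labels(self.forward(features), self.config.threshold)

    # -- persistence -------------------------------------------------------
    def save(self, path, encoder_fingerprint: str = "") -> None:
        meta = {
            "config": asdict(self.config),
            "encoder_fingerprint": encoder_fingerprint,
            "training_log": self.training_log,
            "initial_loss": self.initial_loss,
        }
        np.savez_compressed(path, __meta__=np.array(json.dumps(meta)), **self.params)

    @classmethod
    def load(cls, path) -> tuple["TrainedClassifier", str]:
        with np.load(path) as z:
            meta = json.loads(str(z["__meta__"]))
            params = {k: z[k] for k in z.files if k != "__meta__"}
        model = cls(ClassifierConfig(**meta["config"]), params)
        model.training_log = meta["training_log"]
        model.initial_loss = meta["initial_loss"]
        return model, meta["encoder_fingerprint"]


def train(data: SampleSet, config: ClassifierConfig) -> TrainedClassifier:
    """Mini-batch gradient descent (Adam) on the binary cross-entropy.

    Records the mean per-batch loss of every epoch in ``training_log`` and
    the full-dataset loss before any update in ``initial_loss``.  Aborts on
    a non-finite loss.
    """
    if len(data) == 0:
        raise ValueError("training set is empty")
    model = TrainedClassifier.initialize(config)
    x = data.features[:, None, :].astype(float)
    y = data.labels.astype(float)
    n = len(x)
    rng = np.random.default_rng(config.seed + 1)

    probs, _ = model._forward_full(x)
    model.initial_loss = bce_loss(probs, y)

    m = {k: np.zeros_like(v) for k, v in model.params.items()}
    v = {k: np.zeros_like(p) for k, p in model.params.items()}
    beta1, beta2, eps_adam, t = 0.9, 0.999, 1e-8, 0

    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, yb = x[idx], y[idx]
            probs, aux = model._forward_full(xb)
            loss = bce_loss(probs, yb)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch starting {start}"
                )
            losses.append(loss)
            # combined sigmoid + BCE gradient w.r.t. logits
            dlogits = (probs - yb) / (len(xb) * N_LABELS)
            grads = model._backward(dlogits, aux)
            t += 1
            for k in model.params:
                g = grads[k]
                m[k] = beta1 * m[k] + (1 - beta1) * g
                v[k] = beta2 * v[k] + (1 - beta2) * g * g
                mhat = m[k] / (1 - beta1 ** t)
                vhat = v[k] / (1 - beta2 ** t)
                model.params[k] -= config.learning_rate * mhat / (np.sqrt(vhat) + eps_adam)
        model.training_log.append(float(np.mean(losses)))
    return model
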