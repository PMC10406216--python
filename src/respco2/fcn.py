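"""1D fully convolutional encoder-decoder networks for signal translation.

Four depths are provided. FCN-1L is a single length-7 convolution with
replicate padding (8 parameters). The deeper variants halve the temporal
resolution at each encoder level with stride-2 convolutions and restore
it with stride-2 transposed convolutions; every layer except the last is
followed by instance normalization and a ReLU. The input is squashed by
tanh before the first layer so the (z-scored but unbounded) respiration
amplitude is confined to (-1, 1). Filter counts follow the 1 -> 4 -> 8
ladder.

Layers, backpropagation and the Adam optimizer are implemented directly
in numpy: the networks are tiny (8 to ~1000 parameters) and a
single-threaded numpy implementation keeps training exactly reproducible.

Two training losses are provided: plain MSE, and an amplitude-weighted
MSE whose per-sample weight is 1/max(|y|, eps)^2 (the default), with a
peak-emphasis alternative (weight |y|) behind the ``mode`` switch — the
two readings differ in which part of the waveform they favour, and both
are exposed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DEPTHS = ("1L", "2L", "4L", "6L")
WEIGHT_EPS = 1e-2  # guard on |y| at zero crossings of the normalized CO2


@dataclass
class FCNSpec:
    """Architecture and training hyperparameters."""

    depth: str = "4L"
    kernel_len: int = 7
    loss: str = "mse"            # "mse" | "weighted_mse"
    weight_mode: str = "inverse"  # "inverse" (as printed) | "amplitude" (peak emphasis)
    weight_eps: float = WEIGHT_EPS
    lr: float = 0.03
    epochs: int = 15

    def __post_init__(self) -> None:
        if self.depth not in DEPTHS:
            raise ValueError(f"depth must be one of {DEPTHS}, got {self.depth!r}")
        if self.kernel_len % 2 != 1:
            raise ValueError("kernel_len must be odd (symmetric padding)")
        if self.loss not in ("mse", "weighted_mse"):
            raise ValueError(f"unknown loss {self.loss!r}")

    @property
    def encoder_depth(self) -> int:
        return {"1L": 0, "2L": 1, "4L": 2, "6L": 3}[self.depth]


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class _Layer:
    def parameters(self):
        return []

    def zero_grad(self) -> None:
        for _, g in self.parameters():
            g[...] = 0.0


class Conv1d(_Layer):
    """Strided 1-D convolution; zero or replicate padding of (K-1)/2."""

    def __init__(self, c_in, c_out, k, stride=1, pad_mode="zeros", rng=None):
        self.c_in, self.c_out, self.k, self.stride = c_in, c_out, k, stride
        self.pad = (k - 1) // 2
        self.pad_mode = pad_mode
        s = 1.0 / np.sqrt(c_in * k)
        rng = rng or np.random.default_rng()
        self.W = rng.uniform(-s, s, size=(c_out, c_in, k))
        self.b = rng.uniform(-s, s, size=c_out)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def parameters(self):
        return [(self.W, self.gW), (self.b, self.gb)]

    def _pad(self, x):
        mode = "edge" if self.pad_mode == "replicate" else "constant"
        return np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad)), mode=mode)

    def forward(self, x):
        xp = self._pad(x)
        win = sliding_window_view(xp, self.k, axis=2)[:, :, :: self.stride, :]
        self._win, self._L_in = win, x.shape[2]
        return np.einsum("ocj,bclj->bol", self.W, win) + self.b[None, :, None]

    def backward(self, dy):
        self.gW += np.einsum("bol,bclj->ocj", dy, self._win)
        self.gb += dy.sum(axis=(0, 2))
        B, _, L_out = dy.shape
        L_p = self._L_in + 2 * self.pad
        dxp = np.zeros((B, self.c_in, L_p))
        for j in range(self.k):
            dxp[:, :, j : j + self.stride * L_out : self.stride] += np.einsum(
                "bol,oc->bcl", dy, self.W[:, :, j])
        P, L = self.pad, self._L_in
        dx = dxp[:, :, P : P + L].copy()
        if self.pad_mode == "replicate" and P > 0:
            dx[:, :, 0] += dxp[:, :, :P].sum(axis=2)
            dx[:, :, -1] += dxp[:, :, P + L :].sum(axis=2)
        return dx

    def n_params(self):
        return self.W.size + self.b.size


class ConvTranspose1d(_Layer):
    """Stride-2 transposed convolution inverting the paired Conv1d shape."""

    def __init__(self, c_in, c_out, k, stride=2, output_padding=1, rng=None):
        self.c_in, self.c_out, self.k, self.stride = c_in, c_out, k, stride
        self.pad = (k - 1) // 2
        self.out_pad = output_padding
        s = 1.0 / np.sqrt(c_in * k)
        rng = rng or np.random.default_rng()
        self.W = rng.uniform(-s, s, size=(c_in, c_out, k))
        self.b = rng.uniform(-s, s, size=c_out)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def parameters(self):
        return [(self.W, self.gW), (self.b, self.gb)]

    def forward(self, x):
        B, _, L = x.shape
        L_full = (L - 1) * self.stride + self.k
        L_out = L_full - 2 * self.pad + self.out_pad
        y_full = np.zeros((B, self.c_out, L_full))
        for j in range(self.k):
            y_full[:, :, j : j + self.stride * L : self.stride] += np.einsum(
                "bcl,co->bol", x, self.W[:, :, j])
        self._x = x
        return y_full[:, :, self.pad : self.pad + L_out] + self.b[None, :, None]

    def backward(self, dy):
        x = self._x
        B, _, L = x.shape
        L_full = (L - 1) * self.stride + self.k
        dy_full = np.zeros((B, self.c_out, L_full))
        dy_full[:, :, self.pad : self.pad + dy.shape[2]] = dy
        dx = np.zeros_like(x)
        for j in range(self.k):
            sl = dy_full[:, :, j : j + self.stride * L : self.stride]
            dx += np.einsum("bol,co->bcl", sl, self.W[:, :, j])
            self.gW[:, :, j] += np.einsum("bcl,bol->co", x, sl)
        self.gb += dy.sum(axis=(0, 2))
        return dx

    def n_params(self):
        return self.W.size + self.b.size


class InstanceNorm1d(_Layer):
    """Per-channel, per-sample standardization over time, with affine."""

    def __init__(self, c, eps=1e-5):
        self.eps = eps
        self.gamma = np.ones(c)
        self.beta = np.zeros(c)
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)

    def parameters(self):
        return [(self.gamma, self.ggamma), (self.beta, self.gbeta)]

    def forward(self, x):
        mu = x.mean(axis=2, keepdims=True)
        var = x.var(axis=2, keepdims=True)
        self._istd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._istd
        return self.gamma[None, :, None] * self._xhat + self.beta[None, :, None]

    def backward(self, dy):
        xhat, istd = self._xhat, self._istd
        self.ggamma += (dy * xhat).sum(axis=(0, 2))
        self.gbeta += dy.sum(axis=(0, 2))
        dxhat = dy * self.gamma[None, :, None]
        L = xhat.shape[2]
        return (istd / L) * (
            L * dxhat
            - dxhat.sum(axis=2, keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=2, keepdims=True)
        )

    def n_params(self):
        return self.gamma.size + self.beta.size


class ReLU(_Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask

    def n_params(self):
        return 0


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

@dataclass
class FCNModel:
    """An FCN with its weights, seed and training log."""

    spec: FCNSpec
    layers: list
    seed: int
    training_log: list = field(default_factory=list)

    @property
    def min_input_len(self) -> int:
        return self.spec.kernel_len * 2 ** self.spec.encoder_depth

    def n_params(self) -> int:
        return sum(layer.n_params() for layer in self.layers)

    def parameters(self):
        out = []
        for layer in self.layers:
            out.extend(layer.parameters())
        return out

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()

    def _run(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def _run_backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def forward_batch(self, x: np.ndarray) -> np.ndarray:
        """Forward a (B, 1, L) batch; input is tanh-squashed, right-padded
        by replication to a stride-compatible length, and the output is
        trimmed back to L."""
        if x.ndim != 3:
            raise ValueError("expected a (B, C, L) batch")
        L = x.shape[2]
        if L < self.min_input_len:
            raise ValueError(
                f"input length {L} is below the minimum {self.min_input_len} "
                f"for depth {self.spec.depth}")
        x = np.tanh(x)
        block = 2 ** self.spec.encoder_depth
        pad = (-L) % block
        if pad:
            x = np.concatenate([x, np.repeat(x[:, :, -1:], pad, axis=2)], axis=2)
        self._pad_tail = pad
        y = self._run(x)
        return y[:, :, :L]

    def backward_batch(self, dy: np.ndarray) -> None:
        if self._pad_tail:
            dy = np.concatenate(
                [dy, np.zeros(dy.shape[:2] + (self._pad_tail,))], axis=2)
        self._run_backward(dy)


def forward(model: FCNModel, values: np.ndarray) -> np.ndarray:
    """Predict a CO2 waveform from a 1-D normalized respiration array."""
    values = np.asarray(values, dtype=float)
    out = model.forward_batch(values[None, None, :])
    return out[0, 0]


def build_model(spec: FCNSpec, seed: int = 0) -> FCNModel:
    """Instantiate an untrained FCN with seeded initial weights."""
    rng = np.random.default_rng(seed)
    k = spec.kernel_len
    layers: list = []
    if spec.depth == "1L":
        layers = [Conv1d(1, 1, k, stride=1, pad_mode="replicate", rng=rng)]
    elif spec.depth == "2L":
        layers = [
            Conv1d(1, 4, k, stride=2, rng=rng), InstanceNorm1d(4), ReLU(),
            ConvTranspose1d(4, 1, k, rng=rng),
        ]
    elif spec.depth == "4L":
        layers = [
            Conv1d(1, 4, k, stride=2, rng=rng), InstanceNorm1d(4), ReLU(),
            Conv1d(4, 8, k, stride=2, rng=rng), InstanceNorm1d(8), ReLU(),
            ConvTranspose1d(8, 4, k, rng=rng), InstanceNorm1d(4), ReLU(),
            ConvTranspose1d(4, 1, k, rng=rng),
        ]
    elif spec.depth == "6L":
        layers = [
            Conv1d(1, 4, k, stride=2, rng=rng), InstanceNorm1d(4), ReLU(),
            Conv1d(4, 8, k, stride=2, rng=rng), InstanceNorm1d(8), ReLU(),
            Conv1d(8, 8, k, stride=2, rng=rng), InstanceNorm1d(8), ReLU(),
            ConvTranspose1d(8, 8, k, rng=rng), InstanceNorm1d(8), ReLU(),
            ConvTranspose1d(8, 4, k, rng=rng), InstanceNorm1d(4), ReLU(),
            ConvTranspose1d(4, 1, k, rng=rng),
        ]
    return FCNModel(spec=spec, layers=layers, seed=seed)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def _check_lengths(pred, truth):
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {truth.shape}")
    return pred, truth


def loss_mse(pred, truth) -> float:
    """Mean squared error (1/L) sum (y - yhat)^2."""
    pred, truth = _check_lengths(pred, truth)
    return float(np.mean((truth - pred) ** 2))


def loss_weighted_mse(pred, truth, eps: float = WEIGHT_EPS,
                      mode: str = "inverse") -> float:
    """Amplitude-weighted MSE.

    ``inverse`` (default): (1/L) sum [(y - yhat)/max(|y|, eps)]^2.
    ``amplitude``: (1/L) sum |y| (y - yhat)^2, emphasizing the peaks.
    """
    pred, truth = _check_lengths(pred, truth)
    return float(np.mean(_loss_weights(truth, eps, mode) * (truth - pred) ** 2))


def _loss_weights(truth, eps, mode):
    if mode == "inverse":
        return 1.0 / np.maximum(np.abs(truth), eps) ** 2
    if mode == "amplitude":
        return np.abs(truth)
    raise ValueError(f"unknown weight mode {mode!r}")


def loss_and_grad(pred: np.ndarray, truth: np.ndarray, spec: FCNSpec):
    """Training loss and its gradient with respect to the prediction."""
    pred, truth = _check_lengths(pred, truth)
    if spec.loss == "mse":
        w = 1.0
        value = loss_mse(pred, truth)
    else:
        w = _loss_weights(truth, spec.weight_eps, spec.weight_mode)
        value = loss_weighted_mse(pred, truth, spec.weight_eps, spec.weight_mode)
    grad = 2.0 * w * (pred - truth) / pred.size
    return value, grad


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Standard Adam on a list of (weight, grad) array pairs."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(w) for w, _ in params]
        self.v = [np.zeros_like(w) for w, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, (w, g) in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            w -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: FCNModel, path) -> Path:
    """Serialize spec, seed, weights and training log to JSON."""
    path = Path(path)
    weights = [[w.tolist() for w, _ in layer.parameters()] for layer in model.layers]
    payload = {
        "spec": asdict(model.spec),
        "seed": model.seed,
        "training_log": model.training_log,
        "weights": weights,
    }
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(payload, fh)
        fh.write("\n")
    return path


def load_checkpoint(path) -> FCNModel:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    spec = FCNSpec(**payload["spec"])
    model = build_model(spec, seed=payload["seed"])
    model.training_log = payload["training_log"]
    for layer, stored in zip(model.layers, payload["weights"]):
        for (w, _), vals in zip(layer.parameters(), stored):
            w[...] = np.asarray(vals, dtype=float)
    return model
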