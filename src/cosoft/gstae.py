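"""Gated stacked target-related autoencoder (GSTAE) for quality prediction.

A stack of autoencoder layers with strictly decreasing widths is pretrained
layer by layer.  Unlike a plain stacked autoencoder, each layer's decoder
reconstructs the concatenation [x, y] -- the layer input *and* the quality
target -- so the compressed features stay quality-related from the start.
The two reconstruction terms are mixed by a trade-off coefficient lambda:

    L_pre = (1 - lambda) * MSE(x, x_hat) + lambda * MSE(y, y_hat)

After pretraining, the per-layer decoder heads are discarded.  Prediction
uses a gate unit per layer: with hidden state h_i of layer i,

    y_hat = sum_i sigmoid(wg_i . h_i + bg_i) * tanh(wo_i . h_i + bo_i)

so every layer contributes a bounded, gated amount to the output.  Gates and
encoders are then fine-tuned jointly against the measured labels with a
squared-error loss.  Everything is plain NumPy with hand-derived gradients
(full-batch gradient descent by default), which keeps the model dependency-
free and makes the gradients directly checkable against finite differences.

Encoders use the logistic sigmoid; decoders are linear, since inputs are
z-scored and unbounded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .batch_data import SampleSet

__all__ = [
    "GSTAEModel",
    "TrainingReport",
    "pretrain_layer",
    "gated_predict",
    "finetune",
    "finetune_loss_and_grads",
    "train_gstae",
]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class TrainingReport:
    """Loss traces and summary of one training run."""

    pretrain_losses: list[np.ndarray] = field(default_factory=list)
    finetune_losses: np.ndarray = field(default_factory=lambda: np.empty(0))
    final_train_rmse: float = float("nan")
    seed: int | None = None
    config: dict = field(default_factory=dict)


@dataclass
class GSTAEModel:
    """Parameters of the stacked encoder and the per-layer gate units.

    ``layer_widths`` includes the input width first and must be strictly
    decreasing afterwards.  ``enc_w[l]`` has shape (widths[l+1], widths[l]).
    Decoder parameters are retained from pretraining for inspection but play
    no role in prediction.
    """

    layer_widths: list[int]
    enc_w: list[np.ndarray]
    enc_b: list[np.ndarray]
    gate_wg: list[np.ndarray]
    gate_bg: list[float]
    out_wo: list[np.ndarray]
    out_bo: list[float]
    dec_w: list[np.ndarray] = field(default_factory=list)
    dec_b: list[np.ndarray] = field(default_factory=list)
    lam: float = 0.5
    lr: float = 0.01
    seed: int | None = None

    @property
    def n_layers(self) -> int:
        return len(self.layer_widths) - 1

    @property
    def input_width(self) -> int:
        return self.layer_widths[0]

    # -- serialization (self-describing JSON: shapes + flat arrays) --------
    def to_json(self) -> str:
        def arr(a):
            return np.asarray(a, dtype=float).tolist()
        payload = {
            "layer_widths": self.layer_widths,
            "enc_w": [arr(w) for w in self.enc_w],
            "enc_b": [arr(b) for b in self.enc_b],
            "gate_wg": [arr(w) for w in self.gate_wg],
            "gate_bg": list(map(float, self.gate_bg)),
            "out_wo": [arr(w) for w in self.out_wo],
            "out_bo": list(map(float, self.out_bo)),
            "lam": self.lam,
            "lr": self.lr,
            "seed": self.seed,
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "GSTAEModel":
        d = json.loads(text)
        return cls(
            layer_widths=[int(w) for w in d["layer_widths"]],
            enc_w=[np.asarray(w, dtype=float) for w in d["enc_w"]],
            enc_b=[np.asarray(b, dtype=float) for b in d["enc_b"]],
            gate_wg=[np.asarray(w, dtype=float) for w in d["gate_wg"]],
            gate_bg=[float(b) for b in d["gate_bg"]],
            out_wo=[np.asarray(w, dtype=float) for w in d["out_wo"]],
            out_bo=[float(b) for b in d["out_bo"]],
            lam=float(d["lam"]),
            lr=float(d["lr"]),
            seed=d["seed"],
        )


def _init_weight(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in = shape[-1] if len(shape) > 1 else shape[0]
    return rng.normal(0.0, 1.0 / np.sqrt(fan_in), size=shape)


class _Adam:
    """Adam updates for a flat dict/list of parameter arrays."""

    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: dict = {}
        self.v: dict = {}

    def step(self, params: dict, grads: dict) -> None:
        """Update every array in ``params`` in place; scalars are updated via
        the returned dict from :meth:`step_scalar`."""
        self.t += 1
        for key, value in params.items():
            g = grads[key]
            if key not in self.m:
                self.m[key] = np.zeros_like(np.asarray(g, dtype=float))
                self.v[key] = np.zeros_like(np.asarray(g, dtype=float))
            self.m[key] = self.beta1 * self.m[key] + (1 - self.beta1) * g
            self.v[key] = self.beta2 * self.v[key] + (1 - self.beta2) * np.square(g)
            m_hat = self.m[key] / (1 - self.beta1 ** self.t)
            v_hat = self.v[key] / (1 - self.beta2 ** self.t)
            update = self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
            if np.isscalar(value) or np.ndim(value) == 0:
                params[key] = value - update
            else:
                value -= update


# ---------------------------------------------------------------------------
# supervised layerwise pretraining
# ---------------------------------------------------------------------------

def pretrain_layer(
    inputs: np.ndarray,
    targets: np.ndarray,
    width: int,
    lam: float,
    epochs: int,
    lr: float,
    rng: np.random.Generator,
    optimizer: str = "adam",
) -> tuple[dict, np.ndarray, np.ndarray]:
    """Train one target-related autoencoder layer.

    Minimizes (1-lam)*MSE(x, x_hat) + lam*MSE(y, y_hat) where the linear
    decoder reconstructs [x, y] jointly from h = sigmoid(W1 x + b1).
    Full-batch updates with Adam by default ("gd" selects plain gradient
    descent).  Returns (parameter dict, hidden activations, loss trace).
    """
    x = np.asarray(inputs, dtype=float)
    y = np.asarray(targets, dtype=float).ravel()
    n, d = x.shape
    if y.shape[0] != n:
        raise ValueError("inputs and targets disagree on sample count")
    if width >= d:
        raise ValueError(f"hidden width {width} must be < input width {d}")
    if not 0 <= lam <= 1:
        raise ValueError("lambda must lie in [0, 1]")

    if optimizer not in ("adam", "gd"):
        raise ValueError("optimizer must be 'adam' or 'gd'")
    w1 = _init_weight(rng, (width, d))
    b1 = np.zeros(width)
    w2 = _init_weight(rng, (d + 1, width))
    b2 = np.zeros(d + 1)
    params = {"w1": w1, "b1": b1, "w2": w2, "b2": b2}
    opt = _Adam(lr) if optimizer == "adam" else None

    losses = np.empty(epochs)
    for epoch in range(epochs):
        h = _sigmoid(x @ w1.T + b1)
        recon = h @ w2.T + b2
        x_hat, y_hat = recon[:, :d], recon[:, d]
        loss = (1 - lam) * np.mean((x_hat - x) ** 2) + lam * np.mean((y_hat - y) ** 2)
        if not np.isfinite(loss):
            raise FloatingPointError(f"non-finite pretraining loss at epoch {epoch}")
        losses[epoch] = loss

        d_recon = np.empty_like(recon)
        d_recon[:, :d] = 2.0 * (1 - lam) / (n * d) * (x_hat - x)
        d_recon[:, d] = 2.0 * lam / n * (y_hat - y)
        g_w2 = d_recon.T @ h
        g_b2 = d_recon.sum(axis=0)
        d_h = d_recon @ w2
        d_z = d_h * h * (1.0 - h)
        g_w1 = d_z.T @ x
        g_b1 = d_z.sum(axis=0)

        grads = {"w1": g_w1, "b1": g_b1, "w2": g_w2, "b2": g_b2}
        if opt is None:
            for key in params:
                params[key] -= lr * grads[key]
        else:
            opt.step(params, grads)

    hidden = _sigmoid(x @ w1.T + b1)
    return params, hidden, losses


# ---------------------------------------------------------------------------
# gated forward pass and fine-tuning
# ---------------------------------------------------------------------------

def _forward(model: GSTAEModel, x: np.ndarray) -> tuple[list[np.ndarray], np.ndarray]:
    """Hidden states of every layer and the gated prediction."""
    hiddens = []
    h = x
    for w, b in zip(model.enc_w, model.enc_b):
        h = _sigmoid(h @ w.T + b)
        hiddens.append(h)
    yhat = np.zeros(x.shape[0])
    for h, wg, bg, wo, bo in zip(
        hiddens, model.gate_wg, model.gate_bg, model.out_wo, model.out_bo
    ):
        yhat += _sigmoid(h @ wg + bg) * np.tanh(h @ wo + bo)
    return hiddens, yhat


def gated_predict(model: GSTAEModel, x: np.ndarray) -> float | np.ndarray:
    """Gated prediction: sum over layers of sigmoid-gate times tanh-output.

    Accepts a single vector (returns float) or a row matrix (returns vector).
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    xm = x[None, :] if single else x
    if xm.shape[1] != model.input_width:
        raise ValueError(
            f"input width {xm.shape[1]} does not match model ({model.input_width})"
        )
    _, yhat = _forward(model, xm)
    return float(yhat[0]) if single else yhat


def finetune_loss_and_grads(
    model: GSTAEModel, inputs: np.ndarray, targets: np.ndarray
) -> tuple[float, dict]:
    """Mean squared fine-tune loss and its analytic gradients.

    Exposed so the analytic gradients can be validated against finite
    differences.  Gradient keys: enc_w, enc_b, gate_wg, gate_bg, out_wo,
    out_bo (lists indexed by layer).
    """
    x = np.asarray(inputs, dtype=float)
    y = np.asarray(targets, dtype=float).ravel()
    n = x.shape[0]
    hiddens, yhat = _forward(model, x)
    loss = float(np.mean((yhat - y) ** 2))
    d_yhat = 2.0 * (yhat - y) / n

    n_layers = model.n_layers
    grads = {
        "enc_w": [None] * n_layers, "enc_b": [None] * n_layers,
        "gate_wg": [None] * n_layers, "gate_bg": [0.0] * n_layers,
        "out_wo": [None] * n_layers, "out_bo": [0.0] * n_layers,
    }
    # gate-unit gradients and their contribution to each hidden state
    d_hidden = [np.zeros_like(h) for h in hiddens]
    for l in range(n_layers):
        h = hiddens[l]
        g = _sigmoid(h @ model.gate_wg[l] + model.gate_bg[l])
        t = np.tanh(h @ model.out_wo[l] + model.out_bo[l])
        d_zg = d_yhat * t * g * (1.0 - g)
        d_zo = d_yhat * g * (1.0 - t ** 2)
        grads["gate_wg"][l] = h.T @ d_zg
        grads["gate_bg"][l] = float(d_zg.sum())
        grads["out_wo"][l] = h.T @ d_zo
        grads["out_bo"][l] = float(d_zo.sum())
        d_hidden[l] += np.outer(d_zg, model.gate_wg[l]) + np.outer(d_zo, model.out_wo[l])

    # backprop through the encoder stack
    carry = np.zeros_like(hiddens[-1])
    for l in range(n_layers - 1, -1, -1):
        h = hiddens[l]
        below = x if l == 0 else hiddens[l - 1]
        d_h = d_hidden[l] + carry
        d_z = d_h * h * (1.0 - h)
        grads["enc_w"][l] = d_z.T @ below
        grads["enc_b"][l] = d_z.sum(axis=0)
        carry = d_z @ model.enc_w[l]
    return loss, grads


def finetune(
    model: GSTAEModel,
    inputs: np.ndarray,
    targets: np.ndarray,
    epochs: int,
    lr: float,
    optimizer: str = "adam",
) -> tuple[GSTAEModel, TrainingReport]:
    """Jointly fine-tune encoders and gates on the squared-error loss.

    Full-batch updates, Adam by default ("gd" selects plain gradient
    descent); the model is updated in place and also returned.
    Deterministic given the (already initialized) parameters.
    """
    if optimizer not in ("adam", "gd"):
        raise ValueError("optimizer must be 'adam' or 'gd'")
    y = np.asarray(targets, dtype=float).ravel()
    opt = _Adam(lr) if optimizer == "adam" else None
    losses = np.empty(epochs)
    for epoch in range(epochs):
        loss, grads = finetune_loss_and_grads(model, inputs, y)
        if not np.isfinite(loss):
            raise FloatingPointError(f"non-finite fine-tune loss at epoch {epoch}")
        losses[epoch] = loss
        if opt is None:
            for l in range(model.n_layers):
                model.enc_w[l] -= lr * grads["enc_w"][l]
                model.enc_b[l] -= lr * grads["enc_b"][l]
                model.gate_wg[l] -= lr * grads["gate_wg"][l]
                model.gate_bg[l] -= lr * grads["gate_bg"][l]
                model.out_wo[l] -= lr * grads["out_wo"][l]
                model.out_bo[l] -= lr * grads["out_bo"][l]
        else:
            params: dict = {}
            flat_grads: dict = {}
            for l in range(model.n_layers):
                for name in ("enc_w", "enc_b", "gate_wg", "out_wo"):
                    params[(name, l)] = getattr(model, name)[l]
                    flat_grads[(name, l)] = grads[name][l]
                for name in ("gate_bg", "out_bo"):
                    params[(name, l)] = getattr(model, name)[l]
                    flat_grads[(name, l)] = grads[name][l]
            opt.step(params, flat_grads)
            for l in range(model.n_layers):
                model.gate_bg[l] = float(params[("gate_bg", l)])
                model.out_bo[l] = float(params[("out_bo", l)])

    pred = gated_predict(model, np.asarray(inputs, dtype=float))
    rmse = float(np.sqrt(np.mean((pred - y) ** 2))) if epochs > 0 else float("nan")
    report = TrainingReport(finetune_losses=losses, final_train_rmse=rmse,
                            seed=model.seed)
    return model, report


# ---------------------------------------------------------------------------
# full training: supervised pretraining then fine-tuning
# ---------------------------------------------------------------------------

def train_gstae(
    rows: SampleSet | tuple[np.ndarray, np.ndarray],
    widths: list[int],
    lam: float = 0.5,
    lr: float = 0.01,
    epochs: tuple[int, int] = (200, 500),
    seed: int = 0,
    optimizer: str = "adam",
) -> tuple[GSTAEModel, TrainingReport]:
    """Pretrain each layer in sequence on (hidden, y), then fine-tune.

    ``rows`` is a fully labeled SampleSet (measured or pseudo labels) or a
    (features, labels) pair; ``widths[0]`` must equal the feature dimension
    and the remaining widths must be strictly decreasing.
    """
    if isinstance(rows, SampleSet):
        x = rows.features
        y = rows.labels
        if np.isnan(y).any():
            raise ValueError("training rows must all be labeled")
    else:
        x, y = rows
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float).ravel()

    widths = [int(w) for w in widths]
    if len(widths) < 2:
        raise ValueError("need an input width and at least one hidden width")
    if widths[0] != x.shape[1]:
        raise ValueError(
            f"widths[0]={widths[0]} must equal the input dimension {x.shape[1]}"
        )
    if any(widths[i + 1] >= widths[i] for i in range(len(widths) - 1)):
        raise ValueError("layer widths must be strictly decreasing")

    rng = np.random.default_rng(seed)
    pre_epochs, fine_epochs = epochs

    enc_w, enc_b, dec_w, dec_b = [], [], [], []
    pretrain_losses = []
    hidden = x
    for width in widths[1:]:
        params, hidden, losses = pretrain_layer(
            hidden, y, width, lam, pre_epochs, lr, rng, optimizer=optimizer
        )
        enc_w.append(params["w1"])
        enc_b.append(params["b1"])
        dec_w.append(params["w2"])
        dec_b.append(params["b2"])
        pretrain_losses.append(losses)

    n_layers = len(widths) - 1
    model = GSTAEModel(
        layer_widths=widths,
        enc_w=enc_w, enc_b=enc_b,
        gate_wg=[_init_weight(rng, (widths[l + 1],)) for l in range(n_layers)],
        gate_bg=[0.0] * n_layers,
        out_wo=[_init_weight(rng, (widths[l + 1],)) for l in range(n_layers)],
        out_bo=[0.0] * n_layers,
        dec_w=dec_w, dec_b=dec_b,
        lam=lam, lr=lr, seed=seed,
    )
    model, report = finetune(model, x, y, fine_epochs, lr, optimizer=optimizer)
    report.pretrain_losses = pretrain_losses
    report.seed = seed
    report.config = {
        "widths": widths, "lambda": lam, "lr": lr,
        "pretrain_epochs": pre_epochs, "finetune_epochs": fine_epochs,
        "optimizer": optimizer,
    }
    return model, report
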