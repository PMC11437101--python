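"""Residual deep belief network (RDBN) for tabular diagnosis data.

An RDBN stacks restricted Boltzmann machines (RBMs), pre-trained greedily
with contrastive divergence, adds residual skip connections between
equal-width hidden layers, and is fine-tuned end to end with a softmax
head under cross-entropy.

Two residual placements are supported. With skip span s and activation
sigma:

* ``post_activation`` (default, the canonical y = F(x) + x form)::

      h^l = sigma(W^l h^{l-1} + b^l) + h^{l-s}

* ``pre_activation`` (the skip enters before the nonlinearity)::

      h^l = sigma(W^l h^{l-1} + b^l + h^{l-s})

A skip is only taken when the source layer exists and has the same width
as the target; in particular the input layer rarely matches the hidden
width, so the first hidden layer is usually skip-free.

Visible units are treated as probabilities in [0, 1]; continuous features
must be min-max scaled before training (see synthetic_data.scale_features).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

__all__ = [
    "RBMLayer",
    "RDBNModel",
    "TrainConfig",
    "TrainingDivergedError",
    "sigmoid",
    "rbm_energy",
    "rbm_joint_probability",
    "sample_hidden",
    "sample_visible",
    "cd_update",
    "pretrain_greedy",
    "build_model",
    "forward_residual",
    "fine_tune",
    "predict_proba",
    "predict",
    "get_flat_params",
    "set_flat_params",
    "n_params",
    "loss_and_grads",
    "cross_entropy_loss",
]


class TrainingDivergedError(RuntimeError):
    """Training loss became non-finite (learning rate too large or bad data)."""


def sigmoid(x: np.ndarray) -> np.ndarray:
    # piecewise-stable logistic
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class RBMLayer:
    """One RBM: weights W (visible x hidden), visible bias a, hidden bias b."""

    W: np.ndarray
    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.W.ndim != 2 or self.a.shape != (self.W.shape[0],) \
                or self.b.shape != (self.W.shape[1],):
            raise ValueError(
                f"inconsistent RBM shapes: W{self.W.shape}, a{self.a.shape}, "
                f"b{self.b.shape}"
            )
        if not (np.isfinite(self.W).all() and np.isfinite(self.a).all()
                and np.isfinite(self.b).all()):
            raise ValueError("RBM parameters must be finite")

    @property
    def n_visible(self) -> int:
        return self.W.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.W.shape[1]

    def copy(self) -> "RBMLayer":
        return RBMLayer(self.W.copy(), self.a.copy(), self.b.copy())


@dataclass
class TrainConfig:
    """Training hyperparameters. Defaults mirror the full-scale profile."""

    learning_rate: float = 0.001
    batch_size: int = 64
    local_epochs: int = 5
    cd_steps: int = 1
    hidden_layers: int = 5
    hidden_units: int = 256
    dropout: float = 0.5
    optimizer: Literal["sgd", "adam"] = "adam"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate < 0 or self.batch_size < 1 \
                or self.local_epochs < 0 or self.cd_steps < 1 \
                or self.hidden_layers < 1 or self.hidden_units < 1 \
                or not 0 <= self.dropout < 1:
            raise ValueError("invalid TrainConfig field")
        if self.optimizer not in ("sgd", "adam"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


@dataclass
class RDBNModel:
    """Stacked RBM layers with residual skips and a softmax output head."""

    layers: list[RBMLayer]
    output_W: np.ndarray
    output_b: np.ndarray
    residual_span: int = 1
    residual_mode: Literal["post_activation", "pre_activation"] = "post_activation"
    residual_enabled: bool = True
    activation: Literal["sigmoid", "relu"] = "sigmoid"
    dropout_rate: float = 0.0

    def __post_init__(self) -> None:
        self.output_W = np.asarray(self.output_W, dtype=float)
        self.output_b = np.asarray(self.output_b, dtype=float)
        if self.residual_span < 1:
            raise ValueError("residual_span must be >= 1")
        if self.residual_mode not in ("post_activation", "pre_activation"):
            raise ValueError(f"unknown residual_mode {self.residual_mode!r}")
        if self.layers and self.output_W.shape[0] != self.layers[-1].n_hidden:
            raise ValueError("output head width does not match last hidden layer")

    @property
    def n_features(self) -> int:
        return self.layers[0].n_visible

    @property
    def n_classes(self) -> int:
        return self.output_W.shape[1]

    def copy(self) -> "RDBNModel":
        return replace(
            self,
            layers=[lay.copy() for lay in self.layers],
            output_W=self.output_W.copy(),
            output_b=self.output_b.copy(),
        )


# --------------------------------------------------------------------------
# RBM energy model
# --------------------------------------------------------------------------

def rbm_energy(v: np.ndarray, h: np.ndarray, layer: RBMLayer) -> float:
    """E(v, h) = -sum_i a_i v_i - sum_j b_j h_j - sum_ij v_i W_ij h_j."""
    v = np.asarray(v, dtype=float)
    h = np.asarray(h, dtype=float)
    if v.shape != (layer.n_visible,) or h.shape != (layer.n_hidden,):
        raise ValueError(
            f"dimension mismatch: v{v.shape}, h{h.shape} vs "
            f"RBM {layer.n_visible}x{layer.n_hidden}"
        )
    return float(-(layer.a @ v) - (layer.b @ h) - v @ layer.W @ h)


def rbm_joint_probability(v: np.ndarray, h: np.ndarray, layer: RBMLayer) -> float:
    """Exact P(v, h) = e^{-E(v,h)} / Z by exhaustive enumeration.

    Only feasible for tiny models: requires n_visible + n_hidden <= 16.
    """
    total = layer.n_visible + layer.n_hidden
    if total > 16:
        raise ValueError(
            f"exact enumeration limited to 16 units, model has {total}"
        )
    log_weights = []
    for vv in itertools.product((0.0, 1.0), repeat=layer.n_visible):
        for hh in itertools.product((0.0, 1.0), repeat=layer.n_hidden):
            log_weights.append(-rbm_energy(np.array(vv), np.array(hh), layer))
    log_weights = np.array(log_weights)
    m = log_weights.max()
    log_z = m + np.log(np.exp(log_weights - m).sum())
    return float(np.exp(-rbm_energy(v, h, layer) - log_z))


def sample_hidden(v: np.ndarray, layer: RBMLayer,
                  rng: np.random.Generator) -> np.ndarray:
    """Bernoulli draw of h given v: p(h_j = 1 | v) = sigmoid(b_j + v.W_:j)."""
    v = np.atleast_2d(np.asarray(v, dtype=float))
    p = sigmoid(v @ layer.W + layer.b)
    return (rng.random(p.shape) < p).astype(float).squeeze()


def sample_visible(h: np.ndarray, layer: RBMLayer,
                   rng: np.random.Generator) -> np.ndarray:
    """Bernoulli draw of v given h: p(v_i = 1 | h) = sigmoid(a_i + W_i:.h)."""
    h = np.atleast_2d(np.asarray(h, dtype=float))
    p = sigmoid(h @ layer.W.T + layer.a)
    return (rng.random(p.shape) < p).astype(float).squeeze()


def cd_update(layer: RBMLayer, batch: np.ndarray, lr: float,
              cd_steps: int = 1,
              rng: np.random.Generator | None = None) -> RBMLayer:
    """One contrastive-divergence (CD-k) parameter update on a minibatch.

    Positive phase uses the data; the negative phase reconstructs after
    `cd_steps` Gibbs alternations (mean-field visible reconstructions,
    sampled hidden states driving the chain). Returns a new layer moved by
    lr * (positive statistics - negative statistics), batch-averaged.
    """
    batch = np.atleast_2d(np.asarray(batch, dtype=float))
    if batch.size == 0:
        raise ValueError("empty batch")
    if batch.shape[1] != layer.n_visible:
        raise ValueError("batch width does not match RBM visible units")
    if rng is None:
        rng = np.random.default_rng(0)
    n = batch.shape[0]

    v0 = batch
    ph0 = sigmoid(v0 @ layer.W + layer.b)
    h = (rng.random(ph0.shape) < ph0).astype(float)
    vk = v0
    phk = ph0
    for _ in range(cd_steps):
        vk = sigmoid(h @ layer.W.T + layer.a)
        phk = sigmoid(vk @ layer.W + layer.b)
        h = (rng.random(phk.shape) < phk).astype(float)

    dW = (v0.T @ ph0 - vk.T @ phk) / n
    da = (v0 - vk).mean(axis=0)
    db = (ph0 - phk).mean(axis=0)
    return RBMLayer(layer.W + lr * dW, layer.a + lr * da, layer.b + lr * db)


def pretrain_greedy(data: np.ndarray, cfg: TrainConfig) -> list[RBMLayer]:
    """Greedy layer-wise RBM pre-training.

    The first RBM reconstructs the (min-max scaled) input; each subsequent
    RBM reconstructs the previous layer's hidden activation probabilities.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if not np.isfinite(data).all():
        raise ValueError("pre-training data contains non-finite values")
    rng = np.random.default_rng(cfg.seed)
    layers: list[RBMLayer] = []
    rep = data
    for _ in range(cfg.hidden_layers):
        n_vis = rep.shape[1]
        layer = RBMLayer(
            W=rng.normal(0.0, 0.01, size=(n_vis, cfg.hidden_units)),
            a=np.zeros(n_vis),
            b=np.zeros(cfg.hidden_units),
        )
        for _ in range(cfg.local_epochs):
            perm = rng.permutation(rep.shape[0])
            for start in range(0, rep.shape[0], cfg.batch_size):
                mb = rep[perm[start:start + cfg.batch_size]]
                layer = cd_update(layer, mb, cfg.learning_rate,
                                  cfg.cd_steps, rng)
        layers.append(layer)
        rep = sigmoid(rep @ layer.W + layer.b)  # next layer's input
    return layers


def build_model(n_features: int, n_classes: int, cfg: TrainConfig,
                pretrain_data: np.ndarray | None = None,
                residual_span: int = 1,
                residual_mode: str = "post_activation",
                activation: str = "sigmoid") -> RDBNModel:
    """Construct an RDBN, optionally pre-training its layers.

    Without pre-training data, weights start Gaussian(0, 0.01), biases 0.
    """
    rng = np.random.default_rng(cfg.seed)
    if pretrain_data is not None:
        layers = pretrain_greedy(pretrain_data, cfg)
    else:
        layers = []
        n_vis = n_features
        for _ in range(cfg.hidden_layers):
            layers.append(RBMLayer(
                W=rng.normal(0.0, 0.01, size=(n_vis, cfg.hidden_units)),
                a=np.zeros(n_vis),
                b=np.zeros(cfg.hidden_units),
            ))
            n_vis = cfg.hidden_units
    output_W = rng.normal(0.0, 0.01, size=(cfg.hidden_units, n_classes))
    return RDBNModel(
        layers=layers,
        output_W=output_W,
        output_b=np.zeros(n_classes),
        residual_span=residual_span,
        residual_mode=residual_mode,  # type: ignore[arg-type]
        activation=activation,  # type: ignore[arg-type]
        dropout_rate=cfg.dropout,
    )


# --------------------------------------------------------------------------
# Supervised forward / backward pass through the residual graph
# --------------------------------------------------------------------------

def _act(model: RDBNModel, z: np.ndarray) -> np.ndarray:
    return sigmoid(z) if model.activation == "sigmoid" else np.maximum(z, 0.0)


def _act_grad(model: RDBNModel, z: np.ndarray, a: np.ndarray) -> np.ndarray:
    if model.activation == "sigmoid":
        return a * (1.0 - a)
    return (z > 0).astype(float)


def _skip_source(model: RDBNModel, l: int, widths: list[int]) -> int | None:
    """Index into the activation list h[0..L] feeding layer l's skip, or None."""
    if not model.residual_enabled:
        return None
    src = l - model.residual_span
    if src < 0 or widths[src] != widths[l]:
        return None
    return src


def _forward(model: RDBNModel, X: np.ndarray,
             dropout_rng: np.random.Generator | None = None) -> dict:
    """Forward pass caching everything backprop needs.

    Returns dict with h (activations, h[0]=X), z (pre-activations per hidden
    layer), sigma (the nonlinearity outputs before any post-activation skip),
    masks (inverted-dropout masks or None), logits, probs.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature width {X.shape[1]} does not match model "
            f"{model.n_features}"
        )
    widths = [model.n_features] + [lay.n_hidden for lay in model.layers]
    h = [X]
    zs, sigmas, masks = [], [], []
    for l, lay in enumerate(model.layers, start=1):
        z = h[l - 1] @ lay.W + lay.b
        src = _skip_source(model, l, widths)
        if src is not None and model.residual_mode == "pre_activation":
            z = z + h[src]
        s = _act(model, z)
        out = s.copy()
        if src is not None and model.residual_mode == "post_activation":
            out = out + h[src]
        mask = None
        if dropout_rng is not None and model.dropout_rate > 0:
            keep = 1.0 - model.dropout_rate
            mask = (dropout_rng.random(out.shape) < keep) / keep
            out = out * mask
        zs.append(z)
        sigmas.append(s)
        masks.append(mask)
        h.append(out)
    logits = h[-1] @ model.output_W + model.output_b
    shifted = logits - logits.max(axis=1, keepdims=True)
    expv = np.exp(shifted)
    probs = expv / expv.sum(axis=1, keepdims=True)
    return {"h": h, "z": zs, "sigma": sigmas, "masks": masks,
            "widths": widths, "logits": logits, "probs": probs,
            "log_probs": shifted - np.log(expv.sum(axis=1, keepdims=True))}


def forward_residual(x: np.ndarray, model: RDBNModel) -> list[np.ndarray]:
    """Per-layer activations [h^0 = x, h^1, ..., h^L] of the residual stack."""
    cache = _forward(model, x)
    single = np.asarray(x).ndim == 1
    return [h[0] if single else h for h in cache["h"]]


def predict_proba(model: RDBNModel, X: np.ndarray) -> np.ndarray:
    """Softmax class probabilities; rows sum to 1. Dropout disabled."""
    return _forward(model, X)["probs"]


def predict(model: RDBNModel, X: np.ndarray) -> np.ndarray:
    """Argmax class labels; ties broken toward the lowest class index."""
    return np.argmax(predict_proba(model, X), axis=1)


def cross_entropy_loss(model: RDBNModel, X: np.ndarray, y: np.ndarray) -> float:
    """Mean cross-entropy of the model's predictions against integer labels."""
    y = np.asarray(y, dtype=int)
    lp = _forward(model, X)["log_probs"]
    return float(-lp[np.arange(len(y)), y].mean())


# --- flat parameter vector (federation interface) --------------------------
#
# Flattening order, fixed and relied upon by the FL protocol: for each hidden
# layer in stack order, W raveled row-major then hidden bias b; finally
# output_W raveled row-major then output_b. RBM visible biases take part in
# pre-training only (no supervised gradient) and are excluded.

def n_params(model: RDBNModel) -> int:
    total = sum(lay.W.size + lay.b.size for lay in model.layers)
    return total + model.output_W.size + model.output_b.size


def get_flat_params(model: RDBNModel) -> np.ndarray:
    parts = []
    for lay in model.layers:
        parts.append(lay.W.ravel())
        parts.append(lay.b)
    parts.append(model.output_W.ravel())
    parts.append(model.output_b)
    return np.concatenate(parts)


def set_flat_params(model: RDBNModel, flat: np.ndarray) -> RDBNModel:
    flat = np.asarray(flat, dtype=float)
    if flat.shape != (n_params(model),):
        raise ValueError(
            f"parameter vector length {flat.shape} != {n_params(model)}"
        )
    out = model.copy()
    i = 0
    for lay in out.layers:
        lay.W = flat[i:i + lay.W.size].reshape(lay.W.shape); i += lay.W.size
        lay.b = flat[i:i + lay.b.size].copy(); i += lay.b.size
    out.output_W = flat[i:i + out.output_W.size].reshape(out.output_W.shape)
    i += out.output_W.size
    out.output_b = flat[i:i + out.output_b.size].copy()
    return out


def loss_and_grads(model: RDBNModel, X: np.ndarray, y: np.ndarray,
                   dropout_rng: np.random.Generator | None = None
                   ) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and its gradient w.r.t. the flat parameter vector.

    Backpropagates through the residual graph: skip connections route
    gradient both through the nonlinearity and directly to the source layer.
    Pass `dropout_rng` to apply inverted dropout (training mode).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=int)
    cache = _forward(model, X, dropout_rng=dropout_rng)
    n = X.shape[0]
    probs, h, widths = cache["probs"], cache["h"], cache["widths"]
    loss = float(-cache["log_probs"][np.arange(n), y].mean())

    dlogits = probs.copy()
    dlogits[np.arange(n), y] -= 1.0
    dlogits /= n

    d_out_W = h[-1].T @ dlogits
    d_out_b = dlogits.sum(axis=0)

    # dh[l] accumulates gradient flowing into activation h^l
    dh = [np.zeros_like(hi) for hi in h]
    dh[-1] = dlogits @ model.output_W.T
    grads_W = [np.zeros_like(lay.W) for lay in model.layers]
    grads_b = [np.zeros_like(lay.b) for lay in model.layers]

    for l in range(len(model.layers), 0, -1):
        lay = model.layers[l - 1]
        g = dh[l]
        mask = cache["masks"][l - 1]
        if mask is not None:
            g = g * mask
        src = _skip_source(model, l, widths)
        if src is not None and model.residual_mode == "post_activation":
            dh[src] += g  # identity branch
        dz = g * _act_grad(model, cache["z"][l - 1], cache["sigma"][l - 1])
        if src is not None and model.residual_mode == "pre_activation":
            dh[src] += dz  # skip entered before the nonlinearity
        grads_W[l - 1] = h[l - 1].T @ dz
        grads_b[l - 1] = dz.sum(axis=0)
        dh[l - 1] += dz @ lay.W.T

    parts = []
    for gW, gb in zip(grads_W, grads_b):
        parts.append(gW.ravel())
        parts.append(gb)
    parts.append(d_out_W.ravel())
    parts.append(d_out_b)
    return loss, np.concatenate(parts)


def fine_tune(model: RDBNModel, data: np.ndarray, labels: np.ndarray,
              cfg: TrainConfig, epochs: int | None = None) -> RDBNModel:
    """Supervised fine-tuning by minibatch backpropagation.

    Minimizes cross-entropy with the configured optimizer (Adam default) and
    applies inverted dropout at cfg.dropout during training only. Returns a
    trained copy; the input model is untouched.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    labels = np.asarray(labels, dtype=int)
    epochs = cfg.local_epochs if epochs is None else epochs
    rng = np.random.default_rng(cfg.seed)
    model = replace(model.copy(), dropout_rate=cfg.dropout)
    theta = get_flat_params(model)

    # Adam state
    m_t = np.zeros_like(theta)
    v_t = np.zeros_like(theta)
    step = 0
    beta1, beta2, eps = 0.9, 0.999, 1e-8

    for _ in range(epochs):
        perm = rng.permutation(data.shape[0])
        for start in range(0, data.shape[0], cfg.batch_size):
            idx = perm[start:start + cfg.batch_size]
            work = set_flat_params(model, theta)
            drop_rng = rng if cfg.dropout > 0 else None
            loss, grad = loss_and_grads(work, data[idx], labels[idx],
                                        dropout_rng=drop_rng)
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    "cross-entropy became non-finite; lower the learning "
                    "rate or check the input scaling"
                )
            if cfg.optimizer == "adam":
                step += 1
                m_t = beta1 * m_t + (1 - beta1) * grad
                v_t = beta2 * v_t + (1 - beta2) * grad ** 2
                mhat = m_t / (1 - beta1 ** step)
                vhat = v_t / (1 - beta2 ** step)
                theta = theta - cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)
            else:
                theta = theta - cfg.learning_rate * grad
    out = set_flat_params(model, theta)
    out.dropout_rate = 0.0  # inference mode
    return out
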