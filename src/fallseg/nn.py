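"""Three-layer tanh classifier trained with resilient backpropagation.

The per-sample classifier is a feed-forward network with one hidden layer
(80 tanh units by default) and a 2-unit tanh output layer, one unit per class
(walking, perturbation) with one-hot targets in {-1, +1}. Training minimises
full-batch mean squared error with Rprop — a batch method that adapts a
per-weight step size from the sign history of the gradient and ignores its
magnitude — and early-stops on a held-out validation trial: the returned
weights are those of the epoch with the lowest validation error.

The Rprop variant implemented is iRprop-: on a gradient sign flip the step
size shrinks and the gradient memory is zeroed, so that coordinate skips one
update instead of backtracking.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: output-unit order: index 0 fires for walking, index 1 for perturbation
OUTPUT_CLASSES = ("W", "P")


@dataclass
class TrainConfig:
    """Network size, Rprop constants and stopping rules.

    The Rprop constants are the canonical published ones; ``patience`` is the
    number of epochs without validation improvement before training stops.
    """

    hidden_units: int = 80
    max_epochs: int = 500
    patience: int = 25
    eta_plus: float = 1.2
    eta_minus: float = 0.5
    delta0: float = 0.07
    delta_max: float = 50.0
    delta_min: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.eta_plus > 1.0 > self.eta_minus > 0.0:
            raise ValueError("need eta_plus > 1 > eta_minus > 0")
        if self.hidden_units < 1 or self.max_epochs < 1 or self.patience < 1:
            raise ValueError("hidden_units, max_epochs, patience must be >= 1")


@dataclass
class NNModel:
    """Weights of the 3-layer network: hidden (H x N) and output (2 x H)."""

    W_h: np.ndarray
    b_h: np.ndarray
    W_o: np.ndarray
    b_o: np.ndarray

    def __post_init__(self) -> None:
        H, N = self.W_h.shape
        if self.b_h.shape != (H,) or self.W_o.shape[1] != H \
                or self.W_o.shape[0] != self.b_o.shape[0]:
            raise ValueError("inconsistent layer shapes")
        for arr in (self.W_h, self.b_h, self.W_o, self.b_o):
            if not np.isfinite(arr).all():
                raise ValueError("non-finite weights")

    @property
    def n_inputs(self) -> int:
        return self.W_h.shape[1]

    def to_json(self, path: str | Path, log: dict | None = None) -> None:
        payload = {k: getattr(self, k).tolist() for k in ("W_h", "b_h", "W_o", "b_o")}
        if log is not None:
            payload["training_log"] = log
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "NNModel":
        raw = json.loads(Path(path).read_text())
        return cls(**{k: np.asarray(raw[k], dtype=float)
                      for k in ("W_h", "b_h", "W_o", "b_o")})


def nn_forward(model: NNModel, S: np.ndarray) -> np.ndarray:
    """Raw network outputs, [2 x T], each entry in (-1, 1)."""
    S = np.atleast_2d(np.asarray(S))
    if S.shape[0] != model.n_inputs:
        raise ValueError(f"expected {model.n_inputs} inputs, got {S.shape[0]}")
    hidden = np.tanh(model.W_h @ S + model.b_h[:, None])
    return np.tanh(model.W_o @ hidden + model.b_o[:, None])


def encode_targets(labels: np.ndarray) -> np.ndarray:
    """Map 'W'/'P' labels to one-hot +-1 targets, [2 x T]."""
    labels = np.asarray(labels)
    is_p = labels == "P"
    if not np.all(is_p | (labels == "W")):
        raise ValueError("labels must be 'W' or 'P'")
    Y = np.where(is_p, -1.0, 1.0)[None, :]
    return np.concatenate([Y, -Y], axis=0)


# ---------------------------------------------------------------------------
# Rprop
# ---------------------------------------------------------------------------

@dataclass
class RpropState:
    """Per-weight step sizes and previous-gradient memory."""

    delta: list[np.ndarray]
    prev_grad: list[np.ndarray]

    @classmethod
    def init(cls, params: list[np.ndarray], delta0: float) -> "RpropState":
        return cls(delta=[np.full_like(p, delta0) for p in params],
                   prev_grad=[np.zeros_like(p) for p in params])


def rprop_step(params: list[np.ndarray], grads: list[np.ndarray],
               state: RpropState, cfg: TrainConfig) -> None:
    """One in-place iRprop- update of every parameter array.

    Sign agreement with the previous gradient grows the step size by
    eta_plus (capped at delta_max); a sign flip shrinks it by eta_minus
    (floored at delta_min) and zeroes the gradient memory, so the weight
    moves by -sign(gradient) * delta only where the sign did not flip.
    """
    for p, g, d, pg in zip(params, grads, state.delta, state.prev_grad):
        prod = pg * g
        np.multiply(d, cfg.eta_plus, out=d, where=prod > 0)
        np.multiply(d, cfg.eta_minus, out=d, where=prod < 0)
        np.clip(d, cfg.delta_min, cfg.delta_max, out=d)
        g_eff = np.where(prod < 0, 0.0, g)
        p -= np.sign(g_eff) * d
        pg[...] = g_eff


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _init_model(n_inputs: int, cfg: TrainConfig) -> NNModel:
    rng = np.random.default_rng(cfg.seed)
    H = cfg.hidden_units

    def u(shape, fan_in):
        return rng.uniform(-0.5, 0.5, size=shape) / np.sqrt(fan_in)

    return NNModel(W_h=u((H, n_inputs), n_inputs), b_h=u(H, n_inputs),
                   W_o=u((2, H), H), b_o=u(2, H))


def _loss_and_grads(model: NNModel, S: np.ndarray, Y: np.ndarray):
    """Full-batch MSE and its gradients w.r.t. all four weight arrays."""
    T = S.shape[1]
    A1 = np.tanh(model.W_h @ S + model.b_h[:, None])
    A2 = np.tanh(model.W_o @ A1 + model.b_o[:, None])
    E = A2 - Y
    loss = float(np.mean(E * E))
    dZ2 = (E * (1.0 - A2 * A2)) * (2.0 / E.size)
    gW_o = dZ2 @ A1.T
    gb_o = dZ2.sum(axis=1)
    dZ1 = (model.W_o.T @ dZ2) * (1.0 - A1 * A1)
    gW_h = dZ1 @ S.T
    gb_h = dZ1.sum(axis=1)
    return loss, [gW_h, gb_h, gW_o, gb_o]


def _mse(model: NNModel, S: np.ndarray, Y: np.ndarray) -> float:
    out = nn_forward(model, S)
    return float(np.mean((out - Y) ** 2))


def train_nn(S_train: np.ndarray, labels_train: np.ndarray,
             S_val: np.ndarray, labels_val: np.ndarray,
             cfg: TrainConfig) -> tuple[NNModel, dict]:
    """Train with full-batch Rprop and best-validation-epoch early stopping.

    Returns the model from the epoch with the lowest validation MSE and a log
    with per-epoch training/validation losses and the selected epoch.
    Deterministic given ``cfg.seed`` (weight initialisation is the only
    randomness); full-batch gradients make the result invariant to the order
    of training samples.
    """
    S_train = np.ascontiguousarray(S_train, dtype=float)
    S_val = np.ascontiguousarray(S_val, dtype=float)
    if S_train.size == 0 or S_val.size == 0:
        raise ValueError("empty training or validation set")
    Y_train = encode_targets(labels_train)
    Y_val = encode_targets(labels_val)
    if Y_train.shape[1] != S_train.shape[1] or Y_val.shape[1] != S_val.shape[1]:
        raise ValueError("label count must match sample count")

    model = _init_model(S_train.shape[0], cfg)
    params = [model.W_h, model.b_h, model.W_o, model.b_o]
    state = RpropState.init(params, cfg.delta0)

    best_val = _mse(model, S_val, Y_val)
    best_params = [p.copy() for p in params]
    best_epoch = 0
    train_log: list[float] = []
    val_log: list[float] = [best_val]
    since_best = 0

    for epoch in range(1, cfg.max_epochs + 1):
        loss, grads = _loss_and_grads(model, S_train, Y_train)
        rprop_step(params, grads, state, cfg)
        val = _mse(model, S_val, Y_val)
        train_log.append(loss)
        val_log.append(val)
        if val < best_val:
            best_val = val
            best_params = [p.copy() for p in params]
            best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break

    best = NNModel(*best_params)
    log = {"train_mse": train_log, "val_mse": val_log,
           "best_epoch": best_epoch, "best_val_mse": best_val,
           "epochs_run": len(train_log)}
    return best, log
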