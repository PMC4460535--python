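"""One-hidden-layer feed-forward network decoder.

The architecture is deliberately a single hidden layer with everywhere-
differentiable activations (tanh hidden, per-unit logistic output): the
sensitivity analysis in :mod:`blockdecode.sensmap` differentiates the
forward map o(x) = f_out(W f_hid(V x + b) + c) with diagonal activation-
derivative matrices, which rules out softmax coupling across outputs.
Raw logistic outputs approximate class posteriors; they are clipped at
zero and normalized to sum to one, and the normalized output of the
chosen label is its *confidence*.

Training minimizes mean squared error against one-hot targets with a
gradient-based quasi-Newton optimizer on the closed-form backprop
gradient, with early stopping on validation stagnation.  Because training
is stochastic (random initialization), model selection follows a
two-phase protocol: a grid search over hidden-layer sizes scored on a
held-out validation split, then ``n_restarts`` (default 20) further nets
at the chosen size, keeping the net with the best validation accuracy.
The restart phase substantially reduces the variance of the returned
net's performance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import optimize
from scipy.special import expit

from .dataset import ExampleSet

__all__ = ["TrainedNet", "PosteriorFrame", "train_nn", "predict",
           "ACTIVATIONS"]

#: name -> (f, derivative expressed in terms of the activation value)
ACTIVATIONS = {
    "tanh": (np.tanh, lambda y: 1.0 - y ** 2),
    "logistic": (expit, lambda y: y * (1.0 - y)),
    "identity": (lambda z: z, lambda y: np.ones_like(y)),
}

DEFAULT_HIDDEN_GRID = (4, 8, 16, 32, 64)
DEFAULT_N_RESTARTS = 20
DEFAULT_MAX_EPOCHS = 500
DEFAULT_PATIENCE = 25


@dataclass
class TrainedNet:
    """Weights, biases, activation names, class order, and input scaler."""

    V: np.ndarray                 # (J, I) input-to-hidden
    hidden_bias: np.ndarray       # (J,)
    W: np.ndarray                 # (K, J) hidden-to-output
    output_bias: np.ndarray       # (K,)
    hidden_activation: str = "tanh"
    output_activation: str = "logistic"
    class_order: np.ndarray = None
    input_scaler: tuple[np.ndarray, np.ndarray] = None  # (shift, scale)

    def __post_init__(self) -> None:
        self.V = np.atleast_2d(np.asarray(self.V, dtype=float))
        self.W = np.atleast_2d(np.asarray(self.W, dtype=float))
        self.hidden_bias = np.asarray(self.hidden_bias, dtype=float)
        self.output_bias = np.asarray(self.output_bias, dtype=float)
        J, I = self.V.shape
        K = self.W.shape[0]
        if self.W.shape[1] != J or len(self.hidden_bias) != J or len(self.output_bias) != K:
            raise ValueError("inconsistent weight shapes")
        if self.hidden_activation not in ACTIVATIONS or self.output_activation not in ACTIVATIONS:
            raise ValueError("unknown activation")
        if self.class_order is None:
            self.class_order = np.arange(K)
        self.class_order = np.asarray(self.class_order)
        if len(np.unique(self.class_order)) != K:
            raise ValueError("class_order must hold K distinct labels")
        if self.input_scaler is None:
            self.input_scaler = (np.zeros(I), np.ones(I))
        shift, scale = self.input_scaler
        self.input_scaler = (np.asarray(shift, float), np.asarray(scale, float))

    @property
    def n_inputs(self) -> int:
        return self.V.shape[1]

    @property
    def n_hidden(self) -> int:
        return self.V.shape[0]

    @property
    def n_outputs(self) -> int:
        return self.W.shape[0]

    def standardize(self, X: np.ndarray) -> np.ndarray:
        shift, scale = self.input_scaler
        return (np.atleast_2d(np.asarray(X, float)) - shift) / scale

    def forward(self, Z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Hidden activations and outputs for standardized inputs Z."""
        f_h = ACTIVATIONS[self.hidden_activation][0]
        f_o = ACTIVATIONS[self.output_activation][0]
        Y = f_h(Z @ self.V.T + self.hidden_bias)
        O = f_o(Y @ self.W.T + self.output_bias)
        return Y, O

    def raw_outputs(self, X: np.ndarray) -> np.ndarray:
        """Outputs for raw-space inputs (standardization applied)."""
        return self.forward(self.standardize(X))[1]

    # -- serialization ----------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        obj = {"V": self.V.tolist(), "hidden_bias": self.hidden_bias.tolist(),
               "W": self.W.tolist(), "output_bias": self.output_bias.tolist(),
               "hidden_activation": self.hidden_activation,
               "output_activation": self.output_activation,
               "class_order": np.asarray(self.class_order).tolist(),
               "input_shift": self.input_scaler[0].tolist(),
               "input_scale": self.input_scaler[1].tolist()}
        Path(path).write_text(json.dumps(obj))

    @classmethod
    def from_json(cls, path: str | Path) -> "TrainedNet":
        obj = json.loads(Path(path).read_text())
        return cls(V=np.array(obj["V"]), hidden_bias=np.array(obj["hidden_bias"]),
                   W=np.array(obj["W"]), output_bias=np.array(obj["output_bias"]),
                   hidden_activation=obj["hidden_activation"],
                   output_activation=obj["output_activation"],
                   class_order=np.array(obj["class_order"]),
                   input_scaler=(np.array(obj["input_shift"]),
                                 np.array(obj["input_scale"])))


@dataclass(frozen=True)
class PosteriorFrame:
    """Per-frame decoder output: raw outputs, normalized posteriors, the
    argmax label, and the confidence (posterior of the chosen label)."""

    raw_outputs: np.ndarray
    posteriors: np.ndarray
    label: object
    confidence: float


def predict(net: TrainedNet, X: np.ndarray) -> list[PosteriorFrame]:
    """Forward pass for every row of X.

    Raw outputs are clipped at zero and normalized to sum to one; if every
    raw output is <= 0 the posteriors fall back to uniform.  Argmax ties
    break toward the lowest position in class_order.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if not np.all(np.isfinite(X)):
        raise ValueError("inputs must be finite")
    if X.shape[1] != net.n_inputs:
        raise ValueError("input width does not match the net")
    raw = net.raw_outputs(X)
    clipped = np.clip(raw, 0.0, None)
    sums = clipped.sum(axis=1, keepdims=True)
    K = net.n_outputs
    post = np.where(sums > 0, clipped / np.where(sums > 0, sums, 1.0), 1.0 / K)
    frames = []
    for r, p in zip(raw, post):
        idx = int(np.argmax(p))          # first max = lowest class_order slot
        frames.append(PosteriorFrame(raw_outputs=r, posteriors=p,
                                     label=net.class_order[idx],
                                     confidence=float(p[idx])))
    return frames


def predict_labels(net: TrainedNet, X: np.ndarray) -> np.ndarray:
    return np.array([f.label for f in predict(net, X)])


# -- training ------------------------------------------------------------

def _pack(V, bh, W, bo):
    return np.concatenate([V.ravel(), bh, W.ravel(), bo])


def _unpack(theta, I, J, K):
    i = 0
    V = theta[i:i + J * I].reshape(J, I); i += J * I
    bh = theta[i:i + J]; i += J
    W = theta[i:i + K * J].reshape(K, J); i += K * J
    bo = theta[i:i + K]
    return V, bh, W, bo


def _loss_grad(theta, Z, T, I, J, K, h_act, o_act):
    f_h, d_h = ACTIVATIONS[h_act]
    f_o, d_o = ACTIVATIONS[o_act]
    V, bh, W, bo = _unpack(theta, I, J, K)
    Y = f_h(Z @ V.T + bh)
    O = f_o(Y @ W.T + bo)
    n = Z.shape[0]
    E = O - T
    loss = float((E ** 2).mean())
    dB = E * d_o(O) * (2.0 / (n * K))        # dL/d(pre-activation of outputs)
    gW = dB.T @ Y
    gbo = dB.sum(axis=0)
    dA = (dB @ W) * d_h(Y)
    gV = dA.T @ Z
    gbh = dA.sum(axis=0)
    return loss, _pack(gV, gbh, gW, gbo)


def _train_single(Z_fit, T_fit, Z_val, y_val_idx, J, rng,
                  h_act, o_act, max_epochs, patience):
    I = Z_fit.shape[1]
    K = T_fit.shape[1]
    theta0 = _pack(rng.normal(0, 1.0 / np.sqrt(I), (J, I)), np.zeros(J),
                   rng.normal(0, 1.0 / np.sqrt(J), (K, J)), np.zeros(K))

    state = {"best_val": np.inf, "best_theta": theta0.copy(), "stall": 0}

    def val_mse(theta):
        V, bh, W, bo = _unpack(theta, I, J, K)
        Yv = ACTIVATIONS[h_act][0](Z_val @ V.T + bh)
        Ov = ACTIVATIONS[o_act][0](Yv @ W.T + bo)
        T = np.zeros_like(Ov)
        T[np.arange(len(y_val_idx)), y_val_idx] = 1.0
        return float(((Ov - T) ** 2).mean())

    def callback(theta):
        v = val_mse(theta)
        if v < state["best_val"] - 1e-8:
            state["best_val"] = v
            state["best_theta"] = theta.copy()
            state["stall"] = 0
        else:
            state["stall"] += 1
            if state["stall"] >= patience:
                raise StopIteration

    try:
        optimize.minimize(_loss_grad, theta0, args=(Z_fit, T_fit, I, J, K, h_act, o_act),
                          jac=True, method="L-BFGS-B", callback=callback,
                          options={"maxiter": max_epochs})
    except StopIteration:
        pass
    theta = state["best_theta"]
    if not np.isfinite(state["best_val"]):  # callback never ran
        theta = theta0
    V, bh, W, bo = _unpack(theta, I, J, K)
    return V, bh, W, bo


def _block_stratified_split(trainset: ExampleSet, val_fraction: float,
                            rng: np.random.Generator):
    """Hold out whole blocks, stratified by class, as the validation part.
    Splitting at block granularity avoids temporal leakage between the fit
    and validation frames of the same 15-s block."""
    blocks = np.unique(trainset.block_id)
    block_label = {b: trainset.y[trainset.block_id == b][0] for b in blocks}
    val_blocks = []
    for c in np.unique(trainset.y):
        cb = np.array([b for b in blocks if block_label[b] == c])
        if len(cb) < 2:
            raise ValueError(f"class {c!r} needs >= 2 blocks to split off validation")
        n_val = max(1, int(round(val_fraction * len(cb))))
        n_val = min(n_val, len(cb) - 1)
        val_blocks.extend(rng.permutation(cb)[:n_val])
    val_mask = np.isin(trainset.block_id, val_blocks)
    return ~val_mask, val_mask


def train_nn(trainset: ExampleSet, val_fraction: float = 0.25,
             hidden_grid: tuple[int, ...] = DEFAULT_HIDDEN_GRID,
             n_restarts: int = DEFAULT_N_RESTARTS, seed: int = 0,
             max_epochs: int = DEFAULT_MAX_EPOCHS,
             patience: int = DEFAULT_PATIENCE) -> TrainedNet:
    """Train with grid search over hidden sizes plus restart selection.

    A block-stratified validation split scores each candidate; the best
    hidden size is selected first (ties -> fewer hidden units), then
    ``n_restarts`` further nets at that size are trained and the best by
    validation accuracy (ties -> earliest trained) is returned.
    """
    if not (0 < val_fraction < 0.5):
        raise ValueError("val_fraction must lie in (0, 0.5)")
    if not hidden_grid:
        raise ValueError("hidden_grid must be nonempty")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    rng = np.random.default_rng(seed)
    classes = np.unique(trainset.y)
    K = len(classes)
    class_idx = {c: i for i, c in enumerate(classes)}

    fit_mask, val_mask = _block_stratified_split(trainset, val_fraction, rng)
    for part, name in ((fit_mask, "fit"), (val_mask, "validation")):
        present = np.unique(trainset.y[part])
        if len(present) != K:
            raise ValueError(f"a class is absent from the {name} part")

    shift = trainset.X.mean(axis=0)
    scale = trainset.X.std(axis=0)
    scale = np.where(scale > 1e-12, scale, 1.0)
    Z = (trainset.X - shift) / scale
    y_idx = np.array([class_idx[c] for c in trainset.y])
    Z_fit, Z_val = Z[fit_mask], Z[val_mask]
    T_fit = np.zeros((fit_mask.sum(), K))
    T_fit[np.arange(fit_mask.sum()), y_idx[fit_mask]] = 1.0
    y_val_idx = y_idx[val_mask]

    def finish(weights):
        V, bh, W, bo = weights
        return TrainedNet(V=V, hidden_bias=bh, W=W, output_bias=bo,
                          class_order=classes, input_scaler=(shift, scale))

    def val_acc(weights):
        net = finish(weights)
        O = net.forward(Z_val)[1]
        return float(np.mean(np.argmax(O, axis=1) == y_val_idx))

    # phase 1: hidden-size grid search
    best_J, best_acc, best_w = None, -1.0, None
    for J in sorted(hidden_grid):
        w = _train_single(Z_fit, T_fit, Z_val, y_val_idx, J, rng,
                          "tanh", "logistic", max_epochs, patience)
        a = val_acc(w)
        if a > best_acc:                      # ties -> fewer hidden units
            best_J, best_acc, best_w = J, a, w
    # phase 2: restarts at the chosen size
    for _ in range(n_restarts):
        w = _train_single(Z_fit, T_fit, Z_val, y_val_idx, best_J, rng,
                          "tanh", "logistic", max_epochs, patience)
        a = val_acc(w)
        if a > best_acc:                      # ties -> earlier stream order
            best_acc, best_w = a, w
    return finish(best_w)
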