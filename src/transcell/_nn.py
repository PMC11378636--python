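"""Seeded feed-forward network core (LeakyReLU / identity / sigmoid, Adam).

Minimal on purpose: dense layers only, three activations, three losses,
full determinism from a single integer seed, and best-validation-loss
checkpointing.  Everything higher level (autoencoders, weight transfer,
prediction heads) composes these pieces.

Losses
------
``recon``   (1/n) sum_i ||x_i - x_hat_i||^2   (per-sample squared norm,
            summed over features, averaged over samples)
``mse``     elementwise mean squared error
``bce``     binary cross-entropy on a sigmoid output
"""

from __future__ import annotations

import numpy as np

LEAKY = "leaky_relu"
IDENTITY = "identity"
SIGMOID = "sigmoid"


def _activate(name: str, z: np.ndarray, alpha: float) -> np.ndarray:
    if name == LEAKY:
        return np.where(z > 0, z, alpha * z)
    if name == IDENTITY:
        return z
    if name == SIGMOID:
        # numerically stable logistic
        out = np.empty_like(z)
        pos = z >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
        ez = np.exp(z[~pos])
        out[~pos] = ez / (1.0 + ez)
        return out
    raise ValueError(f"unknown activation {name!r}")


def _activate_grad(name: str, z: np.ndarray, a: np.ndarray, alpha: float) -> np.ndarray:
    if name == LEAKY:
        return np.where(z > 0, 1.0, alpha)
    if name == IDENTITY:
        return np.ones_like(z)
    if name == SIGMOID:
        return a * (1.0 - a)
    raise ValueError(f"unknown activation {name!r}")


def default_init(rng: np.random.Generator, fan_in: int, fan_out: int):
    """Fan-in-scaled uniform initialization, U(-1/sqrt(fan_in), 1/sqrt(fan_in))."""
    bound = 1.0 / np.sqrt(fan_in)
    W = rng.uniform(-bound, bound, size=(fan_in, fan_out))
    b = rng.uniform(-bound, bound, size=fan_out)
    return W, b


class MLP:
    """Dense feed-forward network with per-layer activations."""

    def __init__(self, dims, activations, alpha: float = 0.1, rng=None):
        if len(activations) != len(dims) - 1:
            raise ValueError("need one activation per weight layer")
        self.dims = list(dims)
        self.activations = list(activations)
        self.alpha = float(alpha)
        rng = rng if rng is not None else np.random.default_rng()
        self.weights = []  # list of [W, b]
        for fan_in, fan_out in zip(dims[:-1], dims[1:]):
            W, b = default_init(rng, fan_in, fan_out)
            self.weights.append([W, b])

    # -- weight plumbing ------------------------------------------------
    def get_weights(self):
        return [[W.copy(), b.copy()] for W, b in self.weights]

    def set_weights(self, weights):
        if len(weights) != len(self.weights):
            raise ValueError("layer count mismatch")
        for (W, b), (W0, b0) in zip(weights, self.weights):
            if W.shape != W0.shape or b.shape != b0.shape:
                raise ValueError(
                    f"weight shape mismatch: {W.shape}/{b.shape} vs {W0.shape}/{b0.shape}"
                )
        self.weights = [[np.array(W, dtype=float), np.array(b, dtype=float)] for W, b in weights]

    # -- forward / backward ---------------------------------------------
    def forward(self, X, return_cache: bool = False):
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.dims[0]:
            raise ValueError(f"expected {self.dims[0]} input columns, got {X.shape[1]}")
        a = X
        zs, acts = [], [X]
        for (W, b), name in zip(self.weights, self.activations):
            z = a @ W + b
            a = _activate(name, z, self.alpha)
            if return_cache:
                zs.append(z)
                acts.append(a)
        if return_cache:
            return a, zs, acts
        return a

    def _loss_and_delta(self, loss: str, Y, out):
        n = Y.shape[0]
        diff = out - Y
        if loss == "recon":
            value = float(np.sum(diff**2) / n)
            delta = 2.0 * diff / n
            return value, delta, False
        if loss == "mse":
            value = float(np.mean(diff**2))
            delta = 2.0 * diff / diff.size
            return value, delta, False
        if loss == "bce":
            p = np.clip(out, 1e-12, 1.0 - 1e-12)
            value = float(-np.mean(Y * np.log(p) + (1.0 - Y) * np.log(1.0 - p)))
            # delta w.r.t. pre-activation of the sigmoid output
            delta = (out - Y) / Y.size
            return value, delta, True
        raise ValueError(f"unknown loss {loss!r}")

    def loss(self, X, Y, loss: str) -> float:
        out = self.forward(X)
        return self._loss_and_delta(loss, np.asarray(Y, dtype=float), out)[0]

    def _gradients(self, X, Y, loss: str):
        Y = np.asarray(Y, dtype=float)
        out, zs, acts = self.forward(X, return_cache=True)
        value, delta, at_preact = self._loss_and_delta(loss, Y, out)
        grads = [None] * len(self.weights)
        for layer in reversed(range(len(self.weights))):
            name = self.activations[layer]
            if layer == len(self.weights) - 1 and at_preact:
                dz = delta
            else:
                dz = delta * _activate_grad(name, zs[layer], acts[layer + 1], self.alpha)
            grads[layer] = (acts[layer].T @ dz, dz.sum(axis=0))
            if layer > 0:
                delta = dz @ self.weights[layer][0].T
        return value, grads


class Adam:
    """Adaptive-moment optimizer over an MLP's weight list."""

    def __init__(self, mlp: MLP, lr: float = 1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.mlp = mlp
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [[np.zeros_like(W), np.zeros_like(b)] for W, b in mlp.weights]
        self.v = [[np.zeros_like(W), np.zeros_like(b)] for W, b in mlp.weights]

    def step(self, grads, freeze_layers=()):
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for li, (gW, gb) in enumerate(grads):
            if li in freeze_layers:
                continue
            for pi, g in enumerate((gW, gb)):
                self.m[li][pi] = self.beta1 * self.m[li][pi] + (1 - self.beta1) * g
                self.v[li][pi] = self.beta2 * self.v[li][pi] + (1 - self.beta2) * g**2
                m_hat = self.m[li][pi] / b1c
                v_hat = self.v[li][pi] / b2c
                self.mlp.weights[li][pi] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def split_validation(n: int, val_fraction: float, rng, stratify=None):
    """Seeded train/validation index split; stratified when labels given."""
    if not 0.0 <= val_fraction < 1.0:
        raise ValueError("val_fraction must be in [0, 1)")
    n_val = int(round(n * val_fraction))
    if val_fraction > 0 and n_val == 0:
        n_val = 1
    if stratify is None:
        perm = rng.permutation(n)
        return perm[n_val:], perm[:n_val]
    stratify = np.asarray(stratify)
    val_idx = []
    for cls in np.unique(stratify):
        cls_idx = rng.permutation(np.flatnonzero(stratify == cls))
        k = int(round(len(cls_idx) * val_fraction))
        val_idx.extend(cls_idx[:k])
    val_idx = np.array(sorted(val_idx), dtype=int)
    train_idx = np.setdiff1d(np.arange(n), val_idx)
    return train_idx, val_idx


def train_mlp(
    mlp: MLP,
    X,
    Y,
    *,
    loss: str,
    epochs: int,
    batch_size: int = 32,
    lr: float = 1e-3,
    patience: int = 20,
    val_fraction: float = 0.1,
    val_data=None,
    seed: int = 0,
    stratify=None,
    freeze_layers=(),
) -> dict:
    """Mini-batch Adam training with best-validation-loss checkpointing.

    Returns a history dict with per-epoch ``train_loss`` and ``val_loss``;
    the network is left holding the weights of the best validation epoch
    (epoch 0 = the untouched initialization, so a zero-epoch budget is a
    strict no-op).  Raises on non-finite loss, naming the epoch.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    rng = np.random.default_rng(seed)

    if val_data is not None:
        X_tr, Y_tr = X, Y
        X_val, Y_val = np.asarray(val_data[0], dtype=float), np.asarray(val_data[1], dtype=float)
        if Y_val.ndim == 1:
            Y_val = Y_val[:, None]
    else:
        tr_idx, val_idx = split_validation(len(X), val_fraction, rng, stratify=stratify)
        X_tr, Y_tr = X[tr_idx], Y[tr_idx]
        X_val, Y_val = X[val_idx], Y[val_idx]
        if len(X_val) == 0:
            X_val, Y_val = X_tr, Y_tr

    opt = Adam(mlp, lr=lr)
    best_weights = mlp.get_weights()
    best_val = mlp.loss(X_val, Y_val, loss)
    history = {"train_loss": [mlp.loss(X_tr, Y_tr, loss)], "val_loss": [best_val]}
    since_best = 0

    for epoch in range(epochs):
        order = rng.permutation(len(X_tr))
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, len(X_tr), batch_size):
            idx = order[start : start + batch_size]
            value, grads = mlp._gradients(X_tr[idx], Y_tr[idx], loss)
            if not np.isfinite(value):
                raise FloatingPointError(f"non-finite training loss at epoch {epoch + 1}")
            opt.step(grads, freeze_layers=freeze_layers)
            epoch_loss += value
            n_batches += 1
        val_loss = mlp.loss(X_val, Y_val, loss)
        if not np.isfinite(val_loss):
            raise FloatingPointError(f"non-finite validation loss at epoch {epoch + 1}")
        history["train_loss"].append(epoch_loss / max(n_batches, 1))
        history["val_loss"].append(val_loss)
        if val_loss < best_val:
            best_val = val_loss
            best_weights = mlp.get_weights()
            since_best = 0
        else:
            since_best += 1
            if patience is not None and since_best >= patience:
                break

    mlp.set_weights(best_weights)
    history["best_val_loss"] = best_val
    return history
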