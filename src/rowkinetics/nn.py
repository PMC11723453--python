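"""A small sequence-to-sequence LSTM regressor, implemented in NumPy.

Layer stack (fixed): dense(n_in -> n_in) -> single LSTM layer -> dropout ->
dense(units -> n_out), trained with a per-timestep mean-squared-error
objective.  Variable-length sequences are padded per minibatch and the loss
is masked on pad frames, so padding has no semantic effect.

The implementation is deliberately compact: fused gate matrices (one
``(n_in + units) x 4*units`` weight block, gate order input / forget /
candidate / output), full backpropagation through time, and an Adam
optimizer.  Gradients are validated against finite differences in the test
suite.  float32 is used in the training path; a float64 mode exists for
gradient checking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _glorot(rng: np.random.Generator, shape: tuple[int, int], dtype) -> np.ndarray:
    limit = np.sqrt(6.0 / sum(shape))
    return rng.uniform(-limit, limit, shape).astype(dtype)


class LSTMRegressor:
    """dense -> LSTM -> dropout -> dense sequence regressor."""

    PARAM_NAMES = ("W_in", "b_in", "W_x", "W_h", "b", "W_out", "b_out")

    def __init__(
        self,
        n_in: int,
        units: int,
        n_out: int = 6,
        dropout: float = 0.0,
        seed: int = 0,
        dtype=np.float32,
    ):
        self.n_in, self.units, self.n_out = n_in, units, n_out
        self.dropout = float(dropout)
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        H = units
        self.params: dict[str, np.ndarray] = {
            "W_in": _glorot(rng, (n_in, n_in), dtype),
            "b_in": np.zeros(n_in, dtype),
            "W_x": _glorot(rng, (n_in, 4 * H), dtype),
            "W_h": _glorot(rng, (H, 4 * H), dtype),
            "b": np.zeros(4 * H, dtype),
            "W_out": _glorot(rng, (H, n_out), dtype),
            "b_out": np.zeros(n_out, dtype),
        }
        # standard trick: forget-gate bias starts at 1 so memory persists early
        self.params["b"][H : 2 * H] = 1.0

    # -- parameter bookkeeping ------------------------------------------------

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def n_lstm_params(self) -> int:
        """Parameters of the LSTM layer alone: 4*((n_in + H)*H + H)."""
        return int(self.params["W_x"].size + self.params["W_h"].size + self.params["b"].size)

    def get_weights(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for k in self.PARAM_NAMES:
            self.params[k] = np.asarray(weights[k], self.dtype).copy()

    # -- forward / backward ---------------------------------------------------

    def forward(
        self,
        X: np.ndarray,
        train: bool = False,
        rng: np.random.Generator | None = None,
        want_cache: bool = False,
    ):
        """Run the network on a padded batch ``X`` of shape (B, T, n_in).

        Returns predictions (B, T, n_out); with ``want_cache`` also the
        activation cache needed for :meth:`backward`.
        """
        p = self.params
        B, T, _ = X.shape
        H = self.units
        X = X.astype(self.dtype, copy=False)
        Xd = X @ p["W_in"] + p["b_in"]
        Z_in = Xd @ p["W_x"]  # (B, T, 4H): input projection for all steps at once
        h = np.zeros((B, H), self.dtype)
        c = np.zeros((B, H), self.dtype)
        Hs = np.empty((B, T, H), self.dtype)
        if want_cache:
            gates = np.empty((B, T, 4 * H), self.dtype)
            Cs = np.empty((B, T, H), self.dtype)
        Wh, b = p["W_h"], p["b"]
        for t in range(T):
            z = Z_in[:, t] + h @ Wh + b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c = f * c + i * g
            h = o * np.tanh(c)
            Hs[:, t] = h
            if want_cache:
                gates[:, t, :H] = i
                gates[:, t, H : 2 * H] = f
                gates[:, t, 2 * H : 3 * H] = g
                gates[:, t, 3 * H :] = o
                Cs[:, t] = c
        Hd = Hs
        drop_mask = None
        if train and self.dropout > 0:
            if rng is None:
                rng = np.random.default_rng()
            drop_mask = (rng.uniform(size=Hs.shape) >= self.dropout).astype(self.dtype)
            drop_mask /= self.dtype(1.0 - self.dropout)
            Hd = Hs * drop_mask
        Y = Hd @ p["W_out"] + p["b_out"]
        if not want_cache:
            return Y
        cache = {"X": X, "Xd": Xd, "Hs": Hs, "Hd": Hd, "gates": gates, "Cs": Cs,
                 "drop_mask": drop_mask}
        return Y, cache

    def backward(self, cache: dict, dY: np.ndarray) -> dict[str, np.ndarray]:
        """Backpropagate through time; ``dY`` is dLoss/dY, (B, T, n_out)."""
        p = self.params
        X, Xd, Hs, Hd = cache["X"], cache["Xd"], cache["Hs"], cache["Hd"]
        gates, Cs, drop_mask = cache["gates"], cache["Cs"], cache["drop_mask"]
        B, T, H = Hs.shape
        dY = dY.astype(self.dtype, copy=False)
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        grads["W_out"] = np.einsum("bth,bto->ho", Hd, dY, optimize=True)
        grads["b_out"] = dY.sum(axis=(0, 1))
        dHs = dY @ p["W_out"].T
        if drop_mask is not None:
            dHs = dHs * drop_mask
        dZ = np.empty((B, T, 4 * H), self.dtype)
        dh = np.zeros((B, H), self.dtype)
        dc = np.zeros((B, H), self.dtype)
        WhT = p["W_h"].T
        for t in range(T - 1, -1, -1):
            dh = dh + dHs[:, t]
            i = gates[:, t, :H]
            f = gates[:, t, H : 2 * H]
            g = gates[:, t, 2 * H : 3 * H]
            o = gates[:, t, 3 * H :]
            c = Cs[:, t]
            tc = np.tanh(c)
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc * tc)
            di = dc * g
            dg = dc * i
            c_prev = Cs[:, t - 1] if t > 0 else np.zeros_like(c)
            df = dc * c_prev
            dz = dZ[:, t]
            dz[:, :H] = di * i * (1.0 - i)
            dz[:, H : 2 * H] = df * f * (1.0 - f)
            dz[:, 2 * H : 3 * H] = dg * (1.0 - g * g)
            dz[:, 3 * H :] = do * o * (1.0 - o)
            dh = dz @ WhT
            dc = dc * f
        # accumulate the big weight gradients with single GEMMs
        dZ2 = dZ.reshape(B * T, 4 * H)
        grads["W_x"] = Xd.reshape(B * T, -1).T @ dZ2
        H_prev = np.concatenate(
            [np.zeros((B, 1, H), self.dtype), Hs[:, :-1]], axis=1
        ).reshape(B * T, H)
        grads["W_h"] = H_prev.T @ dZ2
        grads["b"] = dZ2.sum(axis=0)
        dXd = dZ2 @ p["W_x"].T
        grads["W_in"] = X.reshape(B * T, -1).T @ dXd
        grads["b_in"] = dXd.sum(axis=0)
        return grads


def masked_mse_and_grad(
    Y: np.ndarray, targets: np.ndarray, mask: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean-squared error over valid frames, with its gradient w.r.t. Y.

    ``mask`` is (B, T) with 1 on real frames and 0 on padding.
    """
    diff = (Y - targets) * mask[..., None]
    n_valid = float(mask.sum()) * Y.shape[-1]
    loss = float((diff ** 2).sum()) / n_valid
    return loss, (2.0 / n_valid) * diff


@dataclass
class Adam:
    """Adam optimizer over a named parameter dict."""

    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    t: int = 0
    m: dict = field(default_factory=dict)
    v: dict = field(default_factory=dict)

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for k, g in grads.items():
            if k not in self.m:
                self.m[k] = np.zeros_like(params[k])
                self.v[k] = np.zeros_like(params[k])
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * g * g
            m_hat = self.m[k] / b1t
            v_hat = self.v[k] / b2t
            params[k] -= (self.lr * m_hat / (np.sqrt(v_hat) + self.eps)).astype(params[k].dtype)


def pad_batch(
    sequences: list[np.ndarray], targets: list[np.ndarray], dtype=np.float32
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pad variable-length (T_i, k) sequences into (B, T_max, k) plus a mask."""
    B = len(sequences)
    T = max(s.shape[0] for s in sequences)
    X = np.zeros((B, T, sequences[0].shape[1]), dtype)
    Y = np.zeros((B, T, targets[0].shape[1]), dtype)
    mask = np.zeros((B, T), dtype)
    for i, (s, y) in enumerate(zip(sequences, targets)):
        X[i, : len(s)] = s
        Y[i, : len(y)] = y
        mask[i, : len(s)] = 1.0
    return X, Y, mask
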