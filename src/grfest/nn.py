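"""NumPy implementation of the bidirectional LSTM sequence regressor.

Architecture, applied at every timestep of the 400-sample input sequence:

    input dropout
      -> bidirectional LSTM (hidden size H per direction,
         concatenated per-timestep state of size 2H)
      -> linear(2H -> L2) -> activation -> dropout
      -> linear(L2 -> L3) -> activation -> dropout
      -> linear(L3 -> 1)

Training minimises the RMSE between estimated and measured force traces over
the whole batch with the Adam optimiser.  Forward, backpropagation through
time and Adam are implemented explicitly on NumPy arrays; gradient
correctness is pinned by a finite-difference test.
"""

from __future__ import annotations

import numpy as np

GATE_ORDER = "ifgo"  # input, forget, cell, output


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


ACTIVATIONS = ("relu", "leaky_relu", "tanh", "sigmoid")


def _activate(name: str, x: np.ndarray) -> np.ndarray:
    if name == "relu":
        return np.maximum(x, 0.0)
    if name == "leaky_relu":
        return np.where(x > 0.0, x, 0.01 * x)
    if name == "tanh":
        return np.tanh(x)
    if name == "sigmoid":
        return _sigmoid(x)
    raise ValueError(f"unknown activation {name!r}; choose from {ACTIVATIONS}")


def _activate_grad(name: str, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """d activation / d pre-activation, given pre-activation x and output y."""
    if name == "relu":
        return (x > 0.0).astype(x.dtype)
    if name == "leaky_relu":
        return np.where(x > 0.0, 1.0, 0.01).astype(x.dtype)
    if name == "tanh":
        return 1.0 - y * y
    if name == "sigmoid":
        return y * (1.0 - y)
    raise ValueError(f"unknown activation {name!r}")


class BiLSTMRegressor:
    """Sequence-to-sequence force regressor: [B x T x D] -> [B x T]."""

    def __init__(
        self,
        input_size: int,
        hidden_size: int,
        linear2_size: int,
        linear3_size: int,
        activation: str = "relu",
        input_dropout: float = 0.0,
        linear_dropout: float = 0.0,
        seed: int = 0,
        dtype: str = "float64",
    ) -> None:
        if activation not in ACTIVATIONS:
            raise ValueError(f"unknown activation {activation!r}; choose from {ACTIVATIONS}")
        if not (0.0 <= input_dropout < 1.0 and 0.0 <= linear_dropout < 1.0):
            raise ValueError("dropout rates must lie in [0, 1)")
        self.D, self.H = input_size, hidden_size
        self.L2, self.L3 = linear2_size, linear3_size
        self.activation = activation
        self.input_dropout = input_dropout
        self.linear_dropout = linear_dropout
        self.dtype = np.dtype(dtype)
        rng = np.random.default_rng(seed)
        k = 1.0 / np.sqrt(hidden_size)
        p: dict[str, np.ndarray] = {}
        for d in ("f", "b"):  # forward / backward direction
            p[f"Wx_{d}"] = rng.uniform(-k, k, (self.D, 4 * self.H))
            p[f"Wh_{d}"] = rng.uniform(-k, k, (self.H, 4 * self.H))
            p[f"bias_{d}"] = rng.uniform(-k, k, 4 * self.H)
        for name, fan_in, shape in (
            ("W1", 2 * self.H, (2 * self.H, self.L2)),
            ("W2", self.L2, (self.L2, self.L3)),
            ("W3", self.L3, (self.L3, 1)),
        ):
            kk = 1.0 / np.sqrt(fan_in)
            p[name] = rng.uniform(-kk, kk, shape)
            p[name.replace("W", "b")] = rng.uniform(-kk, kk, shape[1])
        self.params = {k_: v.astype(self.dtype) for k_, v in p.items()}

    # -- introspection ---------------------------------------------------

    def parameter_count(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    # -- forward ---------------------------------------------------------

    def _lstm_direction(self, x: np.ndarray, d: str, reverse: bool) -> tuple[np.ndarray, dict]:
        B, T, _ = x.shape
        H = self.H
        p = self.params
        pre_x = x @ p[f"Wx_{d}"] + p[f"bias_{d}"]  # (B, T, 4H)
        order = range(T - 1, -1, -1) if reverse else range(T)
        h = np.zeros((B, H), dtype=self.dtype)
        c = np.zeros((B, H), dtype=self.dtype)
        gates = np.empty((T, B, 4 * H), dtype=self.dtype)  # post-nonlinearity i,f,g,o
        cs = np.empty((T, B, H), dtype=self.dtype)
        tcs = np.empty((T, B, H), dtype=self.dtype)
        hs = np.empty((T, B, H), dtype=self.dtype)
        c_prevs = np.empty((T, B, H), dtype=self.dtype)
        Wh = p[f"Wh_{d}"]
        for t in order:
            z = pre_x[:, t] + h @ Wh
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c_prevs[t] = c
            c = f * c + i * g
            tc = np.tanh(c)
            h = o * tc
            gates[t, :, :H] = i
            gates[t, :, H : 2 * H] = f
            gates[t, :, 2 * H : 3 * H] = g
            gates[t, :, 3 * H :] = o
            cs[t], tcs[t], hs[t] = c, tc, h
        cache = {"x": x, "gates": gates, "cs": cs, "tcs": tcs, "hs": hs, "c_prevs": c_prevs, "reverse": reverse, "d": d}
        return hs.transpose(1, 0, 2), cache  # (B, T, H)

    def forward(
        self, x: np.ndarray, train: bool = False, rng: np.random.Generator | None = None
    ) -> tuple[np.ndarray, dict]:
        """Returns predictions (B, T) and the cache needed for backward()."""
        x = np.asarray(x, dtype=self.dtype)
        cache: dict = {"train": train}
        if train and self.input_dropout > 0.0:
            keep = 1.0 - self.input_dropout
            mask = (rng.random(x.shape) < keep).astype(self.dtype) / keep
            x = x * mask
        h_f, cache_f = self._lstm_direction(x, "f", reverse=False)
        h_b, cache_b = self._lstm_direction(x, "b", reverse=True)
        hcat = np.concatenate([h_f, h_b], axis=2)  # (B, T, 2H)

        p = self.params
        a1 = hcat @ p["W1"] + p["b1"]
        z1 = _activate(self.activation, a1)
        if train and self.linear_dropout > 0.0:
            keep = 1.0 - self.linear_dropout
            m1 = (rng.random(z1.shape) < keep).astype(self.dtype) / keep
        else:
            m1 = None
        z1d = z1 * m1 if m1 is not None else z1
        a2 = z1d @ p["W2"] + p["b2"]
        z2 = _activate(self.activation, a2)
        if train and self.linear_dropout > 0.0:
            keep = 1.0 - self.linear_dropout
            m2 = (rng.random(z2.shape) < keep).astype(self.dtype) / keep
        else:
            m2 = None
        z2d = z2 * m2 if m2 is not None else z2
        y = (z2d @ p["W3"] + p["b3"])[..., 0]  # (B, T)

        cache.update(
            lstm_f=cache_f, lstm_b=cache_b, hcat=hcat,
            a1=a1, z1=z1, m1=m1, z1d=z1d, a2=a2, z2=z2, m2=m2, z2d=z2d,
        )
        return y, cache

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Deterministic inference (dropout disabled)."""
        y, _ = self.forward(x, train=False)
        return y

    # -- backward ----------------------------------------------------------

    def _lstm_backward(self, dh_seq: np.ndarray, cache: dict) -> dict[str, np.ndarray]:
        """BPTT for one direction. dh_seq: (B, T, H) gradient on hidden states."""
        x = cache["x"]
        B, T, _ = x.shape
        H = self.H
        d = cache["d"]
        gates, cs, tcs, c_prevs = cache["gates"], cache["cs"], cache["tcs"], cache["c_prevs"]
        Wh = self.params[f"Wh_{d}"]
        order = range(T) if cache["reverse"] else range(T - 1, -1, -1)
        dh_carry = np.zeros((B, H), dtype=self.dtype)
        dc = np.zeros((B, H), dtype=self.dtype)
        dz_all = np.empty((T, B, 4 * H), dtype=self.dtype)
        dWh = np.zeros_like(Wh)
        for t in order:
            i = gates[t, :, :H]
            f = gates[t, :, H : 2 * H]
            g = gates[t, :, 2 * H : 3 * H]
            o = gates[t, :, 3 * H :]
            dh = dh_seq[:, t] + dh_carry
            do = dh * tcs[t]
            dc = dc + dh * o * (1.0 - tcs[t] ** 2)
            di = dc * g
            dg = dc * i
            df = dc * c_prevs[t]
            dz = np.empty((B, 4 * H), dtype=self.dtype)
            dz[:, :H] = di * i * (1.0 - i)
            dz[:, H : 2 * H] = df * f * (1.0 - f)
            dz[:, 2 * H : 3 * H] = dg * (1.0 - g * g)
            dz[:, 3 * H :] = do * o * (1.0 - o)
            dz_all[t] = dz
            dh_carry = dz @ Wh.T
            dc = dc * f
            # h_{t-1} for the recurrent weight gradient
            t_prev = t + 1 if cache["reverse"] else t - 1
            if (cache["reverse"] and t_prev <= T - 1 and t != (T - 1)) or (
                not cache["reverse"] and t_prev >= 0
            ):
                h_prev = cache["hs"][t_prev]
                dWh += h_prev.T @ dz
        dz_flat = dz_all.transpose(1, 0, 2).reshape(B * T, 4 * H)
        x_flat = x.reshape(B * T, self.D)
        return {
            f"Wx_{d}": x_flat.T @ dz_flat,
            f"Wh_{d}": dWh,
            f"bias_{d}": dz_flat.sum(axis=0),
        }

    def backward(self, dy: np.ndarray, cache: dict) -> dict[str, np.ndarray]:
        """Gradients of the loss w.r.t. every parameter, given dL/dy (B, T)."""
        p = self.params
        hcat = cache["hcat"]
        B, T, _ = hcat.shape
        dy3 = dy[..., None].astype(self.dtype)  # (B, T, 1)

        z2d_flat = cache["z2d"].reshape(B * T, self.L3)
        grads: dict[str, np.ndarray] = {}
        grads["W3"] = z2d_flat.T @ dy3.reshape(B * T, 1)
        grads["b3"] = dy3.sum(axis=(0, 1))
        dz2d = dy3 @ p["W3"].T  # (B, T, L3)
        if cache["m2"] is not None:
            dz2d = dz2d * cache["m2"]
        dz2 = dz2d * _activate_grad(self.activation, cache["a2"], cache["z2"])

        z1d_flat = cache["z1d"].reshape(B * T, self.L2)
        grads["W2"] = z1d_flat.T @ dz2.reshape(B * T, self.L3)
        grads["b2"] = dz2.sum(axis=(0, 1))
        dz1d = dz2 @ p["W2"].T
        if cache["m1"] is not None:
            dz1d = dz1d * cache["m1"]
        dz1 = dz1d * _activate_grad(self.activation, cache["a1"], cache["z1"])

        hcat_flat = hcat.reshape(B * T, 2 * self.H)
        grads["W1"] = hcat_flat.T @ dz1.reshape(B * T, self.L2)
        grads["b1"] = dz1.sum(axis=(0, 1))
        dhcat = dz1 @ p["W1"].T  # (B, T, 2H)

        grads.update(self._lstm_backward(dhcat[:, :, : self.H], cache["lstm_f"]))
        grads.update(self._lstm_backward(dhcat[:, :, self.H :], cache["lstm_b"]))
        return grads


def rmse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Batch RMSE over all timesteps jointly, and its gradient w.r.t. pred."""
    diff = pred - target
    mse = float(np.mean(diff**2))
    rmse = float(np.sqrt(mse))
    if rmse == 0.0:
        return 0.0, np.zeros_like(diff)
    return rmse, diff / (diff.size * rmse)


class Adam:
    """Adaptive Moment Estimation optimiser over a dict of parameter arrays."""

    def __init__(
        self, params: dict[str, np.ndarray], lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8
    ) -> None:
        if lr < 0:
            raise ValueError("learning rate must be non-negative")
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            g = g.reshape(params[k].shape)
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * g**2
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)
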