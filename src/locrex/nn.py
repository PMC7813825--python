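"""Numerical core: LSTM forward / backward passes and the Adam optimizer.

Everything is plain numpy, batched, and deterministic for a fixed seed and
thread configuration.  The recurrent cell follows the standard LSTM equations
with gate order (input, forget, cell, output) and a forget-gate bias of 1.
PAD positions are masked: at a padded timestep the hidden and cell states
carry over unchanged, so trailing padding can never alter the final summary
state.  Gradients are computed by backpropagation through time; correctness
is pinned by a finite-difference check in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def init_lstm_params(
    rng: np.random.Generator, input_dim: int, hidden: int, dtype=np.float32
) -> dict[str, np.ndarray]:
    """Glorot-uniform weights for one direction; forget-gate bias starts at 1."""

    def glorot(fan_in: int, fan_out: int, shape: tuple[int, ...]) -> np.ndarray:
        lim = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-lim, lim, size=shape).astype(dtype)

    b = np.zeros(4 * hidden, dtype=dtype)
    b[hidden:2 * hidden] = 1.0
    return {
        "W": glorot(input_dim, 4 * hidden, (input_dim, 4 * hidden)),
        "U": glorot(hidden, 4 * hidden, (hidden, 4 * hidden)),
        "b": b,
    }


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


@dataclass
class LSTMCache:
    """Per-timestep values needed by BPTT, in processing order."""

    x: list[np.ndarray] = field(default_factory=list)
    h_prev: list[np.ndarray] = field(default_factory=list)
    c_prev: list[np.ndarray] = field(default_factory=list)
    gates: list[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = field(default_factory=list)
    tanh_c: list[np.ndarray] = field(default_factory=list)
    mask: list[np.ndarray] = field(default_factory=list)


def lstm_forward(
    emb: np.ndarray, mask: np.ndarray, params: dict[str, np.ndarray], reverse: bool = False
) -> tuple[np.ndarray, LSTMCache]:
    """Run one direction over ``emb`` (B×T×d) with PAD ``mask`` (B×T).

    Returns the final hidden state (B×h) and the BPTT cache.  With
    ``reverse=True`` timesteps are processed last-to-first (the backward
    reader of a bidirectional network).
    """
    B, T, _ = emb.shape
    hidden = params["U"].shape[0]
    dtype = params["W"].dtype
    h = np.zeros((B, hidden), dtype=dtype)
    c = np.zeros((B, hidden), dtype=dtype)
    cache = LSTMCache()
    order = range(T - 1, -1, -1) if reverse else range(T)
    for t in order:
        x_t = emb[:, t, :]
        m = mask[:, t:t + 1].astype(dtype)
        z = x_t @ params["W"] + h @ params["U"] + params["b"]
        i = _sigmoid(z[:, :hidden])
        f = _sigmoid(z[:, hidden:2 * hidden])
        g = np.tanh(z[:, 2 * hidden:3 * hidden])
        o = _sigmoid(z[:, 3 * hidden:])
        c_new = f * c + i * g
        tc = np.tanh(c_new)
        h_new = o * tc
        cache.x.append(x_t)
        cache.h_prev.append(h)
        cache.c_prev.append(c)
        cache.gates.append((i, f, g, o))
        cache.tanh_c.append(tc)
        cache.mask.append(m)
        h = m * h_new + (1.0 - m) * h
        c = m * c_new + (1.0 - m) * c
    return h, cache


def lstm_backward(
    dh_final: np.ndarray, params: dict[str, np.ndarray], cache: LSTMCache, reverse: bool, T: int
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """BPTT for one direction.

    Returns parameter gradients and d(embedding) of shape B×T×d.
    """
    hidden = params["U"].shape[0]
    dtype = params["W"].dtype
    B = dh_final.shape[0]
    grads = {k: np.zeros_like(v) for k, v in params.items()}
    d_emb = np.zeros((B, T, params["W"].shape[0]), dtype=dtype)
    dh = dh_final.astype(dtype)
    dc = np.zeros((B, hidden), dtype=dtype)
    order = list(range(T - 1, -1, -1) if reverse else range(T))
    for step in range(len(order) - 1, -1, -1):
        t = order[step]
        i, f, g, o = cache.gates[step]
        tc = cache.tanh_c[step]
        m = cache.mask[step]
        dh_new = dh * m
        dh_carry = dh * (1.0 - m)
        dc_new = dc * m
        dc_carry = dc * (1.0 - m)
        do = dh_new * tc
        dc_new = dc_new + dh_new * o * (1.0 - tc * tc)
        di = dc_new * g
        dg = dc_new * i
        df = dc_new * cache.c_prev[step]
        dc = dc_new * f + dc_carry
        dz = np.concatenate(
            [di * i * (1.0 - i), df * f * (1.0 - f), dg * (1.0 - g * g), do * o * (1.0 - o)],
            axis=1,
        )
        grads["W"] += cache.x[step].T @ dz
        grads["U"] += cache.h_prev[step].T @ dz
        grads["b"] += dz.sum(axis=0)
        d_emb[:, t, :] += dz @ params["W"].T
        dh = dz @ params["U"].T + dh_carry
    return grads, d_emb


def log_softmax(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=1, keepdims=True)
    return shifted - np.log(np.exp(shifted).sum(axis=1, keepdims=True))


def clip_gradients(grads: dict[str, np.ndarray], max_norm: float) -> None:
    """In-place global-norm gradient clipping."""
    total = np.sqrt(sum(float((g ** 2).sum()) for g in grads.values()))
    if max_norm > 0 and total > max_norm:
        scale = max_norm / (total + 1e-12)
        for g in grads.values():
            g *= scale


class Adam:
    """Adam with decoupled-from-schedule L2 weight decay added to the gradient."""

    def __init__(
        self,
        params: dict[str, np.ndarray],
        lr: float = 0.01,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
        lr_halving_steps: int = 0,
        no_decay: tuple[str, ...] = (),
    ) -> None:
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.lr_halving_steps = lr_halving_steps
        self.no_decay = set(no_decay)
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def current_lr(self) -> float:
        if self.lr_halving_steps > 0:
            return self.lr * 0.5 ** (self.t // self.lr_halving_steps)
        return self.lr

    def step(self, grads: dict[str, np.ndarray]) -> None:
        lr_t = self.current_lr()
        self.t += 1
        for k, p in self.params.items():
            g = grads[k]
            if self.weight_decay and k not in self.no_decay:
                g = g + self.weight_decay * p
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * (g * g)
            m_hat = self.m[k] / (1 - self.b1 ** self.t)
            v_hat = self.v[k] / (1 - self.b2 ** self.t)
            p -= (lr_t * m_hat / (np.sqrt(v_hat) + self.eps)).astype(p.dtype)
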