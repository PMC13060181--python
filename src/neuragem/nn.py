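"""Minimal numpy neural-network primitives.

The forward model used throughout the package is

    input -> embedding MLP -> (Z-modulated) LSTM core (32 units) -> output MLP

with exact reverse-mode gradients (backpropagation through time) written by
hand and validated against central finite differences in the test suite.
Everything operates on float64 with an explicit leading batch axis so that
frozen-weight evaluation can process many sliding windows at once.

Fast-substrate coupling
-----------------------
The fast substrate Z is a small population of mutually inhibitory units. Its
activity as seen by the network is s = softmax(Z) computed within each
population ("softmax" transform, the default): the units compete, the
winning unit's pathway is expressed, and the network is functional at the
Z = 0 initial condition (uniform mixture). An "affine" transform
(s = 1 + G @ Z for gating) is also provided; it makes the gate exactly
neutral at Z = 0, which is convenient for reduction tests.

Modulation modes
----------------
multiplicative : the embedded input (the recurrent core's input
    pre-activation, upstream of the recurrent weights) is gated elementwise
    by G @ s, where G is a fixed binary matrix drawn once with inclusion
    probability 0.4 and never updated. Each Z unit thus selects a random
    40% sub-population of input channels.
additive : s is concatenated to the embedded input; the corresponding input
    columns of the LSTM are learnable (the "Z projection").
none : Z plays no role (the conventional RNN baselines).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

HIDDEN = 32  # recurrent population size

DEFAULT_SLICES = None


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _softmax(z):
    e = np.exp(z - z.max())
    return e / e.sum()


@dataclass
class NetParams:
    """All learnable parameters W, as a flat name -> array mapping, plus the
    fixed binary gate matrix G (multiplicative mode only; never updated)."""

    params: dict[str, np.ndarray]
    gate_matrix: np.ndarray | None  # (HIDDEN, z_dim) binary, fixed

    def copy(self) -> "NetParams":
        return NetParams(
            {k: v.copy() for k, v in self.params.items()},
            None if self.gate_matrix is None else self.gate_matrix.copy(),
        )


def init_params(
    d_in: int,
    d_out: int,
    z_dim: int,
    mode: str,
    seed: int,
    hidden: int = HIDDEN,
    gate_prob: float = 0.4,
) -> NetParams:
    """Initialise all parameters from a seed.

    The draw order is identical for 'multiplicative' and 'none' modes (the
    gate matrix is always drawn), so a conventional RNN baseline and a
    substrate-disabled multiplicative model share bit-identical initial
    weights at a matched seed.
    """
    rng = np.random.default_rng(seed)
    H = hidden
    d_lstm = H + (z_dim if mode == "additive" else 0)

    def mat(m, n):
        lim = 1.0 / np.sqrt(m)
        return rng.uniform(-lim, lim, size=(m, n))

    p = {
        "We1": mat(d_in, H),
        "be1": np.zeros(H),
        "We2": mat(H, H),
        "be2": np.zeros(H),
        "Wx": mat(d_lstm, 4 * H),
        "Wh": mat(H, 4 * H),
        "b": np.zeros(4 * H),
        "Wo1": mat(H, H),
        "bo1": np.zeros(H),
        "Wo2": mat(H, d_out),
        "bo2": np.zeros(d_out),
    }
    G = (rng.random((H, z_dim)) < gate_prob).astype(float)
    return NetParams(p, G if mode == "multiplicative" else None)


def z_activity(Z: np.ndarray, transform: str, slices=None) -> np.ndarray:
    """Population activity s of the fast substrate.

    softmax : within-population competition (mutually inhibitory units).
    affine  : s = Z unchanged (the multiplicative gate then adds a +1 offset).
    """
    if transform == "softmax":
        s = np.empty_like(Z)
        for sl in slices or [slice(0, Z.shape[0])]:
            s[sl] = _softmax(Z[sl])
        return s
    if transform == "affine":
        return Z.copy()
    raise ValueError(f"unknown z transform {transform!r}")


def z_activity_backward(dS: np.ndarray, Z: np.ndarray, transform: str, slices=None) -> np.ndarray:
    """Chain dL/ds back to dL/dZ through the competition transform."""
    if transform == "affine":
        return dS
    dZ = np.empty_like(dS)
    for sl in slices or [slice(0, Z.shape[0])]:
        s = _softmax(Z[sl])
        dZ[sl] = s * (dS[sl] - float(dS[sl] @ s))
    return dZ


@dataclass
class ForwardCache:
    """Per-window intermediates retained for the backward pass."""

    X: np.ndarray
    Z: np.ndarray
    s: np.ndarray
    gate: np.ndarray | None
    steps: list = field(default_factory=list)
    ys: list = field(default_factory=list)
    h_last: np.ndarray | None = None
    c_last: np.ndarray | None = None


def forward_window(
    net: NetParams,
    X: np.ndarray,
    Z: np.ndarray,
    mode: str,
    z_transform: str = "softmax",
    z_slices=None,
    h0: np.ndarray | None = None,
    c0: np.ndarray | None = None,
) -> tuple[np.ndarray, ForwardCache]:
    """Run the model over a window.

    X : (B, T, d_in); Z : (z_dim,) applied at every step of the window.
    Returns predictions Y (B, T, d_out) and a cache for backward_window.
    """
    p = net.params
    B, T, _ = X.shape
    H = p["Wh"].shape[0]
    h = np.zeros((B, H)) if h0 is None else h0
    c = np.zeros((B, H)) if c0 is None else c0

    s = z_activity(Z, z_transform, z_slices)
    gate = None
    if mode == "multiplicative":
        gate = net.gate_matrix @ s
        if z_transform == "affine":
            gate = 1.0 + gate

    cache = ForwardCache(X=X, Z=Z, s=s, gate=gate)
    Y = np.empty((B, T, p["Wo2"].shape[1]))
    for t in range(T):
        x = X[:, t]
        a1 = x @ p["We1"] + p["be1"]
        e1 = np.maximum(a1, 0.0)
        e = e1 @ p["We2"] + p["be2"]
        if mode == "multiplicative":
            u = e * gate
        elif mode == "additive":
            u = np.concatenate([e, np.broadcast_to(s, (B, s.shape[0]))], axis=1)
        else:
            u = e
        z4 = u @ p["Wx"] + h @ p["Wh"] + p["b"]
        i = _sigmoid(z4[:, :H])
        f = _sigmoid(z4[:, H : 2 * H])
        g = np.tanh(z4[:, 2 * H : 3 * H])
        o = _sigmoid(z4[:, 3 * H :])
        c_new = f * c + i * g
        tc = np.tanh(c_new)
        h_new = o * tc
        a2 = h_new @ p["Wo1"] + p["bo1"]
        r = np.maximum(a2, 0.0)
        y = r @ p["Wo2"] + p["bo2"]
        cache.steps.append((x, a1, e1, e, u, h, c, i, f, g, o, c_new, tc, h_new, a2, r))
        h, c = h_new, c_new
        Y[:, t] = y
    cache.ys = Y
    cache.h_last, cache.c_last = h, c
    return Y, cache


def backward_window(
    net: NetParams,
    cache: ForwardCache,
    dY: np.ndarray,
    mode: str,
    z_transform: str = "softmax",
    z_slices=None,
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Exact gradients of a scalar loss L with dL/dY = dY.

    Returns (grads for every entry of net.params, dL/dZ).
    """
    p = net.params
    H = p["Wh"].shape[0]
    B, T, _ = cache.X.shape
    grads = {k: np.zeros_like(v) for k, v in p.items()}
    z_dim = cache.Z.shape[0]
    dS = np.zeros(z_dim)

    dh_next = np.zeros((B, H))
    dc_next = np.zeros((B, H))
    for t in range(T - 1, -1, -1):
        (x, a1, e1, e, u, h_prev, c_prev, i, f, g, o, c_new, tc, h_new, a2, r) = cache.steps[t]
        dy = dY[:, t]
        grads["Wo2"] += r.T @ dy
        grads["bo2"] += dy.sum(0)
        dr = dy @ p["Wo2"].T
        da2 = dr * (a2 > 0)
        grads["Wo1"] += h_new.T @ da2
        grads["bo1"] += da2.sum(0)
        dh = da2 @ p["Wo1"].T + dh_next

        do = dh * tc
        dc = dh * o * (1.0 - tc * tc) + dc_next
        di = dc * g
        df = dc * c_prev
        dg = dc * i
        dc_next = dc * f

        dz4 = np.concatenate(
            [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g), do * o * (1 - o)], axis=1
        )
        grads["Wx"] += u.T @ dz4
        grads["Wh"] += h_prev.T @ dz4
        grads["b"] += dz4.sum(0)
        dh_next = dz4 @ p["Wh"].T
        du = dz4 @ p["Wx"].T

        if mode == "multiplicative":
            de = du * cache.gate
            dgate = (du * e).sum(0)  # (H,)
            dS += net.gate_matrix.T @ dgate
        elif mode == "additive":
            de = du[:, :H]
            dS += du[:, H:].sum(0)
        else:
            de = du

        grads["We2"] += e1.T @ de
        grads["be2"] += de.sum(0)
        da1 = (de @ p["We2"].T) * (a1 > 0)
        grads["We1"] += x.T @ da1
        grads["be1"] += da1.sum(0)

    dZ = z_activity_backward(dS, cache.Z, z_transform, z_slices)
    return grads, dZ


# ---------------------------------------------------------------------------
# optimizers
# ---------------------------------------------------------------------------


class Adam:
    """Adam; the fast substrate uses responsiveness-oriented momentum
    constants (beta1=0.5, beta2=0.7), the slow substrate the usual defaults."""

    def __init__(self, shapes: dict[str, tuple], lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros(s) for k, s in shapes.items()}
        self.v = {k: np.zeros(s) for k, s in shapes.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, g in grads.items():
            m = self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            v = self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class SGD:
    """Plain gradient descent (multi-timescale experiments)."""

    def __init__(self, shapes: dict[str, tuple], lr: float):
        self.lr = lr

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        for k, g in grads.items():
            params[k] -= self.lr * g


def make_optimizer(name: str, shapes: dict[str, tuple], lr: float, **kw):
    if name == "adam":
        return Adam(shapes, lr, **kw)
    if name == "sgd":
        return SGD(shapes, lr)
    raise ValueError(f"unknown optimizer {name!r}")
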