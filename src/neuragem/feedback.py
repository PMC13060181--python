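"""Learned feedback pathway: a small recurrent network that replaces
backpropagation for the fast-substrate updates at test time.

An 8-unit recurrent net maps the instantaneous output residual
(x_{t+1} - x_hat_{t+1}) together with the current Z activity to a proposed
update dZ_t. During training it is supervised to approximate the true BPTT
gradient, L_fb = ||dZ_t - dE_t/dZ_t||^2; at test, Z is updated locally:

    Z_{t+1} = Z_t - alpha_Z_decay * Z_t - dZ_t

with no gradient computation through the forward network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .model import NeuraGemModel, Trajectory


@dataclass
class FeedbackNet:
    """Vanilla tanh recurrent net: (residual, Z) -> dZ proposal."""

    d_resid: int
    z_dim: int
    hidden: int = 8
    params: dict = field(default_factory=dict)

    @classmethod
    def create(cls, d_resid: int, z_dim: int, hidden: int = 8, seed: int = 0) -> "FeedbackNet":
        rng = np.random.default_rng(seed)
        d_in = d_resid + z_dim

        def mat(m, n):
            return rng.normal(0.0, 1.0 / np.sqrt(m), size=(m, n))

        params = {
            "Wxh": mat(d_in, hidden),
            "Whh": mat(hidden, hidden) * 0.5,
            "bh": np.zeros(hidden),
            "Who": mat(hidden, z_dim),
            "bo": np.zeros(z_dim),
        }
        return cls(d_resid=d_resid, z_dim=z_dim, hidden=hidden, params=params)

    def step(self, residual: np.ndarray, z: np.ndarray, h: np.ndarray):
        """One recurrent step; returns (dZ proposal, new hidden state, cache)."""
        x = np.concatenate([np.atleast_1d(residual), np.atleast_1d(z)])
        p = self.params
        a = x @ p["Wxh"] + h @ p["Whh"] + p["bh"]
        h_new = np.tanh(a)
        out = h_new @ p["Who"] + p["bo"]
        return out, h_new, (x, h, h_new)

    def zero_state(self) -> np.ndarray:
        return np.zeros(self.hidden)


def feedback_forward(net: FeedbackNet, residual: np.ndarray, Z: np.ndarray,
                     h: np.ndarray | None = None) -> np.ndarray:
    """Stateless convenience wrapper: proposed dZ for one (residual, Z) pair."""
    if h is None:
        h = net.zero_state()
    out, _, _ = net.step(residual, Z, h)
    return out


def apply_feedback_update(Z: np.ndarray, deltaZ: np.ndarray, alpha_z_decay: float) -> np.ndarray:
    """Z' = Z - alpha_z_decay * Z - deltaZ."""
    Z = np.asarray(Z, dtype=float)
    return Z - alpha_z_decay * Z - np.asarray(deltaZ, dtype=float)


class _TruncatedBPTT:
    """Online training of the feedback net with truncated backprop through its
    own recurrence (truncation length k)."""

    def __init__(self, net: FeedbackNet, lr: float = 3e-3, k: int = 10):
        self.net = net
        self.k = k
        self.opt = nn.Adam({n: p.shape for n, p in net.params.items()}, lr)
        self.buffer: list = []  # (cache, dout) pairs, most recent last

    def accumulate(self, cache, dout: np.ndarray) -> None:
        self.buffer.append((cache, dout))
        if len(self.buffer) > self.k:
            self.buffer.pop(0)

    def update(self) -> None:
        """Backprop the most recent step's loss through the buffered history."""
        p = self.net.params
        grads = {n: np.zeros_like(v) for n, v in p.items()}
        dh_next = np.zeros(self.net.hidden)
        for idx in range(len(self.buffer) - 1, -1, -1):
            (x, h_prev, h_new), dout = self.buffer[idx]
            if idx == len(self.buffer) - 1:
                grads["Who"] += np.outer(h_new, dout)
                grads["bo"] += dout
                dh = dout @ p["Who"].T + dh_next
            else:
                dh = dh_next
            da = dh * (1.0 - h_new * h_new)
            grads["Wxh"] += np.outer(x, da)
            grads["Whh"] += np.outer(h_prev, da)
            grads["bh"] += da
            dh_next = da @ p["Whh"].T
        self.opt.step(p, grads)


def train_feedback(
    forward_model: NeuraGemModel,
    observations: np.ndarray,
    seed: int = 0,
    lr: float = 3e-3,
    hidden: int = 8,
) -> tuple[FeedbackNet, np.ndarray]:
    """Train the feedback net alongside the forward model's online protocol.

    The forward model runs its usual online steps (W trained unless frozen,
    Z updated by BPTT); at every step the true gradient dE_t/dZ_t serves as
    the teaching signal for the feedback net. Returns the trained net and the
    per-step feedback losses L_fb.
    """
    net = FeedbackNet.create(forward_model.d_out, forward_model.z_dim, hidden, seed)
    trainer = _TruncatedBPTT(net, lr=lr)
    obs = np.asarray(observations)
    cfg = forward_model.config
    losses = np.empty(len(obs) - 1)
    h_fb = net.zero_state()
    for t in range(len(obs) - 1):
        z_before = forward_model.fast.Z.copy()
        lo = max(0, t - cfg.h + 1)
        X = obs[lo : t + 1][None]
        Tgt = obs[lo + 1 : t + 2][None]
        L = X.shape[1]
        Y, cache = nn.forward_window(
            forward_model.net, X, forward_model.fast.Z,
            forward_model.effective_mode, forward_model.z_transform,
            forward_model.fast.slices,
        )
        dY = (Y - Tgt) / L
        grads, dZ = nn.backward_window(
            forward_model.net, cache, dY,
            forward_model.effective_mode, forward_model.z_transform,
            forward_model.fast.slices,
        )
        residual = Tgt[0, -1] - Y[0, -1]
        proposal, h_fb, fb_cache = net.step(residual, z_before, h_fb)
        err = proposal - dZ
        losses[t] = float((err**2).sum())
        trainer.accumulate(fb_cache, 2.0 * err)
        trainer.update()
        # forward model keeps learning as usual
        forward_model.fast.update(dZ)
        if not forward_model.w_frozen:
            forward_model.w_opt.step(forward_model.net.params, grads)
    return net, losses


def run_with_feedback(
    model: NeuraGemModel,
    net: FeedbackNet,
    observations: np.ndarray,
) -> tuple[Trajectory, np.ndarray]:
    """Frozen-W evaluation where Z updates come from the feedback pathway.

    No backward pass through the forward network is performed. Returns the
    trajectory and the per-step ||dZ_t|| series (which spikes at covert
    context transitions).
    """
    obs = np.asarray(observations)
    cfg = model.config
    n = len(obs) - 1
    d = model.d_out
    decay = model.fast.populations[0].decay
    traj = Trajectory(
        predictions=np.empty((n, d)),
        targets=np.empty((n, d)),
        errors=np.empty(n),
        grad_norm_z=np.zeros(n),
        grad_norm_w=np.zeros(n),
        hidden=np.empty((n, nn.HIDDEN)),
        z=np.empty((n, model.z_dim)),
    )
    dz_norms = np.empty(n)
    h_fb = net.zero_state()
    for t in range(n):
        lo = max(0, t - cfg.h + 1)
        X = obs[lo : t + 1][None]
        Y, cache = nn.forward_window(
            model.net, X, model.fast.Z, model.effective_mode,
            model.z_transform, model.fast.slices,
        )
        pred = Y[0, -1]
        target = obs[t + 1]
        residual = target - pred
        proposal, h_fb, _ = net.step(residual, model.fast.Z, h_fb)
        model.fast.Z = apply_feedback_update(model.fast.Z, proposal, decay)
        traj.predictions[t] = pred
        traj.targets[t] = target
        traj.errors[t] = 0.5 * float(((pred - target) ** 2).sum())
        traj.hidden[t] = cache.steps[-1][13][0]
        traj.z[t] = model.fast.Z
        dz_norms[t] = float(np.linalg.norm(proposal))
    return traj, dz_norms
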