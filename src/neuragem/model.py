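"""The two-substrate model and its online train/test protocol.

A slow substrate W (all learnable network weights) and a fast substrate Z
(a small population of mutually inhibitory units) are both updated by
prediction-error gradients, at very different rates. At every online step
the model re-processes the most recent ``h`` observations, predicts the next
sample, incurs the error, and takes one gradient step on Z (fast, with decay
toward baseline) and one on W (slow). At test time W is frozen while Z keeps
adapting, which is what lets the model re-infer the latent context on the
fly.

Fast-substrate semantics
------------------------
``config.z_enabled = False`` means the substrate is absent altogether (the
conventional RNN baselines): the network consumes the embedded input
unmodulated, and a substrate-absent model is bit-identical to an RNN
baseline at a matched seed. Passing ``z_enabled=False`` to a single call of
:meth:`NeuraGemModel.online_step`/:meth:`NeuraGemModel.run` on a model whose
substrate exists merely suspends the Z updates (the gate stays at the
current Z), which is the "Z updates disabled during a curriculum phase"
manipulation.

The Z update is one optimizer step per online step,

    Z <- Z - alpha_Z * adam(dL/dZ + alpha_Z_decay * Z)        (Adam)
    Z <- (1 - alpha_Z_decay) * (Z - alpha_Z * dL/dZ)          (SGD)

i.e. under Adam the L2 decay is folded into the gradient before the adaptive
rescaling (optimizer-level weight decay), while under SGD it acts as
decoupled multiplicative shrinkage.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .tasks import ConfigurationError, ContextStream


@dataclass
class ZPopulation:
    """One fast-substrate population with its own update and decay rates."""

    n_units: int = 2
    alpha: float = 0.5
    decay: float = 1e-4


@dataclass
class TrainConfig:
    """Online-learning hyperparameters.

    h is the input horizon: the number of most recent observations
    re-processed at every step. beta1/beta2 are the Adam momentum constants
    (0.5/0.7, chosen for responsiveness of the fast updates); both substrates
    use them, w_beta1/w_beta2 allowing the slow substrate to be overridden.
    """

    h: int = 5
    alpha_w: float = 1e-3
    optimizer: str = "adam"
    beta1: float = 0.5
    beta2: float = 0.7
    w_beta1: float = 0.5
    w_beta2: float = 0.7
    n_blocks: int = 40
    seed: int = 0
    z_updates_per_step: int = 1
    z_enabled: bool = True

    def validate(self) -> None:
        if self.h < 1:
            raise ConfigurationError("horizon h must be >= 1")
        if self.alpha_w <= 0:
            raise ConfigurationError("alpha_w must be > 0")
        if self.z_updates_per_step < 1:
            raise ConfigurationError("z_updates_per_step must be >= 1")


class FastState:
    """The fast substrate: Z vector, per-population optimizer state and decay.

    Z is initialized to zero at the start of training, where the
    within-population competition outputs a uniform mixture.
    """

    def __init__(
        self,
        populations: list[ZPopulation] | None = None,
        optimizer: str = "adam",
        beta1: float = 0.5,
        beta2: float = 0.7,
    ):
        self.populations = populations or [ZPopulation()]
        self.optimizer_name = optimizer
        self.dim = sum(p.n_units for p in self.populations)
        self.Z = np.zeros(self.dim)
        self.slices: list[slice] = []
        start = 0
        for p in self.populations:
            self.slices.append(slice(start, start + p.n_units))
            start += p.n_units
        kw = {"beta1": beta1, "beta2": beta2} if optimizer == "adam" else {}
        self.opts = [
            nn.make_optimizer(optimizer, {"Z": (p.n_units,)}, p.alpha, **kw)
            for p in self.populations
        ]

    def update(self, grad_z: np.ndarray) -> None:
        for pop, sl, opt in zip(self.populations, self.slices, self.opts):
            zview = self.Z[sl]
            if self.optimizer_name == "adam":
                opt.step({"Z": zview}, {"Z": grad_z[sl] + pop.decay * zview})
            else:
                opt.step({"Z": zview}, {"Z": grad_z[sl]})
                zview -= pop.decay * zview

    def copy(self) -> "FastState":
        import copy as _copy

        return _copy.deepcopy(self)


@dataclass
class StepLog:
    """What one online step produced."""

    prediction: np.ndarray
    target: np.ndarray
    error: float
    grad_norm_z: float
    grad_norm_w: float
    hidden: np.ndarray
    z: np.ndarray


@dataclass
class Trajectory:
    """Column-oriented log of a full run (one row per online step)."""

    predictions: np.ndarray   # (T-1, d)
    targets: np.ndarray       # (T-1, d)
    errors: np.ndarray        # (T-1,) loss 0.5*||.||^2 at the emitted step
    grad_norm_z: np.ndarray
    grad_norm_w: np.ndarray
    hidden: np.ndarray        # (T-1, 32)
    z: np.ndarray             # (T-1, z_dim)

    @property
    def squared_errors(self) -> np.ndarray:
        """Per-step squared prediction error ||x_hat - x||^2 (for MSE metrics)."""
        return ((self.predictions - self.targets) ** 2).sum(axis=1)

    @property
    def per_dim_squared_errors(self) -> np.ndarray:
        return (self.predictions - self.targets) ** 2

    def to_frame(self) -> pd.DataFrame:
        d = {"t": np.arange(len(self.errors))}
        for j in range(self.predictions.shape[1]):
            d[f"prediction{j}"] = self.predictions[:, j]
            d[f"target{j}"] = self.targets[:, j]
        d["error"] = self.errors
        d["grad_norm_z"] = self.grad_norm_z
        d["grad_norm_w"] = self.grad_norm_w
        return pd.DataFrame(d)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


class NeuraGemModel:
    """Coupled (W, Z) state with gating mode, update rates and optimizer state."""

    def __init__(
        self,
        d_in: int = 1,
        d_out: int | None = None,
        z_dim: int = 2,
        gating_mode: str = "multiplicative",
        config: TrainConfig | None = None,
        populations: list[ZPopulation] | None = None,
        z_transform: str = "softmax",
        seed: int = 0,
    ):
        if gating_mode not in ("multiplicative", "additive", "none"):
            raise ConfigurationError(f"unknown gating mode {gating_mode!r}")
        self.config = config or TrainConfig(seed=seed)
        self.config.validate()
        self.d_in = d_in
        self.d_out = d_out if d_out is not None else d_in
        self.mode = gating_mode
        self.z_transform = z_transform
        if populations is None:
            populations = [ZPopulation(n_units=z_dim)]
        self.fast = FastState(
            populations,
            optimizer=self.config.optimizer,
            beta1=self.config.beta1,
            beta2=self.config.beta2,
        )
        self.z_dim = self.fast.dim
        self.net = nn.init_params(d_in, self.d_out, self.z_dim, gating_mode, seed)
        kw = (
            {"beta1": self.config.w_beta1, "beta2": self.config.w_beta2}
            if self.config.optimizer == "adam"
            else {}
        )
        self.w_opt = nn.make_optimizer(
            self.config.optimizer,
            {k: v.shape for k, v in self.net.params.items()},
            self.config.alpha_w,
            **kw,
        )
        self.w_frozen = False

    @property
    def effective_mode(self) -> str:
        """The substrate-absent model is a plain RNN regardless of gating mode."""
        return self.mode if self.config.z_enabled else "none"

    # -- forward ------------------------------------------------------------

    def forward_predict(self, window: np.ndarray, Z: np.ndarray | None = None) -> np.ndarray:
        """Prediction of the next sample from a window (T, d_in) of recent
        observations; deterministic given (W, Z, window)."""
        window = np.atleast_2d(window)
        if window.shape[1] != self.d_in:
            raise ConfigurationError(
                f"window dim {window.shape[1]} != input dim {self.d_in}"
            )
        Z = self.fast.Z if Z is None else np.asarray(Z, dtype=float)
        if Z.shape[0] != self.z_dim:
            raise ConfigurationError("Z dimension mismatch")
        Y, _ = nn.forward_window(
            self.net, window[None], Z, self.effective_mode,
            self.z_transform, self.fast.slices,
        )
        return Y[0, -1]

    # -- online protocol ----------------------------------------------------

    def online_step(
        self,
        observations: np.ndarray,
        t: int,
        train_w: bool | None = None,
        z_enabled: bool | None = None,
    ) -> StepLog:
        """Re-process the last h observations ending at time t, predict t+1,
        incur the error against the realized observation, then update Z (if
        enabled) and W (if not frozen).

        The window loss is sequence-to-sequence: the mean over window steps of
        0.5*||prediction - next observation||^2.
        """
        cfg = self.config
        if train_w is None:
            train_w = not self.w_frozen
        if z_enabled is None:
            z_enabled = cfg.z_enabled
        z_enabled = z_enabled and cfg.z_enabled  # absent substrate never updates
        lo = max(0, t - cfg.h + 1)
        X = observations[lo : t + 1][None]
        Tgt = observations[lo + 1 : t + 2][None]
        L = X.shape[1]

        mode = self.effective_mode
        n_inner = cfg.z_updates_per_step if z_enabled else 1
        for _ in range(n_inner):
            Y, cache = nn.forward_window(
                self.net, X, self.fast.Z, mode, self.z_transform, self.fast.slices
            )
            dY = (Y - Tgt) / L
            grads, dZ = nn.backward_window(
                self.net, cache, dY, mode, self.z_transform, self.fast.slices
            )
            if z_enabled:
                self.fast.update(dZ)
        if train_w:
            self.w_opt.step(self.net.params, grads)

        pred = Y[0, -1]
        target = Tgt[0, -1]
        err = 0.5 * float(((pred - target) ** 2).sum())
        gw = sum(np.abs(g).sum() for g in grads.values())  # L1, as logged for W
        return StepLog(
            prediction=pred,
            target=target,
            error=err,
            grad_norm_z=float(np.linalg.norm(dZ)),
            grad_norm_w=float(gw),
            hidden=cache.steps[-1][13][0].copy(),
            z=self.fast.Z.copy(),
        )

    def run(
        self,
        observations: np.ndarray,
        train_w: bool | None = None,
        z_enabled: bool | None = None,
    ) -> Trajectory:
        """Online loop over a whole observation array (T, d_in)."""
        T = observations.shape[0]
        n = max(T - 1, 0)
        d = self.d_out
        traj = Trajectory(
            predictions=np.empty((n, d)),
            targets=np.empty((n, d)),
            errors=np.empty(n),
            grad_norm_z=np.empty(n),
            grad_norm_w=np.empty(n),
            hidden=np.empty((n, nn.HIDDEN)),
            z=np.empty((n, self.z_dim)),
        )
        for t in range(n):
            log = self.online_step(observations, t, train_w=train_w, z_enabled=z_enabled)
            traj.predictions[t] = log.prediction
            traj.targets[t] = log.target
            traj.errors[t] = log.error
            traj.grad_norm_z[t] = log.grad_norm_z
            traj.grad_norm_w[t] = log.grad_norm_w
            traj.hidden[t] = log.hidden
            traj.z[t] = log.z
        return traj

    def copy(self) -> "NeuraGemModel":
        import copy as _copy

        return _copy.deepcopy(self)

    # -- persistence ---------------------------------------------------------

    def save(self, path) -> None:
        meta = dict(
            d_in=self.d_in,
            d_out=self.d_out,
            mode=self.mode,
            z_transform=self.z_transform,
            populations=[asdict(p) for p in self.fast.populations],
            config=asdict(self.config),
            w_frozen=self.w_frozen,
        )
        arrays = {f"param_{k}": v for k, v in self.net.params.items()}
        if self.net.gate_matrix is not None:
            arrays["gate_matrix"] = self.net.gate_matrix
        arrays["Z"] = self.fast.Z
        np.savez(path, meta=np.array(json.dumps(meta)), **arrays)

    @classmethod
    def load(cls, path) -> "NeuraGemModel":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["meta"]))
        model = cls(
            d_in=meta["d_in"],
            d_out=meta["d_out"],
            gating_mode=meta["mode"],
            z_transform=meta["z_transform"],
            config=TrainConfig(**meta["config"]),
            populations=[ZPopulation(**p) for p in meta["populations"]],
        )
        for k in model.net.params:
            model.net.params[k] = data[f"param_{k}"]
        if "gate_matrix" in data:
            model.net.gate_matrix = data["gate_matrix"]
        model.fast.Z = data["Z"]
        model.w_frozen = meta["w_frozen"]
        return model


# ---------------------------------------------------------------------------
# free functions mirroring the protocol's named operations
# ---------------------------------------------------------------------------


def prediction_error(prediction: np.ndarray, target: np.ndarray) -> float:
    """0.5 * ||prediction - target||^2."""
    prediction = np.asarray(prediction, dtype=float)
    target = np.asarray(target, dtype=float)
    if prediction.shape != target.shape:
        raise ConfigurationError("prediction/target shape mismatch")
    return 0.5 * float(((prediction - target) ** 2).sum())


def run_training(model: NeuraGemModel, stream: ContextStream) -> Trajectory:
    """Train online through the stream's blocks, then freeze W for testing."""
    n_blocks = int(model.config.n_blocks)
    if n_blocks > 0 and stream.block_ids.max() + 1 < n_blocks:
        raise ConfigurationError(
            f"stream covers {stream.block_ids.max() + 1} blocks < n_blocks={n_blocks}"
        )
    traj = model.run(stream.observations, train_w=True)
    model.w_frozen = True
    return traj


def infer_z_frozen(model: NeuraGemModel, observations: np.ndarray) -> Trajectory:
    """Run the online protocol with W fixed and Z updating (the fast-inference
    analogue of an E-step). Returns the full trajectory; Z series in .z."""
    return model.run(np.asarray(observations), train_w=False, z_enabled=True)


def evaluate_frozen(model: NeuraGemModel, observations: np.ndarray) -> Trajectory:
    """Frozen-weight evaluation.

    Models with an active fast substrate run the sequential online protocol
    (Z keeps updating). Pure-W models are evaluated with all sliding windows
    batched, which is mathematically identical and much faster.
    """
    if model.config.z_enabled:
        return model.run(observations, train_w=False, z_enabled=True)
    return _evaluate_frozen_batched(model, observations)


def _evaluate_frozen_batched(model: NeuraGemModel, observations: np.ndarray) -> Trajectory:
    obs = np.asarray(observations)
    T, d = obs.shape
    h = model.config.h
    n = T - 1
    mode = model.effective_mode
    preds = np.empty((n, model.d_out))
    hidden = np.empty((n, nn.HIDDEN))
    Z = model.fast.Z
    # left-truncated windows at the start
    for t in range(min(h - 1, n)):
        Y, cache = nn.forward_window(
            model.net, obs[: t + 1][None], Z, mode, model.z_transform, model.fast.slices
        )
        preds[t] = Y[0, -1]
        hidden[t] = cache.h_last[0]
    if n >= h - 1:
        from numpy.lib.stride_tricks import sliding_window_view

        wins = sliding_window_view(obs, h, axis=0)  # (T-h+1, d, h)
        wins = np.transpose(wins, (0, 2, 1))[: n - h + 1]
        if wins.shape[0] > 0:
            Y, cache = nn.forward_window(
                model.net, wins, Z, mode, model.z_transform, model.fast.slices
            )
            preds[h - 1 :] = Y[:, -1]
            hidden[h - 1 :] = cache.h_last
    targets = obs[1:]
    errors = 0.5 * ((preds - targets) ** 2).sum(axis=1)
    zeros = np.zeros(n)
    return Trajectory(
        predictions=preds,
        targets=targets,
        errors=errors,
        grad_norm_z=zeros,
        grad_norm_w=zeros.copy(),
        hidden=hidden,
        z=np.tile(Z, (n, 1)),
    )


def two_population_model(
    d_in: int = 5,
    seed: int = 0,
    h: int = 5,
    alpha_w: float = 0.1,
    fast: tuple[float, float] = (1.0, 0.3),
    slow: tuple[float, float] = (0.5, 0.15),
    units_per_population: int = 2,
) -> NeuraGemModel:
    """The Z_fast / Z_slow variant: two concatenated populations differing only
    in update and decay rates, trained with plain SGD so the rate differences
    are not washed out by adaptive rescaling. Competition acts within each
    population."""
    cfg = TrainConfig(h=h, alpha_w=alpha_w, optimizer="sgd", seed=seed)
    pops = [
        ZPopulation(units_per_population, *fast),
        ZPopulation(units_per_population, *slow),
    ]
    return NeuraGemModel(
        d_in=d_in, z_dim=2 * units_per_population, gating_mode="multiplicative",
        config=cfg, populations=pops, seed=seed,
    )
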