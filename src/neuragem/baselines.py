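"""Reference predictors: the Bayesian ideal observer (with and without
variance inference), the naive two-sample averager, and the horizon-limited
RNN baselines.

The ideal observer assumes the true generative model of the contextual
switching task: observations x_t ~ N(mu_s, sigma^2) with the latent state s
switching according to a per-step hazard rate rho. Its posterior is updated
recursively,

    p(s_t | x_1:t)  propto  [(1-rho) p(s_{t-1}|x_1:t-1) + rho pi(s_t)] N(x_t; mu_s, sigma^2)

and its prediction is the posterior-weighted mean. The hazard defaults to the
reciprocal of the generative mean block length (1/25).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .model import NeuraGemModel, TrainConfig, Trajectory, evaluate_frozen, run_training
from .tasks import ConfigurationError, ContextStream


@dataclass
class BayesObserver:
    """Recursive posterior over the two latent means under a hazard-rate
    switching prior."""

    mu: tuple[float, float] = (0.2, 0.8)
    sigma: float = 0.3
    hazard: float = 1.0 / 25.0
    switch_prior: tuple[float, float] = (0.5, 0.5)
    posterior: np.ndarray = field(default_factory=lambda: np.array([0.5, 0.5]))

    def __post_init__(self):
        if self.sigma <= 0:
            raise ConfigurationError("sigma must be > 0")
        if not (0 <= self.hazard <= 1):
            raise ConfigurationError("hazard must be in [0, 1]")
        self.posterior = np.asarray(self.posterior, dtype=float)
        self.posterior = self.posterior / self.posterior.sum()


def bayes_step(obs: float, observer: BayesObserver) -> BayesObserver:
    """One recursive posterior update (in place; the observer is returned)."""
    pi = np.asarray(observer.switch_prior)
    prior = (1.0 - observer.hazard) * observer.posterior + observer.hazard * pi
    like = norm.pdf(obs, loc=np.asarray(observer.mu), scale=observer.sigma)
    post = prior * like
    s = post.sum()
    if s <= 0 or not np.isfinite(s):  # numerically degenerate observation
        post = prior
        s = post.sum()
    observer.posterior = post / s
    return observer


def bayes_predict(observer: BayesObserver) -> float:
    """Posterior-weighted predictive mean."""
    return float(observer.posterior @ np.asarray(observer.mu))


def run_bayes(observations: np.ndarray, observer: BayesObserver | None = None) -> np.ndarray:
    """Prediction series: entry t is the prediction of x_{t+1} after
    observing x_0..x_t (aligned with the models' trajectories)."""
    obs = np.asarray(observations).reshape(-1)
    observer = observer or BayesObserver()
    preds = np.empty(len(obs) - 1)
    for t in range(len(obs) - 1):
        bayes_step(obs[t], observer)
        preds[t] = bayes_predict(observer)
    return preds


class BayesSigmaObserver:
    """Ideal observer extended to infer the observation s.d. from the data.

    A grid posterior over sigma in {0.05, 0.10, ..., 1.0} is maintained
    jointly with the state posterior; the state transition kernel (hazard)
    acts on the state only, sigma being static. Predictions marginalise over
    the grid.
    """

    def __init__(
        self,
        mu: tuple[float, float] = (0.2, 0.8),
        hazard: float = 1.0 / 25.0,
        switch_prior: tuple[float, float] = (0.5, 0.5),
        sigma_grid: np.ndarray | None = None,
    ):
        self.mu = np.asarray(mu, dtype=float)
        self.hazard = hazard
        self.pi = np.asarray(switch_prior, dtype=float)
        self.sigma_grid = (
            np.arange(0.05, 1.0001, 0.05) if sigma_grid is None else np.asarray(sigma_grid)
        )
        n_sig = len(self.sigma_grid)
        self.joint = np.full((2, n_sig), 1.0 / (2 * n_sig))

    def step(self, obs: float) -> None:
        prior = (1.0 - self.hazard) * self.joint + self.hazard * (
            self.pi[:, None] * self.joint.sum(axis=0)[None, :]
        )
        like = norm.pdf(obs, loc=self.mu[:, None], scale=self.sigma_grid[None, :])
        post = prior * like
        s = post.sum()
        if s <= 0 or not np.isfinite(s):
            post = prior
            s = post.sum()
        self.joint = post / s

    def predict(self) -> float:
        return float(self.joint.sum(axis=1) @ self.mu)

    @property
    def sigma_estimate(self) -> float:
        """Posterior mean of sigma."""
        return float(self.joint.sum(axis=0) @ self.sigma_grid)


def run_bayes_sigma(
    observations: np.ndarray, observer: BayesSigmaObserver | None = None
) -> np.ndarray:
    obs = np.asarray(observations).reshape(-1)
    observer = observer or BayesSigmaObserver()
    preds = np.empty(len(obs) - 1)
    for t in range(len(obs) - 1):
        observer.step(obs[t])
        preds[t] = observer.predict()
    return preds


def bayes_infer_sigma(observations: np.ndarray, **kw) -> BayesSigmaObserver:
    """Run the sigma-inferring observer over a stream and return it (its
    .sigma_estimate converges to the generating s.d. on stationary data)."""
    obs = np.asarray(observations).reshape(-1)
    if len(obs) < 2:
        raise ConfigurationError("need at least 2 observations")
    observer = BayesSigmaObserver(**kw)
    for x in obs:
        observer.step(float(x))
    return observer


def naive_predict(recent: np.ndarray) -> float:
    """Arithmetic mean of the two most recent values (one value: that value)."""
    recent = np.asarray(recent, dtype=float).reshape(-1)
    if len(recent) == 0:
        raise ConfigurationError("naive_predict needs at least one value")
    return float(recent[-2:].mean())


def run_naive(observations: np.ndarray) -> np.ndarray:
    obs = np.asarray(observations).reshape(-1)
    return np.array([naive_predict(obs[: t + 1]) for t in range(len(obs) - 1)])


# ---------------------------------------------------------------------------
# RNN baselines
# ---------------------------------------------------------------------------

RNN_HORIZONS = {"short": 5, "long": 50}


def make_rnn_baseline(
    variant: str = "short",
    d_in: int = 1,
    seed: int = 0,
    h: int | None = None,
    **config_kw,
) -> NeuraGemModel:
    """A conventional RNN: the same forward model with the fast substrate
    absent (Z permanently at its neutral zero value, never updated)."""
    if h is None:
        try:
            h = RNN_HORIZONS[variant]
        except KeyError:
            raise ConfigurationError(f"unknown RNN variant {variant!r}") from None
    cfg = TrainConfig(h=h, z_enabled=False, seed=seed, **config_kw)
    return NeuraGemModel(d_in=d_in, z_dim=2, gating_mode="multiplicative", config=cfg, seed=seed)


def train_rnn_baseline(
    variant: str, stream: ContextStream, seed: int = 0, h: int | None = None
) -> tuple[NeuraGemModel, Trajectory]:
    """Identical online training loop to the full model, Z absent; weights
    frozen for testing afterwards."""
    model = make_rnn_baseline(variant, d_in=stream.observations.shape[1], seed=seed, h=h)
    traj = run_training(model, stream)
    return model, traj


def horizon_sweep_distance_to_bayes(
    horizons, stream: ContextStream, seed: int = 0
) -> dict[int, float]:
    """L1 distance between RNN and ideal-observer predictions as a function of
    the input horizon (trained and evaluated on the given stream)."""
    bayes_preds = run_bayes(
        stream.observations,
        BayesObserver(mu=tuple(stream.generating_means[0]), sigma=stream.sigma),
    )
    out = {}
    for h in horizons:
        model = make_rnn_baseline("short", d_in=stream.observations.shape[1], seed=seed, h=h)
        run_training(model, stream)
        ev = evaluate_frozen(model, stream.observations)
        out[h] = float(np.abs(ev.predictions[:, 0] - bayes_preds).mean())
    return out
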