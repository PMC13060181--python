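"""Synthetic task generators.

Every input stream the experiments consume is generated here from a seed:

* the contextual switching task (CST) -- a 1-D Gaussian stream whose mean
  alternates covertly between two values in blocks of truncated-geometric
  length;
* a 5-D multi-timescale variant with five independent latent variables, each
  switching at its own rate;
* six-step one-hot "stories" emitted by one of two latent Markov chains under
  blocked / interleaved / mixed / random curricula;
* a 2-D three-cluster Gaussian stream presented in blocks (for the EM demo).

All generators return dataclasses carrying observations together with the
ground-truth latent labels and block boundaries, and are bit-reproducible
given the same seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class ConfigurationError(ValueError):
    """Raised when a generator spec is internally inconsistent."""


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------


@dataclass
class CSTSpec:
    """Contextual switching task parameters.

    Observations ~ N(means[s], sigma^2) where the latent context s strictly
    alternates between the two entries of ``means``; block lengths are
    geometric with mean ``block_mean``, truncated by rejection to
    [block_lo, block_hi].
    """

    means: tuple[float, float] = (0.2, 0.8)
    sigma: float = 0.3
    block_mean: float = 25.0
    block_lo: int = 15
    block_hi: int = 50
    n_blocks: int = 40

    def validate(self) -> None:
        if not (self.block_lo <= self.block_mean <= self.block_hi):
            raise ConfigurationError(
                f"block_mean {self.block_mean} outside [{self.block_lo}, {self.block_hi}]"
            )
        if self.sigma < 0:
            raise ConfigurationError("sigma must be >= 0")


@dataclass
class MultiScaleSpec:
    """Five independent latents, one per observation dimension, each with its
    own geometric block-length mean (no truncation)."""

    n_latents: int = 5
    block_means: tuple[float, ...] = (20.0, 60.0, 80.0, 120.0, 160.0)
    means: tuple[float, float] = (0.2, 0.8)
    sigma: float = 0.3
    n_steps: int = 4000

    def validate(self) -> None:
        if len(self.block_means) != self.n_latents:
            raise ConfigurationError("need one block mean per latent")
        if self.sigma < 0:
            raise ConfigurationError("sigma must be >= 0")


@dataclass
class ChainSpec:
    """Topology of the two story-generating Markov chains.

    Both chains share a one-hot state space of ``n_states`` states and the
    same start state. A story is six states long:

        start -> cid -> rnd -> choice -> tail -> end

    * start -> cid_states[c]      : deterministic, identifies context c (T_cid)
    * cid -> rnd_outcomes[.]      : uniform over the outcomes, identical in
                                    both contexts (T_rnd)
    * rnd -> choice_states[c]     : deterministic given context; the "third
                                    transition" whose prediction is diagnostic
    * choice -> tail_states[c]    : deterministic continuation
    * tail -> end_state           : deterministic shared terminal
    """

    n_states: int = 12
    start_state: int = 0
    cid_states: tuple[int, int] = (1, 2)
    rnd_outcomes: tuple[int, int] = (7, 8)
    choice_states: tuple[int, int] = (5, 6)
    tail_states: tuple[int, int] = (9, 10)
    end_state: int = 11

    def validate(self) -> None:
        used = {self.start_state, self.end_state}
        for pair in (self.cid_states, self.rnd_outcomes, self.choice_states, self.tail_states):
            used.update(pair)
        if max(used) >= self.n_states:
            raise ConfigurationError("state index exceeds n_states")
        if len(used) != 10:
            raise ConfigurationError("chain states must be distinct")


@dataclass
class ClusterSpec:
    """Three (by default) 2-D Gaussian clusters presented block-wise."""

    means: tuple[tuple[float, float], ...] = ((0.2, 0.2), (0.8, 0.2), (0.5, 0.8))
    sigma: float = 0.1
    block_mean: float = 25.0
    block_lo: int = 15
    block_hi: int = 50
    n_blocks: int = 40

    def validate(self) -> None:
        arr = np.asarray(self.means)
        d = np.linalg.norm(arr[:, None] - arr[None, :], axis=-1)
        if np.any(d[np.triu_indices(len(arr), 1)] == 0):
            raise ConfigurationError("cluster means must be pairwise distinct")


# ---------------------------------------------------------------------------
# stream containers
# ---------------------------------------------------------------------------


@dataclass
class ContextStream:
    """Generated observation sequence with ground truth.

    observations   : (T, d) float array
    latent_labels  : (T, n_latents) int array, ground-truth context per latent
    block_boundaries : sorted time indices where any latent switches
    block_ids      : (T, n_latents) int array, running block index per latent
    """

    observations: np.ndarray
    latent_labels: np.ndarray
    block_boundaries: np.ndarray
    block_ids: np.ndarray
    generating_means: np.ndarray
    sigma: float

    def __len__(self) -> int:
        return self.observations.shape[0]

    def to_frame(self) -> pd.DataFrame:
        d = self.observations.shape[1]
        n_lat = self.latent_labels.shape[1]
        cols = {"time": np.arange(len(self))}
        for j in range(d):
            cols[f"x{j}"] = self.observations[:, j]
        for j in range(n_lat):
            cols[f"latent{j}"] = self.latent_labels[:, j]
            cols[f"block{j}"] = self.block_ids[:, j]
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class StoryDataset:
    """One-hot story sequences from two latent Markov chains."""

    states: np.ndarray            # (T, n_states) one-hot
    state_ids: np.ndarray         # (T,) int
    context_ids: np.ndarray       # (n_stories,) 0/1
    story_boundaries: np.ndarray  # (n_stories,) start index of each story
    transition_types: np.ndarray  # (T,) str label of the transition entering each step
    curriculum: str
    chain_spec: ChainSpec = field(default_factory=ChainSpec)
    story_len: int = 6

    @property
    def n_stories(self) -> int:
        return len(self.context_ids)

    def to_frame(self) -> pd.DataFrame:
        story = np.repeat(np.arange(self.n_stories), self.story_len)
        return pd.DataFrame(
            {
                "time": np.arange(len(self.state_ids)),
                "story": story,
                "context": np.repeat(self.context_ids, self.story_len),
                "state": self.state_ids,
                "transition_type": self.transition_types,
            }
        )


@dataclass
class ClusterStream:
    """2-D points presented block-wise by cluster."""

    points: np.ndarray          # (T, 2)
    cluster_labels: np.ndarray  # (T,)
    cluster_means: np.ndarray   # (k, 2)
    cluster_covs: np.ndarray    # (k, 2, 2)
    block_boundaries: np.ndarray
    block_ids: np.ndarray

    def __len__(self) -> int:
        return self.points.shape[0]


# ---------------------------------------------------------------------------
# block lengths
# ---------------------------------------------------------------------------


def sample_block_length(mean: float, lo: int, hi: int, rng: np.random.Generator) -> int:
    """Draw one block length from a geometric distribution with the given
    untruncated mean, rejecting draws outside [lo, hi].

    The marginal is the geometric pmf renormalised over lo..hi.
    """
    if lo > hi:
        raise ConfigurationError(f"invalid bounds lo={lo} > hi={hi}")
    if not (lo <= mean <= hi):
        raise ConfigurationError(f"mean {mean} outside [{lo}, {hi}]")
    if lo == hi:
        return lo
    p = 1.0 / mean
    while True:
        k = rng.geometric(p)
        if lo <= k <= hi:
            return int(k)


def truncated_geometric_pmf(mean: float, lo: int, hi: int) -> np.ndarray:
    """Exact renormalised pmf over lo..hi (oracle for sample_block_length)."""
    p = 1.0 / mean
    k = np.arange(lo, hi + 1)
    w = (1 - p) ** (k - 1) * p
    return w / w.sum()


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def _alternating_labels(block_lengths: np.ndarray, first: int = 0) -> np.ndarray:
    labels = []
    s = first
    for L in block_lengths:
        labels.extend([s] * int(L))
        s = 1 - s
    return np.asarray(labels, dtype=np.int64)


def generate_cst(spec: CSTSpec | None = None, seed: int = 0) -> ContextStream:
    """Generate a contextual switching task stream.

    The latent strictly alternates each block, starting with context 0
    (the lower mean).
    """
    spec = spec or CSTSpec()
    spec.validate()
    rng = np.random.default_rng(seed)
    lengths = np.array(
        [sample_block_length(spec.block_mean, spec.block_lo, spec.block_hi, rng)
         for _ in range(spec.n_blocks)]
    )
    labels = _alternating_labels(lengths)
    means = np.asarray(spec.means)[labels]
    obs = rng.normal(means, spec.sigma)
    block_ids = np.repeat(np.arange(spec.n_blocks), lengths)
    boundaries = np.cumsum(lengths)[:-1]
    return ContextStream(
        observations=obs[:, None],
        latent_labels=labels[:, None],
        block_boundaries=boundaries,
        block_ids=block_ids[:, None],
        generating_means=np.asarray(spec.means)[None, :],
        sigma=spec.sigma,
    )


def generate_fixed_block_cst(
    block_len: int,
    n_steps: int,
    means: tuple[float, float] = (0.2, 0.8),
    sigma: float = 0.3,
    seed: int = 0,
) -> ContextStream:
    """CST variant with a constant block length (test grids for unseen block
    sizes use this so the x-axis is a single block size)."""
    rng = np.random.default_rng(seed)
    n_blocks = int(np.ceil(n_steps / block_len))
    lengths = np.full(n_blocks, block_len)
    labels = _alternating_labels(lengths)[:n_steps]
    obs = rng.normal(np.asarray(means)[labels], sigma)
    block_ids = np.repeat(np.arange(n_blocks), lengths)[:n_steps]
    boundaries = np.flatnonzero(np.diff(labels) != 0) + 1
    return ContextStream(
        observations=obs[:, None],
        latent_labels=labels[:, None],
        block_boundaries=boundaries,
        block_ids=block_ids[:, None],
        generating_means=np.asarray(means)[None, :],
        sigma=sigma,
    )


def generate_multiscale(spec: MultiScaleSpec | None = None, seed: int = 0) -> ContextStream:
    """5-D stream; dimension i is driven solely by latent i, whose blocks are
    geometric with mean spec.block_means[i]. Latents are mutually independent."""
    spec = spec or MultiScaleSpec()
    spec.validate()
    rng = np.random.default_rng(seed)
    T = spec.n_steps
    labels = np.zeros((T, spec.n_latents), dtype=np.int64)
    block_ids = np.zeros((T, spec.n_latents), dtype=np.int64)
    for j, bm in enumerate(spec.block_means):
        t, s, b = 0, 0, 0
        while t < T:
            L = max(1, int(rng.geometric(1.0 / bm)))
            labels[t : t + L, j] = s
            block_ids[t : t + L, j] = b
            t += L
            s = 1 - s
            b += 1
    means = np.asarray(spec.means)[labels]
    obs = rng.normal(means, spec.sigma)
    switches = np.flatnonzero((np.diff(labels, axis=0) != 0).any(axis=1)) + 1
    return ContextStream(
        observations=obs,
        latent_labels=labels,
        block_boundaries=switches,
        block_ids=block_ids,
        generating_means=np.tile(np.asarray(spec.means), (spec.n_latents, 1)),
        sigma=spec.sigma,
    )


CURRICULA = ("blocked", "interleaved", "mixed", "random")


def _curriculum_contexts(
    curriculum: str,
    n_stories: int,
    rng: np.random.Generator,
    block_run: int = 40,
    mixed_block_run: int = 40,
    interleaved_stories: int | None = None,
) -> np.ndarray:
    if curriculum == "blocked":
        return (np.arange(n_stories) // block_run) % 2
    if curriculum == "interleaved":
        return np.arange(n_stories) % 2
    if curriculum == "mixed":
        n_int = interleaved_stories if interleaved_stories is not None else n_stories // 2
        inter = np.arange(n_int) % 2
        rest = n_stories - n_int
        blocked = (np.arange(rest) // mixed_block_run) % 2
        return np.concatenate([inter, blocked])
    if curriculum == "random":
        return rng.integers(0, 2, size=n_stories)
    raise ConfigurationError(f"unknown curriculum {curriculum!r}; expected one of {CURRICULA}")


def generate_stories(
    curriculum: str,
    n_stories: int = 80,
    chain_spec: ChainSpec | None = None,
    seed: int = 0,
    interleaved_stories: int | None = None,
) -> StoryDataset:
    """Generate six-step one-hot stories from the two latent Markov chains.

    Curricula: blocked (context constant in runs of 40 stories), interleaved
    (context alternates every story, same total story count), mixed
    (interleaved phase then blocked phase), random (i.i.d. context per story).
    ``interleaved_stories`` sets the mixed curriculum's interleaved-phase
    length (default: half the stories).
    """
    cs = chain_spec or ChainSpec()
    cs.validate()
    rng = np.random.default_rng(seed)
    contexts = _curriculum_contexts(
        curriculum, n_stories, rng, interleaved_stories=interleaved_stories
    )
    state_ids = []
    ttypes = []
    for c in contexts:
        r = int(rng.integers(0, 2))
        story = [
            cs.start_state,
            cs.cid_states[c],
            cs.rnd_outcomes[r],
            cs.choice_states[c],
            cs.tail_states[c],
            cs.end_state,
        ]
        state_ids.extend(story)
        ttypes.extend(["start", "T_cid", "T_rnd", "T_diag", "deterministic", "deterministic"])
    state_ids = np.asarray(state_ids, dtype=np.int64)
    onehot = np.zeros((len(state_ids), cs.n_states))
    onehot[np.arange(len(state_ids)), state_ids] = 1.0
    return StoryDataset(
        states=onehot,
        state_ids=state_ids,
        context_ids=np.asarray(contexts, dtype=np.int64),
        story_boundaries=np.arange(len(contexts)) * 6,
        transition_types=np.asarray(ttypes),
        curriculum=curriculum,
        chain_spec=cs,
    )


def generate_cluster_stream(
    spec: ClusterSpec | None = None, n_clusters: int = 3, seed: int = 0
) -> ClusterStream:
    """2-D Gaussian clusters presented block-wise (clusters cycle 0,1,2,...)."""
    spec = spec or ClusterSpec()
    spec.validate()
    if len(spec.means) != n_clusters:
        raise ConfigurationError("n_clusters must match spec.means")
    rng = np.random.default_rng(seed)
    lengths = np.array(
        [sample_block_length(spec.block_mean, spec.block_lo, spec.block_hi, rng)
         for _ in range(spec.n_blocks)]
    )
    labels = np.repeat(np.arange(spec.n_blocks) % n_clusters, lengths)
    means = np.asarray(spec.means)
    pts = rng.normal(means[labels], spec.sigma)
    covs = np.stack([np.eye(2) * spec.sigma**2 for _ in range(n_clusters)])
    return ClusterStream(
        points=pts,
        cluster_labels=labels,
        cluster_means=means,
        cluster_covs=covs,
        block_boundaries=np.cumsum(lengths)[:-1],
        block_ids=np.repeat(np.arange(spec.n_blocks), lengths),
    )
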