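"""End-to-end experiment drivers: generate data, train, test with frozen
weights, analyze, and emit tidy result tables.

Experiments
-----------
cst-generalization : train each model on the contextual switching task for 40
    blocks, freeze W, and evaluate on the three generalization grids (unseen
    block lengths, unseen latent means, increased observation noise), plus
    the noise-slope readout against the variance-inferring ideal observer.
multiscale : the two-population (Z_fast/Z_slow) model on the 5-D
    multi-timescale stream; reports shift-null-adjusted Z-latent alignments,
    per-dimension MSEs, and the alignment-vs-error correlation.
sequence-curricula : the story prediction task under blocked / interleaved /
    mixed / random curricula (with the Z-disabled-interleaved manipulation),
    evaluated in a random-curriculum phase with boosted Z updating.
em-demo : blocked 2-D cluster stream; frozen-W Z inference is compared with
    classical EM cluster assignments across training checkpoints.

All randomness derives from the experiment seed list; paired model
comparisons always share streams seed-for-seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import analysis, nn
from .baselines import BayesSigmaObserver, make_rnn_baseline, run_bayes_sigma
from .model import (
    NeuraGemModel,
    TrainConfig,
    ZPopulation,
    evaluate_frozen,
    run_training,
    two_population_model,
)
from .tasks import (
    CSTSpec,
    ConfigurationError,
    MultiScaleSpec,
    generate_cluster_stream,
    generate_cst,
    generate_fixed_block_cst,
    generate_multiscale,
    generate_stories,
)

BLOCK_GRID = (10, 15, 20, 25, 30, 40, 50, 60, 80)
MEANS_GRID = tuple(np.round(np.arange(-0.2, 1.2001, 0.1), 10))
NOISE_GRID = (0.3, 0.35, 0.4, 0.45, 0.5)
TEST_LEN = 240  # steps per test condition

EXPERIMENTS = ("cst-generalization", "multiscale", "sequence-curricula", "em-demo")


@dataclass
class ExperimentConfig:
    experiment: str = "cst-generalization"
    models: tuple[str, ...] = ("neuragem", "rnn-short", "rnn-long")
    seeds: tuple[int, ...] = tuple(range(20))
    block_grid: tuple[int, ...] = BLOCK_GRID
    means_grid: tuple[float, ...] = MEANS_GRID
    noise_grid: tuple[float, ...] = NOISE_GRID
    test_len: int = TEST_LEN
    curricula: tuple[str, ...] = ("blocked", "interleaved", "mixed", "z-disabled-interleaved")
    out_dir: str = "results"

    def validate(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ConfigurationError(f"unknown experiment {self.experiment!r}")
        if len(self.seeds) == 0:
            raise ConfigurationError("seed list must be non-empty")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as f:
            data = yaml.safe_load(f) or {}
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in data.items()})
        cfg.validate()
        return cfg


def _test_seed(seed: int, tag: int) -> int:
    return (seed * 100003 + 7919 * tag + 13) % (2**31 - 1)


# ---------------------------------------------------------------------------
# CST generalization
# ---------------------------------------------------------------------------


def make_model(name: str, seed: int, d_in: int = 1) -> NeuraGemModel:
    """Construct one of the standard CST models by name."""
    if name == "neuragem":
        return NeuraGemModel(d_in=d_in, z_dim=2, config=TrainConfig(h=5, seed=seed), seed=seed)
    if name == "neuragem-add":
        return NeuraGemModel(
            d_in=d_in, z_dim=2, gating_mode="additive",
            config=TrainConfig(h=5, seed=seed), seed=seed,
        )
    if name == "rnn-short":
        return make_rnn_baseline("short", d_in=d_in, seed=seed)
    if name == "rnn-long":
        return make_rnn_baseline("long", d_in=d_in, seed=seed)
    raise ConfigurationError(f"unknown model {name!r}")


def train_cst_models(seed: int, models: tuple[str, ...]) -> dict[str, NeuraGemModel]:
    """Train the requested models on the same CST stream (paired seeds),
    then freeze their weights."""
    stream = generate_cst(CSTSpec(), seed=seed)
    trained = {}
    for name in models:
        model = make_model(name, seed)
        run_training(model, stream)
        trained[name] = model
    return trained


def _condition_mse(model: NeuraGemModel, observations: np.ndarray) -> float:
    ev = evaluate_frozen(model.copy(), observations)
    return float(ev.squared_errors.mean())


def evaluate_cst_generalization(
    trained: dict[str, NeuraGemModel],
    seed: int,
    block_grid=BLOCK_GRID,
    means_grid=MEANS_GRID,
    noise_grid=NOISE_GRID,
    test_len: int = TEST_LEN,
) -> pd.DataFrame:
    """Frozen-weight evaluation of trained models on the three test grids.

    Returns one row per (model, manipulation, condition) with the
    time-averaged MSE; the ideal observer with variance inference is run on
    the noise streams as the reference for slope readouts.
    """
    rows = []
    n_blocks_test = max(3, int(np.ceil(test_len / 25)))
    for i, L in enumerate(block_grid):
        stream = generate_fixed_block_cst(int(L), test_len, seed=_test_seed(seed, i))
        for name, model in trained.items():
            rows.append(dict(model=name, manipulation="block_size", condition=float(L),
                             mse=_condition_mse(model, stream.observations)))
    for i, m in enumerate(means_grid):
        # each novel mean probed as a stationary stream (one long block)
        stream = generate_fixed_block_cst(
            test_len, test_len, means=(float(m), float(m)),
            seed=_test_seed(seed, 100 + i),
        )
        for name, model in trained.items():
            rows.append(dict(model=name, manipulation="means", condition=float(m),
                             mse=_condition_mse(model, stream.observations)))
    for i, s in enumerate(noise_grid):
        spec = CSTSpec(sigma=float(s), n_blocks=n_blocks_test)
        stream = generate_cst(spec, seed=_test_seed(seed, 200 + i))
        bayes_preds = run_bayes_sigma(stream.observations, BayesSigmaObserver())
        bayes_mse = float(((bayes_preds - stream.observations[1:, 0]) ** 2).mean())
        rows.append(dict(model="bayes-sigma", manipulation="noise", condition=float(s),
                         mse=bayes_mse))
        for name, model in trained.items():
            rows.append(dict(model=name, manipulation="noise", condition=float(s),
                             mse=_condition_mse(model, stream.observations)))
    df = pd.DataFrame(rows)
    df.insert(0, "seed", seed)
    return df


def cst_aggregates(df: pd.DataFrame) -> pd.DataFrame:
    """Per-seed aggregate MSE per manipulation plus each model's noise slope:
    the growth of prediction error beyond the irreducible observation
    variance, i.e. the OLS slope of (MSE - sigma^2) against sigma."""
    out = []
    for (seed, model), g in df[df.model != "bayes-sigma"].groupby(["seed", "model"]):
        rec = dict(seed=seed, model=model)
        for manip in ("block_size", "means", "noise"):
            rec[f"agg_{manip}"] = g[g.manipulation == manip].mse.mean()
        noise = g[g.manipulation == "noise"].sort_values("condition")
        if len(noise) >= 2:
            sig = noise.condition.to_numpy()
            excess = noise.mse.to_numpy() - sig**2
            rec["noise_slope"] = float(np.polyfit(sig, excess, 1)[0])
        out.append(rec)
    return pd.DataFrame(out)


def run_cst_experiment(
    seeds,
    models=("neuragem", "rnn-short", "rnn-long"),
    block_grid=BLOCK_GRID,
    means_grid=MEANS_GRID,
    noise_grid=NOISE_GRID,
    test_len: int = TEST_LEN,
    progress=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full CST generalization experiment. Returns (per-condition table,
    per-seed aggregate table)."""
    frames = []
    for seed in seeds:
        trained = train_cst_models(seed, tuple(models))
        frames.append(
            evaluate_cst_generalization(
                trained, seed, block_grid, means_grid, noise_grid, test_len
            )
        )
        if progress:
            progress(seed)
    df = pd.concat(frames, ignore_index=True)
    return df, cst_aggregates(df)


# ---------------------------------------------------------------------------
# multi-timescale specialization
# ---------------------------------------------------------------------------


def multiscale_run(
    seed: int, n_train: int = 4000, n_test: int = 2000
) -> dict:
    """Train the two-population model on the 5-D stream, freeze W, and
    measure Z-latent alignments and per-dimension MSE on a test stream."""
    train_stream = generate_multiscale(MultiScaleSpec(n_steps=n_train), seed=seed)
    model = two_population_model(d_in=5, seed=seed)
    model.config.n_blocks = 0  # block count varies per latent; no gate on length
    model.run(train_stream.observations, train_w=True)
    model.w_frozen = True
    test_stream = generate_multiscale(
        MultiScaleSpec(n_steps=n_test), seed=_test_seed(seed, 500)
    )
    traj = model.run(test_stream.observations, train_w=False, z_enabled=True)
    n = len(traj.errors)
    act = np.stack([
        nn.z_activity(z, model.z_transform, model.fast.slices) for z in traj.z
    ])
    labels = test_stream.latent_labels[:n]
    mse_dim = traj.per_dim_squared_errors.mean(axis=0)
    rng = np.random.default_rng(_test_seed(seed, 501))
    corr = np.zeros((model.z_dim, 5))
    for u in range(model.z_dim):
        for d in range(5):
            corr[u, d] = analysis.shift_null_correlation(
                act[:, u], labels[:, d], rng=rng
            )
    return dict(seed=seed, corr=corr, mse_dim=mse_dim,
                fast_units=list(range(model.fast.slices[0].start, model.fast.slices[0].stop)),
                slow_units=list(range(model.fast.slices[1].start, model.fast.slices[1].stop)))


def multiscale_specialization(seeds, fast_dims=(0, 1), slow_dims=(3, 4)) -> dict:
    """Alignment-vs-error correlations across runs.

    One observation per (seed, latent dimension, Z unit): the unit's
    shift-null-adjusted correlation with that latent paired with the
    prediction MSE on the corresponding input dimension. Pearson r over all
    observations, separately for the fast population on the fast latents and
    the slow population on the slow latents.
    """
    runs = [multiscale_run(s) for s in seeds]
    out = {}
    for tag, units_key, dims in (
        ("fast", "fast_units", fast_dims),
        ("slow", "slow_units", slow_dims),
    ):
        xs, ys, rows = [], [], []
        for r in runs:
            for d in dims:
                for u in r[units_key]:
                    xs.append(r["corr"][u, d])
                    ys.append(r["mse_dim"][d])
                    rows.append(dict(seed=r["seed"], unit=u, dim=d,
                                     alignment=r["corr"][u, d], mse=r["mse_dim"][d]))
        xs, ys = np.asarray(xs), np.asarray(ys)
        out[f"r_{tag}"] = float(np.corrcoef(xs, ys)[0, 1])
        out[f"n_{tag}"] = len(xs)
        out[f"points_{tag}"] = pd.DataFrame(rows)
    out["runs"] = runs
    return out


# ---------------------------------------------------------------------------
# sequence curricula
# ---------------------------------------------------------------------------

SEQ_H = 6
SEQ_ALPHA_Z = 0.2
SEQ_Z_DECAY = 3e-5
SEQ_TEST_ALPHA_Z = 0.4
SEQ_TEST_Z_DECAY = 4e-4
SEQ_TEST_Z_UPDATES = 5


def make_sequence_model(seed: int, kind: str = "neuragem", n_states: int = 12) -> NeuraGemModel:
    if kind == "neuragem":
        cfg = TrainConfig(h=SEQ_H, seed=seed)
        return NeuraGemModel(
            d_in=n_states, z_dim=2, config=cfg,
            populations=[ZPopulation(2, SEQ_ALPHA_Z, SEQ_Z_DECAY)], seed=seed,
        )
    if kind == "rnn-short":
        return make_rnn_baseline("short", d_in=n_states, seed=seed, h=SEQ_H)
    if kind == "rnn-long":
        return make_rnn_baseline("long", d_in=n_states, seed=seed, h=200)
    raise ConfigurationError(f"unknown sequence model {kind!r}")


def boost_z(model: NeuraGemModel, alpha: float = SEQ_TEST_ALPHA_Z,
            decay: float = SEQ_TEST_Z_DECAY, updates: int = SEQ_TEST_Z_UPDATES) -> None:
    """Raise the fast-substrate update and decay rates (random-phase testing)."""
    for pop, opt in zip(model.fast.populations, model.fast.opts):
        pop.alpha = alpha
        pop.decay = decay
        opt.lr = alpha
    model.config.z_updates_per_step = updates


def run_sequence_curriculum(
    curriculum: str,
    seed: int,
    model_kind: str = "neuragem",
    n_train_stories: int = 1600,
    n_test_stories: int = 80,
    interleaved_stories: int | None = None,
    z_disabled_interleaved: bool = False,
) -> dict:
    """Train under one curriculum, then evaluate in the random phase.

    The test phase freezes W, boosts the Z rates (the model receives no
    trial-boundary cues, so residual Z carries over between stories), and
    reports third-transition accuracy plus the |beta| regressions of Z
    activity on the T_cid / T_rnd outcomes.
    """
    train_set = generate_stories(
        "mixed" if z_disabled_interleaved else curriculum,
        n_train_stories, seed=seed, interleaved_stories=interleaved_stories,
    )
    model = make_sequence_model(seed, model_kind, train_set.chain_spec.n_states)
    obs = train_set.states
    if z_disabled_interleaved:
        n_int = interleaved_stories if interleaved_stories is not None else n_train_stories // 2
        split = n_int * train_set.story_len
        for t in range(split):
            model.online_step(obs, t, train_w=True, z_enabled=False)
        for t in range(split, len(obs) - 1):
            model.online_step(obs, t, train_w=True, z_enabled=True)
    else:
        model.run(obs, train_w=True)
    model.w_frozen = True

    test_set = generate_stories("random", n_test_stories, seed=_test_seed(seed, 900))
    if model.config.z_enabled:
        boost_z(model)
    traj = model.run(test_set.states, train_w=False, z_enabled=True)
    acc = analysis.sequence_accuracy(traj.predictions, test_set)
    act = np.stack([
        nn.z_activity(z, model.z_transform, model.fast.slices) for z in traj.z
    ]) if model.config.z_enabled else traj.z
    betas = analysis.regress_z_on_transitions(act, test_set)
    return dict(curriculum="z-disabled-interleaved" if z_disabled_interleaved else curriculum,
                model=model_kind, seed=seed, accuracy=acc, **{f"beta_{k}": v for k, v in betas.items()})


def run_sequence_experiment(
    seeds,
    curricula=("blocked", "interleaved", "mixed", "z-disabled-interleaved"),
    model_kind: str = "neuragem",
) -> pd.DataFrame:
    rows = []
    for seed in seeds:
        for cur in curricula:
            if cur == "z-disabled-interleaved":
                rows.append(run_sequence_curriculum(
                    "mixed", seed, model_kind, z_disabled_interleaved=True))
            else:
                rows.append(run_sequence_curriculum(cur, seed, model_kind))
    df = pd.DataFrame(rows)
    # mixed-curriculum bimodality readout: split runs by above/below-average accuracy
    mixed = df[df.curriculum == "mixed"]
    if len(mixed) > 1:
        mean_acc = mixed.accuracy.mean()
        df.loc[df.curriculum == "mixed", "mixed_group"] = np.where(
            mixed.accuracy > mean_acc, "above", "below"
        )
    return df


# ---------------------------------------------------------------------------
# EM demo
# ---------------------------------------------------------------------------


def _pc1_partition_alignment(z_activity: np.ndarray, labels: np.ndarray, n_clusters: int = 3,
                             seed: int = 0) -> float:
    """Adjusted Rand index between a k-partition of the Z PC1 projection and
    the ground-truth cluster labels."""
    from sklearn.cluster import KMeans
    from sklearn.decomposition import PCA
    from sklearn.metrics import adjusted_rand_score

    pc1 = PCA(n_components=1).fit_transform(z_activity).reshape(-1, 1)
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed).fit(pc1)
    return float(adjusted_rand_score(labels, km.labels_))


def run_em_demo(seed: int, n_checkpoints: int = 4) -> pd.DataFrame:
    """Alternate training with frozen-W Z-inference snapshots.

    At each checkpoint the current model is copied, W is held fixed, Z is
    optimized online over the blocked cluster stream, and the alignment
    between the Z PC1 partition and ground truth is recorded. Classical EM
    (a Gaussian mixture fitted to the shuffled points) provides the
    reference alignment.
    """
    from sklearn.metrics import adjusted_rand_score
    from sklearn.mixture import GaussianMixture

    stream = generate_cluster_stream(seed=seed)
    obs = stream.points
    model = NeuraGemModel(d_in=2, z_dim=2, config=TrainConfig(h=5, seed=seed), seed=seed)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(obs))
    gm = GaussianMixture(n_components=3, random_state=seed).fit(obs[perm])
    em_alignment = float(adjusted_rand_score(stream.cluster_labels, gm.predict(obs)))

    n = len(obs) - 1
    marks = [int(n * (k + 1) / n_checkpoints) for k in range(n_checkpoints)]
    rows = []
    t0 = 0
    for k, t1 in enumerate(marks):
        for t in range(t0, t1):
            model.online_step(obs, t, train_w=True)
        t0 = t1
        probe = model.copy()
        probe.w_frozen = True
        traj = probe.run(obs, train_w=False, z_enabled=True)
        act = np.stack([
            nn.z_activity(z, probe.z_transform, probe.fast.slices) for z in traj.z
        ])
        ari = _pc1_partition_alignment(act, stream.cluster_labels[:len(act)], seed=seed)
        rows.append(dict(seed=seed, checkpoint=k + 1, fraction_trained=t1 / n,
                         alignment=ari, em_alignment=em_alignment))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# dispatch, manifests
# ---------------------------------------------------------------------------


def _manifest(config: ExperimentConfig) -> dict:
    blob = json.dumps(asdict(config), sort_keys=True, default=str)
    import neuragem

    return dict(
        config=asdict(config),
        config_hash=hashlib.sha256(blob.encode()).hexdigest()[:16],
        package_version=getattr(neuragem, "__version__", "unknown"),
        numpy_version=np.__version__,
    )


def run_experiment(config: ExperimentConfig, out_dir: str | Path | None = None) -> dict:
    """Run one experiment end-to-end and write result tables + manifest."""
    config.validate()
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result: dict = {}
    failures = []
    if config.experiment == "cst-generalization":
        frames = []
        for seed in config.seeds:
            try:
                trained = train_cst_models(seed, tuple(config.models))
                frames.append(evaluate_cst_generalization(
                    trained, seed, config.block_grid, config.means_grid,
                    config.noise_grid, config.test_len))
            except Exception as exc:  # pragma: no cover - per-seed resilience
                failures.append(dict(seed=seed, error=repr(exc)))
        df = pd.concat(frames, ignore_index=True)
        agg = cst_aggregates(df)
        df.to_csv(out / "cst_conditions.csv", index=False)
        agg.to_csv(out / "cst_aggregates.csv", index=False)
        summary = agg.groupby("model").mean(numeric_only=True)
        result = dict(summary=summary.to_dict(), n_seeds=len(frames))
    elif config.experiment == "multiscale":
        res = multiscale_specialization(config.seeds)
        res["points_fast"].to_csv(out / "multiscale_fast.csv", index=False)
        res["points_slow"].to_csv(out / "multiscale_slow.csv", index=False)
        result = dict(r_fast=res["r_fast"], r_slow=res["r_slow"],
                      n_fast=res["n_fast"], n_slow=res["n_slow"])
    elif config.experiment == "sequence-curricula":
        df = run_sequence_experiment(config.seeds, config.curricula)
        df.to_csv(out / "sequence_curricula.csv", index=False)
        result = dict(
            accuracy_by_curriculum=df.groupby("curriculum").accuracy.mean().to_dict()
        )
    elif config.experiment == "em-demo":
        frames = [run_em_demo(seed) for seed in config.seeds]
        df = pd.concat(frames, ignore_index=True)
        df.to_csv(out / "em_demo.csv", index=False)
        result = dict(
            alignment_by_checkpoint=df.groupby("checkpoint").alignment.mean().to_dict()
        )
    manifest = _manifest(config)
    manifest["failures"] = failures
    with open(out / "manifest.json", "w") as f:
        json.dump(dict(manifest, result=result), f, indent=2, default=str)
    return result
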