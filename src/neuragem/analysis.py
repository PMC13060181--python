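"""Metrics and population analyses computed from logged trajectories.

Covers the behavioral readouts (trial-by-trial learning rate, switch-aligned
error traces, block MSE, distance to the ideal observer), population-geometry
measures (cross-condition generalization performance, cosine similarity
across context blocks, structure in the Z projections of the additive
variant), dynamical-systems probes (autonomous rollouts, fixed-point
detection, response-bias curves), and the sequence-task quantifications
(third-transition accuracy, Z-on-transition regressions, shift-null adjusted
correlations).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.decomposition import PCA
from sklearn.svm import SVC

from . import nn
from .model import NeuraGemModel
from .tasks import StoryDataset


class AnalysisError(ValueError):
    """Raised when a record does not support the requested analysis."""


@dataclass
class PopulationRecord:
    """Logged population activity sharing one time axis."""

    hidden: np.ndarray          # (T, 32)
    z: np.ndarray               # (T, z_dim)
    latent_labels: np.ndarray   # (T,)
    block_ids: np.ndarray       # (T,)
    inputs: np.ndarray          # (T, d)
    predictions: np.ndarray     # (T, d)

    def __post_init__(self):
        T = self.hidden.shape[0]
        for name in ("z", "latent_labels", "block_ids", "inputs", "predictions"):
            if getattr(self, name).shape[0] != T:
                raise AnalysisError(f"{name} does not share the record's time axis")


def record_from(trajectory, stream) -> PopulationRecord:
    """Align a model trajectory (one row per online step t, predicting t+1)
    with its generating stream's ground truth."""
    n = len(trajectory.errors)
    return PopulationRecord(
        hidden=trajectory.hidden,
        z=trajectory.z,
        latent_labels=stream.latent_labels[:n, 0],
        block_ids=stream.block_ids[:n, 0],
        inputs=stream.observations[:n],
        predictions=trajectory.predictions,
    )


# ---------------------------------------------------------------------------
# behavioral metrics
# ---------------------------------------------------------------------------


def behavioral_learning_rate(predictions: np.ndarray, observations: np.ndarray) -> np.ndarray:
    """eta_t = (xhat_{t+1} - xhat_t) / (x_t - xhat_t + 1e-6).

    The fraction of the previous prediction error corrected by the next
    prediction. Series are aligned so predictions[t] is the prediction of
    observations[t]. Returns one value per t >= 1.
    """
    predictions = np.asarray(predictions, dtype=float).reshape(-1)
    observations = np.asarray(observations, dtype=float).reshape(-1)
    if len(predictions) < 2:
        raise AnalysisError("need at least 2 predictions")
    num = predictions[1:] - predictions[:-1]
    den = observations[:-1] - predictions[:-1] + 1e-6
    return num / den


def switch_aligned_error(
    errors: np.ndarray,
    boundaries: np.ndarray,
    window: tuple[int, int] = (-5, 15),
) -> tuple[np.ndarray, np.ndarray]:
    """Average error segments aligned to each switch time.

    Returns (mean trace, s.e.m. trace) over the window [window[0], window[1])
    relative to each boundary; boundaries whose window falls outside the
    series are skipped.
    """
    errors = np.asarray(errors, dtype=float)
    boundaries = np.asarray(boundaries, dtype=int)
    if len(boundaries) == 0:
        raise AnalysisError("need at least one boundary")
    lo, hi = window
    segs = []
    for b in boundaries:
        if b + lo >= 0 and b + hi <= len(errors):
            segs.append(errors[b + lo : b + hi])
    if not segs:
        raise AnalysisError("no boundary window fits inside the series")
    segs = np.asarray(segs)
    mean = segs.mean(axis=0)
    sem = segs.std(axis=0, ddof=1) / np.sqrt(len(segs)) if len(segs) > 1 else np.zeros_like(mean)
    return mean, sem


def block_mse(errors: np.ndarray, block_ids: np.ndarray, mode: str = "whole") -> np.ndarray:
    """Per-block error averages.

    whole : mean over the block; end : mean over its final 10 steps
    (a shorter block uses all its steps, with a warning).
    """
    errors = np.asarray(errors, dtype=float)
    block_ids = np.asarray(block_ids)
    if errors.shape[0] != block_ids.shape[0]:
        raise AnalysisError("errors and block ids must partition the same series")
    out = []
    for b in np.unique(block_ids):
        e = errors[block_ids == b]
        if mode == "whole":
            out.append(e.mean())
        elif mode == "end":
            if len(e) < 10:
                warnings.warn(f"block {b} shorter than 10 steps; using all {len(e)}")
            out.append(e[-10:].mean())
        else:
            raise AnalysisError(f"unknown mode {mode!r}")
    return np.asarray(out)


def distance_to_bayes(model_preds: np.ndarray, bayes_preds: np.ndarray) -> float:
    """Mean absolute deviation between prediction series."""
    a = np.asarray(model_preds, dtype=float).reshape(-1)
    b = np.asarray(bayes_preds, dtype=float).reshape(-1)
    if a.shape != b.shape:
        raise AnalysisError("series not aligned")
    return float(np.abs(a - b).mean())


# ---------------------------------------------------------------------------
# population geometry
# ---------------------------------------------------------------------------


def ccgp(record: PopulationRecord, seed: int = 0) -> float:
    """Cross-condition generalization performance of a context decoder.

    Within each context, steps are split by whether the instantaneous input
    is above or below that context's mean input. A linear maximum-margin
    classifier decodes context from hidden activity on one stimulus
    condition and is tested on the complementary one; the two directions are
    averaged. Z activity is excluded (hidden units only).
    """
    ctx = np.asarray(record.latent_labels)
    contexts = np.unique(ctx)
    if len(contexts) != 2:
        raise AnalysisError("CCGP needs exactly two contexts present")
    x = record.inputs[:, 0]
    cond = np.zeros(len(ctx), dtype=int)  # 0 below context mean, 1 above
    for c in contexts:
        m = ctx == c
        cond[m] = (x[m] > x[m].mean()).astype(int)
    for c in contexts:
        for s in (0, 1):
            if not np.any((ctx == c) & (cond == s)):
                raise AnalysisError(f"context {c} lacks stimulus condition {s}")
    H = record.hidden
    accs = []
    for train_cond in (0, 1):
        tr = cond == train_cond
        te = ~tr
        clf = SVC(kernel="linear", C=1.0, random_state=seed)
        clf.fit(H[tr], ctx[tr])
        accs.append(clf.score(H[te], ctx[te]))
    return float(np.mean(accs))


def block_cosine_similarity(record: PopulationRecord, blocks: slice = slice(0, 10)) -> float:
    """Cosine similarity between successive blocks' mean hidden vectors,
    averaged over the selected (early-training) blocks."""
    ids = np.unique(record.block_ids)
    if len(ids) < 2:
        raise AnalysisError("need at least two blocks")
    means = np.stack([record.hidden[record.block_ids == b].mean(axis=0) for b in ids])
    sims = []
    for i in range(len(ids) - 1):
        a, b = means[i], means[i + 1]
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        sims.append(float(a @ b / (na * nb)) if na > 0 and nb > 0 else 0.0)
    return float(np.mean(np.asarray(sims)[blocks]))


def z_projection_asymmetry(model: NeuraGemModel, record: PopulationRecord) -> pd.DataFrame:
    """Structure in the learnable Z -> recurrent projections (additive variant).

    Hidden units are grouped by context preference (higher mean activity in
    context A vs B). For each block, the most-active Z component is
    identified and its outgoing weights are averaged separately over the two
    unit groups. Returns one row per block with columns
    (block, z_component, w_pref_A, w_pref_B).
    """
    if model.mode != "additive":
        raise AnalysisError("Z projections are fixed in the multiplicative variant")
    ctx = record.latent_labels
    contexts = np.unique(ctx)
    if len(contexts) != 2:
        raise AnalysisError("need two contexts")
    mean_a = record.hidden[ctx == contexts[0]].mean(axis=0)
    mean_b = record.hidden[ctx == contexts[1]].mean(axis=0)
    prefers_a = mean_a >= mean_b  # ties -> A
    H = nn.HIDDEN
    # outgoing weights of Z unit k: its LSTM input row, averaged over the 4 gates
    Wz = model.net.params["Wx"][H:, :]  # (z_dim, 4H)
    per_unit = Wz.reshape(model.z_dim, 4, H).mean(axis=1)  # (z_dim, H)
    rows = []
    for b in np.unique(record.block_ids):
        m = record.block_ids == b
        k = int(np.argmax(np.abs(record.z[m]).mean(axis=0)))
        rows.append(
            dict(
                block=int(b),
                z_component=k,
                w_pref_A=float(per_unit[k][prefers_a].mean()),
                w_pref_B=float(per_unit[k][~prefers_a].mean())
                if np.any(~prefers_a)
                else np.nan,
            )
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------


def autonomous_rollout(
    model: NeuraGemModel,
    init_input: np.ndarray,
    n_steps: int,
    Z: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Evolve the trained network without external drive.

    The network is initialised with ``init_input``, then its own output is
    fed back as the next input recursively. Returns (hidden states
    (n_steps, 32), outputs (n_steps, d)). Z is held fixed.
    """
    Z = model.fast.Z if Z is None else np.asarray(Z, dtype=float)
    x = np.atleast_1d(np.asarray(init_input, dtype=float)).reshape(1, 1, -1)
    h = None
    c = None
    states = np.empty((n_steps, nn.HIDDEN))
    outputs = np.empty((n_steps, model.d_out))
    for t in range(n_steps):
        Y, cache = nn.forward_window(
            model.net, x, Z, model.effective_mode, model.z_transform,
            model.fast.slices, h0=h, c0=c,
        )
        h, c = cache.h_last, cache.c_last
        states[t] = h[0]
        outputs[t] = Y[0, -1]
        x = Y[:, -1:, :]
    return states, outputs


def project_onto_pcs(states: np.ndarray, reference_activity: np.ndarray, n_components: int = 2):
    """Project rollout states onto the first principal components fitted on
    (test-phase) reference activity."""
    pca = PCA(n_components=n_components)
    pca.fit(reference_activity)
    return pca.transform(states), pca


def find_fixed_points(
    trajectory: np.ndarray, threshold: float = 1e-4, merge_radius: float | None = None
) -> list[np.ndarray]:
    """States where the update norm stays below threshold for three
    consecutive steps; nearby detections are merged to one representative."""
    traj = np.atleast_2d(np.asarray(trajectory, dtype=float))
    if traj.shape[0] < 3 and traj.ndim == 2 and traj.shape[1] > traj.shape[0]:
        traj = traj.T
    if traj.shape[0] < 4:
        # need three consecutive update norms
        if traj.shape[0] >= 2 and np.all(
            np.linalg.norm(np.diff(traj, axis=0), axis=1) < threshold
        ):
            return [traj[-1]]
        return []
    steps = np.linalg.norm(np.diff(traj, axis=0), axis=1)
    small = steps < threshold
    hits = [
        t + 1
        for t in range(2, len(steps))
        if small[t] and small[t - 1] and small[t - 2]
    ]
    if merge_radius is None:
        merge_radius = 100 * threshold
    reps: list[np.ndarray] = []
    for t in hits:
        state = traj[t]
        if not any(np.linalg.norm(state - r) < merge_radius for r in reps):
            reps.append(state)
    return reps


def response_bias_curve(
    model: NeuraGemModel,
    probe_values: np.ndarray | None = None,
    z_values: list[np.ndarray] | None = None,
    settle_steps: int = 20,
) -> pd.DataFrame:
    """Response bias Delta(probe) = output - input for constant-input probes.

    Each probe value is presented as a constant stream for ``settle_steps``
    steps (the block-end asymptotic response); Delta is the final output
    minus the probe. Zero crossings with negative local slope are attracting
    fixed points of the input-output map, positive slope repelling. For
    models with a fast substrate the curve can be computed at several fixed
    Z values.
    """
    if probe_values is None:
        probe_values = np.round(np.arange(-0.2, 1.2001, 0.1), 10)
    zs = z_values if z_values is not None else [model.fast.Z]
    rows = []
    for zi, Z in enumerate(zs):
        for p in probe_values:
            window = np.full((settle_steps, model.d_in), float(p))
            out = model.forward_predict(window, Z=Z)
            rows.append(dict(z_index=zi, probe=float(p), output=float(out[0]),
                             bias=float(out[0] - p)))
    return pd.DataFrame(rows)


def classify_zero_crossings(curve: pd.DataFrame) -> list[dict]:
    """Locate and classify the zero crossings of one response-bias curve
    (attracting: negative slope of Delta; repelling: positive)."""
    out = []
    probes = curve["probe"].to_numpy()
    bias = curve["bias"].to_numpy()
    for i in range(len(bias) - 1):
        if bias[i] == 0.0 or (bias[i] * bias[i + 1] < 0):
            slope = (bias[i + 1] - bias[i]) / (probes[i + 1] - probes[i])
            x0 = (
                probes[i]
                if bias[i] == 0.0
                else probes[i] - bias[i] * (probes[i + 1] - probes[i]) / (bias[i + 1] - bias[i])
            )
            out.append(
                dict(probe=float(x0), kind="attracting" if slope < 0 else "repelling",
                     slope=float(slope))
            )
    return out


# ---------------------------------------------------------------------------
# multi-timescale and sequence-task quantification
# ---------------------------------------------------------------------------


def shift_null_correlation(
    z_series: np.ndarray,
    latent_series: np.ndarray,
    n_shifts: int = 200,
    rng: np.random.Generator | int | None = 0,
) -> float:
    """Absolute correlation adjusted by a circular-shift null.

    Returns |corr(z, latent)| minus the mean |corr| against ``n_shifts``
    circularly shifted versions of the latent series, which discounts the
    spuriously high correlations slow signals achieve by chance.
    """
    z = np.asarray(z_series, dtype=float).reshape(-1)
    lat = np.asarray(latent_series, dtype=float).reshape(-1)
    if z.shape != lat.shape:
        raise AnalysisError("series lengths differ")
    if np.std(z) == 0 or np.std(lat) == 0:
        return 0.0
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    raw = abs(np.corrcoef(z, lat)[0, 1])
    shifts = rng.integers(1, len(lat), size=n_shifts)
    null = np.empty(n_shifts)
    for i, s in enumerate(shifts):
        null[i] = abs(np.corrcoef(z, np.roll(lat, int(s)))[0, 1])
    return float(raw - null.mean())


def regress_z_on_transitions(
    z: np.ndarray, dataset: StoryDataset, response: str = "story_mean"
) -> dict[str, float]:
    """|beta| of Z activity on the story transition outcomes, via OLS.

    Per story, the response is the mean Z activity over the steps following
    the transitions (or the story-end Z); the predictors are the signed
    outcomes of the context-identifying transition T_cid (+1 context A, -1
    context B) and the randomized transition T_rnd (+1/-1 by outcome state).
    Coefficients are averaged in absolute value across Z units. Collinear
    predictors are flagged and dropped with a warning.
    """
    cs = dataset.chain_spec
    L = dataset.story_len
    n = dataset.n_stories
    z = np.asarray(z, dtype=float)
    if z.ndim == 1:
        z = z[:, None]
    n_usable = min(n, z.shape[0] // L)
    resp = np.empty((n_usable, z.shape[1]))
    cid = np.empty(n_usable)
    rnd = np.empty(n_usable)
    for i in range(n_usable):
        seg = slice(i * L, (i + 1) * L)
        zseg = z[seg]
        resp[i] = zseg[2:].mean(axis=0) if response == "story_mean" else zseg[-1]
        states = dataset.state_ids[seg]
        cid[i] = 1.0 if states[1] == cs.cid_states[0] else -1.0
        rnd[i] = 1.0 if states[2] == cs.rnd_outcomes[0] else -1.0
    X = np.column_stack([cid, rnd])
    names = ["T_cid", "T_rnd"]
    keep = [j for j in range(X.shape[1]) if np.std(X[:, j]) > 0]
    dropped = [names[j] for j in range(X.shape[1]) if j not in keep]
    if len(keep) == 2 and abs(np.corrcoef(X[:, 0], X[:, 1])[0, 1]) > 0.999:
        warnings.warn("T_cid and T_rnd are collinear; dropping T_rnd")
        keep = [0]
        dropped.append("T_rnd")
    elif dropped:
        warnings.warn(f"constant predictors dropped: {dropped}")
    Xd = sm.add_constant(X[:, keep])
    betas = {name: 0.0 for name in names}
    for u in range(resp.shape[1]):
        fit = sm.OLS(resp[:, u], Xd).fit()
        for j, col in enumerate(keep):
            betas[names[col]] += abs(fit.params[j + 1]) / resp.shape[1]
    for name in dropped:
        betas[name] = np.nan
    return betas


def sequence_accuracy(predictions: np.ndarray, dataset: StoryDataset) -> float:
    """Fraction of stories whose predicted third-transition outcome (the
    choice between the two diagnostic states) matches the realized state.

    ``predictions[t]`` is the model's prediction of the state at time t+1;
    the diagnostic state sits at position 3 of each six-step story.
    """
    cs = dataset.chain_spec
    L = dataset.story_len
    preds = np.asarray(predictions)
    correct = 0
    total = 0
    for i in range(dataset.n_stories):
        t_pred = i * L + 2  # prediction of position-3 state is emitted at step index 2
        if t_pred >= preds.shape[0]:
            break
        scores = preds[t_pred][list(cs.choice_states)]
        chosen = cs.choice_states[int(np.argmax(scores))]
        realized = dataset.state_ids[i * L + 3]
        correct += chosen == realized
        total += 1
    if total == 0:
        raise AnalysisError("no stories covered by predictions")
    return correct / total
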