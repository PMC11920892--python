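"""Spatially-encoded forward EMG surrogate and grid-posterior inversion.

Stimuli are encoded as 4D vectors in ``[0, 1)``: normalized amplitude,
frequency, and electrode mediolateral/rostrocaudal coordinates.  Because the
electrode enters as a continuous position rather than an index, a forward
model trained on a subset of contacts can predict responses for unseen
contacts.  The forward surrogate is a small feedforward network (two hidden
layers of 64 rectifier units) trained with Adam on mean-absolute (L1) error,
which penalizes errors linearly and is robust to occasional outlier trials.

The inverse model is an explicit grid posterior: for a target muscle-response
vector the density ``exp(-||f(theta) - target||_1 / tau)`` is evaluated on a
grid over the 4D encoding and normalized.  Proposals take the grid argmax,
snap the spatial coordinate to the nearest contact, and clamp the amplitude
to the comfortable range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evoked_potentials import kruskal_wallis
from .paddle_geometry import NORM_EPS, PaddleLayout
from .synthetic_data import (
    ExperimentDesign,
    RecruitmentGroundTruth,
    SyntheticDataset,
    simulate_activation,
)

__all__ = [
    "StimulusEncoder",
    "DensityDataset",
    "TrainConfig",
    "ForwardModel",
    "PosteriorGrid",
    "Proposal",
    "EvaluationReport",
    "AblationReport",
    "build_training_rows",
    "holdout_split",
    "build_density_datasets",
    "train_forward",
    "evaluate_forward",
    "inverse_posterior",
    "propose_stimulation",
    "run_ablation_experiment",
]

ENCODING_COLS = ("a_norm", "f_norm", "x_norm", "y_norm")


@dataclass(frozen=True)
class StimulusEncoder:
    """Linear maps between physical stimulation parameters and ``[0, 1)``.

    Amplitude and frequency map their (min, max) range onto the half-open
    unit interval with the same span-inflation convention used for contact
    coordinates.
    """

    amplitude_range_ua: tuple[float, float]
    frequency_range_hz: tuple[float, float]

    def _fwd(self, v, rng):
        lo, hi = rng
        span = (hi - lo) * (1.0 + NORM_EPS)
        if span <= 0:
            raise ValueError("degenerate parameter range")
        return (np.asarray(v, dtype=float) - lo) / span

    def _inv(self, u, rng):
        lo, hi = rng
        return lo + np.asarray(u, dtype=float) * (hi - lo) * (1.0 + NORM_EPS)

    def encode_amplitude(self, ua):
        return self._fwd(ua, self.amplitude_range_ua)

    def decode_amplitude(self, u):
        return self._inv(u, self.amplitude_range_ua)

    def encode_frequency(self, hz):
        return self._fwd(hz, self.frequency_range_hz)

    def decode_frequency(self, u):
        return self._inv(u, self.frequency_range_hz)


@dataclass(frozen=True)
class DensityDataset:
    """Training rows restricted to a retained electrode subset."""

    label: str
    electrodes: frozenset[str]
    rows: pd.DataFrame


@dataclass(frozen=True)
class TrainConfig:
    hidden: tuple[int, ...] = (64, 64)
    learning_rate: float = 3e-3
    batch_size: int = 128
    max_epochs: int = 500
    patience: int = 40
    val_fraction: float = 0.15


@dataclass
class ForwardModel:
    """Trained feedforward surrogate: 4D encoding -> muscle response vector."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    config: TrainConfig
    seed: int
    muscle_names: tuple[str, ...]
    train_curve: list[float] = field(default_factory=list)
    held_in_l1: float = float("nan")

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predicted responses, clamped non-negative."""
        h = np.atleast_2d(np.asarray(X, dtype=float))
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            h = np.maximum(h @ W + b, 0.0)
        out = h @ self.weights[-1] + self.biases[-1]
        return np.maximum(out, 0.0)


def build_training_rows(
    dataset: SyntheticDataset, encoder: StimulusEncoder | None = None
) -> tuple[pd.DataFrame, StimulusEncoder, pd.DataFrame]:
    """Encode a generated session into per-trial forward-model rows.

    Targets are per-muscle responses min-max normalized to [0, 1] over the
    whole session.  Returns ``(rows, encoder, norm_constants)`` where the
    normalization constants (per-muscle min/range) let later delivery-phase
    responses be expressed on the same scale.
    """
    gt = dataset.ground_truth
    trials = dataset.trials
    encoder = encoder or StimulusEncoder(
        (trials["amplitude_ua"].min(), trials["amplitude_ua"].max()),
        (trials["frequency_hz"].min(), trials["frequency_hz"].max()),
    )
    id_to_idx = {e: k for k, e in enumerate(dataset.layout.electrode_ids)}
    xy = dataset.layout.coords_norm[[id_to_idx[e] for e in trials["electrode"]]]
    rows = trials[["electrode", "amplitude_ua", "frequency_hz", "repeat"]].copy()
    rows["a_norm"] = encoder.encode_amplitude(trials["amplitude_ua"])
    rows["f_norm"] = encoder.encode_frequency(trials["frequency_hz"])
    rows["x_norm"] = xy[:, 0]
    rows["y_norm"] = xy[:, 1]
    consts = []
    for name in gt.muscle_names:
        raw = trials[f"rauc_{name}"]
        lo, hi = float(raw.min()), float(raw.max())
        rng = hi - lo
        if rng <= 0:
            raise ValueError(f"zero response range for muscle {name}")
        rows[f"y_{name}"] = (raw - lo) / rng
        consts.append({"muscle": name, "min": lo, "range": rng})
    return rows, encoder, pd.DataFrame(consts).set_index("muscle")


def holdout_split(
    rows: pd.DataFrame, fraction: float = 0.4, seed: int = 0
) -> tuple[set[tuple], set[tuple]]:
    """Split unique (electrode, amplitude, frequency) conditions.

    Returns ``(train_conditions, heldout_conditions)`` with the held-out set
    holding ``fraction`` of all conditions, sampled uniformly with the given
    seed.
    """
    conds = sorted(
        set(zip(rows["electrode"], rows["amplitude_ua"], rows["frequency_hz"]))
    )
    rng = np.random.default_rng(seed)
    n_held = int(round(fraction * len(conds)))
    held_idx = set(rng.choice(len(conds), size=n_held, replace=False).tolist())
    held = {c for i, c in enumerate(conds) if i in held_idx}
    return set(conds) - held, held


def build_density_datasets(
    rows: pd.DataFrame,
    layout: PaddleLayout,
    removal_counts: tuple[int, int] = (30, 14),
    seed: int = 0,
    mode: str = "stratified",
) -> tuple[DensityDataset, DensityDataset, DensityDataset]:
    """Nested 100% / 50% / 25% density training sets.

    The 50% set removes ``removal_counts[0]`` contacts from the full array
    and the 25% set removes a further ``removal_counts[1]`` from those.
    ``mode="stratified"`` removes by checkerboard parity then even spatial
    subsampling, preserving the paddle span; ``mode="random"`` removes
    seeded-uniformly.
    """
    all_ids = list(layout.electrode_ids)
    r1, r2 = removal_counts
    if r1 > len(all_ids) or r2 > len(all_ids) - r1:
        raise ValueError("removal counts exceed available electrodes")
    if mode == "stratified":
        order = sorted(range(len(all_ids)), key=lambda k: (layout.rows[k], layout.cols[k]))
        parity = [(layout.rows[k] + layout.cols[k]) % 2 == 0 for k in order]
        keep50_idx = [k for k, p in zip(order, parity) if p]
        drop = [k for k, p in zip(order, parity) if not p]
        # top up / trim so exactly r1 contacts are removed
        while len(drop) < r1:
            drop.append(keep50_idx.pop())
        keep50_idx = sorted(set(order) - set(drop[:r1]))
        n25 = len(keep50_idx) - r2
        pick = np.unique(np.round(np.linspace(0, len(keep50_idx) - 1, n25)).astype(int))
        keep25_idx = [keep50_idx[i] for i in pick]
    elif mode == "random":
        rng = np.random.default_rng(seed)
        perm = rng.permutation(len(all_ids))
        keep50_idx = sorted(perm[: len(all_ids) - r1].tolist())
        keep25_idx = sorted(
            rng.permutation(keep50_idx)[: len(keep50_idx) - r2].tolist()
        )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    sets = {
        "100%": frozenset(all_ids),
        "50%": frozenset(all_ids[k] for k in keep50_idx),
        "25%": frozenset(all_ids[k] for k in keep25_idx),
    }
    assert sets["25%"] <= sets["50%"] <= sets["100%"]
    return tuple(
        DensityDataset(label, ids, rows[rows["electrode"].isin(ids)].reset_index(drop=True))
        for label, ids in sets.items()
    )  # type: ignore[return-value]


def _l1_grad_step(params, grads, m, v, t, lr, beta1=0.9, beta2=0.999, eps=1e-8):
    for i, (p, g) in enumerate(zip(params, grads)):
        m[i] = beta1 * m[i] + (1 - beta1) * g
        v[i] = beta2 * v[i] + (1 - beta2) * g * g
        mhat = m[i] / (1 - beta1**t)
        vhat = v[i] / (1 - beta2**t)
        p -= lr * mhat / (np.sqrt(vhat) + eps)


def train_forward(
    dataset: DensityDataset | pd.DataFrame,
    muscle_names,
    config: TrainConfig = TrainConfig(),
    seed: int = 0,
) -> ForwardModel:
    """Fit the forward surrogate by minimizing mean L1 error.

    Deterministic for a fixed (data, config, seed): weight initialization,
    the validation split and minibatch order all derive from ``seed``.
    Training stops early when validation L1 has not improved for
    ``config.patience`` epochs and the best validation weights are restored.
    """
    rows = dataset.rows if isinstance(dataset, DensityDataset) else dataset
    if rows.empty:
        raise ValueError("empty training dataset")
    X = rows[list(ENCODING_COLS)].to_numpy(dtype=float)
    if np.any(X < 0) or np.any(X >= 1):
        raise ValueError("encodings must lie in [0, 1)")
    Y = rows[[f"y_{m}" for m in muscle_names]].to_numpy(dtype=float)

    rng = np.random.default_rng(seed)
    sizes = (X.shape[1], *config.hidden, Y.shape[1])
    weights = [
        rng.normal(0.0, np.sqrt(2.0 / sizes[i]), size=(sizes[i], sizes[i + 1]))
        for i in range(len(sizes) - 1)
    ]
    biases = [np.zeros(s) for s in sizes[1:]]

    n = X.shape[0]
    n_val = max(1, int(round(config.val_fraction * n))) if n > 4 else 0
    perm = rng.permutation(n)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    Xtr, Ytr = X[tr_idx], Y[tr_idx]
    Xval, Yval = X[val_idx], Y[val_idx]

    params = weights + biases
    m_state = [np.zeros_like(p) for p in params]
    v_state = [np.zeros_like(p) for p in params]
    step = 0
    best_val = np.inf
    best = [p.copy() for p in params]
    since_best = 0
    curve: list[float] = []

    def forward_backward(xb, yb):
        acts = [xb]
        h = xb
        for W, b in zip(weights[:-1], biases[:-1]):
            h = np.maximum(h @ W + b, 0.0)
            acts.append(h)
        out = h @ weights[-1] + biases[-1]
        err = out - yb
        loss = float(np.mean(np.abs(err)))
        delta = np.sign(err) / err.size
        gw = [np.zeros_like(W) for W in weights]
        gb = [np.zeros_like(b) for b in biases]
        for layer in range(len(weights) - 1, -1, -1):
            gw[layer] = acts[layer].T @ delta
            gb[layer] = delta.sum(axis=0)
            if layer > 0:
                delta = (delta @ weights[layer].T) * (acts[layer] > 0)
        return loss, gw + gb

    def val_loss():
        if Xval.size == 0:
            return curve[-1] if curve else np.inf
        model = ForwardModel(weights, biases, config, seed, tuple(muscle_names))
        return float(np.mean(np.abs(model.predict(Xval) - Yval)))

    for epoch_i in range(config.max_epochs):
        order = rng.permutation(Xtr.shape[0])
        losses = []
        for s in range(0, Xtr.shape[0], config.batch_size):
            idx = order[s : s + config.batch_size]
            loss, grads = forward_backward(Xtr[idx], Ytr[idx])
            step += 1
            _l1_grad_step(params, grads, m_state, v_state, step, config.learning_rate)
            losses.append(loss)
        curve.append(float(np.mean(losses)))
        vl = val_loss()
        if vl < best_val - 1e-6:
            best_val = vl
            best = [p.copy() for p in params]
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    for p, bp in zip(params, best):
        p[...] = bp
    model = ForwardModel(weights, biases, config, seed, tuple(muscle_names), curve)
    model.held_in_l1 = float(np.mean(np.abs(model.predict(X) - Y)))
    return model


@dataclass
class EvaluationReport:
    """Held-out forward-model errors with seen/unseen split and baseline."""

    per_row: pd.DataFrame  # columns: electrode, l1, l1_baseline, seen
    median_l1: float
    median_l1_baseline: float
    seen_vs_unseen_p: float
    model_vs_baseline_p: float
    n_seen: int
    n_unseen: int


def evaluate_forward(
    model: ForwardModel,
    heldout: pd.DataFrame,
    trained_electrodes: frozenset[str] | set[str],
    baseline_seed: int = 0,
    train_max: pd.Series | None = None,
) -> EvaluationReport:
    """Per-row L1 error on held-out rows, split by electrode familiarity.

    The random baseline predicts each muscle uniformly between 0 and the
    training-set maximum response; Mann–Whitney tests compare unseen vs
    seen errors (one-sided, unseen greater) and model vs baseline errors.
    """
    from scipy.stats import mannwhitneyu

    if heldout.empty:
        raise ValueError("held-out set is empty")
    X = heldout[list(ENCODING_COLS)].to_numpy(dtype=float)
    Y = heldout[[f"y_{m}" for m in model.muscle_names]].to_numpy(dtype=float)
    pred = model.predict(X)
    l1 = np.mean(np.abs(pred - Y), axis=1)
    rng = np.random.default_rng(baseline_seed)
    maxima = (
        train_max.reindex(list(model.muscle_names)).to_numpy(dtype=float)
        if train_max is not None
        else np.ones(Y.shape[1])
    )
    baseline = rng.uniform(0.0, maxima, size=Y.shape)
    l1_base = np.mean(np.abs(baseline - Y), axis=1)
    seen = heldout["electrode"].isin(trained_electrodes).to_numpy()
    per_row = pd.DataFrame(
        {
            "electrode": heldout["electrode"].to_numpy(),
            "l1": l1,
            "l1_baseline": l1_base,
            "seen": seen,
        }
    )
    if seen.any() and (~seen).any():
        p_su = float(mannwhitneyu(l1[~seen], l1[seen], alternative="greater").pvalue)
    else:
        p_su = float("nan")  # partition empty: reported as such
    p_base = float(mannwhitneyu(l1, l1_base, alternative="less").pvalue)
    return EvaluationReport(
        per_row=per_row,
        median_l1=float(np.median(l1)),
        median_l1_baseline=float(np.median(l1_base)),
        seen_vs_unseen_p=p_su,
        model_vs_baseline_p=p_base,
        n_seen=int(seen.sum()),
        n_unseen=int((~seen).sum()),
    )


@dataclass
class PosteriorGrid:
    """Normalized density over the 4D (amplitude, frequency, x, y) grid."""

    axes: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]
    density: np.ndarray  # shape = tuple(len(ax) for ax in axes)
    temperature: float

    def argmax(self) -> tuple[float, float, float, float]:
        idx = np.unravel_index(int(np.argmax(self.density)), self.density.shape)
        return tuple(float(ax[i]) for ax, i in zip(self.axes, idx))  # type: ignore[return-value]


def inverse_posterior(
    target: np.ndarray,
    model: ForwardModel,
    grid_axes: dict[str, np.ndarray] | None = None,
    temperature: float = 0.05,
) -> PosteriorGrid:
    """Grid posterior ``density ∝ exp(-||f(theta) - target||_1 / tau)``.

    ``grid_axes`` supplies 1D arrays for keys amplitude, frequency, x, y
    (defaults 21 x 21 x 41 x 41 over [0, 1)); all values must lie in
    [0, 1).  The density is normalized to sum to 1 over the grid.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    axes_dict = grid_axes or {
        "amplitude": np.linspace(0, 1, 21, endpoint=False),
        "frequency": np.linspace(0, 1, 21, endpoint=False),
        "x": np.linspace(0, 1, 41, endpoint=False),
        "y": np.linspace(0, 1, 41, endpoint=False),
    }
    axes = tuple(np.asarray(axes_dict[k], dtype=float) for k in ("amplitude", "frequency", "x", "y"))
    if any(ax.size == 0 for ax in axes):
        raise ValueError("empty grid axis")
    if any(np.any(ax < 0) or np.any(ax >= 1) for ax in axes):
        raise ValueError("grid axes must lie in [0, 1)")
    mesh = np.meshgrid(*axes, indexing="ij")
    X = np.column_stack([m.ravel() for m in mesh])
    t = np.asarray(target, dtype=float).reshape(1, -1)
    l1 = np.mean(np.abs(model.predict(X) - t), axis=1)
    logd = -l1 / temperature
    logd -= logd.max()
    dens = np.exp(logd)
    dens /= dens.sum()
    return PosteriorGrid(axes, dens.reshape([ax.size for ax in axes]), temperature)


@dataclass(frozen=True)
class Proposal:
    electrode: str
    amplitude_norm: float
    frequency_norm: float
    snap_distance: float
    amplitude_clamped: bool


def propose_stimulation(
    posterior: PosteriorGrid,
    layout: PaddleLayout,
    amplitude_limits: tuple[float, float] = (0.0, 1.0 - NORM_EPS),
) -> Proposal:
    """Argmax proposal snapped to the nearest contact, amplitude clamped.

    The spatial coordinate snaps by Euclidean distance in the normalized
    frame; exact ties resolve to the lowest electrode id.  Amplitude outside
    the comfortable limits is clamped and flagged.
    """
    if layout.coords_norm is None or layout.n_electrodes == 0:
        raise ValueError("layout must be normalized and non-empty")
    a, f, x, y = posterior.argmax()
    d = np.linalg.norm(layout.coords_norm - np.array([x, y]), axis=1)
    best = int(np.argmin(d))  # argmin returns the first (lowest id) on ties
    lo, hi = amplitude_limits
    clamped = a < lo or a > hi
    return Proposal(
        electrode=layout.electrode_ids[best],
        amplitude_norm=float(np.clip(a, lo, hi)),
        frequency_norm=float(f),
        snap_distance=float(d[best]),
        amplitude_clamped=bool(clamped),
    )


@dataclass
class AblationReport:
    """Cross-density experiment: forward errors and closed-loop proposals."""

    evaluations: dict[str, EvaluationReport]
    proposal_l1: dict[str, np.ndarray]  # per model, one mean L1 per target
    gt_repeat_l1: np.ndarray
    proposal_vs_gt_kw: tuple[float, float, bool]
    forward_across_models_kw: tuple[float, float, bool]
    n_heldout_conditions: int
    n_targets: int
    norm_constants: pd.DataFrame
    models: dict[str, ForwardModel]


def _deliver(
    gt: RecruitmentGroundTruth,
    layout: PaddleLayout,
    electrode: str,
    amplitude_ua: float,
    frequency_hz: float,
    norm_constants: pd.DataFrame,
    rng: np.random.Generator,
    n_repeats: int,
    noise_cv: float,
) -> np.ndarray:
    """Simulate delivering a stimulus; responses on the normalized scale."""
    idx = layout.electrode_ids.index(electrode)
    act = simulate_activation(gt, layout.coords_mm[idx], amplitude_ua, frequency_hz)
    lo = norm_constants["min"].to_numpy()
    rng_c = norm_constants["range"].to_numpy()
    out = np.empty((n_repeats, act.size))
    for r in range(n_repeats):
        if noise_cv > 0:
            gains = rng.lognormal(-0.5 * noise_cv**2, noise_cv, size=act.size)
        else:
            gains = 1.0
        raw = act * gains + (np.abs(rng.normal(0, gt.baseline_sd, act.size)) if gt.baseline_sd > 0 else 0.0)
        out[r] = (raw - lo) / rng_c
    return out


def run_ablation_experiment(
    dataset: SyntheticDataset,
    seed: int = 0,
    holdout_fraction: float = 0.4,
    n_targets: int = 32,
    deliver_repeats: int = 10,
    delivery_noise_cv: float | None = None,
    config: TrainConfig = TrainConfig(),
    spatial_grid: int | None = None,
) -> AblationReport:
    """Train 100/50/25% density models and evaluate forward + inverse loops.

    Conditions are split train/held-out; independent models are trained per
    density; forward errors are reported per model with seen/unseen splits
    and random baselines.  Target response vectors are drawn from the
    held-out conditions (stratified over electrodes); each model proposes a
    stimulus via its grid posterior (amplitude/frequency axes are the
    tested values — the deliverable conditions — and a dense spatial grid),
    and every proposal is delivered ``deliver_repeats`` times in the
    simulator, as are the original ground-truth parameters.

    Posterior axes default to the deliverable stimulus set (tested
    amplitudes and frequencies, contact coordinates); ``spatial_grid``
    switches to a dense spatial grid of that many points per axis, with
    proposals snapped back to the nearest contact.
    """
    gt = dataset.ground_truth
    layout = dataset.layout
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(6)]
    rows, encoder, consts = build_training_rows(dataset)
    train_conds, held_conds = holdout_split(rows, holdout_fraction, seeds[0])
    cond_key = list(zip(rows["electrode"], rows["amplitude_ua"], rows["frequency_hz"]))
    in_train = np.array([c in train_conds for c in cond_key])
    train_rows = rows[in_train].reset_index(drop=True)
    held_rows = rows[~in_train].reset_index(drop=True)

    # held-out targets: per-condition mean over repeats
    agg = {c: "first" for c in ENCODING_COLS}
    agg.update({f"y_{m}": "mean" for m in gt.muscle_names})
    held_mean = (
        held_rows.groupby(["electrode", "amplitude_ua", "frequency_hz"])
        .agg(agg)
        .reset_index()
    )

    densities = build_density_datasets(train_rows, layout, seed=seeds[1])
    models: dict[str, ForwardModel] = {}
    evaluations: dict[str, EvaluationReport] = {}
    train_max = train_rows[[f"y_{m}" for m in gt.muscle_names]].max()
    train_max.index = [c.removeprefix("y_") for c in train_max.index]
    for dd, mseed in zip(densities, seeds[2:5]):
        model = train_forward(dd, gt.muscle_names, config, mseed)
        models[dd.label] = model
        evaluations[dd.label] = evaluate_forward(
            model, held_mean, dd.electrodes, baseline_seed=mseed, train_max=train_max
        )

    # stratify target selection over electrodes
    rng = np.random.default_rng(seeds[5])
    by_elec: dict[str, list[int]] = {}
    for i, e in enumerate(held_mean["electrode"]):
        by_elec.setdefault(e, []).append(i)
    elec_order = rng.permutation(sorted(by_elec))
    target_idx: list[int] = []
    while len(target_idx) < min(n_targets, len(held_mean)):
        for e in elec_order:
            if by_elec[e] and len(target_idx) < n_targets:
                target_idx.append(by_elec[e].pop(int(rng.integers(len(by_elec[e])))))
    targets = held_mean.iloc[target_idx].reset_index(drop=True)

    amp_axis = np.sort(np.unique(encoder.encode_amplitude(dataset.trials["amplitude_ua"])))
    freq_axis = np.sort(np.unique(encoder.encode_frequency(dataset.trials["frequency_hz"])))
    if spatial_grid:
        x_axis = np.linspace(0, 1, spatial_grid, endpoint=False)
        y_axis = np.linspace(0, 1, spatial_grid, endpoint=False)
    else:  # deliverable-set axes: the contact coordinates themselves
        x_axis = np.unique(layout.coords_norm[:, 0])
        y_axis = np.unique(layout.coords_norm[:, 1])
    grid = {"amplitude": amp_axis, "frequency": freq_axis, "x": x_axis, "y": y_axis}
    noise_cv = gt.noise_cv if delivery_noise_cv is None else delivery_noise_cv
    y_cols = [f"y_{m}" for m in gt.muscle_names]

    proposal_l1: dict[str, np.ndarray] = {}
    for label, model in models.items():
        tau = max(model.held_in_l1, 1e-3)
        errs = np.empty(len(targets))
        for i, row in targets.iterrows():
            tvec = row[y_cols].to_numpy(dtype=float)
            post = inverse_posterior(tvec, model, grid, temperature=tau)
            prop = propose_stimulation(post, layout)
            resp = _deliver(
                gt,
                layout,
                prop.electrode,
                float(encoder.decode_amplitude(prop.amplitude_norm)),
                float(encoder.decode_frequency(prop.frequency_norm)),
                consts,
                rng,
                deliver_repeats,
                noise_cv,
            )
            errs[i] = float(np.mean(np.abs(resp - tvec)))
        proposal_l1[label] = errs

    gt_errs = np.empty(len(targets))
    for i, row in targets.iterrows():
        tvec = row[y_cols].to_numpy(dtype=float)
        resp = _deliver(
            gt,
            layout,
            row["electrode"],
            float(row["amplitude_ua"]),
            float(row["frequency_hz"]),
            consts,
            rng,
            deliver_repeats,
            noise_cv,
        )
        gt_errs[i] = float(np.mean(np.abs(resp - tvec)))

    kw_prop = kruskal_wallis(*proposal_l1.values(), gt_errs)
    kw_fwd = kruskal_wallis(*(ev.per_row["l1"].to_numpy() for ev in evaluations.values()))
    return AblationReport(
        evaluations=evaluations,
        proposal_l1=proposal_l1,
        gt_repeat_l1=gt_errs,
        proposal_vs_gt_kw=kw_prop,
        forward_across_models_kw=kw_fwd,
        n_heldout_conditions=len(held_conds),
        n_targets=len(targets),
        norm_constants=consts,
        models=models,
    )
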