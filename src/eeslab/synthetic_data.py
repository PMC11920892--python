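"""Seeded generators for synthetic spinal-recruitment experiments.

The simulator plays the role of the animal: a known recruitment ground truth
maps (electrode position, amplitude, frequency) to per-muscle activation in
[0, 1]; trial generators wrap that mapping in EMG burst trains, ECAP sweeps,
SEP trials, and full factorial experiment sessions with stimulation and
multiplexer logs.  Every generator is driven by an explicit seed and is
bit-reproducible, and ground truth always travels with the generated data so
each downstream analysis stage has an oracle.

Recruitment model
-----------------
Activation of muscle ``m`` for a stimulus of amplitude ``A`` (µA) at
frequency ``f`` from an electrode at ``(x, y)`` mm::

    d_m   = sqrt(w_ml * (x - px_m)^2 + (y - py_m)^2)       anisotropic distance
    thr_m = theta0 + kappa * max(0, d_m - r_plateau) + contra_m
    a_m   = sigmoid((A - thr_m) / s) * g(f)                 clipped to [0, 1]

The mediolateral weight ``w_ml < 1`` encodes that recruitment falls off
faster rostrocaudally than across the midline region of a dorsal root entry
zone; the plateau radius makes threshold flat in the immediate pool
neighbourhood.  ``g(f)`` is a mild saturating frequency gain with
``g(f_max) = 1``.  The contralateral penalty raises thresholds for
electrodes on the opposite side of the paddle midline from the muscle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .evoked_potentials import EcapSweep
from .mux_router import MuxConfigLog, default_switch_matrix
from .paddle_geometry import PaddleLayout, build_layout, hd64_spec, normalize_coords

__all__ = [
    "WaveformSpec",
    "RecruitmentGroundTruth",
    "ExperimentDesign",
    "SyntheticDataset",
    "default_ground_truth",
    "clustered_pools_ground_truth",
    "default_design",
    "simulate_activation",
    "synthesize_emg_trial",
    "synthesize_ecap_sweep",
    "synthesize_sep_trials",
    "generate_experiment",
]


@dataclass(frozen=True)
class WaveformSpec:
    """Charge-balanced stimulation pulse train description.

    The default is the cathode-leading 3:1 asymmetric waveform: the anodic
    recharge phase is ``aspect_ratio`` times longer than the cathodic phase
    and proportionally lower in amplitude so cathodic and anodic charge are
    equal.
    """

    amplitude_ua: float
    frequency_hz: float
    cathode_leading: bool = True
    aspect_ratio: float = 3.0
    cathodic_width_us: float = 167.0
    train_duration_ms: float = 300.0
    iti_range_s: tuple[float, float] = (1.0, 2.0)

    def __post_init__(self) -> None:
        if min(self.amplitude_ua, self.frequency_hz, self.cathodic_width_us) <= 0:
            raise ValueError("amplitude, frequency and width must be positive")
        if self.aspect_ratio <= 0 or self.train_duration_ms <= 0:
            raise ValueError("aspect ratio and train duration must be positive")

    @property
    def anodic_amplitude_ua(self) -> float:
        """Anodic-phase amplitude giving exact charge balance."""
        return self.amplitude_ua / self.aspect_ratio

    @property
    def anodic_width_us(self) -> float:
        return self.cathodic_width_us * self.aspect_ratio


@dataclass(frozen=True)
class RecruitmentGroundTruth:
    """Parameters of the distance-dependent sigmoidal recruitment model."""

    pool_centers_mm: np.ndarray  # (n_muscles, 2)
    muscle_names: tuple[str, ...]
    muscle_side: tuple[int, ...]  # -1 left, +1 right, 0 midline
    theta0_ua: float = 250.0
    kappa_ua_per_mm: float = 45.0
    slope_ua: float = 80.0
    plateau_radius_mm: float = 2.0
    ml_weight: float = 0.8
    contra_penalty_ua: float = 200.0
    midline_x_mm: float = 7.25
    freq_half_hz: float = 25.0
    freq_max_hz: float = 100.0
    noise_cv: float = 0.15
    baseline_sd: float = 0.01

    def __post_init__(self) -> None:
        centers = np.asarray(self.pool_centers_mm, dtype=float).reshape(-1, 2)
        if centers.shape[0] != len(self.muscle_names) or centers.shape[0] != len(self.muscle_side):
            raise ValueError("pool centres, names and sides must align")
        object.__setattr__(self, "pool_centers_mm", centers)

    @property
    def n_muscles(self) -> int:
        return len(self.muscle_names)

    def frequency_gain(self, frequency_hz: float) -> float:
        f = float(frequency_hz)
        top = self.freq_max_hz / (self.freq_max_hz + self.freq_half_hz)
        return (f / (f + self.freq_half_hz)) / top


def default_ground_truth(noise_cv: float = 0.15) -> RecruitmentGroundTruth:
    """Six bilateral muscles (biceps femoris, gastrocnemius, extensor
    digitorum longus) with lateralized pools in the caudal half of the
    paddle, where evoked responses are strongest."""
    names = ("BF_L", "Gas_L", "EDL_L", "BF_R", "Gas_R", "EDL_R")
    sides = (-1, -1, -1, 1, 1, 1)
    centers = np.array(
        [
            [2.5, 18.0],
            [2.5, 10.0],
            [2.5, 5.0],
            [12.0, 18.0],
            [12.0, 10.0],
            [12.0, 5.0],
        ]
    )
    return RecruitmentGroundTruth(centers, names, sides, noise_cv=noise_cv)


def clustered_pools_ground_truth(
    layout: PaddleLayout | None = None,
    n_pools: int = 4,
    noise_cv: float = 0.1,
) -> tuple[RecruitmentGroundTruth, np.ndarray]:
    """Ground truth with ``n_pools`` rostrocaudally separated midline pools.

    Built for planted-structure recovery: pool capture radii cover each
    pool's nearest electrodes with a flat threshold, the mediolateral weight
    is small so lateral offset does not blur the rostrocaudal grouping, and
    the distance gain is steep enough that cross-pool activation is
    negligible over the tested amplitude range.  Returns the ground truth
    and the planted per-electrode labels (index of the nearest pool).
    """
    layout = layout or build_layout(hd64_spec())
    # one pool per contiguous rostrocaudal band, centred on the band's median
    # row so every electrode's nearest pool is unambiguous
    uniq_y = np.unique(layout.coords_mm[:, 1])
    chunks = np.array_split(uniq_y, n_pools)
    centers_y = np.array([c[len(c) // 2] for c in chunks])
    x_mid = float(layout.coords_mm[:, 0].mean())
    centers = np.column_stack([np.full(n_pools, x_mid), centers_y])
    gt = RecruitmentGroundTruth(
        pool_centers_mm=centers,
        muscle_names=tuple(f"pool{k}" for k in range(n_pools)),
        muscle_side=(0,) * n_pools,
        theta0_ua=300.0,
        kappa_ua_per_mm=1200.0,
        slope_ua=60.0,
        plateau_radius_mm=5.5,
        ml_weight=0.3,
        contra_penalty_ua=0.0,
        midline_x_mm=x_mid,
        noise_cv=noise_cv,
    )
    labels = np.array(
        [int(np.argmin(_pool_distances(gt, xy))) for xy in layout.coords_mm]
    )
    return gt, labels


def _pool_distances(gt: RecruitmentGroundTruth, electrode_xy) -> np.ndarray:
    xy = np.asarray(electrode_xy, dtype=float).reshape(2)
    delta = gt.pool_centers_mm - xy
    return np.sqrt(gt.ml_weight * delta[:, 0] ** 2 + delta[:, 1] ** 2)


def simulate_activation(
    gt: RecruitmentGroundTruth,
    electrode_xy,
    amplitude_ua: float,
    frequency_hz: float,
) -> np.ndarray:
    """Noise-free per-muscle activation in [0, 1] for one stimulus."""
    if amplitude_ua < 0:
        raise ValueError("amplitude must be non-negative")
    xy = np.asarray(electrode_xy, dtype=float).reshape(2)
    d = _pool_distances(gt, xy)
    d_eff = np.maximum(0.0, d - gt.plateau_radius_mm)
    side = np.sign(xy[0] - gt.midline_x_mm)
    contra = np.array(
        [
            gt.contra_penalty_ua if (s != 0 and side != 0 and s != side) else 0.0
            for s in gt.muscle_side
        ]
    )
    thr = gt.theta0_ua + gt.kappa_ua_per_mm * d_eff + contra
    z = (amplitude_ua - thr) / gt.slope_ua
    act = gt.frequency_gain(frequency_hz) / (1.0 + np.exp(-np.clip(z, -500, 500)))
    return np.clip(act, 0.0, 1.0)


def synthesize_emg_trial(
    activation: np.ndarray,
    waveform: WaveformSpec,
    fs_hz: float,
    rng: np.random.Generator,
    pre_ms: float = 100.0,
    post_ms: float = 300.0,
    noise_cv: float = 0.15,
    baseline_sd: float = 0.02,
    mains_amplitude: float = 0.05,
) -> np.ndarray:
    """One trial of multichannel EMG: stimulus-locked bursts plus noise.

    Each stimulation pulse during the train elicits a short decaying
    oscillatory burst per muscle, scaled by the activation and a lognormal
    trial gain; Gaussian baseline noise and a 60 Hz mains component are
    added so the preprocessing chain (high-pass, notch, RMS envelope) is
    exercised.  Returns (n_muscles, n_samples).
    """
    act = np.asarray(activation, dtype=float)
    if fs_hz < 2 * waveform.frequency_hz * 10:
        raise ValueError("sampling rate too low to represent stimulus-locked bursts")
    n_pre = int(round(pre_ms / 1000 * fs_hz))
    n_train = int(round(waveform.train_duration_ms / 1000 * fs_hz))
    n_post = int(round(post_ms / 1000 * fs_hz))
    n = n_pre + n_train + n_post
    t = np.arange(n) / fs_hz
    traces = rng.normal(0.0, baseline_sd, size=(act.size, n))
    phase = rng.uniform(0, 2 * np.pi)
    traces += mains_amplitude * np.sin(2 * np.pi * 60.0 * t + phase)

    burst_len = int(round(0.015 * fs_hz))
    tb = np.arange(burst_len) / fs_hz
    burst = np.exp(-tb / 0.005) * np.sin(2 * np.pi * 180.0 * tb)
    gains = rng.lognormal(mean=-0.5 * noise_cv**2, sigma=noise_cv, size=act.size)

    n_pulses = int(math.floor(waveform.train_duration_ms / 1000 * waveform.frequency_hz))
    pulse_starts = n_pre + np.round(
        np.arange(max(n_pulses, 1)) / waveform.frequency_hz * fs_hz
    ).astype(int)
    for m in range(act.size):
        amp = act[m] * gains[m]
        if amp <= 0:
            continue
        for s0 in pulse_starts:
            s1 = min(n, s0 + burst_len)
            traces[m, s0:s1] += amp * burst[: s1 - s0]
    return traces


def synthesize_ecap_sweep(
    cv_true_m_per_s: float,
    distances_mm,
    n_trials: int = 50,
    jitter_sd_us: float = 10.0,
    fs_hz: float = 1e6,
    seed: int | np.random.Generator = 0,
    duration_s: float = 600e-6,
    amplitude_ma: float = 4.0,
    noise_sd: float = 0.01,
    template_sigma_us: float = 25.0,
) -> EcapSweep:
    """Synthetic ECAP sweep: artifact at t=0 plus a travelling triphasic wave.

    Each trial/bipole trace contains a decaying stimulus artifact and a
    triphasic Gaussian-derivative (Ricker) template centred at
    ``d / cv + N(0, jitter_sd)`` with amplitude decaying as ``1/d``.  The
    template half-width of ~150 µs matches compound-response durations.
    """
    if cv_true_m_per_s <= 0:
        raise ValueError("conduction velocity must be positive")
    d = np.asarray(distances_mm, dtype=float)
    if np.any(d <= 0):
        raise ValueError("distances must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration_s * fs_hz))
    t = np.arange(n) / fs_hz
    sigma = template_sigma_us * 1e-6
    artifact = 5.0 * np.exp(-t / 8e-6)  # decays below response amplitudes within the blanking window
    traces = np.empty((d.size, n_trials, n))
    for b, dist in enumerate(d):
        centre = dist / 1000.0 / cv_true_m_per_s
        amp = 10.0 / dist
        jitter = rng.normal(0.0, jitter_sd_us * 1e-6, size=n_trials)
        for k in range(n_trials):
            u = (t - centre - jitter[k]) / sigma
            ricker = (1.0 - u**2) * np.exp(-0.5 * u**2)
            traces[b, k] = artifact + amp * ricker + rng.normal(0, noise_sd, n)
    return EcapSweep(traces, tuple(d), fs_hz, amplitude_ma)


def synthesize_sep_trials(
    n_channels: int,
    common_fraction: float,
    n_trials: int,
    fs_hz: float = 2000.0,
    duration_s: float = 0.1,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """SEP-like trials with a shared common-mode and channel-specific parts.

    ``channel_i = rho * c + (1 - rho) * u_i`` with ``c`` shared across
    channels and ``u_i`` independent smooth processes; expected pairwise
    correlation grows with ``rho``.  Returns (n_trials, n_channels,
    n_samples).
    """
    rho = float(common_fraction)
    if not 0.0 <= rho <= 1.0:
        raise ValueError("common fraction must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration_s * fs_hz))

    def smooth(size):
        from scipy.ndimage import gaussian_filter1d

        x = rng.normal(size=size)
        x = gaussian_filter1d(x, sigma=5.0, axis=-1)
        sd = x.std(axis=-1, keepdims=True)
        return x / np.where(sd > 0, sd, 1.0)

    common = smooth((n_trials, 1, n))
    local = smooth((n_trials, n_channels, n))
    return rho * common + (1.0 - rho) * local


@dataclass(frozen=True)
class ExperimentDesign:
    """Factorial stimulation design for one session."""

    amplitudes_ua: tuple[float, ...] = (100.0, 450.0, 800.0, 1150.0, 1500.0)
    frequencies_hz: tuple[float, ...] = (10.0, 25.0, 50.0, 100.0)
    n_repeats: int = 4
    iti_range_s: tuple[float, float] = (1.0, 2.0)

    def __post_init__(self) -> None:
        if not self.amplitudes_ua or not self.frequencies_hz or self.n_repeats < 1:
            raise ValueError("design axes must be non-empty")


def default_design() -> ExperimentDesign:
    return ExperimentDesign()


@dataclass
class SyntheticDataset:
    """A generated session: trial table, ground truth and optional traces.

    ``trials`` columns: trial, electrode, amplitude_ua, frequency_hz,
    repeat, onset_s, iti_s plus one ``act_<muscle>`` (clean activation) and
    one ``rauc_<muscle>`` (noisy single-trial response) column per muscle.
    """

    trials: pd.DataFrame
    layout: PaddleLayout
    ground_truth: RecruitmentGroundTruth
    mux_log: MuxConfigLog
    seed: int
    fs_hz: float
    emg: np.ndarray | None = None  # (n_trials, n_muscles, n_samples)

    def rauc_table(self) -> pd.DataFrame:
        """Long-format per-trial response table: one row per
        (electrode, amplitude, frequency, muscle, repeat)."""
        rows = self.trials.melt(
            id_vars=["electrode", "amplitude_ua", "frequency_hz", "repeat"],
            value_vars=[f"rauc_{m}" for m in self.ground_truth.muscle_names],
            var_name="muscle",
            value_name="rauc_raw",
        )
        rows["muscle"] = rows["muscle"].str.removeprefix("rauc_")
        return rows


def generate_experiment(
    design: ExperimentDesign,
    gt: RecruitmentGroundTruth | None = None,
    layout: PaddleLayout | None = None,
    seed: int = 0,
    electrodes: tuple[str, ...] | None = None,
    fs_hz: float = 2000.0,
    include_traces: bool = False,
) -> SyntheticDataset:
    """Generate a full factorial stimulation session.

    Trials are the full (electrode x amplitude x frequency x repeat)
    factorial in randomized presentation order with inter-train intervals
    drawn uniformly from the design's range.  The per-trial noisy response
    (``rauc_<muscle>``) is the clean activation times a lognormal trial gain
    plus half-normal baseline noise — the summary statistic the analysis
    stages consume.  With ``include_traces`` the raw EMG burst trains are
    synthesized as well (memory-heavy; meant for small designs).
    """
    gt = gt or default_ground_truth()
    layout = layout or normalize_coords(build_layout(hd64_spec()))
    if layout.coords_norm is None:
        layout = normalize_coords(layout)
    rng = np.random.default_rng(seed)
    ids = electrodes if electrodes is not None else layout.electrode_ids
    id_to_idx = {e: k for k, e in enumerate(layout.electrode_ids)}

    conds = [
        (e, a, f, r)
        for e in ids
        for a in design.amplitudes_ua
        for f in design.frequencies_hz
        for r in range(design.n_repeats)
    ]
    order = rng.permutation(len(conds))
    itis = rng.uniform(*design.iti_range_s, size=len(conds))
    onsets = np.cumsum(itis)

    records = []
    raucs = np.empty((len(conds), gt.n_muscles))
    acts = np.empty((len(conds), gt.n_muscles))
    for k, oi in enumerate(order):
        e, a, f, r = conds[oi]
        xy = layout.coords_mm[id_to_idx[e]]
        act = simulate_activation(gt, xy, a, f)
        gains = rng.lognormal(-0.5 * gt.noise_cv**2, gt.noise_cv, size=gt.n_muscles)
        base = np.abs(rng.normal(0.0, gt.baseline_sd, size=gt.n_muscles))
        acts[k] = act
        raucs[k] = act * gains + base
        records.append(
            {
                "trial": k,
                "electrode": e,
                "amplitude_ua": a,
                "frequency_hz": f,
                "repeat": r,
                "onset_s": onsets[k],
                "iti_s": itis[k],
            }
        )
    trials = pd.DataFrame.from_records(records)
    for m, name in enumerate(gt.muscle_names):
        trials[f"act_{name}"] = acts[:, m]
        trials[f"rauc_{name}"] = raucs[:, m]

    matrix = default_switch_matrix()
    entries = []
    prev = None
    for k in range(len(conds)):
        e = trials.loc[k, "electrode"]
        o = id_to_idx[e]
        if o != prev:
            t_sample = int(round(trials.loc[k, "onset_s"] * fs_hz))
            closed = frozenset({(o % matrix.n_inputs, o)})
            t_sample = max(t_sample, (entries[-1][0] + 1) if entries else 0)
            if not entries:
                t_sample = 0
            entries.append((t_sample, closed))
            prev = o
    mux_log = MuxConfigLog(tuple(entries))

    emg = None
    if include_traces:
        n_pre, n_train, n_post = (
            int(round(0.1 * fs_hz)),
            int(round(0.3 * fs_hz)),
            int(round(0.3 * fs_hz)),
        )
        emg = np.empty((len(conds), gt.n_muscles, n_pre + n_train + n_post))
        for k in range(len(conds)):
            wf = WaveformSpec(
                amplitude_ua=trials.loc[k, "amplitude_ua"],
                frequency_hz=trials.loc[k, "frequency_hz"],
            )
            emg[k] = synthesize_emg_trial(
                raucs[k], wf, fs_hz, rng, noise_cv=0.0
            )
    return SyntheticDataset(trials, layout, gt, mux_log, seed, fs_hz, emg)
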