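"""Evoked-potential analysis: ECAP latencies/conduction velocity and SEPs.

ECAPs (evoked compound action potentials) propagate along the cord after an
epidural stimulus; recording bipoles at known rostral distances see the
response at latencies ``d / v``.  Conduction velocity is estimated as the
inverse slope of an ordinary least-squares fit of single-trial peak latency
against bipole distance, pooling all trials.

SEP (somatosensory evoked potential) analysis covers bipolar re-referencing
(common-mode removal), zero-lag pairwise correlation structure, and the
per-channel uniqueness score ``1 - mean |r|``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats

__all__ = [
    "EcapSweep",
    "CvEstimate",
    "UniquenessReport",
    "average_and_filter",
    "peak_latency",
    "sweep_latencies",
    "conduction_velocity",
    "rereference_bipolar",
    "uniqueness_scores",
    "kruskal_wallis",
]


@dataclass(frozen=True)
class EcapSweep:
    """Trial-wise evoked-response traces for several recording bipoles.

    ``traces`` has shape (n_bipoles, n_trials, n_samples); time zero is the
    stimulus onset.  Distances are bipole-centre to stimulating-bipole
    distances in mm, strictly positive and distinct.
    """

    traces: np.ndarray
    distances_mm: tuple[float, ...]
    fs_hz: float
    amplitude_ma: float = float("nan")

    def __post_init__(self) -> None:
        tr = np.asarray(self.traces, dtype=float)
        if tr.ndim != 3 or tr.shape[0] != len(self.distances_mm):
            raise ValueError("traces must be (n_bipoles, n_trials, n_samples)")
        d = np.asarray(self.distances_mm, dtype=float)
        if np.any(d <= 0) or np.unique(d).size != d.size:
            raise ValueError("distances must be positive and distinct")
        object.__setattr__(self, "traces", tr)


@dataclass(frozen=True)
class CvEstimate:
    """Conduction velocity from the latency-distance regression."""

    cv_m_per_s: float
    intercept_s: float
    slope_s_per_m: float
    latencies_s: np.ndarray  # (n_bipoles, n_trials)
    residuals_s: np.ndarray
    physiologic: bool = True


@dataclass(frozen=True)
class UniquenessReport:
    """Per-channel uniqueness = 1 - mean pairwise |zero-lag correlation|."""

    uniqueness: np.ndarray  # (n_channels,)
    mean_abs_corr: np.ndarray  # (n_channels,)
    per_trial: np.ndarray  # (n_trials, n_channels)
    excluded_pairs: tuple[tuple[int, int, int], ...] = field(default=())


def average_and_filter(
    epochs: np.ndarray, fs_hz: float, lowpass_hz: float = 2000.0
) -> tuple[np.ndarray, np.ndarray]:
    """Trial mean and standard deviation, with the mean low-pass filtered.

    The low-pass (default 2 kHz, 4th-order Butterworth) is applied forward
    and backward so peak latencies are not shifted.  sd is the population
    standard deviation across trials.
    """
    ep = np.atleast_2d(np.asarray(epochs, dtype=float))
    if ep.shape[0] < 1 or ep.size == 0:
        raise ValueError("at least one non-empty epoch required")
    if fs_hz <= 2 * lowpass_hz:
        raise ValueError("sampling rate too low for requested low-pass")
    mean = ep.mean(axis=0)
    sd = ep.std(axis=0)
    sos = signal.butter(4, lowpass_hz, btype="low", fs=fs_hz, output="sos")
    padlen = min(3 * 10, mean.size - 1)
    filtered = signal.sosfiltfilt(sos, mean, padlen=padlen)
    return filtered, sd


def peak_latency(
    trace: np.ndarray,
    fs_hz: float,
    search_window_s: tuple[float, float] | None = None,
    artifact_blank_s: float = 50e-6,
) -> tuple[float, bool]:
    """Latency of the largest-magnitude deflection after the blanking window.

    Returns ``(latency_s, confident)``; a flat trace yields the first
    in-window sample flagged low-confidence.  The blanking window discards
    the residual stimulus artifact around time zero.
    """
    tr = np.asarray(trace, dtype=float)
    n = tr.size
    lo = int(np.ceil(artifact_blank_s * fs_hz))
    hi = n
    if search_window_s is not None:
        lo = max(lo, int(np.ceil(search_window_s[0] * fs_hz)))
        hi = min(n, int(np.floor(search_window_s[1] * fs_hz)) + 1)
    if lo >= hi:
        raise ValueError("search window empty after artifact blanking")
    seg = np.abs(tr[lo:hi])
    idx = int(np.argmax(seg))
    confident = bool(seg[idx] > 0)
    return (lo + idx) / fs_hz, confident


def sweep_latencies(
    sweep: EcapSweep,
    artifact_blank_s: float = 50e-6,
    search_window_s: tuple[float, float] | None = None,
) -> np.ndarray:
    """Single-trial peak latencies for every (bipole, trial) trace."""
    n_bipoles, n_trials, _ = sweep.traces.shape
    lat = np.empty((n_bipoles, n_trials))
    for b in range(n_bipoles):
        for t in range(n_trials):
            lat[b, t], _ = peak_latency(
                sweep.traces[b, t], sweep.fs_hz, search_window_s, artifact_blank_s
            )
    return lat


def conduction_velocity(
    latencies_s: np.ndarray, distances_mm: tuple[float, ...] | np.ndarray
) -> CvEstimate:
    """Conduction velocity from pooled single-trial latencies.

    All (bipole, trial) points enter one ordinary least-squares fit of
    latency (s) on distance (m); CV is the inverse slope.  A non-positive
    slope is flagged non-physiologic.
    """
    lat = np.atleast_2d(np.asarray(latencies_s, dtype=float))
    d = np.asarray(distances_mm, dtype=float)
    if np.unique(d).size < 2:
        raise ValueError("at least two distinct distances required")
    if lat.shape[0] != d.size:
        raise ValueError("latency rows must match distances")
    x = np.repeat(d / 1000.0, lat.shape[1])
    y = lat.ravel()
    fit = stats.linregress(x, y)
    slope = float(fit.slope)
    physiologic = slope > 0
    cv = 1.0 / slope if physiologic else float("nan")
    resid = y - (fit.intercept + slope * x)
    return CvEstimate(
        cv_m_per_s=cv,
        intercept_s=float(fit.intercept),
        slope_s_per_m=slope,
        latencies_s=lat,
        residuals_s=resid,
        physiologic=physiologic,
    )


def rereference_bipolar(
    monopolar: np.ndarray, pairs: list[tuple[int, int]]
) -> np.ndarray:
    """Bipolar traces: non-inverting minus inverting monopolar channel.

    ``monopolar`` is (..., n_channels, n_samples); output stacks one bipolar
    trace per pair along the channel axis.  Any component shared by the two
    contacts (common mode) cancels exactly.
    """
    mono = np.asarray(monopolar, dtype=float)
    n_ch = mono.shape[-2]
    for p, m in pairs:
        if not (0 <= p < n_ch and 0 <= m < n_ch):
            raise ValueError(f"unknown channel in pair ({p}, {m})")
    return np.stack([mono[..., p, :] - mono[..., m, :] for p, m in pairs], axis=-2)


def uniqueness_scores(trials: np.ndarray) -> UniquenessReport:
    """Uniqueness of each channel across trials.

    ``trials`` is (n_trials, n_channels, n_samples).  For every trial the
    zero-lag Pearson correlation is computed between all channel pairs; each
    channel's score is ``1 - mean |r|`` over its pairs and all trials.
    Perfectly correlated channels score 0, uncorrelated channels 1.
    Constant channels make ``r`` undefined; those pairs are excluded and
    reported.
    """
    X = np.asarray(trials, dtype=float)
    if X.ndim == 2:
        X = X[None]
    n_trials, n_ch, _ = X.shape
    if n_ch < 2:
        raise ValueError("at least two channels required")
    sums = np.zeros((n_trials, n_ch))
    counts = np.zeros((n_trials, n_ch))
    excluded: list[tuple[int, int, int]] = []
    for t in range(n_trials):
        sd = X[t].std(axis=1)
        ok = sd > 0
        r = np.corrcoef(X[t]) if ok.all() else np.full((n_ch, n_ch), np.nan)
        if not ok.all():
            good = np.where(ok)[0]
            if good.size >= 2:
                r_sub = np.corrcoef(X[t][good])
                for a, ia in enumerate(good):
                    for b, ib in enumerate(good):
                        r[ia, ib] = r_sub[a, b]
        for i in range(n_ch):
            for j in range(n_ch):
                if i == j:
                    continue
                if np.isnan(r[i, j]):
                    if i < j:
                        excluded.append((t, i, j))
                    continue
                sums[t, i] += abs(r[i, j])
                counts[t, i] += 1
    with np.errstate(invalid="ignore"):
        per_trial = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    mean_abs = np.nanmean(per_trial, axis=0)
    uniq = np.clip(1.0 - mean_abs, 0.0, 1.0)
    return UniquenessReport(
        uniqueness=uniq,
        mean_abs_corr=mean_abs,
        per_trial=per_trial,
        excluded_pairs=tuple(excluded),
    )


def kruskal_wallis(*groups) -> tuple[float, float, bool]:
    """Tie-corrected Kruskal–Wallis H test across >= 2 groups.

    Returns ``(H, p, degenerate)``.  When every value in every group is
    identical the rank variance is zero and the statistic is undefined; that
    case is flagged degenerate with ``H = 0`` and ``p = 1``.
    """
    if len(groups) < 2:
        raise ValueError("at least two groups required")
    arrays = [np.asarray(g, dtype=float).ravel() for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("empty group")
    pooled = np.concatenate(arrays)
    if np.allclose(pooled, pooled[0]):
        return 0.0, 1.0, True
    H, p = stats.kruskal(*arrays)
    return float(H), float(p), False
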