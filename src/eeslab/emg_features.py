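"""EMG preprocessing, rectified-AUC responses, recruitment and selectivity.

The per-trial activation measure is the rectified area under the curve
(rAUC): the sum of absolute sample values within a stimulation-triggered
epoch.  Preprocessing is high-pass (3 Hz) -> mains notch (60 Hz, Q = 35) ->
moving-RMS envelope (300 ms window, 50% overlap).  Downstream summaries are
recruitment curves (mean ± sd of normalized rAUC vs amplitude), 33%-of-max
threshold maps with a not-reached sentinel, selectivity indices, and
nonparametric group comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats

__all__ = [
    "EnvelopeParams",
    "preprocess_emg",
    "epoch",
    "compute_rauc",
    "normalize_rauc",
    "recruitment_curve",
    "threshold_amplitude",
    "NOT_REACHED",
    "selectivity_index",
    "compare_groups",
    "rauc_table_from_traces",
]

#: Sentinel for electrodes that never recruit a muscle to the threshold
#: fraction at the tested amplitudes ("N.R.").
NOT_REACHED = float("nan")


@dataclass(frozen=True)
class EnvelopeParams:
    highpass_hz: float = 3.0
    notch_hz: float = 60.0
    notch_q: float = 35.0
    rms_window_ms: float = 300.0
    rms_overlap_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.rms_window_ms <= 0:
            raise ValueError("window must be positive")
        if not 0.0 <= self.rms_overlap_fraction < 1.0:
            raise ValueError("overlap fraction must lie in [0, 1)")


def preprocess_emg(
    trace: np.ndarray, fs_hz: float, params: EnvelopeParams = EnvelopeParams()
) -> tuple[np.ndarray, float]:
    """Filter a raw EMG trace and return its moving-RMS envelope.

    Chain: zero-phase 4th-order Butterworth high-pass, zero-phase IIR notch,
    then the RMS over windows hopping by ``window * (1 - overlap)``; edge
    windows are zero-padded.  Returns ``(envelope, envelope_fs_hz)`` where
    the envelope sampling rate is one value per hop.
    """
    x = np.asarray(trace, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("trace must be a non-empty 1D array")
    if fs_hz <= 2 * params.notch_hz:
        raise ValueError("sampling rate must exceed twice the notch frequency")
    sos = signal.butter(4, params.highpass_hz, btype="high", fs=fs_hz, output="sos")
    y = signal.sosfiltfilt(sos, x, padlen=min(3 * 10, x.size - 1))
    b, a = signal.iirnotch(params.notch_hz, params.notch_q, fs=fs_hz)
    y = signal.filtfilt(b, a, y, padlen=min(3 * max(len(a), len(b)), x.size - 1))

    window = max(1, int(round(params.rms_window_ms / 1000 * fs_hz)))
    hop = max(1, int(round(window * (1.0 - params.rms_overlap_fraction))))
    n_out = 1 + (x.size - 1) // hop
    padded = np.concatenate([y, np.zeros(window)])
    env = np.empty(n_out)
    for k in range(n_out):
        seg = padded[k * hop : k * hop + window]
        env[k] = np.sqrt(np.mean(seg**2))
    return env, fs_hz / hop


def epoch(
    sig: np.ndarray,
    fs_hz: float,
    event_samples,
    pre_ms: float,
    post_ms: float,
) -> np.ndarray:
    """Fixed-length event-aligned epochs with 0-based half-open windows.

    Each epoch spans ``[event - pre, event + post)`` samples; an epoch that
    would leave the recording raises.  Works on 1D (samples,) or 2D
    (channels, samples) signals, returning (n_events, [channels,] length).
    """
    x = np.asarray(sig, dtype=float)
    n = x.shape[-1]
    n_pre = int(round(pre_ms / 1000 * fs_hz))
    n_post = int(round(post_ms / 1000 * fs_hz))
    length = n_pre + n_post
    if length <= 0:
        raise ValueError("epoch window is empty")
    out = []
    for ev in np.atleast_1d(event_samples):
        start = int(ev) - n_pre
        if start < 0 or start + length > n:
            raise ValueError(f"epoch window for event {ev} exceeds recording bounds")
        out.append(x[..., start : start + length])
    return np.stack(out)


def compute_rauc(ep: np.ndarray) -> float:
    """Rectify-and-sum: sum of absolute sample values of one epoch."""
    ep = np.asarray(ep, dtype=float)
    if ep.size == 0:
        raise ValueError("empty epoch")
    return float(np.abs(ep).sum())


def normalize_rauc(
    table: pd.DataFrame,
    value_col: str = "rauc_raw",
    out_col: str = "rauc_norm",
    extra_tables: list[pd.DataFrame] | None = None,
) -> pd.DataFrame:
    """Min-max normalize responses per muscle so min -> 0 and max -> 1.

    With ``extra_tables`` the per-muscle min/max are pooled over all tables
    first (joint normalization, e.g. so monopolar and bipolar responses
    share one scale), then applied to ``table``.  A muscle with zero range
    raises.
    """
    pooled = table if not extra_tables else pd.concat([table, *extra_tables])
    stats_ = pooled.groupby("muscle")[value_col].agg(["min", "max"])
    if (stats_["max"] - stats_["min"] <= 0).any():
        bad = stats_.index[(stats_["max"] - stats_["min"]) <= 0].tolist()
        raise ValueError(f"zero response range for muscle(s): {bad}")
    out = table.copy()
    lo = out["muscle"].map(stats_["min"])
    rng = out["muscle"].map(stats_["max"] - stats_["min"])
    out[out_col] = (out[value_col] - lo) / rng
    return out


def recruitment_curve(
    table: pd.DataFrame,
    electrode: str,
    frequency_hz: float,
    value_col: str = "rauc_norm",
) -> pd.DataFrame:
    """Mean ± sd response vs amplitude for one electrode and frequency.

    Averages the stimulation repeats for every (amplitude, muscle); sd is
    the population standard deviation (a single repeat gives sd = 0).
    Returns columns (amplitude_ua, muscle, mean, sd, n).
    """
    sub = table[
        (table["electrode"] == electrode) & (table["frequency_hz"] == frequency_hz)
    ]
    if sub.empty:
        raise KeyError(f"no rows for electrode {electrode!r} at {frequency_hz} Hz")
    grouped = (
        sub.groupby(["amplitude_ua", "muscle"])[value_col]
        .agg(mean="mean", sd=lambda v: float(np.std(v)), n="count")
        .reset_index()
    )
    return grouped


def threshold_amplitude(
    curve: pd.DataFrame,
    muscle: str,
    fraction: float = 0.33,
    max_activation: float | None = None,
) -> float:
    """Minimum tested amplitude reaching ``fraction`` of maximum activation.

    ``max_activation`` supplies the reference maximum (e.g. the muscle's
    global maximum across all electrodes); by default the curve's own
    maximum is used.  Amplitudes snap to the tested grid; if no tested
    amplitude reaches the target the not-reached sentinel (NaN) is
    returned.
    """
    sub = curve[curve["muscle"] == muscle]
    if sub.empty:
        raise KeyError(f"muscle {muscle!r} absent from curve")
    ref = float(sub["mean"].max()) if max_activation is None else float(max_activation)
    target = fraction * ref
    reached = sub[sub["mean"] >= target]
    if reached.empty:
        return NOT_REACHED
    return float(reached["amplitude_ua"].min())


def selectivity_index(activations: np.ndarray) -> np.ndarray:
    """Per-muscle selectivity: each activation over the summed activations.

    The all-zero vector maps to all-zero indices, so the indices sum to
    either 0 or 1.
    """
    a = np.asarray(activations, dtype=float)
    if np.any(a < 0):
        raise ValueError("activations must be non-negative")
    total = a.sum()
    if total == 0:
        return np.zeros_like(a)
    return a / total


def compare_groups(values_a, values_b) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test (tie-corrected) between two groups.

    Returns ``(U, p)`` with U reported for the first group.
    """
    a = np.asarray(values_a, dtype=float).ravel()
    b = np.asarray(values_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def rauc_table_from_traces(
    emg: np.ndarray,
    fs_hz: float,
    trials: pd.DataFrame,
    muscle_names,
    stim_onset_sample: int,
    epoch_ms: float = 500.0,
) -> pd.DataFrame:
    """Per-trial rAUC table from raw EMG traces.

    ``emg`` is (n_trials, n_muscles, n_samples) with the stimulus at
    ``stim_onset_sample`` in every trace; each trial is rectified and
    summed over the stimulation-triggered epoch (default 500 ms, covering
    the 300 ms train and residual activity).
    """
    n_epoch = int(round(epoch_ms / 1000 * fs_hz))
    rows = []
    for k in range(emg.shape[0]):
        seg = emg[k, :, stim_onset_sample : stim_onset_sample + n_epoch]
        meta = trials.iloc[k]
        for m, name in enumerate(muscle_names):
            rows.append(
                {
                    "electrode": meta["electrode"],
                    "amplitude_ua": meta["amplitude_ua"],
                    "frequency_hz": meta["frequency_hz"],
                    "repeat": meta["repeat"],
                    "muscle": name,
                    "rauc_raw": compute_rauc(seg[m]),
                }
            )
    return pd.DataFrame(rows)
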