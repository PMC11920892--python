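"""File formats: HDF5 recordings, JSON-lines logs, CSV layouts, YAML truth."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .mux_router import DemuxedRecording
from .paddle_geometry import PaddleLayout
from .synthetic_data import RecruitmentGroundTruth

__all__ = [
    "save_recording",
    "load_recording",
    "save_demuxed",
    "load_demuxed",
    "layout_to_csv",
    "layout_from_csv",
    "ground_truth_to_yaml",
    "ground_truth_from_yaml",
    "write_jsonl",
    "read_jsonl",
]


def save_recording(path, raw: np.ndarray, fs_hz: float) -> None:
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("raw", data=np.asarray(raw, dtype=float))
        ds.attrs["fs_hz"] = float(fs_hz)


def load_recording(path) -> tuple[np.ndarray, float]:
    with h5py.File(path, "r") as fh:
        return fh["raw"][...], float(fh["raw"].attrs["fs_hz"])


def save_demuxed(path, demuxed: DemuxedRecording, fs_hz: float) -> None:
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("demux", data=demuxed.data)
        ds.attrs["fs_hz"] = float(fs_hz)
        fh.create_dataset("mask", data=demuxed.mask)


def load_demuxed(path) -> tuple[DemuxedRecording, float]:
    with h5py.File(path, "r") as fh:
        return (
            DemuxedRecording(fh["demux"][...], fh["mask"][...].astype(bool)),
            float(fh["demux"].attrs["fs_hz"]),
        )


def layout_to_csv(path, layout: PaddleLayout) -> None:
    norm = layout.coords_norm
    df = pd.DataFrame(
        {
            "electrode_id": layout.electrode_ids,
            "x_mm": layout.coords_mm[:, 0],
            "y_mm": layout.coords_mm[:, 1],
            "x_norm": norm[:, 0] if norm is not None else np.nan,
            "y_norm": norm[:, 1] if norm is not None else np.nan,
        }
    )
    df.to_csv(path, index=False)


def layout_from_csv(path) -> PaddleLayout:
    df = pd.read_csv(path)
    norm = None
    if df[["x_norm", "y_norm"]].notna().all().all():
        norm = df[["x_norm", "y_norm"]].to_numpy(dtype=float)
    return PaddleLayout(
        tuple(df["electrode_id"].astype(str)),
        df[["x_mm", "y_mm"]].to_numpy(dtype=float),
        coords_norm=norm,
    )


def ground_truth_to_yaml(path, gt: RecruitmentGroundTruth) -> None:
    doc = {
        "pool_centers_mm": gt.pool_centers_mm.tolist(),
        "muscle_names": list(gt.muscle_names),
        "muscle_side": list(gt.muscle_side),
        "theta0_ua": gt.theta0_ua,
        "kappa_ua_per_mm": gt.kappa_ua_per_mm,
        "slope_ua": gt.slope_ua,
        "plateau_radius_mm": gt.plateau_radius_mm,
        "ml_weight": gt.ml_weight,
        "contra_penalty_ua": gt.contra_penalty_ua,
        "midline_x_mm": gt.midline_x_mm,
        "freq_half_hz": gt.freq_half_hz,
        "freq_max_hz": gt.freq_max_hz,
        "noise_cv": gt.noise_cv,
        "baseline_sd": gt.baseline_sd,
    }
    Path(path).write_text(yaml.safe_dump(doc))


def ground_truth_from_yaml(path) -> RecruitmentGroundTruth:
    doc = yaml.safe_load(Path(path).read_text())
    doc["pool_centers_mm"] = np.asarray(doc["pool_centers_mm"], dtype=float)
    doc["muscle_names"] = tuple(doc["muscle_names"])
    doc["muscle_side"] = tuple(doc["muscle_side"])
    return RecruitmentGroundTruth(**doc)


def write_jsonl(path, records: list[dict]) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(rec) + "\n")


def read_jsonl(path) -> list[dict]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                out.append(json.loads(line))
    return out
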