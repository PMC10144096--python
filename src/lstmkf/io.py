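"""File formats: trajectory/measurement CSV, dataset containers, configs.

Trajectories and measurements travel as headered CSV (inspectable, diff-
friendly); gap frames keep their row with ``present=0`` and empty
coordinates.  Full numeric precision is preserved (``%.17g`` formatting
round-trips float64 exactly).  Camera intrinsics and observer poses load
from YAML/JSON configs (K as 9 numbers row-major; pose as quaternion wxyz
plus position xyz).  Every artifact directory gets a manifest recording
the seed and a digest of the generating configuration.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .benchmark import BenchmarkDataset, SimulatedSequence
from .errors import InvalidParameterError
from .geometry import CameraIntrinsics, ObserverPose

__all__ = [
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_estimates_csv",
    "save_dataset",
    "load_dataset",
    "load_camera_config",
    "write_manifest",
    "config_digest",
]

_FLOAT_FMT = "%.17g"
_TRAJ_COLS = ["frame", "t", "x", "y", "z", "present"]


def write_trajectory_csv(path, times, values, present=None) -> None:
    """Write frames as CSV rows ``frame,t,x,y,z,present``; NaN rows = gaps."""
    values = np.asarray(values, dtype=np.float64)
    times = np.asarray(times, dtype=np.float64)
    if present is None:
        present = ~np.all(np.isnan(values), axis=1)
    df = pd.DataFrame({
        "frame": np.arange(len(values)),
        "t": times,
        "x": values[:, 0],
        "y": values[:, 1],
        "z": values[:, 2],
        "present": np.asarray(present).astype(int),
    })
    df.loc[~np.asarray(present, dtype=bool), ["x", "y", "z"]] = np.nan
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_trajectory_csv(path):
    """Read ``frame,t,x,y,z,present`` CSV; returns (times, values, present).

    Gap rows come back as NaN coordinate rows with ``present`` False.
    Malformed rows raise a parse error naming the offending line.
    """
    df = pd.read_csv(path)
    missing = [c for c in _TRAJ_COLS if c not in df.columns]
    if missing:
        raise InvalidParameterError(f"{path}: missing column(s) {missing}")
    present = df["present"].to_numpy().astype(bool)
    values = df[["x", "y", "z"]].apply(pd.to_numeric, errors="coerce") \
        .to_numpy(dtype=np.float64)
    bad = present & ~np.all(np.isfinite(values), axis=1)
    if bad.any():
        line = int(np.flatnonzero(bad)[0]) + 2  # header + 1-based
        raise InvalidParameterError(f"{path}: non-numeric coordinates at line {line}")
    values[~present] = np.nan
    return df["t"].to_numpy(dtype=np.float64), values, present


def write_estimates_csv(path, times, means, cov_diag=None,
                        q_diag=None, r_diag=None) -> None:
    """Estimates CSV mirroring the trajectory schema plus diagnostics columns."""
    means = np.asarray(means, dtype=np.float64)
    df = pd.DataFrame({
        "frame": np.arange(len(means)),
        "t": np.asarray(times, dtype=np.float64),
        "x": means[:, 0], "y": means[:, 1], "z": means[:, 2],
        "present": np.ones(len(means), dtype=int),
    })
    for name, arr in (("P", cov_diag), ("Q", q_diag), ("R", r_diag)):
        if arr is not None:
            arr = np.asarray(arr, dtype=np.float64)
            for k, ax in enumerate("xyz"[: arr.shape[1]]):
                df[f"{name}_{ax}{ax}"] = arr[:, k]
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def save_dataset(dataset: BenchmarkDataset, outdir) -> None:
    """Per-sequence CSVs (truth + measurements + annotations) and a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for i, seq in enumerate(dataset.sequences):
        df = pd.DataFrame({
            "frame": np.arange(len(seq.times)),
            "t": seq.times,
            "x": seq.positions[:, 0], "y": seq.positions[:, 1], "z": seq.positions[:, 2],
            "vx": seq.velocities[:, 0], "vy": seq.velocities[:, 1], "vz": seq.velocities[:, 2],
            "zx": seq.measurements[:, 0], "zy": seq.measurements[:, 1],
            "zz": seq.measurements[:, 2],
            "present": seq.present.astype(int),
            "sigma": seq.sigma,
            "regime": seq.regimes,
        })
        df.to_csv(outdir / f"sequence_{i:02d}.csv", index=False, float_format=_FLOAT_FMT)
    manifest = {
        "seed": dataset.seed,
        "n_sequences": len(dataset.sequences),
        "splits": {"train": dataset.train_idx, "test": dataset.test_idx,
                   "validation": dataset.val_idx},
        "sequence_seeds": [s.seed for s in dataset.sequences],
    }
    write_manifest(outdir / "manifest.json", manifest)


def load_dataset(indir) -> BenchmarkDataset:
    indir = Path(indir)
    with open(indir / "manifest.json") as fh:
        manifest = json.load(fh)
    sequences = []
    for i in range(manifest["n_sequences"]):
        df = pd.read_csv(indir / f"sequence_{i:02d}.csv")
        present = df["present"].to_numpy().astype(bool)
        z = df[["zx", "zy", "zz"]].to_numpy(dtype=np.float64)
        z[~present] = np.nan
        sequences.append(SimulatedSequence(
            times=df["t"].to_numpy(dtype=np.float64),
            positions=df[["x", "y", "z"]].to_numpy(dtype=np.float64),
            velocities=df[["vx", "vy", "vz"]].to_numpy(dtype=np.float64),
            measurements=z,
            present=present,
            sigma=df["sigma"].to_numpy(dtype=np.float64),
            regimes=df["regime"].to_numpy(dtype=str),
            seed=int(manifest["sequence_seeds"][i]),
        ))
    splits = manifest["splits"]
    return BenchmarkDataset(sequences, splits["train"], splits["test"],
                            splits["validation"], manifest["seed"])


def load_camera_config(path) -> tuple[CameraIntrinsics, ObserverPose]:
    """YAML/JSON camera config: K (9 numbers row-major), pose quaternion + position."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    K = np.asarray(cfg["intrinsics"]["K"], dtype=np.float64).reshape(3, 3)
    pose_cfg = cfg["pose"]
    if "quaternion_wxyz" in pose_cfg:
        pose = ObserverPose.from_quaternion(pose_cfg["quaternion_wxyz"],
                                            pose_cfg["position"])
    else:
        pose = ObserverPose(np.asarray(pose_cfg["R"], dtype=np.float64).reshape(3, 3),
                            pose_cfg["position"])
    return CameraIntrinsics(K), pose


def config_digest(obj) -> str:
    """Stable sha256 digest of a JSON-serializable configuration."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def write_manifest(path, config: dict) -> None:
    """Manifest = the config itself plus its digest (regeneration record)."""
    record = dict(config)
    record["config_digest"] = config_digest(config)
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2, default=str)
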