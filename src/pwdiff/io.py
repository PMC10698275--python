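"""Tabular file formats and run manifests.

Trajectories travel as CSV with columns ``traj_id, frame, x, y`` (0-based
integer frames on a fixed interval), labels as ``traj_id, frame, D_true,
alpha_true, model_tag``, pointwise predictions as ``traj_id, frame, value,
target`` and segment tables as ``traj_id, start, end, tau, mean_D,
mean_alpha``.  Every artifact a command writes is accompanied by a YAML
manifest (config, seed, package version, config hash) sufficient to
regenerate it.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .trajectory import GroundTruthProfile, PointwiseProfile, Trajectory

__all__ = [
    "read_trajectories",
    "write_trajectories",
    "read_labels",
    "write_labels",
    "read_profiles",
    "write_profiles",
    "write_manifest",
    "read_manifest",
]

TRAJ_COLUMNS = ["traj_id", "frame", "x", "y"]


def write_trajectories(path, trajectories: list[Trajectory]) -> None:
    frames = [
        pd.DataFrame({
            "traj_id": t.traj_id,
            "frame": np.arange(t.n),
            "x": t.positions[:, 0],
            "y": t.positions[:, 1],
        })
        for t in trajectories
    ]
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=TRAJ_COLUMNS)
    df.to_csv(path, index=False, float_format="%.17g")


def read_trajectories(path, dt: float = 1.0, strict: bool = True) -> list[Trajectory]:
    """Load trajectories from CSV.

    In strict mode a gap or repetition in the frame numbering raises an
    error naming the trajectory and frame; with ``strict=False`` gaps are
    filled by linear interpolation.
    """
    df = pd.read_csv(path)
    if df.empty:
        warnings.warn(f"{path}: no trajectories found", stacklevel=2)
        return []
    missing = set(TRAJ_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if df[["x", "y"]].isna().any().any():
        raise ValueError(f"{path}: NaN coordinates")
    out = []
    for tid, grp in df.groupby("traj_id", sort=False):
        frames = grp["frame"].to_numpy()
        if np.any(np.diff(frames) <= 0):
            bad = frames[np.argmax(np.diff(frames) <= 0) + 1]
            raise ValueError(f"{path}: non-monotone frames in trajectory {tid} at frame {bad}")
        gaps = np.diff(frames) != 1
        if gaps.any():
            if strict:
                bad = int(frames[:-1][gaps][0])
                raise ValueError(
                    f"{path}: frame gap in trajectory {tid} after frame {bad} "
                    "(use strict=False to interpolate)"
                )
            full = np.arange(frames[0], frames[-1] + 1)
            x = np.interp(full, frames, grp["x"].to_numpy())
            y = np.interp(full, frames, grp["y"].to_numpy())
        else:
            x, y = grp["x"].to_numpy(), grp["y"].to_numpy()
        out.append(Trajectory(np.column_stack([x, y]), dt=dt, traj_id=tid))
    return out


def write_labels(path, data: list[tuple[Trajectory, GroundTruthProfile]]) -> None:
    frames = [
        pd.DataFrame({
            "traj_id": t.traj_id,
            "frame": np.arange(g.n),
            "D_true": g.D_true,
            "alpha_true": g.alpha_true,
            "model_tag": g.model_tag,
        })
        for t, g in data
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


def read_labels(path) -> dict[object, GroundTruthProfile]:
    df = pd.read_csv(path)
    out = {}
    for tid, grp in df.groupby("traj_id", sort=False):
        D = grp["D_true"].to_numpy(float)
        cps = np.where(
            (np.diff(D) != 0) | (np.diff(grp["alpha_true"].to_numpy(float)) != 0)
        )[0] + 1
        out[tid] = GroundTruthProfile(
            D_true=D,
            alpha_true=grp["alpha_true"].to_numpy(float),
            model_tag=grp["model_tag"].to_numpy(),
            changepoints=cps,
        )
    return out


def write_profiles(path, profiles: list[PointwiseProfile]) -> None:
    frames = [
        pd.DataFrame({
            "traj_id": p.traj_id,
            "frame": np.arange(p.n),
            "value": p.values,
            "target": p.target,
        })
        for p in profiles
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


def read_profiles(path) -> list[PointwiseProfile]:
    df = pd.read_csv(path)
    return [
        PointwiseProfile(
            values=grp["value"].to_numpy(float),
            target=str(grp["target"].iloc[0]),
            traj_id=tid,
        )
        for tid, grp in df.groupby("traj_id", sort=False)
    ]


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def write_manifest(path, config: dict, seed: int | None) -> None:
    from . import __version__

    manifest = {
        "config": config,
        "seed": seed,
        "version": __version__,
        "config_hash": _config_hash(config),
    }
    Path(path).write_text(yaml.safe_dump(manifest, sort_keys=False))


def read_manifest(path) -> dict:
    return yaml.safe_load(Path(path).read_text())
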