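"""File formats: trajectory CSV, TIFF stacks, sidecar JSON, ground-truth JSON.

Conventions (also stated in every CSV header comment): 0-based pixel
indices, pixel-centre origin, x = column, y = row, micrometres after
scaling; ``t_s`` = frame / fps is stored redundantly for human inspection —
``frame`` is authoritative. Every artifact gets a sidecar JSON recording
the package version, a hash of the resolved configuration, and the seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .trajectory import Spot, Trajectory

TRAJECTORY_COLUMNS = ["track_id", "frame", "t_s", "x_um", "y_um",
                      "radius_um", "intensity"]
_HEADER = ("# spermwall trajectory table; coordinates in um, x=column y=row, "
           "pixel-centre origin, 0-based frames; frame is authoritative, "
           "t_s = frame/fps\n")


def trajectories_to_dataframe(trajectories: Sequence[Trajectory],
                              fps: float) -> pd.DataFrame:
    rows = [
        (t.id, s.frame, s.frame / fps, s.x, s.y, s.radius, s.intensity)
        for t in trajectories for s in t.spots
    ]
    return pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS)


def write_trajectories_csv(path: str | Path, trajectories: Sequence[Trajectory],
                           fps: float) -> Path:
    path = Path(path)
    df = trajectories_to_dataframe(trajectories, fps)
    with open(path, "w") as fh:
        fh.write(_HEADER)
        df.to_csv(fh, index=False)
    return path


def read_trajectories_csv(path: str | Path) -> list[Trajectory]:
    """Read a trajectory CSV back into Trajectory objects (source='imported').

    Schema is validated; malformed rows raise with the offending line
    number.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col in ("frame", "x_um", "y_um"):
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise ValueError(f"{path}: malformed value in column {col!r} "
                             f"at data row {int(bad[0]) + 1}")
    trajectories = []
    for tid, sub in df.groupby("track_id", sort=True):
        sub = sub.sort_values("frame")
        spots = [Spot(frame=int(r.frame), x=float(r.x_um), y=float(r.y_um),
                      radius=float(r.radius_um) if np.isfinite(r.radius_um) else 1.0,
                      intensity=float(r.intensity))
                 for r in sub.itertuples()]
        trajectories.append(Trajectory(id=str(tid), spots=spots, source="imported"))
    return trajectories


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items() if k != "true_path"}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def write_sidecar(artifact_path: str | Path, config, seed: int,
                  extra: dict | None = None) -> Path:
    """Write ``<artifact>.json`` recording version, config hash, and seed."""
    artifact_path = Path(artifact_path)
    cfg = _jsonable(config)
    payload = {"version": __version__, "seed": seed,
               "config_hash": config_hash(cfg), "config": cfg}
    payload.update(extra or {})
    out = artifact_path.with_suffix(artifact_path.suffix + ".json")
    out.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return out


def write_stack_tiff(path: str | Path, stack: np.ndarray, pixel_size_um: float,
                     fps: float) -> Path:
    """Write a (T, H, W) or (T, C, H, W) stack as multi-frame TIFF.

    Pixel size and frame rate are recorded in the ImageJ-style metadata and
    must also travel in the sidecar (TIFF tags alone are easy to lose).
    """
    path = Path(path)
    axes = "TCYX" if stack.ndim == 4 else "TYX"
    tifffile.imwrite(
        path, stack, imagej=True,
        resolution=(1.0 / pixel_size_um, 1.0 / pixel_size_um),
        metadata={"axes": axes, "unit": "um", "finterval": 1.0 / fps})
    return path


def read_stack_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path))


def write_ground_truth_json(path: str | Path, truth) -> Path:
    """Persist wall line, turn events and true effect sizes (not the images)."""
    path = Path(path)
    payload = {
        "wall": {"point": list(truth.wall.point),
                 "direction": list(truth.wall.direction)},
        "turn_events": [dataclasses.asdict(e) for e in truth.turn_events],
        "true_params": _jsonable(truth.true_params),
        "hook_sides": {t.id: t.meta.get("hook_side") for t in truth.trajectories},
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return path
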