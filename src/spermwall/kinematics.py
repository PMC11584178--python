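"""CASA kinetic parameters plus the straight line-to-sideward movement ratio (SWR).

For a trajectory of spots p_0 … p_{n-1} spanning frames f_0 … f_{n-1} at a
frame rate ``fps``:

* duration  T  = (f_{n-1} − f_0) / fps  — gap-closed missing frames count in
  the span;
* VCL (curvilinear velocity)  = Σ‖p_{i+1} − p_i‖ / T, each closed gap
  contributing one straight segment;
* VSL (straight-line velocity) = ‖p_{n-1} − p_0‖ / T;
* LIN (linearity of forward progression) = VSL / VCL ∈ [0, 1];
* maximum sideward movement = width of the narrowest band parallel to the
  displacement line (first→last spot) containing every spot, i.e. the
  peak-to-peak extent of the spots projected on the unit normal of the
  displacement direction;
* SWR = track displacement / maximum sideward movement.

Degenerate quantities (LIN with VCL = 0, SWR of a perfectly straight or
closed track) are reported as NaN — an explicit "undefined" marker that
downstream statistics drop, never as zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trajectory import Trajectory

#: below this band width (µm) a track counts as perfectly straight and SWR is undefined
STRAIGHT_EPS_UM = 1e-9


@dataclass(frozen=True)
class KineticParams:
    """All four kinetic parameters and their intermediates for one trajectory."""

    vcl: float            # µm/s
    vsl: float            # µm/s
    lin: float            # dimensionless, [0, 1]; NaN if VCL = 0
    swr: float            # dimensionless, >= 0; NaN if track is straight/closed
    total_path_um: float
    displacement_um: float
    duration_s: float
    max_sideward_um: float


def _require_spots(traj: Trajectory, n: int = 2) -> None:
    if len(traj) < n:
        raise ValueError(
            f"track {traj.id}: kinematics need >= {n} spots, got {len(traj)}"
        )


def total_time(traj: Trajectory, fps: float) -> float:
    """Track duration in seconds, first frame to last frame (gaps included)."""
    _require_spots(traj)
    if fps <= 0:
        raise ValueError(f"fps must be > 0, got {fps}")
    return (traj.last.frame - traj.first.frame) / fps


def total_path(traj: Trajectory) -> float:
    """Total distance travelled (µm): sum of consecutive inter-spot distances."""
    _require_spots(traj)
    steps = np.diff(traj.xy, axis=0)
    return float(np.hypot(steps[:, 0], steps[:, 1]).sum())


def vcl(traj: Trajectory, fps: float) -> float:
    """Curvilinear velocity (µm/s): total path length over track duration."""
    return total_path(traj) / total_time(traj, fps)


def vsl(traj: Trajectory, fps: float) -> float:
    """Straight-line velocity (µm/s): first→last displacement over duration."""
    _require_spots(traj)
    return traj.displacement_um / total_time(traj, fps)


def lin(traj: Trajectory, fps: float) -> float:
    """Linearity VSL/VCL in [0, 1]; NaN when VCL = 0 (stationary track)."""
    v_curv = vcl(traj, fps)
    if v_curv == 0.0:
        return float("nan")
    return min(vsl(traj, fps) / v_curv, 1.0)


def max_sideward(traj: Trajectory) -> float:
    """Maximum sideward movement distance (µm).

    Width of the narrowest band parallel to the displacement line that
    contains all spots: project every spot on the unit normal of the
    first→last direction and take max − min. NaN when the displacement is
    zero (the band direction is undefined).
    """
    _require_spots(traj)
    p = traj.xy
    d = p[-1] - p[0]
    norm = np.hypot(*d)
    if norm == 0.0:
        return float("nan")
    n_hat = np.array([-d[1], d[0]]) / norm
    proj = p @ n_hat
    return float(proj.max() - proj.min())


def swr(traj: Trajectory) -> float:
    """Straight line-to-sideward movement ratio: displacement / max sideward.

    NaN for zero displacement (closed track) and for perfectly straight
    tracks (band width below ``STRAIGHT_EPS_UM``); both are recorded as
    undefined and excluded from downstream statistics.
    """
    _require_spots(traj)
    disp = traj.displacement_um
    if disp == 0.0:
        return float("nan")
    width = max_sideward(traj)
    if not width > STRAIGHT_EPS_UM:
        return float("nan")
    return disp / width


def compute_all(traj: Trajectory, fps: float) -> KineticParams:
    """All parameters for one trajectory; degenerate fields carry NaN."""
    _require_spots(traj)
    t = total_time(traj, fps)
    path = total_path(traj)
    disp = traj.displacement_um
    v_curv = path / t
    v_str = disp / t
    return KineticParams(
        vcl=v_curv,
        vsl=v_str,
        lin=float("nan") if v_curv == 0.0 else min(v_str / v_curv, 1.0),
        swr=swr(traj),
        total_path_um=path,
        displacement_um=disp,
        duration_s=t,
        max_sideward_um=max_sideward(traj),
    )


def compute_table(trajectories: list[Trajectory], fps: float) -> pd.DataFrame:
    """One-row-per-track parameter table.

    Columns: track_id, n_spots, duration_s, vcl, vsl, lin, swr,
    displacement_um, max_sideward_um. Tracks with fewer than two spots are
    skipped (they have no kinematics) rather than aborting the batch.
    """
    rows = []
    for traj in trajectories:
        if len(traj) < 2:
            continue
        k = compute_all(traj, fps)
        rows.append(
            dict(
                track_id=traj.id,
                n_spots=len(traj),
                duration_s=k.duration_s,
                vcl=k.vcl,
                vsl=k.vsl,
                lin=k.lin,
                swr=k.swr,
                displacement_um=k.displacement_um,
                max_sideward_um=k.max_sideward_um,
            )
        )
    columns = [
        "track_id", "n_spots", "duration_s", "vcl", "vsl", "lin", "swr",
        "displacement_um", "max_sideward_um",
    ]
    return pd.DataFrame(rows, columns=columns)
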