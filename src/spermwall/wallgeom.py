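"""Wall geometry: boundary extraction, line fitting, and trajectory–wall relations.

The uterine wall is modelled as a straight line fitted to the boundary
pixels of a binary wall mask. Each trajectory is then characterised by two
covariates: the perpendicular distance from its temporal midpoint spot to
the line, and the acute angle between its displacement line and the wall.
A turn classifier labels wall-contact events pro- or anti-wall-hook from
the along-wall direction taken after contact relative to the sperm's fixed
hook side.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .trajectory import Trajectory

#: perpendicular distance (µm) below which a spot counts as touching the wall;
#: on the order of one head length.
CONTACT_THRESHOLD_UM = 2.0

HookSide = Literal["left", "right"]
TurnLabel = Literal["pro", "anti", "none"]


@dataclass(frozen=True)
class WallModel:
    """Fitted straight-line wall in µm coordinates (point + unit direction)."""

    point: tuple[float, float]
    direction: tuple[float, float]
    fit_rmse_um: float = 0.0
    n_points: int = 0

    def __post_init__(self) -> None:
        norm = float(np.hypot(*self.direction))
        if not np.isclose(norm, 1.0, atol=1e-9):
            raise ValueError(f"wall direction must be a unit vector, |d| = {norm}")
        if self.fit_rmse_um < 0:
            raise ValueError("fit_rmse_um must be >= 0")

    @property
    def normal(self) -> np.ndarray:
        """Unit normal, 90° counter-clockwise from the direction."""
        dx, dy = self.direction
        return np.array([-dy, dx], dtype=float)

    def signed_offset(self, points: np.ndarray) -> np.ndarray:
        """Signed perpendicular offset (µm) of (..., 2) points; sign follows ``normal``."""
        p = np.asarray(points, dtype=float) - np.asarray(self.point, dtype=float)
        return p @ self.normal

    def distance(self, points: np.ndarray) -> np.ndarray:
        return np.abs(self.signed_offset(points))

    @property
    def angle_rad(self) -> float:
        """Orientation of the line folded to [0, π/2] relative to the x-axis."""
        dx, dy = self.direction
        a = abs(np.arctan2(dy, dx))
        return float(min(a, np.pi - a))


@dataclass(frozen=True)
class WallRelation:
    """The two wall covariates of one trajectory."""

    distance_um: float
    angle_rad: float

    def __post_init__(self) -> None:
        if self.distance_um < 0:
            raise ValueError("distance_um must be >= 0")
        if not (np.isnan(self.angle_rad) or 0.0 <= self.angle_rad <= np.pi / 2 + 1e-12):
            raise ValueError("angle_rad must lie in [0, pi/2]")


def extract_boundary(mask: np.ndarray, pixel_size_um: float) -> np.ndarray:
    """Boundary points (µm) of a binary mask.

    A boundary pixel is foreground with at least one background 4-neighbour;
    the image border itself does not count as background (a half-plane mask
    yields only its true edge row/column). Returns an (n, 2) array of
    (x, y) = (col, row) · pixel_size, pixel-centre convention, sorted by
    (row, col) for determinism.
    """
    m = np.asarray(mask).astype(bool)
    if m.ndim != 2:
        raise ValueError("mask must be a 2-D binary image")
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be > 0")
    if not m.any():
        raise ValueError("mask has no foreground pixels")
    if m.all():
        raise ValueError("mask has no background pixels")
    padded = np.pad(m, 1, mode="edge")  # border pixels see themselves, not background
    interior_bg = (
        ~padded[:-2, 1:-1] | ~padded[2:, 1:-1] | ~padded[1:-1, :-2] | ~padded[1:-1, 2:]
    )
    boundary = m & interior_bg
    rows, cols = np.nonzero(boundary)
    return np.column_stack([cols, rows]).astype(float) * pixel_size_um


def fit_wall(points: np.ndarray, method: Literal["ols", "tls"] = "ols") -> WallModel:
    """Fit a straight line to boundary points.

    ``ols`` regresses the minor-extent coordinate on the major-extent one
    (y on x when the x-range dominates, x on y otherwise), which keeps
    near-vertical walls well-posed. ``tls`` is an orthogonal
    (total-least-squares) fit via the principal axis of the point cloud.
    ``fit_rmse_um`` is the RMS perpendicular residual in both cases.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    if len(np.unique(pts, axis=0)) < 2:
        raise ValueError("need >= 2 distinct points to fit a wall line")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        raise ValueError("zero variance on both axes")

    centre = pts.mean(axis=0)
    if method == "tls":
        _, _, vt = np.linalg.svd(pts - centre, full_matrices=False)
        direction = vt[0]
    elif np.ptp(x) >= np.ptp(y):
        slope = np.polyfit(x, y, 1)[0]
        direction = np.array([1.0, slope])
    else:
        slope = np.polyfit(y, x, 1)[0]
        direction = np.array([slope, 1.0])
    direction = direction / np.hypot(*direction)

    model = WallModel(
        point=(float(centre[0]), float(centre[1])),
        direction=(float(direction[0]), float(direction[1])),
        fit_rmse_um=0.0,
        n_points=len(pts),
    )
    rmse = float(np.sqrt(np.mean(model.signed_offset(pts) ** 2)))
    return WallModel(point=model.point, direction=model.direction,
                     fit_rmse_um=rmse, n_points=len(pts))


def wall_distance(traj: Trajectory, wall: WallModel,
                  midpoint: Literal["temporal", "centroid"] = "temporal") -> float:
    """Perpendicular distance (µm) from the trajectory's midpoint to the wall.

    The midpoint is the temporal midpoint spot (index ⌊(n−1)/2⌋) by default;
    the spatial centroid is available behind the ``midpoint`` switch.
    """
    if len(traj) == 0:
        raise ValueError(f"track {traj.id}: empty trajectory")
    if midpoint == "centroid":
        p = traj.xy.mean(axis=0)
    else:
        p = traj.midpoint_spot().xy
    return float(wall.distance(p))


def wall_angle(traj: Trajectory, wall: WallModel) -> float:
    """Acute angle (rad, in [0, π/2]) between the displacement line and the wall.

    NaN when the trajectory has zero displacement (no direction).
    """
    if len(traj) < 2 or traj.displacement_um == 0.0:
        return float("nan")
    d = traj.xy[-1] - traj.xy[0]
    u = d / np.hypot(*d)
    w = np.asarray(wall.direction)
    return float(np.arccos(np.clip(abs(u @ w), 0.0, 1.0)))


def relate(traj: Trajectory, wall: WallModel, **kwargs) -> WallRelation:
    return WallRelation(distance_um=wall_distance(traj, wall, **kwargs),
                        angle_rad=wall_angle(traj, wall))


def _cross(a: np.ndarray, b: np.ndarray) -> float:
    return float(a[0] * b[1] - a[1] * b[0])


def classify_turn(traj: Trajectory, wall: WallModel, hook_side: HookSide,
                  contact_threshold_um: float = CONTACT_THRESHOLD_UM,
                  k: int = 3) -> TurnLabel:
    """Label a wall-contact turn pro- or anti-wall-hook.

    The contact frame is the first spot whose perpendicular wall distance
    falls below ``contact_threshold_um``. Headings are averaged over ``k``
    frames on each side of contact (net displacement over the window). The
    post-contact along-wall direction is the wall direction signed by the
    post-contact heading; the turn is **pro** when that direction lies on
    the sperm's hook side of the pre-contact heading ("left" = positive
    cross product pre × along-wall), **anti** on the opposite side, and
    **none** when the track never touches the wall. Ambiguous geometry
    (pre-contact heading exactly along the wall) resolves to anti.
    """
    if hook_side not in ("left", "right"):
        raise ValueError(f"hook_side must be 'left' or 'right', got {hook_side!r}")
    p = traj.xy
    dist = wall.distance(p)
    contact = np.nonzero(dist < contact_threshold_um)[0]
    if contact.size == 0:
        return "none"
    i = int(contact[0])
    if i - k < 0 or i + k >= len(p):
        raise ValueError(
            f"track {traj.id}: contact at spot {i} leaves < {k} spots on one side"
        )
    pre = p[i] - p[i - k]
    post = p[i + k] - p[i]
    w = np.asarray(wall.direction, dtype=float)
    along = w if post @ w >= 0 else -w
    z = _cross(pre, along)
    if z == 0.0:
        return "anti"
    return "pro" if (z > 0) == (hook_side == "left") else "anti"


def classify_turns(trajectories: Sequence[Trajectory], wall: WallModel,
                   contact_threshold_um: float = CONTACT_THRESHOLD_UM,
                   k: int = 3) -> dict[str, TurnLabel]:
    """Classify every trajectory carrying a ``hook_side`` in its metadata.

    Tracks that are too short to average headings around contact are skipped.
    """
    labels: dict[str, TurnLabel] = {}
    for traj in trajectories:
        side = traj.meta.get("hook_side")
        if side is None:
            continue
        try:
            labels[traj.id] = classify_turn(
                traj, wall, side, contact_threshold_um=contact_threshold_um, k=k)
        except ValueError:
            continue
    return labels
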