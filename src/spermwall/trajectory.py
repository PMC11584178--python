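"""Core containers: detected/simulated spots and time-ordered trajectories.

Coordinates are 2-D, in micrometres, image convention: x = column, y = row,
origin at the centre of pixel (0, 0). Frames are 0-based integer indices;
gaps (missing frames inside a track) are allowed and carry no interpolated
spots.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np

Source = Literal["tracked", "simulated", "imported"]


@dataclass(frozen=True)
class Spot:
    """One sperm-head position at one frame.

    ``radius`` is the equivalent-disc radius of the detected component in
    micrometres; ``intensity`` is in arbitrary camera units.
    """

    frame: int
    x: float
    y: float
    radius: float = 1.0
    intensity: float = 0.0

    def __post_init__(self) -> None:
        if self.frame < 0:
            raise ValueError(f"frame must be >= 0, got {self.frame}")
        if not self.radius > 0:
            raise ValueError(f"radius must be > 0, got {self.radius}")

    @property
    def xy(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


@dataclass
class Trajectory:
    """Time-ordered spots of one sperm head.

    Frames must be strictly increasing; gaps are permitted (the tracker's
    gap-closing step produces them) and downstream kinematics bridge each
    gap with a single straight segment.
    """

    id: str
    spots: list[Spot]
    source: Source = "imported"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        frames = [s.frame for s in self.spots]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise ValueError(f"track {self.id}: frames must be strictly increasing")

    def __len__(self) -> int:
        return len(self.spots)

    @property
    def frames(self) -> np.ndarray:
        return np.array([s.frame for s in self.spots], dtype=int)

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) array of spot positions in µm."""
        if not self.spots:
            return np.empty((0, 2), dtype=float)
        return np.array([[s.x, s.y] for s in self.spots], dtype=float)

    @property
    def first(self) -> Spot:
        return self.spots[0]

    @property
    def last(self) -> Spot:
        return self.spots[-1]

    @property
    def displacement_um(self) -> float:
        """Euclidean distance between the first and last spots (track displacement)."""
        if len(self.spots) < 2:
            return 0.0
        return float(np.hypot(self.last.x - self.first.x, self.last.y - self.first.y))

    def midpoint_spot(self) -> Spot:
        """Temporal midpoint spot: index floor((n-1)/2) of the retained spots."""
        if not self.spots:
            raise ValueError(f"track {self.id}: empty trajectory has no midpoint")
        return self.spots[(len(self.spots) - 1) // 2]

    def transformed(self, rotation_rad: float = 0.0, dx: float = 0.0, dy: float = 0.0,
                    scale: float = 1.0) -> "Trajectory":
        """Return a copy under rotation-then-scale-then-translation (testing aid)."""
        c, s = np.cos(rotation_rad), np.sin(rotation_rad)
        spots = [
            Spot(
                frame=sp.frame,
                x=scale * (c * sp.x - s * sp.y) + dx,
                y=scale * (s * sp.x + c * sp.y) + dy,
                radius=sp.radius,
                intensity=sp.intensity,
            )
            for sp in self.spots
        ]
        return Trajectory(id=self.id, spots=spots, source=self.source, meta=dict(self.meta))


def group_spots_by_frame(spots: Iterable[Spot]) -> dict[int, list[Spot]]:
    """Bucket spots by frame index, each bucket sorted by (x, y) for determinism."""
    by_frame: dict[int, list[Spot]] = {}
    for s in spots:
        by_frame.setdefault(s.frame, []).append(s)
    for f in by_frame:
        by_frame[f].sort(key=lambda s: (s.x, s.y))
    return by_frame
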