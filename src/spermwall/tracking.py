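"""Spot detection and trajectory linking.

A simplified single-particle tracker in the TrackMate mould:

1. **detect** — Gaussian smoothing, global (Otsu or absolute) threshold,
   8-connected components, intensity-weighted centroids; components whose
   equivalent-disc radius is at or below a minimum head radius are dropped.
2. **link** — for each consecutive frame pair, a gated linear assignment
   problem: link cost is the squared Euclidean distance, links longer than
   the gate are forbidden, and every spot has a non-link alternative priced
   at the squared gate, so the solution is the maximum-cardinality matching
   of minimum total squared distance within the gate.
3. **close gaps** — a second assignment over (segment end, segment start)
   pairs separated by 1..max_gap_frames frames and at most the gap-closing
   distance; accepted pairs are concatenated with the missing frames left
   absent.
4. **filter** — minimum spots per track and a minimum net displacement to
   reject immotile debris.

Splitting/merging and motion-model prediction are deliberately out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label, regionprops

from .trajectory import Spot, Trajectory, group_spots_by_frame

logger = logging.getLogger(__name__)

_FORBIDDEN = 1e30  # cost of a gated-out link; never selected when alternatives exist


@dataclass(frozen=True)
class TrackingConfig:
    """Detection and linking parameters (lengths in µm).

    Defaults follow the gates used for uterine sperm-head tracking:
    minimum head radius 0.75 µm, frame-to-frame linking and gap-closing
    distance 11 µm, at most 2 skipped frames, at least 7 spots per track,
    and a 2.5 µm minimum net displacement. ``detect_threshold`` is either
    the string ``"otsu"`` or an absolute intensity value.
    """

    detect_sigma_um: float = 1.0
    detect_threshold: float | Literal["otsu"] = "otsu"
    min_radius_um: float = 0.75
    max_link_um: float = 11.0
    max_gap_frames: int = 2
    max_gap_um: float = 11.0
    min_spots: int = 7
    min_displacement_um: float = 2.5

    def __post_init__(self) -> None:
        for name in ("detect_sigma_um", "min_radius_um", "max_link_um", "max_gap_um"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.max_gap_frames < 0:
            raise ValueError("max_gap_frames must be >= 0")


@dataclass
class RejectedTrack:
    track_id: str
    reason: str
    n_spots: int
    displacement_um: float


@dataclass
class FilterReport:
    kept: list[Trajectory]
    rejected: list[RejectedTrack] = field(default_factory=list)


def detect_spots(frame: np.ndarray, pixel_size_um: float,
                 config: TrackingConfig = TrackingConfig()) -> list[Spot]:
    """Detect sperm-head spots in one image frame.

    Returns spots in µm coordinates (x = column, y = row, pixel-centre
    origin), sorted by (x, y). A blank or constant frame yields an empty
    list.
    """
    img = np.asarray(frame, dtype=float)
    if img.ndim != 2:
        raise ValueError("frame must be a single-channel 2-D image")
    if img.size == 0:
        raise ValueError("empty image")
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be > 0")

    smoothed = gaussian(img, sigma=config.detect_sigma_um / pixel_size_um,
                        preserve_range=True)
    if config.detect_threshold == "otsu":
        if np.ptp(smoothed) == 0:
            return []
        thr = threshold_otsu(smoothed)
    else:
        thr = float(config.detect_threshold)
    binary = smoothed > thr
    if not binary.any():
        return []

    spots: list[Spot] = []
    for region in regionprops(label(binary, connectivity=2), intensity_image=img):
        radius = float(np.sqrt(region.area / np.pi) * pixel_size_um)
        if radius <= config.min_radius_um:
            continue
        row, col = region.centroid_weighted
        spots.append(Spot(frame=0, x=float(col) * pixel_size_um,
                          y=float(row) * pixel_size_um, radius=radius,
                          intensity=float(region.intensity_mean)))
    spots.sort(key=lambda s: (s.x, s.y))
    return spots


def detect_stack(stack: np.ndarray, pixel_size_um: float,
                 config: TrackingConfig = TrackingConfig()) -> dict[int, list[Spot]]:
    """Run detection on every frame of a (T, H, W) stack; keys are frame indices."""
    out: dict[int, list[Spot]] = {}
    for f, frame in enumerate(np.asarray(stack)):
        found = detect_spots(frame, pixel_size_um, config)
        out[f] = [Spot(frame=f, x=s.x, y=s.y, radius=s.radius, intensity=s.intensity)
                  for s in found]
    return out


def _gated_assignment(src: np.ndarray, dst: np.ndarray, gate: float
                      ) -> list[tuple[int, int]]:
    """Maximum-cardinality, minimum-total-squared-distance matching within a gate.

    Solved as a padded linear assignment problem: real links cost d², the
    non-link alternative for each point costs gate², and links with d > gate
    are forbidden. Because d² ≤ gate² < 2·gate², every admissible link is
    preferred over leaving both endpoints unmatched, so the optimum is the
    maximum matching of least total squared distance.
    """
    n, m = len(src), len(dst)
    if n == 0 or m == 0:
        return []
    d2 = ((src[:, None, :] - dst[None, :, :]) ** 2).sum(axis=2)
    gate2 = gate * gate
    top_left = np.where(d2 <= gate2, d2, _FORBIDDEN)
    top_right = np.full((n, n), _FORBIDDEN)
    np.fill_diagonal(top_right, gate2)
    bottom_left = np.full((m, m), _FORBIDDEN)
    np.fill_diagonal(bottom_left, gate2)
    bottom_right = np.zeros((m, n))
    cost = np.block([[top_left, top_right], [bottom_left, bottom_right]])
    rows, cols = linear_sum_assignment(cost)
    return [(int(r), int(c)) for r, c in zip(rows, cols)
            if r < n and c < m and d2[r, c] <= gate2]


def link_spots(spots_by_frame: dict[int, Sequence[Spot]],
               config: TrackingConfig = TrackingConfig()) -> list[Trajectory]:
    """Link spots frame-to-frame into track segments.

    Consecutive frame pairs are solved independently with the gated
    assignment; spots left unmatched start new segments. Segment identities
    are assigned deterministically by (first frame, first x, first y); spots
    inside a frame are processed in (x, y) order so equal-cost assignments
    resolve reproducibly. Duplicate coordinates within one frame are
    permitted but logged.
    """
    by_frame = group_spots_by_frame(
        s for frame_spots in spots_by_frame.values() for s in frame_spots)
    if not by_frame:
        return []
    for f, spots in by_frame.items():
        coords = {(s.x, s.y) for s in spots}
        if len(coords) < len(spots):
            logger.warning("frame %d: duplicate spot coordinates", f)

    frames = sorted(by_frame)
    segments: list[list[Spot]] = []
    open_by_spot: dict[int, int] = {}  # index into current frame's spots -> segment idx

    prev_spots: list[Spot] = []
    for f in range(frames[0], frames[-1] + 1):
        cur_spots = by_frame.get(f, [])
        next_open: dict[int, int] = {}
        if prev_spots and cur_spots:
            src = np.array([[s.x, s.y] for s in prev_spots])
            dst = np.array([[s.x, s.y] for s in cur_spots])
            for i, j in _gated_assignment(src, dst, config.max_link_um):
                seg = open_by_spot[i]
                segments[seg].append(cur_spots[j])
                next_open[j] = seg
        for j, s in enumerate(cur_spots):
            if j not in next_open:
                segments.append([s])
                next_open[j] = len(segments) - 1
        prev_spots, open_by_spot = cur_spots, next_open

    ordered = sorted(segments, key=lambda ss: (ss[0].frame, ss[0].x, ss[0].y))
    width = max(4, len(str(len(ordered))))
    return [Trajectory(id=f"t{idx:0{width}d}", spots=ss, source="tracked")
            for idx, ss in enumerate(ordered)]


def close_gaps(segments: Sequence[Trajectory],
               config: TrackingConfig = TrackingConfig()) -> list[Trajectory]:
    """Merge segments across short gaps.

    Candidate pairs are (end of A, start of B) with frame gap in
    [1, max_gap_frames] and end-to-start distance at most ``max_gap_um``;
    the gated assignment picks the globally best set, and chains of merges
    are concatenated. Missing frames stay absent (no interpolation).
    """
    segs = list(segments)
    if len(segs) < 2:
        return list(segs)

    n = len(segs)
    ends = np.array([[s.last.x, s.last.y] for s in segs])
    starts = np.array([[s.first.x, s.first.y] for s in segs])
    end_f = np.array([s.last.frame for s in segs])
    start_f = np.array([s.first.frame for s in segs])

    gap = start_f[None, :] - end_f[:, None]
    d2 = ((ends[:, None, :] - starts[None, :, :]) ** 2).sum(axis=2)
    gate2 = config.max_gap_um ** 2
    admissible = (gap >= 1) & (gap <= config.max_gap_frames) & (d2 <= gate2)
    np.fill_diagonal(admissible, False)

    top_left = np.where(admissible, d2, _FORBIDDEN)
    top_right = np.full((n, n), _FORBIDDEN)
    np.fill_diagonal(top_right, gate2)
    bottom_left = np.full((n, n), _FORBIDDEN)
    np.fill_diagonal(bottom_left, gate2)
    cost = np.block([[top_left, top_right], [bottom_left, np.zeros((n, n))]])
    rows, cols = linear_sum_assignment(cost)
    successor: dict[int, int] = {int(r): int(c) for r, c in zip(rows, cols)
                                 if r < n and c < n and admissible[r, c]}

    has_predecessor = set(successor.values())
    merged: list[Trajectory] = []
    for i, seg in enumerate(segs):
        if i in has_predecessor:
            continue
        spots = list(seg.spots)
        j = i
        while j in successor:
            j = successor[j]
            spots.extend(segs[j].spots)
        merged.append(Trajectory(id=seg.id, spots=spots, source="tracked",
                                 meta=dict(seg.meta)))
    merged.sort(key=lambda t: (t.first.frame, t.first.x, t.first.y))
    return merged


def filter_tracks(tracks: Sequence[Trajectory],
                  config: TrackingConfig = TrackingConfig()) -> FilterReport:
    """Apply the track-quality gates.

    Keeps tracks with at least ``min_spots`` spots (default 7, i.e. more
    than 6) whose net displacement exceeds ``min_displacement_um`` (default
    2.5 µm — a minimum gate that removes immotile debris). Everything else
    lands in the rejection report with a reason.
    """
    report = FilterReport(kept=[])
    for t in tracks:
        if len(t) < config.min_spots:
            report.rejected.append(RejectedTrack(t.id, "min_spots", len(t),
                                                 t.displacement_um))
        elif not t.displacement_um > config.min_displacement_um:
            report.rejected.append(RejectedTrack(t.id, "min_displacement", len(t),
                                                 t.displacement_um))
        else:
            report.kept.append(t)
    return report


def track_stack(stack: np.ndarray, pixel_size_um: float,
                config: TrackingConfig = TrackingConfig()) -> FilterReport:
    """Full pipeline on a (T, H, W) stack: detect → link → close gaps → filter."""
    spots = detect_stack(stack, pixel_size_um, config)
    segments = link_spots(spots, config)
    closed = close_gaps(segments, config)
    return filter_tracks(closed, config)
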