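"""Synthetic near-wall sperm swimming: ground-truth trajectories and image stacks.

The generator emulates the regime the analysis pipeline is built for:
two-photon time-lapse movies (512×512 px, 30 fps by default) of
fluorescent sperm heads swimming in a uterine lumen bounded by a dark wall
with a roughly straight boundary. Each sperm is a persistent random walk
whose log frame-speed follows a linear model in its wall distance and wall
angle,

    log s_t = base_log_vcl + beta_distance · d_t + beta_angle · θ_t + ε_t,
    ε_t ~ N(0, speed_noise_sd),

with small angular diffusion of the heading and optional positional
measurement jitter. When a sperm reaches the wall (perpendicular distance
below the contact threshold) a turn event fires: with probability
``pro_hook_prob`` the new heading is the along-wall direction on the
sperm's hook side (a pro-wall-hook turn); otherwise the sperm turns to the
along-wall direction on the opposite side, lifted away from the wall (an
anti-wall-hook turn that leaves the wall). Every sperm carries a fixed
hook side (left or right of its heading), assigned 50/50 at birth — head
chirality is anatomy, not state.

All randomness flows from one global seed; each sperm draws from its own
counter-derived substream, so track k is reproducible independently of
``n_sperm``. Identical configs give bit-identical output.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .trajectory import Spot, Trajectory
from .wallgeom import CONTACT_THRESHOLD_UM, WallModel

TurnLabel = Literal["pro", "anti"]


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters.

    Geometry mirrors the target acquisition: 512×512 px at 1 µm/px, 30 fps,
    60-frame (2 s) clips. The wall is a line through two points in pixel
    coordinates; the wall (dark) region occupies the side where
    cross(direction, p − p0) is positive, so with the default near-bottom
    wall the lumen is the image centre. Effect sizes are the generative
    counterparts of the fitted wall effects: log-speed intercept
    ``base_log_vcl`` (log µm/s), slope per µm of wall distance and per
    radian of wall angle. ``pro_hook_prob`` defaults to 0.8254, the
    observed pro-wall-hook proportion.
    """

    field_width_px: int = 512
    field_height_px: int = 512
    pixel_size_um: float = 1.0
    fps: float = 30.0
    n_frames: int = 60
    n_sperm: int = 50
    wall: tuple[tuple[float, float], tuple[float, float]] = ((0.0, 430.0), (512.0, 442.0))
    base_log_vcl: float = float(np.log(80.0))   # ~80 µm/s at the wall, heading along it
    beta_distance: float = -0.02                # per µm of wall distance
    beta_angle: float = -0.5                    # per radian of wall angle
    speed_noise_sd: float = 0.1                 # SD of ε (log-units per frame)
    angular_diffusion_rad: float = 0.2          # heading SD per frame
    noise_sd_um: float = 0.3                    # positional measurement jitter per axis
    pro_hook_prob: float = 0.8254
    contact_threshold_um: float = CONTACT_THRESHOLD_UM
    anti_lift_rad: float = float(np.pi / 4)     # how far an anti turn points off-wall
    min_birth_distance_um: float = 5.0
    # rendering
    blob_sd_um: float = 1.0
    blob_peak: float = 4000.0
    background: float = 100.0
    wall_dim_factor: float = 0.2
    read_noise_sd: float = 20.0
    two_channels: bool = False
    midpiece_offset_um: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if not 0.0 <= self.pro_hook_prob <= 1.0:
            raise ValueError("pro_hook_prob must lie in [0, 1]")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        for name in ("base_log_vcl", "beta_distance", "beta_angle"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        (x0, y0), (x1, y1) = self.wall
        if x0 == x1 and y0 == y1:
            raise ValueError("wall line has zero length")
        if self.blob_sd_um <= 0:
            raise ValueError("blob_sd_um must be > 0")

    @property
    def field_um(self) -> tuple[float, float]:
        return (self.field_width_px * self.pixel_size_um,
                self.field_height_px * self.pixel_size_um)

    def wall_model(self) -> WallModel:
        """True wall line in µm coordinates."""
        p0 = np.asarray(self.wall[0], dtype=float) * self.pixel_size_um
        p1 = np.asarray(self.wall[1], dtype=float) * self.pixel_size_um
        d = p1 - p0
        d = d / np.hypot(*d)
        return WallModel(point=(p0[0], p0[1]), direction=(d[0], d[1]),
                         fit_rmse_um=0.0, n_points=2)

    def lumen_normal(self) -> np.ndarray:
        """Unit normal of the wall line pointing into the lumen (swim side)."""
        # wall region sits on the positive side of WallModel.normal's negation:
        # cross(direction, p - p0) > 0 is the wall side, so the lumen normal is
        # minus the left normal.
        return -self.wall_model().normal


@dataclass(frozen=True)
class TurnEvent:
    track_id: str
    frame: int
    label: TurnLabel


@dataclass
class GroundTruth:
    """Everything the simulator knows: the oracle for recovery tests.

    ``frame_records`` holds one row per (sperm, step) with the covariates
    and log-speed actually used by the generative model — the raw material
    for regression-recovery checks. ``trajectories`` carry the observed
    (jittered) spot positions; each trajectory's ``meta`` records its hook
    side and true (noise-free) path.
    """

    trajectories: list[Trajectory]
    wall: WallModel
    turn_events: list[TurnEvent]
    true_params: dict
    frame_records: pd.DataFrame
    config: SimConfig = field(repr=False, default=None)


def _sperm_rng(seed: int, index: int) -> np.random.Generator:
    """Counter-derived per-sperm substream; stable when n_sperm changes."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def _turn_headings(heading: np.ndarray, wall_dir: np.ndarray, hook_side: str,
                   lumen_normal: np.ndarray, anti_lift_rad: float
                   ) -> tuple[np.ndarray, np.ndarray]:
    """(pro, anti) post-turn headings for a contact with incoming ``heading``.

    Pro: the along-wall unit vector lying on the hook side of the incoming
    heading ("left" = positive cross product). Anti: the along-wall vector
    on the opposite side, rotated ``anti_lift_rad`` away from the wall into
    the lumen, so the sperm leaves the wall having turned against its hook.
    """
    z = heading[0] * wall_dir[1] - heading[1] * wall_dir[0]
    if z == 0.0:  # grazing contact exactly along the wall: keep forward sense
        sign = 1.0 if heading @ wall_dir >= 0 else -1.0
    else:
        sign = 1.0 if (z > 0) == (hook_side == "left") else -1.0
    pro = sign * wall_dir
    anti_along = -pro
    anti = np.cos(anti_lift_rad) * anti_along + np.sin(anti_lift_rad) * lumen_normal
    return pro, anti / np.hypot(*anti)


def simulate_trajectories(config: SimConfig) -> GroundTruth:
    """Simulate the ground-truth trajectory set for one synthetic movie."""
    wall = config.wall_model()
    wall_dir = np.asarray(wall.direction)
    lumen_n = config.lumen_normal()
    w_um, h_um = config.field_um
    dt = 1.0 / config.fps

    trajectories: list[Trajectory] = []
    turn_events: list[TurnEvent] = []
    records: list[tuple] = []
    width = max(3, len(str(max(config.n_sperm, 1))))

    for i in range(config.n_sperm):
        rng = _sperm_rng(config.seed, i)
        track_id = f"sim{i:0{width}d}"
        hook_side = "left" if rng.random() < 0.5 else "right"

        # birth: uniform over the lumen side, away from the wall
        for _ in range(1000):
            pos = rng.uniform([0.0, 0.0], [w_um, h_um])
            off = float((pos - np.asarray(wall.point)) @ lumen_n)
            if off >= config.min_birth_distance_um:
                break
        else:  # pragma: no cover - degenerate geometry
            raise ValueError("could not place a sperm on the lumen side of the wall")
        heading = rng.uniform(0.0, 2.0 * np.pi)
        h = np.array([np.cos(heading), np.sin(heading)])

        true_path = [pos.copy()]
        spots = [Spot(frame=0,
                      x=pos[0] + rng.normal(0.0, config.noise_sd_um),
                      y=pos[1] + rng.normal(0.0, config.noise_sd_um))]
        in_contact = float(wall.distance(pos)) < config.contact_threshold_um

        for t in range(config.n_frames - 1):
            d = float(wall.distance(pos))
            cos_a = abs(float(h @ wall_dir))
            theta = float(np.arccos(np.clip(cos_a, 0.0, 1.0)))
            eps = rng.normal(0.0, config.speed_noise_sd)
            log_s = config.base_log_vcl + config.beta_distance * d \
                + config.beta_angle * theta + eps
            records.append((track_id, t, d, theta, log_s))
            pos = pos + np.exp(log_s) * dt * h

            # keep the sperm out of the wall: reflect positional overshoot back
            # (the heading itself is redirected by the turn rule below)
            off = float((pos - np.asarray(wall.point)) @ lumen_n)
            if off < 0.0:
                pos = pos - 2.0 * off * lumen_n
            pos = np.clip(pos, [0.0, 0.0], [w_um, h_um])

            d_new = float(wall.distance(pos))
            if d_new < config.contact_threshold_um and not in_contact:
                in_contact = True
                pro_h, anti_h = _turn_headings(h, wall_dir, hook_side, lumen_n,
                                               config.anti_lift_rad)
                if rng.random() < config.pro_hook_prob:
                    h, label = pro_h, "pro"
                else:
                    h, label = anti_h, "anti"
                turn_events.append(TurnEvent(track_id, t + 1, label))
            elif d_new >= config.contact_threshold_um:
                in_contact = False

            dpsi = rng.normal(0.0, config.angular_diffusion_rad)
            c, s = np.cos(dpsi), np.sin(dpsi)
            h = np.array([c * h[0] - s * h[1], s * h[0] + c * h[1]])

            true_path.append(pos.copy())
            spots.append(Spot(frame=t + 1,
                              x=pos[0] + rng.normal(0.0, config.noise_sd_um),
                              y=pos[1] + rng.normal(0.0, config.noise_sd_um)))

        trajectories.append(Trajectory(
            id=track_id, spots=spots, source="simulated",
            meta={"hook_side": hook_side,
                  "true_path": np.array(true_path)}))

    frame_records = pd.DataFrame(
        records, columns=["track_id", "frame", "distance_um", "angle_rad", "log_speed"])
    true_params = {k: asdict(config)[k] for k in
                   ("base_log_vcl", "beta_distance", "beta_angle",
                    "speed_noise_sd", "pro_hook_prob")}
    return GroundTruth(trajectories=trajectories, wall=wall,
                       turn_events=turn_events, true_params=true_params,
                       frame_records=frame_records, config=config)


def make_wall_mask(config: SimConfig) -> np.ndarray:
    """Binary mask (H, W) of the wall-side half-plane, pixel-centre convention.

    A pixel belongs to the wall when cross(direction, centre − p0) ≥ 0 in
    pixel coordinates; the mask boundary therefore lies within one pixel of
    the true line.
    """
    (x0, y0), (x1, y1) = config.wall
    dx, dy = x1 - x0, y1 - y0
    cols, rows = np.meshgrid(np.arange(config.field_width_px),
                             np.arange(config.field_height_px))
    cross = dx * (rows - y0) - dy * (cols - x0)
    return cross >= 0.0


def render_image_stack(truth: GroundTruth, config: SimConfig) -> np.ndarray:
    """Render ground truth into a 16-bit fluorescence stack.

    Shape (n_frames, H, W), or (n_frames, 2, H, W) with ``two_channels``
    (channel 0 = head, channel 1 = a trailing midpiece blob). Heads are
    isotropic Gaussian blobs at the observed spot positions (clipped to the
    field), the wall half-plane is darkened, and Gaussian read noise is
    added before quantisation.
    """
    H, W = config.field_height_px, config.field_width_px
    px = config.pixel_size_um
    sd_px = config.blob_sd_um / px
    win = max(3, int(np.ceil(4 * sd_px)))
    wall_mask = make_wall_mask(config)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed,
                                                       spawn_key=(0xFFFF,)))
    n_ch = 2 if config.two_channels else 1
    stack = np.zeros((config.n_frames, n_ch, H, W), dtype=float)

    def splat(img: np.ndarray, cx_px: float, cy_px: float, peak: float) -> None:
        cx_px = float(np.clip(cx_px, 0, W - 1))
        cy_px = float(np.clip(cy_px, 0, H - 1))
        c0, r0 = int(round(cx_px)), int(round(cy_px))
        rows = np.arange(max(0, r0 - win), min(H, r0 + win + 1))
        cols = np.arange(max(0, c0 - win), min(W, c0 + win + 1))
        gy = np.exp(-0.5 * ((rows - cy_px) / sd_px) ** 2)
        gx = np.exp(-0.5 * ((cols - cx_px) / sd_px) ** 2)
        img[np.ix_(rows, cols)] += peak * np.outer(gy, gx)

    for traj in truth.trajectories:
        prev = None
        for sp in traj.spots:
            cx, cy = sp.x / px, sp.y / px
            splat(stack[sp.frame, 0], cx, cy, config.blob_peak)
            if config.two_channels:
                if prev is not None:
                    v = np.array([sp.x - prev.x, sp.y - prev.y])
                    nrm = np.hypot(*v)
                    u = v / nrm if nrm > 0 else np.array([1.0, 0.0])
                else:
                    u = np.array([1.0, 0.0])
                mx = (sp.x - config.midpiece_offset_um * u[0]) / px
                my = (sp.y - config.midpiece_offset_um * u[1]) / px
                splat(stack[sp.frame, 1], mx, my, 0.6 * config.blob_peak)
            prev = sp

    stack += config.background
    stack[:, :, wall_mask] *= config.wall_dim_factor
    if config.read_noise_sd > 0:
        stack += rng.normal(0.0, config.read_noise_sd, size=stack.shape)
    stack = np.clip(np.round(stack), 0, 65535).astype(np.uint16)
    if not config.two_channels:
        stack = stack[:, 0]
    return stack


def sample_turn_labels(n: int, pro_prob: float, rng: np.random.Generator) -> int:
    """Number of pro-labelled turns among ``n`` independent wall contacts.

    The same Bernoulli law the simulator applies per contact, exposed for
    replicate-level power and type-I studies without re-running full
    trajectory simulations.
    """
    if not 0.0 <= pro_prob <= 1.0:
        raise ValueError("pro_prob must lie in [0, 1]")
    return int(rng.binomial(n, pro_prob))
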