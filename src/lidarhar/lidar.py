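"""2D Lidar simulation: ray casting, the four-parameter noise model, and
interpolation of every rotation onto the fixed 720-beam grid.

Beam angles are expressed in the *sensor* frame, which rotates with the
carrying robot; the world-frame direction of beam ``theta`` is
``theta + pose.heading``.  No-return beams carry ``r = NaN``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .footprints import Primitive, footprint_at, ray_primitive_hits
from .world import GroundTruth, Pose2D, RoomMap, Trajectory

log = logging.getLogger(__name__)

# provenance codes (testing aid only; the pipeline never reads these)
PROV_NONE = 0
PROV_WALL = 1
PROV_OBSTACLE = 2
PROV_HUMAN = 3
PROV_SPURIOUS = 4


@dataclass
class LidarConfig:
    scan_rate: float = 20.0     # rotations per second (Hz)
    n_beams: int = 720          # measurements per rotation (0.5 deg pitch)
    r_min: float = 0.2          # m
    r_max: float = 25.0         # m
    height: float = 0.10        # sensing-plane height, m

    def __post_init__(self) -> None:
        if self.scan_rate <= 0 or self.n_beams <= 0:
            raise ValueError("scan_rate and n_beams must be positive")

    @property
    def grid_angles(self) -> np.ndarray:
        return np.arange(self.n_beams) * (2.0 * np.pi / self.n_beams)


@dataclass
class NoiseConfig:
    """Four-parameter Lidar imperfection model.

    d_error         multiplicative range error half-width (fraction)
    p_lost          probability a beam's return is lost
    p_extra         spurious points added, as a fraction of the beam count
    theta_error_deg full width of the uniform angle-jitter interval (degrees)
    """

    d_error: float = 0.02
    p_lost: float = 0.04
    p_extra: float = 0.02
    theta_error_deg: float = 0.04

    def __post_init__(self) -> None:
        if min(self.d_error, self.p_lost, self.p_extra,
               self.theta_error_deg) < 0:
            raise ValueError("noise parameters must be non-negative")
        if self.p_lost > 1 or self.p_extra > 1:
            raise ValueError("p_lost and p_extra are fractions <= 1")


#: Default noise parameters of the simulated sensor.
DEFAULT_NOISE = NoiseConfig()


@dataclass
class Scan:
    """One Lidar rotation: ranges + sensor-frame angles + the sensor pose."""

    t: float
    pose: Pose2D
    r: np.ndarray                 # m; NaN = no return
    theta: np.ndarray             # rad, sensor frame
    provenance: np.ndarray | None = field(default=None, repr=False)
    gridded: bool = False

    def n_valid(self) -> int:
        return int(np.isfinite(self.r).sum())


@njit(cache=True)
def _dda_cast(kind, res, ox, oy, x0, y0, angles, r_max):  # pragma: no cover
    """DDA traversal of the occupancy grid; returns (dist, cell_kind) per
    beam, dist = inf on no hit within r_max."""
    n = angles.shape[0]
    ny, nx = kind.shape
    dists = np.full(n, np.inf)
    codes = np.zeros(n, dtype=np.uint8)
    for i in range(n):
        dx = math.cos(angles[i])
        dy = math.sin(angles[i])
        ix = int(math.floor((x0 - ox) / res))
        iy = int(math.floor((y0 - oy) / res))
        if ix < 0 or ix >= nx or iy < 0 or iy >= ny:
            continue
        step_x = 1 if dx > 0 else -1
        step_y = 1 if dy > 0 else -1
        if dx != 0.0:
            t_dx = abs(res / dx)
            if dx > 0:
                t_mx = ((ix + 1) * res + ox - x0) / dx
            else:
                t_mx = (ix * res + ox - x0) / dx
        else:
            t_dx = 1e30
            t_mx = 1e30
        if dy != 0.0:
            t_dy = abs(res / dy)
            if dy > 0:
                t_my = ((iy + 1) * res + oy - y0) / dy
            else:
                t_my = (iy * res + oy - y0) / dy
        else:
            t_dy = 1e30
            t_my = 1e30
        t = 0.0
        while t <= r_max:
            if kind[iy, ix] > 0:
                dists[i] = t
                codes[i] = kind[iy, ix]
                break
            if t_mx < t_my:
                t = t_mx
                t_mx += t_dx
                ix += step_x
            else:
                t = t_my
                t_my += t_dy
                iy += step_y
            if ix < 0 or ix >= nx or iy < 0 or iy >= ny:
                break
    return dists, codes


def cast_scan(room: RoomMap, primitives: list[Primitive], pose: Pose2D,
              cfg: LidarConfig, t: float = 0.0) -> Scan:
    """Ideal (noiseless) scan: nearest hit per beam among grid cells and
    human primitives, occlusion respected; hits outside [r_min, r_max] are
    no-returns."""
    ix, iy = room.cell_of(pose.x, pose.y)
    if not (0 <= ix < room.nx and 0 <= iy < room.ny):
        raise ValueError("sensor pose outside the map")
    if room.kind[iy, ix] > 0:
        raise ValueError("sensor pose inside an obstacle")
    theta = cfg.grid_angles
    world_angles = (theta + pose.heading) % (2.0 * np.pi)
    d_grid, codes = _dda_cast(room.kind, room.resolution,
                              room.origin[0], room.origin[1],
                              pose.x, pose.y, world_angles, cfg.r_max)
    d_hum = ray_primitive_hits(primitives, np.array([pose.x, pose.y]),
                               world_angles)
    r = np.where(d_hum < d_grid, d_hum, d_grid)
    prov = np.where(d_hum < d_grid, PROV_HUMAN, codes).astype(np.uint8)
    bad = ~np.isfinite(r) | (r < cfg.r_min) | (r > cfg.r_max)
    r = np.where(bad, np.nan, r)
    prov = np.where(bad, PROV_NONE, prov).astype(np.uint8)
    return Scan(t=t, pose=pose, r=r, theta=theta.copy(), provenance=prov,
                gridded=True)


def apply_noise(scan: Scan, noise: NoiseConfig, rng: np.random.Generator,
                r_min: float = 0.2) -> Scan:
    """Apply the four noise parameters: per-point loss, multiplicative range
    error, uniform angle jitter, and spurious extra points (range drawn
    uniformly between ``r_min`` and the largest observed return)."""
    valid = np.isfinite(scan.r)
    keep = valid & (rng.random(len(scan.r)) >= noise.p_lost)
    r = scan.r[keep]
    theta = scan.theta[keep]
    prov = (scan.provenance[keep] if scan.provenance is not None
            else np.full(keep.sum(), PROV_NONE, dtype=np.uint8))
    if noise.d_error > 0:
        r = r * (1.0 + rng.uniform(-noise.d_error, noise.d_error, len(r)))
    if noise.theta_error_deg > 0:
        half = math.radians(noise.theta_error_deg) / 2.0
        theta = (theta + rng.uniform(-half, half, len(theta))) % (2 * np.pi)
    n_extra = math.ceil(noise.p_extra * len(scan.r))
    if n_extra > 0:
        r_hi = float(r.max()) if len(r) else scan.r[valid].max() \
            if valid.any() else 1.0
        r_hi = max(r_hi, r_min + 0.01)
        extra_theta = rng.uniform(0, 2 * np.pi, n_extra)
        extra_r = rng.uniform(r_min, r_hi, n_extra)
        r = np.concatenate([r, extra_r])
        theta = np.concatenate([theta, extra_theta])
        prov = np.concatenate(
            [prov, np.full(n_extra, PROV_SPURIOUS, dtype=np.uint8)])
    return Scan(t=scan.t, pose=scan.pose, r=r, theta=theta,
                provenance=prov, gridded=False)


def interpolate_scan(scan: Scan, n_beams: int = 720,
                     max_gap_deg: float = 2.0) -> Scan:
    """Normalize a scan onto the fixed ``n_beams`` angular grid.

    Each grid angle takes the nearest measured point within half a pitch;
    otherwise the range is linearly interpolated between its circular
    angular neighbors, provided they are less than ``max_gap_deg`` apart
    (wider gaps are genuine no-return sectors and stay empty).  Idempotent
    on already-gridded scans.
    """
    pitch = 2.0 * np.pi / n_beams
    grid = np.arange(n_beams) * pitch
    valid = np.isfinite(scan.r)
    r_in = scan.r[valid]
    th_in = scan.theta[valid] % (2.0 * np.pi)
    prov_in = (scan.provenance[valid] if scan.provenance is not None
               else np.full(valid.sum(), PROV_NONE, dtype=np.uint8))
    r_out = np.full(n_beams, np.nan)
    prov_out = np.zeros(n_beams, dtype=np.uint8)
    if len(r_in) < 2:
        log.warning("scan at t=%.3f has %d valid points; emitting "
                    "all-no-return scan", scan.t, len(r_in))
        return Scan(t=scan.t, pose=scan.pose, r=r_out, theta=grid,
                    provenance=prov_out, gridded=True)
    order = np.argsort(th_in)
    th_s, r_s, prov_s = th_in[order], r_in[order], prov_in[order]
    m = len(th_s)
    # wrap-extend so every grid angle has circular neighbors
    th_ext = np.concatenate([th_s[-1:] - 2 * np.pi, th_s,
                             th_s[:1] + 2 * np.pi])
    r_ext = np.concatenate([r_s[-1:], r_s, r_s[:1]])
    prov_ext = np.concatenate([prov_s[-1:], prov_s, prov_s[:1]])
    hi = np.searchsorted(th_ext, grid, side="left")
    lo = hi - 1
    d_lo = grid - th_ext[lo]
    d_hi = th_ext[hi] - grid
    nearest = np.where(d_lo <= d_hi, lo, hi)
    d_near = np.minimum(d_lo, d_hi)
    take = d_near <= pitch / 2.0
    r_out[take] = r_ext[nearest[take]]
    prov_out[take] = prov_ext[nearest[take]]
    gap = th_ext[hi] - th_ext[lo]
    interp = (~take) & (gap < math.radians(max_gap_deg))
    if interp.any():
        w = d_lo[interp] / gap[interp]
        r_out[interp] = (1 - w) * r_ext[lo[interp]] + w * r_ext[hi[interp]]
        prov_out[interp] = np.where(w < 0.5, prov_ext[lo[interp]],
                                    prov_ext[hi[interp]])
    return Scan(t=scan.t, pose=scan.pose, r=r_out, theta=grid,
                provenance=prov_out, gridded=True)


# ---------------------------------------------------------------------------
# scenario runner


#: Default corner placements for the fixed-sensor comparison (m inset from
#: each corner, heading toward the room center).
def corner_poses(room: RoomMap, inset: float = 0.3) -> list[Pose2D]:
    cx, cy = room.dlength / 2.0, room.dwidth / 2.0
    corners = [(inset, inset), (room.dlength - inset, inset),
               (room.dlength - inset, room.dwidth - inset),
               (inset, room.dwidth - inset)]
    return [Pose2D(x, y, math.atan2(cy - y, cx - x)) for x, y in corners]


@dataclass
class ScenarioRun:
    """Scan streams per sensor, plus the geometry they were cast against."""

    room: RoomMap
    truth: GroundTruth
    scans: dict[str, list[Scan]]

    def sensors(self) -> list[str]:
        return list(self.scans)


def run_scenario(room: RoomMap, truth: GroundTruth, robot_traj: Trajectory,
                 lidar_config: LidarConfig | None = None,
                 noise: NoiseConfig | None = None,
                 seed: int | np.random.Generator = 0,
                 fixed_poses: dict[str, Pose2D] | None = None) -> ScenarioRun:
    """Simulate every tick of a scenario for the mobile sensor (id
    ``"mobile"``) and any fixed sensors.

    The empty-room reference for localization is the occupancy map carried in
    the returned :class:`ScenarioRun`; scans are noisy and interpolated to
    the fixed beam grid.  Bit-identical under a fixed seed.
    """
    cfg = lidar_config or LidarConfig()
    nz = DEFAULT_NOISE if noise is None else noise
    if len(truth) != len(robot_traj):
        raise ValueError(
            f"tick mismatch: truth has {len(truth)} ticks, trajectory "
            f"{len(robot_traj)}")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    sensors: dict[str, list[Scan]] = {"mobile": []}
    fixed_poses = fixed_poses or {}
    for sid in fixed_poses:
        sensors[sid] = []
    for k in range(len(truth)):
        t = float(truth.timestamps[k])
        prims = footprint_at(truth.labels[k], float(truth.phases[k]),
                             truth.poses[k], cfg.height)
        poses = {"mobile": robot_traj.poses[k], **fixed_poses}
        for sid, pose in poses.items():
            ideal = cast_scan(room, prims, pose, cfg, t=t)
            noisy = apply_noise(ideal, nz, rng)
            sensors[sid].append(interpolate_scan(noisy, cfg.n_beams))
    return ScenarioRun(room=room, truth=truth, scans=sensors)
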