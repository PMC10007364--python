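"""Rooms, trajectories, activity scripts and ground truth.

Everything downstream (ray casting, localization, classification) consumes the
objects built here.  Coordinate convention, used throughout the package:

* absolute frame origin at the room's south-west **inner** corner, x east,
  y north, units meters;
* headings in radians, counter-clockwise from +x, normalized to [0, 2pi);
* the occupancy grid is indexed ``grid[iy, ix]`` with
  ``ix = floor((x - origin_x) / resolution)`` (0-based), so pixel (0, 0)
  covers ``[0, res) x [0, res)`` in world coordinates.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

TWO_PI = 2.0 * math.pi

# The nine activity classes, in canonical index order.
ACTIVITIES = (
    "crawling",
    "falling down",
    "getting up",
    "lying down",
    "running",
    "sitting",
    "standing",
    "walking",
    "unsteady walk",
)
ACTIVITY_INDEX = {name: i for i, name in enumerate(ACTIVITIES)}
N_CLASSES = len(ACTIVITIES)

#: Which activity may follow which.  A fall is always followed by lying down,
#: and a lying person must get up before doing anything else; the rest of the
#: graph encodes ordinary ambulatory transitions.
LEGAL_TRANSITIONS = {
    "standing": {"walking", "running", "unsteady walk", "sitting", "crawling",
                 "falling down", "lying down"},
    "walking": {"standing", "running", "unsteady walk", "falling down"},
    "running": {"walking", "standing", "falling down"},
    "unsteady walk": {"walking", "standing", "falling down"},
    "sitting": {"standing", "lying down"},
    "crawling": {"standing", "lying down"},
    "falling down": {"lying down"},
    "lying down": {"getting up"},
    "getting up": {"standing", "sitting"},
}

#: Activities a script may open with ("getting up" needs a prior lying state).
LEGAL_START = set(ACTIVITIES) - {"getting up"}

#: Nominal ground speed per locomotion activity, as a fraction of the
#: configured maximum human velocity.
SPEED_FRACTION = {
    "walking": 0.5,
    "running": 1.0,
    "unsteady walk": 0.35,
    "crawling": 0.2,
}

#: Stride length (m) driving the gait phase of each locomotion activity.
STRIDE_LENGTH = {"walking": 0.6, "running": 0.9, "unsteady walk": 0.6,
                 "crawling": 0.5}

UNSTEADY_SWAY_AMPLITUDE = 0.15  # m
UNSTEADY_SWAY_PERIOD = 1.5      # s


class PlacementError(RuntimeError):
    """Raised when obstacles or start cells cannot be placed."""


class ScriptError(ValueError):
    """Raised for activity scripts violating the transition graph."""


def normalize_angle(a: float) -> float:
    """Wrap an angle to [0, 2pi)."""
    return a % TWO_PI


@dataclass
class Pose2D:
    x: float
    y: float
    heading: float = 0.0

    def __post_init__(self) -> None:
        self.heading = normalize_angle(self.heading)

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.heading])


@dataclass
class RoomMap:
    """Binary occupancy grid of a single rectangular room.

    ``kind`` distinguishes boundary walls (1) from interior obstacles (2) so
    that the simulator can tag the provenance of every Lidar return; the
    pipeline itself only ever sees the binary ``grid``.
    """

    kind: np.ndarray            # uint8, (ny, nx): 0 free, 1 wall, 2 obstacle
    resolution: float           # meters per pixel
    dlength: float              # room extent along x, meters
    dwidth: float               # room extent along y, meters
    origin: tuple[float, float] = (0.0, 0.0)
    _clearance: np.ndarray | None = field(default=None, repr=False)

    @property
    def grid(self) -> np.ndarray:
        """Binary occupancy: 1 = obstacle (walls included), 0 = free."""
        return (self.kind > 0).astype(np.uint8)

    @property
    def nx(self) -> int:
        return self.kind.shape[1]

    @property
    def ny(self) -> int:
        return self.kind.shape[0]

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        ix = int(math.floor((x - self.origin[0]) / self.resolution))
        iy = int(math.floor((y - self.origin[1]) / self.resolution))
        return ix, iy

    def center_of(self, ix: int, iy: int) -> tuple[float, float]:
        return (self.origin[0] + (ix + 0.5) * self.resolution,
                self.origin[1] + (iy + 0.5) * self.resolution)

    def is_free(self, x: float, y: float) -> bool:
        ix, iy = self.cell_of(x, y)
        if not (0 <= ix < self.nx and 0 <= iy < self.ny):
            return False
        return self.kind[iy, ix] == 0

    def clearance(self) -> np.ndarray:
        """Distance (m) from each cell center to the nearest occupied cell
        center; 0 inside occupied cells.  Cached."""
        if self._clearance is None:
            free = self.kind == 0
            self._clearance = (
                ndimage.distance_transform_edt(free) * self.resolution
            )
        return self._clearance

    def validate(self) -> None:
        k = self.kind
        if not np.all(np.isin(k, (0, 1, 2))):
            raise ValueError("kind cells must be 0, 1 or 2")
        border = np.concatenate([k[0, :], k[-1, :], k[:, 0], k[:, -1]])
        if not np.all(border == 1):
            raise ValueError("outer boundary must be closed walls")
        if self.nx * self.resolution < self.dlength - 1e-9:
            raise ValueError("grid narrower than room length")
        if self.ny * self.resolution < self.dwidth - 1e-9:
            raise ValueError("grid shorter than room width")


@dataclass
class Trajectory:
    timestamps: np.ndarray      # seconds, strictly increasing, step 1/scan_rate
    poses: list[Pose2D]

    def __len__(self) -> int:
        return len(self.poses)

    def xy(self) -> np.ndarray:
        return np.array([[p.x, p.y] for p in self.poses])


@dataclass
class ActivityScript:
    """Ordered (activity, duration-seconds) segments."""

    segments: list[tuple[str, float]]

    def validate(self) -> None:
        if not self.segments:
            raise ScriptError("empty script")
        prev = None
        for name, dur in self.segments:
            if name not in ACTIVITY_INDEX:
                raise ScriptError(f"unknown activity {name!r}")
            if dur <= 0:
                raise ScriptError(f"non-positive duration for {name!r}")
            if prev is None:
                if name not in LEGAL_START:
                    raise ScriptError(f"{name!r} cannot open a script")
            elif name != prev and name not in LEGAL_TRANSITIONS[prev]:
                raise ScriptError(f"illegal transition {prev!r} -> {name!r}")
            prev = name

    @property
    def duration(self) -> float:
        return sum(d for _, d in self.segments)


@dataclass
class GroundTruth:
    """Per-tick subject state: pose, active label and animation phase."""

    timestamps: np.ndarray
    poses: list[Pose2D]
    labels: list[str]
    phases: np.ndarray          # in [0, 1)

    def __len__(self) -> int:
        return len(self.labels)


# ---------------------------------------------------------------------------
# room construction


def build_room(dlength: float, dwidth: float, resolution: float,
               n_obstacles: int, seed: int | np.random.Generator = 0,
               max_tries: int = 200) -> RoomMap:
    """Build a closed rectangular room with axis-aligned box obstacles.

    Obstacles are placed with at least 0.5 m clearance from the walls and
    from each other so the free space stays connected (verified by connected
    component labelling; placement retries until it is).
    """
    if dlength <= 0 or dwidth <= 0 or resolution <= 0:
        raise ValueError("room dimensions and resolution must be positive")
    if n_obstacles < 0:
        raise ValueError("n_obstacles must be >= 0")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    nx = int(round(dlength / resolution))
    ny = int(round(dwidth / resolution))
    for _ in range(max_tries):
        kind = np.zeros((ny, nx), dtype=np.uint8)
        kind[0, :] = kind[-1, :] = 1
        kind[:, 0] = kind[:, -1] = 1
        placed = 0
        rects: list[tuple[float, float, float, float]] = []
        attempts = 0
        while placed < n_obstacles and attempts < 50 * max(1, n_obstacles):
            attempts += 1
            w = rng.uniform(0.3, 0.9)
            h = rng.uniform(0.3, 0.9)
            if dlength - 0.6 - w <= 0.6 or dwidth - 0.6 - h <= 0.6:
                continue            # room too small for this obstacle
            x0 = rng.uniform(0.6, dlength - 0.6 - w)
            y0 = rng.uniform(0.6, dwidth - 0.6 - h)
            ok = all(x0 > rx1 + 0.5 or rx0 > x0 + w + 0.5
                     or y0 > ry1 + 0.5 or ry0 > y0 + h + 0.5
                     for rx0, ry0, rx1, ry1 in rects)
            if not ok:
                continue
            i0, j0 = int(x0 / resolution), int(y0 / resolution)
            i1 = int(math.ceil((x0 + w) / resolution))
            j1 = int(math.ceil((y0 + h) / resolution))
            kind[j0:j1, i0:i1] = 2
            rects.append((x0, y0, x0 + w, y0 + h))
            placed += 1
        if placed < n_obstacles:
            continue
        labels, n_comp = ndimage.label(kind == 0)
        if n_comp == 1:
            room = RoomMap(kind=kind, resolution=resolution,
                           dlength=dlength, dwidth=dwidth)
            room.validate()
            return room
    raise PlacementError(
        f"could not place {n_obstacles} obstacles in {max_tries} tries")


def count_obstacle_components(room: RoomMap) -> int:
    _, n = ndimage.label(room.kind == 2)
    return int(n)


# ---------------------------------------------------------------------------
# grid path planning helpers (shared by robot and human motion)


def _astar(passable: np.ndarray, start: tuple[int, int],
           goal: tuple[int, int]) -> list[tuple[int, int]] | None:
    """4-connected A* over a boolean grid; cells are (ix, iy)."""
    ny, nx = passable.shape
    if not passable[start[1], start[0]] or not passable[goal[1], goal[0]]:
        return None
    openq: list[tuple[float, tuple[int, int]]] = [(0.0, start)]
    g = {start: 0.0}
    came: dict[tuple[int, int], tuple[int, int]] = {}
    while openq:
        _, cur = heapq.heappop(openq)
        if cur == goal:
            path = [cur]
            while cur in came:
                cur = came[cur]
                path.append(cur)
            return path[::-1]
        cx, cy = cur
        for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            nxt = (cx + dx, cy + dy)
            if not (0 <= nxt[0] < nx and 0 <= nxt[1] < ny):
                continue
            if not passable[nxt[1], nxt[0]]:
                continue
            ng = g[cur] + 1.0
            if ng < g.get(nxt, math.inf):
                g[nxt] = ng
                came[nxt] = cur
                h = abs(goal[0] - nxt[0]) + abs(goal[1] - nxt[1])
                heapq.heappush(openq, (ng + h, nxt))
    return None


def _resample_polyline(points: np.ndarray, step: float,
                       n_ticks: int) -> np.ndarray:
    """Walk along a polyline at a constant arclength step, ping-ponging back
    and forth once the end is reached, for exactly ``n_ticks`` positions."""
    if len(points) == 1:
        return np.repeat(points, n_ticks, axis=0)
    seg = np.diff(points, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    total = cum[-1]
    if total <= 0:
        return np.repeat(points[:1], n_ticks, axis=0)
    s = np.arange(n_ticks) * step
    # reflect (triangle wave) so the sweep reverses instead of stopping
    s = np.abs((s + total) % (2 * total) - total)
    x = np.interp(s, cum, points[:, 0])
    y = np.interp(s, cum, points[:, 1])
    return np.column_stack([x, y])


def _headings_from_xy(xy: np.ndarray, fallback: float = 0.0) -> np.ndarray:
    d = np.diff(xy, axis=0)
    h = np.arctan2(d[:, 1], d[:, 0])
    h = np.concatenate([h, h[-1:]]) if len(h) else np.array([fallback])
    # carry the last real heading through stationary stretches
    still = np.concatenate([[False], (np.hypot(d[:, 0], d[:, 1]) < 1e-12)])
    for i in range(1, len(h)):
        if still[i]:
            h[i] = h[i - 1]
    return h % TWO_PI


def _inflate(room: RoomMap, radius: float) -> np.ndarray:
    """Boolean passable grid after inflating occupied cells by ``radius``."""
    r = int(math.ceil(radius / room.resolution))
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    disc = (xx ** 2 + yy ** 2) <= r ** 2
    blocked = ndimage.binary_dilation(room.kind > 0, structure=disc)
    return ~blocked


def plan_robot_path(room: RoomMap, v_robot: float, scan_rate: float,
                    t_scenario: float,
                    seed: int | np.random.Generator = 0,
                    robot_radius: float = 0.18,
                    row_gap: float = 0.3) -> Trajectory:
    """Boustrophedon (lawnmower) sweep of the free space.

    Serpentine rows spaced ``row_gap`` apart are visited left-to-right then
    right-to-left; consecutive row ends are connected by A* detours around
    obstacles.  The sweep polyline is traversed at constant speed
    ``v_robot`` and ping-pongs if the scenario outlasts one full sweep.
    Returns exactly ``round(t_scenario * scan_rate)`` poses.
    """
    if v_robot <= 0:
        raise ValueError("v_robot must be positive")
    passable = _inflate(room, robot_radius)
    if not passable.any():
        raise PlacementError("no passable cells for the robot")
    res = room.resolution
    gap_cells = max(1, int(round(row_gap / res)))
    waypoints: list[tuple[int, int]] = []
    for row_i, iy in enumerate(range(1, room.ny - 1, gap_cells)):
        xs = np.nonzero(passable[iy])[0]
        if len(xs) == 0:
            continue
        if row_i % 2 == 1:
            xs = xs[::-1]
        # keep row endpoints and interval breaks only; A* fills the rest
        keep = [0, len(xs) - 1]
        gaps = np.nonzero(np.abs(np.diff(xs)) > 1)[0]
        for gi in gaps:
            keep.extend([gi, gi + 1])
        for i in sorted(set(keep)):
            waypoints.append((int(xs[i]), iy))
    if not waypoints:
        raise PlacementError("sweep produced no waypoints")
    cells: list[tuple[int, int]] = [waypoints[0]]
    for wp in waypoints[1:]:
        leg = _astar(passable, cells[-1], wp)
        if leg is None:
            continue
        cells.extend(leg[1:])
    xy = np.array([room.center_of(ix, iy) for ix, iy in cells])
    n_ticks = int(round(t_scenario * scan_rate))
    step = v_robot / scan_rate
    path = _resample_polyline(xy, step, n_ticks)
    headings = _headings_from_xy(path)
    ts = np.arange(n_ticks) / scan_rate
    poses = [Pose2D(x, y, h) for (x, y), h in zip(path, headings)]
    return Trajectory(timestamps=ts, poses=poses)


def sweep_coverage(room: RoomMap, traj: Trajectory,
                   radius: float = 0.3) -> float:
    """Fraction of free cells within ``radius`` of any trajectory pose."""
    free = room.kind == 0
    visited = np.zeros_like(free)
    r = int(math.ceil(radius / room.resolution))
    for p in traj.poses:
        ix, iy = room.cell_of(p.x, p.y)
        visited[max(0, iy - r):iy + r + 1, max(0, ix - r):ix + r + 1] = True
    return float((visited & free).sum() / free.sum())


# ---------------------------------------------------------------------------
# human animation


def _random_clear_cell(room: RoomMap, rng: np.random.Generator,
                       min_clearance: float) -> tuple[float, float]:
    ok = room.clearance() >= min_clearance
    iys, ixs = np.nonzero(ok)
    if len(ixs) == 0:
        raise PlacementError("no cell with the requested clearance")
    i = rng.integers(len(ixs))
    return room.center_of(int(ixs[i]), int(iys[i]))


def animate_human(script: ActivityScript, room: RoomMap, v_human: float,
                  scan_rate: float, seed: int | np.random.Generator = 0,
                  start: tuple[float, float] | None = None,
                  min_clearance: float = 1.0) -> GroundTruth:
    """Animate the subject through the script, one state per scan tick.

    Locomotion activities wander between random waypoints (A* around
    obstacles) at an activity-specific speed; their phase is the gait cycle
    (distance / stride length, mod 1).  Stationary activities hold the pose;
    transitions ("falling down", "getting up") ramp their phase 0 -> 1 over
    the segment.  Unsteady walking superimposes a sinusoidal lateral sway on
    the walking path.  Waypoints keep ``min_clearance`` meters from geometry
    so that a lying body never intersects an obstacle.
    """
    script.validate()
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    passable = _inflate(room, 0.25)
    if start is None:
        start = _random_clear_cell(room, rng, min_clearance)
    if not room.is_free(*start):
        raise PlacementError("human start cell is not free")
    dt = 1.0 / scan_rate
    pos = np.array(start, dtype=float)
    heading = rng.uniform(0, TWO_PI)
    ts_all: list[float] = []
    poses: list[Pose2D] = []
    labels: list[str] = []
    phases: list[float] = []
    t = 0.0
    clear_ok = room.clearance() >= min_clearance
    for name, dur in script.segments:
        n = int(round(dur * scan_rate))
        if name in SPEED_FRACTION:
            speed = SPEED_FRACTION[name] * v_human
            stride = STRIDE_LENGTH[name]
            xy = _wander(room, passable, clear_ok, pos, speed, dt, n, rng)
            base_head = _headings_from_xy(xy, heading)
            dist = np.concatenate(
                [[0.0], np.cumsum(np.hypot(*np.diff(xy, axis=0).T))])
            ph = (dist / stride) % 1.0
            if name == "unsteady walk":
                sway = UNSTEADY_SWAY_AMPLITUDE * np.sin(
                    TWO_PI * (t + np.arange(n) * dt) / UNSTEADY_SWAY_PERIOD)
                normal = np.column_stack(
                    [-np.sin(base_head), np.cos(base_head)])
                xy = xy + normal * sway[:, None]
            for i in range(n):
                poses.append(Pose2D(xy[i, 0], xy[i, 1], base_head[i]))
                labels.append(name)
                phases.append(float(ph[i]))
                ts_all.append(t + i * dt)
            pos = xy[-1].copy()
            heading = float(base_head[-1])
        else:
            if name in ("falling down", "getting up"):
                ph = np.arange(n) / max(n, 1)
            else:
                # slow idle cycle; keeps phase continuous and bounded
                ph = ((t + np.arange(n) * dt) * 0.25) % 1.0
            for i in range(n):
                poses.append(Pose2D(pos[0], pos[1], heading))
                labels.append(name)
                phases.append(float(ph[i]))
                ts_all.append(t + i * dt)
        t += n * dt
    return GroundTruth(timestamps=np.array(ts_all), poses=poses,
                       labels=labels, phases=np.array(phases))


def _wander(room: RoomMap, passable: np.ndarray, clear_ok: np.ndarray,
            pos: np.ndarray, speed: float, dt: float, n_ticks: int,
            rng: np.random.Generator) -> np.ndarray:
    """Random-waypoint locomotion path of n_ticks positions from ``pos``."""
    pts = [pos.copy()]
    length_needed = speed * dt * (n_ticks + 1)
    total = 0.0
    cur = room.cell_of(*pos)
    guard = 0
    while total < length_needed and guard < 200:
        guard += 1
        iys, ixs = np.nonzero(clear_ok & passable)
        i = rng.integers(len(ixs))
        goal = (int(ixs[i]), int(iys[i]))
        leg = _astar(passable, cur, goal)
        if leg is None or len(leg) < 2:
            continue
        xy = np.array([room.center_of(ix, iy) for ix, iy in leg[1:]])
        pts.extend(xy)
        total += np.hypot(*np.diff(np.array(pts[-len(xy) - 1:]), axis=0).T).sum()
        cur = goal
    poly = np.array(pts)
    return _resample_polyline(poly, speed * dt, n_ticks)
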