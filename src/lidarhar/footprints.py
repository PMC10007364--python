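"""Parametric human footprints: the 2D cross-section a horizontal Lidar
plane cuts through a body, per activity and animation phase.

Each activity is modelled as a small set of primitives (circles, ellipses,
capsules) in the body frame (+x = facing direction), each carrying a vertical
span ``(zlo, zhi)``; ``footprint_at`` keeps the primitives whose span contains
the sensing height and transforms them into the world frame.  The model is
deliberately coarse but geometrically discriminable: a low plane sees two leg
discs for upright gaits, a long body ellipse for a person on the ground, and
nothing at all for a lying body once the plane is above torso thickness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .world import ACTIVITY_INDEX, Pose2D

LEG_RADIUS = 0.07          # m, calf cross-section
LEG_HALF_GAP = 0.10        # m, lateral half-separation of the feet
LEG_TOP = 0.75             # m, top of the leg span
BODY_THICKNESS = 0.20      # m, torso thickness of a body on the ground
LYING_SEMI_LENGTH = 0.85   # m  (1.7 m body)
LYING_SEMI_WIDTH = 0.20    # m  (0.4 m across)
LYING_CENTER_FWD = 0.45    # m, body center ahead of the feet after a fall

#: forward leg swing half-amplitude per gait (m)
GAIT_SWING = {"walking": 0.15, "running": 0.25, "unsteady walk": 0.15,
              "crawling": 0.10}


@dataclass(frozen=True)
class Primitive:
    """One convex body-section primitive.

    kind 'circle':  center=(cx, cy), a = radius
    kind 'ellipse': center, semi-axes (a, b), orientation angle
    kind 'capsule': segment from center to center + a*(cos angle, sin angle),
                    radius b
    All lengths in meters; zlo/zhi bound the vertical span of the body part.
    """

    kind: str
    cx: float
    cy: float
    a: float
    b: float = 0.0
    angle: float = 0.0
    zlo: float = 0.0
    zhi: float = 2.0

    def transformed(self, pose: Pose2D) -> "Primitive":
        c, s = math.cos(pose.heading), math.sin(pose.heading)
        return replace(self,
                       cx=pose.x + c * self.cx - s * self.cy,
                       cy=pose.y + s * self.cx + c * self.cy,
                       angle=self.angle + pose.heading)


def _legs(phase: float, activity: str) -> list[Primitive]:
    swing = GAIT_SWING.get(activity, 0.0)
    dx = swing * math.sin(2.0 * math.pi * phase)
    return [
        Primitive("circle", dx, +LEG_HALF_GAP, LEG_RADIUS, zhi=LEG_TOP),
        Primitive("circle", -dx, -LEG_HALF_GAP, LEG_RADIUS, zhi=LEG_TOP),
    ]


def _falling(phase: float) -> list[Primitive]:
    """Interpolates an upright body into the lying ellipse as phase 0 -> 1."""
    p = min(max(phase, 0.0), 1.0)
    legs = [
        Primitive("circle", 0.0, +LEG_HALF_GAP * (1 - p), LEG_RADIUS,
                  zhi=LEG_TOP * (1 - p) + BODY_THICKNESS * p),
        Primitive("circle", 0.0, -LEG_HALF_GAP * (1 - p), LEG_RADIUS,
                  zhi=LEG_TOP * (1 - p) + BODY_THICKNESS * p),
    ]
    body = Primitive(
        "ellipse",
        LYING_CENTER_FWD * p, 0.0,
        0.15 + (LYING_SEMI_LENGTH - 0.15) * p,
        LYING_SEMI_WIDTH,
        zlo=0.0,
        zhi=1.2 * (1 - p) + BODY_THICKNESS * p,
    )
    return legs + [body]


def _body_frame_primitives(activity: str, phase: float) -> list[Primitive]:
    if activity in ("standing",):
        return _legs(0.0, activity)
    if activity in ("walking", "running", "unsteady walk"):
        return _legs(phase, activity)
    if activity == "sitting":
        return [
            Primitive("circle", 0.05, 0.0, 0.22, zhi=0.45),   # folded legs
            Primitive("circle", -0.10, 0.0, 0.14, zhi=0.95),  # torso
        ]
    if activity == "lying down":
        return [Primitive("ellipse", LYING_CENTER_FWD, 0.0,
                          LYING_SEMI_LENGTH, LYING_SEMI_WIDTH,
                          zhi=BODY_THICKNESS)]
    if activity == "crawling":
        dx = GAIT_SWING["crawling"] * math.sin(2.0 * math.pi * phase)
        return [
            Primitive("ellipse", 0.0, 0.0, 0.35, 0.15, zlo=0.05, zhi=0.5),
            Primitive("circle", 0.32 + dx, +0.12, 0.06, zhi=0.30),
            Primitive("circle", 0.32 - dx, -0.12, 0.06, zhi=0.30),
            Primitive("circle", -0.28 - dx, +0.12, 0.06, zhi=0.30),
            Primitive("circle", -0.28 + dx, -0.12, 0.06, zhi=0.30),
        ]
    if activity == "falling down":
        return _falling(phase)
    if activity == "getting up":
        return _falling(1.0 - phase)
    raise KeyError(f"unknown activity {activity!r}")


def footprint_at(activity: str, phase: float, pose: Pose2D,
                 height: float) -> list[Primitive]:
    """World-frame primitives of the body section at the given sensor height.

    Raises KeyError for unknown activity labels.  May return an empty list,
    e.g. a lying body observed from a plane above its torso thickness.
    """
    if activity not in ACTIVITY_INDEX:
        raise KeyError(f"unknown activity {activity!r}")
    prims = _body_frame_primitives(activity, phase)
    return [pr.transformed(pose) for pr in prims
            if pr.zlo <= height <= pr.zhi]


def primitive_distance(prim: Primitive, x: float, y: float) -> float:
    """Unsigned distance from a point to the primitive surface (approximate
    for ellipses: scaled-space estimate, adequate for half-cell checks)."""
    dx, dy = x - prim.cx, y - prim.cy
    c, s = math.cos(-prim.angle), math.sin(-prim.angle)
    u, v = c * dx - s * dy, s * dx + c * dy
    if prim.kind == "circle":
        return abs(math.hypot(u, v) - prim.a)
    if prim.kind == "ellipse":
        r = math.hypot(u / prim.a, v / prim.b)
        scale = min(prim.a, prim.b)
        return abs(r - 1.0) * scale
    if prim.kind == "capsule":
        t = min(max(u, 0.0), prim.a)
        return abs(math.hypot(u - t, v) - prim.b)
    raise ValueError(prim.kind)


def max_extent(prims: list[Primitive], pose: Pose2D) -> float:
    """Largest distance from the pose to any primitive surface point."""
    worst = 0.0
    for p in prims:
        d = math.hypot(p.cx - pose.x, p.cy - pose.y)
        worst = max(worst, d + max(p.a, p.b))
    return worst


def _ray_circle(ox: float, oy: float, dx: float, dy: float,
                cx: float, cy: float, r: float) -> float:
    """Smallest positive ray parameter hitting the circle, or inf."""
    fx, fy = ox - cx, oy - cy
    b = fx * dx + fy * dy
    c = fx * fx + fy * fy - r * r
    disc = b * b - c
    if disc < 0:
        return math.inf
    root = math.sqrt(disc)
    t = -b - root
    if t >= 0:
        return t
    t = -b + root
    return t if t >= 0 else math.inf


def ray_primitive_hits(prims: list[Primitive], origin: np.ndarray,
                       angles: np.ndarray) -> np.ndarray:
    """Nearest-hit distance per ray against a primitive list.

    origin: (2,), angles: world-frame beam angles (n,).  Returns (n,)
    distances, inf where a ray misses everything.
    """
    n = len(angles)
    best = np.full(n, np.inf)
    if not prims:
        return best
    dxs, dys = np.cos(angles), np.sin(angles)
    ox, oy = float(origin[0]), float(origin[1])
    for pr in prims:
        if pr.kind == "circle":
            for i in range(n):
                t = _ray_circle(ox, oy, dxs[i], dys[i], pr.cx, pr.cy, pr.a)
                if t < best[i]:
                    best[i] = t
        elif pr.kind == "ellipse":
            c, s = math.cos(-pr.angle), math.sin(-pr.angle)
            # ray in the ellipse frame, scaled to a unit circle
            rox = (c * (ox - pr.cx) - s * (oy - pr.cy)) / pr.a
            roy = (s * (ox - pr.cx) + c * (oy - pr.cy)) / pr.b
            for i in range(n):
                rdx = (c * dxs[i] - s * dys[i]) / pr.a
                rdy = (s * dxs[i] + c * dys[i]) / pr.b
                norm = math.hypot(rdx, rdy)
                if norm == 0:
                    continue
                t = _ray_circle(rox, roy, rdx / norm, rdy / norm, 0, 0, 1.0)
                t /= norm
                if t < best[i]:
                    best[i] = t
        elif pr.kind == "capsule":
            c, s = math.cos(-pr.angle), math.sin(-pr.angle)
            rox = c * (ox - pr.cx) - s * (oy - pr.cy)
            roy = s * (ox - pr.cx) + c * (oy - pr.cy)
            for i in range(n):
                rdx = c * dxs[i] - s * dys[i]
                rdy = s * dxs[i] + c * dys[i]
                t = min(_ray_circle(rox, roy, rdx, rdy, 0.0, 0.0, pr.b),
                        _ray_circle(rox, roy, rdx, rdy, pr.a, 0.0, pr.b))
                # flat sides y = +-b for x in [0, a]
                for sign in (1.0, -1.0):
                    if rdy != 0.0:
                        tt = (sign * pr.b - roy) / rdy
                        if tt >= 0 and 0.0 <= rox + tt * rdx <= pr.a:
                            t = min(t, tt)
                if t < best[i]:
                    best[i] = t
        else:
            raise ValueError(pr.kind)
    return best
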