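"""Subject localization from a moving sensor.

Per scan: project the polar returns into the absolute room frame (adding the
sensor heading, since the beam angles are measured in the rotating sensor
frame), discard every point within ``delta_d`` of the empty-room geometry,
cluster what remains with DBSCAN, and gate the clusters against the track
from previous scans (``delta_r``).  The empty-room reference is the occupancy
map plus its distance transform, which is available at any sensor pose --
unlike a literal stored empty scan, which would exist only for poses visited
beforehand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import DBSCAN

from .lidar import Scan
from .world import RoomMap


@dataclass
class LocalizationConfig:
    delta_d: float = 0.2       # m, background-subtraction threshold
    delta_r: float = 0.8       # m, track gate radius
    eps_db: float = 0.3        # m, DBSCAN neighborhood radius
    min_pts: int = 3           # DBSCAN core threshold (neighbors incl. self)
    t_lost: int = 40           # ticks of coasting before the track is dropped

    def __post_init__(self) -> None:
        if min(self.delta_d, self.delta_r, self.eps_db) <= 0 \
                or self.min_pts <= 0:
            raise ValueError("localization parameters must be positive")


@dataclass
class Track:
    location: np.ndarray | None = None     # (2,) or None
    age: int = 0                           # ticks since last confirmation


@dataclass
class Cluster:
    points: np.ndarray                     # (n, 2)
    centroid: np.ndarray                   # (2,)


@dataclass
class SubjectObservation:
    t: float
    status: str                            # detected | coasting | lost
    subject_points: np.ndarray             # (n, 2); empty unless detected
    location: np.ndarray | None            # (2,) or None
    provenance: np.ndarray | None = field(default=None, repr=False)


def to_absolute(scan: Scan) -> tuple[np.ndarray, np.ndarray]:
    """Project valid beams to absolute coordinates.

    ``x = x_l + r cos(theta + heading)`` (and likewise for y): the classical
    polar-to-Cartesian transform with the sensor pose folded in.  Returns
    (points (n, 2), provenance (n,)).
    """
    if scan.pose is None:
        raise ValueError("scan carries no pose")
    valid = np.isfinite(scan.r)
    r = scan.r[valid]
    a = scan.theta[valid] + scan.pose.heading
    pts = np.column_stack([scan.pose.x + r * np.cos(a),
                           scan.pose.y + r * np.sin(a)])
    prov = (scan.provenance[valid] if scan.provenance is not None
            else np.zeros(valid.sum(), dtype=np.uint8))
    return pts, prov


def subtract_background(points: np.ndarray, room: RoomMap,
                        delta_d: float) -> np.ndarray:
    """Boolean mask of points farther than ``delta_d`` from the empty-room
    geometry (nearest occupied cell, via the map's distance transform)."""
    if len(points) == 0:
        return np.zeros(0, dtype=bool)
    clr = room.clearance()
    ix = np.floor((points[:, 0] - room.origin[0]) / room.resolution)
    iy = np.floor((points[:, 1] - room.origin[1]) / room.resolution)
    ix = np.clip(ix.astype(int), 0, room.nx - 1)
    iy = np.clip(iy.astype(int), 0, room.ny - 1)
    return clr[iy, ix] > delta_d


def cluster_candidates(points: np.ndarray, eps_db: float,
                       min_pts: int) -> list[Cluster]:
    """DBSCAN over the candidate points; noise labels are discarded.

    ``min_pts`` counts the point itself (scikit-learn's ``min_samples``
    convention).
    """
    if len(points) == 0:
        return []
    labels = DBSCAN(eps=eps_db, min_samples=min_pts).fit_predict(points)
    clusters = []
    for lbl in np.unique(labels):
        if lbl < 0:
            continue
        member = points[labels == lbl]
        clusters.append(Cluster(points=member, centroid=member.mean(axis=0)))
    return clusters


def select_subject(clusters: list[Cluster], track: Track,
                   cfg: LocalizationConfig, t: float,
                   room_center: np.ndarray) -> SubjectObservation:
    """Pick the subject cluster and update the track in place.

    With a live track: nearest cluster centroid within ``delta_r``.  Without
    one: the largest cluster (ties toward the room center).  No eligible
    cluster: coast on the held location until ``t_lost`` ticks, then lost.
    """
    chosen: Cluster | None = None
    if track.location is not None:
        best = np.inf
        for cl in clusters:
            d = float(np.linalg.norm(cl.centroid - track.location))
            if d <= cfg.delta_r and d < best:
                best, chosen = d, cl
    elif clusters:
        chosen = max(
            clusters,
            key=lambda cl: (len(cl.points),
                            -float(np.linalg.norm(cl.centroid - room_center))))
    if chosen is not None:
        track.location = chosen.centroid.copy()
        track.age = 0
        return SubjectObservation(t=t, status="detected",
                                  subject_points=chosen.points,
                                  location=chosen.centroid.copy())
    if track.location is not None:
        track.age += 1
        if track.age <= cfg.t_lost:
            return SubjectObservation(t=t, status="coasting",
                                      subject_points=np.empty((0, 2)),
                                      location=track.location.copy())
        track.location = None
    return SubjectObservation(t=t, status="lost",
                              subject_points=np.empty((0, 2)), location=None)


def localize_scan(scan: Scan, room: RoomMap, cfg: LocalizationConfig,
                  track: Track) -> SubjectObservation:
    pts, prov = to_absolute(scan)
    mask = subtract_background(pts, room, cfg.delta_d)
    cand, cand_prov = pts[mask], prov[mask]
    clusters = cluster_candidates(cand, cfg.eps_db, cfg.min_pts)
    center = np.array([room.dlength / 2.0, room.dwidth / 2.0])
    obs = select_subject(clusters, track, cfg, scan.t, center)
    if obs.status == "detected" and len(cand):
        # recover the provenance rows of the selected members (testing aid)
        sel = {tuple(p) for p in obs.subject_points.round(9).tolist()}
        hit = np.array([tuple(p) in sel
                        for p in cand.round(9).tolist()], dtype=bool)
        obs.provenance = cand_prov[hit]
    return obs


def localize_stream(scans: list[Scan], room: RoomMap,
                    cfg: LocalizationConfig | None = None
                    ) -> list[SubjectObservation]:
    """Run the per-scan pipeline over a time-ordered scan stream, threading
    one track through it."""
    cfg = cfg or LocalizationConfig()
    ts = [s.t for s in scans]
    if any(b < a for a, b in zip(ts, ts[1:])):
        raise ValueError("scans must be time-ordered")
    track = Track()
    return [localize_scan(s, room, cfg, track) for s in scans]
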