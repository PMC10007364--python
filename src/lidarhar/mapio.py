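"""File formats: PGM+YAML occupancy maps, NDJSON scan streams, CSV ground
truth and observations.

The map dialect is the common occupancy-map convention: a P5 PGM where
occupied cells are written as 0 (displayed black) and free cells as 254,
with a YAML sidecar holding resolution, origin and the negate flag.
"""

from __future__ import annotations

import csv
import json
import math
from pathlib import Path

import numpy as np
import yaml

from .lidar import Scan
from .localization import SubjectObservation
from .world import GroundTruth, Pose2D, RoomMap

OCCUPIED_PIXEL = 0      # display convention: occupied drawn black
FREE_PIXEL = 254


def write_room(room: RoomMap, stem: str | Path) -> tuple[Path, Path]:
    """Write ``stem.pgm`` + ``stem.yaml``; returns both paths.

    PGM rows run top-to-bottom, so row 0 of the file is the *north* edge of
    the room (largest y).
    """
    stem = Path(stem)
    pgm = stem.with_suffix(".pgm")
    img = np.where(room.kind > 0, OCCUPIED_PIXEL, FREE_PIXEL).astype(np.uint8)
    img = img[::-1]                      # north row first
    with open(pgm, "wb") as fh:
        fh.write(b"P5\n# occupancy map: 0 = occupied, 254 = free\n")
        fh.write(f"{room.nx} {room.ny}\n255\n".encode())
        fh.write(img.tobytes())
    meta = {"image": pgm.name, "resolution": float(room.resolution),
            "origin": [float(room.origin[0]), float(room.origin[1]), 0.0],
            "negate": 0, "occupied_thresh": 0.65, "free_thresh": 0.196,
            "dlength": float(room.dlength), "dwidth": float(room.dwidth)}
    ypath = stem.with_suffix(".yaml")
    ypath.write_text(yaml.safe_dump(meta))
    return pgm, ypath


def _read_pgm(path: Path) -> np.ndarray:
    data = path.read_bytes()
    # header: magic, width, height, maxval as whitespace-separated tokens,
    # comments starting with '#'
    tokens: list[bytes] = []
    i = 0
    while len(tokens) < 4:
        if data[i:i + 1] == b"#":
            i = data.index(b"\n", i) + 1
            continue
        j = i
        while j < len(data) and not data[j:j + 1].isspace():
            j += 1
        if j > i:
            tokens.append(data[i:j])
        i = j + 1
    if tokens[0] != b"P5":
        raise ValueError("only binary (P5) PGM is supported")
    w, h, maxval = int(tokens[1]), int(tokens[2]), int(tokens[3])
    if maxval > 255:
        raise ValueError("16-bit PGM not supported")
    img = np.frombuffer(data[i:i + w * h], dtype=np.uint8).reshape(h, w)
    return img


def read_room(yaml_path: str | Path) -> RoomMap:
    yaml_path = Path(yaml_path)
    meta = yaml.safe_load(yaml_path.read_text())
    img = _read_pgm(yaml_path.parent / meta["image"])[::-1]
    occupied = (img < 128) ^ bool(meta.get("negate", 0))
    kind = np.zeros(img.shape, dtype=np.uint8)
    kind[occupied] = 2
    border = np.zeros_like(occupied)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    kind[occupied & border] = 1
    res = float(meta["resolution"])
    room = RoomMap(kind=kind, resolution=res,
                   dlength=float(meta.get("dlength", img.shape[1] * res)),
                   dwidth=float(meta.get("dwidth", img.shape[0] * res)),
                   origin=(float(meta["origin"][0]), float(meta["origin"][1])))
    return room


# ---------------------------------------------------------------------------
# scans as NDJSON: one object per scan, theta implicit by beam index


def write_scans(scans: list[Scan], path: str | Path,
                sensor_id: str = "mobile") -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for s in scans:
            if not s.gridded:
                raise ValueError("only gridded scans are serialized")
            r = [None if math.isnan(v) else round(float(v), 6)
                 for v in s.r]
            fh.write(json.dumps({
                "t": round(float(s.t), 6), "sensor_id": sensor_id,
                "pose": [round(s.pose.x, 6), round(s.pose.y, 6),
                         round(s.pose.heading, 6)],
                "r": r}) + "\n")
    return path


def read_scans(path: str | Path) -> list[Scan]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            r = np.array([np.nan if v is None else v for v in obj["r"]],
                         dtype=float)
            n = len(r)
            theta = np.arange(n) * (2.0 * np.pi / n)
            x, y, h = obj["pose"]
            out.append(Scan(t=float(obj["t"]), pose=Pose2D(x, y, h),
                            r=r, theta=theta, gridded=True))
    return out


# ---------------------------------------------------------------------------
# CSV: ground truth and observations


def write_ground_truth(truth: GroundTruth, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["tick", "t", "x", "y", "heading", "activity", "phase"])
        for k in range(len(truth)):
            p = truth.poses[k]
            wr.writerow([k, f"{truth.timestamps[k]:.6f}", f"{p.x:.6f}",
                         f"{p.y:.6f}", f"{p.heading:.6f}", truth.labels[k],
                         f"{truth.phases[k]:.6f}"])
    return path


def read_ground_truth(path: str | Path) -> GroundTruth:
    ts, poses, labels, phases = [], [], [], []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            ts.append(float(row["t"]))
            poses.append(Pose2D(float(row["x"]), float(row["y"]),
                                float(row["heading"])))
            labels.append(row["activity"])
            phases.append(float(row["phase"]))
    return GroundTruth(timestamps=np.array(ts), poses=poses, labels=labels,
                       phases=np.array(phases))


def write_observations(obs: list[SubjectObservation],
                       path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["t", "status", "x", "y", "n_points"])
        for o in obs:
            x = "" if o.location is None else f"{o.location[0]:.6f}"
            y = "" if o.location is None else f"{o.location[1]:.6f}"
            wr.writerow([f"{o.t:.6f}", o.status, x, y,
                         len(o.subject_points)])
    return path


def write_subject_points(obs: list[SubjectObservation],
                         path: str | Path) -> Path:
    """Per-tick subject point sets as NDJSON for the representation stage."""
    path = Path(path)
    with open(path, "w") as fh:
        for o in obs:
            fh.write(json.dumps({
                "t": round(float(o.t), 6), "status": o.status,
                "points": [[round(float(x), 6), round(float(y), 6)]
                           for x, y in o.subject_points]}) + "\n")
    return path
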