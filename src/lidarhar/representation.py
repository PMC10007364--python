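"""Scan-to-image representations and sliding-window sample assembly.

Three variants turn a per-tick subject point set into a fixed-size image
anchored to the absolute room frame: a coarse Boolean occupancy grid, and
two high-resolution renderings that stamp a filled circle or ellipse at each
point so sparse returns stay visible.  A sliding window then cuts the frame
stream into fixed-length labeled samples for the sequence classifier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .localization import SubjectObservation
from .world import ACTIVITIES, ACTIVITY_INDEX


@dataclass
class RepresentationConfig:
    variant: str = "grid"            # grid | circles | ellipses
    xpx: int = 60
    ypx: int = 60
    dlength: float = 6.0             # room extent mapped onto the image, m
    dwidth: float = 6.0
    origin: tuple[float, float] = (0.0, 0.0)
    rc: int = 5                      # circle radius, px
    ra: int = 8                      # ellipse semi-axes, px
    rb: int = 4
    window_len: int = 40             # ticks (2 s at 20 Hz)
    stride: int = 10                 # ticks

    def __post_init__(self) -> None:
        if self.variant not in ("grid", "circles", "ellipses"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.window_len <= 0 or self.stride <= 0:
            raise ValueError("window_len and stride must be positive")

    @property
    def res_x(self) -> float:
        return self.dlength / self.xpx

    @property
    def res_y(self) -> float:
        return self.dwidth / self.ypx


@dataclass
class LabeledSample:
    frames: np.ndarray               # (window_len, ypx, xpx) in [0, 1]
    label: int                       # class index in [0, N_CLASSES)

    @property
    def label_name(self) -> str:
        return ACTIVITIES[self.label]


def _pixel_indices(points: np.ndarray, cfg: RepresentationConfig
                   ) -> tuple[np.ndarray, np.ndarray, int]:
    """Map points to (ix, iy) pixel indices; drops out-of-bounds points and
    returns how many were dropped."""
    if len(points) == 0:
        empty = np.empty(0, dtype=int)
        return empty, empty, 0
    ix = np.floor((points[:, 0] - cfg.origin[0]) / cfg.res_x).astype(int)
    iy = np.floor((points[:, 1] - cfg.origin[1]) / cfg.res_y).astype(int)
    ok = (ix >= 0) & (ix < cfg.xpx) & (iy >= 0) & (iy < cfg.ypx)
    return ix[ok], iy[ok], int((~ok).sum())


def rasterize_grid(points: np.ndarray, cfg: RepresentationConfig
                   ) -> np.ndarray:
    """Boolean grid: pixel (floor(x/res), floor(y/res)) = 1 per point."""
    img = np.zeros((cfg.ypx, cfg.xpx), dtype=np.float32)
    ix, iy, _ = _pixel_indices(points, cfg)
    img[iy, ix] = 1.0
    return img


def _disc_offsets(ra: int, rb: int) -> tuple[np.ndarray, np.ndarray]:
    dy, dx = np.mgrid[-rb:rb + 1, -ra:ra + 1]
    inside = (dx / ra) ** 2 + (dy / rb) ** 2 <= 1.0
    return dx[inside], dy[inside]


def _stamp(points: np.ndarray, cfg: RepresentationConfig,
           ra: int, rb: int) -> np.ndarray:
    img = np.zeros((cfg.ypx, cfg.xpx), dtype=np.float32)
    ix, iy, _ = _pixel_indices(points, cfg)
    if len(ix) == 0:
        return img
    offx, offy = _disc_offsets(ra, rb)
    xs = (ix[:, None] + offx[None, :]).ravel()
    ys = (iy[:, None] + offy[None, :]).ravel()
    ok = (xs >= 0) & (xs < cfg.xpx) & (ys >= 0) & (ys < cfg.ypx)
    img[ys[ok], xs[ok]] = 1.0       # overlaps saturate at 1
    return img


def render_circles(points: np.ndarray, cfg: RepresentationConfig
                   ) -> np.ndarray:
    """Filled disc of radius ``rc`` px stamped at every mapped point."""
    return _stamp(points, cfg, cfg.rc, cfg.rc)


def render_ellipses(points: np.ndarray, cfg: RepresentationConfig
                    ) -> np.ndarray:
    """Axis-aligned filled ellipse (semi-axes ``ra``, ``rb`` px) per point."""
    return _stamp(points, cfg, cfg.ra, cfg.rb)


_RENDERERS = {"grid": rasterize_grid, "circles": render_circles,
              "ellipses": render_ellipses}


def frames_from_observations(obs: list[SubjectObservation],
                             cfg: RepresentationConfig) -> np.ndarray:
    """One image per observation from its subject point set."""
    render = _RENDERERS[cfg.variant]
    return np.stack([render(o.subject_points, cfg) for o in obs])


def window_label(labels: list[str], lo: int, hi: int) -> int:
    """Majority ground-truth label over ticks [lo, hi); count ties break
    toward the label seen latest in the window (the more recent state)."""
    counts: dict[str, int] = {}
    last_seen: dict[str, int] = {}
    for k in range(lo, hi):
        counts[labels[k]] = counts.get(labels[k], 0) + 1
        last_seen[labels[k]] = k
    top = max(counts.values())
    winners = [name for name, c in counts.items() if c == top]
    winner = max(winners, key=lambda name: last_seen[name])
    return ACTIVITY_INDEX[winner]


def make_windows(frames: np.ndarray, labels: list[str],
                 statuses: list[str] | None,
                 cfg: RepresentationConfig) -> list[LabeledSample]:
    """Slide a window of ``window_len`` frames by ``stride`` ticks.

    Windows in which the subject was lost for more than half their ticks are
    discarded (there is nothing to classify).  Fewer frames than one window
    yields an empty list.
    """
    n = len(frames)
    if len(labels) != n:
        raise ValueError("frames and labels are not aligned")
    out: list[LabeledSample] = []
    for lo in range(0, n - cfg.window_len + 1, cfg.stride):
        hi = lo + cfg.window_len
        if statuses is not None:
            n_lost = sum(1 for s in statuses[lo:hi] if s == "lost")
            if n_lost > cfg.window_len // 2:
                continue
        out.append(LabeledSample(frames=frames[lo:hi],
                                 label=window_label(labels, lo, hi)))
    return out


def class_histogram(samples: list[LabeledSample]) -> np.ndarray:
    hist = np.zeros(len(ACTIVITIES), dtype=int)
    for s in samples:
        hist[s.label] += 1
    return hist
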