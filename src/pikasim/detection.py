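"""Virtual camera traps.

The physical detection zone is a circular sector of radius ``r`` and
central angle ``theta``; for geometry tests it is replaced by the
equal-area isosceles triangle whose apex sits at the camera and whose apex
angle is ``theta``.  Equal sides have length ``s = sqrt(theta * r^2 /
sin(theta))`` so the triangle area ``s^2 sin(theta) / 2`` equals the sector
area ``theta r^2 / 2``.

A capture tally supports two counting rules:

``step``
    the camera fires once per movement step whose segment intersects the
    zone.  This mirrors the trigger/record/re-arm cycle of the field
    cameras — the simulation time step was chosen equal to the camera's
    30-s recording window precisely so that one step in range equals one
    shot.
``entry``
    only outside->inside transitions count; consecutive in-zone steps are
    de-duplicated, a later re-entry counts again.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from shapely.geometry import LineString, Polygon

from .config import SimulationConfig
from .movement import SegmentBatch

__all__ = [
    "CameraTrap",
    "CaptureLog",
    "build_triangle",
    "triangle_side_length",
    "segment_hits",
    "count_captures",
    "count_captures_batch",
    "default_camera_layout",
    "build_cameras",
]


def triangle_side_length(r: float, theta: float) -> float:
    """Equal-side length of the equal-area triangle: sqrt(theta r^2 / sin theta)."""
    return math.sqrt(theta * r * r / math.sin(theta))


@dataclass(frozen=True)
class CameraTrap:
    """A virtual camera with its triangular detection zone."""

    id: int
    apex: tuple[float, float]
    orientation: float  # rad, direction of the apex-angle bisector
    r: float
    theta: float
    vertices: np.ndarray  # (3, 2): apex first, then base corners, CCW

    @property
    def side(self) -> float:
        return triangle_side_length(self.r, self.theta)

    @property
    def area(self) -> float:
        s = self.side
        return 0.5 * s * s * math.sin(self.theta)

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)


def build_triangle(
    apex: tuple[float, float],
    orientation: float,
    r: float,
    theta: float,
    camera_id: int = 0,
) -> CameraTrap:
    """Construct the equal-area triangular detection zone."""
    if r <= 0:
        raise ValueError(f"r must be > 0, got {r!r}")
    if not 0.0 < theta < math.pi:
        raise ValueError(f"theta must be in (0, pi), got {theta!r}")
    s = triangle_side_length(r, theta)
    ax, ay = float(apex[0]), float(apex[1])
    b = (ax + s * math.cos(orientation - theta / 2.0),
         ay + s * math.sin(orientation - theta / 2.0))
    c = (ax + s * math.cos(orientation + theta / 2.0),
         ay + s * math.sin(orientation + theta / 2.0))
    vertices = np.array([[ax, ay], b, c])  # CCW: cross((b-a),(c-a)) = s^2 sin(theta) > 0
    return CameraTrap(
        id=camera_id, apex=(ax, ay), orientation=float(orientation),
        r=float(r), theta=float(theta), vertices=vertices,
    )


def default_camera_layout(L: float, rng: np.random.Generator) -> list[tuple[float, float, float]]:
    """Six apexes on a 2x3 grid (x at L/4, 3L/4; y at L/4, L/2, 3L/4),
    orientations uniform on [0, 2*pi)."""
    xs = [L / 4.0, 3.0 * L / 4.0]
    ys = [L / 4.0, L / 2.0, 3.0 * L / 4.0]
    orientations = rng.uniform(0.0, 2.0 * math.pi, size=6)
    return [
        (x, y, float(o))
        for (x, y), o in zip([(x, y) for x in xs for y in ys], orientations)
    ]


def build_cameras(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> list[CameraTrap]:
    """Cameras from the config layout, or the default grid if unset."""
    layout = config.camera_layout
    if layout is None:
        if rng is None:
            raise ValueError("rng required to draw default camera orientations")
        layout = default_camera_layout(config.L, rng)
    return [
        build_triangle((x, y), o, config.r, config.theta, camera_id=i)
        for i, (x, y, o) in enumerate(layout)
    ]


# Geometry ------------------------------------------------------------------


def segment_hits(camera: CameraTrap, p0, p1) -> bool:
    """True iff the closed segment p0->p1 intersects the closed zone.

    Delegates to shapely, which handles tangency and collinear touching;
    the vectorised engine below is tested against this as an oracle.
    """
    return bool(LineString([tuple(p0), tuple(p1)]).intersects(camera.polygon))


def _cross(ox, oy, ax, ay, bx, by):
    return (ax - ox) * (by - oy) - (ay - oy) * (bx - ox)


def _points_in_triangle(tri: np.ndarray, px, py):
    """Vectorised inclusive point-in-triangle test (tri is CCW)."""
    (ax, ay), (bx, by), (cx, cy) = tri
    d0 = _cross(ax, ay, bx, by, px, py)
    d1 = _cross(bx, by, cx, cy, px, py)
    d2 = _cross(cx, cy, ax, ay, px, py)
    return (d0 >= 0) & (d1 >= 0) & (d2 >= 0)


def _segments_intersect(p0x, p0y, p1x, p1y, q0, q1):
    """Vectorised closed-segment intersection with fixed segment q0->q1."""
    q0x, q0y = q0
    q1x, q1y = q1
    d1 = _cross(q0x, q0y, q1x, q1y, p0x, p0y)
    d2 = _cross(q0x, q0y, q1x, q1y, p1x, p1y)
    d3 = _cross(p0x, p0y, p1x, p1y, q0x, q0y)
    d4 = _cross(p0x, p0y, p1x, p1y, q1x, q1y)
    proper = (
        ((d1 > 0) & (d2 < 0) | (d1 < 0) & (d2 > 0))
        & ((d3 > 0) & (d4 < 0) | (d3 < 0) & (d4 > 0))
    )

    def on_seg(ax, ay, bx, by, px, py):
        return (
            (np.minimum(ax, bx) - 1e-12 <= px) & (px <= np.maximum(ax, bx) + 1e-12)
            & (np.minimum(ay, by) - 1e-12 <= py) & (py <= np.maximum(ay, by) + 1e-12)
        )

    touch = (
        ((d1 == 0) & on_seg(q0x, q0y, q1x, q1y, p0x, p0y))
        | ((d2 == 0) & on_seg(q0x, q0y, q1x, q1y, p1x, p1y))
        | ((d3 == 0) & on_seg(p0x, p0y, p1x, p1y, q0x, q0y))
        | ((d4 == 0) & on_seg(p0x, p0y, p1x, p1y, q1x, q1y))
    )
    return proper | touch


def segments_hit_triangle(tri: np.ndarray, p0: np.ndarray, p1: np.ndarray) -> np.ndarray:
    """Vectorised segment-vs-triangle intersection.

    ``tri`` is (3, 2) CCW; ``p0``/``p1`` are (..., 2).  Returns a boolean
    array of the leading shape.
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    hit = _points_in_triangle(tri, p0[..., 0], p0[..., 1])
    hit |= _points_in_triangle(tri, p1[..., 0], p1[..., 1])
    for i in range(3):
        q0 = tri[i]
        q1 = tri[(i + 1) % 3]
        hit |= _segments_intersect(
            p0[..., 0], p0[..., 1], p1[..., 0], p1[..., 1], q0, q1
        )
    return hit


# Capture tallies -----------------------------------------------------------


@dataclass
class CaptureLog:
    """Per-camera per-day capture counts q[i, j]."""

    q: np.ndarray  # (N cameras, T days) of non-negative ints

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q)
        if self.q.ndim != 2 or self.q.shape[0] < 1 or self.q.shape[1] < 1:
            raise ValueError("q must be a non-empty (N, T) matrix")
        if np.any(self.q < 0) or not np.issubdtype(self.q.dtype, np.integer):
            raise ValueError("q must contain non-negative integers")

    @property
    def N(self) -> int:
        return self.q.shape[0]

    @property
    def T(self) -> int:
        return self.q.shape[1]

    def to_frame(self):
        import pandas as pd

        rows = [
            (i, j, int(self.q[i, j]))
            for i in range(self.N)
            for j in range(self.T)
        ]
        return pd.DataFrame(rows, columns=["camera_id", "day", "count"])

    @classmethod
    def from_frame(cls, df) -> "CaptureLog":
        n = int(df["camera_id"].max()) + 1
        t = int(df["day"].max()) + 1
        q = np.zeros((n, t), dtype=np.int64)
        for _, row in df.iterrows():
            q[int(row["camera_id"]), int(row["day"])] = int(row["count"])
        return cls(q=q)


def _hit_matrix(camera: CameraTrap, batch: SegmentBatch, d_max: float) -> np.ndarray:
    """Boolean (n_pikas, n_steps): does each step's segment touch the zone?

    Wrapped (seam-crossing) steps are handled by also testing the
    translated copy of the segment that places the wrapped endpoint at its
    real in-square position.
    """
    p0, p1, L = batch.p0, batch.p1, batch.L
    n, steps = p0.shape[0], p0.shape[1]
    hits = np.zeros((n, steps), dtype=bool)
    if n == 0 or steps == 0:
        return hits
    tri = camera.vertices
    apex = np.asarray(camera.apex)
    reach = camera.side + d_max + 1e-9

    # prefilter: a segment can only touch the zone if its start lies within
    # side-length + d_max of the apex (segment length <= d_max)
    close = ((p0 - apex) ** 2).sum(axis=2) <= reach * reach
    if close.any():
        idx = np.where(close)
        hits[idx] = segments_hit_triangle(tri, p0[idx], p1[idx])

    # seam-crossing steps: test the copy translated by -(p1 - wrap(p1))
    p1w = np.mod(p1, L)
    offset = p1 - p1w
    wrapped = (offset != 0).any(axis=2)
    if wrapped.any():
        idx = np.where(wrapped)
        o = offset[idx]
        hits[idx] |= segments_hit_triangle(tri, p0[idx] - o, p1w[idx])
    return hits


def count_captures_batch(
    batches: list[SegmentBatch],
    cameras: list[CameraTrap],
    config: SimulationConfig,
) -> CaptureLog:
    """Tally captures for a multi-day run (one SegmentBatch per day)."""
    if not cameras:
        raise ValueError("need at least one camera")
    if not batches:
        raise ValueError("need at least one day of movement")
    q = np.zeros((len(cameras), len(batches)), dtype=np.int64)
    for j, batch in enumerate(batches):
        for i, cam in enumerate(cameras):
            hits = _hit_matrix(cam, batch, config.d_max)
            q[i, j] = _tally(hits, config.capture_rule)
    return CaptureLog(q=q)


def _tally(hits: np.ndarray, rule: str) -> int:
    if hits.size == 0:
        return 0
    if rule == "step":
        return int(hits.sum())
    if rule == "entry":
        prev = np.zeros_like(hits)
        prev[:, 1:] = hits[:, :-1]
        return int((hits & ~prev).sum())
    raise ValueError(f"unknown capture rule {rule!r}")


def count_captures(paths, cameras: list[CameraTrap], config: SimulationConfig) -> CaptureLog:
    """Tally captures from a list of :class:`~pikasim.movement.PikaPath`.

    Paths may span several days; ``q`` is indexed by camera and day (days
    renumbered 0..T-1 in sorted order).
    """
    if not cameras:
        raise ValueError("need at least one camera")
    days = sorted({p.day for p in paths}) or [0]
    day_index = {d: j for j, d in enumerate(days)}
    q = np.zeros((len(cameras), len(days)), dtype=np.int64)
    for path in paths:
        if not path.segments:
            continue
        p0 = np.array([seg[1] for seg in path.segments], dtype=float)
        p1 = np.array([seg[2] for seg in path.segments], dtype=float)
        batch = SegmentBatch(
            p0=p0[None, :, :],
            p1=p1[None, :, :],
            total_distance=np.array([path.total_distance]),
            L=config.L,
        )
        j = day_index[path.day]
        for i, cam in enumerate(cameras):
            hits = _hit_matrix(cam, batch, config.d_max)
            q[i, j] += _tally(hits, config.capture_rule)
    return CaptureLog(q=q)
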