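"""Burrow-system landscape generation.

Territories are modelled as a bounded Voronoi (Thiessen) tessellation of
uniformly scattered control points inside the square study area.  Each cell
receives a uniform number of surface entrances (with a minimum spacing
constraint) and a uniform number of resident pikas.

The bounded tessellation uses the mirror trick: the control points are
reflected across the four sides of the square, the plain Voronoi diagram of
the 5N points is computed, and the cells of the original N points are then
finite and clipped exactly to the square.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.spatial import Voronoi
from shapely.geometry import Polygon

import logging

from ._rng import child_rng
from .config import SimulationConfig

logger = logging.getLogger("pikasim.territory")

__all__ = [
    "BurrowSystem",
    "Landscape",
    "PlacementError",
    "bounded_voronoi",
    "place_entrances",
    "allocate_pikas",
    "generate_landscape",
    "save_landscape",
    "load_landscape",
]

#: Rejection-sampling attempts per cell before giving up.
MAX_PLACEMENT_ATTEMPTS = 10_000


class PlacementError(RuntimeError):
    """Raised when entrances cannot be placed in a cell at the required
    spacing within the attempt budget (the spacing is never relaxed)."""


@dataclass
class BurrowSystem:
    """One pika family territory: a Voronoi cell with entrances."""

    id: int
    control_point: np.ndarray  # (2,)
    cell: np.ndarray  # (k, 2) CCW exterior vertices
    entrances: np.ndarray  # (H, 2)
    n_pikas: int = 0

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.cell)

    @property
    def area(self) -> float:
        return float(self.polygon.area)


@dataclass
class Landscape:
    """The tessellated square with all burrow systems."""

    L: float
    systems: list[BurrowSystem]
    #: systems whose entrance spacing had to be relaxed (infeasible cells)
    relaxed_system_ids: list[int] = field(default_factory=list)

    @property
    def n_pikas(self) -> int:
        return int(sum(s.n_pikas for s in self.systems))

    @property
    def true_density(self) -> float:
        """Pikas per hectare over the whole square."""
        return self.n_pikas / (self.L**2 / 1e4)

    # Packed views used by the vectorised movement engine -----------------

    def packed_entrances(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (entrances, counts).

        ``entrances`` has shape (n_systems, H_max, 2) padded with +inf so
        padded slots can never win a nearest-entrance comparison; ``counts``
        holds the true entrance count per system.
        """
        counts = np.array([len(s.entrances) for s in self.systems], dtype=np.int64)
        h_max = int(counts.max()) if len(counts) else 0
        packed = np.full((len(self.systems), h_max, 2), np.inf)
        for i, s in enumerate(self.systems):
            packed[i, : counts[i]] = s.entrances
        return packed, counts

    def pika_system_index(self) -> np.ndarray:
        """System index of every pika, shape (n_pikas,)."""
        return np.repeat(
            np.arange(len(self.systems)),
            [s.n_pikas for s in self.systems],
        )


def bounded_voronoi(points: np.ndarray, L: float) -> list[np.ndarray]:
    """Voronoi tessellation of ``points`` clipped to the square [0, L]^2.

    Returns one (k, 2) CCW vertex array per input point.  Cell areas sum to
    L^2 and each cell contains exactly the locations nearer to its
    generating point than to any other.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise ValueError("points must have shape (n, 2)")
    if len(points) == 0:
        raise ValueError("need at least one point")
    if np.any(points < 0) or np.any(points > L):
        raise ValueError("all points must lie inside the bounding square")
    if len(np.unique(points, axis=0)) != len(points):
        raise ValueError("duplicate control points produce a degenerate tessellation")

    square = shapely.box(0.0, 0.0, L, L)
    if len(points) == 1:
        return [np.asarray(square.exterior.coords)[:-1]]

    # Mirror across the four sides; original cells become finite and
    # bounded exactly by the square.
    left = points * [-1.0, 1.0]
    right = points * [-1.0, 1.0] + [2.0 * L, 0.0]
    down = points * [1.0, -1.0]
    up = points * [1.0, -1.0] + [0.0, 2.0 * L]
    vor = Voronoi(np.vstack([points, left, right, down, up]))

    cells: list[np.ndarray] = []
    for i in range(len(points)):
        region = vor.regions[vor.point_region[i]]
        if -1 in region:  # cannot happen with the mirror construction
            raise RuntimeError(f"unbounded Voronoi region for point {i}")
        verts = vor.vertices[region]
        # cells are convex: angular sort around the centroid gives a CCW ring
        centroid = verts.mean(axis=0)
        order = np.argsort(np.arctan2(verts[:, 1] - centroid[1], verts[:, 0] - centroid[0]))
        verts = verts[order]
        poly = Polygon(verts)
        if not poly.within(square):
            poly = poly.intersection(square)
        cells.append(np.asarray(poly.exterior.coords)[:-1])
    return cells


def place_entrances(
    cell: np.ndarray | Polygon,
    H_min: int,
    H_max: int,
    l_min: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Place a uniform number of entrances in ``cell`` with min spacing.

    Rejection sampling from the cell's bounding box; candidates are accepted
    if inside the cell and at least ``l_min`` from all previously accepted
    entrances.  Raises :class:`PlacementError` after
    :data:`MAX_PLACEMENT_ATTEMPTS` failed candidates.
    """
    poly = cell if isinstance(cell, Polygon) else Polygon(np.asarray(cell))
    if poly.is_empty or poly.area <= 0:
        raise PlacementError("cell is degenerate (zero area)")
    n_target = int(rng.integers(H_min, H_max + 1))
    minx, miny, maxx, maxy = poly.bounds
    shapely.prepare(poly)

    accepted = np.empty((n_target, 2))
    n_acc = 0
    attempts = 0
    l2 = l_min * l_min
    while n_acc < n_target:
        if attempts >= MAX_PLACEMENT_ATTEMPTS:
            raise PlacementError(
                f"could not place {n_target} entrances at spacing {l_min} m "
                f"in cell with area {poly.area:.2f} m^2 "
                f"(placed {n_acc} after {attempts} attempts)"
            )
        # draw candidates in batches to amortise the point-in-polygon test
        batch = min(64, MAX_PLACEMENT_ATTEMPTS - attempts)
        xs = rng.uniform(minx, maxx, batch)
        ys = rng.uniform(miny, maxy, batch)
        inside = shapely.contains_xy(poly, xs, ys)
        for x, y, ok in zip(xs, ys, inside):
            attempts += 1
            if not ok:
                continue
            if n_acc:
                d2 = (accepted[:n_acc, 0] - x) ** 2 + (accepted[:n_acc, 1] - y) ** 2
                if d2.min() < l2:
                    continue
            accepted[n_acc] = (x, y)
            n_acc += 1
            if n_acc == n_target:
                break
    return accepted


def allocate_pikas(
    systems: list[BurrowSystem],
    Q_min: int,
    Q_max: int,
    rng: np.random.Generator,
) -> list[BurrowSystem]:
    """Draw each system's occupant count uniformly from {Q_min..Q_max}."""
    if Q_min > Q_max:
        raise ValueError(f"Q_min ({Q_min}) > Q_max ({Q_max})")
    counts = rng.integers(Q_min, Q_max + 1, size=len(systems))
    for s, q in zip(systems, counts):
        s.n_pikas = int(q)
    return systems


def generate_landscape(
    config: SimulationConfig,
    seed: int | None = None,
) -> Landscape:
    """Build the full landscape for one trial.

    Child RNG streams (root = ``seed`` or ``config.seed``):
    ``("control",)`` control points, ``("entrances", i)`` per-system
    entrance placement, ``("pikas",)`` occupant allocation.

    Uniform control points make occasional cells too small to hold
    ``H_min`` entrances at ``l_min`` spacing (nearest-neighbour distances
    below ``l_min`` itself occur with probability ~3% per point at the
    default intensity).  For exactly those infeasible cells the spacing is
    progressively halved until placement succeeds; the affected system ids
    are recorded in ``Landscape.relaxed_system_ids`` and logged.  Entrance
    counts always stay within [H_min, H_max].
    """
    if seed is None:
        seed = config.seed
    rng_pts = child_rng(seed, "control")
    n = config.n_systems
    points = rng_pts.uniform(0.0, config.L, size=(n, 2))
    # reject exact duplicates (practically impossible with float64 uniforms)
    while len(np.unique(points, axis=0)) != len(points):
        _, idx = np.unique(points, axis=0, return_index=True)
        dup = np.setdiff1d(np.arange(n), idx)
        points[dup] = rng_pts.uniform(0.0, config.L, size=(len(dup), 2))

    cells = bounded_voronoi(points, config.L)
    systems = []
    relaxed: list[int] = []
    for i, (pt, cell) in enumerate(zip(points, cells)):
        rng_i = child_rng(seed, "entrances", i)
        l_eff = config.l_min
        while True:
            try:
                entrances = place_entrances(
                    cell, config.H_min, config.H_max, l_eff, rng_i
                )
                break
            except PlacementError as err:
                if l_eff <= 0:
                    raise PlacementError(f"system {i}: {err}") from err
                l_eff = l_eff / 2.0 if l_eff > config.l_min / 64.0 else 0.0
        if l_eff != config.l_min:
            relaxed.append(i)
            logger.warning(
                "system %d: cell area %.1f m^2 cannot hold %d-%d entrances "
                "at %.2g m spacing; relaxed to %.2g m",
                i, Polygon(cell).area, config.H_min, config.H_max,
                config.l_min, l_eff,
            )
        systems.append(
            BurrowSystem(
                id=i,
                control_point=pt,
                cell=cell,
                entrances=entrances,
            )
        )
    allocate_pikas(systems, config.Q_min, config.Q_max, child_rng(seed, "pikas"))
    return Landscape(L=config.L, systems=systems, relaxed_system_ids=relaxed)


# CSV round-trip -----------------------------------------------------------


def save_landscape(landscape: Landscape, directory) -> None:
    """Write systems.csv, entrances.csv and cells.csv into ``directory``."""
    import pandas as pd
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "id": [s.id for s in landscape.systems],
            "cx": [s.control_point[0] for s in landscape.systems],
            "cy": [s.control_point[1] for s in landscape.systems],
            "n_pikas": [s.n_pikas for s in landscape.systems],
        }
    ).to_csv(directory / "systems.csv", index=False)
    ent_rows = [
        (s.id, x, y) for s in landscape.systems for x, y in s.entrances
    ]
    pd.DataFrame(ent_rows, columns=["system_id", "x", "y"]).to_csv(
        directory / "entrances.csv", index=False
    )
    cell_rows = [
        (s.id, j, x, y)
        for s in landscape.systems
        for j, (x, y) in enumerate(s.cell)
    ]
    pd.DataFrame(cell_rows, columns=["system_id", "vertex_index", "x", "y"]).to_csv(
        directory / "cells.csv", index=False
    )
    with open(directory / "bounds.csv", "w") as fh:
        fh.write("L\n")
        fh.write(f"{landscape.L!r}\n")


def load_landscape(directory) -> Landscape:
    """Inverse of :func:`save_landscape`."""
    import pandas as pd
    from pathlib import Path

    directory = Path(directory)
    sys_df = pd.read_csv(directory / "systems.csv")
    ent_df = pd.read_csv(directory / "entrances.csv")
    cell_df = pd.read_csv(directory / "cells.csv")
    L = float(pd.read_csv(directory / "bounds.csv")["L"].iloc[0])
    systems = []
    for _, row in sys_df.iterrows():
        sid = int(row["id"])
        ent = ent_df[ent_df["system_id"] == sid][["x", "y"]].to_numpy(float)
        cell = (
            cell_df[cell_df["system_id"] == sid]
            .sort_values("vertex_index")[["x", "y"]]
            .to_numpy(float)
        )
        systems.append(
            BurrowSystem(
                id=sid,
                control_point=np.array([row["cx"], row["cy"]], dtype=float),
                cell=cell,
                entrances=ent,
                n_pikas=int(row["n_pikas"]),
            )
        )
    return Landscape(L=L, systems=systems)
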