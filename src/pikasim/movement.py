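"""Ground-movement simulation.

Each pika starts every day inside its burrow with a ground-time budget
``t_tol``.  An excursion begins at a uniformly chosen entrance of the
pika's own system.  At each step of length ``dt`` the animal draws an
activity intensity (high with probability ``p_high``), a Gaussian speed for
that intensity (negative draws truncated to 0), and a uniform heading; the
displacement ``s_t = min(v_t * dt, d_max)`` is applied and the position is
wrapped torus-fashion into the square.  The excursion ends as soon as the
animal comes within ``l_home`` of one of its own entrances (strict
inequality); the next excursion, if budget remains, starts afresh at a
random own entrance.  Only outside time consumes budget — in-burrow dwell
is not modelled.

Two engines are provided: a per-animal reference implementation
(:func:`simulate_day`, returning a :class:`PikaPath`) and a vectorised
population engine (:func:`simulate_population_day`) used by the experiment
sweeps.  They implement the same process; tests check their statistics
agree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import SimulationConfig
from .territory import Landscape

__all__ = [
    "PikaState",
    "PikaPath",
    "SegmentBatch",
    "sample_speed",
    "wrap",
    "check_return",
    "advance",
    "simulate_day",
    "simulate_population_day",
    "expected_daily_distance",
]

TWO_PI = 2.0 * math.pi


@dataclass
class PikaState:
    """Mutable per-animal state within a day."""

    id: int
    system_id: int
    position: np.ndarray  # (2,), wrapped into [0, L)
    status: str = "inside"  # "inside" | "outside"
    intensity: str = "low"  # of the most recent step
    budget_remaining: float = 0.0  # min
    heading: float = 0.0  # rad, of the most recent step
    step_distance: float = 0.0  # m, of the most recent step
    cum_distance: float = 0.0  # m, within the day


@dataclass
class PikaPath:
    """One animal's track for one day.

    ``segments`` holds (t_start, p0, p1) with p1 *pre-wrap* so that
    |p1 - p0| equals the step displacement; ``excursions`` holds
    (exit_entrance_index, return_entrance_index or None) where ``None``
    flags a forced stop at budget exhaustion.
    """

    pika_id: int
    day: int
    segments: list = field(default_factory=list)
    excursions: list = field(default_factory=list)
    total_distance: float = 0.0


@dataclass
class SegmentBatch:
    """Vectorised day of movement for a whole population.

    ``p0``/``p1`` have shape (n_pikas, n_steps, 2); ``p1`` is pre-wrap so
    segment geometry is Euclidean.  ``total_distance`` has shape
    (n_pikas,).
    """

    p0: np.ndarray
    p1: np.ndarray
    total_distance: np.ndarray
    L: float

    @property
    def n_pikas(self) -> int:
        return self.p0.shape[0]

    @property
    def n_steps(self) -> int:
        return self.p0.shape[1]


def sample_speed(
    intensity: str,
    config: SimulationConfig,
    rng: np.random.Generator,
    size=None,
) -> float | np.ndarray:
    """Gaussian speed draw for an intensity class, truncated at 0 (m/min)."""
    if intensity == "high":
        mu, sigma = config.v_large, config.sigma_large
    elif intensity == "low":
        mu, sigma = config.v_small, config.sigma_small
    else:
        raise ValueError(f"intensity must be 'high' or 'low', got {intensity!r}")
    v = rng.normal(mu, sigma, size=size)
    return np.maximum(v, 0.0) if size is not None else max(float(v), 0.0)


def wrap(position, L: float):
    """Map coordinates into [0, L) by modular arithmetic (torus boundary)."""
    w = np.mod(np.asarray(position, dtype=float), L)
    # np.mod(-eps, L) can round to exactly L; fold it back to 0
    return np.where(w >= L, 0.0, w)


def check_return(position, entrances, l_home: float) -> bool:
    """True iff the distance to the nearest own entrance is < l_home."""
    entrances = np.asarray(entrances, dtype=float)
    if entrances.size == 0:
        raise ValueError("entrances must be non-empty")
    d2 = ((entrances - np.asarray(position, dtype=float)) ** 2).sum(axis=1)
    return bool(d2.min() < l_home * l_home)


def advance(
    state: PikaState, config: SimulationConfig, rng: np.random.Generator
) -> PikaState:
    """One movement step: draw intensity, speed and heading, move, wrap.

    Consumes ``dt`` of budget.  Must only be called while outside.
    """
    if state.status != "outside":
        raise RuntimeError("advance() called on a pika that is inside its burrow")
    if not state.budget_remaining > 0:
        raise RuntimeError("advance() called with no activity budget remaining")
    intensity = "high" if rng.random() < config.p_high else "low"
    v = sample_speed(intensity, config, rng)
    s = min(v * config.dt, config.d_max)
    phi = rng.uniform(0.0, TWO_PI)
    new = state.position + s * np.array([math.cos(phi), math.sin(phi)])
    state.intensity = intensity
    state.heading = phi
    state.step_distance = s
    state.cum_distance += s
    state.budget_remaining -= config.dt
    state.position = wrap(new, config.L)
    return state


def simulate_day(
    pika_id: int,
    system_id: int,
    landscape: Landscape,
    config: SimulationConfig,
    rng: np.random.Generator,
    day: int = 0,
) -> PikaPath:
    """Reference per-animal simulation of one day; returns the full path."""
    system = landscape.systems[system_id]
    entrances = np.asarray(system.entrances, dtype=float)
    if len(entrances) == 0:
        raise ValueError(f"system {system_id} has no entrances")

    path = PikaPath(pika_id=pika_id, day=day)
    state = PikaState(
        id=pika_id,
        system_id=system_id,
        position=entrances[0].copy(),
        budget_remaining=float(config.t_tol),
    )
    t = 0.0
    exit_idx = None
    while state.budget_remaining > 1e-9:
        if state.status == "inside":
            exit_idx = int(rng.integers(len(entrances)))
            state.position = entrances[exit_idx].copy()
            state.status = "outside"
        p0 = state.position.copy()
        advance(state, config, rng)
        p1_prewrap = p0 + state.step_distance * np.array(
            [math.cos(state.heading), math.sin(state.heading)]
        )
        path.segments.append((t, p0, p1_prewrap))
        t += config.dt
        if check_return(state.position, entrances, config.l_home):
            d2 = ((entrances - state.position) ** 2).sum(axis=1)
            path.excursions.append((exit_idx, int(np.argmin(d2))))
            state.status = "inside"
    if state.status == "outside":
        path.excursions.append((exit_idx, None))  # forced stop, budget spent
    path.total_distance = float(
        sum(np.linalg.norm(p1 - p0) for _, p0, p1 in path.segments)
    )
    return path


def simulate_population_day(
    landscape: Landscape,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> SegmentBatch:
    """Vectorised simulation of one day for every pika in the landscape."""
    entrances, counts = landscape.packed_entrances()
    sys_idx = landscape.pika_system_index()
    n = len(sys_idx)
    n_steps = config.n_steps_per_day
    p0_out = np.empty((n, n_steps, 2))
    p1_out = np.empty((n, n_steps, 2))
    total = np.zeros(n)
    if n == 0 or n_steps == 0:
        return SegmentBatch(
            p0=p0_out[:, :0], p1=p1_out[:, :0], total_distance=total, L=config.L
        )

    ent_per_pika = entrances[sys_idx]  # (n, H_max, 2), +inf padded
    n_ent = counts[sys_idx]  # (n,)
    pos = np.empty((n, 2))
    inside = np.ones(n, dtype=bool)
    l_home2 = config.l_home * config.l_home

    for step in range(n_steps):
        if inside.any():
            idx = np.flatnonzero(inside)
            pick = rng.integers(0, n_ent[idx])
            pos[idx] = ent_per_pika[idx, pick]
            inside[idx] = False
        high = rng.random(n) < config.p_high
        v = np.where(
            high,
            rng.normal(config.v_large, config.sigma_large, n),
            rng.normal(config.v_small, config.sigma_small, n),
        )
        s = np.minimum(np.maximum(v, 0.0) * config.dt, config.d_max)
        phi = rng.uniform(0.0, TWO_PI, n)
        disp = s[:, None] * np.stack([np.cos(phi), np.sin(phi)], axis=1)
        p1 = pos + disp
        p0_out[:, step] = pos
        p1_out[:, step] = p1
        total += s
        pos = wrap(p1, config.L)
        d2 = ((ent_per_pika - pos[:, None, :]) ** 2).sum(axis=2)
        inside = d2.min(axis=1) < l_home2

    return SegmentBatch(p0=p0_out, p1=p1_out, total_distance=total, L=config.L)


def expected_daily_distance(config: SimulationConfig) -> float:
    """Closed-form E[total daily distance], m.

    n_steps * dt * (p_high*v_large + (1-p_high)*v_small); exact when the
    0-truncation and d_max cap are inactive, as at the default parameters.
    """
    v_mean = config.p_high * config.v_large + (1.0 - config.p_high) * config.v_small
    return config.n_steps_per_day * config.dt * v_mean
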