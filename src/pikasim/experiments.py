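"""Full-pipeline trials and Monte Carlo parameter sweeps.

A *trial* generates a landscape, simulates every pika for the configured
number of days, tallies virtual-camera captures, and reduces them to the
mean daily capture rate P, the true density D, and λ = P / D.

Three sweeps reproduce the published computational experiments:

* a density sweep varying the occupants-per-system range (Q_min, Q_max),
  which probes λ's invariance to population density;
* parameter sweeps over the daily activity time t_tol and the two
  movement-speed means v_large and v_small, which probe λ's monotone
  response to behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import child_rng
from .config import SimulationConfig
from .detection import CaptureLog, build_cameras, count_captures_batch
from .estimation import mean_capture_rate
from .movement import simulate_population_day
from .territory import generate_landscape

__all__ = [
    "SweepRecord",
    "run_trial",
    "density_sweep",
    "parameter_sweep",
    "records_to_frame",
    "group_means",
]

SWEEPABLE = ("t_tol", "v_large", "v_small")


@dataclass(frozen=True)
class SweepRecord:
    """One trial's outcome within a sweep."""

    parameter: str
    value: object  # swept value; a (Q_min, Q_max) tuple for density sweeps
    trial: int
    seed: int
    n_pikas: int
    true_density: float  # ha^-1
    P: float  # mean daily captures per camera
    lam: float  # ha; 0 by convention for empty landscapes
    mean_daily_distance: float  # m, averaged over pikas and days


def run_trial(
    config: SimulationConfig,
    seed: int,
    parameter: str = "baseline",
    value: object = None,
    trial: int = 0,
    return_log: bool = False,
):
    """Run the full pipeline once, reproducibly for a given seed.

    Child streams: ``("landscape",)``, ``("cameras",)``, ``("day", j)``.
    """
    landscape = generate_landscape(config, seed=child_rng(seed, "landscape").integers(2**31))
    cameras = build_cameras(config, rng=child_rng(seed, "cameras"))

    batches = []
    dist_sum = 0.0
    for day in range(config.D_tol):
        batch = simulate_population_day(landscape, config, child_rng(seed, "day", day))
        batches.append(batch)
        if batch.n_pikas:
            dist_sum += float(batch.total_distance.mean())
    log = count_captures_batch(batches, cameras, config)
    P = mean_capture_rate(log)
    D = landscape.true_density
    lam = P / D if D > 0 else 0.0
    record = SweepRecord(
        parameter=parameter,
        value=value,
        trial=trial,
        seed=seed,
        n_pikas=landscape.n_pikas,
        true_density=D,
        P=P,
        lam=lam,
        mean_daily_distance=dist_sum / config.D_tol if config.D_tol else 0.0,
    )
    return (record, log) if return_log else record


def density_sweep(
    config: SimulationConfig,
    q_ranges: list[tuple[int, int]] | None = None,
    trials: int = 15,
) -> list[SweepRecord]:
    """One record per ((Q_min, Q_max) range, trial)."""
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if q_ranges is None:
        q_ranges = [(1, 3), (2, 4), (3, 5), (4, 6), (5, 7), (6, 8)]
    records = []
    for g, (q_min, q_max) in enumerate(q_ranges):
        cfg = config.replace(Q_min=q_min, Q_max=q_max)
        for trial in range(trials):
            seed = int(child_rng(config.seed, "density-sweep", g, trial).integers(2**31))
            records.append(
                run_trial(cfg, seed, parameter="q_range", value=(q_min, q_max), trial=trial)
            )
    return records


def parameter_sweep(
    config: SimulationConfig,
    name: str,
    values,
    trials: int = 15,
) -> list[SweepRecord]:
    """Sweep one of t_tol, v_large, v_small over strictly increasing values."""
    if name not in SWEEPABLE:
        raise ValueError(f"name must be one of {SWEEPABLE}, got {name!r}")
    values = list(values)
    if any(b <= a for a, b in zip(values, values[1:])):
        raise ValueError("values must be strictly increasing")
    if trials < 1:
        raise ValueError("trials must be >= 1")
    records = []
    for g, value in enumerate(values):
        cfg = config.replace(**{name: value})
        for trial in range(trials):
            seed = int(child_rng(config.seed, f"{name}-sweep", g, trial).integers(2**31))
            records.append(
                run_trial(cfg, seed, parameter=name, value=value, trial=trial)
            )
    return records


def records_to_frame(records: list[SweepRecord]) -> pd.DataFrame:
    """Tidy DataFrame, one record per row."""
    return pd.DataFrame(
        {
            "parameter": [r.parameter for r in records],
            "value": [str(r.value) for r in records],
            "trial": [r.trial for r in records],
            "seed": [r.seed for r in records],
            "n_pikas": [r.n_pikas for r in records],
            "true_density": [r.true_density for r in records],
            "P": [r.P for r in records],
            "lambda": [r.lam for r in records],
            "mean_daily_distance": [r.mean_daily_distance for r in records],
        }
    )


def group_means(records: list[SweepRecord]) -> dict:
    """Mean λ per swept value."""
    out: dict = {}
    for r in records:
        out.setdefault(r.value, []).append(r.lam)
    return {k: float(np.mean(v)) for k, v in out.items()}
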