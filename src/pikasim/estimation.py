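"""Random encounter model (REM) density estimation and the λ index.

The REM converts an independent-photograph rate into an animal density
without individual identification:

    D = (y / t) * pi / (v * r * (2 + theta))

with y photographs over t camera-days, daily travel distance v, detection
radius r and detection angle theta.  D is reported per hectare.

λ = P / D ("activity intensity per population density", in hectares)
links the mean daily per-camera capture rate P to density; algebraically
λ = v * r * (2 + theta) / pi when P and D come from the same REM inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .detection import CaptureLog

__all__ = [
    "DensityEstimate",
    "LambdaRecord",
    "FitResult",
    "rem_density",
    "mean_capture_rate",
    "lambda_index",
    "lambda_closed_form",
    "fit_P_vs_D",
]

M2_PER_HA = 1e4


@dataclass(frozen=True)
class DensityEstimate:
    """REM output with its inputs (v stored in m/day)."""

    y: float  # independent photographs
    t: float  # camera-days
    v: float  # m/day
    r: float  # m
    theta: float  # rad
    D: float  # animals per hectare


@dataclass(frozen=True)
class LambdaRecord:
    P: float  # mean daily captures per camera
    D: float  # density, ha^-1
    lam: float  # ha


@dataclass(frozen=True)
class FitResult:
    """OLS fit of P on D; both with-intercept and through-origin slopes."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int
    slope_through_origin: float


def rem_density(y: float, t: float, v: float, r: float, theta: float) -> DensityEstimate:
    """REM density, per hectare.

    ``v`` is accepted in km/day (as configured in the field protocol) and
    converted to m/day internally.  Full precision is kept; round only for
    presentation.
    """
    if t <= 0:
        raise ValueError(f"t (camera-days) must be > 0, got {t!r}")
    if v <= 0 or r <= 0:
        raise ValueError("v and r must be > 0")
    if theta < 0:
        raise ValueError(f"theta must be >= 0, got {theta!r}")
    if y < 0:
        raise ValueError(f"y must be >= 0, got {y!r}")
    v_m = v * 1000.0  # km/day -> m/day
    d_per_m2 = (y / t) * math.pi / (v_m * r * (2.0 + theta))
    return DensityEstimate(
        y=float(y), t=float(t), v=v_m, r=float(r), theta=float(theta),
        D=d_per_m2 * M2_PER_HA,
    )


def mean_capture_rate(log: CaptureLog) -> float:
    """P: grand total of q over all cameras and days, divided by T*N."""
    if log.q.size == 0:
        raise ValueError("empty capture log")
    return float(log.q.sum()) / (log.T * log.N)


def lambda_index(P: float, D: float) -> float:
    """λ = P / D, in hectares.  Undefined (error) at D = 0."""
    if D <= 0:
        raise ValueError(f"lambda_index undefined for D <= 0 (got D={D!r})")
    return P / D


def lambda_closed_form(v: float, r: float, theta: float) -> float:
    """λ = v * r * (2 + theta) / pi, converted from m^2 to hectares.

    ``v`` in m/day here (the REM identity uses the daily travel distance).
    """
    if v <= 0 or r <= 0 or theta < 0:
        raise ValueError("v, r must be > 0 and theta >= 0")
    return v * r * (2.0 + theta) / math.pi / M2_PER_HA


def fit_P_vs_D(pairs) -> FitResult:
    """Ordinary least squares of P on D.

    ``pairs`` is an iterable of (D, P).  The with-intercept slope is the λ
    estimate; a through-origin slope is reported alongside for
    sensitivity.  Requires at least two distinct D values.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need at least two (D, P) pairs")
    d, p = arr[:, 0], arr[:, 1]
    if np.ptp(d) == 0:
        raise ValueError("all D values identical; slope undefined")
    slope, intercept = np.polyfit(d, p, 1)
    pred = slope * d + intercept
    ss_res = float(((p - pred) ** 2).sum())
    ss_tot = float(((p - p.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    slope_origin = float((d @ p) / (d @ d))
    return FitResult(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=float(r2),
        n_points=len(d),
        slope_through_origin=slope_origin,
    )
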