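"""Numerical integration of the tumor / CAR T-cell / dexamethasone model.

The nonautonomous two-species system is integrated with an adaptive,
stiffness-capable solver (scipy's LSODA) at tight default tolerances; the
Dex concentration is appended analytically from its closed form.  Closed
form solutions for the two decoupled limits (logistic tumor growth without
killing; CAR T-cell decay without tumor) are provided as independent
oracles for testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model import ModelParameters, dex_concentration, rhs_nonautonomous

__all__ = [
    "Trajectory",
    "SimulationError",
    "simulate",
    "detect_outcome",
    "Outcome",
    "logistic_solution",
    "cart_decay_solution",
]

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10
#: Tumor CI below which the tumor is considered eradicated (~100 cells).
EXTINCTION_EPS = 0.01
HOURS_PER_DAY = 24.0


class SimulationError(RuntimeError):
    """Raised when the integrator fails; carries the failing time (days)."""

    def __init__(self, message: str, t_fail: Optional[float] = None):
        super().__init__(message)
        self.t_fail = t_fail


@dataclass
class Trajectory:
    """Time-stamped solution path in CI / ug/ml units (times in days)."""

    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    D: np.ndarray
    params: ModelParameters
    solver_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.D = np.asarray(self.D, dtype=float)
        n = self.times.size
        if not (self.x.size == self.y.size == self.D.size == n):
            raise ValueError("series lengths must match the time grid")
        if n > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def to_dataframe(self) -> pd.DataFrame:
        """Export with hour-denominated time, as used at the I/O boundary."""
        return pd.DataFrame(
            {
                "time_hr": self.times * HOURS_PER_DAY,
                "x_ci": self.x,
                "y_ci": self.y,
                "dex_ugml": self.D,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def simulate(
    params: ModelParameters,
    x0: float,
    y0: float,
    t_grid: np.ndarray,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the nonautonomous system on ``t_grid`` (days).

    Parameters
    ----------
    x0, y0 : float
        Non-negative initial tumor and CAR T-cell populations (CI) at
        ``t_grid[0]``.
    t_grid : array-like
        Strictly increasing times in days, ``t_grid[0] >= 0``.

    Returns
    -------
    Trajectory
        Solution sampled at ``t_grid``; the Dex series is the analytic
        exponential.  Tiny negative excursions within solver tolerance are
        clipped to zero on output only.

    Raises
    ------
    SimulationError
        If the integrator fails; the failing time is reported rather than
        returning a silently truncated path.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 2:
        raise ValueError("t_grid must be a 1-d array with at least two points")
    if t_grid[0] < 0 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing with t_grid[0] >= 0")
    if x0 < 0 or y0 < 0:
        raise ValueError("initial populations must be non-negative")

    def rhs(t: float, state: np.ndarray):
        return rhs_nonautonomous(params, t, state[0], state[1])

    sol = solve_ivp(
        rhs,
        (t_grid[0], t_grid[-1]),
        [x0, y0],
        t_eval=t_grid,
        method=method,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        t_fail = float(sol.t[-1]) if sol.t.size else float(t_grid[0])
        raise SimulationError(f"integration failed at t={t_fail:.4f} d: {sol.message}", t_fail)

    x = np.clip(sol.y[0], 0.0, None)
    y = np.clip(sol.y[1], 0.0, None)
    D = params.D0 * np.exp(-params.sigma * t_grid)
    meta = {"method": method, "rtol": rtol, "atol": atol, "nfev": int(sol.nfev)}
    return Trajectory(times=t_grid, x=x, y=y, D=D, params=params, solver_meta=meta)


@dataclass(frozen=True)
class Outcome:
    """Classified fate of a simulated tumor population."""

    label: str  # "tumor_death" | "tumor_progression"
    time: Optional[float]  # first sustained crossing time (days), if death
    x_final: float  # tumor CI at the final time


def detect_outcome(traj: Trajectory, extinction_eps: float = EXTINCTION_EPS) -> Outcome:
    """Label a trajectory as tumor death or progression.

    Tumor death requires the tumor series to drop below ``extinction_eps``
    and stay below it through the final time (a strict zero is unreachable
    numerically); anything else is progression.
    """
    if traj.times.size == 0:
        raise ValueError("empty trajectory")
    if not (np.all(np.isfinite(traj.x)) and np.all(np.isfinite(traj.y))):
        raise ValueError("trajectory contains non-finite values")
    below = traj.x < extinction_eps
    if below[-1]:
        # walk back to the start of the final sustained below-threshold run
        idx = len(below) - 1
        while idx > 0 and below[idx - 1]:
            idx -= 1
        return Outcome("tumor_death", float(traj.times[idx]), float(traj.x[-1]))
    return Outcome("tumor_progression", None, float(traj.x[-1]))


def logistic_solution(rho: float, K: float, x0: float, t) -> np.ndarray:
    """Closed-form logistic tumor growth (no killing, no Dex effect).

    ``x(t) = K x0 e^{rho t} / (K + x0 (e^{rho t} - 1))``.
    """
    t = np.asarray(t, dtype=float)
    e = np.exp(rho * t)
    return K * x0 * e / (K + x0 * (e - 1.0))


def cart_decay_solution(params: ModelParameters, y0: float, t) -> np.ndarray:
    """Closed-form CAR T-cell path with no tumor (``x = 0``).

    With ``x = 0`` the predator equation is separable:
    ``y(t) = y0 exp(-theta t + (c3/sigma)(e^{-sigma t} - 1))``.
    """
    t = np.asarray(t, dtype=float)
    if params.sigma > 0:
        drug_term = (params.c3 / params.sigma) * (np.exp(-params.sigma * t) - 1.0)
    else:
        drug_term = -params.c3 * t
    return y0 * np.exp(-params.theta * t + drug_term)
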