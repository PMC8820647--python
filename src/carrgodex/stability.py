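"""Equilibria, time-resolved eigenvalues, stability labels and Hopf timing.

With the drug concentration written in closed form, time acts as a
bifurcation parameter: the coexistence equilibrium and its Jacobian
eigenvalues drift as dexamethasone clears, and a Hopf bifurcation occurs
when the leading real part crosses zero.  The closed-form eigenvalues

.. math::

   \\lambda_\\pm = \\frac{\\rho(t)\\theta(t)}{2\\kappa_2 K(t)}
   \\left\\{-1 \\pm \\left[1 + \\frac{4\\kappa_2 K(t)}{\\rho(t)}
   \\left(1 - \\frac{\\kappa_2 K(t)}{\\theta(t)}\\right)\\right]^{1/2}\\right\\}

are used wherever :math:`\\theta(t) \\neq 0`; at the singular point the
numeric Jacobian spectrum is substituted.  The oscillation condition is
implemented as the sign of the bracketed discriminant, which is exactly
equivalent to requiring a non-zero imaginary part of the pair.
"""

from __future__ import annotations

import cmath
from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .model import (
    ModelParameters,
    effective_rates,
    unscaled_dex_constants,
)

__all__ = [
    "Equilibrium",
    "EigenvaluePair",
    "BifurcationDiagram",
    "equilibria",
    "coexistence_jacobian",
    "coexistence_eigenvalues",
    "oscillation_test",
    "hopf_times",
    "bifurcation_diagram",
    "autonomous_coexistence_eigenvalues",
]

#: Half-width of the zero-real-part band used for stability labelling, day^-1.
STABILITY_TOL = 1e-10
#: Grid size for Hopf bracketing and root refinement tolerance (days).
HOPF_GRID_POINTS = 1000
HOPF_XTOL = 1e-6
HOURS_PER_DAY = 24.0


@dataclass(frozen=True)
class Equilibrium:
    """A fixed point of the frozen-time system, with quadrant flag."""

    label: str  # "death" | "tumor_proliferation" | "coexistence"
    x_star: float
    y_star: float
    t: float
    in_quadrant: bool = True


@dataclass(frozen=True)
class EigenvaluePair:
    """Coexistence eigenvalues at a frozen time, with the discriminant."""

    lambda_plus: complex
    lambda_minus: complex
    t: float
    discriminant: float

    @property
    def max_real(self) -> float:
        return max(self.lambda_plus.real, self.lambda_minus.real)


def equilibria(params: ModelParameters, t: float = 0.0) -> Tuple[Equilibrium, Equilibrium, Equilibrium]:
    """The three fixed points of the frozen-time system at time ``t``.

    Returns the extinction point (0, 0), the tumor-proliferation point
    (K(t), 0), and the coexistence point
    ``(theta(t)/kappa2, rho(t)(K(t)kappa2 - theta(t)) / (K(t) kappa1 kappa2))``.
    Coexistence coordinates falling outside the non-negative quadrant are
    reported as-is with ``in_quadrant=False``.
    """
    if params.kappa1 == 0 or params.kappa2 == 0:
        raise ValueError("kappa1 and kappa2 must be positive for the coexistence point")
    rates = effective_rates(params, t)
    death = Equilibrium("death", 0.0, 0.0, t)
    prolif = Equilibrium("tumor_proliferation", rates.K_t, 0.0, t, in_quadrant=rates.K_t >= 0)
    x_star = rates.theta_t / params.kappa2
    y_star = (
        rates.rho_t
        * (rates.K_t * params.kappa2 - rates.theta_t)
        / (rates.K_t * params.kappa1 * params.kappa2)
    )
    coex = Equilibrium("coexistence", x_star, y_star, t, in_quadrant=(x_star >= 0 and y_star >= 0))
    return death, prolif, coex


def coexistence_jacobian(params: ModelParameters, t: float = 0.0) -> np.ndarray:
    """Numeric 2x2 Jacobian of the frozen-time system at coexistence.

    ``[[-rho(t) x*/K(t), -kappa1 x*], [kappa2 y*, 0]]``; serves as the
    independent linear-algebra route to the closed-form eigenvalues.
    """
    rates = effective_rates(params, t)
    _, _, coex = equilibria(params, t)
    return np.array(
        [
            [-rates.rho_t * coex.x_star / rates.K_t, -params.kappa1 * coex.x_star],
            [params.kappa2 * coex.y_star, 0.0],
        ]
    )


def _ordered(a: complex, b: complex) -> Tuple[complex, complex]:
    """lambda_plus is the lexicographically larger of (Re, Im) — for a
    conjugate pair that is the +Im branch."""
    return (a, b) if (a.real, a.imag) >= (b.real, b.imag) else (b, a)


def _pair_from_matrix(jac: np.ndarray, t: float, discriminant: float) -> EigenvaluePair:
    vals = np.linalg.eigvals(jac)
    plus, minus = _ordered(complex(vals[0]), complex(vals[1]))
    return EigenvaluePair(plus, minus, t, discriminant)


def coexistence_eigenvalues(params: ModelParameters, t: float = 0.0) -> EigenvaluePair:
    """Closed-form eigenvalues of the coexistence Jacobian at time ``t``.

    The pair sums to the Jacobian trace and multiplies to its determinant;
    the branch is complex exactly when the discriminant is negative.  At the
    singular point ``theta(t) == 0`` the numeric Jacobian spectrum is
    returned instead (the formula divides by ``theta(t)``), with the
    discriminant evaluated as the trace-determinant combination
    ``trace^2 - 4 det`` rescaled to the formula's convention.
    """
    if params.rho == 0 or params.K == 0 or params.kappa2 == 0:
        raise ValueError("rho, K and kappa2 must be positive")
    rates = effective_rates(params, t)
    if rates.theta_t == 0.0:
        jac = coexistence_jacobian(params, t)
        tr = float(np.trace(jac))
        det = float(np.linalg.det(jac))
        return _pair_from_matrix(jac, t, tr * tr - 4.0 * det)
    prefactor = rates.rho_t * rates.theta_t / (2.0 * params.kappa2 * rates.K_t)
    radicand = 1.0 + (4.0 * params.kappa2 * rates.K_t / rates.rho_t) * (
        1.0 - params.kappa2 * rates.K_t / rates.theta_t
    )
    root = cmath.sqrt(radicand)
    lam_plus, lam_minus = _ordered(prefactor * (-1.0 + root), prefactor * (-1.0 - root))
    return EigenvaluePair(complex(lam_plus), complex(lam_minus), t, float(radicand))


def oscillation_test(params: ModelParameters, t: float = 0.0) -> bool:
    """True when the coexistence eigenvalues have non-zero imaginary part.

    Equivalent to a negative discriminant of the closed-form pair, i.e. to
    the oscillation inequality on ``rho(t)/theta(t)``.
    """
    return coexistence_eigenvalues(params, t).discriminant < 0


def _max_real(params: ModelParameters, t: float) -> float:
    return coexistence_eigenvalues(params, t).max_real


def hopf_times(
    params: ModelParameters,
    t_max: float,
    grid_points: int = HOPF_GRID_POINTS,
) -> List[float]:
    """Times in ``(0, t_max]`` where the leading real part changes sign.

    Sign changes are bracketed on a uniform grid and refined by root
    finding to about 1e-6 day.  With no drug effect (``c0 == c3 == 0``)
    the eigenvalues are time-independent and the list is empty.
    """
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    if params.c0 == 0 and params.c3 == 0:
        return []
    grid = np.linspace(0.0, t_max, grid_points + 1)
    values = np.array([_max_real(params, t) for t in grid])
    crossings: List[float] = []
    for i in range(len(grid) - 1):
        a, b = values[i], values[i + 1]
        if a == 0.0:
            continue
        if a * b < 0:
            root = brentq(lambda t: _max_real(params, t), grid[i], grid[i + 1], xtol=HOPF_XTOL)
            crossings.append(float(root))
        elif b == 0.0 and i + 1 == len(grid) - 1:
            crossings.append(float(grid[i + 1]))
    return crossings


@dataclass
class BifurcationDiagram:
    """Eigenvalue flow, stability labels and Hopf crossings on a time grid."""

    times: np.ndarray  # days
    lambda_plus: np.ndarray  # complex
    lambda_minus: np.ndarray  # complex
    labels: List[str]
    hopf_times: List[float]
    x_star: np.ndarray
    y_star: np.ndarray
    params: ModelParameters = field(repr=False, default=None)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_hr": self.times * HOURS_PER_DAY,
                "re_lambda_plus": self.lambda_plus.real,
                "im_lambda_plus": self.lambda_plus.imag,
                "re_lambda_minus": self.lambda_minus.real,
                "im_lambda_minus": self.lambda_minus.imag,
                "label": self.labels,
                "x_star": self.x_star,
                "y_star": self.y_star,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _stability_label(pair: EigenvaluePair, tol: float = STABILITY_TOL) -> str:
    re_max = pair.max_real
    oscillatory = pair.discriminant < 0
    if abs(re_max) <= tol:
        return "limit_cycle_crossing"
    if oscillatory:
        return "stable_spiral" if re_max < 0 else "unstable_spiral"
    return "stable_node" if re_max < 0 else "unstable"


def bifurcation_diagram(params: ModelParameters, t_grid: np.ndarray) -> BifurcationDiagram:
    """Assemble the eigenvalue flow of the coexistence point over ``t_grid``."""
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or (t_grid.size > 1 and np.any(np.diff(t_grid) <= 0)):
        raise ValueError("t_grid must be 1-d and strictly increasing")
    pairs = [coexistence_eigenvalues(params, t) for t in t_grid]
    eq_path = [equilibria(params, t)[2] for t in t_grid]
    return BifurcationDiagram(
        times=t_grid,
        lambda_plus=np.array([p.lambda_plus for p in pairs]),
        lambda_minus=np.array([p.lambda_minus for p in pairs]),
        labels=[_stability_label(p) for p in pairs],
        hopf_times=hopf_times(params, float(t_grid[-1])) if t_grid[-1] > 0 else [],
        x_star=np.array([e.x_star for e in eq_path]),
        y_star=np.array([e.y_star for e in eq_path]),
        params=params,
    )


def autonomous_coexistence_eigenvalues(params: ModelParameters, D: float) -> np.ndarray:
    """Spectrum of the 3x3 autonomous Jacobian at coexistence, given ``D``.

    The drug row decouples (``dD/dt = -sigma D`` is independent of x, y), so
    the Jacobian is block triangular: the spectrum is the 2x2 coexistence
    pair evaluated at the matching drug level together with ``-sigma``.
    Returned sorted by descending real part.
    """
    if D < 0:
        raise ValueError("D must be non-negative")
    if params.kappa1 == 0 or params.kappa2 == 0:
        raise ValueError("kappa1 and kappa2 must be positive")
    c0p, c3p = unscaled_dex_constants(params)
    rho, K = params.rho, params.K
    x_star = (params.theta + c3p * D) / params.kappa2
    y_star = (rho - (rho / K) * x_star - c0p * D) / params.kappa1
    jac = np.array(
        [
            [-(rho / K) * x_star, -params.kappa1 * x_star, -c0p * x_star],
            [params.kappa2 * y_star, 0.0, -c3p * y_star],
            [0.0, 0.0, -params.sigma],
        ]
    )
    vals = np.linalg.eigvals(jac)
    return vals[np.argsort(-vals.real)]
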