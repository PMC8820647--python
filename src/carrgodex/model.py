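"""Core model definitions: parameters, state, dexamethasone pharmacokinetics,
time-dependent effective rates, and both right-hand-side formulations.

The model is a predator-prey system of tumor cells (prey, ``x``) and CAR
T-cells (predator, ``y``) in cell-index (CI) units, extended with an
exponentially clearing dexamethasone (Dex) concentration ``D`` that perturbs
the tumor growth rate and the CAR T-cell death rate.  Two equivalent
formulations are provided:

* the autonomous three-species system

  .. math::

     \\dot x = \\rho x - (\\rho/K) x^2 - \\kappa_1 x y - c_0' D x, \\qquad
     \\dot y = \\kappa_2 x y - \\theta y - c_3' D y, \\qquad
     \\dot D = -\\sigma D;

* the nonautonomous two-species reduction obtained by substituting the
  closed-form clearance :math:`D(t) = D_0 e^{-\\sigma t}`,

  .. math::

     \\dot x = \\rho(t)\\,x\\,(1 - x/K(t)) - \\kappa_1 x y, \\qquad
     \\dot y = \\kappa_2 x y - \\theta(t)\\,y,

  with effective rates :math:`\\rho(t) = \\rho - c_0 e^{-\\sigma t}`,
  :math:`K(t) = \\rho(t) K / \\rho` and
  :math:`\\theta(t) = \\theta + c_3 e^{-\\sigma t}`.

The nonautonomous form is canonical throughout the package: the stored
``c0`` and ``c3`` are the rescaled constants (units day^-1, the initial Dex
concentration ``D0`` absorbed).  The conversion to the unscaled constants of
the autonomous form is :math:`c' = c / D_0` for :math:`D_0 > 0` (and the Dex
terms vanish identically when :math:`D_0 = 0`).

All rates are per day; times are in days; populations in CI (1 CI is
roughly 10,000 adherent cells); Dex concentration in ug/ml.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Tuple

import numpy as np

__all__ = [
    "ModelParameters",
    "SystemState",
    "EffectiveRates",
    "dex_concentration",
    "effective_rates",
    "unscaled_dex_constants",
    "rhs_autonomous",
    "rhs_nonautonomous",
    "DEX_CLEARANCE_PER_DAY",
    "dex_clearance_from_half_life",
]

#: Dex clearance rate used throughout, derived from a plasma half-life of
#: about 200 minutes: 24*ln(2)/(10/3 hr) ~= 5 per day.
DEX_CLEARANCE_PER_DAY: float = 5.0


def dex_clearance_from_half_life(half_life_minutes: float) -> float:
    """Clearance rate (day^-1) for a first-order drug with the given half-life.

    ``half_life_minutes=200`` gives ~4.99 day^-1, conventionally rounded to
    the package default of 5 day^-1.
    """
    if half_life_minutes <= 0:
        raise ValueError("half-life must be positive")
    half_life_days = half_life_minutes / (60.0 * 24.0)
    return float(np.log(2.0) / half_life_days)


@dataclass(frozen=True)
class ModelParameters:
    """The eight model constants plus the Dex clearance rate and initial dose.

    Attributes
    ----------
    rho : float
        Tumor net growth rate, day^-1.
    K : float
        Tumor carrying capacity, CI.
    kappa1 : float
        Tumor killing rate by CAR T-cells, day^-1 CI^-1.
    kappa2 : float
        Net CAR T-cell proliferation/exhaustion rate when stimulated by
        tumor cells, day^-1 CI^-1.
    theta : float
        CAR T-cell death rate, day^-1.
    c0 : float
        Effect of Dex on tumor growth, day^-1 (rescaled; ``D0`` absorbed).
        Positive values are anti-proliferative to the tumor, negative
        pro-proliferative.
    c3 : float
        Effect of Dex on CAR T-cell death, day^-1 (rescaled).  Positive
        values increase CAR T-cell death, negative decrease it.
    sigma : float
        Dex clearance rate, day^-1 (default 5, from a ~200 min half-life).
    D0 : float
        Initial Dex concentration, ug/ml.
    """

    rho: float
    K: float
    kappa1: float
    kappa2: float
    theta: float
    c0: float = 0.0
    c3: float = 0.0
    sigma: float = DEX_CLEARANCE_PER_DAY
    D0: float = 0.0

    def __post_init__(self) -> None:
        for name in ("rho", "K", "kappa1", "kappa2", "theta", "sigma", "D0"):
            value = getattr(self, name)
            if not np.isfinite(value):
                raise ValueError(f"{name} must be finite, got {value!r}")
            if value < 0:
                raise ValueError(f"{name} must be non-negative, got {value!r}")
        # c0 and c3 may take either sign (Dex can be anti- or
        # pro-proliferative to either population) but must be finite.
        for name in ("c0", "c3"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def with_updates(self, **kwargs: float) -> "ModelParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class SystemState:
    """Instantaneous state of the three-species system."""

    t: float  # days
    x: float  # tumor cells, CI
    y: float  # CAR T-cells, CI
    D: float  # Dex concentration, ug/ml


@dataclass(frozen=True)
class EffectiveRates:
    """Time-dependent effective rates of the nonautonomous reduction.

    ``K_t / rho_t == K / rho`` holds exactly for every ``t`` by
    construction, and all three rates relax to the Dex-free constants as
    the drug clears (``t -> inf``).
    """

    rho_t: float  # day^-1
    K_t: float  # CI
    theta_t: float  # day^-1
    t: float = field(default=0.0)


def dex_concentration(params: ModelParameters, t):
    """Dex concentration ``D0 * exp(-sigma * t)`` at time ``t`` (days).

    Accepts scalar or array ``t``; every entry must be non-negative.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be non-negative")
    result = params.D0 * np.exp(-params.sigma * t_arr)
    return float(result) if np.isscalar(t) or t_arr.ndim == 0 else result


def effective_rates(params: ModelParameters, t: float) -> EffectiveRates:
    """Evaluate ``rho(t)``, ``K(t)`` and ``theta(t)`` at time ``t`` (days)."""
    if params.rho == 0:
        raise ValueError("rho must be positive: K(t) = rho(t)*K/rho is undefined at rho=0")
    decay = np.exp(-params.sigma * t)
    rho_t = params.rho - params.c0 * decay
    K_t = rho_t * params.K / params.rho
    theta_t = params.theta + params.c3 * decay
    return EffectiveRates(rho_t=float(rho_t), K_t=float(K_t), theta_t=float(theta_t), t=float(t))


def unscaled_dex_constants(params: ModelParameters) -> Tuple[float, float]:
    """Unscaled interaction constants ``(c0', c3')`` of the autonomous form.

    The stored ``c0``/``c3`` absorb ``D0``; the autonomous three-species
    system multiplies its constants by the instantaneous concentration, so
    ``c' = c / D0``.  When ``D0 == 0`` the Dex terms vanish identically and
    the unscaled constants are reported as zero.
    """
    if params.D0 == 0:
        return 0.0, 0.0
    return params.c0 / params.D0, params.c3 / params.D0


def rhs_autonomous(params: ModelParameters, state: SystemState) -> Tuple[float, float, float]:
    """Right-hand side of the autonomous three-species system at ``state``."""
    c0p, c3p = unscaled_dex_constants(params)
    x, y, D = state.x, state.y, state.D
    dx = params.rho * x - (params.rho / params.K) * x * x - params.kappa1 * x * y - c0p * D * x
    dy = params.kappa2 * x * y - params.theta * y - c3p * D * y
    dD = -params.sigma * D
    return dx, dy, dD


def rhs_nonautonomous(params: ModelParameters, t: float, x: float, y: float) -> Tuple[float, float]:
    """Right-hand side of the nonautonomous two-species reduction.

    Equivalent to the (x, y) components of :func:`rhs_autonomous` evaluated
    at ``D = D0 * exp(-sigma t)`` under the ``c' = c/D0`` rescaling.
    """
    rates = effective_rates(params, t)
    # rho(t) * x * (1 - x/K(t)) written as rho(t)*x - (rho/K)*x^2, which is
    # exact for all signs of rho(t) because K(t)/rho(t) == K/rho.
    dx = rates.rho_t * x - (params.rho / params.K) * x * x - params.kappa1 * x * y
    dy = params.kappa2 * x * y - rates.theta_t * y
    return dx, dy
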