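"""Staged parameter estimation from cell-killing-assay time series.

The data per condition are a densely sampled tumor cell-index series plus
CAR T-cell index at just two time points (treatment start and assay end).
Estimation minimizes a weighted sum-of-squares error between these
measurements and the simulated model, using a global particle-swarm search
for rough estimates followed by Levenberg-Marquardt refinement (via lmfit)
for fine-tuning.

All eight parameters become practically identifiable through a staged
design over four condition types:

1. tumor only, no Dex        -> rho, K (logistic growth)
2. tumor only, with Dex      -> c0 (rho, K fixed)
3. tumor + CAR T, no Dex     -> kappa1, kappa2, theta
4. tumor + CAR T, with Dex   -> kappa1, kappa2, theta, c3 per Dex
                                condition (rho, K, c0 fixed)

The Dex clearance rate sigma is never a free parameter (fixed from the
drug's plasma half-life).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

import lmfit
import numpy as np

from .model import ModelParameters, DEX_CLEARANCE_PER_DAY
from .simulate import SimulationError, simulate

__all__ = [
    "AssayDataset",
    "ParameterBounds",
    "FitResult",
    "StagedFitResult",
    "objective",
    "pso_search",
    "lma_refine",
    "fit_condition",
    "staged_fit",
    "DEFAULT_BOUNDS",
]

#: Observed parameter ranges used as default fitting bounds.
DEFAULT_BOUNDS: Dict[str, Tuple[float, float]] = {
    "rho": (0.5, 12.0),       # day^-1
    "K": (1.0, 20.0),         # CI
    "kappa1": (0.8, 90.0),    # day^-1 CI^-1
    "kappa2": (0.1, 2.0),     # day^-1 CI^-1
    "theta": (1e-12, 3.0),    # day^-1; strictly positive keeps the
                              # eigenvalue formula nonsingular
    "c0": (-10.0, 4.0),       # day^-1
    "c3": (-11.0, 11.0),      # day^-1
}

#: Finite penalty returned when the integrator fails inside the objective,
#: so population-based search can continue past pathological parameter sets.
INTEGRATION_PENALTY = 1e12

HOURS_PER_DAY = 24.0
_FIT_RTOL = 1e-7
_FIT_ATOL = 1e-9
#: Residuals are scaled by max(|data|, floor): impedance noise is
#: signal-proportional, so relative errors are the homoscedastic quantity.
#: The floor (0.05 CI ~ 500 cells) stops near-extinct readings from
#: dominating the objective.
RESIDUAL_FLOOR_CI = 0.05
# coarser integration during the global swarm phase; LMA refines at _FIT_RTOL
_PSO_RTOL = 1e-5
_PSO_ATOL = 1e-8


@dataclass
class AssayDataset:
    """One experimental condition: tumor series plus CAR T endpoints.

    Times are in days with t=0 at treatment (24 h post-seeding); tumor and
    CAR T populations in CI.  Series are duplicate averages unless a
    ``well_id`` marks an individual replicate.
    """

    cell_line: str
    et_ratio: Optional[str]  # e.g. "1:4"; None when no CAR T-cells added
    d0: float  # initial Dex concentration, ug/ml
    times: np.ndarray
    tumor_ci: np.ndarray
    cart_times: Optional[np.ndarray] = None  # (initial, final), days
    cart_ci: Optional[np.ndarray] = None
    well_id: str = "avg"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.tumor_ci = np.asarray(self.tumor_ci, dtype=float)
        if self.times.size != self.tumor_ci.size:
            raise ValueError("tumor series and times must have equal length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.tumor_ci < 0):
            raise ValueError("cell index values must be non-negative")
        if self.d0 < 0:
            raise ValueError("Dex concentration must be non-negative")
        if (self.cart_times is None) != (self.cart_ci is None):
            raise ValueError("cart_times and cart_ci must be given together")
        if self.cart_ci is not None:
            self.cart_times = np.asarray(self.cart_times, dtype=float)
            self.cart_ci = np.asarray(self.cart_ci, dtype=float)
            if self.cart_times.size != self.cart_ci.size:
                raise ValueError("CAR T endpoint arrays must have equal length")
            if np.any(self.cart_ci < 0):
                raise ValueError("cell index values must be non-negative")

    @property
    def has_cart(self) -> bool:
        return self.cart_ci is not None and self.cart_ci.size > 0

    @property
    def has_dex(self) -> bool:
        return self.d0 > 0

    @property
    def x0(self) -> float:
        return float(self.tumor_ci[0])

    @property
    def y0(self) -> float:
        return float(self.cart_ci[0]) if self.has_cart else 0.0


@dataclass(frozen=True)
class ParameterBounds:
    """Box bounds per free parameter; sigma is never free."""

    bounds: Mapping[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS)
    )

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if name == "sigma":
                raise ValueError("sigma is fixed by the drug half-life, not fitted")
            if lo > hi:
                raise ValueError(f"lower bound exceeds upper bound for {name}")

    def lower(self, names: Sequence[str]) -> np.ndarray:
        return np.array([self.bounds[n][0] for n in names])

    def upper(self, names: Sequence[str]) -> np.ndarray:
        return np.array([self.bounds[n][1] for n in names])


@dataclass
class FitResult:
    """Estimates for one condition with provenance and diagnostics."""

    estimates: ModelParameters
    objective_value: float
    free: Tuple[str, ...]
    fixed: Dict[str, float]
    diagnostics: Dict[str, object]
    seed: Optional[int] = None


def _default_weights(dataset: AssayDataset) -> Tuple[float, float]:
    """Tumor weight 1; CAR T endpoints up-weighted so each species
    contributes comparably (about 600 tumor points vs 2 endpoints)."""
    w_x = 1.0
    n_cart = dataset.cart_ci.size if dataset.has_cart else 0
    w_y = (dataset.times.size / n_cart) * w_x if n_cart else 0.0
    return w_x, w_y


def _residuals(
    params: ModelParameters,
    dataset: AssayDataset,
    weights: Optional[Tuple[float, float]] = None,
    rtol: float = _FIT_RTOL,
    atol: float = _FIT_ATOL,
    x0: Optional[float] = None,
) -> np.ndarray:
    """Weighted residual vector (sqrt-weight scaled) for least squares.

    Each residual is relative: ``(model - data) / max(|data|, floor)``,
    matching the signal-proportional noise of impedance readings; the
    species weights multiply on top of that scaling.
    """
    w_x, w_y = weights if weights is not None else _default_weights(dataset)
    t_eval = dataset.times
    if dataset.has_cart:
        t_eval = np.union1d(dataset.times, dataset.cart_times)
    traj = simulate(params, dataset.x0 if x0 is None else x0, dataset.y0,
                    t_eval, rtol=rtol, atol=atol)
    idx_tumor = np.searchsorted(t_eval, dataset.times)
    scale_x = np.maximum(np.abs(dataset.tumor_ci), RESIDUAL_FLOOR_CI)
    res = [np.sqrt(w_x) * (traj.x[idx_tumor] - dataset.tumor_ci) / scale_x]
    if dataset.has_cart:
        idx_cart = np.searchsorted(t_eval, dataset.cart_times)
        scale_y = np.maximum(np.abs(dataset.cart_ci), RESIDUAL_FLOOR_CI)
        res.append(np.sqrt(w_y) * (traj.y[idx_cart] - dataset.cart_ci) / scale_y)
    return np.concatenate(res)


def objective(
    params: ModelParameters,
    dataset: AssayDataset,
    weights: Optional[Tuple[float, float]] = None,
    rtol: float = _FIT_RTOL,
    atol: float = _FIT_ATOL,
    x0: Optional[float] = None,
) -> float:
    """Weighted sum-of-squares error of the model against one condition.

    Sums ``w_x r_x^2`` over the tumor series and ``w_y r_y^2`` over the
    CAR T endpoints, where each residual ``r`` is relative to the
    measurement magnitude (see :func:`_residuals`).  Integration failures
    return a large finite penalty so swarm search continues.
    """
    try:
        r = _residuals(params, dataset, weights, rtol=rtol, atol=atol, x0=x0)
    except (SimulationError, OverflowError):
        return INTEGRATION_PENALTY
    value = float(np.dot(r, r))
    return value if np.isfinite(value) else INTEGRATION_PENALTY


# ---------------------------------------------------------------------------
# Particle swarm optimization (global-best topology)
# ---------------------------------------------------------------------------

def pso_search(
    func: Callable[[np.ndarray], float],
    lower: np.ndarray,
    upper: np.ndarray,
    seed: int,
    n_particles: int = 50,
    n_iters: int = 200,
    inertia: float = 0.729,
    cognitive: float = 1.49445,
    social: float = 1.49445,
    init: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, float, Dict[str, object]]:
    """Minimize ``func`` over a box with global-best particle swarm.

    Standard constriction-style hyperparameters; positions are clamped to
    the box and velocities to the box width.  Fully reproducible from
    ``seed``.  ``init`` may supply warm-start points (rows) that replace
    the first random particles.

    Returns ``(best_position, best_value, diagnostics)``.
    """
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    if lower.size == 0:
        raise ValueError("at least one free parameter is required")
    if not (np.all(np.isfinite(lower)) and np.all(np.isfinite(upper))):
        raise ValueError("bounds must be finite for swarm search")
    rng = np.random.default_rng(seed)
    dim = lower.size
    span = upper - lower
    pos = lower + rng.random((n_particles, dim)) * span
    if init is not None:
        init = np.atleast_2d(np.asarray(init, dtype=float))
        k = min(len(init), n_particles)
        pos[:k] = np.clip(init[:k], lower, upper)
    vel = (rng.random((n_particles, dim)) - 0.5) * span
    pbest = pos.copy()
    pbest_val = np.array([func(p) for p in pos])
    g_idx = int(np.argmin(pbest_val))
    gbest, gbest_val = pbest[g_idx].copy(), float(pbest_val[g_idx])
    history = [gbest_val]
    for _ in range(n_iters):
        r1 = rng.random((n_particles, dim))
        r2 = rng.random((n_particles, dim))
        vel = inertia * vel + cognitive * r1 * (pbest - pos) + social * r2 * (gbest - pos)
        np.clip(vel, -span, span, out=vel)
        pos = np.clip(pos + vel, lower, upper)
        vals = np.array([func(p) for p in pos])
        improved = vals < pbest_val
        pbest[improved] = pos[improved]
        pbest_val[improved] = vals[improved]
        g_idx = int(np.argmin(pbest_val))
        if pbest_val[g_idx] < gbest_val:
            gbest, gbest_val = pbest[g_idx].copy(), float(pbest_val[g_idx])
        history.append(gbest_val)
    diagnostics = {
        "n_particles": n_particles,
        "n_iters": n_iters,
        "history": history,
        "n_evals": n_particles * (n_iters + 1),
    }
    return gbest, gbest_val, diagnostics


# ---------------------------------------------------------------------------
# Levenberg-Marquardt refinement
# ---------------------------------------------------------------------------

def _apply(base: ModelParameters, names: Sequence[str], values: np.ndarray) -> ModelParameters:
    return base.with_updates(**{n: float(v) for n, v in zip(names, values) if n != "x0"})


def _x0_from(names: Sequence[str], values: np.ndarray) -> Optional[float]:
    for n, v in zip(names, values):
        if n == "x0":
            return float(v)
    return None


def _x0_bounds(dataset: AssayDataset) -> Tuple[float, float]:
    """Nuisance bounds for the initial tumor reading: a factor of two
    around the measured value (the measurement error is a few percent)."""
    meas = max(dataset.x0, 1e-3)
    return 0.5 * meas, 2.0 * meas


def lma_refine(
    dataset: AssayDataset,
    start: Mapping[str, float],
    base: ModelParameters,
    bounds: Optional[ParameterBounds] = None,
    weights: Optional[Tuple[float, float]] = None,
    seed: Optional[int] = None,
) -> FitResult:
    """Refine the free parameters in ``start`` by Levenberg-Marquardt.

    ``base`` supplies every fixed parameter.  ``start`` may include the
    nuisance key ``"x0"`` (initial tumor reading); model parameters use
    the box ``bounds``.  The refined objective is never worse than at
    ``start`` (the best iterate is kept even without formal convergence,
    which is then flagged in the diagnostics).
    """
    bounds = bounds or ParameterBounds()
    names = tuple(start.keys())
    lm_params = lmfit.Parameters()
    for n in names:
        lo, hi = _x0_bounds(dataset) if n == "x0" else bounds.bounds[n]
        if not (lo <= start[n] <= hi):
            raise ValueError(f"start value for {n} outside bounds")
        lm_params.add(n, value=float(start[n]), min=lo, max=hi)

    def resid(p: lmfit.Parameters) -> np.ndarray:
        vals = np.array([float(p[n].value) for n in names])
        candidate = _apply(base, names, vals)
        try:
            return _residuals(candidate, dataset, weights, x0=_x0_from(names, vals))
        except (SimulationError, OverflowError):
            return np.full(dataset.times.size + 2, np.sqrt(INTEGRATION_PENALTY))

    out = lmfit.minimize(resid, lm_params, method="leastsq")
    refined = np.array([float(out.params[n].value) for n in names])
    start_vec = np.array([start[n] for n in names])
    f_start = objective(_apply(base, names, start_vec), dataset, weights,
                        x0=_x0_from(names, start_vec))
    f_refined = objective(_apply(base, names, refined), dataset, weights,
                          x0=_x0_from(names, refined))
    if f_refined > f_start:  # keep the best iterate
        refined, f_refined = start_vec, f_start
    estimates = _apply(base, names, refined)
    fixed = {
        n: getattr(base, n)
        for n in ("rho", "K", "kappa1", "kappa2", "theta", "c0", "c3", "sigma", "D0")
        if n not in names
    }
    diagnostics = {
        "lma_success": bool(out.success),
        "lma_nfev": int(out.nfev),
        "lma_message": str(out.message),
    }
    x0_fit = _x0_from(names, refined)
    if x0_fit is not None:
        diagnostics["x0_fit"] = x0_fit
    return FitResult(estimates, f_refined, names, fixed, diagnostics, seed)


def fit_condition(
    dataset: AssayDataset,
    free: Sequence[str],
    base: ModelParameters,
    bounds: Optional[ParameterBounds] = None,
    weights: Optional[Tuple[float, float]] = None,
    seed: int = 0,
    pso_particles: int = 50,
    pso_iters: int = 200,
    init: Optional[np.ndarray] = None,
) -> FitResult:
    """Fit the ``free`` parameters of one condition: PSO then LMA.

    ``init`` optionally warm-starts the swarm (e.g. with estimates from a
    related condition).  ``free`` may include the nuisance name ``"x0"``
    (initial tumor reading, bounded around the measured value)."""
    bounds = bounds or ParameterBounds()
    names = tuple(free)
    x0_lo, x0_hi = _x0_bounds(dataset)
    lower = np.array([x0_lo if n == "x0" else bounds.bounds[n][0] for n in names])
    upper = np.array([x0_hi if n == "x0" else bounds.bounds[n][1] for n in names])

    def vec_objective(vec: np.ndarray) -> float:
        return objective(_apply(base, names, vec), dataset, weights,
                         rtol=_PSO_RTOL, atol=_PSO_ATOL, x0=_x0_from(names, vec))

    rough, rough_val, pso_diag = pso_search(
        vec_objective, lower, upper, seed=seed,
        n_particles=pso_particles, n_iters=pso_iters, init=init,
    )
    result = lma_refine(
        dataset, dict(zip(names, rough)), base, bounds, weights, seed=seed
    )
    result.diagnostics.update(
        {"pso_value": rough_val, "pso_n_evals": pso_diag["n_evals"],
         "pso_particles": pso_particles, "pso_iters": pso_iters}
    )
    return result


@dataclass
class StagedFitResult:
    """Combined estimates from the four-stage identifiability design."""

    stages: Dict[str, FitResult]
    params_no_dex: Optional[ModelParameters]
    params_dex: Optional[ModelParameters]
    skipped: List[str]
    seed: int

    @property
    def estimates(self) -> ModelParameters:
        """Full parameter set of the Dex-treated condition (falls back to
        the Dex-free set when no Dex stages were run)."""
        if self.params_dex is not None:
            return self.params_dex
        if self.params_no_dex is not None:
            return self.params_no_dex
        raise ValueError("no stage produced estimates")


def staged_fit(
    tumor_only: Optional[AssayDataset],
    tumor_dex: Optional[AssayDataset],
    cart_only: Optional[AssayDataset],
    cart_dex: Optional[AssayDataset],
    bounds: Optional[ParameterBounds] = None,
    seed: int = 1,
    pso_particles: int = 50,
    pso_iters: int = 200,
    sigma: float = DEX_CLEARANCE_PER_DAY,
) -> StagedFitResult:
    """Run the four-stage fitting protocol for one cell line / condition set.

    Stage 1 fits (rho, K) on the untreated well; Stage 2 fits c0 on the
    Dex-only well with (rho, K) frozen; Stage 3 fits (kappa1, kappa2,
    theta) on the CAR T-only well; Stage 4 refits (kappa1, kappa2, theta)
    together with c3 on the combined-treatment well, with (rho, K, c0)
    frozen — the killing, proliferation/exhaustion and death rates are
    allowed to differ between the Dex-free and Dex-treated conditions.

    A missing condition skips the dependent stage (recorded in
    ``skipped``).  Later stages reuse a seed derived from ``seed`` so the
    whole protocol is reproducible from one integer.
    """
    bounds = bounds or ParameterBounds()
    stages: Dict[str, FitResult] = {}
    skipped: List[str] = []

    def stage_kwargs(dim: int) -> Dict[str, object]:
        # the swarm budget scales with stage dimensionality; the given
        # pso_particles/pso_iters are spent on the hardest (5-d) stage
        return dict(
            bounds=bounds,
            pso_particles=max(15, round(pso_particles * dim / 5)),
            pso_iters=max(25, round(pso_iters * dim / 5)),
        )

    rho, K = 1.0, 5.0
    if tumor_only is not None:
        base1 = ModelParameters(rho=1.0, K=5.0, kappa1=0.0, kappa2=0.0, theta=0.0,
                                sigma=sigma, D0=0.0)
        stages["tumor_growth"] = fit_condition(
            tumor_only, ("rho", "K", "x0"), base1, seed=seed, **stage_kwargs(3)
        )
        rho, K = stages["tumor_growth"].estimates.rho, stages["tumor_growth"].estimates.K
    else:
        skipped.append("tumor_growth")

    c0 = 0.0
    if tumor_dex is not None and tumor_only is not None:
        base2 = ModelParameters(rho=rho, K=K, kappa1=0.0, kappa2=0.0, theta=0.0,
                                sigma=sigma, D0=tumor_dex.d0)
        stages["dex_on_tumor"] = fit_condition(
            tumor_dex, ("c0", "x0"), base2, seed=seed + 1, **stage_kwargs(2)
        )
        c0 = stages["dex_on_tumor"].estimates.c0
    else:
        skipped.append("dex_on_tumor")

    params_no_dex = None
    if cart_only is not None and tumor_only is not None:
        base3 = ModelParameters(rho=rho, K=K, kappa1=1.0, kappa2=0.5, theta=0.1,
                                sigma=sigma, D0=0.0)
        stages["cart_kinetics"] = fit_condition(
            cart_only, ("kappa1", "kappa2", "theta", "x0"), base3, seed=seed + 2,
            **stage_kwargs(4)
        )
        est3 = stages["cart_kinetics"].estimates
        params_no_dex = ModelParameters(
            rho=rho, K=K, kappa1=est3.kappa1, kappa2=est3.kappa2, theta=est3.theta,
            c0=0.0, c3=0.0, sigma=sigma, D0=0.0,
        )
    else:
        skipped.append("cart_kinetics")

    params_dex = None
    if cart_dex is not None and tumor_only is not None:
        base4 = ModelParameters(rho=rho, K=K, kappa1=1.0, kappa2=0.5, theta=0.1,
                                c0=c0, c3=0.0, sigma=sigma, D0=cart_dex.d0)
        # warm-start the swarm at the Dex-free CAR T kinetics (c3 = 0):
        # the Dex condition is expected in the same region of parameter space
        init4 = None
        if params_no_dex is not None:
            init4 = np.array(
                [[params_no_dex.kappa1, params_no_dex.kappa2, params_no_dex.theta,
                  0.0, cart_dex.x0]]
            )
        stages["dex_on_cart"] = fit_condition(
            cart_dex, ("kappa1", "kappa2", "theta", "c3", "x0"), base4, seed=seed + 3,
            init=init4, **stage_kwargs(5)
        )
        est4 = stages["dex_on_cart"].estimates
        params_dex = ModelParameters(
            rho=rho, K=K, kappa1=est4.kappa1, kappa2=est4.kappa2, theta=est4.theta,
            c0=c0, c3=est4.c3, sigma=sigma, D0=cart_dex.d0,
        )
    else:
        skipped.append("dex_on_cart")

    return StagedFitResult(stages, params_no_dex, params_dex, skipped, seed)
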