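"""Synthetic impedance-assay (cell index) data generation.

Emulates the layout and statistical structure of an xCELLigence cell
killing experiment: a grid of patient-derived glioblastoma lines, CAR
T-cell effector-to-target (E:T) ratios and initial dexamethasone doses,
with the tumor cell index sampled every 15 minutes over 6-8 days and the
non-adherent CAR T-cells observed only at treatment start and assay end.
Treatment occurs 24 h after plating; pre-treatment growth is simulated so
the tumor population at treatment reflects a day of drug-free logistic
expansion from the seeding density (10-20k cells, i.e. 1-2 CI).

Every generated study carries its generating parameters so the estimation
pipeline can be validated by parameter recovery without any downloads.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .estimation import AssayDataset
from .model import ModelParameters
from .simulate import logistic_solution, simulate

__all__ = [
    "ExperimentDesign",
    "NoiseModel",
    "SyntheticStudy",
    "default_condition_truth",
    "generate_dataset",
    "downsample",
    "write_dataset",
    "read_dataset",
    "DatasetFormatError",
]

HOURS_PER_DAY = 24.0
#: Condition key: (cell_line, et_ratio or None, D0, has_cart)
ConditionKey = Tuple[str, Optional[str], float, bool]


@dataclass(frozen=True)
class ExperimentDesign:
    """The experimental grid and sampling scheme of the assay."""

    cell_lines: Tuple[str, ...] = ("SYN1",)
    seeding_ci_range: Tuple[float, float] = (1.0, 2.0)  # 10k-20k cells
    et_ratios: Tuple[str, ...] = ("1:4", "1:8", "1:20")
    dex_concentrations: Tuple[float, ...] = (0.0, 1e-4, 1e-3, 1e-2, 1e-1, 1.0)
    sampling_interval_hr: float = 0.25  # one reading per 15 minutes
    duration_hr: float = 144.0
    replicates: int = 2
    lead_time_hr: float = 24.0  # plating-to-treatment interval

    def __post_init__(self) -> None:
        if self.duration_hr <= 0 or self.sampling_interval_hr <= 0 or self.lead_time_hr < 0:
            raise ValueError("durations must be positive")
        if self.replicates < 1:
            raise ValueError("at least one replicate is required")
        if not (self.cell_lines and self.dex_concentrations):
            raise ValueError("design grid must be non-empty")
        if any(d < 0 for d in self.dex_concentrations):
            raise ValueError("Dex concentrations must be non-negative")

    @property
    def times_days(self) -> np.ndarray:
        """Post-treatment tumor sampling grid in days (t=0 at treatment)."""
        n = int(round(self.duration_hr / self.sampling_interval_hr))
        return np.arange(n + 1) * self.sampling_interval_hr / HOURS_PER_DAY


@dataclass(frozen=True)
class NoiseModel:
    """Measurement noise applied independently per well and time point."""

    kind: str = "multiplicative_lognormal"  # none | multiplicative_lognormal | additive_gaussian
    cv: float = 0.05
    floor_ci: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "multiplicative_lognormal", "additive_gaussian"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.cv < 0:
            raise ValueError("coefficient of variation must be non-negative")

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if self.kind == "none" or self.cv == 0:
            out = values.copy()
        elif self.kind == "multiplicative_lognormal":
            # unit-mean lognormal factor with the requested CV
            s = np.sqrt(np.log1p(self.cv**2))
            out = values * rng.lognormal(-0.5 * s * s, s, size=values.shape)
        else:
            out = values + rng.normal(0.0, self.cv, size=values.shape) * np.maximum(values, 1.0)
        return np.maximum(out, self.floor_ci)


def _et_fraction(et_ratio: str) -> float:
    effector, target = et_ratio.split(":")
    return float(effector) / float(target)


def default_condition_truth(et_ratio: Optional[str], d0: float) -> ModelParameters:
    """Default generating parameters for one condition.

    A single synthetic cell line with logistic growth (rho = 0.8 /day,
    K = 5 CI, so untreated wells are still expanding through most of the
    6-day observation window) and a drug response that mirrors the
    qualitative biology:
    Dex is mildly pro-proliferative to the tumor (c0 < 0, scaling with
    dose), while its effect on the CAR T-cells switches regime with dose.
    At low doses (D0 <= 0.01 ug/ml) the CAR T compartment is effective
    (theta/kappa2 = 0.2 CI, c3 > 0: transient extra death with high
    turnover).  At high doses (D0 >= 0.1 ug/ml) the cells are exhausted:
    weaker killing, higher death, lower antigen-driven proliferation
    (theta/kappa2 = 0.875 CI) and c3 < -theta, which transiently
    destabilizes coexistence until the drug clears about two half-lives
    in (a Hopf bifurcation in time, near 7 h post-treatment).
    """
    rho, K, kappa1 = 0.8, 5.0, 5.0
    c0 = -2.0 * d0  # rescaled constant grows with dose
    if d0 < 0.05:  # effective regime
        kappa2, theta = 1.0, 0.2
        c3 = 2.0 * d0
    else:  # exhausted regime
        kappa1, kappa2, theta = 2.5, 0.8, 0.7
        c3 = -3.0
    if et_ratio is None:
        kappa1 = kappa2 = theta = c3 = 0.0
    return ModelParameters(rho=rho, K=K, kappa1=kappa1, kappa2=kappa2,
                           theta=theta, c0=c0, c3=c3, D0=d0)


@dataclass
class SyntheticStudy:
    """Generated conditions (duplicate-averaged), raw wells, and truth."""

    conditions: List[AssayDataset]
    wells: List[AssayDataset]
    truth: Dict[ConditionKey, ModelParameters]
    design: ExperimentDesign
    noise: NoiseModel
    seed: int

    def condition(self, cell_line: str, et_ratio: Optional[str], d0: float) -> AssayDataset:
        for ds in self.conditions:
            if ds.cell_line == cell_line and ds.et_ratio == et_ratio and ds.d0 == d0:
                return ds
        raise KeyError(f"no condition ({cell_line}, {et_ratio}, {d0})")

    def staged_quartet(
        self, cell_line: str, et_ratio: str, d0: float
    ) -> Tuple[AssayDataset, AssayDataset, AssayDataset, AssayDataset]:
        """The four condition types feeding the staged fit for one
        (cell line, E:T, dose) choice: untreated, Dex-only, CAR T-only,
        and combined treatment."""
        return (
            self.condition(cell_line, None, 0.0),
            self.condition(cell_line, None, d0),
            self.condition(cell_line, et_ratio, 0.0),
            self.condition(cell_line, et_ratio, d0),
        )


def _simulate_condition(
    params: ModelParameters,
    x_treat: float,
    et_ratio: Optional[str],
    times: np.ndarray,
) -> Tuple[np.ndarray, Optional[np.ndarray], float]:
    y0 = x_treat * _et_fraction(et_ratio) if et_ratio is not None else 0.0
    traj = simulate(params, x_treat, y0, times)
    y_series = traj.y if et_ratio is not None else None
    return traj.x, y_series, y0


def generate_dataset(
    design: ExperimentDesign = ExperimentDesign(),
    truth: Optional[Callable[[Optional[str], float], ModelParameters]] = None,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
) -> SyntheticStudy:
    """Generate a full synthetic study over the design grid.

    For every cell line the grid covers tumor-only wells at each Dex dose
    and combined tumor + CAR T wells at each (E:T, dose) pair.  Each
    condition is seeded from the design's plating density, grown drug-free
    for the lead time, then treated at t=0 and sampled on the design grid;
    noise is drawn independently per replicate and the replicates averaged
    into the condition-level dataset (the raw wells are kept too).

    Returns the study together with the generating parameters per
    condition, keyed by ``(cell_line, et_ratio, d0, has_cart)``.
    """
    truth_fn = truth or default_condition_truth
    rng = np.random.default_rng(seed)
    times = design.times_days
    lead_days = design.lead_time_hr / HOURS_PER_DAY
    conditions: List[AssayDataset] = []
    wells: List[AssayDataset] = []
    truth_map: Dict[ConditionKey, ModelParameters] = {}

    grid: List[Optional[str]] = [None] + list(design.et_ratios)
    for cell_line in design.cell_lines:
        for et_ratio in grid:
            for d0 in design.dex_concentrations:
                params = truth_fn(et_ratio, d0)
                if params.D0 != d0:
                    raise ValueError(
                        f"truth for condition d0={d0} has mismatched D0={params.D0}"
                    )
                lo, hi = design.seeding_ci_range
                x_seed = rng.uniform(lo, hi)
                x_treat = float(
                    logistic_solution(params.rho, params.K, x_seed, lead_days)
                )
                x_true, y_true, y0 = _simulate_condition(params, x_treat, et_ratio, times)
                rep_tumor = []
                rep_cart = []
                for rep in range(design.replicates):
                    tumor_obs = noise.apply(x_true, rng)
                    cart_times = cart_obs = None
                    if et_ratio is not None:
                        y_final = noise.apply(np.array([y_true[-1]]), rng)[0]
                        cart_times = np.array([times[0], times[-1]])
                        cart_obs = np.array([y0, y_final])
                        rep_cart.append(cart_obs)
                    rep_tumor.append(tumor_obs)
                    wells.append(
                        AssayDataset(cell_line, et_ratio, d0, times, tumor_obs,
                                     cart_times, cart_obs, well_id=f"w{rep + 1}")
                    )
                tumor_avg = np.mean(rep_tumor, axis=0)
                cart_times_avg = cart_avg = None
                if et_ratio is not None:
                    cart_times_avg = np.array([times[0], times[-1]])
                    cart_avg = np.mean(rep_cart, axis=0)
                conditions.append(
                    AssayDataset(cell_line, et_ratio, d0, times, tumor_avg,
                                 cart_times_avg, cart_avg, well_id="avg")
                )
                truth_map[(cell_line, et_ratio, d0, et_ratio is not None)] = params
    return SyntheticStudy(conditions, wells, truth_map, design, noise, seed)


def downsample(dataset: AssayDataset, factor: int) -> AssayDataset:
    """Keep every ``factor``-th tumor point (first point always kept);
    CAR T endpoints are untouched."""
    if int(factor) != factor or factor < 1:
        raise ValueError("factor must be a positive integer")
    factor = int(factor)
    return AssayDataset(
        dataset.cell_line, dataset.et_ratio, dataset.d0,
        dataset.times[::factor], dataset.tumor_ci[::factor],
        None if dataset.cart_times is None else dataset.cart_times.copy(),
        None if dataset.cart_ci is None else dataset.cart_ci.copy(),
        well_id=dataset.well_id,
    )


class DatasetFormatError(ValueError):
    """Malformed dataset file; message names the offending row."""


_COLUMNS = ["cell_line", "et_ratio", "dex0_ugml", "well_id", "species", "time_hr", "cell_index"]


def write_dataset(datasets: Iterable[AssayDataset], path) -> None:
    """Write datasets in the long CSV schema (time in hours)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_COLUMNS)
        for ds in datasets:
            meta = [ds.cell_line, ds.et_ratio or "", repr(float(ds.d0)), ds.well_id]
            for t, ci in zip(ds.times, ds.tumor_ci):
                writer.writerow(meta + ["tumor", repr(float(t) * HOURS_PER_DAY), repr(float(ci))])
            if ds.has_cart:
                for t, ci in zip(ds.cart_times, ds.cart_ci):
                    writer.writerow(meta + ["cart", repr(float(t) * HOURS_PER_DAY), repr(float(ci))])


def read_dataset(path) -> List[AssayDataset]:
    """Read the long CSV schema back into datasets (lossless round trip)."""
    groups: Dict[Tuple[str, Optional[str], float, str], Dict[str, list]] = {}
    order: List[Tuple[str, Optional[str], float, str]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != _COLUMNS:
            raise DatasetFormatError(f"unexpected header {header!r}")
        for i, row in enumerate(reader, start=2):
            if len(row) != len(_COLUMNS):
                raise DatasetFormatError(f"row {i}: expected {len(_COLUMNS)} fields, got {len(row)}")
            cell_line, et_raw, d0_raw, well_id, species, t_raw, ci_raw = row
            try:
                d0, t_hr, ci = float(d0_raw), float(t_raw), float(ci_raw)
            except ValueError as exc:
                raise DatasetFormatError(f"row {i}: non-numeric field ({exc})") from None
            if ci < 0:
                raise DatasetFormatError(f"row {i}: negative cell index {ci}")
            if species not in ("tumor", "cart"):
                raise DatasetFormatError(f"row {i}: unknown species {species!r}")
            key = (cell_line, et_raw or None, d0, well_id)
            if key not in groups:
                groups[key] = {"tumor_t": [], "tumor_ci": [], "cart_t": [], "cart_ci": []}
                order.append(key)
            groups[key][f"{species}_t"].append(t_hr / HOURS_PER_DAY)
            groups[key][f"{species}_ci"].append(ci)
    datasets = []
    for key in order:
        cell_line, et_ratio, d0, well_id = key
        g = groups[key]
        cart_t = np.array(g["cart_t"]) if g["cart_t"] else None
        cart_ci = np.array(g["cart_ci"]) if g["cart_ci"] else None
        datasets.append(
            AssayDataset(cell_line, et_ratio, d0, np.array(g["tumor_t"]),
                         np.array(g["tumor_ci"]), cart_t, cart_ci, well_id=well_id)
        )
    return datasets
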