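"""Treatment success/failure classification from fitted parameters.

After the drug has cleared, the tumor coordinate of the coexistence
equilibrium is the ratio of the CAR T-cell death rate to the CAR T-cell
proliferation/exhaustion rate, ``theta / kappa2`` (in CI).  Conditions
whose ratio falls below a threshold are predicted to end in tumor death
(after possible pseudo-progression); above it, in tumor progression.  The
threshold itself can be estimated from a collection of fitted conditions
with observed outcomes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import ModelParameters

__all__ = [
    "OutcomeRecord",
    "ThresholdEstimate",
    "equilibrium_ratio",
    "classify",
    "estimate_threshold",
    "records_to_dataframe",
]

#: Threshold reported for the assay system studied here, CI units.
DEFAULT_THRESHOLD_CI = 0.4


def equilibrium_ratio(params: ModelParameters) -> float:
    """Predicted post-clearance equilibrium tumor burden ``theta/kappa2`` (CI).

    Uses the asymptotic (drug-free) values: the transient ``theta(t)`` has
    relaxed to ``theta`` once the drug has cleared.
    """
    if params.kappa2 == 0:
        raise ValueError("kappa2 must be positive")
    return params.theta / params.kappa2


def classify(ratio: float, threshold: float = DEFAULT_THRESHOLD_CI) -> str:
    """Predict the outcome of one condition from its equilibrium ratio.

    Returns ``"death"`` for ratios strictly below the threshold,
    ``"progression"`` strictly above, and ``"indeterminate"`` on the
    boundary.
    """
    if ratio < 0 or threshold < 0:
        raise ValueError("ratio and threshold must be non-negative")
    if ratio < threshold:
        return "death"
    if ratio > threshold:
        return "progression"
    return "indeterminate"


@dataclass(frozen=True)
class OutcomeRecord:
    """One condition's ratio, observed outcome, and optional metadata."""

    ratio: float  # theta/kappa2, CI
    observed: str  # "death" | "progression"
    cell_line: str = ""
    et_ratio: Optional[str] = None
    d0: float = 0.0

    def __post_init__(self) -> None:
        if self.ratio < 0:
            raise ValueError("ratio must be non-negative")
        if self.observed not in ("death", "progression"):
            raise ValueError(f"unknown outcome {self.observed!r}")

    def predicted(self, threshold: float = DEFAULT_THRESHOLD_CI) -> str:
        return classify(self.ratio, threshold)


@dataclass(frozen=True)
class ThresholdEstimate:
    """Separating threshold with a separability report."""

    threshold: float  # CI
    separable: bool
    n_misclassified: int
    gap: Optional[tuple] = None  # (max death ratio, min progression ratio) when separable


def estimate_threshold(records: Sequence[OutcomeRecord]) -> ThresholdEstimate:
    """Estimate the outcome-separating threshold from labelled conditions.

    When the death-outcome ratios all lie below the progression-outcome
    ratios the sets are perfectly separable and the midpoint of the
    separating gap is returned.  Otherwise an exhaustive scan over
    candidate cut points returns the threshold minimizing the number of
    misclassifications (ties resolved toward the lower threshold).
    """
    deaths = np.array([r.ratio for r in records if r.observed == "death"])
    progs = np.array([r.ratio for r in records if r.observed == "progression"])
    if deaths.size == 0 or progs.size == 0:
        raise ValueError("need at least one record of each observed outcome")
    hi_death, lo_prog = float(deaths.max()), float(progs.min())
    if hi_death < lo_prog:
        return ThresholdEstimate(
            threshold=0.5 * (hi_death + lo_prog),
            separable=True,
            n_misclassified=0,
            gap=(hi_death, lo_prog),
        )
    ratios = np.concatenate([deaths, progs])
    # candidate cuts: midpoints between adjacent distinct ratios plus the ends
    uniq = np.unique(ratios)
    candidates = np.concatenate([[uniq[0] - 1e-12], 0.5 * (uniq[:-1] + uniq[1:]), [uniq[-1] + 1e-12]])
    candidates = np.maximum(candidates, 0.0)
    best_t, best_err = None, None
    for cut in candidates:
        err = int(np.sum(deaths >= cut) + np.sum(progs < cut))
        if best_err is None or err < best_err or (err == best_err and cut < best_t):
            best_t, best_err = float(cut), err
    return ThresholdEstimate(threshold=best_t, separable=False, n_misclassified=best_err)


def records_to_dataframe(
    records: Sequence[OutcomeRecord], threshold: float = DEFAULT_THRESHOLD_CI
) -> pd.DataFrame:
    """Tabulate records with predictions at ``threshold`` for export."""
    return pd.DataFrame(
        {
            "cell_line": [r.cell_line for r in records],
            "et_ratio": [r.et_ratio for r in records],
            "dex0_ugml": [r.d0 for r in records],
            "ratio_ci": [r.ratio for r in records],
            "observed": [r.observed for r in records],
            "predicted": [r.predicted(threshold) for r in records],
            "threshold_ci": threshold,
        }
    )
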