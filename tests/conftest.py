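import numpy as np
import pytest

from carrgodex import (
    ExperimentDesign,
    ModelParameters,
    NoiseModel,
    generate_dataset,
)


@pytest.fixture(scope="session")
def coexistence_params() -> ModelParameters:
    """Symmetric parameters whose coexistence point is (0.5, 0.5)."""
    return ModelParameters(rho=1.0, K=1.0, kappa1=1.0, kappa2=1.0, theta=0.5)


@pytest.fixture(scope="session")
def dex_params() -> ModelParameters:
    """Exhausted-regime parameters: transiently unstable (c3 < -theta)."""
    return ModelParameters(
        rho=0.8, K=5.0, kappa1=2.5, kappa2=0.8, theta=0.7,
        c0=-0.2, c3=-3.0, sigma=5.0, D0=0.1,
    )


@pytest.fixture(scope="session")
def small_design() -> ExperimentDesign:
    """Reduced grid for fast pipeline tests: one E:T ratio, two doses,
    hourly sampling over four days."""
    return ExperimentDesign(
        cell_lines=("SYN1",),
        et_ratios=("1:4",),
        dex_concentrations=(0.0, 0.1),
        sampling_interval_hr=1.0,
        duration_hr=96.0,
        replicates=2,
    )


@pytest.fixture(scope="session")
def clean_study(small_design):
    """Noise-free reduced study with its generating parameters."""
    return generate_dataset(small_design, noise=NoiseModel(kind="none"), seed=42)


def random_table_params(rng: np.random.Generator, interior: bool = False) -> ModelParameters:
    """Draw parameters from the observed fitting ranges.

    ``interior=True`` additionally enforces an admissible coexistence point
    (theta < kappa2 * K) and rho(t) > 0 at all times.
    """
    while True:
        p = ModelParameters(
            rho=rng.uniform(0.5, 12.0),
            K=rng.uniform(1.0, 20.0),
            kappa1=rng.uniform(0.8, 90.0),
            kappa2=rng.uniform(0.1, 2.0),
            theta=rng.uniform(1e-6, 3.0),
            c0=rng.uniform(-10.0, 4.0),
            c3=rng.uniform(-11.0, 11.0),
            sigma=5.0,
            D0=rng.uniform(1e-4, 1.0),
        )
        if not interior:
            return p
        if p.theta < p.kappa2 * p.K and p.rho > p.c0:
            return p
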