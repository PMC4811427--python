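import numpy as np
import pytest

from previnc import AgeTimeGrid, RateModel, run_validation, simulate_prevalence


@pytest.fixture(scope="session")
def danish_validation():
    """The full trended simulate-then-estimate scenario, run once per session."""
    return run_validation(method="both")


def constant_rate_model(i=0.01, m0=0.02, m1=0.02):
    return RateModel(
        incidence=lambda t, a: np.full_like(np.asarray(a, dtype=float) + np.asarray(t, dtype=float), i),
        mortality_healthy=lambda t, a: np.full_like(np.asarray(a, dtype=float) + np.asarray(t, dtype=float), m0),
        mortality_ill=lambda t, a: np.full_like(np.asarray(a, dtype=float) + np.asarray(t, dtype=float), m1),
        reference_time=2000.0,
    )


@pytest.fixture(scope="session")
def constant_rate_surface():
    """Constant i = 0.01, m1 = m0, p0 = 0: p(t, a) = 1 - exp(-i (a - 30)) exactly."""
    grid = AgeTimeGrid.regular(2000, 2010, 30, 60, step=1.0, integration_substep=0.1)
    model = constant_rate_model()
    p0 = 1.0 - np.exp(-0.01 * (grid.ages - 30.0))  # stationary profile of the constant-rate model
    return model, grid, simulate_prevalence(model, p0, grid)
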