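import numpy as np
import pytest

from capca import LexisGrid, StratumData
from capca.design import build_design


@pytest.fixture
def small_grid() -> LexisGrid:
    return LexisGrid(A=5, P=4, age_start=30, period_start=1990, width=5)


@pytest.fixture
def constant_stratum(small_grid):
    """Noiseless constant-hazard table: rate 2e-4, 1e5 person-years/cell."""
    T = np.full((small_grid.A, small_grid.P), 1e5)
    return StratumData("const", 2e-4 * T, T)


@pytest.fixture
def drift_stratum(small_grid):
    """Noiseless pure-drift table: log-rate linear in cohort index."""
    _, _, c = small_grid.cell_indices()
    cbar = (small_grid.C + 1) / 2
    eta = np.log(2e-4) + 0.08 * (c - cbar)
    T = np.full(small_grid.A * small_grid.P, 1e5)
    counts = (np.exp(eta) * T).reshape(small_grid.A, small_grid.P)
    return StratumData("drift", counts, T.reshape(small_grid.A, small_grid.P))


def expected_counts(grid: LexisGrid, theta: np.ndarray, person_years: float = 1e5):
    """Noiseless expected counts from an identifiable parameter vector."""
    design = build_design(grid)
    eta = design.matrix @ theta
    T = np.full(grid.A * grid.P, person_years)
    return (np.exp(eta) * T).reshape(grid.A, grid.P), T.reshape(grid.A, grid.P)


def theta_from(grid, mu=0.0, tau_long=0.0, tau_drift=0.0, age_dev=None,
               period_dev=None, cohort_dev=None):
    design = build_design(grid)
    th = np.zeros(design.k)
    th[design.slices["intercept"]] = mu
    th[design.slices["age_slope"]] = tau_long
    th[design.slices["drift"]] = tau_drift
    for name, val in (("age_dev", age_dev), ("period_dev", period_dev),
                      ("cohort_dev", cohort_dev)):
        if val is not None:
            th[design.slices[name]] = val
    return th


@pytest.fixture
def noisy_stratum(small_grid):
    """Poisson-noised table from a fully structured truth."""
    rng = np.random.default_rng(7)
    th = theta_from(
        small_grid, mu=np.log(3e-4), tau_long=0.25, tau_drift=0.04,
        age_dev=rng.normal(0, 0.1, small_grid.A - 2),
        period_dev=rng.normal(0, 0.05, small_grid.P - 2),
        cohort_dev=rng.normal(0, 0.1, small_grid.C - 2),
    )
    mean, T = expected_counts(small_grid, th)
    return StratumData("noisy", rng.poisson(mean).astype(float), T), th
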