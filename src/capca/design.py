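"""Identifiable design matrix for the extended APC model.

The age-period-cohort linear predictor is over-parameterized because
cohort = period - age. The extended model resolves this by fitting an
intercept, a centered age-index linear term, and a centered cohort-index
linear term (the period linear term is dropped), plus *detrended*
deviation contrasts for each axis. Under this parameterization the age
coefficient is the longitudinal age trend and the cohort coefficient is
the net drift; both are estimable functions. The individual linear age,
period, and cohort effects are not estimable and are never reported.

Deviation contrasts are orthogonal-polynomial columns of degree >= 2,
explicitly orthogonalized against the constant and linear trend of their
own index, so every reconstructed deviation curve sums to zero and has
zero least-squares linear trend. Estimable functions are invariant to the
particular basis spanning this detrended complement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .errors import LexisValidationError
from .lexis import LexisGrid

BLOCKS = ("intercept", "age_slope", "drift", "age_dev", "period_dev", "cohort_dev")


def detrended_contrasts(L: int) -> np.ndarray:
    """Orthonormal basis (L x (L-2)) for detrended deviations on 1..L.

    Columns are orthonormal, and each is orthogonal to the constant and to
    the centered linear trend; together they span the full detrended
    complement. Built from a QR factorization of the polynomial Vandermonde
    matrix, dropping the constant and linear columns.
    """
    if L < 2:
        raise LexisValidationError(f"axis length must be >= 2, got {L}")
    x = np.arange(1, L + 1, dtype=float)
    V = np.vander(x - x.mean(), N=L, increasing=True)
    Q, R = np.linalg.qr(V)
    # fix signs for determinism
    Q = Q * np.sign(np.diag(R))
    return Q[:, 2:]


def block_sizes(A: int, P: int) -> dict[str, int]:
    C = A + P - 1
    return {
        "intercept": 1,
        "age_slope": 1,
        "drift": 1,
        "age_dev": A - 2,
        "period_dev": P - 2,
        "cohort_dev": C - 2,
    }


@dataclass(frozen=True)
class Design:
    """Single-stratum design matrix and its block structure.

    ``matrix`` has A*P rows (age-major cell order) and 2(A+P-2) columns:
    [1, a - abar, c - cbar, age contrasts, period contrasts, cohort
    contrasts]. ``basis_age/period/cohort`` map deviation coefficients to
    deviation curves. ``x_age/x_period/x_cohort`` are the centered index
    columns; x_period = x_age + x_cohort, which is what lets constrained
    multi-stratum models swap the cohort slope (net drift) column for a
    period column carrying the same coefficient.
    """

    grid: LexisGrid
    matrix: np.ndarray
    slices: dict[str, slice]
    basis_age: np.ndarray
    basis_period: np.ndarray
    basis_cohort: np.ndarray
    x_age: np.ndarray
    x_period: np.ndarray
    x_cohort: np.ndarray

    @property
    def k(self) -> int:
        return self.matrix.shape[1]

    def matrix_cross(self) -> np.ndarray:
        """Design with the cohort-slope column replaced by a period column.

        Reparameterizes the linear block from (longitudinal age trend, net
        drift) to (cross-sectional age trend, net drift); the two span the
        same column space and give identical fits.
        """
        X = self.matrix.copy()
        X[:, self.slices["drift"]] = self.x_period[:, None]
        return X


def build_design(
    grid: LexisGrid,
    basis_fn: Callable[[int], np.ndarray] = detrended_contrasts,
) -> Design:
    """Construct the full-rank extended-APC design for one stratum.

    ``basis_fn`` may supply any basis of the detrended complement (used in
    tests to confirm estimable functions do not depend on the choice).
    """
    A, P, C = grid.A, grid.P, grid.C
    a, p, c = grid.cell_indices()
    abar, pbar, cbar = (A + 1) / 2.0, (P + 1) / 2.0, (C + 1) / 2.0
    x_age = a - abar
    x_period = p - pbar
    x_cohort = c - cbar

    Ba = basis_fn(A)
    Bp = basis_fn(P)
    Bc = basis_fn(C)

    sizes = block_sizes(A, P)
    slices: dict[str, slice] = {}
    start = 0
    for name in BLOCKS:
        slices[name] = slice(start, start + sizes[name])
        start += sizes[name]

    X = np.zeros((A * P, start))
    X[:, slices["intercept"]] = 1.0
    X[:, slices["age_slope"]] = x_age[:, None]
    X[:, slices["drift"]] = x_cohort[:, None]
    X[:, slices["age_dev"]] = Ba[a - 1, :]
    X[:, slices["period_dev"]] = Bp[p - 1, :]
    X[:, slices["cohort_dev"]] = Bc[c - 1, :]
    return Design(
        grid=grid,
        matrix=X,
        slices=slices,
        basis_age=Ba,
        basis_period=Bp,
        basis_cohort=Bc,
        x_age=x_age,
        x_period=x_period,
        x_cohort=x_cohort,
    )
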