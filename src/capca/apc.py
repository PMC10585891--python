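"""Single-stratum extended APC model: Poisson fit and estimable functions.

The model for cell (a, p) with cohort c = p - a + A is

    log E[y] = log T + mu + tauL * (a - abar) + tauD * (c - cbar)
               + adev(a) + pdev(p) + cdev(c)

where T is person-years, ``tauL`` is the longitudinal age trend (per
interval), ``tauD`` is the net drift (per interval), and the deviation
curves are detrended (zero sum, zero linear trend). The cross-sectional
age trend is ``tauL - tauD``. All reported quantities are estimable
functions (EF): linear combinations of these parameters invariant to the
APC identifiability constraint. Delta-method covariances accompany every
curve; drifts are reported as annual percent change 100*(exp(b/width)-1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .design import Design, build_design, detrended_contrasts
from .errors import ConvergenceError, LexisValidationError
from .lexis import LexisGrid, StratumData

Z95 = float(stats.norm.ppf(0.975))


def default_ref(L: int) -> int:
    """Central 1-based reference index for an axis of length L."""
    return int(np.ceil((L + 1) / 2))


def _slope_weights(n: int) -> np.ndarray:
    """Least-squares slope weights for n equally spaced observations."""
    x = np.arange(n, dtype=float)
    x -= x.mean()
    return x / np.sum(x * x)


@dataclass(frozen=True)
class APCParameters:
    """Identifiable parameter vector of one extended APC model.

    ``tau_long`` and ``tau_drift`` are per-interval log-rate slopes; the
    cross-sectional age trend ``tau_cross = tau_long - tau_drift`` is
    derived, not stored. Deviation coefficients refer to the orthonormal
    detrended contrast basis of :func:`capca.design.detrended_contrasts`.
    """

    mu: float
    tau_long: float
    tau_drift: float
    age_dev: np.ndarray
    period_dev: np.ndarray
    cohort_dev: np.ndarray
    grid: LexisGrid

    @property
    def tau_cross(self) -> float:
        return self.tau_long - self.tau_drift

    def theta(self, design: Design | None = None) -> np.ndarray:
        d = design or build_design(self.grid)
        th = np.zeros(d.k)
        th[d.slices["intercept"]] = self.mu
        th[d.slices["age_slope"]] = self.tau_long
        th[d.slices["drift"]] = self.tau_drift
        th[d.slices["age_dev"]] = self.age_dev
        th[d.slices["period_dev"]] = self.period_dev
        th[d.slices["cohort_dev"]] = self.cohort_dev
        return th

    def deviation_curves(self, design: Design | None = None):
        d = design or build_design(self.grid)
        return (
            d.basis_age @ self.age_dev,
            d.basis_period @ self.period_dev,
            d.basis_cohort @ self.cohort_dev,
        )

    @staticmethod
    def from_theta(theta: np.ndarray, design: Design) -> "APCParameters":
        sl = design.slices
        return APCParameters(
            mu=float(theta[sl["intercept"]][0]),
            tau_long=float(theta[sl["age_slope"]][0]),
            tau_drift=float(theta[sl["drift"]][0]),
            age_dev=np.asarray(theta[sl["age_dev"]]),
            period_dev=np.asarray(theta[sl["period_dev"]]),
            cohort_dev=np.asarray(theta[sl["cohort_dev"]]),
            grid=design.grid,
        )


@dataclass(frozen=True)
class APCFit:
    """A converged single-stratum extended APC fit."""

    label: str
    grid: LexisGrid
    design: Design
    theta: np.ndarray
    covariance: np.ndarray
    loglik: float
    deviance: float
    fitted: np.ndarray  # A x P fitted counts
    observed: np.ndarray  # A x P observed counts

    @property
    def params(self) -> APCParameters:
        return APCParameters.from_theta(self.theta, self.design)

    @property
    def n_cells(self) -> int:
        return self.grid.A * self.grid.P

    @property
    def k(self) -> int:
        return self.design.k

    @property
    def df_resid(self) -> int:
        return self.n_cells - self.k

    @property
    def fitted_log_rates(self) -> np.ndarray:
        return (self.design.matrix @ self.theta).reshape(self.grid.A, self.grid.P)


@dataclass(frozen=True)
class EFCurve:
    """One estimable-function curve with its delta-method covariance.

    ``kind`` is "log-rate" (log of an expected rate), "log-ratio" (log of
    a rate ratio), "deviation" (detrended log-scale deviations), or
    "slope" (per-interval log-linear trend, reported as annual percent
    change via 100*(exp(b/width)-1)).
    """

    name: str
    x: np.ndarray
    estimate: np.ndarray
    cov: np.ndarray
    kind: str
    width: float = 1.0

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov), 0.0, None))

    @property
    def lo95(self) -> np.ndarray:
        return self.estimate - Z95 * self.se

    @property
    def hi95(self) -> np.ndarray:
        return self.estimate + Z95 * self.se

    def _pct(self, v: np.ndarray) -> np.ndarray:
        return 100.0 * np.expm1(v / self.width)

    @property
    def percent(self) -> np.ndarray:
        """Annual percent change (only meaningful for kind == 'slope')."""
        return self._pct(self.estimate)

    @property
    def percent_lo95(self) -> np.ndarray:
        return self._pct(self.lo95)

    @property
    def percent_hi95(self) -> np.ndarray:
        return self._pct(self.hi95)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "index": self.x,
                "estimate": self.estimate,
                "lo95": self.lo95,
                "hi95": self.hi95,
            }
        )
        if self.kind == "slope":
            df["percent"] = self.percent
            df["percent_lo95"] = self.percent_lo95
            df["percent_hi95"] = self.percent_hi95
        return df


def ef_operators(design: Design, a_ref: int, p_ref: int, c_ref: int) -> dict[str, np.ndarray]:
    """Linear operators mapping the parameter vector to each EF curve.

    Every estimable function here is a linear map L of the identifiable
    parameter vector; the delta method then gives Cov(curve) = L C L'.
    """
    grid = design.grid
    A, P, C = grid.A, grid.P, grid.C
    k = design.k
    sl = design.slices
    abar, pbar, cbar = (A + 1) / 2.0, (P + 1) / 2.0, (C + 1) / 2.0

    def unit(name: str) -> np.ndarray:
        row = np.zeros(k)
        row[sl[name]] = 1.0
        return row

    mu_r, tl_r, td_r = unit("intercept"), unit("age_slope"), unit("drift")
    Da = np.zeros((A, k))
    Da[:, sl["age_dev"]] = design.basis_age
    Dp = np.zeros((P, k))
    Dp[:, sl["period_dev"]] = design.basis_period
    Dc = np.zeros((C, k))
    Dc[:, sl["cohort_dev"]] = design.basis_cohort

    ages = np.arange(1, A + 1)
    periods = np.arange(1, P + 1)
    cohorts = np.arange(1, C + 1)
    tx_r = tl_r - td_r  # cross-sectional age trend

    # Longitudinal age curve: fitted rates along the reference cohort,
    # adjusted for period deviations.
    long_age = (
        mu_r
        + (c_ref - cbar) * td_r
        + Dc[c_ref - 1]
        + (ages - abar)[:, None] * tl_r
        + Da
    )
    # Cross-sectional age curve: fitted rates in the reference period,
    # adjusted for cohort deviations.
    cross_age = (
        mu_r
        + (p_ref - pbar) * td_r
        + Dp[p_ref - 1]
        + (ages - abar)[:, None] * tx_r
        + Da
    )
    # Fitted temporal trend: rates over period at the reference age,
    # adjusted for cohort deviations.
    ftt = (
        mu_r
        + (a_ref - abar) * tx_r
        + Da[a_ref - 1]
        + (periods - pbar)[:, None] * td_r
        + Dp
    )
    # Fitted cohort pattern: rates over cohort at the reference age,
    # adjusted for period deviations.
    fcp = (
        mu_r
        + (a_ref - abar) * tl_r
        + Da[a_ref - 1]
        + (cohorts - cbar)[:, None] * td_r
        + Dc
    )

    # Local drifts: net drift plus the least-squares slope of the width-P
    # window of cohort deviations observed at each age.
    w_p = _slope_weights(P)
    LD = np.tile(td_r, (A, 1))
    for a in ages:
        start = A - a  # 0-based first cohort row in the window
        LD[a - 1] += w_p @ Dc[start : start + P]

    # Gradient shifts: cross-sectional age trend plus the least-squares
    # slope (with respect to age) of the cohort deviations cross-secting
    # each period; cohort decreases as age increases at fixed period.
    w_a = _slope_weights(A)
    GS = np.tile(tx_r, (P, 1))
    for p in periods:
        rows = np.array([p - a + A - 1 for a in ages])  # 0-based cohort rows
        GS[p - 1] += w_a @ Dc[rows]

    return {
        "long_age": long_age,
        "cross_age": cross_age,
        "ftt": ftt,
        "fcp": fcp,
        "crr": fcp - fcp[c_ref - 1],
        "prr": ftt - ftt[p_ref - 1],
        "carr": cross_age - cross_age[a_ref - 1],
        "larr": long_age - long_age[a_ref - 1],
        "net_drift": td_r[None, :],
        "local_drifts": LD,
        "gradient_shifts": GS,
        "age_deviations": Da,
        "period_deviations": Dp,
        "cohort_deviations": Dc,
    }


_CURVE_META = {
    # name -> (axis, kind)
    "long_age": ("age", "log-rate"),
    "cross_age": ("age", "log-rate"),
    "ftt": ("period", "log-rate"),
    "fcp": ("cohort", "log-rate"),
    "crr": ("cohort", "log-ratio"),
    "prr": ("period", "log-ratio"),
    "carr": ("age", "log-ratio"),
    "larr": ("age", "log-ratio"),
    "net_drift": ("scalar", "slope"),
    "local_drifts": ("age", "slope"),
    "gradient_shifts": ("period", "slope"),
    "age_deviations": ("age", "deviation"),
    "period_deviations": ("period", "deviation"),
    "cohort_deviations": ("cohort", "deviation"),
}


@dataclass(frozen=True)
class EstimableFunctions:
    """The named EF curves of one stratum, on the log scale, with refs.

    Rate curves are per person-year on the log scale; multiply by 1e5
    after exponentiating for rates per 100,000.
    """

    label: str
    grid: LexisGrid
    refs: tuple[int, int, int]  # (a_ref, p_ref, c_ref), 1-based
    curves: dict[str, EFCurve]

    def __getitem__(self, name: str) -> EFCurve:
        return self.curves[name]

    @property
    def net_drift(self) -> EFCurve:
        return self.curves["net_drift"]

    @property
    def local_drifts(self) -> EFCurve:
        return self.curves["local_drifts"]

    @property
    def gradient_shifts(self) -> EFCurve:
        return self.curves["gradient_shifts"]

    def reconstruct(self, which: str = "a|c") -> np.ndarray:
        """Rebuild the fitted log-rate surface from one EF decomposition.

        which: "a|c" LongAge x CRR x exp(pdev); "p|a" FTT x CARR x
        exp(cdev); "c|a" FCP x LARR x exp(pdev); "a|p" CrossAge x PRR x
        exp(cdev). All four reproduce the fitted surface cellwise.
        """
        a, p, c = self.grid.cell_indices()
        cv = self.curves
        if which == "a|c":
            eta = (
                cv["long_age"].estimate[a - 1]
                + cv["crr"].estimate[c - 1]
                + cv["period_deviations"].estimate[p - 1]
            )
        elif which == "p|a":
            eta = (
                cv["ftt"].estimate[p - 1]
                + cv["carr"].estimate[a - 1]
                + cv["cohort_deviations"].estimate[c - 1]
            )
        elif which == "c|a":
            eta = (
                cv["fcp"].estimate[c - 1]
                + cv["larr"].estimate[a - 1]
                + cv["period_deviations"].estimate[p - 1]
            )
        elif which == "a|p":
            eta = (
                cv["cross_age"].estimate[a - 1]
                + cv["prr"].estimate[p - 1]
                + cv["cohort_deviations"].estimate[c - 1]
            )
        else:
            raise ValueError(f"unknown decomposition {which!r}")
        return eta.reshape(self.grid.A, self.grid.P)

    def to_frames(self) -> dict[str, pd.DataFrame]:
        return {name: curve.to_frame() for name, curve in self.curves.items()}


def compute_ef(
    design: Design,
    theta: np.ndarray,
    cov: np.ndarray,
    label: str = "",
    a_ref: int | None = None,
    p_ref: int | None = None,
    c_ref: int | None = None,
) -> EstimableFunctions:
    """Estimable functions of a parameter vector with covariance ``cov``."""
    grid = design.grid
    a_ref = a_ref if a_ref is not None else default_ref(grid.A)
    p_ref = p_ref if p_ref is not None else default_ref(grid.P)
    c_ref = c_ref if c_ref is not None else default_ref(grid.C)
    for name, ref, L in (("a_ref", a_ref, grid.A), ("p_ref", p_ref, grid.P), ("c_ref", c_ref, grid.C)):
        if not (1 <= ref <= L):
            raise LexisValidationError(f"{name}={ref} outside 1..{L}")

    ops = ef_operators(design, a_ref, p_ref, c_ref)
    axes = {
        "age": grid.age_mids,
        "period": grid.period_mids,
        "cohort": grid.cohort_mids,
        "scalar": np.array([0.0]),
    }
    curves = {}
    for name, L in ops.items():
        axis, kind = _CURVE_META[name]
        curves[name] = EFCurve(
            name=name,
            x=axes[axis],
            estimate=L @ theta,
            cov=L @ cov @ L.T,
            kind=kind,
            width=grid.width,
        )
    return EstimableFunctions(
        label=label, grid=grid, refs=(a_ref, p_ref, c_ref), curves=curves
    )


def _fit_poisson(y: np.ndarray, X: np.ndarray, log_offset: np.ndarray, context: str):
    """Shared Poisson IRLS wrapper with convergence checks."""
    model = sm.GLM(y, X, family=sm.families.Poisson(), offset=log_offset)
    try:
        import warnings

        with warnings.catch_warnings():
            # noiseless expected-count tables fit perfectly; statsmodels
            # flags that as possible separation, which the finite-parameter
            # check below covers
            from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

            warnings.simplefilter("ignore", PerfectSeparationWarning)
            res = model.fit(maxiter=100, tol=1e-10)
    except (np.linalg.LinAlgError, ValueError) as exc:
        raise ConvergenceError(f"{context}: Poisson IRLS failed ({exc})") from exc
    if not getattr(res, "converged", True):
        raise ConvergenceError(f"{context}: IRLS did not converge in 100 iterations")
    if not np.all(np.isfinite(res.params)):
        raise ConvergenceError(
            f"{context}: non-finite parameter estimates (possible separation "
            "or empty rows)"
        )
    return res


def fit_apc(
    stratum: StratumData,
    grid: LexisGrid,
    basis_fn: Callable[[int], np.ndarray] = detrended_contrasts,
) -> APCFit:
    """Maximum-likelihood Poisson rate fit of the extended APC model.

    Uses a log person-years offset; the covariance is the inverse observed
    (= expected, canonical link) information at the MLE.
    """
    if stratum.counts.shape != (grid.A, grid.P):
        raise LexisValidationError(
            f"stratum {stratum.label!r} shape {stratum.counts.shape} does not "
            f"match grid ({grid.A}, {grid.P})"
        )
    if stratum.counts.sum() == 0:
        raise ConvergenceError(
            f"stratum {stratum.label!r}: all counts are zero; the log-rate "
            "model is degenerate"
        )
    design = build_design(grid, basis_fn=basis_fn)
    y = stratum.counts.ravel()
    log_T = np.log(stratum.offset.ravel())
    res = _fit_poisson(y, design.matrix, log_T, f"stratum {stratum.label!r}")
    return APCFit(
        label=stratum.label,
        grid=grid,
        design=design,
        theta=np.asarray(res.params),
        covariance=np.asarray(res.cov_params()),
        loglik=float(res.llf),
        deviance=float(res.deviance),
        fitted=np.asarray(res.fittedvalues).reshape(grid.A, grid.P),
        observed=stratum.counts.copy(),
    )


def estimable_functions(
    fit: APCFit,
    a_ref: int | None = None,
    p_ref: int | None = None,
    c_ref: int | None = None,
) -> EstimableFunctions:
    """All EF curves of a converged fit, with delta-method covariances."""
    return compute_ef(
        fit.design, fit.theta, fit.covariance, fit.label, a_ref, p_ref, c_ref
    )


def local_drifts(fit: APCFit, **refs) -> EFCurve:
    """Age-specific annual percent changes (net drift + window slopes)."""
    return estimable_functions(fit, **refs).local_drifts


def gradient_shifts(fit: APCFit, **refs) -> EFCurve:
    """Period-specific annual-percent-change-per-year-of-age gradients."""
    return estimable_functions(fit, **refs).gradient_shifts


@dataclass(frozen=True)
class LOFReport:
    """Lack-of-fit diagnostics; descriptive only, no remediation."""

    deviance_ratio: float
    pearson_dispersion: float
    n_large_residuals: int
    df_resid: int
    assessable: bool


def lack_of_fit(fit: APCFit, resid_threshold: float = 3.0) -> LOFReport:
    """Deviance/df, Pearson dispersion, and |standardized residual| > 3 count."""
    if fit.df_resid <= 0:
        return LOFReport(np.nan, np.nan, 0, fit.df_resid, assessable=False)
    mu = fit.fitted.ravel()
    y = fit.observed.ravel()
    pearson = (y - mu) / np.sqrt(mu)
    x2 = float(np.sum(pearson**2))
    return LOFReport(
        deviance_ratio=fit.deviance / fit.df_resid,
        pearson_dispersion=x2 / fit.df_resid,
        n_large_residuals=int(np.sum(np.abs(pearson) > resid_threshold)),
        df_resid=fit.df_resid,
        assessable=True,
    )
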