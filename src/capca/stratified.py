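"""Joint constrained APC models across strata.

Cross-stratum proportionality is encoded by *sharing* parameter blocks of
the extended APC model between strata in one stacked Poisson regression:

* N-PH   : nothing shared (equivalent to independent per-stratum fits);
* PH-L   : shared longitudinal age trend, age deviations, and period
           deviations -> cross-hazard rate ratios depend only on cohort;
* PH-T   : shared net drift, period deviations, and cohort deviations
           -> CH-RRs depend only on age;
* PH-X   : shared cross-sectional age trend, age deviations, and cohort
           deviations -> CH-RRs depend only on period;
* PH-A   : everything shared except intercepts -> constant CH-RRs;
* Par-LAC / Par-CAC / Par-FTT / Par-FCP : parallelism of a single named
           EF family (its shape block plus matching slope shared).

Each model is screened against N-PH by a likelihood-ratio test, and the
ensemble is ranked by the bias-corrected Akaike criterion (AICc), the
selection statistic recommended for small samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .apc import EstimableFunctions, APCParameters, _fit_poisson, compute_ef
from .design import BLOCKS, Design, block_sizes, build_design, detrended_contrasts
from .errors import CapcaError, LexisValidationError
from .lexis import LexisGrid, StratifiedLexis

SHAREABLE = ("age_slope", "drift", "age_dev", "period_dev", "cohort_dev")


@dataclass(frozen=True)
class ModelSpec:
    """Sharing map for one constrained multi-stratum model.

    ``shared`` lists the parameter blocks pooled across strata (the
    intercept is always per-stratum). ``linear`` chooses the linear-block
    parameterization: "long" fits (longitudinal age trend, net drift),
    "cross" fits (cross-sectional age trend, net drift); the spanned
    column space is identical, but sharing the first linear coefficient
    means sharing a different estimable trend in each case.
    """

    name: str
    shared: frozenset
    linear: str = "long"

    def __post_init__(self) -> None:
        bad = set(self.shared) - set(SHAREABLE)
        if bad:
            raise ValueError(f"unknown shareable blocks: {sorted(bad)}")
        if self.linear not in ("long", "cross"):
            raise ValueError(f"linear must be 'long' or 'cross', got {self.linear!r}")


def _spec(name: str, shared: Iterable[str], linear: str = "long") -> ModelSpec:
    return ModelSpec(name=name, shared=frozenset(shared), linear=linear)


MODEL_SPECS: dict[str, ModelSpec] = {
    s.name: s
    for s in (
        _spec("N-PH", ()),
        _spec("PH-L", ("age_slope", "age_dev", "period_dev")),
        _spec("PH-T", ("drift", "period_dev", "cohort_dev")),
        _spec("PH-X", ("age_slope", "age_dev", "cohort_dev"), linear="cross"),
        _spec("PH-A", SHAREABLE),
        _spec("Par-LAC", ("age_slope", "age_dev")),
        _spec("Par-CAC", ("age_slope", "age_dev"), linear="cross"),
        _spec("Par-FTT", ("drift", "period_dev")),
        _spec("Par-FCP", ("drift", "cohort_dev")),
    )
}

PH_SPECS = ("N-PH", "PH-L", "PH-T", "PH-X", "PH-A")


def model_df(spec: ModelSpec | str, G: int, A: int, P: int) -> int:
    """Free-parameter count of a sharing map on a G x A x P problem.

    Shared blocks contribute their size once; per-stratum blocks G times;
    intercepts are always per-stratum. At G = 1 every spec collapses to
    the single-stratum count 2(A+P-2).
    """
    if isinstance(spec, str):
        spec = MODEL_SPECS[spec]
    if G < 1 or A < 2 or P < 2:
        raise LexisValidationError(f"invalid dimensions G={G}, A={A}, P={P}")
    sizes = block_sizes(A, P)
    k = G * sizes["intercept"]
    for name in SHAREABLE:
        k += sizes[name] if name in spec.shared else G * sizes[name]
    return k


def aicc(loglik: float, k: int, n: int) -> float:
    """Bias-corrected Akaike criterion -2 loglik + 2k + 2k(k+1)/(n-k-1)."""
    if n - k - 1 <= 0:
        raise CapcaError(
            f"AICc undefined: n - k - 1 = {n - k - 1} (n={n}, k={k})"
        )
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


@dataclass(frozen=True)
class JointFit:
    """A fitted constrained multi-stratum APC model.

    ``param_maps[label]`` is the matrix M_g with theta_g = M_g beta, the
    per-stratum identifiable parameter vector (longitudinal
    parameterization) as a linear function of the joint free parameters;
    it carries shared-block aliasing and the cross->long reparameterization.
    """

    spec: ModelSpec
    labels: tuple[str, ...]
    grid: LexisGrid
    design: Design
    beta: np.ndarray
    covariance: np.ndarray
    loglik: float
    deviance: float
    param_maps: dict[str, np.ndarray]
    fitted: np.ndarray  # G x A x P fitted counts

    @property
    def G(self) -> int:
        return len(self.labels)

    @property
    def k(self) -> int:
        return self.beta.size

    @property
    def n(self) -> int:
        return self.G * self.grid.A * self.grid.P

    @property
    def aicc(self) -> float:
        try:
            return aicc(self.loglik, self.k, self.n)
        except CapcaError:
            return float("nan")

    def stratum_theta(self, label: str) -> np.ndarray:
        return self.param_maps[label] @ self.beta

    def stratum_params(self, label: str) -> APCParameters:
        return APCParameters.from_theta(self.stratum_theta(label), self.design)

    def stratum_covariance(self, label: str) -> np.ndarray:
        M = self.param_maps[label]
        return M @ self.covariance @ M.T

    def estimable_functions(self, label: str, **refs) -> EstimableFunctions:
        return compute_ef(
            self.design,
            self.stratum_theta(label),
            self.stratum_covariance(label),
            label,
            **refs,
        )

    def fitted_log_rates(self, label: str) -> np.ndarray:
        eta = self.design.matrix @ self.stratum_theta(label)
        return eta.reshape(self.grid.A, self.grid.P)


def _joint_layout(spec: ModelSpec, labels: Sequence[str], sizes: dict[str, int]):
    """Column layout: shared blocks first, then per-stratum blocks."""
    cols: dict[tuple[str, str | None], slice] = {}
    start = 0
    for name in SHAREABLE:
        if name in spec.shared:
            cols[(name, None)] = slice(start, start + sizes[name])
            start += sizes[name]
    for label in labels:
        for name in BLOCKS:
            if name == "intercept" or name not in spec.shared:
                cols[(name, label)] = slice(start, start + sizes[name])
                start += sizes[name]
    return cols, start


def fit_constrained(
    data: StratifiedLexis,
    spec: ModelSpec | str,
    basis_fn=detrended_contrasts,
) -> JointFit:
    """Fit one Poisson GLM on the stacked G*A*P cells under a sharing map."""
    if isinstance(spec, str):
        spec = MODEL_SPECS[spec]
    grid = data.grid
    labels = tuple(data.labels)
    design = build_design(grid, basis_fn=basis_fn)
    sizes = block_sizes(grid.A, grid.P)
    cols, k_joint = _joint_layout(spec, labels, sizes)

    Xbase = design.matrix if spec.linear == "long" else design.matrix_cross()
    n_cells = grid.A * grid.P
    X = np.zeros((len(labels) * n_cells, k_joint))
    y = np.empty(len(labels) * n_cells)
    log_T = np.empty_like(y)
    for g, s in enumerate(data.strata):
        rows = slice(g * n_cells, (g + 1) * n_cells)
        y[rows] = s.counts.ravel()
        log_T[rows] = np.log(s.offset.ravel())
        for name in BLOCKS:
            key = (name, None) if (name, None) in cols and name in spec.shared else (name, s.label)
            X[rows, cols[key]] = Xbase[:, design.slices[name]]

    res = _fit_poisson(y, X, log_T, f"model {spec.name}")
    beta = np.asarray(res.params)
    cov = np.asarray(res.cov_params())

    # per-stratum maps back to the longitudinal parameterization
    param_maps = {}
    for label in labels:
        M = np.zeros((design.k, k_joint))
        for name in BLOCKS:
            key = (name, None) if name in spec.shared else (name, label)
            src = cols[key]
            dst = design.slices[name]
            M[dst, src] = np.eye(sizes[name])
        if spec.linear == "cross":
            # joint age_slope coefficient is tau_cross; tau_long = tau_cross + tau_drift
            d_key = ("drift", None) if "drift" in spec.shared else ("drift", label)
            M[design.slices["age_slope"].start, cols[d_key].start] += 1.0
        param_maps[label] = M

    return JointFit(
        spec=spec,
        labels=labels,
        grid=grid,
        design=design,
        beta=beta,
        covariance=cov,
        loglik=float(res.llf),
        deviance=float(res.deviance),
        param_maps=param_maps,
        fitted=np.asarray(res.fittedvalues).reshape(len(labels), grid.A, grid.P),
    )


@dataclass(frozen=True)
class FittedRateRatio:
    """Model-implied CH-RR of stratum j over k, in its natural shape.

    ``kind`` is "scalar" (PH-A), "age" (PH-T), "period" (PH-X), "cohort"
    (PH-L) or "grid" (unconstrained shapes). Estimates are log CH-RRs with
    delta-method standard errors.
    """

    numerator_label: str
    denominator_label: str
    kind: str
    x: np.ndarray
    log_estimate: np.ndarray
    se: np.ndarray
    grid_shape: tuple[int, int] | None = None

    @property
    def estimate(self) -> np.ndarray:
        return np.exp(self.log_estimate)

    @property
    def lo95(self) -> np.ndarray:
        return np.exp(self.log_estimate - 1.959963984540054 * self.se)

    @property
    def hi95(self) -> np.ndarray:
        return np.exp(self.log_estimate + 1.959963984540054 * self.se)


_CHRR_SOURCE = {
    "PH-L": ("cohort", "fcp"),
    "PH-T": ("age", "cross_age"),
    "PH-X": ("period", "ftt"),
}


def fitted_ch_rr(fit: JointFit, j: str, k: str, **refs) -> FittedRateRatio:
    """Cross-hazard rate ratio implied by a joint fit, with uncertainty.

    The returned shape follows the model: a scalar under PH-A, an
    age-indexed curve under PH-T, a period curve under PH-X, a cohort
    curve under PH-L, and the full A x P grid otherwise.
    """
    if j == k:
        raise LexisValidationError("numerator and denominator strata must differ")
    for lab in (j, k):
        if lab not in fit.labels:
            raise KeyError(f"unknown stratum label {lab!r}; have {list(fit.labels)}")
    name = fit.spec.name
    Mdiff = fit.param_maps[j] - fit.param_maps[k]
    if name == "PH-A":
        d = Mdiff[fit.design.slices["intercept"].start][None, :]
        est = d @ fit.beta
        se = np.sqrt(np.einsum("ij,jk,ik->i", d, fit.covariance, d))
        return FittedRateRatio(j, k, "scalar", np.array([0.0]), est, se)
    if name in _CHRR_SOURCE:
        kind, curve = _CHRR_SOURCE[name]
        from .apc import default_ref, ef_operators

        grid = fit.grid
        a_ref = refs.get("a_ref") or default_ref(grid.A)
        p_ref = refs.get("p_ref") or default_ref(grid.P)
        c_ref = refs.get("c_ref") or default_ref(grid.C)
        L = ef_operators(fit.design, a_ref, p_ref, c_ref)[curve]
        D = L @ Mdiff
        est = D @ fit.beta
        se = np.sqrt(np.clip(np.einsum("ij,jk,ik->i", D, fit.covariance, D), 0, None))
        axis = {
            "age": grid.age_mids,
            "period": grid.period_mids,
            "cohort": grid.cohort_mids,
        }[kind]
        return FittedRateRatio(j, k, kind, axis, est, se)
    # unconstrained / parallelism models: full grid of log-rate differences
    D = fit.design.matrix @ Mdiff
    est = D @ fit.beta
    se = np.sqrt(np.clip(np.einsum("ij,jk,ik->i", D, fit.covariance, D), 0, None))
    return FittedRateRatio(
        j, k, "grid", np.arange(est.size), est, se, grid_shape=(fit.grid.A, fit.grid.P)
    )


@dataclass(frozen=True)
class ComparisonReport:
    """Nine-model comparison: likelihood-ratio screens and AICc ranking."""

    table: pd.DataFrame
    selected: str
    fits: dict[str, JointFit]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def composite_tests(
    data: StratifiedLexis,
    specs: Sequence[str] | None = None,
) -> ComparisonReport:
    """Fit all specs, test each against N-PH by LRT, and rank by AICc.

    P-values are descriptive screens (chi-square upper tail on the
    parameter-count difference); selection is driven by AICc alone.
    """
    if data.G < 2:
        raise LexisValidationError("model comparison requires at least two strata")
    names = list(specs) if specs is not None else list(MODEL_SPECS)
    if "N-PH" not in names:
        names = ["N-PH"] + names
    fits: dict[str, JointFit] = {}
    errors: dict[str, str] = {}
    for name in names:
        try:
            fits[name] = fit_constrained(data, name)
        except CapcaError as exc:
            errors[name] = str(exc)
    if "N-PH" not in fits:
        raise CapcaError(f"reference N-PH fit failed: {errors.get('N-PH')}")
    ll0 = fits["N-PH"].loglik
    k0 = fits["N-PH"].k

    rows = []
    for name in names:
        if name not in fits:
            rows.append(
                {"model": name, "loglik": np.nan, "k": np.nan, "deviance": np.nan,
                 "LRT": np.nan, "df": np.nan, "p_value": np.nan,
                 "neglog10p": np.nan, "aicc": np.nan, "error": errors[name]}
            )
            continue
        f = fits[name]
        if name == "N-PH":
            lrt = df = p = nlp = np.nan
        else:
            lrt = max(2.0 * (ll0 - f.loglik), 0.0)
            df = k0 - f.k
            p = float(stats.chi2.sf(lrt, df)) if df > 0 else np.nan
            nlp = -np.log10(p) if p > 0 else np.inf
        rows.append(
            {"model": name, "loglik": f.loglik, "k": f.k, "deviance": f.deviance,
             "LRT": lrt, "df": df, "p_value": p, "neglog10p": nlp,
             "aicc": f.aicc, "error": ""}
        )
    table = pd.DataFrame(rows)
    finite = table["aicc"].to_numpy(float)
    best = int(np.nanargmin(finite))
    table["delta_aicc"] = table["aicc"] - table.loc[best, "aicc"]
    table["selected"] = [i == best for i in range(len(table))]
    return ComparisonReport(table=table, selected=str(table.loc[best, "model"]), fits=fits)


def select_model(data: StratifiedLexis) -> ComparisonReport:
    """Rank all nine sharing maps by AICc; the argmin is the selection."""
    return composite_tests(data, specs=list(MODEL_SPECS))
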