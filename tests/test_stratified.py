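"""Constrained joint models: df accounting, structural theorems, selection."""

import numpy as np
import pytest

from capca import (
    CapcaError,
    LexisGrid,
    MODEL_SPECS,
    ModelSpec,
    StratifiedLexis,
    StratumData,
    aicc,
    composite_tests,
    cross_hazard_rr,
    fit_apc,
    fit_constrained,
    fitted_ch_rr,
    model_df,
    select_model,
)
from capca.stratified import _joint_layout
from capca.design import block_sizes
from capca.synthetic import ScenarioConfig, add_noise, make_scenario, preset

from conftest import expected_counts, theta_from


def pha_data(G=2, A=6, P=5, ratios=(1.0, 2.0), mu0=np.log(1e-4)):
    cfg = ScenarioConfig(
        A=A, P=P, labels=tuple(f"s{i}" for i in range(G)),
        mu=tuple(mu0 + np.log(r) for r in ratios),
        tau_long=0.3, tau_drift=0.04,
        age_dev=("quadratic", -0.4), cohort_dev=("sinusoid", 0.1),
        regime="PH-A", noise="none",
    )
    return make_scenario(cfg)[0]


class TestModelDF:
    @pytest.mark.parametrize(
        "name,G,A,P,expected",
        [
            ("N-PH", 2, 13, 10, 84),
            ("PH-A", 4, 6, 5, 21),
            ("PH-L", 2, 13, 10, (2 + 1) * (13 + 10 - 3) + 4),
            ("PH-T", 2, 13, 10, 2 * 13 + 13 + 2 * 10 - 4),
            ("PH-X", 2, 13, 10, 2 * 10 + 2 * 13 + 10 - 4),
        ],
    )
    def test_printed_formulas(self, name, G, A, P, expected):
        assert model_df(name, G, A, P) == expected

    @pytest.mark.parametrize("name", list(MODEL_SPECS))
    def test_g1_collapse(self, name):
        assert model_df(name, 1, 5, 5) == 16 == 2 * (5 + 5 - 2)

    @pytest.mark.parametrize("name", list(MODEL_SPECS))
    @pytest.mark.parametrize("G,A,P", [(2, 5, 4), (3, 4, 6)])
    def test_df_matches_design_rank_oracle(self, name, G, A, P):
        """Parameter counts verified against the stacked design's rank."""
        data = pha_data(G=G, A=A, P=P, ratios=tuple(1.0 + i for i in range(G)))
        fit = fit_constrained(data, name)
        k = model_df(name, G, A, P)
        assert fit.k == k
        # build the stacked design again and check rank
        from capca.stratified import MODEL_SPECS as SPECS
        assert np.linalg.matrix_rank(_stacked_design(data, SPECS[name])) == k


def _stacked_design(data, spec):
    from capca.design import build_design
    from capca.stratified import BLOCKS

    design = build_design(data.grid)
    sizes = block_sizes(data.grid.A, data.grid.P)
    cols, k = _joint_layout(spec, data.labels, sizes)
    Xbase = design.matrix if spec.linear == "long" else design.matrix_cross()
    n = data.grid.A * data.grid.P
    X = np.zeros((data.G * n, k))
    for g, s in enumerate(data.strata):
        rows = slice(g * n, (g + 1) * n)
        for name in BLOCKS:
            key = (name, None) if name in spec.shared else (name, s.label)
            X[rows, cols[key]] = Xbase[:, design.slices[name]]
    return X


class TestAICc:
    def test_direct_formula(self):
        assert aicc(-100.0, 10, 50) == pytest.approx(220 + 220 / 39)

    def test_zero_parameter_limit(self):
        assert aicc(-5.0, 0, 100) == pytest.approx(10.0)

    def test_large_n_approaches_aic(self):
        k, ll = 7, -123.4
        assert abs(aicc(ll, k, int(1e9)) - (-2 * ll + 2 * k)) < 1e-6

    def test_undefined_when_correction_blows_up(self):
        with pytest.raises(CapcaError):
            aicc(-1.0, 10, 11)


class TestJointFitting:
    def test_nph_equals_independent_fits(self, small_grid):
        data = pha_data(G=3, A=5, P=4, ratios=(1.0, 1.5, 2.0))
        noisy = add_noise(data, seed=4, noise="poisson")
        joint = fit_constrained(noisy, "N-PH")
        total = sum(fit_apc(s, noisy.grid).loglik for s in noisy.strata)
        assert joint.loglik == pytest.approx(total, abs=1e-8)

    def test_pha_noiseless_exact(self):
        data = pha_data(ratios=(1.0, 2.0))
        fit = fit_constrained(data, "PH-A")
        assert fit.deviance == pytest.approx(0, abs=1e-6)
        rr = fitted_ch_rr(fit, "s1", "s0")
        assert rr.kind == "scalar"
        assert rr.estimate[0] == pytest.approx(2.0, abs=1e-8)

    def test_pha_ci_shrinks_with_person_years(self):
        wide, narrow = [], []
        for py, out in ((1e4, wide), (1e7, narrow)):
            cfg = ScenarioConfig(
                A=5, P=4, labels=("a", "b"), mu=(np.log(2e-4), np.log(4e-4)),
                regime="PH-A", person_years=py, noise="none",
            )
            data, _ = make_scenario(cfg)
            rr = fitted_ch_rr(fit_constrained(data, "PH-A"), "b", "a")
            out.append(rr.hi95[0] - rr.lo95[0])
        assert narrow[0] < wide[0] / 10

    def test_nesting_of_likelihoods(self):
        data = add_noise(pha_data(G=2, ratios=(1.0, 1.7)), seed=9, noise="poisson")
        lls = {name: fit_constrained(data, name).loglik for name in MODEL_SPECS}
        for name, ll in lls.items():
            assert ll <= lls["N-PH"] + 1e-6, name
            assert ll >= lls["PH-A"] - 1e-6, name

    def test_pht_shared_blocks_identical_across_strata(self):
        """Under the PH-T map the net drifts and cohort deviations coincide."""
        cfg = preset("meningioma_like_PHT")
        data = add_noise(make_scenario(cfg)[0], seed=2, noise="poisson")
        fit = fit_constrained(data, "PH-T")
        pF, pM = fit.stratum_params("F"), fit.stratum_params("M")
        assert pF.tau_drift == pytest.approx(pM.tau_drift, abs=1e-12)
        np.testing.assert_allclose(pF.cohort_dev, pM.cohort_dev, atol=1e-12)
        np.testing.assert_allclose(pF.period_dev, pM.period_dev, atol=1e-12)
        assert pF.tau_long != pytest.approx(pM.tau_long, abs=1e-6)

    def test_both_pht_routes_equivalent(self):
        """Sharing (FTT shape + cohort devs) via either linear parameterization
        gives identical fitted surfaces and likelihood."""
        cfg = preset("meningioma_like_PHT")
        data = add_noise(make_scenario(cfg)[0], seed=12, noise="poisson")
        spec_long = MODEL_SPECS["PH-T"]
        spec_cross = ModelSpec("PH-T-alt", spec_long.shared, linear="cross")
        f1 = fit_constrained(data, spec_long)
        f2 = fit_constrained(data, spec_cross)
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-10)
        for lab in data.labels:
            np.testing.assert_allclose(
                f1.fitted_log_rates(lab), f2.fitted_log_rates(lab), atol=1e-10
            )

    def test_two_of_three_implies_third(self):
        """Imposing PH-L and PH-T sharing jointly forces PH-X structure."""
        data = add_noise(pha_data(G=2, ratios=(1.0, 1.6)), seed=3, noise="poisson")
        union = frozenset(MODEL_SPECS["PH-L"].shared | MODEL_SPECS["PH-T"].shared)
        fit = fit_constrained(data, ModelSpec("L+T", union))
        # CH-RR of the fitted surface must be constant down every column
        diff = fit.fitted_log_rates("s1") - fit.fitted_log_rates("s0")
        assert np.ptp(diff) < 1e-10  # L+T shares everything but intercepts -> PH-A


class TestFittedCHRR:
    def test_pht_age_curve_both_corollary_routes(self):
        """Under PH-T the LongAge and CrossAge ratios agree exactly."""
        cfg = preset("meningioma_like_PHT")
        data = add_noise(make_scenario(cfg)[0], seed=21, noise="poisson")
        fit = fit_constrained(data, "PH-T")
        rr = fitted_ch_rr(fit, "F", "M")
        assert rr.kind == "age"
        efF = fit.estimable_functions("F")
        efM = fit.estimable_functions("M")
        long_ratio = efF["long_age"].estimate - efM["long_age"].estimate
        cross_ratio = efF["cross_age"].estimate - efM["cross_age"].estimate
        np.testing.assert_allclose(long_ratio, cross_ratio, atol=1e-10)
        np.testing.assert_allclose(rr.log_estimate, cross_ratio, atol=1e-10)
        # and the FCP/FTT ratios are constant and equal (cohort/period free)
        fcp_ratio = efF["fcp"].estimate - efM["fcp"].estimate
        ftt_ratio = efF["ftt"].estimate - efM["ftt"].estimate
        assert np.ptp(fcp_ratio) < 1e-10 and np.ptp(ftt_ratio) < 1e-10
        assert fcp_ratio[0] == pytest.approx(ftt_ratio[0], abs=1e-10)

    def test_nph_grid_reproduces_observed_ratios(self):
        data = pha_data(G=2, ratios=(1.0, 2.0))
        fit = fit_constrained(data, "N-PH")
        rr = fitted_ch_rr(fit, "s1", "s0")
        assert rr.kind == "grid"
        obs = cross_hazard_rr(data, "s1", "s0")
        np.testing.assert_allclose(
            rr.estimate.reshape(rr.grid_shape), obs.values, rtol=1e-6
        )

    def test_phl_returns_cohort_curve(self):
        cfg = preset("melanoma_like_partition")
        data, _ = make_scenario(cfg)
        sub = data.subset(["HN", "UL"])
        fit = fit_constrained(sub, "PH-L")
        rr = fitted_ch_rr(fit, "HN", "UL")
        assert rr.kind == "cohort" and rr.x.size == data.grid.C
        # noiseless: fitted cohort CH-RR equals the true FCP ratio
        truth = make_scenario(cfg)[1]
        expected = (truth.ef["HN"]["fcp"].estimate - truth.ef["UL"]["fcp"].estimate)
        np.testing.assert_allclose(rr.log_estimate, expected, atol=1e-7)


class TestLocalDriftTaxonomy:
    """Parallelism of Local Drift curves under each regime (noiseless)."""

    def _ld(self, fit, label):
        return fit.estimable_functions(label).local_drifts.estimate

    def test_identical_under_pht_and_pha(self):
        dataT, _ = make_scenario(preset("meningioma_like_PHT"))
        fit = fit_constrained(dataT, "PH-T")
        np.testing.assert_allclose(self._ld(fit, "F"), self._ld(fit, "M"), atol=1e-12)
        dataA = pha_data(ratios=(1.0, 2.0))
        fitA = fit_constrained(dataA, "PH-A")
        np.testing.assert_allclose(self._ld(fitA, "s0"), self._ld(fitA, "s1"), atol=1e-12)

    def test_parallel_with_net_drift_offset_under_phx(self):
        data, _ = make_scenario(preset("melanoma_like_partition"))
        sub = data.subset(["Tr", "LL"])
        fit = fit_constrained(sub, "PH-X")
        d = self._ld(fit, "Tr") - self._ld(fit, "LL")
        gap = fit.stratum_params("Tr").tau_drift - fit.stratum_params("LL").tau_drift
        np.testing.assert_allclose(d, gap, atol=1e-12)

    def test_unconstrained_under_phl(self):
        data, _ = make_scenario(preset("melanoma_like_partition"))
        sub = data.subset(["HN", "UL"])
        fit = fit_constrained(sub, "PH-L")
        d = self._ld(fit, "HN") - self._ld(fit, "UL")
        assert np.ptp(d) > 1e-3  # genuinely non-parallel

    def test_ftt_differences_linear_under_phl(self):
        data, _ = make_scenario(preset("melanoma_like_partition"))
        sub = data.subset(["HN", "UL"])
        fit = fit_constrained(sub, "PH-L")
        dftt = (fit.estimable_functions("HN")["ftt"].estimate
                - fit.estimable_functions("UL")["ftt"].estimate)
        assert np.ptp(np.diff(dftt)) < 1e-10


class TestSelection:
    def test_composite_df_arithmetic(self):
        cfg = preset("meningioma_like_PHT")
        data = add_noise(make_scenario(cfg)[0], seed=1, noise="poisson")
        rep = composite_tests(data)
        row = rep.table.set_index("model").loc["PH-A"]
        assert row["df"] == 84 - 43 == 41
        assert (rep.table["delta_aicc"].dropna() >= 0).all()
        assert rep.table["selected"].sum() == 1

    def test_duplicated_stratum_prefers_sharing(self, small_grid, noisy_stratum):
        stratum, _ = noisy_stratum
        from capca import StratumData
        twin = StratumData("copy", stratum.counts, stratum.offset)
        data = StratifiedLexis(small_grid, (stratum, twin))
        rep = select_model(data)
        t = rep.table.set_index("model")
        assert t.loc["PH-A", "aicc"] < t.loc["N-PH", "aicc"]
        assert t.loc["PH-A", "loglik"] == pytest.approx(t.loc["N-PH", "loglik"], abs=1e-6)

    def test_requires_two_strata(self, small_grid, constant_stratum):
        data = StratifiedLexis(small_grid, (constant_stratum,))
        with pytest.raises(CapcaError):
            select_model(data)

    def test_shared_ef_more_precise_than_unconstrained(self):
        """Model-based EF under the true constraint beat N-PH in CI width."""
        cfg = preset("meningioma_like_PHT")
        data = add_noise(make_scenario(cfg)[0], seed=33, noise="poisson")
        fT = fit_constrained(data, "PH-T")
        fN = fit_constrained(data, "N-PH")
        for label in data.labels:
            seT = fT.estimable_functions(label)["ftt"].se.mean()
            seN = fN.estimable_functions(label)["ftt"].se.mean()
            assert seT < seN
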