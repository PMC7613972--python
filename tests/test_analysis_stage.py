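"""Analysis stage: outcome variants, uncertainty propagation, imputation,
selection model, percent-change reporting."""

import copy
import warnings

import numpy as np
import pytest

from ecoeps import (
    ImputationModelSpec,
    MCMCSettings,
    MissingnessModelSpec,
    OutcomeModelSpec,
    SimulationConfig,
    build_lattice,
    fit_design_stage,
    fit_outcome_model,
    generate_dataset,
    percent_change,
)
from ecoeps.basis import make_basis
from ecoeps.design_stage import DesignStageResult

FAST = MCMCSettings(n_iter=2500, n_burnin=1250, seed=3)


def _fake_design_result(domain, eco, z, var):
    sub, idx = domain.subdomain(eco.ell == 0)
    z = z[idx] if len(z) == eco.n_areas else z
    return DesignStageResult(
        in_sample_ids=list(sub.area_ids), in_sample_idx=idx,
        Z0_mean=z - z.mean(), Z0_var=np.full(len(z), var), Z0_var_pooled=var,
        M_mean=np.zeros((len(z), 5)), M_sd=np.ones((len(z), 5)),
        mcmc=None, subdomain=sub,
    )


class TestBases:
    def test_quadratic_and_linear_shapes(self):
        ref = np.linspace(-2, 2, 50)
        for kind, p in [("linear", 1), ("quadratic", 2)]:
            b = make_basis(kind, ref)
            assert b.evaluate(ref).shape == (50, p)

    def test_natural_cubic_spline_linear_beyond_boundaries(self):
        rng = np.random.default_rng(0)
        ref = rng.normal(0, 1, 200)
        b = make_basis("spline", ref, df=4)
        assert b.evaluate(ref).shape == (200, 4)
        # second differences vanish outside the boundary knots
        far = np.linspace(5, 8, 40)
        F = b.evaluate(far)
        second = np.diff(F, n=2, axis=0)
        assert np.max(np.abs(second)) < 1e-8

    def test_basis_is_deterministic(self):
        ref = np.linspace(0, 1, 30)
        b1, b2 = make_basis("spline", ref), make_basis("spline", ref)
        x = np.array([0.1, 0.4, 0.9])
        assert np.array_equal(b1.evaluate(x), b2.evaluate(x))


class TestPercentChange:
    def test_zero_draws_convention(self):
        out = percent_change(np.zeros(100), delta_x=1.0)
        assert out["mean"] == 0.0
        assert out["p_risk_gt_1"] == 0.5  # undefined-at-0 convention

    def test_exact_five_percent(self):
        d = 2.0
        draws = np.full(10, np.log(1.05) / d)
        out = percent_change(draws, delta_x=d)
        assert out["mean"] == pytest.approx(5.0, rel=1e-12)

    def test_lognormal_mean_oracle(self):
        # draws ~ N(0.2, 0.05^2), Delta=1: E[100(e^b - 1)] =
        # 100(e^{0.2 + 0.05^2/2} - 1) ~ 22.42 (lognormal mean, closed form).
        rng = np.random.default_rng(1)
        draws = rng.normal(0.2, 0.05, 200_000)
        out = percent_change(draws, delta_x=1.0)
        expected = 100 * (np.exp(0.2 + 0.05 ** 2 / 2) - 1)
        assert out["mean"] == pytest.approx(expected, abs=0.05)
        assert out["p_risk_gt_1"] > 0.999

    def test_sqrt_scale_requires_baseline(self):
        with pytest.raises(ValueError, match="baseline"):
            percent_change(np.zeros(5), delta_x=10.0, transform="sqrt_scale")

    def test_sqrt_scale_increment(self):
        d = np.sqrt(30.0) - np.sqrt(20.0)
        draws = np.full(10, np.log(1.10) / d)
        out = percent_change(draws, delta_x=10.0, transform="sqrt_scale", baseline=20.0)
        assert out["mean"] == pytest.approx(10.0, rel=1e-9)


@pytest.fixture(scope="module")
def linear_full_data():
    dom = build_lattice(9, 9)
    cfg = SimulationConfig(design="full", scenario="linear")
    eco, indiv = generate_dataset(dom, cfg, seed=23)
    return dom, cfg, eco, indiv


class TestVariantPlumbing:
    def test_unknown_variant_rejected(self, linear_full_data):
        dom, _, eco, _ = linear_full_data
        with pytest.raises(ValueError, match="variant"):
            fit_outcome_model(eco, None, dom, "nope", mcmc=FAST)

    def test_score_variant_requires_design_result(self, linear_full_data):
        dom, _, eco, _ = linear_full_data
        with pytest.raises(ValueError, match="design-stage"):
            fit_outcome_model(eco, None, dom, "eps_mar", mcmc=FAST)

    def test_interval_contains_mean(self, linear_full_data):
        dom, _, eco, _ = linear_full_data
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = fit_outcome_model(eco, None, dom, "naive", mcmc=FAST)
        s = res.beta_X_summary
        assert s["lower"] <= s["mean"] <= s["upper"]

    def test_spline_needs_enough_areas(self, linear_full_data):
        dom, _, eco, _ = linear_full_data
        fake = _fake_design_result(dom, eco, eco.Z_true, 0.01)
        fake.Z0_mean = fake.Z0_mean[:3]
        fake.Z0_var = fake.Z0_var[:3]
        with pytest.raises(ValueError):
            fit_outcome_model(eco, fake, dom, "complete_case",
                              outcome=OutcomeModelSpec(f_spec="spline", f_df=4),
                              mcmc=FAST)


class TestUncertaintyModel:
    def test_zero_variance_collapses_to_point_score(self, linear_full_data):
        # sigma2hat -> 0: the latent in-sample score must collapse onto the
        # design-stage posterior mean (plug-in limit).
        dom, _, eco, _ = linear_full_data
        fake = _fake_design_result(dom, eco, eco.Z_true, 1e-12)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = fit_outcome_model(eco, fake, dom, "eps_mar",
                                    outcome=OutcomeModelSpec(f_spec="linear"),
                                    mcmc=FAST)
        assert np.allclose(res.Zstar0["mean"], fake.Z0_mean, atol=1e-4)
        assert np.all(res.Zstar0["sd"] < 1e-4)

    def test_true_score_recovers_exposure_effect(self, linear_full_data):
        # With the generating score supplied nearly exactly, the EPS variant
        # matches the benchmark-quality recovery of beta_X = 0.2.
        dom, _, eco, _ = linear_full_data
        fake = _fake_design_result(dom, eco, eco.Z_true, 1e-10)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = fit_outcome_model(eco, fake, dom, "eps_mar",
                                    outcome=OutcomeModelSpec(f_spec="linear"),
                                    mcmc=FAST)
        s = res.beta_X_summary
        assert s["lower"] - 0.1 < 0.2 < s["upper"] + 0.1


@pytest.fixture(scope="module")
def mar_fit():
    dom = build_lattice(9, 9)
    cfg = SimulationConfig(design="MAR", scenario="linear")
    eco, indiv = generate_dataset(dom, cfg, seed=29)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dres = fit_design_stage(indiv, eco, dom,
                                mcmc=MCMCSettings(n_iter=2500, n_burnin=1250, seed=7))
    return dom, cfg, eco, indiv, dres


class TestImputation:
    def test_imputed_scores_defined_exactly_for_missing_areas(self, mar_fit):
        dom, _, eco, _, dres = mar_fit
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = fit_outcome_model(eco, dres, dom, "eps_mar",
                                    outcome=OutcomeModelSpec(f_spec="linear"),
                                    mcmc=FAST)
        missing_ids = {a for a, m in zip(eco.area_ids, eco.ell) if m == 1}
        assert set(res.Z_imputed["area_ids"]) == missing_ids
        assert set(res.Zstar0["area_ids"]) == set(eco.area_ids) - missing_ids
        # ICAR field sum-to-zero holds in every retained draw
        assert np.all(np.abs(res.mcmc.stacked("_phi_sum")) < 1e-8)

    def test_imputation_tracks_truth(self, mar_fit):
        # Imputed out-of-sample scores correlate with the generating score
        # after affine alignment (threshold fixed from pilot runs).
        dom, _, eco, _, dres = mar_fit
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = fit_outcome_model(eco, dres, dom, "eps_mar",
                                    outcome=OutcomeModelSpec(f_spec="linear"),
                                    mcmc=FAST)
        out_idx = np.flatnonzero(eco.ell == 1)
        r = np.corrcoef(res.Z_imputed["mean"], eco.Z_true[out_idx])[0, 1]
        assert r > 0.5

    def test_intercept_only_imputation(self):
        # With the exposure/covariate/spatial terms disabled and no outcome
        # signal, imputed scores concentrate at the imputation intercept.
        dom = build_lattice(7, 7)
        cfg = SimulationConfig(design="MAR", beta_M_true=np.zeros(5),
                               beta_X_true=0.0, beta_C_true=0.0)
        eco, indiv = generate_dataset(dom, cfg, 31)
        fake = _fake_design_result(dom, eco, eco.Z_true, 1e-6)
        imp = ImputationModelSpec(include_X=False, include_phi=False, s_q_spec="none")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = fit_outcome_model(eco, fake, dom, "eps_mar",
                                    outcome=OutcomeModelSpec(f_spec="linear"),
                                    imputation=imp, mcmc=FAST)
        g0 = res.mcmc.stacked("gamma")[:, 0].mean()
        spread = np.abs(res.Z_imputed["mean"] - g0)
        assert np.median(spread) < 2.5 * res.Z_imputed["sd"].mean()

    def test_icar_smoothing_direction(self):
        # An out-of-sample area surrounded by high-score in-sample
        # neighbours is imputed above the global mean.  The outcome carries
        # no signal and the covariate terms are disabled, so the ICAR field
        # is the only channel: the direction is forced by the prior.
        dom = build_lattice(7, 7)
        cfg = SimulationConfig(design="MAR", beta_M_true=np.zeros(5),
                               beta_X_true=0.0, beta_C_true=0.0,
                               missingness_coefs={"intercept": 0.0, "X": 0.0, "C": 0.0})
        eco, _ = generate_dataset(dom, cfg, 53)
        gradient = dom.centroids[:, 0] - dom.centroids[:, 0].mean()
        fake = _fake_design_result(dom, eco, gradient, 1e-6)
        imp = ImputationModelSpec(include_X=False, s_q_spec="none")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = fit_outcome_model(eco, fake, dom, "eps_mar",
                                    outcome=OutcomeModelSpec(f_spec="linear"),
                                    imputation=imp, mcmc=FAST)
        out_idx = np.flatnonzero(eco.ell == 1)
        r = np.corrcoef(res.Z_imputed["mean"], gradient[out_idx])[0, 1]
        assert r > 0.5
        high = gradient[out_idx] > np.quantile(gradient, 0.75)
        if high.any():
            assert res.Z_imputed["mean"][high].mean() > res.Z_imputed["mean"].mean()


class TestSelectionModel:
    def test_az_zero_matches_mar(self):
        # With a_Z fixed at 0 the selection model decouples from the score:
        # the exposure-effect posterior matches the MAR variant within
        # Monte-Carlo error.
        dom = build_lattice(9, 9)
        cfg = SimulationConfig(design="MNAR", scenario="linear")
        eco, indiv = generate_dataset(dom, cfg, 37)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dres = fit_design_stage(indiv, eco, dom,
                                    mcmc=MCMCSettings(n_iter=2500, n_burnin=1250, seed=9))
            mar = fit_outcome_model(eco, dres, dom, "eps_mar",
                                    outcome=OutcomeModelSpec(f_spec="linear"), mcmc=FAST)
            mnar0 = fit_outcome_model(eco, dres, dom, "eps_mnar",
                                      outcome=OutcomeModelSpec(f_spec="linear"),
                                      missingness=MissingnessModelSpec(a_Z_mode=("fixed", 0.0)),
                                      mcmc=FAST)
        d = abs(mar.beta_X_summary["mean"] - mnar0.beta_X_summary["mean"])
        mc = 3 * np.sqrt(mar.beta_X_summary["sd"] ** 2 / 500
                         + mnar0.beta_X_summary["sd"] ** 2 / 500) + 0.02
        assert d < max(mc, 0.05)

    def test_az_sensitivity_grid_is_stable(self):
        # Fixing a_Z over a small grid moves the posterior mean smoothly:
        # neighbouring grid values stay within a modest band.
        dom = build_lattice(8, 8)
        cfg = SimulationConfig(design="MNAR", scenario="linear")
        eco, indiv = generate_dataset(dom, cfg, 41)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dres = fit_design_stage(indiv, eco, dom,
                                    mcmc=MCMCSettings(n_iter=2000, n_burnin=1000, seed=11))
            means = []
            for az in (-1.0, 0.0, 1.0):
                res = fit_outcome_model(
                    eco, dres, dom, "eps_mnar",
                    outcome=OutcomeModelSpec(f_spec="linear"),
                    missingness=MissingnessModelSpec(a_Z_mode=("fixed", az)),
                    mcmc=FAST)
                means.append(res.beta_X_summary["mean"])
        diffs = np.abs(np.diff(means))
        assert np.all(diffs < 0.2)

    def test_estimated_az_mode_runs(self):
        dom = build_lattice(7, 7)
        cfg = SimulationConfig(design="MNAR", scenario="linear")
        eco, indiv = generate_dataset(dom, cfg, 43)
        fake = _fake_design_result(dom, eco, eco.Z_true, 0.01)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = fit_outcome_model(eco, fake, dom, "eps_mnar",
                                    outcome=OutcomeModelSpec(f_spec="linear"),
                                    missingness=MissingnessModelSpec(a_Z_mode="estimated"),
                                    mcmc=FAST)
        a = res.mcmc.stacked("a")
        assert a.shape[1] == 4  # a0, a_X, a_C, a_Z
        assert a[:, -1].std() > 0  # a_Z actually sampled


class TestCutContract:
    def test_design_result_untouched_by_analysis(self, mar_fit):
        dom, _, eco, _, dres = mar_fit
        before = copy.deepcopy((dres.Z0_mean, dres.Z0_var, dres.M_mean))
        eco2 = copy.deepcopy(eco)
        eco2.Y = eco.Y + 3  # different outcome data
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit_outcome_model(eco2, dres, dom, "eps_mar",
                              outcome=OutcomeModelSpec(f_spec="linear"), mcmc=FAST)
        assert np.array_equal(dres.Z0_mean, before[0])
        assert np.array_equal(dres.Z0_var, before[1])
        assert np.array_equal(dres.M_mean, before[2])


class TestNullConfoundingEquivalence:
    def test_variants_agree_without_confounding(self):
        # All M coefficients zero in both X and Y: naive, benchmark and EPS
        # posteriors for beta_X agree within Monte-Carlo error.
        dom = build_lattice(9, 9)
        cfg = SimulationConfig(beta_M_true=np.zeros(5), delta_M_true=np.zeros(5))
        eco, indiv = generate_dataset(dom, cfg, 47)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dres = fit_design_stage(indiv, eco, dom,
                                    mcmc=MCMCSettings(n_iter=2500, n_burnin=1250, seed=13))
            means = {}
            for v in ("naive", "benchmark", "eps_mar"):
                res = fit_outcome_model(eco, dres if v == "eps_mar" else None, dom, v,
                                        outcome=OutcomeModelSpec(f_spec="linear"),
                                        mcmc=FAST)
                means[v] = res.beta_X_summary["mean"]
        vals = list(means.values())
        assert max(vals) - min(vals) < 0.1
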