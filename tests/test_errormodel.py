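"""Cmax error model: gap-sd function, priors, fitting, predictive distributions."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from toxber import (
    CmaxRecord,
    Dataset,
    ExposureScenario,
    McmcConfig,
    ModelSpec,
    PosteriorFit,
    SyntheticConfig,
    fit_error_model,
    generate_portfolio,
    level_gap_sd,
    posterior_predict_cmax,
    predict_withheld_measurement,
)
from toxber.errormodel import PARAM_NAMES


def _record(**obs):
    scen = ExposureScenario(
        chemical_name=obs.pop("chemical", "x"), route="oral", exposure_label=obs.pop("label", "e")
    )
    return CmaxRecord(scenario=scen, **obs)


class TestLevelGapSd:
    @pytest.mark.parametrize(
        "sigma,beta,f,expected",
        [
            (1.0, 1.0, 0.0, 0.0),
            (0.8, 0.2, 0.5, 0.8 * 0.5 / 0.7),
            (1.0, 0.5, 1.0, 2.0 / 3.0),
            (1.0, 0.0, 0.0, 0.0),  # limit convention at beta = f = 0
        ],
    )
    def test_values(self, sigma, beta, f, expected):
        assert level_gap_sd(sigma, beta, f) == pytest.approx(expected, abs=1e-12)

    @given(
        sigma=st.floats(0.01, 5), beta=st.floats(0.01, 5),
        f=st.floats(0.0, 1.0), g=st.floats(0.0, 1.0),
    )
    def test_monotone_in_f_and_bounded_by_sigma(self, sigma, beta, f, g):
        lo, hi = sorted((f, g))
        assert level_gap_sd(sigma, beta, lo) <= level_gap_sd(sigma, beta, hi) + 1e-12
        assert level_gap_sd(sigma, beta, hi) <= sigma

    def test_vanishes_at_zero_over_grid(self):
        for sigma in np.linspace(0.01, 3, 7):
            for beta in np.linspace(0.0, 2, 7):
                assert level_gap_sd(sigma, beta, 0.0) == 0.0


class TestPriorOnlyFit:
    def test_empty_dataset_posterior_matches_clinical_noise_prior(self):
        """With no data the sigma_clinical posterior reproduces the
        InverseGamma(4.6, 0.22) prior, whose 95% credible range is about
        [0.0225, 0.155] log10 units (1.1-fold to 2-fold measurement error)."""
        fit = fit_error_model(Dataset(), mcmc=McmcConfig(chains=4, warmup=500, samples=500, seed=5))
        lo, hi = np.quantile(fit.param_array("sigma_clinical"), [0.025, 0.975])
        plo, phi = stats.invgamma.ppf([0.025, 0.975], 4.6, scale=0.22)
        assert plo == pytest.approx(0.0225, abs=0.005)
        assert phi == pytest.approx(0.155, abs=0.03)
        assert lo == pytest.approx(plo, rel=0.15)
        assert hi == pytest.approx(phi, rel=0.15)


class TestFit:
    def test_posterior_covers_generating_parameters(self, main_fit, default_config):
        for name, truth in default_config.true_params.items():
            lo, hi = np.quantile(main_fit.param_array(name), [0.05, 0.95])
            assert lo <= truth <= hi, f"{name}: truth {truth} outside ({lo:.3f}, {hi:.3f})"

    def test_positivity_and_size_invariants(self, main_fit):
        for name in PARAM_NAMES:
            assert np.all(main_fit.param_array(name) >= 0)
        assert main_fit.n_draws >= 1000
        assert set(main_fit.diagnostics) == set(PARAM_NAMES)

    def test_latents_and_imputations_attached(self, main_fit, portfolio):
        ds, _ = portfolio
        zeta_cols = [c for c in main_fit.draws.columns if c.startswith("zeta[")]
        assert len(zeta_cols) == len(ds)
        n_missing_L3 = sum(r.zhat_L3 is None for r in ds.scenarios)
        imput_cols = [c for c in main_fit.draws.columns if c.startswith("zhat_L3[")]
        assert len(imput_cols) == n_missing_L3

    def test_zero_gap_data_concentrates_alpha_L2_near_zero(self):
        rng = np.random.default_rng(0)
        recs = []
        for i in range(12):
            z3 = rng.uniform(-1, 2)
            recs.append(
                _record(chemical=f"c{i}", zhat_L3=z3, zhat_L2=z3, zhat_L1=z3 + 0.3,
                        f_L2L3=0.0, f_L1L2=0.8)
            )
        fit = fit_error_model(
            Dataset(scenarios=recs), mcmc=McmcConfig(chains=2, warmup=400, samples=400, seed=2)
        )
        assert np.quantile(fit.param_array("alpha_L2"), 0.95) < 0.01

    def test_fit_is_deterministic_under_seed(self):
        ds, _ = generate_portfolio(SyntheticConfig(n_scenarios=6, seed=9))
        cfg = McmcConfig(chains=2, warmup=150, samples=150, seed=21)
        a = fit_error_model(ds, mcmc=cfg)
        b = fit_error_model(ds, mcmc=cfg)
        assert a.draws.equals(b.draws)


class TestPredictive:
    def test_measured_scenario_anchors_predictive(self, main_fit, portfolio):
        ds, _ = portfolio
        rec = next(r for r in ds.scenarios if r.zhat_clinical is not None)
        pred = posterior_predict_cmax(main_fit, rec)
        tol = 2 * float(np.mean(main_fit.param_array("sigma_clinical")))
        assert abs(pred.quantile(0.5) - rec.zhat_clinical) < tol

    def test_variance_ordering_by_information(self, main_fit):
        full = _record(chemical="match", zhat_L1=1.2, zhat_L2=1.0, zhat_L3=0.9,
                       zhat_clinical=0.95, f_L2L3=0.2, f_L1L2=0.8)
        pbk_only = full.model_copy(update={"zhat_clinical": None})
        l12_only = full.model_copy(update={"zhat_clinical": None, "zhat_L3": None})
        sds = [posterior_predict_cmax(main_fit, r).sd() for r in (full, pbk_only, l12_only)]
        assert sds[0] < sds[1] < sds[2]

    def test_quantiles_monotone_and_nested(self, main_fit, portfolio):
        ds, _ = portfolio
        for rec in ds.scenarios[:5]:
            pred = posterior_predict_cmax(main_fit, rec)
            qs = pred.quantile(np.array([0.025, 0.25, 0.5, 0.75, 0.975]))
            assert np.all(np.diff(qs) > 0)
            lo50, hi50 = pred.interval(0.5)
            lo95, hi95 = pred.interval(0.95)
            assert lo95 < lo50 < hi50 < hi95

    def test_degenerate_fit_matches_closed_form(self):
        fit = PosteriorFit.from_fixed_params(
            {"sigma_clinical": 0.05, "alpha_L3": 0.2, "sigma_L3pop": 0.4,
             "sigma": 0.5, "beta": 0.3}
        )
        pred = posterior_predict_cmax(fit, _record(zhat_L3=1.0))
        # conditional normal with the Normal(0, 10) zeta prior
        tau, s3 = 10.0, 0.4
        var = 1.0 / (1.0 / s3**2 + 1.0 / tau**2)
        mu = var * (1.0 - 0.2) / s3**2
        assert pred.quantile(0.5) == pytest.approx(mu, abs=1e-6)
        q975 = mu + np.sqrt(var) * stats.norm.ppf(0.975)
        assert pred.quantile(0.975) == pytest.approx(q975, abs=1e-6)
        # the flat-prior reading 0.8 + 1.96*0.4 = 1.584 agrees to prior shrinkage
        assert pred.quantile(0.975) == pytest.approx(1.584, abs=5e-3)

    def test_withheld_prediction_adds_clinical_noise_in_quadrature(self):
        fit = PosteriorFit.from_fixed_params(
            {"sigma_clinical": 0.05, "alpha_L3": 0.2, "sigma_L3pop": 0.4,
             "sigma": 0.5, "beta": 0.3}
        )
        rec = _record(zhat_L3=1.0, zhat_clinical=0.9)
        pop = posterior_predict_cmax(fit, rec.model_copy(update={"zhat_clinical": None}))
        withheld = predict_withheld_measurement(fit, rec, "L3")
        assert withheld.sds[0] == pytest.approx(np.sqrt(pop.sds[0] ** 2 + 0.05**2), rel=1e-9)
        assert withheld.target == "withheld_measurement"

    def test_withheld_errors_when_level_absent(self, main_fit):
        rec = _record(zhat_L1=1.0, zhat_clinical=0.9)
        with pytest.raises(ValueError, match="no L3 observation"):
            predict_withheld_measurement(main_fit, rec, "L3")
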