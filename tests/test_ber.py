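"""BER distributions, decision thresholds, protectiveness/utility, correlation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import special, stats

from toxber import (
    Dataset,
    McmcConfig,
    ModelSpec,
    PosteriorFit,
    SyntheticConfig,
    decide,
    derive_consistent_thresholds,
    evaluate_decisions,
    fit_error_model,
    generate_portfolio,
    level_gap_sd,
    point_biserial_distribution,
    prob_ber_above,
    protectiveness,
    threshold_from_confidence,
    utility,
)
from toxber.ber import LOW_RISK, UNCERTAIN_RISK, BERDistribution
from toxber.data import CmaxRecord, ExposureScenario, PODRecord

FIXED_PARAMS = {
    "sigma_clinical": 0.05,
    "alpha_L1": 0.2,
    "alpha_L2": 0.15,
    "alpha_L3": 0.1,
    "sigma_L3pop": 0.4,
    "sigma": 0.6,
    "beta": 0.3,
}


class TestBERDistribution:
    def test_constant_cmax_gives_constant_ber(self):
        dist = BERDistribution(("x",), "L3", 1.0, np.full(100, 1.0))  # Cmax = 10 µM
        assert np.allclose(dist.draws, 0.1)
        assert dist.point_estimate == pytest.approx(0.1)

    def test_point_estimate_is_geometric_mean(self, rng):
        zeta = rng.normal(0.5, 0.8, size=5000)
        dist = BERDistribution(("x",), "L2", 2.0, zeta)
        assert dist.point_estimate == pytest.approx(
            10.0 ** np.mean(np.log10(dist.draws)), rel=1e-9
        )

    def test_lognormal_median_oracle(self, rng):
        m, s, pod = 1.3, 0.6, 4.0
        dist = BERDistribution(("x",), None, pod, rng.normal(m, s, size=200_000))
        assert dist.quantile(0.5) == pytest.approx(pod * 10.0 ** (-m), rel=0.02)

    def test_quantile_identity_exact_on_draw_set(self, rng):
        zeta = rng.normal(0.0, 1.0, size=777)
        pod = 3.7
        dist = BERDistribution(("x",), None, pod, zeta)
        for p in (0.025, 0.1, 0.5, 0.9, 0.975):
            lhs = dist.quantile(p) * 10.0 ** np.quantile(zeta, 1.0 - p)
            assert lhs == pytest.approx(pod, rel=1e-12)

    def test_prob_above(self, rng):
        dist = BERDistribution(("x",), None, 1.0, np.repeat([-1.0, 1.0], 50))
        assert prob_ber_above(dist, 1.0) == 0.5
        all_above = BERDistribution(("x",), None, 100.0, np.zeros(10))
        assert prob_ber_above(all_above, 1.0) == 1.0
        assert 0 <= dist.mc_se_prob_above() <= 0.5

    def test_nonpositive_pod_rejected(self):
        with pytest.raises(ValueError, match="pod_um"):
            BERDistribution(("x",), None, -1.0, np.zeros(5))


class TestThresholdFromConfidence:
    def test_half_confidence_gives_unit_threshold(self):
        assert threshold_from_confidence(0.5, 0.3) == pytest.approx(1.0)

    def test_quantile_oracle(self):
        assert threshold_from_confidence(0.95, 0.5) == pytest.approx(
            10.0 ** (stats.norm.ppf(0.95) * 0.5), rel=1e-9
        )

    @given(
        p=st.floats(0.55, 0.99), q=st.floats(0.55, 0.99),
        s=st.floats(0.05, 2.0), t=st.floats(0.05, 2.0),
    )
    def test_strictly_increasing_in_both_arguments(self, p, q, s, t):
        plo, phi = sorted((p, q))
        slo, shi = sorted((s, t))
        if phi > plo:
            assert threshold_from_confidence(phi, s) > threshold_from_confidence(plo, s)
        if shi > slo:
            assert threshold_from_confidence(phi, shi) > threshold_from_confidence(phi, slo)


class TestDecide:
    def _model(self):
        from toxber.ber import DecisionModel

        return DecisionModel(
            p_threshold={"L1": 0.98, "L2": 0.97, "L3": 0.95},
            threshold_ber={"L1": 110.0, "L2": 11.0, "L3": 2.5},
        )

    def test_point_estimate_above_threshold_is_low_risk(self):
        assert decide(2.6, "L3", self._model()) == LOW_RISK

    def test_below_threshold_is_uncertain(self):
        for lev in ("L1", "L2", "L3"):
            assert decide(0.5, lev, self._model()) == UNCERTAIN_RISK

    def test_boundary_is_strict(self):
        assert decide(2.5, "L3", self._model()) == UNCERTAIN_RISK


class TestProtectivenessUtility:
    def test_counts(self):
        labels = {i: ("high" if i < 2 else "low") for i in range(5)}
        decisions = {0: UNCERTAIN_RISK, 1: LOW_RISK, 2: LOW_RISK, 3: LOW_RISK, 4: UNCERTAIN_RISK}
        assert protectiveness(decisions, labels) == pytest.approx(0.5)
        assert utility(decisions, labels) == pytest.approx(2 / 3)

    def test_degenerate_extremes(self):
        labels = {0: "high", 1: "low"}
        assert protectiveness({0: LOW_RISK, 1: LOW_RISK}, labels) == 0.0
        assert utility({0: LOW_RISK, 1: LOW_RISK}, labels) == 1.0

    def test_order_invariance(self):
        labels = {i: ("high" if i % 2 else "low") for i in range(6)}
        decisions = {i: (LOW_RISK if i < 3 else UNCERTAIN_RISK) for i in range(6)}
        rev_labels = dict(reversed(list(labels.items())))
        assert protectiveness(decisions, labels) == protectiveness(decisions, rev_labels)
        assert utility(decisions, labels) == utility(decisions, rev_labels)

    def test_missing_label_class_errors(self):
        with pytest.raises(ValueError, match="high-risk"):
            protectiveness({0: LOW_RISK}, {0: "low"})
        with pytest.raises(ValueError, match="low-risk"):
            utility({0: LOW_RISK}, {0: "high"})


class TestConsistentThresholds:
    def test_zero_gap_model_gives_identical_levels(self):
        spec = ModelSpec(default_f_L2L3=0.0, default_f_L1L2=0.0)
        fit = PosteriorFit.from_fixed_params(FIXED_PARAMS, spec=spec)
        model = derive_consistent_thresholds(fit, 0.95, 0.1, n_mc=10_000)
        t = model.threshold_ber
        assert t["L1"] == pytest.approx(t["L3"], rel=1e-6)
        assert model.p_threshold["L1"] == pytest.approx(model.p_threshold["L3"], abs=1e-6)

    def test_matches_closed_form_bivariate_normal_oracle(self):
        fit = PosteriorFit.from_fixed_params(FIXED_PARAMS)
        model = derive_consistent_thresholds(fit, 0.95, 0.1, n_mc=400_000)
        tau = 10.0
        s3sq = FIXED_PARAMS["sigma_L3pop"] ** 2
        sd3 = np.sqrt(tau**2 - tau**4 / (tau**2 + s3sq))
        t3 = 10.0 ** (special.ndtri(0.95) * sd3)
        assert model.threshold_ber["L3"] == pytest.approx(t3, rel=0.02)
        # L2: boundary point estimate shifts by the L2-L3 gap noise
        gap2 = level_gap_sd(FIXED_PARAMS["sigma"], FIXED_PARAMS["beta"], 0.5)
        t2 = t3 * 10.0 ** (-special.ndtri(0.1) * gap2)
        assert model.threshold_ber["L2"] == pytest.approx(t2, rel=0.02)
        # equivalent confidence from the bivariate-normal conditional sd at L2
        v2 = s3sq + gap2**2
        cov = np.array(
            [
                [tau**2 + v2, tau**2 + v2],
                [tau**2 + v2, tau**2 + v2 + level_gap_sd(
                    FIXED_PARAMS["sigma"], FIXED_PARAMS["beta"], 1.0
                ) ** 2],
            ]
        )
        ones = np.ones(2)
        sd2 = np.sqrt(tau**2 - tau**4 * ones @ np.linalg.solve(cov, ones))
        p2 = stats.norm.cdf(np.log10(t2) / sd2)
        assert model.p_threshold["L2"] == pytest.approx(p2, abs=0.01)

    def test_thresholds_decrease_with_level_on_fitted_model(self, main_fit):
        model = derive_consistent_thresholds(main_fit)
        t = model.threshold_ber
        assert t["L1"] > t["L2"] > t["L3"]
        p = model.p_threshold
        assert p["L1"] >= p["L2"] >= p["L3"]

    def test_utility_nondecreasing_across_levels_on_replicates(self):
        """With consistent thresholds, refining the PBK level should not lose
        correctly identified low-risk scenarios on average."""
        gains = []
        for rep in range(20):
            ds, _ = generate_portfolio(SyntheticConfig(seed=100 + rep))
            fit = fit_error_model(ds, mcmc=McmcConfig(chains=2, warmup=300, samples=300, seed=rep))
            model = derive_consistent_thresholds(fit, n_mc=20_000)
            ev = evaluate_decisions(fit, ds, model)
            gains.append(ev["L3"]["utility"] - ev["L1"]["utility"])
        assert np.mean(gains) >= 0


class TestPointBiserial:
    def _fit_with_fixed_zetas(self, zetas, labels):
        recs, pods = [], []
        for i, (z, lab) in enumerate(zip(zetas, labels)):
            scen = ExposureScenario(
                chemical_name=f"c{i}", route="oral", exposure_label="e", risk_label=lab
            )
            recs.append(CmaxRecord(scenario=scen, zhat_L3=z))
            pods.append(PODRecord(chemical_name=f"c{i}", platform="IPP", pod_um=1.0))
        ds = Dataset(scenarios=recs, pods=pods)
        fit = PosteriorFit.from_fixed_params(FIXED_PARAMS)
        draws = pd.concat([fit.draws] * 50, ignore_index=True)
        for rec, z in zip(recs, zetas):
            draws[f"zeta[{'|'.join(rec.key)}]"] = z  # degenerate latent posterior
        fit.draws = draws
        return fit, ds

    def test_matches_direct_point_biserial_formula(self):
        rng = np.random.default_rng(3)
        labels = ["high"] * 6 + ["low"] * 13
        zetas = np.concatenate([rng.normal(2, 0.3, 6), rng.normal(-1, 0.5, 13)])
        fit, ds = self._fit_with_fixed_zetas(zetas, labels)
        res = point_biserial_distribution(fit, ds)
        y = np.array([1.0] * 6 + [0.0] * 13)
        expected = stats.pointbiserialr(y, np.log10(1.0) - zetas).correlation
        assert res["mean"] == pytest.approx(expected, abs=1e-9)
        assert res["mean"] < -0.9  # well-separated groups

    def test_constant_ber_gives_zero_correlation(self):
        fit, ds = self._fit_with_fixed_zetas(np.zeros(6), ["high"] * 3 + ["low"] * 3)
        res = point_biserial_distribution(fit, ds)
        assert res["mean"] == 0.0

    def test_single_label_errors(self):
        fit, ds = self._fit_with_fixed_zetas(np.arange(4.0), ["low"] * 4)
        with pytest.raises(ValueError, match="per risk label"):
            point_biserial_distribution(fit, ds)

    def test_fitted_portfolio_correlation_is_strongly_negative(self, main_fit, portfolio):
        ds, _ = portfolio
        res = point_biserial_distribution(main_fit, ds)
        lo, hi = res["interval_95"]
        assert lo < res["mean"] < hi
        assert res["mean"] < -0.4  # high risk <-> small BER by construction
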