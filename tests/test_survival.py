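"""Parametric MLE fitting, AIC selection and HR-transformed curves."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from pscea.distributions import DistSpec
from pscea.survival import (
    FitError,
    SurvivalFit,
    apply_hr,
    fit_all,
    fit_parametric,
    hazard_at,
    select_best,
    survival_at,
)
from pscea.synthetic import CensorSpec, simulate_ipd

# (family, generating parameters) for recovery runs
RECOVERY_CASES = [
    ("exponential", {"rate": 0.08}),
    ("weibull", {"scale": 12.0, "shape": 1.4}),
    ("lognormal", {"mu": 2.2, "sigma": 0.9}),
    ("loglogistic", {"scale": 9.8, "shape": 1.5}),
    ("gompertz", {"shape": 0.08, "rate": 0.04}),
]


def simulate_family(family, params, n, seed, censored=True):
    spec = DistSpec(family, params)
    censor = CensorSpec(admin_cutoff=1e12, dropout_rate=0.0)
    ipd = simulate_ipd(spec, censor, n, seed=seed)
    if censored:
        # ~20% independent right censoring at a fixed quantile of the data
        rng = np.random.default_rng(seed + 1)
        cut = np.quantile(ipd["time_months"], 0.8)
        cens = rng.uniform(0, 2 * cut, size=n)
        time = np.minimum(ipd["time_months"].to_numpy(), np.maximum(cens, cut))
        event = (ipd["time_months"].to_numpy() <= time).astype(int)
        ipd = pd.DataFrame({"time_months": time, "event": event})
    return spec, ipd


class TestFitParametric:
    def test_exponential_closed_form_mle(self):
        # uncensored times {1,2,3}: MLE rate = n / sum(t) = 0.5
        ipd = pd.DataFrame({"time_months": [1.0, 2.0, 3.0], "event": [1, 1, 1]})
        fit = fit_parametric(ipd, "exponential")
        assert fit.params["rate"] == pytest.approx(0.5, rel=1e-5)
        # AIC identity: 2k - 2 loglik
        assert fit.aic == pytest.approx(2 * 1 - 2 * fit.loglik)

    def test_aic_identity_all_families(self):
        _, ipd = simulate_family("loglogistic", {"scale": 9.8, "shape": 1.5}, 400, seed=2)
        for fit in fit_all(ipd):
            assert fit.aic == pytest.approx(2 * fit.n_params - 2 * fit.loglik, rel=1e-12)

    def test_all_censored_rejected(self):
        ipd = pd.DataFrame({"time_months": [1.0, 2.0], "event": [0, 0]})
        with pytest.raises(FitError):
            fit_parametric(ipd, "weibull")

    @pytest.mark.parametrize("family,params", RECOVERY_CASES)
    def test_parameter_recovery_within_10pct(self, family, params):
        # n = 5000 with ~20% censoring; every parameter back within 10%
        _, ipd = simulate_family(family, params, 5000, seed=17)
        assert 0.1 < 1 - ipd["event"].mean() < 0.3
        fit = fit_parametric(ipd, family)
        for name, truth in params.items():
            assert fit.params[name] == pytest.approx(truth, rel=0.10), (family, name)

    def test_loglik_matches_lifelines(self):
        # independent oracle: lifelines' fitters on the same censored data
        from lifelines import LogLogisticFitter, WeibullFitter

        _, ipd = simulate_family("loglogistic", {"scale": 9.8, "shape": 1.5}, 1000, seed=5)
        t, e = ipd["time_months"], ipd["event"]
        for family, fitter in [("weibull", WeibullFitter()), ("loglogistic", LogLogisticFitter())]:
            fit = fit_parametric(ipd, family)
            fitter.fit(t, e)
            assert fit.loglik == pytest.approx(fitter.log_likelihood_, rel=1e-4)


class TestSelection:
    def test_minimum_aic_wins(self):
        a = SurvivalFit(DistSpec("exponential", {"rate": 0.1}), loglik=-104.0, converged=True)
        b = SurvivalFit(DistSpec("loglogistic", {"scale": 9, "shape": 1.5}), loglik=-100.0,
                        converged=True)
        assert select_best([a, b]) is b  # AIC 210 vs 204

    def test_single_fit_identity(self):
        a = SurvivalFit(DistSpec("exponential", {"rate": 0.1}), loglik=-10.0, converged=True)
        assert select_best([a]) is a

    def test_tie_broken_by_fewer_parameters(self):
        one = SurvivalFit(DistSpec("exponential", {"rate": 0.1}), loglik=-100.0, converged=True)
        two = SurvivalFit(DistSpec("weibull", {"scale": 10, "shape": 1.0}), loglik=-99.0,
                          converged=True)
        assert select_best([one, two]) is one  # both AIC 202

    def test_empty_rejected(self):
        with pytest.raises(FitError):
            select_best([])

    def test_loglogistic_wins_on_loglogistic_data(self):
        _, ipd = simulate_family("loglogistic", {"scale": 9.8, "shape": 1.5}, 5000, seed=23)
        assert select_best(fit_all(ipd)).family == "loglogistic"


class TestCurves:
    def test_survival_starts_at_one(self):
        fit = SurvivalFit(DistSpec("loglogistic", {"scale": 9.8, "shape": 1.5}),
                          loglik=0.0, converged=True)
        assert survival_at(fit, 0.0) == pytest.approx(1.0)
        assert survival_at(fit, 9.8) == pytest.approx(0.5)

    def test_negative_time_rejected(self):
        fit = SurvivalFit(DistSpec("exponential", {"rate": 0.1}), loglik=0.0, converged=True)
        with pytest.raises(ValueError):
            survival_at(fit, -1.0)

    def test_weibull_cumhazard_matches_quadrature(self):
        fit = SurvivalFit(DistSpec("weibull", {"scale": 12.0, "shape": 1.4}),
                          loglik=0.0, converged=True)
        t = 15.0
        cumhaz = quad(lambda u: float(hazard_at(fit, u)), 0, t, limit=400)[0]
        assert -np.log(float(survival_at(fit, t))) == pytest.approx(cumhaz, rel=1e-3)

    def test_apply_hr_identity(self):
        ref = DistSpec("loglogistic", {"scale": 9.8, "shape": 1.5})
        curve = apply_hr(ref, 1.0)
        t = np.linspace(0, 40, 50)
        assert np.allclose(curve.sf(t), ref.sf(t))

    def test_apply_hr_power_law(self):
        ref = DistSpec("loglogistic", {"scale": 9.8, "shape": 1.5})
        curve = apply_hr(ref, 0.73)
        # S_ref(median) = 0.5 -> S_adj = 0.5^0.73, cross-check via exp(0.73 ln 0.5)
        assert float(curve.sf(9.8)) == pytest.approx(np.exp(0.73 * np.log(0.5)), rel=1e-12)
        assert float(curve.sf(9.8)) == pytest.approx(0.6029, abs=5e-5)

    def test_hr_2_is_square(self):
        ref = DistSpec("loglogistic", {"scale": 9.8, "shape": 1.5})
        sq = apply_hr(ref, 2.0)
        assert float(sq.sf(9.8)) == pytest.approx(0.25)

    def test_nonpositive_hr_rejected(self):
        ref = DistSpec("exponential", {"rate": 0.1})
        with pytest.raises(ValueError):
            apply_hr(ref, 0.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(hr=st.floats(0.05, 5.0), t=st.floats(0.0, 100.0))
    def test_hr_curve_is_valid_survival(self, hr, t):
        ref = DistSpec("loglogistic", {"scale": 9.8, "shape": 1.5})
        curve = apply_hr(ref, hr)
        s0 = float(curve.sf(0.0))
        st_ = float(curve.sf(t))
        assert s0 == pytest.approx(1.0)
        assert 0.0 <= st_ <= 1.0
        assert st_ <= s0 + 1e-12
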