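"""One-way, probabilistic, CEAC, threshold and subgroup analyses."""

import numpy as np
import pandas as pd
import pytest

from pscea import analyses as an
from pscea.params import Param

WTP = 31304.31


def frozen_space(model):
    """Parameter space with every PSA distribution degenerate at base."""
    return {
        name: Param(name, p.base, p.base, p.base, p.dist, p.role)
        for name, p in model.param_space.items()
    }


class TestBaseCase:
    def test_equal_arms_zero_effect(self, model):
        res = model.evaluate({"hr_os": 1.0, "hr_pfs": 1.0})
        assert res.delta_qaly == pytest.approx(0.0, abs=1e-12)
        assert res.status == "non-comparable"  # pembrolizumab still costs money

    def test_doubling_price_raises_icer(self, model):
        base = model.evaluate().icer
        doubled = model.evaluate({"cost_pembrolizumab": 2 * 5625.75}).icer
        assert doubled > base

    def test_lower_hrs_never_raise_icer(self, model):
        base = model.evaluate().icer
        better = model.evaluate({"hr_os": 0.65, "hr_pfs": 0.55}).icer
        assert better <= base

    def test_summary_reports_icer(self, results):
        text = results.summary()
        assert "Cost per QALY gained" in text
        assert f"{results.icer:,.2f}" in text


class TestOneWay:
    def test_degenerate_parameter_zero_spread(self, model):
        space = {"utility_pd": Param("utility_pd", 0.58, 0.58, 0.58, "beta", "utility")}
        row = an.one_way(model, space=space).iloc[0]
        assert row["spread"] == 0.0

    def test_high_hr_pfs_raises_icer(self, model):
        # less effective on PFS -> worse value (directional, synthetic curves)
        base = model.evaluate().icer
        space = {"hr_pfs": model.param_space["hr_pfs"]}
        row = an.one_way(model, space=space).iloc[0]
        assert row["icer_high"] > base

    def test_pembrolizumab_midpoint_identity(self, model):
        base = model.evaluate().icer
        space = {"cost_pembrolizumab": model.param_space["cost_pembrolizumab"]}
        row = an.one_way(model, space=space).iloc[0]
        assert (row["icer_low"] + row["icer_high"]) / 2 == pytest.approx(base, rel=1e-6)

    def test_rows_sorted_by_spread_and_complete(self, model):
        df = an.one_way(model)
        assert (df["spread"].to_numpy()[:-1] >= df["spread"].to_numpy()[1:]).all()
        # every tabulated parameter plus start age is present
        assert set(df["parameter"]) == set(model.param_space)
        assert "start_age" in set(df["parameter"])

    def test_unknown_parameter_rejected(self, model):
        with pytest.raises(KeyError):
            an.one_way(model, space={"nope": Param("nope", 1, 0, 2, None, "cost")})


class TestPSA:
    def test_seeded_reproducibility(self, model):
        a = an.psa(model, n=20, seed=7)
        b = an.psa(model, n=20, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_zero_variance_collapses_to_base_case(self, model):
        base = model.evaluate()
        samples = an.psa(model, n=5, seed=1, space=frozen_space(model))
        assert np.allclose(samples["icer"], base.icer)
        assert np.allclose(samples["delta_qaly"], base.delta_qaly)

    def test_utility_draws_in_unit_interval(self, model):
        samples = an.psa(model, n=200, seed=3)
        assert samples["utility_pfs"].between(0, 1).all()
        assert samples["utility_pd"].between(0, 1).all()

    def test_hr_os_mean_within_3_se(self, model):
        n = 1000
        samples = an.psa(model, n=n, seed=5)
        sd_log = (np.log(0.88) - np.log(0.58)) / 3.92
        analytic_mean = 0.73 * np.exp(sd_log**2 / 2)
        se = analytic_mean * np.sqrt(np.exp(sd_log**2) - 1) / np.sqrt(n)
        assert abs(samples["hr_os"].mean() - analytic_mean) < 3 * se

    def test_infeasible_beta_variance_falls_back(self, model):
        wide = Param("utility_pd", 0.98, 0.0, 1.0, "beta", "utility")
        space = {"utility_pd": wide}
        with pytest.warns(UserWarning, match="infeasible"):
            samples = an.psa(model, n=50, seed=2, space=space)
        assert samples["utility_pd"].between(0, 1).all()


@pytest.fixture(scope="module")
def samples(model):
    return an.psa(model, n=300, seed=13)


class TestCEAC:
    def test_monotone_nondecreasing_in_wtp(self, samples):
        curve = an.ceac(samples)
        assert (np.diff(curve["probability"]) >= -1e-12).all()

    def test_zero_wtp_all_costly_draws_rejected(self, samples):
        if (samples["delta_cost"] > 0).all():
            assert an.probability_cost_effective(samples, 0.0) == 0.0

    def test_huge_wtp_accepts_all_effective_draws(self, samples):
        frac_effective = (samples["delta_qaly"] > 0).mean()
        assert an.probability_cost_effective(samples, 1e12) == pytest.approx(frac_effective)

    def test_empty_samples_rejected(self):
        with pytest.raises(ValueError):
            an.ceac(pd.DataFrame())


class TestThreshold:
    def test_confirmation_run_matches_wtp(self, model):
        res = an.threshold_price(model)
        assert res["feasible"]
        assert abs(res["icer"] - WTP) / WTP <= 1e-4
        assert 0 < res["price"] < 5625.75
        assert 0 < res["reduction_pct"] < 100

    def test_wtp_at_base_icer_zero_reduction(self, model):
        base = model.evaluate().icer
        res = an.threshold_price(model, wtp=base * 1.001)
        assert res["reduction_pct"] == 0.0

    def test_unreachable_wtp_flagged(self, model):
        floor_icer = model.evaluate({"cost_pembrolizumab": 0.0}).icer
        res = an.threshold_price(model, wtp=floor_icer * 0.5)
        assert not res["feasible"]
        assert res["reduction_pct"] == 100.0


class TestSubgroups:
    def test_base_hrs_reproduce_base_case(self, model):
        base = model.evaluate()
        res = an.subgroup_run(model, 0.73, 0.65)
        assert res.icer == base.icer
        assert res.delta_cost == base.delta_cost

    def test_cps10_below_all_comers(self, model):
        base = model.evaluate().icer
        res = an.subgroup_run(model, 0.62, 0.51)
        assert res.icer < base

    def test_null_hrs_no_gain(self, model):
        res = an.subgroup_run(model, 1.0, 1.0)
        assert res.status in ("non-comparable", "dominated")

    def test_table_contains_both_subgroups(self, model):
        df = an.subgroup_table(model)
        assert set(df["subgroup"]) == {"oesophageal_squamous_cell_carcinoma", "pd_l1_cps_ge_10"}
        assert (df["icer"] > 0).all()

    def test_nonpositive_hr_rejected(self, model):
        with pytest.raises(ValueError):
            an.subgroup_run(model, -0.5, 0.5)
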