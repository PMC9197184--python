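"""Cost/QALY accrual and incremental results against hand-computed ledgers."""

import numpy as np
import pytest

from pscea.cohort import ModelSettings
from pscea.econ import (
    RegimenLine,
    StrategyTotals,
    Utilities,
    accrue,
    ae_lump_cost,
    drug_cost_vector,
    icer,
)

CY = 21 / 365.25  # cycle length in years


class TestDrugCosts:
    def test_single_cycle_cap(self, toy_trace):
        line = RegimenLine("drug", 100.0, "pfs", max_cycles=1)
        assert drug_cost_vector(line, toy_trace).tolist() == [100.0, 0.0]

    def test_zero_uptake(self, toy_trace):
        line = RegimenLine("drug", 100.0, "pd", None, uptake_fraction=0.0)
        assert (drug_cost_vector(line, toy_trace) == 0.0).all()

    def test_start_of_cycle_occupancy(self, toy_trace):
        # pembrolizumab on PFS occupancy (1.0, 0.6): cycle-1 cost 5625.75 * 0.6
        line = RegimenLine("pembrolizumab", 5625.75, "pfs", 35)
        vec = drug_cost_vector(line, toy_trace)
        assert vec[1] == pytest.approx(5625.75 * 0.6)

    def test_unknown_state_rejected(self):
        with pytest.raises(ValueError, match="state"):
            RegimenLine("drug", 1.0, "dead")


class TestAELump:
    def test_zero_incidence(self):
        assert ae_lump_cost({"nausea": 0.0}, {"nausea": 71.0}) == 0.0

    def test_single_event_product(self):
        assert ae_lump_cost({"neutropenia": 0.5}, {"neutropenia": 466.0}) == pytest.approx(233.0)

    def test_hand_sum(self):
        inc = {"nausea": 0.1, "anaemia": 0.2}
        cost = {"nausea": 71.00, "anaemia": 73.68}
        assert ae_lump_cost(inc, cost) == pytest.approx(0.1 * 71.00 + 0.2 * 73.68)

    def test_invalid_incidence_rejected(self):
        with pytest.raises(ValueError):
            ae_lump_cost({"nausea": 1.5}, {"nausea": 71.0})


class TestAccrue:
    def test_toy_trace_hand_ledger(self, toy_trace):
        """Every totals component recomputed with explicit arithmetic."""
        s = ModelSettings(discount_annual=0.03)
        d1 = 1.03 ** (-CY)  # discount factor at cycle 1
        lines = [
            RegimenLine("pembrolizumab", 5625.75, "pfs", 35),
            RegimenLine("paclitaxel", 351.81, "pd", None, 0.43),
        ]
        res = accrue(toy_trace, lines, Utilities(0.74, 0.58), 55.18, 125.47,
                     ae_lump=10.0, settings=s)
        # QALY: hcc of (0.74*pfs + 0.58*pd) = hcc([0.74, 0.618]) = [0.679, 0.309]
        exp_qaly = (0.679 * 1.0 + 0.309 * d1) * CY
        assert res.qaly == pytest.approx(exp_qaly, rel=1e-12)
        # LY: hcc of alive [1.0, 0.9] = [0.95, 0.45]
        assert res.ly == pytest.approx((0.95 + 0.45 * d1) * CY, rel=1e-12)
        # drugs at start-of-cycle occupancy, no half-cycle correction
        exp_pembro = 5625.75 * (1.0 + 0.6 * d1)
        exp_pac = 351.81 * 0.43 * (0.0 + 0.3 * d1)
        # follow-up on hcc(pfs) = [0.8, 0.3]; supportive on hcc(pd) = [0.15, 0.15]
        exp_follow = 55.18 * (0.8 + 0.3 * d1)
        exp_supp = 125.47 * (0.15 + 0.15 * d1)
        assert res.cost == pytest.approx(10.0 + exp_pembro + exp_pac + exp_follow + exp_supp,
                                         rel=1e-12)

    def test_unit_utilities_zero_discount_qaly_equals_ly(self, toy_trace):
        s = ModelSettings(discount_annual=0.0)
        res = accrue(toy_trace, [], Utilities(1.0, 1.0), 0.0, 0.0, 0.0, s)
        assert res.qaly == res.ly

    def test_zero_costs_zero_total(self, toy_trace):
        s = ModelSettings()
        res = accrue(toy_trace, [], Utilities(0.74, 0.58), 0.0, 0.0, 0.0, s)
        assert res.cost == 0.0


class TestICER:
    def test_ratio_and_labels(self):
        a = StrategyTotals("a", cost=14_412.14, ly=3.71, qaly=2.32)
        b = StrategyTotals("b", cost=135_890.90, ly=5.36, qaly=3.37)
        res = icer(a, b)
        assert res.delta_cost == pytest.approx(121_478.76)
        assert res.icer == pytest.approx(121_478.76 / 1.05, rel=1e-9)
        assert res.status == "icer"

    def test_identical_strategies_non_comparable_flag(self):
        a = StrategyTotals("a", cost=10.0, ly=1.0, qaly=1.0)
        res = icer(a, StrategyTotals("b", cost=10.0, ly=1.0, qaly=1.0))
        assert res.status == "equivalent"
        b = StrategyTotals("b", cost=11.0, ly=1.0, qaly=1.0)
        res = icer(a, b)
        assert res.status == "non-comparable"
        assert np.isinf(res.icer)

    def test_dominance_labels(self):
        a = StrategyTotals("a", cost=10.0, ly=1.0, qaly=1.0)
        cheaper_better = StrategyTotals("b", cost=9.0, ly=1.2, qaly=1.1)
        assert icer(a, cheaper_better).status == "dominant"
        dearer_worse = StrategyTotals("c", cost=11.0, ly=0.9, qaly=0.9)
        assert icer(a, dearer_worse).status == "dominated"

    def test_common_cost_cancels(self):
        a = StrategyTotals("a", cost=100.0, ly=1.0, qaly=1.0)
        b = StrategyTotals("b", cost=300.0, ly=2.0, qaly=2.0)
        base = icer(a, b)
        shifted = icer(
            StrategyTotals("a", cost=100.0 + 5000, ly=1.0, qaly=1.0),
            StrategyTotals("b", cost=300.0 + 5000, ly=2.0, qaly=2.0),
        )
        assert shifted.delta_cost == base.delta_cost
        assert shifted.icer == base.icer

    def test_qaly_never_exceeds_ly(self, model):
        res = model.evaluate()
        for s in (res.reference, res.comparator):
            assert s.qaly <= s.ly + 1e-12


class TestPriceLinearity:
    def test_icer_affine_in_pembrolizumab_price(self, model):
        # ICER at the base price equals the mean of the ICERs at +/-50% exactly
        base = model.evaluate().icer
        lo = model.evaluate({"cost_pembrolizumab": 5625.75 * 0.5}).icer
        hi = model.evaluate({"cost_pembrolizumab": 5625.75 * 1.5}).icer
        assert base == pytest.approx((lo + hi) / 2, rel=1e-9)
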