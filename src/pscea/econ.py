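"""Cost and QALY accrual over a cohort trace, and incremental results.

Regimen rules: drug acquisition costs multiply the start-of-cycle occupancy
of the state in which the drug is given (drugs are dispensed at visits, so
no half-cycle correction), capped at the regimen's maximum cycle count and
weighted by an uptake fraction.  Routine follow-up applies to PFS occupancy
and supportive care to PD occupancy, both half-cycle-corrected like the
utilities, which accrue continuously.  Grade >= 3 adverse-event management
enters as a one-off expected lump cost at model start (incidence x unit
cost, discount factor 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import ModelSettings, discount_factor, half_cycle_correct, life_years

STATES = ("pfs", "pd")


@dataclass(frozen=True)
class RegimenLine:
    """One drug line: per-cycle cost applied to a state's occupancy."""

    drug: str
    cost_per_cycle: float
    state: str  # "pfs" or "pd"
    max_cycles: int | None = None  # None = for as long as the state is occupied
    uptake_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.cost_per_cycle < 0:
            raise ValueError(f"{self.drug}: cost must be >= 0")
        if self.state not in STATES:
            raise ValueError(f"{self.drug}: unknown state {self.state!r}")
        if not 0 <= self.uptake_fraction <= 1:
            raise ValueError(f"{self.drug}: uptake fraction must lie in [0, 1]")
        if self.max_cycles is not None and self.max_cycles < 1:
            raise ValueError(f"{self.drug}: max_cycles must be >= 1 or None")


@dataclass(frozen=True)
class Utilities:
    """Health-state utility weights (dead = 0)."""

    pfs: float = 0.74
    pd: float = 0.58

    def __post_init__(self) -> None:
        for name, u in (("pfs", self.pfs), ("pd", self.pd)):
            if not 0 <= u <= 1:
                raise ValueError(f"utility {name} must lie in [0, 1], got {u}")


def drug_cost_vector(line: RegimenLine, trace: pd.DataFrame) -> np.ndarray:
    """Undiscounted per-cycle drug cost series for one regimen line."""
    occ = trace[line.state].to_numpy(float)
    cost = line.cost_per_cycle * line.uptake_fraction * occ
    if line.max_cycles is not None:
        cost[line.max_cycles:] = 0.0
    return cost


def ae_lump_cost(incidence: dict[str, float], unit_cost: dict[str, float]) -> float:
    """Expected adverse-event management cost: sum of incidence x unit cost."""
    total = 0.0
    for name, inc in incidence.items():
        if not 0 <= inc <= 1:
            raise ValueError(f"AE incidence for {name!r} must lie in [0, 1]")
        total += inc * unit_cost[name]
    return total


@dataclass(frozen=True)
class StrategyTotals:
    """Discounted totals for one strategy."""

    name: str
    cost: float
    ly: float
    qaly: float
    breakdown: dict = field(default_factory=dict)


def accrue(
    trace: pd.DataFrame,
    lines: list[RegimenLine],
    utilities: Utilities,
    followup_per_cycle: float,
    supportive_per_cycle: float,
    ae_lump: float,
    settings: ModelSettings,
    name: str = "strategy",
) -> StrategyTotals:
    """Total discounted cost, LY and QALY for one strategy over its trace."""
    disc = discount_factor(trace["cycle"].to_numpy(float), settings)
    pfs = trace["pfs"].to_numpy(float)
    pd_ = trace["pd"].to_numpy(float)

    qaly = float(np.sum(half_cycle_correct(utilities.pfs * pfs + utilities.pd * pd_) * disc)
                 * settings.cycle_years)
    ly = life_years(trace, settings)

    drug = {ln.drug: float(np.sum(drug_cost_vector(ln, trace) * disc)) for ln in lines}
    admin = float(np.sum(half_cycle_correct(followup_per_cycle * pfs) * disc))
    support = float(np.sum(half_cycle_correct(supportive_per_cycle * pd_) * disc))
    cost = ae_lump + sum(drug.values()) + admin + support
    return StrategyTotals(
        name=name, cost=cost, ly=ly, qaly=qaly,
        breakdown={"drugs": drug, "followup": admin, "supportive": support, "ae": ae_lump},
    )


@dataclass(frozen=True)
class CEResult:
    """Incremental cost-effectiveness of a comparator vs a reference strategy."""

    reference: StrategyTotals
    comparator: StrategyTotals
    wtp: float

    @property
    def delta_cost(self) -> float:
        return self.comparator.cost - self.reference.cost

    @property
    def delta_ly(self) -> float:
        return self.comparator.ly - self.reference.ly

    @property
    def delta_qaly(self) -> float:
        return self.comparator.qaly - self.reference.qaly

    @property
    def status(self) -> str:
        if abs(self.delta_qaly) < 1e-12:
            return "non-comparable" if abs(self.delta_cost) > 1e-9 else "equivalent"
        if self.delta_cost < 0 and self.delta_qaly > 0:
            return "dominant"
        if self.delta_cost > 0 and self.delta_qaly < 0:
            return "dominated"
        return "icer"

    @property
    def icer(self) -> float:
        """Incremental cost per QALY gained; +/-inf when effects are tied."""
        if abs(self.delta_qaly) < 1e-12:
            return float(np.sign(self.delta_cost)) * np.inf if abs(self.delta_cost) > 1e-9 else 0.0
        return self.delta_cost / self.delta_qaly

    @property
    def icer_per_ly(self) -> float:
        if abs(self.delta_ly) < 1e-12:
            return float(np.sign(self.delta_cost)) * np.inf if abs(self.delta_cost) > 1e-9 else 0.0
        return self.delta_cost / self.delta_ly

    def nmb(self, wtp: float | None = None) -> float:
        """Incremental net monetary benefit at a willingness-to-pay threshold."""
        w = self.wtp if wtp is None else wtp
        return w * self.delta_qaly - self.delta_cost

    @property
    def cost_effective(self) -> bool:
        return self.nmb() >= 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in (self.comparator, self.reference):
            rows.append({"strategy": s.name, "cost": s.cost, "ly": s.ly, "qaly": s.qaly})
        rows.append({
            "strategy": "incremental",
            "cost": self.delta_cost, "ly": self.delta_ly, "qaly": self.delta_qaly,
        })
        df = pd.DataFrame(rows)
        df.loc[df["strategy"] == "incremental", "cost_per_ly"] = self.icer_per_ly
        df.loc[df["strategy"] == "incremental", "cost_per_qaly"] = self.icer
        return df


def icer(reference: StrategyTotals, comparator: StrategyTotals, wtp: float = 31304.31) -> CEResult:
    """Incremental comparison of two strategies (comparator minus reference)."""
    return CEResult(reference=reference, comparator=comparator, wtp=wtp)
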