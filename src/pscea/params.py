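"""Model parameters: base-case values, ranges and sampling distributions.

Base-case inputs are the published model parameter table for first-line
pembrolizumab + chemotherapy vs placebo + chemotherapy in advanced
oesophageal cancer (2020 USD, Chinese healthcare-system perspective):
per-cycle drug acquisition costs, per-cycle administration costs, grade >= 3
adverse-event management costs, health-state utilities, hazard ratios with
95% CIs, and the 3% annual discount rate.  Ranges are 95% CIs where
published and +/-20% otherwise, except the pembrolizumab price which is
varied +/-50% of the base price.

Each parameter carries the sampling distribution used in probabilistic
sensitivity analysis: beta for utilities, gamma for costs (method-of-moments
from base value and range treated as a 95% interval) and lognormal for
hazard ratios from their CIs.  Parameters without a distribution (discount
rate, start age) enter one-way analysis only.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class Param:
    """One model parameter: base value, one-way bounds and PSA role."""

    name: str
    base: float
    low: float
    high: float
    dist: str | None  # beta | gamma | lognormal | None (one-way only)
    role: str  # utility | cost | hr | rate | age

    def __post_init__(self) -> None:
        if not self.low <= self.base <= self.high:
            raise ValueError(f"{self.name}: need low <= base <= high, got "
                             f"({self.low}, {self.base}, {self.high})")
        if self.role == "utility" and not (0 <= self.low and self.high <= 1):
            raise ValueError(f"{self.name}: utility bounds must lie in [0, 1]")
        if self.role in ("cost", "hr") and self.low < 0:
            raise ValueError(f"{self.name}: must be non-negative")


@dataclass(frozen=True)
class HazardRatio:
    """Point estimate with 95% CI; all positive, ci_low <= point <= ci_high."""

    point: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not (0 < self.ci_low <= self.point <= self.ci_high):
            raise ValueError(f"invalid hazard ratio {self}")


def _pm20(x: float) -> tuple[float, float]:
    return 0.8 * x, 1.2 * x


PEMBRO_COST = 5625.75  # $ per 3-week cycle (200 mg)

#: Second-line uptake after progression (fraction receiving paclitaxel).
UPTAKE_TREATMENT = 0.43
UPTAKE_CONTROL = 0.47

#: Treatment-duration caps, in cycles.
PEMBRO_MAX_CYCLES = 35
CHEMO_MAX_CYCLES = 6

#: Grade >= 3 adverse-event incidences per arm.  The source model table does
#: not print these; the values below are synthetic defaults with trial-like
#: magnitudes for an immunochemotherapy vs chemotherapy comparison, and are
#: config-overridable.  They enter only through a small one-off lump cost.
AE_INCIDENCE = {
    "treatment": {
        "nausea": 0.07,
        "anaemia": 0.12,
        "neutrophil_count_decreased": 0.17,
        "neutropenia": 0.19,
        "white_blood_cells_decreased": 0.09,
    },
    "control": {
        "nausea": 0.06,
        "anaemia": 0.10,
        "neutrophil_count_decreased": 0.14,
        "neutropenia": 0.16,
        "white_blood_cells_decreased": 0.07,
    },
}


def default_param_space() -> dict[str, Param]:
    """The full parameter table with bounds and PSA distributions."""
    params = [
        Param("hr_os", 0.73, 0.58, 0.88, "lognormal", "hr"),
        Param("hr_pfs", 0.65, 0.52, 0.78, "lognormal", "hr"),
        # drug acquisition, $ per cycle; pembrolizumab varied +/-50% of price
        Param("cost_pembrolizumab", PEMBRO_COST, 0.5 * PEMBRO_COST, 1.5 * PEMBRO_COST,
              "gamma", "cost"),
        Param("cost_fluorouracil", 256.67, 205.34, 308.01, "gamma", "cost"),
        Param("cost_cisplatin", 17.52, 14.01, 21.02, "gamma", "cost"),
        Param("cost_paclitaxel", 351.81, 281.44, 422.17, "gamma", "cost"),
        # health-state utilities
        Param("utility_pfs", 0.74, 0.59, 0.89, "beta", "utility"),
        Param("utility_pd", 0.58, 0.46, 0.70, "beta", "utility"),
        # administration, $ per cycle
        Param("cost_followup", 55.18, 44.14, 66.21, "gamma", "cost"),
        Param("cost_supportive", 125.47, 100.37, 150.56, "gamma", "cost"),
        # adverse-event management, $ per event (+/-20%)
        Param("cost_ae_nausea", 71.00, *_pm20(71.00), "gamma", "cost"),
        Param("cost_ae_anaemia", 73.68, *_pm20(73.68), "gamma", "cost"),
        Param("cost_ae_neutrophil_count_decreased", 466.00, *_pm20(466.00), "gamma", "cost"),
        Param("cost_ae_neutropenia", 466.00, *_pm20(466.00), "gamma", "cost"),
        Param("cost_ae_white_blood_cells_decreased", 466.00, *_pm20(466.00), "gamma", "cost"),
        # one-way-only structural parameters
        Param("discount", 0.03, 0.0, 0.05, None, "rate"),
        Param("start_age", 63.0, 55.0, 70.0, None, "age"),
    ]
    return {p.name: p for p in params}


def base_values(space: dict[str, Param] | None = None) -> dict[str, float]:
    space = space or default_param_space()
    return {name: p.base for name, p in space.items()}


@dataclass(frozen=True)
class EconDefaults:
    """Bundle of non-sampled structural economics inputs."""

    uptake_treatment: float = UPTAKE_TREATMENT
    uptake_control: float = UPTAKE_CONTROL
    pembro_max_cycles: int = PEMBRO_MAX_CYCLES
    chemo_max_cycles: int = CHEMO_MAX_CYCLES
    ae_incidence: dict = field(default_factory=lambda: {k: dict(v) for k, v in AE_INCIDENCE.items()})
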