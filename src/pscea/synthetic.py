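"""Trial-like synthetic survival data and fixtures.

Everything downstream of curve digitization is testable without access to the
original trial: this module simulates per-patient event times from calibrated
parametric distributions, censors them, and emits the artifacts a digitization
workflow would produce — a step-function survival curve sampled on a time
grid plus a number-at-risk table — together with a Gompertz–Makeham life
table standing in for national background mortality.

Default calibration reflects a two-arm first-line trial in advanced
oesophageal cancer: control overall survival median 9.8 months, control
progression-free survival median 5.8 months, hazard ratios 0.73 (OS) and
0.65 (PFS) for the immunotherapy arm, ~374 patients per arm, administrative
cutoff 22.6 months and a small dropout hazard.  Event times in the treated
arm are drawn so that S_trt(t) = S_ctrl(t)^HR (proportional hazards).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .distributions import DistSpec, InvalidParameterError

# Default study conditions for the synthetic trial.
N_PER_ARM = 374          # 749 randomized, ~1:1
OS_MEDIAN_CONTROL = 9.8  # months
PFS_MEDIAN_CONTROL = 5.8
OS_SHAPE = 1.5           # log-logistic shape; free parameter, plausible tail
PFS_SHAPE = 1.6
HR_OS = 0.73
HR_PFS = 0.65
ADMIN_CUTOFF = 22.6      # months of follow-up
DROPOUT_RATE = 0.01      # per-month dropout hazard


@dataclass(frozen=True)
class CensorSpec:
    """Right-censoring mechanism: administrative cutoff plus random dropout."""

    admin_cutoff: float = ADMIN_CUTOFF
    dropout_rate: float = DROPOUT_RATE

    def __post_init__(self) -> None:
        if not np.isfinite(self.admin_cutoff) or self.admin_cutoff <= 0:
            raise InvalidParameterError("admin_cutoff must be a positive finite number of months")
        if self.dropout_rate < 0:
            raise InvalidParameterError("dropout_rate must be >= 0")


def calibrate_loglogistic(median: float, shape: float) -> DistSpec:
    """Log-logistic distribution with the given median survival.

    Under S(t) = 1 / (1 + (t/alpha)^k) the scale alpha is exactly the median,
    so calibration to a printed median is immediate; the shape k controls the
    tail and is a free parameter.
    """
    if not median > 0 or not shape > 0:
        raise InvalidParameterError("median and shape must be positive")
    return DistSpec("loglogistic", {"scale": float(median), "shape": float(shape)})


def simulate_ipd(
    spec: DistSpec,
    censor: CensorSpec,
    n: int,
    seed: int | np.random.Generator,
    hr: float = 1.0,
) -> pd.DataFrame:
    """Simulate right-censored individual patient data.

    Event times are drawn by inverse transform from ``spec``; with ``hr``
    different from 1 the draw uses S(t)^hr, i.e. a proportional-hazards
    transform of the reference distribution.  Observed time is the minimum of
    event time, exponential dropout time and the administrative cutoff; the
    event flag is 1 iff the event time is the minimum.
    """
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    if hr <= 0:
        raise InvalidParameterError("hr must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = rng.uniform(size=n)
    # S_adj(t) = S(t)^hr = u  =>  S(t) = u^(1/hr)
    t_event = spec.ppf_survival(np.power(u, 1.0 / hr))
    if censor.dropout_rate > 0:
        t_drop = rng.exponential(1.0 / censor.dropout_rate, size=n)
    else:
        t_drop = np.full(n, np.inf)
    t_cens = np.minimum(t_drop, censor.admin_cutoff)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    # guard against zero observed times (degenerate cutoffs)
    time = np.maximum(time, 1e-9)
    return pd.DataFrame({"time_months": time, "event": event})


def make_km_artifacts(
    ipd: pd.DataFrame,
    grid_step: float = 0.5,
    risk_interval: float = 3.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Produce the artifacts of a curve-digitization workflow.

    Returns a digitized curve — the product-limit estimate sampled on a
    regular time grid (step-function value at each grid time) — and a
    number-at-risk table counting subjects with observed time >= each
    interval boundary.
    """
    if len(ipd) == 0:
        raise ValueError("empty IPD")
    if grid_step <= 0 or risk_interval <= 0:
        raise ValueError("grid_step and risk_interval must be positive")
    time = ipd["time_months"].to_numpy(float)
    event = ipd["event"].to_numpy(int)
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    t_max = float(time.max())
    grid = np.arange(0.0, t_max + grid_step / 2, grid_step)
    surv = kmf.survival_function_at_times(grid).to_numpy(float)
    curve = pd.DataFrame({"time_months": grid, "survival": surv})
    bounds = np.arange(0.0, t_max + risk_interval / 2, risk_interval)
    n_at_risk = np.array([(time >= b).sum() for b in bounds], int)
    risk = pd.DataFrame({"time_months": bounds, "n_at_risk": n_at_risk})
    return curve, risk


def make_life_table(
    a: float = 0.001,
    b: float = 5e-5,
    c: float = 1.09,
    max_age: int = 100,
) -> pd.DataFrame:
    """Gompertz–Makeham annual death probabilities, one row per year of age.

    q(age) = 1 - exp(-(a + b * c^age)), clipped to [0, 1]; the terminal age
    carries q = 1 so a cohort model can never outlive the table.
    """
    if not (b > 0 and c > 0):
        raise InvalidParameterError("b and c must be positive")
    if max_age > 120:
        raise InvalidParameterError("max_age must be <= 120")
    for v in (a, b, c):
        if not np.isfinite(v):
            raise InvalidParameterError("life-table parameters must be finite")
    ages = np.arange(0, max_age + 1)
    q = 1.0 - np.exp(-(a + b * np.power(c, ages.astype(float))))
    q = np.clip(q, 0.0, 1.0)
    q[-1] = 1.0
    return pd.DataFrame({"age": ages, "q_annual": q})


def default_fixture_bundle(
    seed: int,
    n_per_arm: int = N_PER_ARM,
    grid_step: float = 0.5,
    risk_interval: float = 3.0,
) -> dict:
    """Generate the full default synthetic study: IPD, curves and risk tables
    for both arms and both endpoints, plus a life table.

    Keys: ``ipd``, ``curves``, ``risk`` are dicts indexed by
    ``(arm, endpoint)`` with arm in {"control", "treatment"} and endpoint in
    {"os", "pfs"}; ``life_table`` is a DataFrame; ``specs`` holds the control
    generating distributions.
    """
    rng = np.random.default_rng(seed)
    censor = CensorSpec()
    specs = {
        "os": calibrate_loglogistic(OS_MEDIAN_CONTROL, OS_SHAPE),
        "pfs": calibrate_loglogistic(PFS_MEDIAN_CONTROL, PFS_SHAPE),
    }
    hrs = {"os": HR_OS, "pfs": HR_PFS}
    ipd, curves, risk = {}, {}, {}
    for endpoint in ("os", "pfs"):
        for arm in ("control", "treatment"):
            hr = 1.0 if arm == "control" else hrs[endpoint]
            df = simulate_ipd(specs[endpoint], censor, n_per_arm, rng, hr=hr)
            ipd[(arm, endpoint)] = df
            curves[(arm, endpoint)], risk[(arm, endpoint)] = make_km_artifacts(
                df, grid_step=grid_step, risk_interval=risk_interval
            )
    return {
        "ipd": ipd,
        "curves": curves,
        "risk": risk,
        "life_table": make_life_table(),
        "specs": specs,
        "hrs": hrs,
        "censor": censor,
        "n_per_arm": n_per_arm,
    }
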