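"""Sensitivity, threshold, probabilistic and subgroup analyses.

One-way analysis sets each parameter to its lower and upper bound with all
others at base (two full model runs per parameter) and reports tornado rows
sorted by ICER spread.  The probabilistic sensitivity analysis draws beta
utilities and gamma costs by method of moments (sd = range / 3.92, treating
the published range as a 95% interval) and lognormal hazard ratios from
their CIs, evaluates the full model per draw, and summarises as a
cost-effectiveness acceptability curve: the fraction of draws with positive
incremental net monetary benefit at each willingness-to-pay value.

The threshold analysis exploits that the ICER is affine in the
pembrolizumab cycle price (the price enters only the treated arm's cost,
linearly), so the price at which the ICER equals the WTP solves in closed
form from two model runs and is confirmed by a third.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .econ import CEResult
from .params import Param

#: Default CEAC willingness-to-pay grid, $/QALY.
WTP_GRID = np.arange(0.0, 340_000.0 + 1, 2_500.0)

#: Published subgroup hazard ratios (OS, PFS).
SUBGROUPS = {
    "oesophageal_squamous_cell_carcinoma": (0.72, 0.65),
    "pd_l1_cps_ge_10": (0.62, 0.51),
}


def run_base_case(model) -> CEResult:
    """Deterministic run at base parameters."""
    return model.evaluate()


def one_way(model, space: dict[str, Param] | None = None) -> pd.DataFrame:
    """Tornado table: ICER at each parameter's low and high bound.

    Returns rows (parameter, low, high, icer_low, icer_high, spread) sorted
    by spread descending.
    """
    space = space or model.param_space
    unknown = set(space) - set(model.param_space)
    if unknown:
        raise KeyError(f"parameter(s) not in model: {sorted(unknown)}")
    rows = []
    for name, p in space.items():
        icer_low = model.evaluate({name: p.low}).icer
        icer_high = model.evaluate({name: p.high}).icer
        rows.append({
            "parameter": name,
            "low": p.low,
            "high": p.high,
            "icer_low": icer_low,
            "icer_high": icer_high,
            "spread": abs(icer_high - icer_low),
        })
    df = pd.DataFrame(rows).sort_values("spread", ascending=False, ignore_index=True)
    return df


def _beta_moments(mean: float, sd: float) -> tuple[float, float]:
    """Beta shape parameters by method of moments; rescales infeasible variance."""
    max_sd2 = mean * (1 - mean)
    sd2 = sd**2
    if sd2 >= max_sd2:
        warnings.warn(f"beta variance {sd2:.4g} infeasible for mean {mean}; scaling down")
        sd2 = 0.95 * max_sd2
    nu = mean * (1 - mean) / sd2 - 1.0
    return mean * nu, (1 - mean) * nu


def _draw(p: Param, rng: np.random.Generator, n: int) -> np.ndarray:
    sd = (p.high - p.low) / 3.92
    if sd == 0 or p.dist is None:
        return np.full(n, p.base)
    if p.dist == "beta":
        a, b = _beta_moments(p.base, sd)
        return rng.beta(a, b, size=n)
    if p.dist == "gamma":
        shape = (p.base / sd) ** 2
        scale = sd**2 / p.base
        return rng.gamma(shape, scale, size=n)
    if p.dist == "lognormal":
        sd_log = (np.log(p.high) - np.log(p.low)) / 3.92
        return rng.lognormal(np.log(p.base), sd_log, size=n)
    raise ValueError(f"unknown distribution {p.dist!r} for {p.name}")


def psa(model, n: int = 1000, seed: int = 0,
        space: dict[str, Param] | None = None) -> pd.DataFrame:
    """Probabilistic sensitivity analysis: n seeded Monte-Carlo model runs.

    Returns one row per draw with the sampled parameter values and the
    paired incremental outcomes (delta_cost, delta_qaly, icer, nmb at the
    model's WTP).  Bit-reproducible for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    space = space or model.param_space
    rng = np.random.default_rng(seed)
    sampled = {name: _draw(p, rng, n) for name, p in space.items() if p.dist is not None}
    rows = []
    for i in range(n):
        overrides = {name: float(v[i]) for name, v in sampled.items()}
        res = model.evaluate(overrides)
        row = dict(overrides)
        row.update({
            "delta_cost": res.delta_cost,
            "delta_qaly": res.delta_qaly,
            "icer": res.icer,
            "nmb": res.nmb(),
        })
        rows.append(row)
    return pd.DataFrame(rows)


def ceac(samples: pd.DataFrame, wtp_grid=None) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve from PSA samples.

    P(wtp) = fraction of draws with wtp * delta_qaly - delta_cost >= 0.
    """
    if len(samples) == 0:
        raise ValueError("no PSA samples")
    grid = np.asarray(WTP_GRID if wtp_grid is None else wtp_grid, float)
    dq = samples["delta_qaly"].to_numpy(float)
    dc = samples["delta_cost"].to_numpy(float)
    prob = [(w * dq - dc >= 0).mean() for w in grid]
    return pd.DataFrame({"wtp": grid, "probability": prob})


def probability_cost_effective(samples: pd.DataFrame, wtp: float) -> float:
    """Fraction of PSA draws cost-effective at a single WTP value."""
    dq = samples["delta_qaly"].to_numpy(float)
    dc = samples["delta_cost"].to_numpy(float)
    return float((wtp * dq - dc >= 0).mean())


def threshold_price(model, wtp: float | None = None, price_param: str = "cost_pembrolizumab") -> dict:
    """Cycle price at which the ICER falls to the WTP threshold.

    Uses the affine dependence of incremental cost on the price: two model
    runs identify intercept and slope, the threshold price solves in closed
    form, and a confirmation run checks |ICER - wtp| / wtp <= 1e-4.
    """
    wtp = model.settings.wtp if wtp is None else wtp
    base_price = model.param_space[price_param].base
    res_base = model.evaluate()
    res_zero = model.evaluate({price_param: base_price * 0.5})
    dq = res_base.delta_qaly
    slope = (res_base.delta_cost - res_zero.delta_cost) / (base_price * 0.5)
    intercept = res_base.delta_cost - slope * base_price
    if res_base.icer <= wtp:
        return {"price": base_price, "reduction_pct": 0.0, "icer": res_base.icer,
                "feasible": True, "note": "already cost-effective at base price"}
    price = (wtp * dq - intercept) / slope
    if price < 0:
        return {"price": 0.0, "reduction_pct": 100.0,
                "icer": model.evaluate({price_param: 0.0}).icer,
                "feasible": False, "note": "ICER exceeds WTP even at zero price"}
    check = model.evaluate({price_param: price})
    if abs(check.icer - wtp) / wtp > 1e-4:
        raise RuntimeError(f"threshold confirmation failed: ICER {check.icer} vs WTP {wtp}")
    return {
        "price": float(price),
        "reduction_pct": float(100.0 * (1.0 - price / base_price)),
        "icer": float(check.icer),
        "feasible": True,
    }


def subgroup_run(model, hr_os: float, hr_pfs: float) -> CEResult:
    """Rerun the full pipeline with subgroup hazard ratios."""
    if hr_os <= 0 or hr_pfs <= 0:
        raise ValueError("hazard ratios must be positive")
    return model.evaluate({"hr_os": hr_os, "hr_pfs": hr_pfs})


def subgroup_table(model, subgroups: dict[str, tuple[float, float]] | None = None) -> pd.DataFrame:
    """Subgroup results shaped like the published subgroup table."""
    subgroups = subgroups or SUBGROUPS
    rows = []
    for name, (hr_os, hr_pfs) in subgroups.items():
        res = subgroup_run(model, hr_os, hr_pfs)
        rows.append({
            "subgroup": name, "hr_os": hr_os, "hr_pfs": hr_pfs,
            "delta_cost": res.delta_cost, "delta_qaly": res.delta_qaly, "icer": res.icer,
        })
    return pd.DataFrame(rows)
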