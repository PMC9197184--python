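"""Closed-form survival distributions used for parametric curve fitting.

Five families are supported: exponential, Weibull, log-normal, log-logistic
and Gompertz.  Each family exposes the survival function, hazard, log-density
and log-survival on the time scale (months), a quantile function for
simulation, and method-of-moments style starting values for maximum
likelihood.  Parameters are stored on their natural scale; all are strictly
positive except the Gompertz shape, which may be any real (negative values
give a decreasing hazard and a defective distribution — admissible for
censored-data likelihoods).

Parameterisations:

- exponential(rate):        S(t) = exp(-rate * t)
- weibull(scale, shape):    S(t) = exp(-(t/scale)^shape)
- lognormal(mu, sigma):     log T ~ Normal(mu, sigma^2)
- loglogistic(scale, shape): S(t) = 1 / (1 + (t/scale)^shape)
- gompertz(shape, rate):    h(t) = rate * exp(shape * t)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import special, stats

FAMILIES = ("exponential", "weibull", "lognormal", "loglogistic", "gompertz")

# Parameter names, in fixed order, per family.
PARAM_NAMES: dict[str, tuple[str, ...]] = {
    "exponential": ("rate",),
    "weibull": ("scale", "shape"),
    "lognormal": ("mu", "sigma"),
    "loglogistic": ("scale", "shape"),
    "gompertz": ("shape", "rate"),
}

# Parameters that must be strictly positive (others are unconstrained reals).
_POSITIVE: dict[str, tuple[str, ...]] = {
    "exponential": ("rate",),
    "weibull": ("scale", "shape"),
    "lognormal": ("sigma",),
    "loglogistic": ("scale", "shape"),
    "gompertz": ("rate",),
}


class InvalidParameterError(ValueError):
    """A distribution parameter violates its constraint."""


@dataclass(frozen=True)
class DistSpec:
    """A parametric survival distribution: family name plus parameters."""

    family: str
    params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise InvalidParameterError(
                f"unknown family {self.family!r}; expected one of {FAMILIES}"
            )
        expected = PARAM_NAMES[self.family]
        if set(self.params) != set(expected):
            raise InvalidParameterError(
                f"{self.family} needs parameters {expected}, got {tuple(self.params)}"
            )
        for name in _POSITIVE[self.family]:
            v = float(self.params[name])
            if not np.isfinite(v) or v <= 0:
                raise InvalidParameterError(
                    f"{self.family} parameter {name!r} must be positive, got {v}"
                )
        for name, v in self.params.items():
            if not np.isfinite(float(v)):
                raise InvalidParameterError(f"non-finite parameter {name}={v}")

    @property
    def n_params(self) -> int:
        return len(PARAM_NAMES[self.family])

    def ordered_params(self) -> np.ndarray:
        return np.array([self.params[k] for k in PARAM_NAMES[self.family]], float)

    # -- survival quantities ------------------------------------------------

    def sf(self, t):
        """Survival function S(t)."""
        t = np.asarray(t, float)
        if np.any(t < 0):
            raise ValueError("time must be non-negative")
        return np.exp(self.logsf(t))

    def logsf(self, t):
        t = np.asarray(t, float)
        p = self.params
        if self.family == "exponential":
            return -p["rate"] * t
        if self.family == "weibull":
            return -np.power(t / p["scale"], p["shape"], where=t > 0, out=np.zeros_like(t))
        if self.family == "lognormal":
            with np.errstate(divide="ignore"):
                z = np.where(t > 0, (np.log(np.maximum(t, 1e-300)) - p["mu"]) / p["sigma"], -np.inf)
            return stats.norm.logsf(z)
        if self.family == "loglogistic":
            x = np.power(t / p["scale"], p["shape"], where=t > 0, out=np.zeros_like(t))
            return -np.log1p(x)
        # gompertz: H(t) = rate/shape * (exp(shape t) - 1); -> rate*t as shape->0
        a, b = p["shape"], p["rate"]
        if abs(a) < 1e-9:
            return -b * t * (1 + a * t / 2)
        return -(b / a) * np.expm1(a * t)

    def logpdf(self, t):
        t = np.asarray(t, float)
        return self.loghazard(t) + self.logsf(t)

    def loghazard(self, t):
        t = np.asarray(t, float)
        p = self.params
        with np.errstate(divide="ignore"):
            logt = np.log(np.maximum(t, 1e-300))
        if self.family == "exponential":
            return np.full_like(t, np.log(p["rate"]))
        if self.family == "weibull":
            k, lam = p["shape"], p["scale"]
            return np.log(k / lam) + (k - 1) * (logt - np.log(lam))
        if self.family == "lognormal":
            # h = f / S with f the lognormal density
            z = (logt - p["mu"]) / p["sigma"]
            logf = stats.norm.logpdf(z) - np.log(p["sigma"]) - logt
            return logf - stats.norm.logsf(z)
        if self.family == "loglogistic":
            k, alpha = p["shape"], p["scale"]
            x = (k - 1) * (logt - np.log(alpha))
            return np.log(k / alpha) + x - np.log1p(np.exp(np.minimum(k * (logt - np.log(alpha)), 700)))
        a, b = p["shape"], p["rate"]
        return np.log(b) + a * t

    def hazard(self, t):
        t = np.asarray(t, float)
        if np.any(t < 0):
            raise ValueError("time must be non-negative")
        return np.exp(self.loghazard(t))

    def ppf_survival(self, s):
        """Time t at which S(t) = s (quantile of survival); vectorised."""
        s = np.asarray(s, float)
        if np.any((s <= 0) | (s > 1)):
            raise ValueError("survival quantile must lie in (0, 1]")
        p = self.params
        if self.family == "exponential":
            return -np.log(s) / p["rate"]
        if self.family == "weibull":
            return p["scale"] * np.power(-np.log(s), 1.0 / p["shape"])
        if self.family == "lognormal":
            return np.exp(p["mu"] + p["sigma"] * stats.norm.isf(s))
        if self.family == "loglogistic":
            return p["scale"] * np.power((1.0 - s) / s, 1.0 / p["shape"])
        a, b = p["shape"], p["rate"]
        if abs(a) < 1e-9:
            return -np.log(s) / b
        arg = 1.0 - (a / b) * np.log(s)
        # defective for a < 0: quantiles beyond the survival plateau are inf
        return np.where(arg > 0, np.log(np.maximum(arg, 1e-300)) / a, np.inf)

    def mean(self, upper: float = np.inf) -> float:
        """(Restricted) mean survival time, by closed form where available."""
        p = self.params
        if np.isinf(upper):
            if self.family == "exponential":
                return 1.0 / p["rate"]
            if self.family == "weibull":
                return p["scale"] * special.gamma(1 + 1 / p["shape"])
            if self.family == "lognormal":
                return float(np.exp(p["mu"] + p["sigma"] ** 2 / 2))
            if self.family == "loglogistic":
                k = p["shape"]
                if k <= 1:
                    return np.inf
                return p["scale"] * (np.pi / k) / np.sin(np.pi / k)
        from scipy.integrate import quad

        hi = min(upper, float(self.ppf_survival(1e-12)))
        return float(quad(lambda t: self.sf(t), 0, hi, limit=200)[0])


def loglikelihood(spec: DistSpec, time, event) -> float:
    """Right-censored log-likelihood: sum of log f over events, log S over censorings."""
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    ll = float(np.sum(spec.logsf(time[~event])))
    ll += float(np.sum(spec.logpdf(time[event])))
    return ll


def starting_values(family: str, time, event) -> dict[str, float]:
    """Rough moment-based starting values for MLE."""
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    t_ev = time[event] if event.any() else time
    mean_t = float(np.mean(t_ev))
    med_t = float(np.median(t_ev))
    rate0 = event.sum() / max(float(time.sum()), 1e-12) if event.any() else 1.0 / mean_t
    if family == "exponential":
        return {"rate": rate0}
    if family == "weibull":
        return {"scale": max(mean_t, 1e-6), "shape": 1.2}
    if family == "lognormal":
        logs = np.log(np.maximum(t_ev, 1e-12))
        return {"mu": float(np.mean(logs)), "sigma": max(float(np.std(logs)), 0.2)}
    if family == "loglogistic":
        return {"scale": max(med_t, 1e-6), "shape": 1.5}
    if family == "gompertz":
        return {"shape": 0.01, "rate": max(rate0, 1e-6)}
    raise InvalidParameterError(f"unknown family {family!r}")


def to_unconstrained(family: str, params: Mapping[str, float]) -> np.ndarray:
    """Map natural parameters to the unconstrained optimisation scale (log for positives)."""
    out = []
    for name in PARAM_NAMES[family]:
        v = float(params[name])
        out.append(np.log(v) if name in _POSITIVE[family] else v)
    return np.array(out)


def from_unconstrained(family: str, x: np.ndarray) -> DistSpec:
    params = {}
    for name, xi in zip(PARAM_NAMES[family], x):
        params[name] = float(np.exp(xi)) if name in _POSITIVE[family] else float(xi)
    return DistSpec(family, params)
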