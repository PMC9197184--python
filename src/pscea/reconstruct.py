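"""Pseudo individual-patient data from digitized Kaplan–Meier curves.

Published KM plots plus their number-at-risk tables contain almost all the
information in the underlying censored sample.  The reconstruction here
follows the standard iterative algorithm: within each interval between
consecutive risk-table times, a censoring count is solved for such that,
after distributing those censorings evenly through the interval and reading
event counts off the digitized survival drops, the implied number at risk at
the next boundary matches the published table.

This implementation is fully deterministic (no RNG): censoring times are
placed at evenly spaced midpoints within the interval, so repeated runs and
downstream fits are bit-reproducible.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

# Digitization noise tolerance: survival increases up to this size are
# clamped to the running minimum; anything larger is treated as a real
# input error.
MONOTONE_TOL = 0.005


class InputValidationError(ValueError):
    """Digitized curve / risk table inputs are inconsistent."""


def km_estimate(ipd: pd.DataFrame) -> pd.DataFrame:
    """Product-limit survival estimate of an IPD table.

    Returns a step function as a DataFrame (time_months, survival) including
    the origin (0, 1).  Ties are handled events-before-censorings, the
    product-limit convention.
    """
    if len(ipd) == 0:
        raise InputValidationError("empty IPD")
    kmf = KaplanMeierFitter()
    kmf.fit(ipd["time_months"].to_numpy(float), ipd["event"].to_numpy(int))
    sf = kmf.survival_function_
    return pd.DataFrame(
        {"time_months": sf.index.to_numpy(float), "survival": sf.iloc[:, 0].to_numpy(float)}
    )


def km_at(curve: pd.DataFrame, times) -> np.ndarray:
    """Evaluate a step-function curve at arbitrary times (last value carried forward)."""
    t = curve["time_months"].to_numpy(float)
    s = curve["survival"].to_numpy(float)
    times = np.atleast_1d(np.asarray(times, float))
    idx = np.searchsorted(t, times, side="right") - 1
    out = np.where(idx >= 0, s[np.clip(idx, 0, len(s) - 1)], 1.0)
    return out


def _validate(curve: pd.DataFrame, risk: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Check invariants, repair pixel-level noise, return clean (t, S) arrays."""
    t = curve["time_months"].to_numpy(float)
    s = curve["survival"].to_numpy(float).copy()
    if len(t) == 0:
        raise InputValidationError("empty digitized curve")
    if np.any(np.diff(t) <= 0):
        raise InputValidationError("curve times must be strictly increasing")
    if np.any((s < -1e-9) | (s > 1 + 1e-9)):
        raise InputValidationError("survival values must lie in [0, 1]")
    # monotonicity repair: tolerate digitization noise, surface real errors
    running = s[0]
    bad_rows = []
    for i in range(1, len(s)):
        if s[i] > running + MONOTONE_TOL:
            bad_rows.append(i)
        running = min(running, s[i])
        s[i] = running
    if bad_rows:
        raise InputValidationError(
            f"survival increases beyond tolerance {MONOTONE_TOL} at curve rows {bad_rows}"
        )
    rt = risk["time_months"].to_numpy(float)
    rn = risk["n_at_risk"].to_numpy(float)
    if len(rt) < 2:
        raise InputValidationError("risk table needs at least 2 rows")
    if np.any(np.diff(rt) <= 0):
        raise InputValidationError("risk-table times must be increasing")
    inc = np.where(np.diff(rn) > 0)[0]
    if len(inc):
        raise InputValidationError(f"n_at_risk increases at risk-table rows {list(inc + 1)}")
    if rn[0] <= 0:
        raise InputValidationError("initial number at risk must be positive")
    return t, s


def _pass_interval(
    n_start: int,
    s_run: float,
    click_t: np.ndarray,
    click_s: np.ndarray,
    t_lo: float,
    t_hi: float,
    n_censor: int,
):
    """Walk one risk-table interval with a fixed censoring count.

    Censorings are placed at evenly spaced midpoints of the interval; at each
    digitized click time the event count is the rounded product-limit drop
    given the current at-risk count.  Returns (events, censorings, n_end,
    s_end) with events/censorings lists of (time, count).
    """
    if n_censor > 0:
        cens_times = t_lo + (np.arange(n_censor) + 0.5) * (t_hi - t_lo) / n_censor
    else:
        cens_times = np.empty(0)
    marks = [(t, "click", s) for t, s in zip(click_t, click_s)]
    marks += [(t, "cens", np.nan) for t in cens_times]
    marks.sort(key=lambda m: (m[0], m[1]))  # censorings before clicks at ties
    n = n_start
    s = s_run
    events, censorings = [], []
    for t, kind, sk in marks:
        if kind == "cens":
            if n > 0:
                censorings.append((t, 1))
                n -= 1
        else:
            if n <= 0 or s <= 0:
                continue
            d = int(round(n * (1.0 - sk / s)))
            d = max(0, min(d, n))
            if d > 0:
                events.append((t, d))
                s *= 1.0 - d / n
                n -= d
    return events, censorings, n, s


def reconstruct_ipd(
    curve: pd.DataFrame,
    risk: pd.DataFrame,
    total_events: int | None = None,
) -> pd.DataFrame:
    """Reconstruct pseudo-IPD from a digitized curve and a number-at-risk table.

    Per risk interval the censoring count is solved by fixed-point iteration
    so that the implied at-risk count at the next boundary matches the table;
    beyond the last boundary remaining subjects are censored at the final
    curve time.  If ``total_events`` is given, a final pass converts the
    latest censorings/events so the overall event count matches it.

    Output sample size equals the initial number at risk and conservation
    (events + censorings + carried-forward = entering at-risk) holds exactly
    per interval.
    """
    t, s = _validate(curve, risk)
    rt = risk["time_months"].to_numpy(float)
    rn = risk["n_at_risk"].to_numpy(int)
    if rt[0] > t[0] + 1e-9:
        raise InputValidationError("curve must cover the first risk-table time")

    records: list[tuple[float, int]] = []  # (time, event_flag)
    n_cur = int(rn[0])
    s_run = 1.0
    boundaries = list(rt) + [t[-1] + 1e-9]
    for i in range(len(rt)):
        t_lo, t_hi = boundaries[i], boundaries[i + 1]
        if t_hi <= t_lo:
            continue
        in_iv = (t > t_lo + 1e-12) & (t <= t_hi + 1e-12)
        click_t, click_s = t[in_iv], s[in_iv]
        last = i == len(rt) - 1
        if not last:
            target = int(rn[i + 1])
            c = max(0, n_cur - target)  # initial guess: all attrition is censoring
            best = None
            seen = set()
            for _ in range(60):
                ev, ce, n_end, s_end = _pass_interval(n_cur, s_run, click_t, click_s, t_lo, t_hi, c)
                gap = n_end - target
                if best is None or abs(gap) < abs(best[0]):
                    best = (gap, c, ev, ce, n_end, s_end)
                if gap == 0 or c in seen:
                    break
                seen.add(c)
                c = int(np.clip(c + gap, 0, n_cur))
            _, c, ev, ce, n_end, s_end = best
        else:
            ev, ce, n_end, s_end = _pass_interval(n_cur, s_run, click_t, click_s, t_lo, t_hi, 0)
            # everyone still at risk at the end of the curve is censored there
            if n_end > 0:
                ce = ce + [(t[-1], n_end)]
                n_end = 0
        for tt, d in ev:
            records.extend([(tt, 1)] * d)
        for tt, d in ce:
            records.extend([(tt, 0)] * d)
        n_cur, s_run = n_end, s_end

    if total_events is not None:
        records.sort(key=lambda r: r[0])
        n_ev = sum(e for _, e in records)
        diff = total_events - n_ev
        if diff > 0:  # convert latest censorings to events
            for j in range(len(records) - 1, -1, -1):
                if diff == 0:
                    break
                if records[j][1] == 0:
                    records[j] = (records[j][0], 1)
                    diff -= 1
        elif diff < 0:  # convert latest events to censorings
            for j in range(len(records) - 1, -1, -1):
                if diff == 0:
                    break
                if records[j][1] == 1:
                    records[j] = (records[j][0], 0)
                    diff += 1

    if not records:
        raise InputValidationError("reconstruction produced no records")
    records.sort(key=lambda r: r[0])
    out = pd.DataFrame(records, columns=["time_months", "event"])
    out["time_months"] = np.maximum(out["time_months"].to_numpy(float), 1e-9)
    return out
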