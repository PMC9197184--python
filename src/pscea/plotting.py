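"""Optional plotting helpers: tornado diagram and CEAC.

Thin matplotlib layer over the analysis tables; everything here renders data
the analyses already computed.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def plot_tornado(tornado: pd.DataFrame, base_icer: float, top: int = 12, ax=None):
    """Horizontal tornado diagram of one-way ICER spreads."""
    df = tornado.head(top).iloc[::-1]
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 0.4 * len(df) + 1))
    lo = df[["icer_low", "icer_high"]].min(axis=1)
    hi = df[["icer_low", "icer_high"]].max(axis=1)
    ax.barh(df["parameter"], hi - lo, left=lo, color="#4878a8")
    ax.axvline(base_icer, color="k", lw=1, ls="--", label="base-case ICER")
    ax.set_xlabel("ICER, $/QALY")
    ax.legend()
    return ax


def plot_ceac(ceac: pd.DataFrame, wtp: float | None = None, ax=None):
    """Probability cost-effective vs willingness-to-pay."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.plot(ceac["wtp"], ceac["probability"], color="#a84848")
    if wtp is not None:
        ax.axvline(wtp, color="k", lw=1, ls="--", label=f"WTP ${wtp:,.0f}")
        ax.legend()
    ax.set_xlabel("Willingness-to-pay, $/QALY")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(-0.02, 1.02)
    return ax
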