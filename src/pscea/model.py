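"""The decision model: a statsmodels-style Model/Results pair.

:class:`CostEffectivenessModel` bundles the fitted control-arm OS and PFS
curves, a life table and the economic parameter table; ``fit()`` evaluates
the deterministic base case and returns :class:`CEAResults`, which carries
the incremental estimates, a ``summary()`` table and methods for the
sensitivity, threshold, probabilistic and subgroup analyses.

Two constructors cover the usual entry points: ``from_ipd`` fits the five
candidate survival families to control-arm pseudo-IPD and selects by AIC;
``from_synthetic`` runs the whole upstream pipeline (simulate a trial,
emit digitized-curve artifacts, reconstruct pseudo-IPD, fit, select) from a
single seed.  The comparator arm is driven by hazard ratios applied to the
control fits, which is what makes HR-based sensitivity and subgroup
analyses coherent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from . import synthetic
from .cohort import ModelSettings, build_trace
from .econ import CEResult, RegimenLine, Utilities, accrue, ae_lump_cost, icer
from .params import EconDefaults, Param, base_values, default_param_space
from .reconstruct import reconstruct_ipd
from .survival import SurvivalFit, apply_hr, fit_all, select_best


class CostEffectivenessModel:
    """Partitioned-survival cost-effectiveness model of two strategies.

    Parameters
    ----------
    os_control, pfs_control : objects with a vectorised ``sf(t_months)``
        Control-arm survival curves (typically :class:`SurvivalFit`).
    life_table : DataFrame (age, q_annual)
        Background mortality; defaults to the package's Gompertz–Makeham
        fixture emulating a national life table.
    param_space : mapping name -> :class:`Param`
        Parameter table with bounds and PSA distributions; defaults to the
        published base-case table.
    settings : :class:`ModelSettings`
    econ : :class:`EconDefaults`
        Structural economics inputs (uptake fractions, cycle caps, AE
        incidences).
    """

    def __init__(
        self,
        os_control,
        pfs_control,
        life_table: pd.DataFrame | None = None,
        param_space: Mapping[str, Param] | None = None,
        settings: ModelSettings | None = None,
        econ: EconDefaults | None = None,
    ) -> None:
        self.os_control = os_control
        self.pfs_control = pfs_control
        self.life_table = life_table if life_table is not None else synthetic.make_life_table()
        self.param_space = dict(param_space or default_param_space())
        self.settings = settings or ModelSettings()
        self.econ = econ or EconDefaults()
        self.fit_reports: dict = {}

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_ipd(
        cls,
        os_ipd: pd.DataFrame,
        pfs_ipd: pd.DataFrame,
        **kwargs,
    ) -> "CostEffectivenessModel":
        """Fit all candidate families to control-arm IPD and select by AIC."""
        os_fits = fit_all(os_ipd)
        pfs_fits = fit_all(pfs_ipd)
        model = cls(select_best(os_fits), select_best(pfs_fits), **kwargs)
        model.fit_reports = {"os": os_fits, "pfs": pfs_fits}
        return model

    @classmethod
    def from_synthetic(
        cls,
        seed: int,
        n_per_arm: int = synthetic.N_PER_ARM,
        reconstruct: bool = True,
        **kwargs,
    ) -> "CostEffectivenessModel":
        """Full upstream pipeline from a seed: simulate, digitize, reconstruct, fit.

        With ``reconstruct=False`` the simulated IPD is fitted directly,
        skipping the digitization/reconstruction round trip.
        """
        bundle = synthetic.default_fixture_bundle(seed, n_per_arm=n_per_arm)
        if reconstruct:
            os_ipd = reconstruct_ipd(bundle["curves"][("control", "os")],
                                     bundle["risk"][("control", "os")])
            pfs_ipd = reconstruct_ipd(bundle["curves"][("control", "pfs")],
                                      bundle["risk"][("control", "pfs")])
        else:
            os_ipd = bundle["ipd"][("control", "os")]
            pfs_ipd = bundle["ipd"][("control", "pfs")]
        kwargs.setdefault("life_table", bundle["life_table"])
        model = cls.from_ipd(os_ipd, pfs_ipd, **kwargs)
        model.bundle = bundle
        return model

    # -- evaluation ---------------------------------------------------------

    def evaluate(self, overrides: Mapping[str, float] | None = None) -> CEResult:
        """Run the deterministic model at base parameters, with optional overrides.

        Override keys are parameter names from the parameter table
        (``hr_os``, ``cost_pembrolizumab``, ``utility_pfs``, ``discount``,
        ``start_age``, ...).
        """
        p = base_values(self.param_space)
        if overrides:
            unknown = set(overrides) - set(p)
            if unknown:
                raise KeyError(f"unknown parameter(s): {sorted(unknown)}")
            p.update(overrides)

        settings = self.settings.with_(discount_annual=p["discount"], start_age=p["start_age"])
        os_trt = apply_hr(self.os_control, p["hr_os"])
        pfs_trt = apply_hr(self.pfs_control, p["hr_pfs"])

        trace_ctrl = build_trace(self.os_control, self.pfs_control, self.life_table, settings)
        trace_trt = build_trace(os_trt, pfs_trt, self.life_table, settings)

        utilities = Utilities(pfs=p["utility_pfs"], pd=p["utility_pd"])
        chemo = [
            RegimenLine("fluorouracil", p["cost_fluorouracil"], "pfs", self.econ.chemo_max_cycles),
            RegimenLine("cisplatin", p["cost_cisplatin"], "pfs", self.econ.chemo_max_cycles),
        ]
        lines_trt = [
            RegimenLine("pembrolizumab", p["cost_pembrolizumab"], "pfs", self.econ.pembro_max_cycles),
            *chemo,
            RegimenLine("paclitaxel", p["cost_paclitaxel"], "pd", None, self.econ.uptake_treatment),
        ]
        lines_ctrl = [
            *chemo,
            RegimenLine("paclitaxel", p["cost_paclitaxel"], "pd", None, self.econ.uptake_control),
        ]
        ae_unit = {name.removeprefix("cost_ae_"): p[name]
                   for name in p if name.startswith("cost_ae_")}
        totals = {}
        for name, trace, lines in (
            ("placebo_chemotherapy", trace_ctrl, lines_ctrl),
            ("pembrolizumab_chemotherapy", trace_trt, lines_trt),
        ):
            arm = "control" if name.startswith("placebo") else "treatment"
            lump = ae_lump_cost(self.econ.ae_incidence[arm], ae_unit)
            totals[name] = accrue(
                trace, lines, utilities, p["cost_followup"], p["cost_supportive"],
                lump, settings, name=name,
            )
        return icer(totals["placebo_chemotherapy"], totals["pembrolizumab_chemotherapy"],
                    wtp=self.settings.wtp)

    def fit(self) -> "CEAResults":
        """Evaluate the base case and return a results object."""
        return CEAResults(model=self, base=self.evaluate())


@dataclass
class CEAResults:
    """Base-case estimates plus entry points for the sensitivity analyses."""

    model: CostEffectivenessModel
    base: CEResult
    _cache: dict = field(default_factory=dict, repr=False)

    # convenient scalar views
    @property
    def icer(self) -> float:
        return self.base.icer

    @property
    def delta_cost(self) -> float:
        return self.base.delta_cost

    @property
    def delta_qaly(self) -> float:
        return self.base.delta_qaly

    def summary(self) -> str:
        """Plain-text base-case table: per-strategy LY/QALY/cost plus increments."""
        b = self.base
        lines = [
            "Cost-effectiveness base case (discounted)",
            "=" * 62,
            f"{'':32s}{'LYs':>8s}{'QALYs':>8s}{'Cost, $':>14s}",
        ]
        for s in (b.comparator, b.reference):
            lines.append(f"{s.name:32s}{s.ly:8.2f}{s.qaly:8.2f}{s.cost:14,.2f}")
        lines.append(f"{'incremental':32s}{b.delta_ly:8.2f}{b.delta_qaly:8.2f}{b.delta_cost:14,.2f}")
        lines.append("-" * 62)
        lines.append(f"Cost per LY gained, $ {b.icer_per_ly:>14,.2f}")
        lines.append(f"Cost per QALY gained, $ {b.icer:>12,.2f}")
        lines.append(f"WTP threshold, $/QALY {b.wtp:>14,.2f}   "
                     f"cost-effective: {'yes' if b.cost_effective else 'no'}")
        return "\n".join(lines)

    # -- analyses (delegated) ----------------------------------------------

    def one_way(self, space=None) -> pd.DataFrame:
        from . import analyses

        return analyses.one_way(self.model, space=space)

    def psa(self, n: int = 1000, seed: int = 0, space=None) -> pd.DataFrame:
        from . import analyses

        return analyses.psa(self.model, n=n, seed=seed, space=space)

    def ceac(self, samples: pd.DataFrame | None = None, wtp_grid=None,
             n: int = 1000, seed: int = 0) -> pd.DataFrame:
        from . import analyses

        if samples is None:
            samples = self.psa(n=n, seed=seed)
        return analyses.ceac(samples, wtp_grid=wtp_grid)

    def threshold_price(self, wtp: float | None = None) -> dict:
        from . import analyses

        return analyses.threshold_price(self.model, wtp=wtp)

    def subgroup(self, hr_os: float, hr_pfs: float) -> CEResult:
        from . import analyses

        return analyses.subgroup_run(self.model, hr_os, hr_pfs)
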