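"""Configuration parsing, validation and end-to-end pipeline wiring.

A model configuration is a YAML (or JSON) document with optional blocks;
every omitted field falls back to the published base-case defaults, so an
empty file is a valid pure-synthetic run.  Schema (all blocks optional)::

    synthetic:
      seed: 1
      n_per_arm: 374
      os_median: 9.8        # control-arm medians, months
      pfs_median: 5.8
      os_shape: 1.5         # log-logistic shapes
      pfs_shape: 1.6
      dropout_rate: 0.01    # per-month
      admin_cutoff: 22.6    # months
      grid_step: 0.5
      risk_interval: 3.0
    inputs:                 # digitized files instead of synthetic generation
      os_curve: path.csv    # columns time_months,survival
      os_risk: path.csv     # columns time_months,n_at_risk
      pfs_curve: path.csv
      pfs_risk: path.csv
      life_table: path.csv  # columns age,q_annual
    parameters:             # any subset; each {base, low, high}
      cost_pembrolizumab: {base: 5625.75, low: 2812.875, high: 8438.625}
      ...
    settings:
      cycle_days: 21
      horizon_years: 40
      wtp: 31304.31
      start_age: 63
      pembro_max_cycles: 35
      chemo_max_cycles: 6
      uptake_treatment: 0.43
      uptake_control: 0.47
      reconstruct: true     # run the Guyot round trip (false = fit raw IPD)
    analyses:
      psa_n: 1000
      run_psa: true
      run_oneway: true
      run_subgroups: true
      run_threshold: true

``run_pipeline`` executes synthetic generation (or file loading), IPD
reconstruction, parametric fitting, the base case and all enabled analyses,
writes every output CSV plus a manifest JSON (seed, config echo, assumption
flags) to a run directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from . import analyses as an
from . import synthetic
from .cohort import ModelSettings
from .model import CostEffectivenessModel
from .params import EconDefaults, Param, default_param_space
from .reconstruct import reconstruct_ipd
from .survival import fit_report


class ConfigError(ValueError):
    """Configuration file violates the schema; message names the field."""


_SYNTH_DEFAULTS = {
    "seed": 1,
    "n_per_arm": synthetic.N_PER_ARM,
    "os_median": synthetic.OS_MEDIAN_CONTROL,
    "pfs_median": synthetic.PFS_MEDIAN_CONTROL,
    "os_shape": synthetic.OS_SHAPE,
    "pfs_shape": synthetic.PFS_SHAPE,
    "dropout_rate": synthetic.DROPOUT_RATE,
    "admin_cutoff": synthetic.ADMIN_CUTOFF,
    "grid_step": 0.5,
    "risk_interval": 3.0,
}

_SETTINGS_DEFAULTS = {
    "cycle_days": 21.0,
    "horizon_years": 40.0,
    "wtp": 31304.31,
    "start_age": 63.0,
    "pembro_max_cycles": 35,
    "chemo_max_cycles": 6,
    "uptake_treatment": 0.43,
    "uptake_control": 0.47,
    "reconstruct": True,
}

_ANALYSES_DEFAULTS = {
    "psa_n": 1000,
    "run_psa": True,
    "run_oneway": True,
    "run_subgroups": True,
    "run_threshold": True,
}


@dataclasses.dataclass
class ModelConfig:
    """Validated configuration with all defaults filled."""

    synthetic: dict
    inputs: dict
    parameters: dict  # name -> Param
    settings: dict
    analyses: dict

    def to_dict(self) -> dict:
        return {
            "synthetic": dict(self.synthetic),
            "inputs": dict(self.inputs),
            "parameters": {
                k: {"base": p.base, "low": p.low, "high": p.high}
                for k, p in self.parameters.items()
            },
            "settings": dict(self.settings),
            "analyses": dict(self.analyses),
        }


def _merge(defaults: dict, user: dict, block: str) -> dict:
    out = dict(defaults)
    for key, val in (user or {}).items():
        if key not in defaults:
            raise ConfigError(f"unknown field {block}.{key}")
        out[key] = val
    return out


def load_config(path: str | Path | None = None) -> ModelConfig:
    """Load and validate a YAML/JSON config; None or empty file = defaults."""
    raw = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config root must be a mapping")
    for block in raw:
        if block not in ("synthetic", "inputs", "parameters", "settings", "analyses"):
            raise ConfigError(f"unknown block {block!r}")

    space = default_param_space()
    parameters = dict(space)
    for name, override in (raw.get("parameters") or {}).items():
        if name not in space:
            raise ConfigError(f"unknown parameter parameters.{name}")
        ref = space[name]
        vals = {"base": ref.base, "low": ref.low, "high": ref.high}
        for k, v in (override or {}).items():
            if k not in vals:
                raise ConfigError(f"unknown field parameters.{name}.{k}")
            vals[k] = float(v)
        try:
            parameters[name] = Param(name, vals["base"], vals["low"], vals["high"],
                                     ref.dist, ref.role)
        except ValueError as exc:
            raise ConfigError(f"parameters.{name}: {exc}") from exc

    inputs = {k: None for k in ("os_curve", "os_risk", "pfs_curve", "pfs_risk", "life_table")}
    inputs = _merge(inputs, raw.get("inputs"), "inputs")
    for key, p in inputs.items():
        if p is not None and not Path(p).exists():
            raise ConfigError(f"inputs.{key}: file not found: {p}")

    return ModelConfig(
        synthetic=_merge(_SYNTH_DEFAULTS, raw.get("synthetic"), "synthetic"),
        inputs=inputs,
        parameters=parameters,
        settings=_merge(_SETTINGS_DEFAULTS, raw.get("settings"), "settings"),
        analyses=_merge(_ANALYSES_DEFAULTS, raw.get("analyses"), "analyses"),
    )


def save_config(config: ModelConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def build_model(config: ModelConfig, seed: int | None = None) -> CostEffectivenessModel:
    """Construct the decision model a config describes (synthetic or from files)."""
    s = config.settings
    settings = ModelSettings(
        cycle_days=float(s["cycle_days"]),
        discount_annual=float(config.parameters["discount"].base),
        start_age=float(s["start_age"]),
        horizon_years=float(s["horizon_years"]),
        wtp=float(s["wtp"]),
    )
    econ = EconDefaults(
        uptake_treatment=float(s["uptake_treatment"]),
        uptake_control=float(s["uptake_control"]),
        pembro_max_cycles=int(s["pembro_max_cycles"]),
        chemo_max_cycles=int(s["chemo_max_cycles"]),
    )
    # start_age in the parameter table must track the settings block
    params = dict(config.parameters)
    sa = params["start_age"]
    if settings.start_age != sa.base:
        lo = min(sa.low, settings.start_age)
        hi = max(sa.high, settings.start_age)
        params["start_age"] = Param("start_age", settings.start_age, lo, hi, sa.dist, sa.role)

    file_mode = config.inputs.get("os_curve") is not None
    if file_mode:
        for key in ("os_curve", "os_risk", "pfs_curve", "pfs_risk"):
            if config.inputs[key] is None:
                raise ConfigError(f"inputs.{key} required when digitized files are given")
        os_ipd = reconstruct_ipd(pd.read_csv(config.inputs["os_curve"]),
                                 pd.read_csv(config.inputs["os_risk"]))
        pfs_ipd = reconstruct_ipd(pd.read_csv(config.inputs["pfs_curve"]),
                                  pd.read_csv(config.inputs["pfs_risk"]))
        life = (pd.read_csv(config.inputs["life_table"])
                if config.inputs["life_table"] else synthetic.make_life_table())
        return CostEffectivenessModel.from_ipd(
            os_ipd, pfs_ipd, life_table=life, param_space=params,
            settings=settings, econ=econ,
        )

    sy = config.synthetic
    use_seed = int(sy["seed"] if seed is None else seed)
    model = CostEffectivenessModel.from_synthetic(
        seed=use_seed,
        n_per_arm=int(sy["n_per_arm"]),
        reconstruct=bool(s["reconstruct"]),
        param_space=params,
        settings=settings,
        econ=econ,
    )
    return model


def run_pipeline(config: ModelConfig, seed: int, outdir: str | Path) -> dict:
    """Execute all enabled stages and write the results bundle.

    Outputs (CSV/JSON) in ``outdir``: fits.json, base_case.csv, tornado.csv,
    psa_samples.csv, ceac.csv, threshold.json, subgroups.csv, manifest.json.
    Returns a dict of the in-memory results.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    model = build_model(config, seed=seed)
    results = model.fit()
    out: dict = {"model": model, "results": results}

    json.dump(
        {ep: fit_report(fits) for ep, fits in model.fit_reports.items()},
        open(outdir / "fits.json", "w"), indent=2,
    )
    results.base.to_frame().to_csv(outdir / "base_case.csv", index=False)

    a = config.analyses
    if a["run_oneway"]:
        out["tornado"] = results.one_way()
        out["tornado"].to_csv(outdir / "tornado.csv", index=False)
    if a["run_psa"]:
        out["psa"] = results.psa(n=int(a["psa_n"]), seed=seed + 1)
        out["psa"].to_csv(outdir / "psa_samples.csv", index=False)
        out["ceac"] = results.ceac(samples=out["psa"])
        out["ceac"].to_csv(outdir / "ceac.csv", index=False)
    if a["run_threshold"]:
        out["threshold"] = results.threshold_price()
        json.dump(out["threshold"], open(outdir / "threshold.json", "w"), indent=2)
    if a["run_subgroups"]:
        out["subgroups"] = an.subgroup_table(model)
        out["subgroups"].to_csv(outdir / "subgroups.csv", index=False)

    manifest = {
        "seed": seed,
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "assumptions": [
            "start_age and horizon are modelling assumptions (not printed in the source)",
            "comparator arm driven by HR transform of the control fits",
            "AE incidences are synthetic defaults",
            "HRs sampled lognormal in PSA",
        ],
        "icer": results.icer,
    }
    json.dump(manifest, open(outdir / "manifest.json", "w"), indent=2)
    out["manifest"] = manifest
    return out
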