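"""End-to-end orchestration: characterization -> stoichiometry -> energetics
-> kinetics -> electricity, with a reproducible JSON report.

Every report embeds the fully resolved configuration and seed, and the JSON
is serialized with sorted keys and fixed float formatting so that two runs
of the same configuration are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, Field, field_validator

from . import energetics, kinetics, stoichiometry
from .electricity import CP_CH4_DEFAULT, ETA_ELEC_DEFAULT, electricity_from_biogas
from .errors import StageError
from .feedstock import load_proximate_analysis, load_ultimate_analysis, to_empirical_formula

__all__ = ["PipelineConfig", "run_pipeline"]


class PipelineConfig(BaseModel):
    """Resolved configuration for one pipeline run."""

    ultimate_csv: str
    proximate_csv: Optional[str] = None
    basis: str = "dry"
    basis_mass_g: float = Field(default=100.0, gt=0)
    molar_volume_l: float = Field(default=stoichiometry.STP_MOLAR_VOLUME_L, gt=0)
    include_trace: bool = True
    cp_ch4: float = Field(default=CP_CH4_DEFAULT, gt=0)
    eta_elec: float = Field(default=ETA_ELEC_DEFAULT, ge=0, le=1)
    model_id: str = "gompertz"
    b0: float = Field(default=450.0, gt=0)
    rmax: float = Field(default=28.0, gt=0)
    lag: float = Field(default=2.0, ge=0)
    k: float = Field(default=0.15, gt=0)
    temperatures_c: tuple[float, ...] = (25.0, 35.0, 45.0)
    t_min: float = 10.0
    t_opt: float = 35.0
    t_max: float = 45.0
    hrt_criterion: str = "fraction_of_asymptote"
    hrt_q: float = Field(default=0.95, gt=0, lt=1)
    digester_biogas_m3: Optional[float] = None
    seed: int = 0
    outdir: Optional[str] = None

    @field_validator("model_id")
    @classmethod
    def _check_model(cls, v: str) -> str:
        if v not in ("gompertz", "first_order"):
            raise ValueError(f"unknown model_id {v!r}")
        return v

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, exc) from exc
        return wrapped
    return deco


@_stage("feedstock")
def _feedstock_stage(cfg: PipelineConfig):
    ua = load_ultimate_analysis(cfg.ultimate_csv, basis=cfg.basis)
    pa = load_proximate_analysis(cfg.proximate_csv) if cfg.proximate_csv else None
    formula = to_empirical_formula(ua, basis_mass=cfg.basis_mass_g)
    return ua, pa, formula


@_stage("stoichiometry")
def _stoichiometry_stage(cfg: PipelineConfig, formula, pa):
    s = stoichiometry.boyle_coefficients(formula)
    vs_frac = pa.volatile_solid_frac if pa is not None else None
    out = {
        "coefficients": {
            "water": s.water_coeff,
            "CH4": s.ch4_coeff,
            "CO2": s.co2_coeff,
            "NH3": s.nh3_coeff,
            "H2S": s.h2s_coeff,
        },
        "gas_fractions": s.gas_fractions(include_trace=cfg.include_trace),
        "gas_fractions_major": s.gas_fractions(include_trace=False),
        "methane_yield_l_per_kg_dry": stoichiometry.theoretical_methane_yield(
            formula, cfg.molar_volume_l
        ),
        "biogas_yield_l_per_kg_dry": stoichiometry.theoretical_biogas_yield(
            formula, cfg.molar_volume_l, include_trace=cfg.include_trace
        ),
    }
    if vs_frac:
        out["methane_yield_l_per_kg_vs"] = stoichiometry.theoretical_methane_yield(
            formula, cfg.molar_volume_l, vs_fraction=vs_frac
        )
    return s, out


@_stage("energetics")
def _energetics_stage(cfg: PipelineConfig, ua, pa):
    hhv = energetics.dulong_hhv(ua)
    ev = energetics.hhv_to_lhv(hhv, ua.h_frac)
    return {
        "hhv_kj_per_kg": hhv,
        "lhv_kj_per_kg": ev.lhv,
        "water_mass_per_kg": ev.water_mass_per_kg,
        "hhv_mj_per_kg": energetics.convert_energy(hhv, "kJ/kg", "MJ/kg"),
        "hhv_cal_per_g": energetics.convert_energy(hhv, "kJ/kg", "cal/g"),
    }


@_stage("kinetics")
def _kinetics_stage(cfg: PipelineConfig):
    params = kinetics.BatchKineticsParams(
        b0=cfg.b0, rmax=cfg.rmax, lag=cfg.lag, k=cfg.k, model_id=cfg.model_id
    )
    tr = kinetics.TemperatureResponse(cfg.t_min, cfg.t_opt, cfg.t_max)
    per_temp = {}
    for T in cfg.temperatures_c:
        f = kinetics.temperature_factor(T, tr)
        entry = {"temperature_factor": f}
        if f == 0.0:
            entry.update({"optimal_hrt_days": None, "no_production": True})
        else:
            entry.update(
                {
                    "optimal_hrt_days": kinetics.optimal_hrt(
                        params.scaled_rate(f), criterion=cfg.hrt_criterion, q=cfg.hrt_q
                    ),
                    "no_production": False,
                }
            )
        per_temp[f"{T:g}"] = entry
    return params, tr, per_temp


@_stage("electricity")
def _electricity_stage(cfg: PipelineConfig, gas_fractions, kinetics_params, tr):
    f_ch4 = gas_fractions["CH4"]
    if cfg.digester_biogas_m3 is not None:
        q = cfg.digester_biogas_m3
    else:
        # asymptotic production of the configured digester, expressed in m3
        # assuming the kinetic volume unit is litres
        q = kinetics_params.b0 / 1000.0
    est = electricity_from_biogas(q, f_ch4, cp_ch4=cfg.cp_ch4, eta_elec=cfg.eta_elec)
    return {
        "q_biogas_m3": est.q_biogas,
        "f_ch4": est.f_ch4,
        "cp_ch4_kwh_per_m3": est.cp_ch4,
        "eta_elec": est.eta_elec,
        "e_elec_kwh": est.e_elec,
        "e_elec_kwh_rounded": est.e_elec_rounded,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; return (and optionally write) the report dict."""
    ua, pa, formula = _feedstock_stage(config)
    s, stoich_report = _stoichiometry_stage(config, formula, pa)
    energy_report = _energetics_stage(config, ua, pa)
    params, tr, hrt_report = _kinetics_stage(config)
    elec_report = _electricity_stage(
        config, stoich_report["gas_fractions"], params, tr
    )

    report = {
        "config": config.model_dump(mode="json"),
        "feedstock": {
            "ultimate_fractions": ua.fractions(),
            "basis": ua.basis,
            "formula": {
                "a": formula.a,
                "b": formula.b,
                "c": formula.c,
                "d": formula.d,
                "e": formula.e,
                "basis_mass_g": formula.basis_mass,
            },
            "proximate": (
                {
                    "moisture": pa.moisture,
                    "volatile_solid": pa.volatile_solid,
                    "ash": pa.ash,
                    "fixed_carbon": pa.fixed_carbon,
                    "sulfur": pa.sulfur,
                }
                if pa is not None
                else None
            ),
        },
        "stoichiometry": stoich_report,
        "energetics": energy_report,
        "kinetics": hrt_report,
        "electricity": elec_report,
    }

    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(report_json(report))
    return report


def report_json(report: dict) -> str:
    """Canonical serialization: sorted keys, stable float formatting."""
    return json.dumps(report, sort_keys=True, indent=2, allow_nan=False) + "\n"
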