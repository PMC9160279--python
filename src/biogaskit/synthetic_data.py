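"""Synthetic feedstock tables and batch-digestion studies.

No public repository carries raw time series for sludge batch-digestion
optimization experiments of the kind this package analyses, so this module
generates them with the statistical structure the analysis assumes: a
factorial design over initial pH {5.5 ... 9.5}, substrate:water loading
ratio {1:3 ... 1:6} and incubation temperature {25, 35, 45} degC, run in
triplicate 500 mL reactors sampled on a weekly grid over a 30-day (extensible
to 48-day) hydraulic retention time.

Each condition's true curve is a modified Gompertz whose asymptote b0 and
peak rate rmax are both scaled by the product of three multipliers in
[0, 1]: a Gaussian bump in pH centred on the optimum 8.5, a monotone
dilution penalty optimal at 1:3, and the CTMI temperature factor (1 at
35 degC, 0 at 45 degC).  Observations add independent Gaussian noise
(sd = noise_sd_frac * b0 of the condition) and are floored at the previous
reading, since a cumulative gas record cannot decrease.  Methane fraction
is drawn near a configurable mean (default 0.41, a typical methane share
for this substrate class).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .kinetics import (
    BatchKineticsParams,
    BatchSeries,
    TemperatureResponse,
    cumulative_model,
    temperature_factor,
)

__all__ = [
    "REFERENCE_ULTIMATE",
    "REFERENCE_PROXIMATE",
    "ExperimentDesign",
    "ResponseSurface",
    "generate_feedstock_table",
    "generate_study",
    "truth_manifest",
    "condition_key",
]

#: Template ultimate analysis (percent of dry mass) of a sugary beverage
#: wastewater sludge; used as the generator's central composition.
REFERENCE_ULTIMATE: Mapping[str, float] = {
    "C": 45.19,
    "N": 3.579,
    "H": 7.299,
    "S": 0.94,
    "O": 42.992,
}

#: Template proximate analysis (percent) for the same sludge.
REFERENCE_PROXIMATE: Mapping[str, float] = {
    "moisture": 6.3,
    "volatile_solid": 60.1,
    "ash": 27.0,
    "fixed_carbon": 6.7,
    "sulfur": 0.9,
}

_DEFAULT_BASE = BatchKineticsParams(b0=450.0, rmax=28.0, lag=2.0)


def _dilution_fraction(ratio: str) -> float:
    """Substrate share of a 'substrate:water' ratio string, e.g. '1:3' -> 0.25."""
    s, w = ratio.split(":")
    s_f, w_f = float(s), float(w)
    if s_f <= 0 or w_f < 0:
        raise ValueError(f"invalid loading ratio {ratio!r}")
    return s_f / (s_f + w_f)


@dataclass(frozen=True)
class ExperimentDesign:
    """Factorial layout and sampling/noise settings of a synthetic study."""

    ph_levels: tuple[float, ...] = (5.5, 6.5, 7.5, 8.5, 9.5)
    loading_ratios: tuple[str, ...] = ("1:3", "1:4", "1:5", "1:6")
    temperatures_c: tuple[float, ...] = (25.0, 35.0, 45.0)
    replicates: int = 3
    sampling_days: tuple[float, ...] = (7.0, 14.0, 21.0, 28.0, 30.0)
    noise_sd_frac: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.noise_sd_frac < 0:
            raise ValueError("noise_sd_frac must be non-negative")
        if np.any(np.diff(self.sampling_days) <= 0):
            raise ValueError("sampling_days must be strictly increasing")
        for r in self.loading_ratios:
            _dilution_fraction(r)


@dataclass(frozen=True)
class ResponseSurface:
    """True multiplicative response of yield/rate to pH, loading, temperature.

    The multiplier at each factor's optimum is exactly 1, so
    ``base_params`` are the true kinetics at (ph_opt, loading_opt, t_opt).
    """

    ph_opt: float = 8.5
    ph_width: float = 1.2
    loading_opt: str = "1:3"
    loading_slope: float = 1.0
    temperature: TemperatureResponse = field(default_factory=TemperatureResponse)
    base_params: BatchKineticsParams = field(default_factory=lambda: _DEFAULT_BASE)
    ch4_frac_mean: float = 0.41
    ch4_frac_sd: float = 0.02

    def ph_multiplier(self, ph: float) -> float:
        return float(np.exp(-0.5 * ((ph - self.ph_opt) / self.ph_width) ** 2))

    def loading_multiplier(self, ratio: str) -> float:
        f = _dilution_fraction(ratio)
        f_opt = _dilution_fraction(self.loading_opt)
        return float(min(1.0, (f / f_opt) ** self.loading_slope))

    def condition_multiplier(self, ph: float, ratio: str, T: float) -> float:
        return (
            self.ph_multiplier(ph)
            * self.loading_multiplier(ratio)
            * temperature_factor(T, self.temperature)
        )


def condition_key(ph: float, ratio: str, T: float) -> str:
    return f"ph={ph:g}|loading={ratio}|T={T:g}C"


def generate_feedstock_table(
    seed: int = 0,
    n_samples: int = 1,
    jitter_frac: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded ultimate+proximate characterization tables.

    Each sample is the reference composition perturbed multiplicatively by
    ``1 + jitter_frac * z`` (z standard normal, truncated at +/-3 sigma)
    then renormalized so each table keeps its template closure sum.
    Returns ``(ultimate_df, proximate_df)`` with columns
    ``sample,element,percent`` and ``sample,component,percent``.
    """
    if not (0.0 <= jitter_frac <= 0.2):
        raise ValueError("jitter_frac must lie in [0, 0.2]")
    rng = np.random.default_rng(seed)

    def jitter(values: np.ndarray) -> np.ndarray:
        z = np.clip(rng.standard_normal(len(values)), -3.0, 3.0)
        out = values * (1.0 + jitter_frac * z)
        return np.clip(out, 0.0, None)

    u_keys = list(REFERENCE_ULTIMATE)
    u_vals = np.array([REFERENCE_ULTIMATE[k] for k in u_keys])
    p_keys = list(REFERENCE_PROXIMATE)
    p_vals = np.array([REFERENCE_PROXIMATE[k] for k in p_keys])
    # closure is over the four mass-partition components; sulfur is reported
    # separately in proximate tables
    p_closure = [k != "sulfur" for k in p_keys]

    u_rows, p_rows = [], []
    for i in range(n_samples):
        sample = f"s{i}"
        u = jitter(u_vals)
        u *= u_vals.sum() / u.sum()
        for k, v in zip(u_keys, u):
            u_rows.append({"sample": sample, "element": k, "percent": v})
        p = jitter(p_vals)
        mask = np.array(p_closure)
        p[mask] *= p_vals[mask].sum() / p[mask].sum()
        for k, v in zip(p_keys, p):
            p_rows.append({"sample": sample, "component": k, "percent": v})
    return pd.DataFrame(u_rows), pd.DataFrame(p_rows)


def _true_params(surface: ResponseSurface, ph: float, ratio: str, T: float):
    m = surface.condition_multiplier(ph, ratio, T)
    base = surface.base_params
    if m == 0.0:
        return None, 0.0
    return (
        BatchKineticsParams(
            b0=base.b0 * m,
            rmax=base.rmax * m,
            lag=base.lag,
            k=base.k * m if base.k else 0.0,
            model_id=base.model_id,
        ),
        m,
    )


def generate_study(
    design: ExperimentDesign = ExperimentDesign(),
    surface: ResponseSurface = ResponseSurface(),
) -> list[BatchSeries]:
    """Generate every (pH, loading, temperature, replicate) batch series.

    Deterministic for a fixed ``design.seed``.  See the module docstring
    for the noise and monotonicity model.
    """
    rng = np.random.default_rng(design.seed)
    t = np.asarray(design.sampling_days, dtype=float)
    series: list[BatchSeries] = []
    for ph in design.ph_levels:
        for ratio in design.loading_ratios:
            for T in design.temperatures_c:
                params, m = _true_params(surface, ph, ratio, T)
                for rep in range(design.replicates):
                    rid = f"{condition_key(ph, ratio, T)}|rep={rep}"
                    # draw both noise vectors unconditionally so the stream
                    # stays aligned across conditions for a given seed
                    gas_noise = rng.standard_normal(len(t))
                    mf_noise = rng.standard_normal(len(t))
                    if params is None:
                        obs = np.zeros_like(t)
                        flags = ("no_production",)
                    else:
                        truth = np.asarray(cumulative_model(params, t), dtype=float)
                        obs = truth + design.noise_sd_frac * params.b0 * gas_noise
                        obs = np.maximum.accumulate(np.clip(obs, 0.0, None))
                        flags = ()
                    mf = np.clip(
                        surface.ch4_frac_mean + surface.ch4_frac_sd * mf_noise, 0.0, 1.0
                    )
                    series.append(
                        BatchSeries(
                            times=t,
                            cumulative_biogas=obs,
                            methane_fraction=mf,
                            reactor_id=rid,
                            temperature_c=T,
                            ph=ph,
                            loading_ratio=ratio,
                            flags=flags,
                        )
                    )
    return series


def truth_manifest(
    design: ExperimentDesign = ExperimentDesign(),
    surface: ResponseSurface = ResponseSurface(),
) -> dict:
    """JSON-serializable record of the true parameters behind a study."""
    conditions = {}
    for ph in design.ph_levels:
        for ratio in design.loading_ratios:
            for T in design.temperatures_c:
                params, m = _true_params(surface, ph, ratio, T)
                conditions[condition_key(ph, ratio, T)] = {
                    "multiplier": m,
                    "b0": params.b0 if params else 0.0,
                    "rmax": params.rmax if params else 0.0,
                    "lag": params.lag if params else 0.0,
                    "model_id": surface.base_params.model_id,
                }
    return {
        "seed": design.seed,
        "noise_sd_frac": design.noise_sd_frac,
        "sampling_days": list(design.sampling_days),
        "replicates": design.replicates,
        "ch4_frac_mean": surface.ch4_frac_mean,
        "conditions": conditions,
    }
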