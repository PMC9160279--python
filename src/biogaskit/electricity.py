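"""Biogas-to-electricity potential via an internal-combustion engine.

    E_elec = Q_biogas * F_CH4 * Cp_CH4 * eta_elec

with Q_biogas the biogas volume (m3), F_CH4 the methane fraction, Cp_CH4
the specific (net heating) energy of methane per cubic metre, and eta_elec
the engine's electrical efficiency.  Default Cp = 10 kWh/m3 (a common
engineering figure; the Swedish Gas Centre value 9.97 kWh/m3 is provided
as an alternative constant) and eta = 0.30, mid-range for small gas
engines (25-40%).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import UnitError

__all__ = [
    "CP_CH4_DEFAULT",
    "CP_CH4_SWEDISH_GAS_CENTRE",
    "ETA_ELEC_DEFAULT",
    "ElectricityEstimate",
    "electricity_from_biogas",
    "electricity_from_methane",
    "aggregate_period",
]

CP_CH4_DEFAULT = 10.0  # kWh per m3 methane
CP_CH4_SWEDISH_GAS_CENTRE = 9.97  # kWh per m3 methane
ETA_ELEC_DEFAULT = 0.30


@dataclass(frozen=True)
class ElectricityEstimate:
    """E_elec (kWh) together with the four factors that produced it."""

    q_biogas: float  # m3
    f_ch4: float  # fraction in [0, 1]
    cp_ch4: float  # kWh/m3
    eta_elec: float  # fraction in [0, 1]
    e_elec: float  # kWh
    unit: str = "kWh"

    @property
    def e_elec_rounded(self) -> float:
        """One-decimal report, the precision these estimates are quoted at."""
        return round(self.e_elec, 1)


def _check_fraction(name: str, value: float) -> None:
    if value > 1.0:
        raise UnitError(
            f"{name}={value} exceeds 1; it must be a fraction, not a percent "
            f"(did you mean {value / 100.0}?)"
        )
    if value < 0.0:
        raise ValueError(f"{name} must be non-negative")


def electricity_from_biogas(
    q_biogas: float,
    f_ch4: float,
    cp_ch4: float = CP_CH4_DEFAULT,
    eta_elec: float = ETA_ELEC_DEFAULT,
) -> ElectricityEstimate:
    """Electrical energy (kWh) obtainable from a biogas volume.

    ``E = Q * F * Cp * eta``, exactly multilinear in all four factors.
    """
    if q_biogas < 0:
        raise ValueError("q_biogas must be non-negative")
    if cp_ch4 <= 0:
        raise ValueError("cp_ch4 must be positive")
    _check_fraction("f_ch4", f_ch4)
    _check_fraction("eta_elec", eta_elec)
    e = q_biogas * f_ch4 * cp_ch4 * eta_elec
    return ElectricityEstimate(
        q_biogas=q_biogas, f_ch4=f_ch4, cp_ch4=cp_ch4, eta_elec=eta_elec, e_elec=e
    )


def electricity_from_methane(
    v_ch4: float,
    cp_ch4: float = CP_CH4_DEFAULT,
    eta_elec: float = ETA_ELEC_DEFAULT,
) -> ElectricityEstimate:
    """Electrical energy (kWh) from a methane volume (F_CH4 = 1)."""
    return electricity_from_biogas(v_ch4, 1.0, cp_ch4=cp_ch4, eta_elec=eta_elec)


def aggregate_period(
    estimates: Sequence[ElectricityEstimate] | Iterable[ElectricityEstimate],
    period_label: str = "total",
) -> dict:
    """Sum estimates over a reporting period (arithmetic total in kWh)."""
    items = list(estimates)
    if not items:
        raise ValueError("cannot aggregate an empty list of estimates")
    units = {e.unit for e in items}
    if len(units) > 1:
        raise UnitError(f"mixed units in aggregation: {sorted(units)}")
    return {
        "period": period_label,
        "total_kwh": sum(e.e_elec for e in items),
        "n_estimates": len(items),
    }
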