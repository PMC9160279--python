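"""Heating-value estimation from elemental composition.

The Dulong correlation estimates the higher heating value (HHV) of a fuel
from its dry-basis C, H, O and S mass fractions:

    HHV (kJ/kg) = 33801*C + 144158*(H - 0.125*O) + 9413*S

The ``H - O/8`` term is the "available hydrogen" convention: hydrogen
already bound to oxygen is assumed unavailable for combustion.  The lower
heating value (LHV) subtracts the latent heat of the water formed:

    HHV = LHV + n * dHv(H2O, 25 degC),   dHv = 44.013 kJ/mol

where n is the water produced per unit fuel (9 kg per kg of hydrogen burnt,
plus any fuel moisture if requested).
"""

from __future__ import annotations

from dataclasses import dataclass

import math

from .errors import UnitError
from .feedstock import UltimateAnalysis

__all__ = [
    "LATENT_HEAT_MOLAR_KJ",
    "LATENT_HEAT_MASS_MJ",
    "WATER_MOLAR_MASS",
    "EnergyValues",
    "dulong_hhv",
    "latent_heat_of_water",
    "hhv_to_lhv",
    "convert_energy",
]

#: Molar enthalpy of vaporization of water at 25 degC (kJ/mol).
LATENT_HEAT_MOLAR_KJ = 44.013
#: Standard molar mass of water (g/mol).
WATER_MOLAR_MASS = 18.015
#: Conventional rounded mass latent heat (MJ/kg water), i.e. 44.013/18.0.
LATENT_HEAT_MASS_MJ = 2.445

_H2O_PER_H2 = 18.015 / 2.016  # kg water formed per kg hydrogen burnt

_CAL = 4.184  # thermochemical calorie, J
_TO_KJ_PER_KG = {"cal/g": _CAL, "kJ/kg": 1.0, "MJ/kg": 1000.0}


@dataclass(frozen=True)
class EnergyValues:
    """HHV/LHV pair with the water bookkeeping that links them.

    Invariant: ``hhv - lhv == water_mass_per_kg * dhv_mass * 1000`` (kJ/kg),
    exactly as computed.  ``degenerate`` flags a (physically meaningless)
    negative LHV rather than raising.
    """

    hhv: float  # kJ/kg fuel
    lhv: float  # kJ/kg fuel
    water_mass_per_kg: float  # kg water per kg fuel
    dhv_mass: float  # MJ/kg water
    degenerate: bool = False


def dulong_hhv(ua: UltimateAnalysis) -> float:
    """Dulong higher heating value (kJ/kg) from dry-basis mass fractions."""
    for name, v in ua.fractions().items():
        if math.isnan(v):
            raise ValueError(f"NaN mass fraction for {name}")
    return (
        33801.0 * ua.c_frac
        + 144158.0 * (ua.h_frac - 0.125 * ua.o_frac)
        + 9413.0 * ua.s_frac
    )


def latent_heat_of_water(water_molar_mass: float = WATER_MOLAR_MASS) -> float:
    """Mass latent heat of vaporization (MJ/kg) from the molar value.

    With the standard molar mass 18.015 g/mol this is 2.4431 MJ/kg; with
    the rounded 18.0 g/mol convention it is 2.445 MJ/kg, the figure most
    handbooks print.
    """
    if water_molar_mass <= 0:
        raise ValueError("water_molar_mass must be positive")
    return LATENT_HEAT_MOLAR_KJ / water_molar_mass


def hhv_to_lhv(
    hhv: float,
    h_frac: float,
    moisture_frac: float = 0.0,
    include_moisture: bool = False,
    dhv_mass: float = LATENT_HEAT_MASS_MJ,
) -> EnergyValues:
    """Convert HHV to LHV by subtracting latent heat of the formed water.

    ``water_mass_per_kg = h_frac * (18.015/2.016) [+ moisture_frac]``; the
    moisture term is optional (off by default) because the classical n in
    HHV = LHV + n*dHv counts combustion water only.  ``dhv_mass`` defaults
    to the conventional 2.445 MJ/kg; pass
    :func:`latent_heat_of_water` () for the unrounded constant.
    """
    for name, v in (("h_frac", h_frac), ("moisture_frac", moisture_frac)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name}={v!r} outside [0, 1]")
    water = h_frac * _H2O_PER_H2
    if include_moisture:
        water += moisture_frac
    lhv = hhv - water * dhv_mass * 1000.0
    return EnergyValues(
        hhv=hhv,
        lhv=lhv,
        water_mass_per_kg=water,
        dhv_mass=dhv_mass,
        degenerate=lhv < 0.0,
    )


def convert_energy(value: float, from_unit: str, to_unit: str) -> float:
    """Convert a specific energy among cal/g, kJ/kg and MJ/kg.

    Uses the thermochemical calorie (1 cal = 4.184 J).
    """
    for u in (from_unit, to_unit):
        if u not in _TO_KJ_PER_KG:
            raise UnitError(
                f"unknown unit {u!r}; supported: {sorted(_TO_KJ_PER_KG)}"
            )
    return value * _TO_KJ_PER_KG[from_unit] / _TO_KJ_PER_KG[to_unit]
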