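"""Buswell-Boyle stoichiometry: theoretical biogas composition and yield.

Given an empirical feedstock formula C_a H_b O_c N_d S_e, the Buswell
equation (extended by Boyle to nitrogen and sulfur) balances complete
anaerobic conversion to CH4, CO2, NH3 and H2S:

    C_a H_b O_c N_d S_e + (a - b/4 - c/2 + 3d/4 + e/2) H2O ->
        (a/2 + b/8 - c/4 - 3d/8 - e/4) CH4
      + (a/2 - b/8 + c/4 + 3d/8 + e/4) CO2
      + d NH3 + e H2S

The model assumes the substrate contains only C, H, O, N, S, that the
reaction goes to completion, and that the only products are the four gases
above; it therefore gives a *theoretical* upper bound on methane potential,
not a biodegradability-corrected one.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InfeasibleFeedstockError
from .feedstock import ElementalFormula

__all__ = [
    "STP_MOLAR_VOLUME_L",
    "StoichiometryResult",
    "boyle_coefficients",
    "gas_composition",
    "theoretical_methane_yield",
    "theoretical_biogas_yield",
]

#: Ideal-gas molar volume at 0 degC, 1 atm (L/mol).
STP_MOLAR_VOLUME_L = 22.414

_BALANCE_TOL = 1e-9


@dataclass(frozen=True)
class StoichiometryResult:
    """Reaction coefficients per mole of the feedstock formula.

    All coefficients are moles per ``formula.basis_mass`` grams of feedstock.
    ``water_coeff`` is the water *demand* on the reactant side; the four gas
    coefficients are products.
    """

    water_coeff: float
    ch4_coeff: float
    co2_coeff: float
    nh3_coeff: float
    h2s_coeff: float
    formula: ElementalFormula

    @property
    def total_gas(self) -> float:
        return self.ch4_coeff + self.co2_coeff + self.nh3_coeff + self.h2s_coeff

    def gas_fractions(self, include_trace: bool = True) -> dict[str, float]:
        return gas_composition(self, include_trace=include_trace)


def boyle_coefficients(f: ElementalFormula) -> StoichiometryResult:
    """Balance the extended Buswell reaction for formula ``f``.

    Closed-form coefficients (see module docstring); the element balances
    for C, H, O, N and S hold exactly and are asserted on every call.
    Raises :class:`InfeasibleFeedstockError` when the composition is too
    oxidized or too reduced for non-negative CH4/CO2 coefficients.
    """
    a, b, c, d, e = f.a, f.b, f.c, f.d, f.e
    water = a - b / 4.0 - c / 2.0 + 3.0 * d / 4.0 + e / 2.0
    ch4 = a / 2.0 + b / 8.0 - c / 4.0 - 3.0 * d / 8.0 - e / 4.0
    co2 = a / 2.0 - b / 8.0 + c / 4.0 + 3.0 * d / 8.0 + e / 4.0

    if ch4 < 0 or co2 < 0:
        raise InfeasibleFeedstockError(
            f"formula {f} yields negative gas coefficients "
            f"(CH4={ch4:.4g}, CO2={co2:.4g}); composition outside the "
            "model's feasible range"
        )

    scale = max(1.0, abs(a), abs(b), abs(c))
    # Algebraic conservation identities, checked defensively.
    assert abs((ch4 + co2) - a) <= _BALANCE_TOL * scale, "carbon balance"
    assert abs((4 * ch4 + 3 * d + 2 * e) - (b + 2 * water)) <= _BALANCE_TOL * scale, "hydrogen balance"
    assert abs(2 * co2 - (c + water)) <= _BALANCE_TOL * scale, "oxygen balance"

    return StoichiometryResult(
        water_coeff=water,
        ch4_coeff=ch4,
        co2_coeff=co2,
        nh3_coeff=d,
        h2s_coeff=e,
        formula=f,
    )


def gas_composition(s: StoichiometryResult, include_trace: bool = True) -> dict[str, float]:
    """Mole fractions of the product gas, normalized to sum to 1.

    With ``include_trace`` the denominator covers CH4+CO2+NH3+H2S (the
    model's full "biogas"); without it only the two major gases, the view
    most gas analyzers and most published composition numbers use.
    """
    if include_trace:
        parts = {
            "CH4": s.ch4_coeff,
            "CO2": s.co2_coeff,
            "NH3": s.nh3_coeff,
            "H2S": s.h2s_coeff,
        }
    else:
        parts = {"CH4": s.ch4_coeff, "CO2": s.co2_coeff}
    total = sum(parts.values())
    if total <= 0:
        raise InfeasibleFeedstockError(
            "all gas coefficients are zero; composition undefined"
        )
    return {k: v / total for k, v in parts.items()}


def theoretical_methane_yield(
    f: ElementalFormula,
    molar_volume: float = STP_MOLAR_VOLUME_L,
    vs_fraction: float | None = None,
) -> float:
    """Theoretical methane yield in L CH4 per kg of the formula's basis.

    ``yield = ch4_coeff * molar_volume / basis_mass(kg)``.  When
    ``vs_fraction`` is given the yield is re-expressed per kg of volatile
    solids (divide by the VS fraction of dry mass), the normalization used
    for biochemical methane potential.
    """
    if molar_volume <= 0:
        raise ValueError("molar_volume must be positive")
    s = boyle_coefficients(f)
    y = s.ch4_coeff * molar_volume / (f.basis_mass / 1000.0)
    if vs_fraction is not None:
        if not (0 < vs_fraction <= 1):
            raise ValueError("vs_fraction must be in (0, 1]")
        y /= vs_fraction
    return y


def theoretical_biogas_yield(
    f: ElementalFormula,
    molar_volume: float = STP_MOLAR_VOLUME_L,
    include_trace: bool = True,
    vs_fraction: float | None = None,
) -> float:
    """Theoretical total gas yield (L/kg basis), all products counted."""
    if molar_volume <= 0:
        raise ValueError("molar_volume must be positive")
    s = boyle_coefficients(f)
    total = s.total_gas if include_trace else s.ch4_coeff + s.co2_coeff
    y = total * molar_volume / (f.basis_mass / 1000.0)
    if vs_fraction is not None:
        if not (0 < vs_fraction <= 1):
            raise ValueError("vs_fraction must be in (0, 1]")
        y /= vs_fraction
    return y
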