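"""Buswell-Boyle balancing against an independent element-balance oracle."""

import numpy as np
import pytest

from biogaskit.errors import InfeasibleFeedstockError
from biogaskit.feedstock import ElementalFormula
from biogaskit.stoichiometry import (
    StoichiometryResult,
    boyle_coefficients,
    gas_composition,
    theoretical_biogas_yield,
    theoretical_methane_yield,
)


def solve_element_balances(f: ElementalFormula) -> dict[str, float]:
    """Independent oracle: solve the 5x5 element-balance linear system.

    Unknowns [water, CH4, CO2, NH3, H2S] for
    CaHbOcNdSe + w H2O -> x CH4 + y CO2 + n NH3 + s H2S, balancing each
    element with a generic linear solver rather than the closed form.
    """
    A = np.array(
        [
            [0.0, 1.0, 1.0, 0.0, 0.0],  # C: x + y = a
            [2.0, -4.0, 0.0, -3.0, -2.0],  # H: b + 2w = 4x + 3n + 2s
            [1.0, 0.0, -2.0, 0.0, 0.0],  # O: c + w = 2y
            [0.0, 0.0, 0.0, 1.0, 0.0],  # N: n = d
            [0.0, 0.0, 0.0, 0.0, 1.0],  # S: s = e
        ]
    )
    rhs = np.array([f.a, -f.b, -f.c, f.d, f.e])
    w, x, y, n, s = np.linalg.solve(A, rhs)
    return {"water": w, "CH4": x, "CO2": y, "NH3": n, "H2S": s}


GLUCOSE = ElementalFormula(a=6, b=12, c=6, d=0, e=0, basis_mass=180.156)
CELLULOSE_UNIT = ElementalFormula(a=6, b=10, c=5, d=0, e=0, basis_mass=162.14)


class TestBoyleCoefficients:
    def test_glucose_splits_fifty_fifty(self):
        s = boyle_coefficients(GLUCOSE)
        assert s.water_coeff == pytest.approx(0.0, abs=1e-12)
        assert s.ch4_coeff == pytest.approx(3.0, abs=1e-12)
        assert s.co2_coeff == pytest.approx(3.0, abs=1e-12)
        assert gas_composition(s)["CH4"] == pytest.approx(0.5, abs=1e-12)

    def test_cellulose_unit(self):
        s = boyle_coefficients(CELLULOSE_UNIT)
        assert s.water_coeff == pytest.approx(1.0, abs=1e-12)
        assert s.ch4_coeff == pytest.approx(3.0, abs=1e-12)
        assert s.co2_coeff == pytest.approx(3.0, abs=1e-12)

    def test_reference_sludge(self, sludge_formula):
        s = boyle_coefficients(sludge_formula)
        assert s.ch4_coeff == pytest.approx(2.011, abs=1e-3)
        assert s.co2_coeff == pytest.approx(1.751, abs=1e-3)
        assert s.nh3_coeff == pytest.approx(sludge_formula.d)
        assert s.h2s_coeff == pytest.approx(sludge_formula.e)

    def test_carbon_conservation(self, sludge_formula):
        s = boyle_coefficients(sludge_formula)
        assert s.ch4_coeff + s.co2_coeff == pytest.approx(sludge_formula.a, abs=1e-9)

    def test_matches_oracle_on_random_formulas(self):
        """Closed form == generic linear solve on 1000 random formulas (1e-10)."""
        rng = np.random.default_rng(20260924)
        checked = 0
        while checked < 1000:
            comp = np.array(
                [
                    rng.uniform(0.3, 0.6),  # C
                    rng.uniform(0.03, 0.12),  # H
                    rng.uniform(0.0, 0.10),  # N
                    rng.uniform(0.0, 0.03),  # S
                    rng.uniform(0.2, 0.55),  # O
                ]
            )
            comp /= comp.sum()
            w = np.array([12.011, 1.008, 14.007, 32.06, 15.999])
            moles = 100.0 * comp / w
            f = ElementalFormula(
                a=moles[0], b=moles[1], c=moles[4], d=moles[2], e=moles[3],
                basis_mass=100.0,
            )
            try:
                s = boyle_coefficients(f)
            except InfeasibleFeedstockError:
                continue
            oracle = solve_element_balances(f)
            assert s.water_coeff == pytest.approx(oracle["water"], abs=1e-10)
            assert s.ch4_coeff == pytest.approx(oracle["CH4"], abs=1e-10)
            assert s.co2_coeff == pytest.approx(oracle["CO2"], abs=1e-10)
            assert s.nh3_coeff == pytest.approx(oracle["NH3"], abs=1e-10)
            assert s.h2s_coeff == pytest.approx(oracle["H2S"], abs=1e-10)
            checked += 1

    def test_reduces_to_buswell_without_n_and_s(self):
        f = ElementalFormula(a=2.0, b=6.0, c=1.0, d=0.0, e=0.0, basis_mass=46.07)
        s = boyle_coefficients(f)  # ethanol
        assert s.nh3_coeff == 0.0
        assert s.h2s_coeff == 0.0
        assert s.ch4_coeff == pytest.approx(1.5)
        assert s.co2_coeff == pytest.approx(0.5)

    def test_overreduced_feedstock_is_infeasible(self):
        f = ElementalFormula(a=1.0, b=6.0, c=0.0, d=0.0, e=0.0, basis_mass=18.06)
        with pytest.raises(InfeasibleFeedstockError):
            boyle_coefficients(f)


class TestGasComposition:
    def test_reference_sludge_trace_on_and_off(self, sludge_formula):
        s = boyle_coefficients(sludge_formula)
        assert gas_composition(s, include_trace=True)["CH4"] == pytest.approx(
            0.497, abs=1e-3
        )
        assert gas_composition(s, include_trace=False)["CH4"] == pytest.approx(
            0.535, abs=1e-3
        )

    def test_fractions_sum_to_one(self, sludge_formula):
        s = boyle_coefficients(sludge_formula)
        for flag in (True, False):
            assert sum(gas_composition(s, include_trace=flag).values()) == pytest.approx(
                1.0, abs=1e-12
            )

    def test_all_zero_coefficients_undefined(self, sludge_formula):
        s = StoichiometryResult(0.0, 0.0, 0.0, 0.0, 0.0, sludge_formula)
        with pytest.raises(InfeasibleFeedstockError):
            gas_composition(s)


class TestTheoreticalYields:
    def test_glucose_reference_value(self):
        # 3 mol CH4 x 22.414 L/mol per 0.180156 kg
        assert theoretical_methane_yield(GLUCOSE) == pytest.approx(373.2, abs=0.5)

    def test_molar_volume_linearity(self, sludge_formula):
        y1 = theoretical_methane_yield(sludge_formula, molar_volume=22.414)
        y2 = theoretical_methane_yield(sludge_formula, molar_volume=44.828)
        assert y2 == pytest.approx(2.0 * y1, rel=1e-14)

    def test_reference_sludge_per_kg_dry(self, sludge_formula):
        assert theoretical_methane_yield(sludge_formula) == pytest.approx(450.8, abs=0.5)

    def test_vs_normalization(self, sludge_formula, sludge_pa):
        dry = theoretical_methane_yield(sludge_formula)
        vs = theoretical_methane_yield(
            sludge_formula, vs_fraction=sludge_pa.volatile_solid_frac
        )
        assert vs == pytest.approx(dry / 0.601, rel=1e-12)

    def test_biogas_yield_exceeds_methane_yield(self, sludge_formula):
        assert theoretical_biogas_yield(sludge_formula) > theoretical_methane_yield(
            sludge_formula
        )

    def test_bad_molar_volume(self, sludge_formula):
        with pytest.raises(ValueError):
            theoretical_methane_yield(sludge_formula, molar_volume=0.0)
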