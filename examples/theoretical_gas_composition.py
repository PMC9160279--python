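"""Predict biogas composition and theoretical methane yield (Buswell-Boyle)."""

from biogaskit import (
    UltimateAnalysis,
    boyle_coefficients,
    theoretical_methane_yield,
    to_empirical_formula,
)

ua = UltimateAnalysis(
    c_frac=0.4519, h_frac=0.07299, n_frac=0.03579, s_frac=0.0094, o_frac=0.42992
)
f = to_empirical_formula(ua, basis_mass=100.0)
s = boyle_coefficients(f)

print(f"per mole of {f}:")
print(f"  water demand : {s.water_coeff:.3f} mol")
print(f"  CH4 {s.ch4_coeff:.3f}  CO2 {s.co2_coeff:.3f}  "
      f"NH3 {s.nh3_coeff:.4f}  H2S {s.h2s_coeff:.5f} mol")
print("gas composition (all products):",
      {k: round(v, 3) for k, v in s.gas_fractions().items()})
print("gas composition (CH4+CO2 only):",
      {k: round(v, 3) for k, v in s.gas_fractions(include_trace=False).items()})
print(f"theoretical methane yield: {theoretical_methane_yield(f):.0f} L/kg dry")
print(f"  ... per kg volatile solids: "
      f"{theoretical_methane_yield(f, vs_fraction=0.601):.0f} L/kg VS")
# ~50% methane in the full product gas is typical for a partly oxidized
# sludge; the theoretical yield is an upper bound (complete conversion).
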