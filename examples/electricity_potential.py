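"""Convert gas volumes into electricity, including the full analysis chain."""

from biogaskit import (
    UltimateAnalysis,
    boyle_coefficients,
    electricity_from_biogas,
    electricity_from_methane,
    to_empirical_formula,
)
from biogaskit.electricity import aggregate_period

# Worked estimates at Cp(CH4) = 10 kWh/m3 and 30% electrical efficiency:
opt = electricity_from_methane(6.3)  # 6.3 m3 methane at the optimum condition
upgraded = electricity_from_biogas(17.9, 0.616)  # 17.9 m3 biogas at 61.6% CH4
print(f"6.3 m3 CH4            -> {opt.e_elec_rounded} kWh")
print(f"17.9 m3 biogas @61.6% -> {upgraded.e_elec_rounded} kWh")
print("period total:", aggregate_period([opt, upgraded], "example period"))

# Chaining from the elemental analysis: use the Boyle methane fraction for a
# hypothetical 10 m3 of digester biogas.
ua = UltimateAnalysis(0.4519, 0.07299, 0.03579, 0.0094, 0.42992)
f_ch4 = boyle_coefficients(to_empirical_formula(ua)).gas_fractions()["CH4"]
chain = electricity_from_biogas(10.0, f_ch4)
print(f"10 m3 biogas at the stoichiometric CH4 fraction {f_ch4:.3f} "
      f"-> {chain.e_elec_rounded} kWh")
# Each kWh figure is Q x F_CH4 x Cp x eta: gas volume, methane share,
# methane energy density, and engine efficiency.
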