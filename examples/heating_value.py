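"""Estimate heating values from elemental composition (Dulong)."""

from biogaskit import UltimateAnalysis, convert_energy, dulong_hhv, hhv_to_lhv

ua = UltimateAnalysis(
    c_frac=0.4519, h_frac=0.07299, n_frac=0.03579, s_frac=0.0094, o_frac=0.42992
)
hhv = dulong_hhv(ua)
ev = hhv_to_lhv(hhv, ua.h_frac)

print(f"Dulong HHV: {hhv:,.0f} kJ/kg "
      f"({convert_energy(hhv, 'kJ/kg', 'MJ/kg'):.1f} MJ/kg, "
      f"{convert_energy(hhv, 'kJ/kg', 'cal/g'):,.0f} cal/g)")
print(f"LHV       : {ev.lhv:,.0f} kJ/kg "
      f"(subtracting {ev.water_mass_per_kg:.3f} kg combustion water/kg fuel "
      f"x {ev.dhv_mass} MJ/kg latent heat)")
# A bomb-calorimeter value of 5042.2 cal/g corresponds to
print(f"bomb calorimeter 5042.2 cal/g = "
      f"{convert_energy(5042.2, 'cal/g', 'MJ/kg'):.1f} MJ/kg")
# Both figures sit inside the 11-25.5 MJ/kg range reported for sewage
# sludges; Dulong underestimates sugary sludges by roughly 15%.
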