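"""Parse a feedstock characterization and derive its empirical formula."""

import io

from biogaskit import load_proximate_analysis, load_ultimate_analysis, to_empirical_formula

ULTIMATE = """element,percent
C,45.19
N,3.579
H,7.299
S,0.94
O,42.992
"""

PROXIMATE = """component,percent
moisture,6.3
volatile_solid,60.1
ash,27.0
fixed_carbon,6.7
sulfur,0.9
"""

ua = load_ultimate_analysis(io.StringIO(ULTIMATE))
pa = load_proximate_analysis(io.StringIO(PROXIMATE))
formula = to_empirical_formula(ua, basis_mass=100.0)

print("mass fractions:", {k: round(v, 5) for k, v in ua.fractions().items()})
print("empirical formula:", formula)
print(f"volatile solids: {pa.volatile_solid:.1f}% of dry mass")
# The formula's subscripts are moles of each element in 100 g of dry sludge;
# they are the inputs to both the gas stoichiometry and the Dulong estimate.
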