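"""Simulate batch digestion across temperature regimes and locate optimal HRT."""

import numpy as np

from biogaskit import (
    BatchKineticsParams,
    TemperatureResponse,
    optimal_hrt,
    simulate_batch,
    temperature_factor,
)

params = BatchKineticsParams(b0=450.0, rmax=28.0, lag=2.0)  # mL, mL/day, days
tr = TemperatureResponse()  # cardinal temperatures 10 / 35 / 45 degC
days = np.arange(0.0, 49.0)

for T in (25.0, 35.0, 45.0):
    f = temperature_factor(T, tr)
    s = simulate_batch(params, tr, T, days)
    if "no_production" in s.flags:
        print(f"{T:>4.0f} degC: rate factor {f:.2f} -> no gas production")
        continue
    hrt = optimal_hrt(params.scaled_rate(f), q=0.95)
    print(f"{T:>4.0f} degC: rate factor {f:.2f}, "
          f"day-30 volume {s.cumulative_biogas[30]:.0f} mL, "
          f"optimal HRT (95% of asymptote) {hrt:.1f} days")
# The mesophilic optimum finishes in ~25 days; at 25 degC the same digester
# needs ~41 days, and at the thermophilic boundary (45 degC) nothing is
# produced -- the qualitative ordering seen in sludge digestion studies.
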