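# Methods

## Scope and model chain

biogaskit models the desk-calculation chain used in waste-to-bioenergy
assessments of an organic substrate:

1. characterization (ultimate + proximate analysis) → empirical formula;
2. Buswell–Boyle stoichiometry → theoretical gas composition and methane
   potential;
3. Dulong correlation → higher/lower heating value;
4. batch kinetics with a temperature response → production curves and
   optimal hydraulic retention time (HRT);
5. E = Q·F·Cp·η → electricity potential.

Each stage is usable on its own; `pipeline.run_pipeline` chains them and
emits a canonical JSON report.

## Characterization

`UltimateAnalysis` stores dry-basis mass fractions of C, H, N, S, O and
enforces closure: each fraction in [0, 1] and the five-element sum in
[0.95, 1.00], tolerating small analytic closure error.  Published tables
are sometimes dry-basis, sometimes dry-ash-free; since the two read
identically, a `basis` flag ("dry" / "daf") records the caller's intent and
changes only the denominator of reported yields, never the arithmetic.
When a table omits rows, missing non-carbon elements default to 0% (an
assay reporting only carbon is a legitimate degenerate input); carbon is
mandatory and unknown element symbols are rejected by name.  Closure then
rejects genuinely incomplete assays.

Proximate closure (moisture + volatile solids + ash + fixed carbon) is
allowed in [95, 105]% because printed tables often do not close exactly;
the reference beverage-sludge composition shipped with the synthetic
generator closes at 100.1%.  Where a source document disagrees with itself
on a value (e.g. moisture 6.26 vs 6.3%), the tabulated value is stored.

Atomic weights are fixed 4-decimal IUPAC values (C 12.011, H 1.008,
O 15.999, N 14.007, S 32.06) so that formula conversion is bit-reproducible.
The formula→fractions→formula round trip is exact to 1e-9 relative and the
conversion is exactly linear in basis mass (both property-tested).

## Stoichiometry

The Boyle extension of the Buswell equation is implemented in closed form
(coefficients in the module docstring).  C, H and O conservation are
asserted on every call at 1e-9 (scaled); the closed form is additionally
cross-checked in the test suite against an *independent* oracle — a numpy
`linalg.solve` of the explicit 5×5 element-balance system — on 1000 random
compositions at 1e-10.  Compositions whose CH₄ or CO₂ coefficient would be
negative (too reduced / too oxidized for the model) raise
`InfeasibleFeedstockError`.

Gas composition is reported both over all four products (the model's
"biogas") and over CH₄+CO₂ only, since most published composition figures
ignore trace gases.  The molar volume defaults to 22.414 L/mol (0 °C,
1 atm) and is configurable because gas reference conditions are frequently
unstated in the literature this feeds on.

The yield is *theoretical*: the model assumes complete conversion, no
biomass synthesis and no ash interaction, so it upper-bounds measured
biochemical methane potential.

## Energetics

Dulong: `HHV = 33801·C + 144158·(H − 0.125·O) + 9413·S` (kJ/kg, mass
fractions).  Negative available hydrogen (H < O/8) is allowed — the
correlation simply debits the oxygen-bound hydrogen.

HHV→LHV uses `water_mass_per_kg = H·(18.015/2.016)` (kg water formed per
kg fuel), optionally plus fuel moisture (off by default: the classical n
counts combustion water only).  The mass latent heat defaults to the
conventional rounded 2.445 MJ/kg (= 44.013 kJ/mol over 18.0 g/mol);
`latent_heat_of_water(18.015)` supplies the unrounded 2.4431 MJ/kg for
callers who prefer standard constants.  The identity
`hhv − lhv = water·ΔHv·1000` holds exactly by construction and is
property-tested.  A negative LHV is flagged (`degenerate`), not raised.

Unit conversion uses the thermochemical calorie (4.184 J).  For the
reference sludge the Dulong estimate (18.1 MJ/kg) sits ~14% below the
bomb-calorimeter value (5042.2 cal/g = 21.1 MJ/kg); both fall inside the
11–25.5 MJ/kg range reported for sewage sludges, and the gap is expected —
Dulong systematically underestimates carbohydrate-rich fuels.

## Kinetics

No single rate law is canonical for batch digestion curves; the package
defaults to the modified Gompertz model (the standard choice for batch
anaerobic digestion data) with first-order kinetics as the alternative:

    Gompertz:    B(t) = b0 · exp(−exp(rmax·e/b0 · (λ − t) + 1))
    first-order: B(t) = b0 · (1 − exp(−k·t))

Both are non-decreasing and bounded by b0 (property-tested on random
parameters).

**Temperature** enters as a CTMI (cardinal temperature model with
inflection) multiplier f(T) ∈ [0, 1] applied to rmax or k, with defaults
(t_min, t_opt, t_max) = (10, 35, 45) °C: f(35) = 1, f(25) = 0.6 exactly,
f ≡ 0 at or beyond the cardinal bounds.  A digester outside the viable
window returns an all-zero, `"no_production"`-flagged series rather than an
error.  One parameterization quirk is documented rather than hidden:
because rmax sits inside the double exponential, scaling it down *raises*
the curve slightly in the sub-lag region (t < λ, values bounded by
B(λ) = b0·e^−e ≈ 6.6% of b0); pointwise temperature ordering therefore
holds from the lag onward, which is the region that matters for HRT.

**Fitting** is Levenberg–Marquardt nonlinear least squares via lmfit, with
a deterministic heuristic start (b0 ← 1.2·max observation; rmax ← max
finite difference; λ ← first time above 5% of max) and an optional seeded
random perturbation (±30%) for sensitivity probing.  At least 4
observations are required.  Diagnostics: SSE, per-parameter standard
errors, convergence flag; non-convergence raises `FitError` carrying the
last iterate.

**Optimal HRT** is a convention, made explicit: the smallest t with
B(t) ≥ q·b0 (default q = 0.95), found by bracketing + Brent root finding
to 0.01 days, or the argmax of dB/dt (the Gompertz inflection
t = λ + b0/(rmax·e); t = 0 for first-order).  Both are cross-checked
against closed forms and brute-force grids in the tests.

## Synthetic studies

The generator emulates triplicate 500 mL batch optimization experiments:
full factorial over pH {5.5, 6.5, 7.5, 8.5, 9.5}, substrate:water loading
{1:3, 1:4, 1:5, 1:6} and temperature {25, 35, 45} °C, sampled on a weekly
grid over a 30-day HRT (extensible to 48 days).

The true response is multiplicative on (b0, rmax): a Gaussian bump in pH
centred at 8.5 (width 1.2 pH units), a dilution penalty
(f/f_opt)^slope with optimum at 1:3, and the CTMI factor.  Base parameters
b0 = 450 mL, rmax = 28 mL/d, λ = 2 d were chosen so the 95%-of-asymptote
HRT is ≈25 d at 35 °C and ≈41 d at 25 °C — the mesophilic-vs-psychrophilic
ordering and day counts typical of sludge digestion — without digitizing
any published curve.  Methane fraction is drawn around a configurable mean
(default 0.41 ± 0.02), a typical methane share of total gas for a partly
oxidized sludge.

Noise is additive Gaussian with sd = `noise_sd_frac` (default 2%) × the
condition's b0, floored at the previous reading because a cumulative gas
record cannot decrease; syringe/gas-bag volume reads are approximately
symmetric-error, so the additive model is reasonable.  Replicate variance
in real studies of this kind is rarely reported; 2% is a convention, and a
calibration test confirms the realized day-30 sd matches it within 30%.

What passing tests on these data do *not* show: the generator has no
mechanistic pH/VFA chemistry, no ammonia or H₂S inhibition, no adaptation
or replicate-specific lag variation, and its noise is homoscedastic.
Parameter-recovery results therefore demonstrate the estimator's
correctness under the stated noise model, not robustness to real-world
artefacts.

## Pipeline and reproducibility

`PipelineConfig` (pydantic) validates all knobs; every report embeds the
fully resolved configuration and seed, and `report_json` serializes with
sorted keys and stable float formatting so identical configurations yield
byte-identical reports (tested).  Stage failures propagate as `StageError`
tagged with the stage name.  The CLI is a thin click layer; YAML config
values are overridden by CLI options.

## Problem sizes

The test suite runs the full stack at small scale by design: 1000 random
formulas for the stoichiometry oracle, 20 seeds × 3 replicates × 31 daily
points for parameter recovery, and the default factorial design (180
series × 5 time points) for the generator checks — together a few seconds
of compute.

## Known limitations

- Theoretical yields assume complete conversion; no biodegradability or
  ADM1-style speciation is attempted.
- The Dulong correlation is fuel-class dependent; alternatives
  (Boie, Channiwala–Parikh) are out of scope.
- Volumes are treated as unit-tagged numbers; the package never converts
  between per-mass and absolute volumes implicitly, because upstream
  sources are frequently inconsistent about these units.
- Period aggregation of electricity estimates is a plain sum; no
  load-profile or engine-dispatch modelling.
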