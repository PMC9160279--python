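"""Generate a synthetic triplicate study and recover its kinetics by fitting."""

from biogaskit import ExperimentDesign, ResponseSurface, fit_kinetics, generate_study, truth_manifest
from biogaskit.synthetic_data import condition_key

design = ExperimentDesign(
    ph_levels=(8.5,),
    loading_ratios=("1:3",),
    temperatures_c=(35.0,),
    replicates=3,
    sampling_days=tuple(float(d) for d in range(31)),
    noise_sd_frac=0.02,
    seed=7,
)
surface = ResponseSurface()
truth = truth_manifest(design, surface)["conditions"][condition_key(8.5, "1:3", 35.0)]

print(f"true parameters: b0={truth['b0']:.0f} rmax={truth['rmax']:.1f} lag={truth['lag']:.1f}")
for s in generate_study(design, surface):
    r = fit_kinetics(s)
    err = abs(r.params.b0 - truth["b0"]) / truth["b0"]
    print(f"{s.reactor_id}: b0={r.params.b0:.1f} (+-{r.stderr['b0']:.1f}), "
          f"rmax={r.params.rmax:.2f}, lag={r.params.lag:.2f}, "
          f"SSE={r.sse:.0f}, |b0 error|={err:.1%}")
# With 2% measurement noise and daily sampling the asymptote is typically
# recovered to within a couple of percent per replicate.
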