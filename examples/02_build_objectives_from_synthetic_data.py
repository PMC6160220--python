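"""Generate a synthetic 'experimental' dataset and turn it into optimization
objectives.

Draws a small population of ground-truth pyramidal cAC cells (each with its
own morphology and conductance vector), simulates noisy step responses,
pools electrophysiological features into per-(feature, amplitude) mean ± sd,
and prints the resulting objective set — the constraints a model optimization
must satisfy.
"""

import warnings

warnings.simplefilter("ignore")

from ca1degen import synthetic as syn

ensemble = syn.make_ensemble("pyr_cAC_desk", n=12, seed=0)
counts = ensemble.spike_counts(0.8)
print(f"{len(ensemble.traces)} cells; spike counts at 0.8 nA: {sorted(counts)}")

objectives = syn.build_objective_sets(ensemble)["pyr_cAC_desk"]
print(f"\n{len(objectives)} objectives (feature @ amplitude: mean ± sd):")
for o in objectives.objectives:
    print(f"  {o.feature:22s} @{o.protocol_amplitude:+.1f} nA: "
          f"{o.exp_mean:9.3f} ± {o.exp_sd:.3f}")

print("\nA candidate model scores |value - mean|/sd per objective; it is")
print("acceptable when every objective deviates by less than 2 sd.")
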