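"""Fit peak conductances to feature objectives with the evolutionary search.

A deliberately tiny run (population 16, 12 generations, a few minutes): the
indicator-based selection operates on the per-objective z-score vectors,
variation uses simulated-binary crossover and polynomial mutation on the
log-scaled conductances.  Prints the per-generation best total score and the
best individual's objective breakdown.
"""

import warnings

warnings.simplefilter("ignore")

import numpy as np

from ca1degen import load_template
from ca1degen import synthetic as syn
from ca1degen.objectives import ModelEvaluator
from ca1degen.optimizer import EvolutionConfig, evolve

ensemble = syn.make_ensemble("pyr_cAC_desk", n=12, seed=0)
objectives = syn.build_objective_sets(ensemble)["pyr_cAC_desk"]
template = load_template("pyr_cAC_desk")

run = evolve(
    template.parameter_space(),
    ModelEvaluator(template, objectives),
    EvolutionConfig(pop_size=16, generations=12, seed=42),
    etype="pyr_cAC_desk",
)

print("best total score per generation:")
print(" ", np.round(run.history, 2))
best = run.best
print(f"\nbest individual: total {best.total:.2f}, acceptable={best.acceptable}")
for (feature, amp), z in sorted(best.score.scores.items()):
    print(f"  {feature:22s} @{amp:+.1f} nA: z = {z:.2f}")
print("\nThe total is the sum of absolute deviations from the data means in")
print("units of the data sd; every z < 2 makes the individual acceptable.")
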