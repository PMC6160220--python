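"""Analyze ion-channel degeneracy in a population of model solutions.

Uses a synthetic population with known structure (two co-regulated pairs,
tightly-clamped and loose parameters) as a stand-in for pooled hall-of-fame
individuals, and runs the statistical battery: per-parameter stability,
flagged pairwise Spearman correlations, channel proportions, and a Dunn
comparison between two e-type populations.
"""

import numpy as np

from ca1degen import synthetic as syn
from ca1degen.degeneracy import (
    ParameterMatrix,
    channel_proportions,
    etype_comparison,
    normalize_parameter_matrix,
    pairwise_spearman,
    stability_analysis,
)

pop = syn.make_ground_truth("pyr_cAC_desk", n=60, seed=7)
matrix = normalize_parameter_matrix(
    ParameterMatrix("pyr_cAC_desk", pop.param_names, pop.vectors))

stable = stability_analysis(matrix)
print("stable parameters (normalized sd < 0.2):", stable)

table = pairwise_spearman(matrix)
print("\nflagged correlations (|rho| > 0.25, p < 0.05):")
for _, r in table[table.flagged].iterrows():
    print(f"  {r.param_a:12s} ~ {r.param_b:12s}  rho={r.rho:+.2f}  p={r.p:.2e}")

props = channel_proportions(matrix)
print("\ntop channel proportions of total average peak conductance:")
for _, r in props.sort_values("fraction", ascending=False).head(5).iterrows():
    print(f"  {r.parameter:12s} {100 * r.fraction:5.1f}%")

pyr = syn.make_ground_truth("pyr_cAC_desk", n=20, seed=1)
nac = syn.make_ground_truth("int_cNAC", n=20, seed=2)
shared = sorted(set(pyr.param_names) & set(nac.param_names))
samples = {
    "pyr_cAC": {p: pyr.vectors[:, pyr.param_names.index(p)] for p in shared},
    "int_cNAC": {p: nac.vectors[:, nac.param_names.index(p)] for p in shared},
}
comp = etype_comparison(samples)
print(f"\n{len(comp)} parameter(s) differ between e-types (Dunn p < 0.05), e.g.:")
print(comp.head(5).to_string(index=False))
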