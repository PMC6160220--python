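# Methods

## Compartmental model

Morphologies are trees of unbranched sections tagged soma / axon / basal /
apical. The soma is a single isopotential compartment (sphere surface area
πd² for a single-point soma); each other section is split into ⌈L/Δx⌉ equal
compartments (Δx = 50 µm default, 100 µm in the desk-scale template), with
membrane area and volume integrated exactly from the piecewise-cylinder
geometry so discretization conserves both. Path distance is measured along
the tree from the soma centre; children of the soma start at the soma
radius. Stylized generators provide a pyramidal template (20 µm soma, 400 µm
tapering apical trunk, 200 µm basal dendrite, 60 µm axon stub) and an
interneuron template (15 µm soma, two 150 µm dendrites, axon stub); standard
7-column SWC files are read and written, with unknown type codes mapped to
basal under a warning. Axons are represented as two-compartment stubs —
sufficient to give the axonal conductance class a distinct electrical
location without committing to unconstrained arbor geometry.

Membrane currents are ohmic HH-type currents, outward positive:
i = ḡ(x)·Πₖ xₖ^{pₖ}·(V−E), with fixed reversals E_Na = +50, E_K = −90,
E_h = −30, E_Ca = +120 mV (no GHK). The 11-current roster is Na, K_DR, K_A,
K_M, K_D, CaN, CaL, CaT, I_h, K_Ca and Cagk. Every gate is parameterized in
steady-state/time-constant form — voltage gates as a Boltzmann x_inf with a
bell-shaped τ(V), calcium gates as Hill functions of shell calcium, the BK
gate (Cagk) as the product of a Hill term and a voltage sigmoid — with all
parameter values in the versioned `data/kinetics.json`. The parameter values
are this package's own calibration of standard functional forms (tuned so the
pyramidal template fires accommodating trains at 0.4 nA and the interneuron
templates express their firing classes); temperature effects are considered
folded into the stored τ values. In pyramidal cells K_A and I_h rise
linearly with apical path distance, ḡ·min(1 + d/100 µm, 6); interneurons use
uniform profiles.

Shell calcium (0.1 µm shell, rest 50 nM) integrates
dCa/dt = −k·I_Ca/(2F·depth) − (Ca−Ca_rest)/τ_Ca with τ_Ca = 100 ms, advanced
by the exact per-step solution of the linear ODE, so free decay is exactly a
100 ms single exponential at any step size.

## Numerical integration

Fixed step dt = 0.025 ms with a 200 ms settle phase from V = e_pas. Gates
advance by analytic exponential relaxation toward x_inf; the voltage system,
linear once gates are frozen, is solved implicitly on the tree with Hines
elimination. The default order-2 scheme solves for the half-step voltage and
extrapolates (Crank–Nicolson); order 1 (backward Euler) is available. Axial
coupling between neighbours is the series combination of each compartment's
half-cylinder conductance (π/4)d²/(Ra·L/2). Voltage-only gate rates are
tabulated on a 0.05 mV grid per (parameter-set, dt) and linearly
interpolated inside the compiled kernel; calcium-dependent gates stay
analytic. |V| > 200 mV marks divergence; during optimization a diverged
individual receives the penalty score on every objective rather than raising.
Verification: a passive compartment reproduces ΔV = I/(gA) to 0.5% and
τ = Cm/g_pas to 1%; a ≤5-compartment passive cable matches an independent
dense-matrix implementation of the same scheme to 1e-6 mV; active spike
times at dt = 0.025 ms lie within 0.5 ms of a 20×-finer integration.

## Features, objectives, scoring

The feature registry covers spike count, time to first spike, mean ISI, ISI
values, adaptation index (mean of (ISIₖ₊₁−ISIₖ)/(ISIₖ₊₁+ISIₖ)), mean AP
amplitude and AHP depth, baseline/steady-state voltage, voltage deflection
and input resistance (hyperpolarizing steps only). Spikes are upward
crossings of −20 mV with a re-arm level 10 mV below threshold; the re-arm
suppresses double counts from the axo-somatic AP shoulder, which briefly
recrosses threshold mid-spike, while genuine inter-spike intervals always
repolarize far below it. Undefined features (e.g. ISI statistics with <3
spikes) are flagged, never zero-filled.

Statistics pool features across all cells of an e-type (sample sd, n−1).
When a pooled sd collapses it is floored at max(sd, 0.05·|mean|, 1e-3) to
keep z-scores finite. The default objective list is a curated robust subset:
spike count at every amplitude, subthreshold features on the hyperpolarizing
step, mean ISI and AP amplitude on depolarizing steps, accommodation at the
lowest suprathreshold amplitude and spike latency at the strongest — 13
objectives for the three-step protocol (the full registry can be used
instead). Scoring: z = |value−mean|/sd per objective, total = Σz,
acceptable ⇔ every z < 2 (strict); undefined features and failed simulations
take a fixed penalty of 250 per objective, large enough to dominate any
feasible score while remaining finite for rank-based selection.

E-type classification uses the lowest suprathreshold amplitude with ≥4
spikes — accommodation and bursting are most expressed near rheobase. Burst
index b = ISI₁/mean(later ISIs) < 0.4 → bAC; otherwise adaptation
index > 0.01 → cAC, else cNAC. The burst threshold sits below the ~0.45
values that long continuously-accommodating trains reach (their late ISIs
dominate the mean) yet far above genuine onset bursts (b ≈ 0.1–0.2); both
thresholds are arguments.

## Evolutionary search

Parameters are peak conductances per compartment class
(`g<channel>bar s|a|b|d`) plus passive entries (`g_pas c`, `e_pas c`, `Cm`,
`Ra`). Conductance bounds span at least one order of magnitude (a decade
around the template default; two decades for the adaptation conductances
K_M, K_Ca, Cagk) and are sampled and varied on a log scale. Each generation
draws offspring by simulated-binary crossover (η = 10, p = 0.7) and bounded
polynomial mutation (η = 20, per-gene p = 1/dim), evaluates them, and
applies additive-ε indicator-based environmental selection over the
per-objective z-vectors to the combined parent+offspring pool; an elitist
step keeps the best-total individual in the population, making the best-score
history non-increasing. Runs are bit-reproducible from their seed. The
hall of fame holds the k = 10 lowest totals, ties broken by earlier
generation then insertion order. The desk-scale configuration is population
32 on a 12-parameter pyramidal space over an 8-compartment morphology, 30
generations (the best score stabilizes by generation ~20–30); the full-scale
configuration mirrors a production setting (population 128, full 37-parameter
space) and is exercised only indirectly.

## Synthetic ground truth

The generator emulates the structure of a pooled experimental step-response
dataset. A population draws each parameter from one of three roles: clamped
(lognormal with small relative sd around the template default — the
tightly-regulated currents), loose (log-uniform over the full bounds), or
fixed; couplings (e.g. K_M–Cagk inverse at strength 0.9, Na–K_DR positive at
0.8) are imposed on latent Gaussians before the monotone transforms, so
Spearman structure survives by construction. Latents are truncated at ±2σ —
a tightly-regulated population without extreme outlier cells. Each cell
additionally receives its own morphology (truncated-normal soma diameter and
neurite lengths), and recordings get 0.5 mV additive white noise, which is
far below the spike-detection margin.

Two presets express two study questions. The default preset keeps the
spiking machinery tight and co-regulated so that ≥95% of generated cells
classify as their generating e-type; the variability preset widens the
adaptation-current spreads and the morphology range to reproduce the ≥2-fold
inter-cell spike-count range at 0.8 nA seen in pooled recordings (cells near
rheobase may then stay silent at 0.4 nA, as real near-threshold cells do).
No single parameterization does both: class purity and maximal heterogeneity
trade off directly, which is itself a faithful property of pooled datasets.

What passing tests on these data do and do not show: they demonstrate that
the pipeline recovers imposed statistical structure (clamped vs loose
parameters, coupling signs, group differences) and that the optimization
closes the loop on data generated by its own model family. They do not
certify kinetics against voltage-clamp measurements, nor feature parity with
full-scale feature libraries, nor behaviour on morphologies far outside the
stylized templates.

Against objectives built from the default ensemble, the generating parameter
vectors score acceptable on the reference morphology in ~85% of cells
(83–97% across draws): with ~13 objectives and a strict 2-sample-sd
acceptance, a few cells per 30 necessarily sit beyond 2 sd on some feature.
The end-to-end experiment is unaffected — the optimizer targets the
acceptance region directly and reaches it in every seeded run.

## Statistical conventions

Sample sd (n−1) throughout. Spearman ρ is tie-corrected; p-values are exact
permutation enumerations for n ≤ 8 (evaluated as batched rank
cross-products) and t-approximations above; correlation flags use raw
p < 0.05 with |ρ| > 0.25, and Benjamini–Hochberg adjusted values are
reported alongside. Dunn's pairwise test runs on pooled tie-corrected ranks
after a significant Kruskal–Wallis test, unadjusted by default (a plain
p < 0.05 rule) with an optional Holm switch. Channel proportions divide each
conductance's mean over individuals by the summed means (raw S/cm², no area
weighting), optionally pooled per channel across compartment classes. bAP
attenuation classifies the distal/somatic amplitude ratio as
strong-attenuating (< 0.3), weak-attenuating (≥ 0.5) or intermediate;
the thresholds bracket the observed bimodality and are arguments.

## Known limitations

- Kinetics are calibrated functional forms, not fits to voltage-clamp data;
  analyses that depend on one kinetic digit should swap in their own
  `kinetics.json`.
- The desk morphologies are few-compartment stylizations; spatial phenomena
  finer than the compartment length (Δx = 50–100 µm) are not resolved.
- The acceptance rule and penalty constant are conventions; results are
  reported with them fixed.
- Higher-order (beyond pairwise) correlation structure among parameters is
  not analyzed.
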