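"""Synthetic ground-truth model populations and noisy trace ensembles.

This module stands in for an experimental dataset: it draws populations of
conductance vectors with a controlled statistical structure — tightly
clamped parameters, loosely (log-uniformly) varying parameters, and
rank-preserving couplings between chosen pairs — simulates each cell's step
responses, and adds Gaussian recording noise.  Feature statistics built from
such an ensemble exhibit the large inter-cell variability the analyses
assume (e.g. a ≥2-fold spread in spike count at 0.8 nA), while the imposed
structure gives every downstream statistic a known truth to recover.

Couplings are realized through a Gaussian copula: latent standard normals
are correlated with the requested sign and strength, then mapped through
monotone transforms, so Spearman rank correlations are preserved by
construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr

from .efeatures import aggregate_statistics, classify_etype, detect_spikes
from .morphology import GeometryConfig, Morphology, make_synthetic_morphology
from .objectives import ObjectiveSet, default_objective_keys
from .parameters import ParameterSpace
from .simulator import IntegrationError, VoltageTrace, build_model, run_protocol
from .templates import EtypeTemplate, StimulusProtocol, load_template

__all__ = [
    "StructureConfig",
    "MorphologyVariability",
    "GroundTruthPopulation",
    "SyntheticEnsemble",
    "default_structure",
    "variability_structure",
    "WIDE_MORPHOLOGY",
    "make_ground_truth",
    "sample_morphologies",
    "simulate_trace_ensemble",
    "build_objective_sets",
    "make_ensemble",
    "classification_accuracy",
]

DEFAULT_NOISE_SD = 0.5  # mV additive white recording noise


@dataclass
class StructureConfig:
    """Which parameters are clamped (small relative spread), loose
    (log-uniform over the full bounds, ≥1 decade), or coupled (sign ±1 and
    copula strength in (0,1)).  Unlisted parameters stay at the template
    default with zero spread."""

    clamped: dict[str, float] = field(default_factory=dict)  # name -> relative sd
    loose: list[str] = field(default_factory=list)
    coupled: list[tuple[str, str, int, float]] = field(default_factory=list)
    centre_overrides: dict[str, float] = field(default_factory=dict)  # name -> centre

    def validate(self, space: ParameterSpace) -> None:
        names = set(space.names)
        for n in list(self.clamped) + self.loose + list(self.centre_overrides):
            if n not in names:
                raise KeyError(f"structure names unknown parameter {n!r}")
        dependents = [b for _a, b, _s, _r in self.coupled]
        if len(set(dependents)) != len(dependents):
            raise ValueError(
                "a parameter appears as the dependent member of two couplings"
            )
        for a, b, sign, strength in self.coupled:
            if a not in names or b not in names:
                raise KeyError(f"coupling ({a}, {b}) names unknown parameter")
            if a == b or sign not in (-1, 1) or not (0.0 < strength < 1.0):
                raise ValueError(f"invalid coupling ({a}, {b}, {sign}, {strength})")


@dataclass
class GroundTruthPopulation:
    etype: str  # template name, e.g. "pyr_cAC_desk"
    n: int
    param_names: list[str]
    vectors: np.ndarray  # (n, dim), raw scale
    seed: int
    structure: StructureConfig

    @property
    def label(self) -> str:
        """Expected firing-class label (cAC/bAC/cNAC) from the template name."""
        for tag in ("cAC", "bAC", "cNAC"):
            if tag in self.etype:
                return tag
        return "cAC"

    def cell_params(self, i: int) -> dict[str, float]:
        return dict(zip(self.param_names, self.vectors[i]))


@dataclass
class MorphologyVariability:
    """Truncated-normal per-cell geometry spread (µm) around the template's
    defaults — the morphological component of inter-cell variability."""

    soma_centre: float = 20.5
    soma_sd: float = 1.3
    soma_range: tuple[float, float] = (19.2, 22.6)
    apical_sd: float = 55.0
    apical_range: tuple[float, float] = (325.0, 475.0)
    basal_sd: float = 25.0
    basal_range: tuple[float, float] = (150.0, 250.0)
    dend_sd: float = 20.0
    dend_range: tuple[float, float] = (110.0, 190.0)


def sample_morphologies(
    template: str | EtypeTemplate,
    n: int,
    seed: int,
    variability: MorphologyVariability | None = None,
) -> list[Morphology]:
    """Draw ``n`` per-cell morphologies around the template geometry."""
    tpl = load_template(template) if isinstance(template, str) else template
    var = variability or MorphologyVariability()
    rng = np.random.default_rng(seed)
    base = GeometryConfig(**tpl.geometry)

    def draw(centre, sd, rng_range):
        return float(np.clip(rng.normal(centre, sd), *rng_range))

    out = []
    for i in range(n):
        cfg = GeometryConfig(**tpl.geometry)
        cfg.soma_diameter = draw(var.soma_centre, var.soma_sd, var.soma_range)
        cfg.apical_length = draw(base.apical_length, var.apical_sd, var.apical_range)
        cfg.basal_length = draw(base.basal_length, var.basal_sd, var.basal_range)
        cfg.dend_length = draw(base.dend_length, var.dend_sd, var.dend_range)
        out.append(
            make_synthetic_morphology(cfg, tpl.cell_template, f"{tpl.name}_cell{i}")
        )
    return out


@dataclass
class SyntheticEnsemble:
    population: GroundTruthPopulation
    traces: list[list[VoltageTrace]]  # per cell, one trace per amplitude
    noise_sd: float
    noise_seed: int
    morphologies: list[Morphology] | None = None

    @property
    def labels(self) -> list[str]:
        return [self.population.label] * len(self.traces)

    def spike_counts(self, amplitude: float) -> np.ndarray:
        out = []
        for cell in self.traces:
            for tr in cell:
                if tr.protocol_amplitude == amplitude:
                    s = detect_spikes(tr).spike_times
                    s = s[(s >= tr.stim_start) & (s <= tr.stim_end)]
                    out.append(s.size)
        return np.array(out)


# Default structure per e-type: the tightly-constrained parameters are the
# passive leak plus the adaptation/integration currents (K_M, K_Ca/Cagk, Ih,
# Ca), with an inverse K_M–Cagk coupling and a compensatory Na–K_DR coupling;
# the excitability conductances vary log-uniformly over their full decade.
_DESK_STRUCTURE = StructureConfig(
    clamped={
        "g_pas c": 0.05,
        # spiking machinery: tight and co-regulated, preserving the firing class
        "gnabar s": 0.08,
        "gkdrbar s": 0.08,
        "gkabar s": 0.08,
        # adaptation currents: wide lognormal spreads drive the inter-cell
        # spike-count variability; K_M and Cagk are inversely coupled
        "gkmbar s": 0.15,
        "gkcabar s": 0.30,
        "gcagkbar s": 0.40,
        "gcalbar s": 0.20,
        "gihbar d": 0.20,
    },
    loose=["gnabar d", "gkdrbar d", "gkabar d",
           "gnabar b", "gkdrbar b", "gkabar b"],
    coupled=[
        ("gkmbar s", "gcagkbar s", -1, 0.9),
        ("gnabar s", "gkdrbar s", 1, 0.8),
    ],
)


def default_structure(etype: str, space: ParameterSpace) -> StructureConfig:
    """The class-pure default: tight co-regulated spiking currents, lognormal
    adaptation-current spreads, loose dendritic conductances, with the
    K_M–Cagk inverse and Na–K_DR positive couplings."""
    names = set(space.names)
    clamped = {k: v for k, v in _DESK_STRUCTURE.clamped.items() if k in names}
    for extra in ("e_pas c", "Cm", "Ra", "gihbar s", "gcanbar s", "gcatbar s"):
        if extra in names:
            clamped.setdefault(extra, 0.05)
    loose = [n for n in _DESK_STRUCTURE.loose if n in names]
    coupled = [c for c in _DESK_STRUCTURE.coupled if c[0] in names and c[1] in names]
    cfg = StructureConfig(clamped=clamped, loose=loose, coupled=coupled)
    cfg.validate(space)
    return cfg


def variability_structure(etype: str, space: ParameterSpace) -> StructureConfig:
    """The high-heterogeneity preset: widened spreads on the adaptation
    currents on top of :func:`default_structure`.  Used when the study
    question is the dataset's full inter-cell variability (I/O-curve spread,
    the ≥2-fold spike-count range at 0.8 nA) rather than a class-pure
    training ensemble."""
    cfg = default_structure(etype, space)
    for name, rel in (("gkmbar s", 0.35), ("gkcabar s", 0.80),
                      ("gcagkbar s", 0.70), ("gnabar s", 0.12),
                      ("gkdrbar s", 0.12)):
        if name in cfg.clamped:
            cfg.clamped[name] = rel
    # stronger slow-AHP centre: adaptation dominates the strong-drive spike
    # count, spreading it across the ensemble
    if "gkcabar s" in set(space.names):
        cfg.centre_overrides["gkcabar s"] = 5e-4
    cfg.validate(space)
    return cfg


# morphology spread used alongside variability_structure
WIDE_MORPHOLOGY = MorphologyVariability(
    soma_centre=20.5, soma_sd=1.8, soma_range=(18.0, 23.4),
    apical_sd=70.0, apical_range=(305.0, 495.0),
)


def make_ground_truth(
    etype: str | EtypeTemplate,
    n: int,
    seed: int,
    structure_config: StructureConfig | None = None,
    space: ParameterSpace | None = None,
) -> GroundTruthPopulation:
    """Draw ``n`` parameter vectors with the requested structure.

    Clamped entries get a truncated-normal relative spread around the
    template default; loose entries are log-uniform over the space bounds;
    coupled dependents are driven by their source's latent with the given
    sign/strength.  Deterministic given the seed; every vector is inside the
    parameter-space bounds.
    """
    tpl = load_template(etype) if isinstance(etype, str) else etype
    space = space or tpl.parameter_space()
    cfg = structure_config or default_structure(tpl.name, space)
    cfg.validate(space)

    rng = np.random.default_rng(seed)
    names = space.names
    dim = space.dim
    defaults = tpl.default_params()

    z = rng.standard_normal((n, dim))
    col = {name: j for j, name in enumerate(names)}
    for a, b, sign, strength in cfg.coupled:
        za = z[:, col[a]]
        z[:, col[b]] = sign * strength * za + np.sqrt(1 - strength**2) * z[:, col[b]]
    # truncate at ±2σ: tightly-regulated parameters do not produce extreme
    # outlier cells (monotone clip, so imposed rank couplings survive)
    z = np.clip(z, -2.0, 2.0)

    lo, hi = space.bounds_arrays()
    vectors = np.empty((n, dim))
    for j, name in enumerate(names):
        centre = cfg.centre_overrides.get(name, defaults[name])
        if name in cfg.loose:
            u = ndtr(z[:, j])  # Gaussian copula -> uniform
            if space.entries[j].scale == "log":
                vals = lo[j] * (hi[j] / lo[j]) ** u
            else:
                vals = lo[j] + (hi[j] - lo[j]) * u
        elif name in cfg.clamped:
            rel = cfg.clamped[name]
            if space.entries[j].scale == "log":
                # lognormal keeps wide relative spreads positive and monotone
                vals = centre * np.exp(rel * z[:, j])
            else:
                vals = centre * (1.0 + rel * z[:, j])
        else:
            vals = np.full(n, centre)
        vectors[:, j] = np.clip(vals, lo[j], hi[j])

    return GroundTruthPopulation(
        etype=tpl.name, n=n, param_names=list(names), vectors=vectors,
        seed=seed, structure=cfg,
    )


def simulate_trace_ensemble(
    pop: GroundTruthPopulation,
    protocol: StimulusProtocol | None = None,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    morphologies=None,
    dt: float = 0.025,
) -> SyntheticEnsemble:
    """Simulate every cell of a population over the step protocol and add
    Gaussian recording noise.

    Cells may share the template morphology (default) or draw from an
    explicit morphology list (cycled).  A cell that spikes at no depolarizing
    amplitude is kept with a warning — it emulates a near-threshold neuron.
    """
    tpl = load_template(pop.etype)
    protocol = protocol or tpl.protocol
    noise_rng = np.random.default_rng(seed)
    traces: list[list[VoltageTrace]] = []
    for i in range(pop.n):
        morph = None if morphologies is None else morphologies[i % len(morphologies)]
        mesh = tpl.make_mesh(morph)
        model = build_model(mesh, tpl, pop.cell_params(i))
        try:
            cell = run_protocol(model, protocol, dt=dt)
        except IntegrationError:
            warnings.warn(f"cell {i}: integration diverged; cell dropped", stacklevel=2)
            continue
        spiked = False
        for tr in cell:
            tr.metadata["cell"] = i
            if noise_sd > 0:
                tr.voltage = tr.voltage + noise_rng.normal(0.0, noise_sd, tr.voltage.size)
            if tr.protocol_amplitude > 0 and detect_spikes(tr).n > 0:
                spiked = True
        if not spiked:
            warnings.warn(
                f"cell {i}: no spikes at any depolarizing amplitude", stacklevel=2
            )
        traces.append(cell)
    return SyntheticEnsemble(
        population=pop, traces=traces, noise_sd=noise_sd, noise_seed=seed,
        morphologies=list(morphologies) if morphologies is not None else None,
    )


def make_ensemble(
    etype: str | EtypeTemplate,
    n: int,
    seed: int,
    structure_config: StructureConfig | None = None,
    morphology_variability: MorphologyVariability | None | bool = None,
    noise_sd: float = DEFAULT_NOISE_SD,
) -> SyntheticEnsemble:
    """Full synthetic-dataset pipeline: ground-truth population + per-cell
    morphologies + noisy traces, all deterministic from one seed.

    Pass ``morphology_variability=False`` to put every cell on the template
    morphology.
    """
    pop = make_ground_truth(etype, n, seed, structure_config)
    if morphology_variability is False:
        morphs = None
    else:
        var = None if morphology_variability in (None, True) else morphology_variability
        morphs = sample_morphologies(etype, n, seed + 1_000_003, var)
    return simulate_trace_ensemble(pop, morphologies=morphs, noise_sd=noise_sd,
                                   seed=seed + 2_000_003)


def build_objective_sets(
    ensembles: SyntheticEnsemble | list[SyntheticEnsemble],
    features: str = "default",
) -> dict[str, ObjectiveSet]:
    """Aggregate feature statistics per e-type into objective sets (sd floor
    applied).

    ``features="default"`` keeps the curated robust objective list (the
    features stable enough across cells to constrain an optimization);
    ``"all"`` keeps every registry feature defined in the ensemble.
    """
    if isinstance(ensembles, SyntheticEnsemble):
        ensembles = [ensembles]
    out = {}
    for ens in ensembles:
        if len(ens.traces) < 2:
            raise ValueError("need >=2 cells per e-type to build objectives")
        with warnings.catch_warnings():
            # spike-timing features are never defined on hyperpolarizing
            # steps; their omission there is expected, not noteworthy
            warnings.filterwarnings("ignore", message=".*undefined in every trace.*")
            stats = aggregate_statistics(ens.traces)
        if features == "default":
            amps = sorted({tr.protocol_amplitude for cell in ens.traces for tr in cell})
            keep = default_objective_keys(amps)
            stats.stats = {k: v for k, v in stats.stats.items() if k in keep}
        out[ens.population.etype] = ObjectiveSet.from_statistics(ens.population.etype, stats)
    return out


def classification_accuracy(ensemble: SyntheticEnsemble) -> float:
    """Fraction of cells whose heuristic classification matches the
    generating e-type label."""
    hits = 0
    for cell in ensemble.traces:
        if classify_etype(cell) == ensemble.population.label:
            hits += 1
    return hits / len(ensemble.traces)
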