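"""E-type model templates: which channels live in which compartment class,
their default peak conductances and spatial profiles, and the bounded
parameter space optimized for each e-type.

Four e-types are shipped (``pyr_cAC``, ``int_cAC``, ``int_bAC``,
``int_cNAC``) plus a coarser desk-scale pyramidal variant
(``pyr_cAC_desk``) with a reduced search space.  Everything is read from the
editable JSON template file in ``data/templates.json``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .channels import ChannelDistribution, PassiveProperties
from .morphology import GeometryConfig, Morphology, discretize, make_synthetic_morphology
from .parameters import CLASS_TO_SUFFIX, ParameterSpace, SpaceEntry

__all__ = ["EtypeTemplate", "load_template", "available_etypes", "CHANNEL_SHORT"]

CHANNEL_SHORT = {
    "Na": "na", "K_DR": "kdr", "K_A": "ka", "K_M": "km", "K_D": "kd",
    "CaN": "can", "CaL": "cal", "CaT": "cat", "Ih": "ih", "K_Ca": "kca",
    "Cagk": "cagk",
}
SHORT_TO_CHANNEL = {v: k for k, v in CHANNEL_SHORT.items()}

# Bound-derivation conventions: conductances span one decade (x/÷ sqrt(10))
# around the template default on a log scale; passive bounds are fixed windows.
_GBAR_HALF_SPAN = 10.0 ** 0.5
_PASSIVE_BOUNDS = {
    "g_pas c": (None, None, "log"),     # derived like a conductance
    "e_pas c": (-80.0, -60.0, "linear"),
    "Cm": (0.6, 1.8, "linear"),
    "Ra": (80.0, 300.0, "log"),
}


def param_name(channel: str, klass: str) -> str:
    return f"g{CHANNEL_SHORT[channel]}bar {CLASS_TO_SUFFIX[klass]}"


def parse_param_name(name: str) -> tuple[str, str]:
    """Return (channel, compartment_class) for a gbar parameter name."""
    stem, suffix = name.rsplit(" ", 1)
    short = stem[1:-3]  # strip leading 'g' and trailing 'bar'
    klass = {v: k for k, v in CLASS_TO_SUFFIX.items()}[suffix]
    return SHORT_TO_CHANNEL[short], klass


@dataclass
class StimulusProtocol:
    """Somatic step-current protocol: each amplitude applied for ``duration``
    ms after ``delay`` ms of baseline, with ``post`` ms recorded afterwards."""

    amplitudes: list[float] = field(default_factory=lambda: [-0.4, 0.4, 0.8])
    delay: float = 100.0
    duration: float = 400.0
    post: float = 200.0
    recording_sites: list[tuple[str, float]] = field(default_factory=lambda: [("soma", 0.0)])

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")

    @property
    def total_time(self) -> float:
        return self.delay + self.duration + self.post


@dataclass
class EtypeTemplate:
    name: str
    cell_template: str  # pyramidal | interneuron
    geometry: dict
    max_compartment_length: float
    placement: dict[str, dict[str, float]]  # class -> channel -> default gbar
    profiles: dict[str, dict[str, tuple[float, float]]]  # class -> channel -> (slope, cap)
    passive: dict[str, float]
    protocol: StimulusProtocol
    space_names: list[str]  # optimized parameter subset ("full" resolved)
    bounds_overrides: dict[str, tuple[float, float]]

    # -- morphology ---------------------------------------------------------

    def make_morphology(self, identifier: str | None = None) -> Morphology:
        return make_synthetic_morphology(
            GeometryConfig(**self.geometry), self.cell_template, identifier
        )

    def make_mesh(self, morphology: Morphology | None = None):
        morph = morphology or self.make_morphology(self.name)
        return discretize(morph, self.max_compartment_length)

    # -- parameters ---------------------------------------------------------

    def all_param_names(self) -> list[str]:
        names = [
            param_name(ch, klass)
            for klass in ("soma", "axon", "basal", "apical")
            if klass in self.placement
            for ch in self.placement[klass]
        ]
        names += ["g_pas c", "e_pas c", "Cm", "Ra"]
        return names

    def default_params(self) -> dict[str, float]:
        out = {}
        for klass, chans in self.placement.items():
            for ch, gbar in chans.items():
                out[param_name(ch, klass)] = gbar
        out["g_pas c"] = self.passive["g_pas"]
        out["e_pas c"] = self.passive["e_pas"]
        out["Cm"] = self.passive["Cm"]
        out["Ra"] = self.passive["Ra"]
        return out

    def parameter_space(self, names: list[str] | None = None) -> ParameterSpace:
        names = names or self.space_names
        defaults = self.default_params()
        entries = []
        for n in names:
            if n in self.bounds_overrides:
                lo, hi = self.bounds_overrides[n]
                scale = "log" if (n.endswith("bar " + n[-1]) or n == "g_pas c") else "linear"
                klass = "all"
            elif n in _PASSIVE_BOUNDS:
                lo, hi, scale = _PASSIVE_BOUNDS[n]
                if lo is None:  # g_pas: decade around the default
                    centre = defaults[n]
                    lo, hi = centre / _GBAR_HALF_SPAN, centre * _GBAR_HALF_SPAN
                klass = "all"
            else:
                centre = defaults[n]
                lo, hi, scale = centre / _GBAR_HALF_SPAN, centre * _GBAR_HALF_SPAN, "log"
                klass = parse_param_name(n)[1]
            entries.append(SpaceEntry(n, klass, float(lo), float(hi), scale))
        return ParameterSpace(entries)

    # -- model assembly -----------------------------------------------------

    def distributions(
        self, params: dict[str, float] | None = None
    ) -> tuple[list[ChannelDistribution], PassiveProperties]:
        """Instantiate channel distributions and passive properties, taking
        values from ``params`` where given and template defaults otherwise."""
        defaults = self.default_params()
        merged = dict(defaults)
        if params:
            unknown = set(params) - set(defaults)
            if unknown:
                raise KeyError(f"unknown parameter name(s): {sorted(unknown)}")
            merged.update(params)
        dists = []
        for klass, chans in self.placement.items():
            for ch in chans:
                slope, cap = self.profiles.get(klass, {}).get(ch, (0.0, 1.0))
                dists.append(
                    ChannelDistribution(
                        channel=ch,
                        compartment_class=klass,
                        gbar=merged[param_name(ch, klass)],
                        profile="linear_distance" if slope > 0 else "uniform",
                        slope_per_100um=slope,
                        cap=cap,
                    )
                )
        passive = PassiveProperties(
            g_pas=merged["g_pas c"], e_pas=merged["e_pas c"],
            Cm=merged["Cm"], Ra=merged["Ra"],
        )
        passive.validate()
        return dists, passive


def _load_doc(path: str | Path | None = None) -> dict:
    if path is None:
        return json.loads(resources.files("ca1degen").joinpath("data/templates.json").read_text())
    return json.loads(Path(path).read_text())


def available_etypes(path: str | Path | None = None) -> list[str]:
    return list(_load_doc(path)["etypes"])


def load_template(name: str, path: str | Path | None = None) -> EtypeTemplate:
    doc = _load_doc(path)
    try:
        t = doc["etypes"][name]
    except KeyError:
        raise KeyError(f"unknown e-type template {name!r}; available: {list(doc['etypes'])}")
    proto = t.get("protocol", {})
    tpl = EtypeTemplate(
        name=name,
        cell_template=t["morphology"]["template"],
        geometry=t["morphology"].get("config", {}),
        max_compartment_length=float(t["morphology"].get("max_compartment_length", 50.0)),
        placement=t["gbar"],
        profiles={k: {c: tuple(v) for c, v in d.items()} for k, d in t.get("profiles", {}).items()},
        passive=t["passive"],
        protocol=StimulusProtocol(
            amplitudes=list(proto.get("amplitudes", [-0.4, 0.4, 0.8])),
            delay=float(proto.get("delay", 100.0)),
            duration=float(proto.get("duration", 400.0)),
            post=float(proto.get("post", 200.0)),
        ),
        space_names=[],
        bounds_overrides={k: tuple(v) for k, v in t.get("bounds_overrides", {}).items()},
    )
    space = t.get("space", "full")
    tpl.space_names = tpl.all_param_names() if space == "full" else list(space)
    return tpl
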