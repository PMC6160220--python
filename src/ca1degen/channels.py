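"""The 11-current CA1 channel ensemble: gating kinetics, ohmic currents,
calcium dynamics and spatial conductance profiles.

The ensemble comprises a sodium current (Na), four potassium currents (K_DR,
K_A, K_M, K_D), three calcium currents (CaN, CaL, CaT), the nonspecific Ih
current, and two calcium-dependent potassium currents (K_Ca and Cagk).  Each
gate is parameterized in steady-state/time-constant form:

    volt:   x_inf(V) = 1 / (1 + exp((vh - V)/k))
            tau(V)   = tau_min + tau_amp / (exp((V-v_tau)/k1) + exp(-(V-v_tau)/k2))
    ca:     x_inf(Ca) = 1 / (1 + (kd/Ca)^hill),              tau = tau0
    cavolt: x_inf(V,Ca) = ca-part(Ca) * volt-part(V),        tau = tau0

All parameter values live in the versioned JSON kinetics file shipped with the
package (``data/kinetics.json``) and can be swapped for alternative
formulations.  Reversal potentials are fixed (E_Na = +50 mV, E_K = -90 mV,
E_h = -30 mV, E_Ca = +120 mV; no GHK).  Units follow NEURON conventions:
mV, ms, nA, S/cm², µF/cm², Ω·cm, mM.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "CHANNEL_NAMES",
    "FARADAY",
    "GatingVariable",
    "ChannelSpec",
    "ChannelDistribution",
    "PassiveProperties",
    "CalciumState",
    "load_kinetics",
    "default_kinetics",
    "gating_rates",
    "conductance_profile",
    "channel_current",
    "calcium_update",
]

CHANNEL_NAMES = ("Na", "K_DR", "K_A", "K_M", "K_D", "CaN", "CaL", "CaT", "Ih", "K_Ca", "Cagk")
FARADAY = 96485.332  # C/mol

GATE_KIND_VOLT = 0
GATE_KIND_CA = 1
GATE_KIND_CAVOLT = 2
_KIND_CODES = {"volt": GATE_KIND_VOLT, "ca": GATE_KIND_CA, "cavolt": GATE_KIND_CAVOLT}


@dataclass(frozen=True)
class GatingVariable:
    """One Hodgkin–Huxley-style gate in inf/tau form."""

    name: str
    exponent: int
    kind: str
    params: dict

    def x_inf(self, V: float, Ca: float = 5e-5) -> float:
        p = self.params
        if self.kind == "volt":
            return 1.0 / (1.0 + math.exp((p["vh"] - V) / p["k"]))
        if self.kind == "ca":
            return 1.0 / (1.0 + (p["kd"] / max(Ca, 1e-12)) ** p["hill"])
        # cavolt: calcium-dependence times voltage sigmoid
        ca_part = 1.0 / (1.0 + (p["kd"] / max(Ca, 1e-12)) ** p["hill"])
        v_part = 1.0 / (1.0 + math.exp((p["vh"] - V) / p["k"]))
        return ca_part * v_part

    def tau(self, V: float, Ca: float = 5e-5) -> float:
        p = self.params
        if self.kind == "volt":
            u = V - p["v_tau"]
            return p["tau_min"] + p["tau_amp"] / (math.exp(u / p["k1"]) + math.exp(-u / p["k2"]))
        return p["tau0"]

    @property
    def kind_code(self) -> int:
        return _KIND_CODES[self.kind]

    def param_row(self, width: int = 7) -> np.ndarray:
        """Flat parameter row for the compiled solver kernel."""
        p = self.params
        if self.kind == "volt":
            row = [p["vh"], p["k"], p["tau_min"], p["tau_amp"], p["v_tau"], p["k1"], p["k2"]]
        elif self.kind == "ca":
            row = [p["kd"], p["hill"], p["tau0"], 0.0, 0.0, 0.0, 0.0]
        else:
            row = [p["kd"], p["hill"], p["vh"], p["k"], p["tau0"], 0.0, 0.0]
        return np.array(row, dtype=np.float64)


@dataclass(frozen=True)
class ChannelSpec:
    """Kinetics and reversal of one membrane current."""

    name: str
    ion: str  # na | k | ca | nonspecific
    reversal: float  # mV
    gates: tuple[GatingVariable, ...]

    @property
    def is_calcium(self) -> bool:
        return self.ion == "ca"

    def gate(self, name: str) -> GatingVariable:
        for g in self.gates:
            if g.name == name:
                return g
        raise KeyError(f"channel {self.name} has no gate {name!r}")


@dataclass
class ChannelDistribution:
    """Peak conductance and spatial profile of one channel in one compartment class.

    ``linear_distance`` profiles scale the peak conductance as
    ``gbar * min(1 + slope * d/100µm, cap)`` with ``d`` the somatic path
    distance — the distance-dependent rise described for K_A and Ih in
    pyramidal apical dendrites.
    """

    channel: str
    compartment_class: str
    gbar: float  # S/cm²
    profile: str = "uniform"  # uniform | linear_distance
    slope_per_100um: float = 0.0
    cap: float = 1.0

    def __post_init__(self) -> None:
        if self.gbar < 0:
            raise ValueError("gbar must be >= 0")
        if self.profile not in ("uniform", "linear_distance"):
            raise ValueError(f"unknown profile {self.profile!r}")
        if self.profile == "linear_distance" and self.cap < 1:
            raise ValueError("cap must be >= 1 for linear_distance profiles")


@dataclass
class PassiveProperties:
    """Leak, capacitance and axial resistivity (uniform across classes unless
    a per-class dict is given)."""

    g_pas: float | dict = 5e-5  # S/cm²
    e_pas: float | dict = -70.0  # mV
    Cm: float = 1.0  # µF/cm²
    Ra: float = 150.0  # Ω·cm

    def g_pas_of(self, klass: str) -> float:
        return self.g_pas[klass] if isinstance(self.g_pas, dict) else self.g_pas

    def e_pas_of(self, klass: str) -> float:
        return self.e_pas[klass] if isinstance(self.e_pas, dict) else self.e_pas

    def validate(self) -> None:
        gvals = self.g_pas.values() if isinstance(self.g_pas, dict) else [self.g_pas]
        if any(g <= 0 for g in gvals) or self.Cm <= 0 or self.Ra <= 0:
            raise ValueError("g_pas, Cm and Ra must be positive")


@dataclass
class CalciumState:
    """Intracellular calcium in a thin submembrane shell with first-order
    extrusion (single-exponential decay, 100 ms by default)."""

    Ca: float = 5e-5  # mM
    Ca_rest: float = 5e-5  # mM
    tau_Ca: float = 100.0  # ms
    depth: float = 0.1  # µm
    clamp_count: int = 0  # times a negative Ca was clamped to 0


# ---------------------------------------------------------------------------
# Kinetics registry


def _parse_kinetics(doc: dict) -> dict[str, ChannelSpec]:
    reversals = doc["reversals"]
    specs: dict[str, ChannelSpec] = {}
    for name, ch in doc["channels"].items():
        gates = tuple(
            GatingVariable(
                name=g["name"],
                exponent=int(g["exponent"]),
                kind=g["kind"],
                params={k: v for k, v in g.items() if k not in ("name", "exponent", "kind")},
            )
            for g in ch["gates"]
        )
        specs[name] = ChannelSpec(
            name=name, ion=ch["ion"], reversal=float(reversals[ch["ion"]]), gates=gates
        )
    missing = set(CHANNEL_NAMES) - set(specs)
    if missing:
        raise ValueError(f"kinetics file is missing channels: {sorted(missing)}")
    return specs


def load_kinetics(path: str | Path | None = None) -> dict[str, ChannelSpec]:
    """Load a kinetics JSON file (the packaged default when ``path`` is None)."""
    if path is None:
        doc = json.loads(
            resources.files("ca1degen").joinpath("data/kinetics.json").read_text()
        )
    else:
        doc = json.loads(Path(path).read_text())
    return _parse_kinetics(doc)


_DEFAULT: dict[str, ChannelSpec] | None = None


def default_kinetics() -> dict[str, ChannelSpec]:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = load_kinetics()
    return _DEFAULT


def calcium_defaults() -> dict:
    doc = json.loads(resources.files("ca1degen").joinpath("data/kinetics.json").read_text())
    return doc["calcium"]


# ---------------------------------------------------------------------------
# Operations


def gating_rates(
    channel: ChannelSpec | str, gate: str, V: float, Ca: float = 5e-5
) -> tuple[float, float]:
    """Steady state and time constant of one gate at (V, Ca)."""
    spec = default_kinetics()[channel] if isinstance(channel, str) else channel
    g = spec.gate(gate)
    return g.x_inf(V, Ca), g.tau(V, Ca)


def conductance_profile(dist: ChannelDistribution, path_distance: float) -> float:
    """Local peak conductance (S/cm²) at a somatic path distance (µm)."""
    if path_distance < 0:
        raise ValueError("path_distance must be >= 0")
    if dist.profile == "uniform":
        return dist.gbar
    scale = min(1.0 + dist.slope_per_100um * path_distance / 100.0, dist.cap)
    return dist.gbar * scale


def channel_current(
    dist: ChannelDistribution,
    gates_state,
    V: float,
    path_distance: float = 0.0,
    Ca: float = 5e-5,
    kinetics: dict[str, ChannelSpec] | None = None,
) -> float:
    """Ohmic current density i = g(d) · Π x_k^{p_k} · (V − E), outward positive (mA/cm²).

    S/cm² · mV = mA/cm², so no unit factor is needed.
    """
    spec = (kinetics or default_kinetics())[dist.channel]
    states = np.atleast_1d(np.asarray(gates_state, dtype=float))
    if states.size != len(spec.gates):
        raise ValueError(f"{spec.name} expects {len(spec.gates)} gate states")
    if np.any((states < 0) | (states > 1)):
        raise ValueError("gate states must lie in [0, 1]")
    g = conductance_profile(dist, path_distance)
    open_frac = 1.0
    for x, gate in zip(states, spec.gates):
        open_frac *= x ** gate.exponent
    return g * open_frac * (V - spec.reversal)


# mM per ms per (mA/cm²) per µm of shell depth: 1e2/(2*F)
CA_INFLUX_FACTOR = 100.0 / (2.0 * FARADAY)


def calcium_update(state: CalciumState, I_Ca: float, dt: float) -> CalciumState:
    """Advance shell calcium one step under current density ``I_Ca`` (mA/cm²,
    outward positive; calcium influx is negative).

    dCa/dt = −k·I_Ca/(2F·depth) − (Ca − Ca_rest)/tau_Ca, integrated with the
    same exponential (analytic per-step) scheme used for the gates: the decay
    toward Ca_rest after influx ceases is a single exponential with time
    constant exactly ``tau_Ca``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    ca_inf = state.Ca_rest - state.tau_Ca * CA_INFLUX_FACTOR * I_Ca / state.depth
    new = ca_inf + (state.Ca - ca_inf) * math.exp(-dt / state.tau_Ca)
    clamped = state.clamp_count
    if new < 0:
        new = 0.0
        clamped += 1
    return CalciumState(
        Ca=new, Ca_rest=state.Ca_rest, tau_Ca=state.tau_Ca, depth=state.depth,
        clamp_count=clamped,
    )
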