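"""Compartmental model assembly and step-current simulation.

``build_model`` installs an e-type template's channel distributions and
passive properties onto a discretized morphology; ``run_protocol`` integrates
the cable equation under somatic step currents and records voltage traces;
``bap_protocol`` measures the dendritic attenuation profile of a
backpropagating action potential along the apical trunk.

Integration uses a fixed step (0.025 ms default) with a 200 ms settle-to-rest
phase before each protocol, staggered implicit voltage updates and analytic
exponential gate updates (see :mod:`ca1degen._kernel`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _kernel
from .channels import (
    ChannelDistribution,
    PassiveProperties,
    calcium_defaults,
    conductance_profile,
    default_kinetics,
)
from .morphology import CLASSES, CompartmentalMesh, Morphology, discretize
from .templates import EtypeTemplate, StimulusProtocol, load_template

__all__ = [
    "CompartmentalModel",
    "VoltageTrace",
    "IntegrationError",
    "ProtocolError",
    "build_model",
    "run_protocol",
    "bap_protocol",
    "traces_to_csv",
    "traces_from_csv",
]

DEFAULT_DT = 0.025  # ms
SETTLE_TIME = 200.0  # ms to rest before stimulus onset


class IntegrationError(RuntimeError):
    """Numerical divergence (|V| > 200 mV); carries the offending parameters."""


class ProtocolError(RuntimeError):
    """A protocol's precondition failed (e.g. no somatic spike elicited)."""


@dataclass
class VoltageTrace:
    """Membrane potential at one recording site under one step amplitude."""

    time: np.ndarray  # ms, uniform dt, 0 at recording onset
    voltage: np.ndarray  # mV
    protocol_amplitude: float  # nA
    stim_start: float  # ms
    stim_end: float  # ms
    site: tuple[str, float] = ("soma", 0.0)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.time.size != self.voltage.size:
            raise ValueError("time and voltage must have equal length")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])


@dataclass
class CompartmentalModel:
    mesh: CompartmentalMesh
    distributions: list[ChannelDistribution]
    passive: PassiveProperties
    initial_V: float = -70.0
    kinetics: dict = field(default_factory=default_kinetics)
    calcium: dict = field(default_factory=calcium_defaults)
    identifier: str = "model"
    _packed: dict | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        present = {CLASSES[k] for k in np.unique(self.mesh.class_id)}
        for d in self.distributions:
            if d.compartment_class not in present:
                raise ValueError(
                    f"distribution {d.channel}/{d.compartment_class}: class not in mesh"
                )

    def packed(self) -> dict:
        if self._packed is None:
            self._packed = _pack(self)
        return self._packed


def build_model(
    morphology: Morphology | CompartmentalMesh,
    etype_template: str | EtypeTemplate,
    parameters: dict[str, float] | None = None,
    max_compartment_length: float | None = None,
) -> CompartmentalModel:
    """Assemble a simulatable model from a morphology, an e-type template and
    a (possibly partial) parameter dictionary.

    Unknown parameter names raise ``KeyError``.  The initial voltage is the
    leak reversal so the settle phase starts near rest.
    """
    tpl = load_template(etype_template) if isinstance(etype_template, str) else etype_template
    if isinstance(morphology, CompartmentalMesh):
        mesh = morphology
    else:
        mesh = discretize(morphology, max_compartment_length or tpl.max_compartment_length)
    dists, passive = tpl.distributions(parameters)
    present = {CLASSES[k] for k in np.unique(mesh.class_id)}
    dists = [d for d in dists if d.compartment_class in present]
    return CompartmentalModel(
        mesh=mesh,
        distributions=dists,
        passive=passive,
        initial_V=passive.e_pas_of("soma"),
        identifier=f"{tpl.name}:{mesh.identifier}",
    )


def _pack(model: CompartmentalModel) -> dict:
    """Flatten a model into the kernel's array form."""
    mesh = model.mesh
    n = mesh.n
    area_cm2 = mesh.area * 1e-8  # µm² -> cm²
    cap_nF = model.passive.Cm * area_cm2 * 1e3  # µF/cm² * cm² -> nF
    gpas_uS = np.array(
        [model.passive.g_pas_of(CLASSES[k]) for k in mesh.class_id]
    ) * area_cm2 * 1e6
    epas = np.array([model.passive.e_pas_of(CLASSES[k]) for k in mesh.class_id])

    # axial half-conductance of each compartment (series combination with the
    # parent's half): g_half = (π/4) d² / (Ra · L/2), d and L in cm
    Ra = model.passive.Ra
    d_cm = mesh.diameter * 1e-4
    L_cm = mesh.length * 1e-4
    g_half = (math.pi / 4.0) * d_cm**2 / (Ra * L_cm / 2.0)  # S
    g_ax = np.zeros(n)
    for c in range(1, n):
        p = mesh.parent[c]
        g_ax[c] = 1.0 / (1.0 / g_half[c] + 1.0 / g_half[p]) * 1e6  # µS

    by_class: dict[str, list[ChannelDistribution]] = {}
    for d in model.distributions:
        by_class.setdefault(d.compartment_class, []).append(d)

    ci_comp, ci_g_uS, ci_gdens, ci_erev, ci_isca = [], [], [], [], []
    gate_kind, gate_exp, gate_par = [], [], []
    ci_gate_start, ci_gate_count = [], []
    has_ca = np.zeros(n, dtype=np.int8)
    for c in range(n):
        klass = CLASSES[mesh.class_id[c]]
        for dist in by_class.get(klass, []):
            spec = model.kinetics[dist.channel]
            gdens = conductance_profile(dist, float(mesh.path_mid[c]))  # S/cm²
            ci_comp.append(c)
            ci_gdens.append(gdens)
            ci_g_uS.append(gdens * area_cm2[c] * 1e6)
            ci_erev.append(spec.reversal)
            ci_isca.append(1 if spec.is_calcium else 0)
            if spec.is_calcium:
                has_ca[c] = 1
            ci_gate_start.append(len(gate_kind))
            ci_gate_count.append(len(spec.gates))
            for g in spec.gates:
                gate_kind.append(g.kind_code)
                gate_exp.append(g.exponent)
                gate_par.append(g.param_row())

    # voltage-table bookkeeping: one table row per unique volt-gate parameter set
    gate_tab = np.full(len(gate_kind), -1, dtype=np.int64)
    row_of: dict[tuple, int] = {}
    for g, kind in enumerate(gate_kind):
        if kind == 0:
            key = tuple(gate_par[g])
            gate_tab[g] = row_of.setdefault(key, len(row_of))
    unique_rows = np.empty(len(row_of), dtype=np.int64)
    for g in range(len(gate_kind)):
        if gate_tab[g] >= 0:
            unique_rows[gate_tab[g]] = g

    return {
        "gate_tab": gate_tab,
        "unique_rows": unique_rows,
        "parent": mesh.parent.astype(np.int64),
        "g_ax": g_ax,
        "cap_nF": cap_nF,
        "gpas_uS": gpas_uS,
        "epas": epas,
        "has_ca": has_ca,
        "ci_comp": np.array(ci_comp, dtype=np.int64),
        "ci_g_uS": np.array(ci_g_uS, dtype=np.float64),
        "ci_gdens": np.array(ci_gdens, dtype=np.float64),
        "ci_erev": np.array(ci_erev, dtype=np.float64),
        "ci_isca": np.array(ci_isca, dtype=np.int8),
        "ci_gate_start": np.array(ci_gate_start, dtype=np.int64),
        "ci_gate_count": np.array(ci_gate_count, dtype=np.int64),
        "gate_kind": np.array(gate_kind, dtype=np.int8),
        "gate_exp": np.array(gate_exp, dtype=np.int64),
        "gate_par": (
            np.array(gate_par) if gate_par else np.zeros((0, 7))
        ),
        "ca_rest": float(model.calcium["rest_mM"]),
        "ca_tau": float(model.calcium["tau_ms"]),
        "ca_depth": float(model.calcium["shell_depth_um"]),
    }


_TAB_VMIN = -110.0
_TAB_DV = 0.05
_TAB_NV = 3601  # up to +70 mV; index clamped beyond


def _integrate(
    model: CompartmentalModel,
    stim: np.ndarray,
    dt: float,
    rec_comps: np.ndarray,
    order: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    p = model.packed()
    cache = p.setdefault("_tables", {})
    key = round(float(dt), 12)
    if key not in cache:
        cache[key] = _kernel.build_gate_tables(
            p["gate_par"], p["unique_rows"], dt, _TAB_VMIN, _TAB_DV, _TAB_NV
        )
    tab_inf, tab_eta = cache[key]
    status, vrec, carec = _kernel.integrate(
        float(dt),
        stim.size,
        float(model.initial_V),
        p["parent"], p["g_ax"], p["cap_nF"], p["gpas_uS"], p["epas"], p["has_ca"],
        p["ci_comp"], p["ci_g_uS"], p["ci_gdens"], p["ci_erev"], p["ci_isca"],
        p["ci_gate_start"], p["ci_gate_count"],
        p["gate_kind"], p["gate_exp"], p["gate_par"],
        p["gate_tab"], tab_inf, tab_eta, _TAB_VMIN, _TAB_DV,
        p["ca_rest"], p["ca_tau"], p["ca_depth"],
        stim, 0, rec_comps, order,
    )
    if status != 0:
        raise IntegrationError(
            f"voltage diverged (|V| > 200 mV) in model {model.identifier}"
        )
    return vrec, carec


def run_protocol(
    model: CompartmentalModel,
    protocol: StimulusProtocol | None = None,
    dt: float = DEFAULT_DT,
    settle: float = SETTLE_TIME,
    order: int = 2,
    record_calcium: bool = False,
) -> list[VoltageTrace]:
    """Run every step amplitude of ``protocol`` and return one trace per
    amplitude per recording site.  Current is injected at the soma."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    protocol = protocol or StimulusProtocol()
    rec_comps = np.array(
        [model.mesh.nearest_compartment(k, d) for k, d in protocol.recording_sites],
        dtype=np.int64,
    )
    n_settle = int(round(settle / dt))
    n_rec = int(round(protocol.total_time / dt))
    i_on = n_settle + int(round(protocol.delay / dt))
    i_off = n_settle + int(round((protocol.delay + protocol.duration) / dt))

    traces: list[VoltageTrace] = []
    for amp in protocol.amplitudes:
        stim = np.zeros(n_settle + n_rec)
        stim[i_on:i_off] = amp
        vrec, carec = _integrate(model, stim, dt, rec_comps, order)
        t = np.arange(n_rec + 1) * dt
        for r, site in enumerate(protocol.recording_sites):
            meta = {"model": model.identifier}
            if record_calcium:
                meta["calcium"] = carec[r, n_settle:]
            traces.append(
                VoltageTrace(
                    time=t,
                    voltage=vrec[r, n_settle:].copy(),
                    protocol_amplitude=amp,
                    stim_start=protocol.delay,
                    stim_end=protocol.delay + protocol.duration,
                    site=site,
                    metadata=meta,
                )
            )
    return traces


def bap_protocol(
    model: CompartmentalModel,
    distances: list[float] | None = None,
    pulse_amplitude: float = 2.0,
    pulse_duration: float = 5.0,
    dt: float = DEFAULT_DT,
    settle: float = SETTLE_TIME,
) -> list[tuple[float, float]]:
    """Backpropagating-AP attenuation profile along the apical trunk.

    A brief suprathreshold somatic step elicits an AP; at each apical
    recording distance the first AP's peak depolarization relative to the
    local resting potential is returned, ordered by distance.  Raises
    :class:`ProtocolError` if no somatic spike is elicited.
    """
    apical = model.mesh.compartments_of_class("apical")
    if apical.size < 3:
        raise ProtocolError("bAP protocol needs an apical trunk with >=3 compartments")
    if distances is None:
        sites = list(apical)
    else:
        sites = [model.mesh.nearest_compartment("apical", d) for d in distances]
    soma = 0
    rec = np.array([soma] + list(dict.fromkeys(sites)), dtype=np.int64)

    n_settle = int(round(settle / dt))
    window = 25.0  # ms after pulse onset searched for the first AP peak
    n_post = int(round((pulse_duration + window) / dt))
    stim = np.zeros(n_settle + n_post)
    stim[n_settle : n_settle + int(round(pulse_duration / dt))] = pulse_amplitude
    vrec, _ = _integrate(model, stim, dt, rec)

    v_soma = vrec[0, n_settle:]
    if v_soma.max() < -20.0:
        raise ProtocolError(
            f"no somatic spike elicited by {pulse_amplitude} nA / {pulse_duration} ms"
        )
    out = []
    for r in range(1, rec.size):
        rest = vrec[r, n_settle - 1]
        peak = vrec[r, n_settle:].max()
        out.append((float(model.mesh.path_mid[rec[r]]), float(peak - rest)))
    out.sort(key=lambda p: p[0])
    return out


# ---------------------------------------------------------------------------
# Trace CSV I/O (t_ms column, one voltage column per site/amplitude)


def traces_to_csv(traces: list[VoltageTrace], path: str | Path) -> None:
    cols = {"t_ms": traces[0].time}
    for tr in traces:
        key = f"v_{tr.site[0]}{tr.site[1]:g}_{tr.protocol_amplitude:+g}nA"
        cols[key] = tr.voltage
    pd.DataFrame(cols).to_csv(path, index=False)


def traces_from_csv(
    path: str | Path, stim_start: float = 100.0, stim_end: float = 500.0
) -> list[VoltageTrace]:
    df = pd.read_csv(path)
    t = df["t_ms"].to_numpy()
    out = []
    for col in df.columns:
        if not col.startswith("v_"):
            continue
        amp = float(col.rsplit("_", 1)[1].removesuffix("nA"))
        out.append(
            VoltageTrace(
                time=t,
                voltage=df[col].to_numpy(),
                protocol_amplitude=amp,
                stim_start=stim_start,
                stim_end=stim_end,
            )
        )
    return out
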