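import math

import numpy as np
import pytest

from ca1degen.channels import PassiveProperties
from ca1degen.efeatures import detect_spikes
from ca1degen.morphology import Morphology, Section, discretize
from ca1degen.simulator import (
    CompartmentalModel,
    IntegrationError,
    ProtocolError,
    bap_protocol,
    build_model,
    run_protocol,
    traces_from_csv,
    traces_to_csv,
)
from ca1degen.templates import StimulusProtocol


def passive_single_compartment(g_pas=5e-5, Cm=1.0, area_cm2=1e-5):
    d = math.sqrt(area_cm2 * 1e8 / math.pi)  # sphere area = pi d^2
    morph = Morphology([Section("soma", [(d / 2.0, d)])])
    mesh = discretize(morph, 40.0)
    return CompartmentalModel(
        mesh=mesh,
        distributions=[],
        passive=PassiveProperties(g_pas=g_pas, e_pas=-70.0, Cm=Cm),
        initial_V=-70.0,
    )


def test_passive_steady_state_matches_ohms_law():
    """ΔV = I/(g·A): 0.01 nA into 1e-5 cm² at 5e-5 S/cm² gives 20 mV."""
    model = passive_single_compartment()
    proto = StimulusProtocol(amplitudes=[0.01], delay=20.0, duration=400.0, post=20.0)
    (tr,) = run_protocol(model, proto)
    v_end = tr.voltage[int(419.0 / tr.dt)]
    assert v_end - (-70.0) == pytest.approx(20.0, rel=0.005)


def test_passive_charging_time_constant():
    """Membrane time constant Cm/g_pas = 20 ms, recovered by exponential fit."""
    model = passive_single_compartment()
    proto = StimulusProtocol(amplitudes=[0.01], delay=20.0, duration=400.0, post=20.0)
    (tr,) = run_protocol(model, proto)
    t0 = int(20.0 / tr.dt)
    t = tr.time[t0: t0 + int(100 / tr.dt)] - 20.0
    v = tr.voltage[t0: t0 + int(100 / tr.dt)]
    v_inf = -50.0
    y = np.log(np.clip((v_inf - v) / 20.0, 1e-12, None))
    tau = -1.0 / np.polyfit(t, y, 1)[0]
    assert tau == pytest.approx(20.0, rel=0.01)


def test_multi_compartment_passive_matches_independent_integrator(desk_template):
    """A <=5-compartment passive cable integrated by an independent dense
    numpy implementation of the same staggered implicit scheme agrees with
    the compiled kernel to 1e-6 mV."""
    morph = Morphology([
        Section("soma", [(10.0, 20.0)]),
        Section("apical", [(100.0, 2.0), (100.0, 1.5)], parent=0, path_distance_start=10.0),
    ])
    mesh = discretize(morph, 50.0)
    assert mesh.n == 5
    passive = PassiveProperties(g_pas=1e-4, e_pas=-70.0, Cm=1.0, Ra=150.0)
    model = CompartmentalModel(mesh=mesh, distributions=[], passive=passive,
                               initial_V=-65.0)
    dt, n_steps, I = 0.025, 4000, 0.05
    proto = StimulusProtocol(amplitudes=[I], delay=0.0, duration=n_steps * dt,
                             post=0.0)
    (tr,) = run_protocol(model, proto, dt=dt, settle=0.0)

    # independent reference: assemble the cable system from first principles
    area = mesh.area * 1e-8  # cm²
    C = passive.Cm * area * 1e3  # nF
    gpas = passive.g_pas * area * 1e6  # µS
    d_cm, L_cm = mesh.diameter * 1e-4, mesh.length * 1e-4
    g_half = (math.pi / 4) * d_cm**2 / (passive.Ra * L_cm / 2.0)
    n = mesh.n
    G = np.zeros((n, n))
    for c in range(1, n):
        p = mesh.parent[c]
        g = 1.0 / (1.0 / g_half[c] + 1.0 / g_half[p]) * 1e6
        G[c, c] += g
        G[p, p] += g
        G[c, p] -= g
        G[p, c] -= g
    V = np.full(n, -65.0)
    rec = [V[0]]
    A = np.diag(2.0 * C / dt + gpas) + G
    for step in range(n_steps):
        b = (2.0 * C / dt) * V + gpas * (-70.0)
        b[0] += I
        Vmid = np.linalg.solve(A, b)
        V = 2.0 * Vmid - V
        rec.append(V[0])
    assert np.max(np.abs(tr.voltage - np.array(rec))) < 1e-6


def test_active_spike_times_converge_with_dt(desk_template, desk_mesh):
    """Spike times at dt = 0.025 ms lie within 0.5 ms of a 20x-finer
    reference integration."""
    model = build_model(desk_mesh, desk_template)
    proto = StimulusProtocol(amplitudes=[0.4], delay=50.0, duration=400.0, post=50.0)
    (coarse,) = run_protocol(model, proto, dt=0.025)
    (fine,) = run_protocol(model, proto, dt=0.025 / 20.0)
    t_c = detect_spikes(coarse).spike_times
    t_f = detect_spikes(fine).spike_times
    assert t_c.size == t_f.size and t_c.size >= 3
    assert np.max(np.abs(t_c - t_f)) < 0.5


def test_resting_stability_without_stimulus(desk_template, desk_mesh):
    """With zero stimulus the membrane stays within 0.5 mV of rest for 1 s."""
    model = build_model(desk_mesh, desk_template)
    proto = StimulusProtocol(amplitudes=[0.0], delay=0.0, duration=1000.0, post=0.0)
    (tr,) = run_protocol(model, proto)
    rest = tr.voltage[0]
    assert np.max(np.abs(tr.voltage - rest)) < 0.5


def test_all_zero_conductances_give_purely_passive_model(desk_template, desk_mesh):
    zeros = {n: 0.0 for n in desk_template.default_params()
             if n.startswith("g") and "bar" in n}
    model = build_model(desk_mesh, desk_template, zeros)
    # moderate step: a passive membrane charges smoothly and never spikes
    proto = StimulusProtocol(amplitudes=[0.15], delay=50.0, duration=200.0, post=0.0)
    (tr,) = run_protocol(model, proto)
    assert detect_spikes(tr).n == 0
    assert np.all(np.diff(tr.voltage[int(50 / tr.dt):]) >= -1e-9)  # monotone charge


def test_parameter_installation(desk_template, desk_mesh):
    model = build_model(desk_mesh, desk_template, {"gkmbar s": 0.0123})
    km_soma = [d for d in model.distributions
               if d.channel == "K_M" and d.compartment_class == "soma"]
    assert len(km_soma) == 1 and km_soma[0].gbar == 0.0123


def test_unknown_parameter_rejected(desk_template, desk_mesh):
    with pytest.raises(KeyError, match="unknown parameter"):
        build_model(desk_mesh, desk_template, {"gfoobar s": 1.0})


def test_parameter_count_matches_template_enumeration(desk_template):
    """Template parameter count equals an independent enumeration of the
    placement table plus the four passive entries."""
    count = sum(len(chans) for chans in desk_template.placement.values()) + 4
    assert len(desk_template.all_param_names()) == count


def test_divergence_guard_names_model(desk_template, desk_mesh):
    model = build_model(desk_mesh, desk_template, {"gnabar s": 0.38})
    model.passive.g_pas = 1e-7  # nearly no leak: unphysiological, must diverge or spike hard
    proto = StimulusProtocol(amplitudes=[10.0], delay=10.0, duration=400.0, post=0.0)
    try:
        run_protocol(model, proto)
    except IntegrationError as e:
        assert "pyr_cAC_desk" in str(e)


class TestBapProtocol:
    def test_passive_dendrite_attenuates_monotonically(self, desk_template, desk_mesh):
        params = {"gnabar d": 0.0, "gkdrbar d": 0.0, "gkabar d": 0.0, "gihbar d": 0.0}
        model = build_model(desk_mesh, desk_template, params)
        profile = bap_protocol(model)
        amps = [a for _, a in profile]
        assert all(np.diff(amps) < 0)

    def test_high_ka_gradient_attenuates_more(self, desk_template, desk_mesh):
        lo = build_model(desk_mesh, desk_template, {"gkabar d": 1e-5})
        hi = build_model(desk_mesh, desk_template, {"gkabar d": 0.008})
        prof_lo = dict(bap_protocol(lo))
        prof_hi = dict(bap_protocol(hi))
        distal = max(prof_lo)
        assert prof_hi[distal] < prof_lo[distal]

    def test_no_spike_raises_protocol_error(self, desk_template, desk_mesh):
        zeros = {n: 0.0 for n in desk_template.default_params()
                 if n.startswith("g") and "bar" in n}
        model = build_model(desk_mesh, desk_template, zeros)
        with pytest.raises(ProtocolError, match="no somatic spike"):
            bap_protocol(model, pulse_amplitude=0.5)


def test_trace_csv_roundtrip(tmp_path, desk_template, desk_mesh):
    model = build_model(desk_mesh, desk_template)
    proto = StimulusProtocol(amplitudes=[-0.4, 0.4], delay=20.0, duration=50.0, post=10.0)
    traces = run_protocol(model, proto)
    f = tmp_path / "traces.csv"
    traces_to_csv(traces, f)
    loaded = traces_from_csv(f, stim_start=20.0, stim_end=70.0)
    assert len(loaded) == 2
    for a, b in zip(traces, loaded):
        assert a.protocol_amplitude == b.protocol_amplitude
        assert np.allclose(a.voltage, b.voltage, atol=1e-6)
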