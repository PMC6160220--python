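"""Compiled inner loop of the compartmental cable solver.

The voltage step is the staggered implicit scheme used by standard
compartmental simulators: gate states are advanced analytically (exponential
update toward their steady state), then the voltage system — linear in V once
the gates are frozen — is solved implicitly on the tree with a Hines-ordered
elimination.  ``order=2`` (default) solves for the half-step voltage and
extrapolates (Crank–Nicolson); ``order=1`` is plain backward Euler.

Units: mV, ms, nA, µS, nF, mM.  µS·mV = nA and nF·mV/ms = nA, so the system
is assembled without conversion factors.
"""

import math

import numpy as np
from numba import njit

# gate parameterization codes (mirrors channels.py)
KIND_VOLT = 0
KIND_CA = 1
KIND_CAVOLT = 2

CA_INFLUX_FACTOR = 100.0 / (2.0 * 96485.332)  # mM/ms per (mA/cm²)/µm

DIVERGENCE_LIMIT = 200.0  # mV


@njit(cache=True)
def _gate_inf_tau(kind, par, V, Ca):
    if kind == KIND_VOLT:
        inf = 1.0 / (1.0 + math.exp((par[0] - V) / par[1]))
        u = V - par[4]
        tau = par[2] + par[3] / (math.exp(u / par[5]) + math.exp(-u / par[6]))
        return inf, tau
    if kind == KIND_CA:
        ca = Ca if Ca > 1e-12 else 1e-12
        inf = 1.0 / (1.0 + (par[0] / ca) ** par[1])
        return inf, par[2]
    ca = Ca if Ca > 1e-12 else 1e-12
    inf = (1.0 / (1.0 + (par[0] / ca) ** par[1])) * (
        1.0 / (1.0 + math.exp((par[2] - V) / par[3]))
    )
    return inf, par[4]


@njit(cache=True)
def build_gate_tables(gate_par, rows, dt, vmin, dv, nv):
    """Tabulate x_inf and 1-exp(-dt/tau) on a voltage grid for the
    voltage-only gates listed in ``rows`` (indices into gate_par)."""
    inf_tab = np.empty((rows.size, nv))
    eta_tab = np.empty((rows.size, nv))
    for r in range(rows.size):
        par = gate_par[rows[r]]
        for i in range(nv):
            V = vmin + i * dv
            inf, tau = _gate_inf_tau(KIND_VOLT, par, V, 0.0)
            inf_tab[r, i] = inf
            eta_tab[r, i] = 1.0 - math.exp(-dt / tau)
    return inf_tab, eta_tab


@njit(cache=True)
def integrate(
    dt,
    n_steps,
    v_init,
    parent,
    g_ax,
    cap_nF,
    gpas_uS,
    epas,
    has_ca,
    ci_comp,
    ci_g_uS,
    ci_gdens,
    ci_erev,
    ci_isca,
    ci_gate_start,
    ci_gate_count,
    gate_kind,
    gate_exp,
    gate_par,
    gate_tab,
    tab_inf,
    tab_eta,
    tab_vmin,
    tab_dv,
    ca_rest,
    ca_tau,
    ca_depth,
    stim,
    stim_comp,
    rec_comps,
    order,
):
    """Integrate ``n_steps`` steps; returns (status, V_rec, Ca_rec).

    status 0 = ok, 1 = divergence (|V| > 200 mV).  ``V_rec`` has shape
    (len(rec_comps), n_steps+1) and contains the initial state in column 0.
    ``Ca_rec`` records shell calcium at the same sites.
    """
    n = parent.size
    n_ci = ci_comp.size
    n_rec = rec_comps.size

    Vm = np.full(n, np.float64(v_init))
    Ca = np.full(n, np.float64(ca_rest))
    n_gates = gate_kind.size
    x = np.empty(n_gates)
    for ci in range(n_ci):
        c = ci_comp[ci]
        for g in range(ci_gate_start[ci], ci_gate_start[ci] + ci_gate_count[ci]):
            inf, _ = _gate_inf_tau(gate_kind[g], gate_par[g], Vm[c], Ca[c])
            x[g] = inf

    Gsum = np.zeros(n)
    GEsum = np.zeros(n)
    ica = np.zeros(n)
    diag = np.empty(n)
    rhs = np.empty(n)
    vrec = np.empty((n_rec, n_steps + 1))
    carec = np.empty((n_rec, n_steps + 1))
    for r in range(n_rec):
        vrec[r, 0] = Vm[rec_comps[r]]
        carec[r, 0] = Ca[rec_comps[r]]

    cfac = 2.0 / dt if order == 2 else 1.0 / dt
    exp_ca = math.exp(-dt / ca_tau)
    nv = tab_inf.shape[1]
    inv_dv = 1.0 / tab_dv

    status = 0
    for step in range(n_steps):
        # --- gates: exponential update at the current (V, Ca); voltage-only
        # gates use the tabulated (x_inf, 1-exp(-dt/tau)) with linear
        # interpolation, calcium-dependent gates stay analytic
        for ci in range(n_ci):
            c = ci_comp[ci]
            V = Vm[c]
            CaC = Ca[c]
            for g in range(ci_gate_start[ci], ci_gate_start[ci] + ci_gate_count[ci]):
                row = gate_tab[g]
                if row >= 0:
                    u = (V - tab_vmin) * inv_dv
                    if u < 0.0:
                        u = 0.0
                    elif u > nv - 1.001:
                        u = nv - 1.001
                    i0 = int(u)
                    w = u - i0
                    inf = tab_inf[row, i0] * (1.0 - w) + tab_inf[row, i0 + 1] * w
                    eta = tab_eta[row, i0] * (1.0 - w) + tab_eta[row, i0 + 1] * w
                    x[g] += (inf - x[g]) * eta
                else:
                    inf, tau = _gate_inf_tau(gate_kind[g], gate_par[g], V, CaC)
                    x[g] += (inf - x[g]) * (1.0 - math.exp(-dt / tau))

        # --- membrane currents at the new gate states
        for c in range(n):
            Gsum[c] = 0.0
            GEsum[c] = 0.0
            ica[c] = 0.0
        for ci in range(n_ci):
            o = 1.0
            for g in range(ci_gate_start[ci], ci_gate_start[ci] + ci_gate_count[ci]):
                xv = x[g]
                p = xv
                for _ in range(gate_exp[g] - 1):
                    p *= xv
                o *= p
            c = ci_comp[ci]
            gval = ci_g_uS[ci] * o
            Gsum[c] += gval
            GEsum[c] += gval * ci_erev[ci]
            if ci_isca[ci] == 1:
                ica[c] += ci_gdens[ci] * o * (Vm[c] - ci_erev[ci])

        # --- shell calcium (analytic per-step update of the linear ODE)
        for c in range(n):
            if has_ca[c] == 1:
                ca_inf = ca_rest - ca_tau * CA_INFLUX_FACTOR * ica[c] / ca_depth
                newca = ca_inf + (Ca[c] - ca_inf) * exp_ca
                Ca[c] = newca if newca > 0.0 else 0.0

        # --- implicit voltage solve on the tree (Hines elimination)
        for c in range(n):
            a = cap_nF[c] * cfac
            diag[c] = a + gpas_uS[c] + Gsum[c]
            rhs[c] = a * Vm[c] + gpas_uS[c] * epas[c] + GEsum[c]
        rhs[stim_comp] += stim[step]
        for c in range(1, n):
            diag[c] += g_ax[c]
            diag[parent[c]] += g_ax[c]
        for c in range(n - 1, 0, -1):
            f = g_ax[c] / diag[c]
            diag[parent[c]] -= f * g_ax[c]
            rhs[parent[c]] += f * rhs[c]
        vsol0 = rhs[0] / diag[0]
        # reuse rhs as solution buffer
        rhs[0] = vsol0
        for c in range(1, n):
            rhs[c] = (rhs[c] + g_ax[c] * rhs[parent[c]]) / diag[c]

        if order == 2:
            for c in range(n):
                Vm[c] = 2.0 * rhs[c] - Vm[c]
        else:
            for c in range(n):
                Vm[c] = rhs[c]

        for c in range(n):
            if not (-DIVERGENCE_LIMIT < Vm[c] < DIVERGENCE_LIMIT):
                status = 1
        for r in range(n_rec):
            vrec[r, step + 1] = Vm[rec_comps[r]]
            carec[r, step + 1] = Ca[rec_comps[r]]
        if status == 1:
            for r in range(n_rec):
                for s in range(step + 2, n_steps + 1):
                    vrec[r, s] = vrec[r, step + 1]
                    carec[r, s] = carec[r, step + 1]
            break

    return status, vrec, carec
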