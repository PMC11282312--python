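"""Numba time-stepping core for the leaky integrate-and-fire network.

Separated from :mod:`eiclust.dynamics` so that the jitted function has a
plain-arrays signature.  Integration is exponential-Euler per term: over one
step the synaptic currents are treated as constant for the membrane update
(exact for piecewise-constant input) and then decayed by their exponential
factors.  Spikes emitted at step t increment the source-matched synaptic
current of their targets at step t+1 (one-step synaptic delay).
"""

import numpy as np
from numba import njit


@njit(cache=True)
def run_network(
    # connectivity (CSC by presynaptic unit)
    indptr, indices, weights, is_exc,
    # per-unit constants
    tau_m, I_x,
    # scalars
    E_L, V_th, V_R, C_m, dt, n_steps, refr_steps,
    d_syn_E, d_syn_I,
    # stimulus events: at step ev_step[k], add ev_amp[k] to the stimulus
    # current of units ev_units[ev_uptr[k]:ev_uptr[k+1]]
    ev_step, ev_amp, ev_uptr, ev_units,
    # initial membrane potentials
    V0,
    # probes: unit ids to record (length 0 disables recording)
    probe_units,
):
    n = V0.shape[0]
    V = V0.copy()
    I_e = np.zeros(n)
    I_i = np.zeros(n)
    I_stim = np.zeros(n)
    refr = np.zeros(n, dtype=np.int64)

    exp_m = np.exp(-dt / tau_m)
    gain = tau_m / C_m

    cap = 1024
    sp_step = np.empty(cap, dtype=np.int64)
    sp_unit = np.empty(cap, dtype=np.int64)
    n_spikes = 0

    # spiking units of the previous step (delivery buffer)
    prev = np.empty(n, dtype=np.int64)
    n_prev = 0

    n_probe = probe_units.shape[0]
    trace_Ie = np.zeros((n_steps if n_probe > 0 else 0, n_probe))
    trace_Ii = np.zeros((n_steps if n_probe > 0 else 0, n_probe))
    trace_Ix = np.zeros((n_steps if n_probe > 0 else 0, n_probe))
    trace_V = np.zeros((n_steps if n_probe > 0 else 0, n_probe))

    ev_ptr = 0
    n_ev = ev_step.shape[0]
    error_step = np.int64(-1)

    for step in range(n_steps):
        if step % 1000 == 0:
            for i in range(n):
                if not np.isfinite(V[i]):
                    error_step = step
                    break
            if error_step >= 0:
                break
        # stimulus current changes scheduled for this step
        while ev_ptr < n_ev and ev_step[ev_ptr] == step:
            a = ev_amp[ev_ptr]
            for k in range(ev_uptr[ev_ptr], ev_uptr[ev_ptr + 1]):
                I_stim[ev_units[k]] += a
            ev_ptr += 1

        # deliver last step's spikes
        for s in range(n_prev):
            j = prev[s]
            if is_exc[j]:
                for k in range(indptr[j], indptr[j + 1]):
                    I_e[indices[k]] += weights[k]
            else:
                for k in range(indptr[j], indptr[j + 1]):
                    I_i[indices[k]] += weights[k]

        # membrane update (currents held constant over the step), then
        # exponential decay of the synaptic currents
        for i in range(n):
            if refr[i] > 0:
                refr[i] -= 1
                V[i] = V_R
            else:
                I_tot = I_e[i] + I_i[i] + I_x[i] + I_stim[i]
                V_inf = E_L + gain[i] * I_tot
                V[i] = V_inf + (V[i] - V_inf) * exp_m[i]
            I_e[i] *= d_syn_E
            I_i[i] *= d_syn_I

        if n_probe > 0:
            for p in range(n_probe):
                u = probe_units[p]
                trace_Ie[step, p] = I_e[u]
                trace_Ii[step, p] = I_i[u]
                trace_Ix[step, p] = I_x[u] + I_stim[u]
                trace_V[step, p] = V[u]

        # threshold crossings
        n_prev = 0
        for i in range(n):
            if refr[i] == 0 and V[i] >= V_th:
                if n_spikes == cap:
                    cap *= 2
                    tmp_s = np.empty(cap, dtype=np.int64)
                    tmp_u = np.empty(cap, dtype=np.int64)
                    tmp_s[:n_spikes] = sp_step[:n_spikes]
                    tmp_u[:n_spikes] = sp_unit[:n_spikes]
                    sp_step = tmp_s
                    sp_unit = tmp_u
                sp_step[n_spikes] = step
                sp_unit[n_spikes] = i
                n_spikes += 1
                V[i] = V_R
                refr[i] = refr_steps
                prev[n_prev] = i
                n_prev += 1

    return (sp_step[:n_spikes], sp_unit[:n_spikes],
            trace_Ie, trace_Ii, trace_Ix, trace_V, error_step)
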