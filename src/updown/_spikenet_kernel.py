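"""Jitted integration loop for the spiking EI network.

One call advances the network by a chunk of steps, consuming a pre-drawn
noise array. All-to-all connectivity collapses the recurrent drive to the
population synaptic variables s_E, s_I driven by delayed population spike
counts; membrane and synaptic linear dynamics use exact exponential
propagators with impulses applied at step boundaries.
"""

import numpy as np
from numba import njit

__all__ = ["run_chunk"]


@njit(cache=True)
def run_chunk(
    step0, S, dt, V, Ia, buf_E, buf_I, win_buf, scal, noise,
    delay_steps, targeted, NE, NI,
    VL_E, VL_I, Vr_E, Vr_I, th_E, th_I,
    dec_E, dec_I, namp_E, namp_I, dec_a, ahp_inc,
    er_E, ed_E, c_E, er_I, ed_I, c_I, imp_E, imp_I,
    J_EE, J_EI, J_IE, J_II,
    kick_steps, kick_K_E, kick_K_I,
    K_E_D, K_E_U, K_I_D, K_I_U, tau_k, dur_steps,
    rate_norm, rate_thr,
    trace_stride, tr_sE, tr_sI, tr_Ia, tr_cE, tr_cI,
    probe_ids, probe_v,
    sp_units, sp_steps,
):  # pragma: no cover - jitted
    buf_len = buf_E.shape[0]
    win_steps = win_buf.shape[0]
    N = NE + NI
    cap = sp_units.shape[0]
    nk = kick_steps.shape[0]
    n_trace = tr_sE.shape[0]

    u_E = scal[0]
    s_E = scal[1]
    u_I = scal[2]
    s_I = scal[3]
    win_sum = scal[5]

    resolve_ptr = 0
    while resolve_ptr < nk and kick_steps[resolve_ptr] < step0:
        resolve_ptr += 1
    first_active = 0
    while first_active < nk and kick_steps[first_active] + dur_steps < step0:
        first_active += 1

    n_spk = 0
    acc_cE = 0.0
    acc_cI = 0.0

    for s_local in range(S):
        g = step0 + s_local
        slot = g % buf_len
        arr_E = buf_E[slot]
        arr_I = buf_I[slot]
        buf_E[slot] = 0.0
        buf_I[slot] = 0.0

        # synaptic filters (population level)
        u_E += imp_E * arr_E
        u_I += imp_I * arr_I
        s_E = s_E * ed_E + u_E * c_E
        u_E *= er_E
        s_I = s_I * ed_I + u_I * c_I
        u_I *= er_I

        Irec_E = J_EE * s_E + J_EI * s_I
        Irec_I = J_IE * s_E + J_II * s_I

        # kicks: resolve state-dependent amplitude at onset, sum active pulses
        while resolve_ptr < nk and kick_steps[resolve_ptr] <= g:
            up = win_sum * rate_norm >= rate_thr
            kick_K_E[resolve_ptr] = K_E_U if up else K_E_D
            kick_K_I[resolve_ptr] = K_I_U if up else K_I_D
            resolve_ptr += 1
        while first_active < nk and kick_steps[first_active] + dur_steps < g:
            first_active += 1
        IkE = 0.0
        IkI = 0.0
        k = first_active
        while k < nk and kick_steps[k] < g:
            trel = (g - kick_steps[k]) * dt
            w = 1.0 - np.exp(-trel / tau_k)
            IkE += kick_K_E[k] * w
            IkI += kick_K_I[k] * w
            k += 1

        cnt_E = 0.0
        cnt_I = 0.0
        base_E = VL_E + Irec_E
        base_I = VL_I + Irec_I

        for i in range(NE):
            Ia[i] *= dec_a
            a = base_E - Ia[i]
            if targeted[i]:
                a += IkE
            v = a + (V[i] - a) * dec_E + namp_E * noise[s_local, i]
            if v >= th_E:
                if n_spk >= cap:
                    return -1
                sp_units[n_spk] = i
                sp_steps[n_spk] = g
                n_spk += 1
                v = Vr_E
                Ia[i] += ahp_inc
                buf_E[(g + delay_steps[i] + 1) % buf_len] += 1.0
                cnt_E += 1.0
            V[i] = v

        for j in range(NI):
            i = NE + j
            a = base_I
            if targeted[i]:
                a += IkI
            v = a + (V[i] - a) * dec_I + namp_I * noise[s_local, i]
            if v >= th_I:
                if n_spk >= cap:
                    return -1
                sp_units[n_spk] = i
                sp_steps[n_spk] = g
                n_spk += 1
                v = Vr_I
                buf_I[(g + delay_steps[i] + 1) % buf_len] += 1.0
                cnt_I += 1.0
            V[i] = v

        # trailing-window E rate for the online U/D proxy
        wslot = g % win_steps
        win_sum += cnt_E - win_buf[wslot]
        win_buf[wslot] = cnt_E
        acc_cE += cnt_E
        acc_cI += cnt_I

        if (g + 1) % trace_stride == 0:
            ti = (g + 1) // trace_stride - 1
            if 0 <= ti < n_trace:
                tr_sE[ti] = s_E
                tr_sI[ti] = s_I
                ia_sum = 0.0
                for i in range(NE):
                    ia_sum += Ia[i]
                tr_Ia[ti] = ia_sum / NE
                tr_cE[ti] = acc_cE
                tr_cI[ti] = acc_cI
                for p in range(probe_ids.shape[0]):
                    probe_v[p, ti] = V[probe_ids[p]]
                if not (np.isfinite(s_E) and np.isfinite(V[0])):
                    return -2
            acc_cE = 0.0
            acc_cI = 0.0

    scal[0] = u_E
    scal[1] = s_E
    scal[2] = u_I
    scal[3] = s_I
    scal[5] = win_sum
    return n_spk
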