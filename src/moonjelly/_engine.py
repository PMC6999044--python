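"""Fixed-step RK4 core for membrane dynamics, compiled with numba.

One kernel integrates any number of neurons on a shared time grid and handles
event scheduling (synaptic EPSC onsets, transmitter reflux) through a ring
buffer of per-step onset counts.  The EPSC kernel is a sum of four
exponentials, so the total synaptic drive of a neuron is carried by four
accumulator variables that decay analytically between steps; an onset adds 1
to each accumulator.  Gate steady-state/time-constant curves and the gate
powers are tabulated on dense grids and linearly interpolated.

Units: mV, ms, pF, nS, pA.
"""

import numpy as np
from numba import njit

# status codes returned by the kernel
STATUS_T_END = 0
STATUS_QUIESCENT = 1
STATUS_ALL_SPIKED = 2
STATUS_RUNAWAY = 3
STATUS_NONFINITE = 4

MAX_SPIKES = 5

V_GRID_LO = -150.0
V_GRID_HI = 150.0
V_GRID_N = 30001
POW_GRID_N = 4096

# indices into the scalar-parameter vector
(SC_CM, SC_GI, SC_GFT, SC_GST, SC_GSS, SC_GL,
 SC_EI, SC_EO, SC_EL, SC_GSYN, SC_AFRAC, SC_ESYN,
 SC_RECT, SC_THRESH) = range(14)
N_SC = 14


@njit(inline="always", cache=True)
def _interp_v(tab, k, v, inv_dv):
    pos = (v - V_GRID_LO) * inv_dv
    if pos <= 0.0:
        return tab[k, 0]
    last = tab.shape[1] - 1
    if pos >= last:
        return tab[k, last]
    i0 = int(pos)
    w = pos - i0
    return tab[k, i0] * (1.0 - w) + tab[k, i0 + 1] * w


@njit(inline="always", cache=True)
def _interp_g(tab, k, g, inv_dg):
    pos = g * inv_dg
    if pos <= 0.0:
        return tab[k, 0]
    last = tab.shape[1] - 1
    if pos >= last:
        return tab[k, last]
    i0 = int(pos)
    w = pos - i0
    return tab[k, i0] * (1.0 - w) + tab[k, i0 + 1] * w


@njit(inline="always", cache=True)
def _deriv(v, g, ksyn, sc, ginf_tab, tau_tab, pow_tab, inv_dv, inv_dg, dg_out):
    for k in range(7):
        gi = _interp_v(ginf_tab, k, v, inv_dv)
        tk = _interp_v(tau_tab, k, v, inv_dv)
        dg_out[k] = (gi - g[k]) / tk
    pa = _interp_g(pow_tab, 0, g[0], inv_dg)
    pb = _interp_g(pow_tab, 1, g[1], inv_dg)
    pc = _interp_g(pow_tab, 2, g[2], inv_dg)
    pd = _interp_g(pow_tab, 3, g[3], inv_dg)
    pe = _interp_g(pow_tab, 4, g[4], inv_dg)
    pf = _interp_g(pow_tab, 5, g[5], inv_dg)
    pg = _interp_g(pow_tab, 6, g[6], inv_dg)
    i_i = sc[SC_GI] * pa * pb * (v - sc[SC_EI])
    i_ft = sc[SC_GFT] * pc * pd * (v - sc[SC_EO])
    i_st = sc[SC_GST] * pe * pf * (v - sc[SC_EO])
    i_ss = sc[SC_GSS] * pg * (v - sc[SC_EO])
    i_l = sc[SC_GL] * (v - sc[SC_EL])
    drive = sc[SC_ESYN] - v
    if sc[SC_RECT] != 0.0 and drive < 0.0:
        drive = 0.0
    i_syn = sc[SC_GSYN] * ksyn * drive
    return (i_syn - i_i - i_ft - i_st - i_ss - i_l) / sc[SC_CM]


@njit(cache=True)
def run_core(V, G, X, active, sc, ginf_tab, tau_tab, pow_tab, lam,
             syn_off, syn_nbr, syn_delay, refl_off, refl_delay,
             stim_step, stim_neuron,
             n_steps, dt, ring,
             spike_t, spike_n, rec, record,
             v_rest, g_rest, stop_mode, runaway_limit, out):
    """Advance all neurons over ``n_steps`` steps of size ``dt``.

    stop_mode: 0 = run to n_steps (or quiescence), 1 = additionally stop as
    soon as every neuron has spiked at least once.
    runaway_limit: abort once any neuron accumulates this many spikes.
    out: float64[4] -> [status, t_end, steps_done, runaway_neuron].
    """
    n = V.shape[0]
    ring_len = ring.shape[0]
    inv_dv = (V_GRID_N - 1.0) / (V_GRID_HI - V_GRID_LO)
    inv_dg = POW_GRID_N - 1.0

    dh = np.exp(-0.5 * dt * lam)
    dful = np.exp(-dt * lam)
    a = sc[SC_AFRAC]
    c0 = a
    c1 = 1.0 - a
    c2 = -a
    c3 = -(1.0 - a)
    thresh = sc[SC_THRESH]

    k1 = np.empty(7)
    k2 = np.empty(7)
    k3 = np.empty(7)
    k4 = np.empty(7)
    gt = np.empty(7)

    pending = 0
    total_spikes = 0
    n_active = 0
    for i in range(n):
        if active[i] != 0:
            n_active += 1
    sp = 0
    n_stim = stim_step.shape[0]

    status = STATUS_T_END
    steps_done = 0
    t_end = n_steps * dt
    runaway_neuron = -1

    for s in range(n_steps):
        t = s * dt
        # exogenous EPSC onsets scheduled for this step
        while sp < n_stim and stim_step[sp] == s:
            j = stim_neuron[sp]
            X[j, 0] += 1.0
            X[j, 1] += 1.0
            X[j, 2] += 1.0
            X[j, 3] += 1.0
            if active[j] == 0:
                active[j] = 1
                n_active += 1
            sp += 1
        # synaptic onsets from the ring buffer
        row = s % ring_len
        for j in range(n):
            cval = ring[row, j]
            if cval > 0.0:
                X[j, 0] += cval
                X[j, 1] += cval
                X[j, 2] += cval
                X[j, 3] += cval
                pending -= int(cval)
                ring[row, j] = 0.0
                if active[j] == 0:
                    active[j] = 1
                    n_active += 1
        if record:
            for i in range(n):
                rec[s, i, 0] = V[i]
                for k in range(7):
                    rec[s, i, 1 + k] = G[i, k]
                for k in range(4):
                    rec[s, i, 8 + k] = X[i, k]

        abort = False
        for i in range(n):
            if active[i] == 0:
                continue
            x0 = X[i, 0]
            x1 = X[i, 1]
            x2 = X[i, 2]
            x3 = X[i, 3]
            ks0 = c0 * x0 + c1 * x1 + c2 * x2 + c3 * x3
            ksh = (c0 * x0 * dh[0] + c1 * x1 * dh[1]
                   + c2 * x2 * dh[2] + c3 * x3 * dh[3])
            ksf = (c0 * x0 * dful[0] + c1 * x1 * dful[1]
                   + c2 * x2 * dful[2] + c3 * x3 * dful[3])
            v = V[i]
            g = G[i]

            dv1 = _deriv(v, g, ks0, sc, ginf_tab, tau_tab, pow_tab,
                         inv_dv, inv_dg, k1)
            for k in range(7):
                gt[k] = g[k] + 0.5 * dt * k1[k]
            dv2 = _deriv(v + 0.5 * dt * dv1, gt, ksh, sc, ginf_tab, tau_tab,
                         pow_tab, inv_dv, inv_dg, k2)
            for k in range(7):
                gt[k] = g[k] + 0.5 * dt * k2[k]
            dv3 = _deriv(v + 0.5 * dt * dv2, gt, ksh, sc, ginf_tab, tau_tab,
                         pow_tab, inv_dv, inv_dg, k3)
            for k in range(7):
                gt[k] = g[k] + dt * k3[k]
            dv4 = _deriv(v + dt * dv3, gt, ksf, sc, ginf_tab, tau_tab,
                         pow_tab, inv_dv, inv_dg, k4)

            vnew = v + dt / 6.0 * (dv1 + 2.0 * dv2 + 2.0 * dv3 + dv4)
            for k in range(7):
                gk = g[k] + dt / 6.0 * (k1[k] + 2.0 * k2[k] + 2.0 * k3[k] + k4[k])
                if gk < 0.0:
                    gk = 0.0
                elif gk > 1.0:
                    gk = 1.0
                G[i, k] = gk
            X[i, 0] = x0 * dful[0]
            X[i, 1] = x1 * dful[1]
            X[i, 2] = x2 * dful[2]
            X[i, 3] = x3 * dful[3]

            if not np.isfinite(vnew):
                status = STATUS_NONFINITE
                t_end = t
                abort = True
                break

            if v <= thresh and vnew > thresh:
                # upward crossing of the transmission threshold -> spike
                ts = t + dt * (thresh - v) / (vnew - v)
                cnt = spike_n[i]
                if cnt < spike_t.shape[1]:
                    spike_t[i, cnt] = ts
                spike_n[i] = cnt + 1
                total_spikes += 1
                if spike_n[i] >= runaway_limit:
                    status = STATUS_RUNAWAY
                    t_end = ts
                    runaway_neuron = i
                    abort = True
                    V[i] = vnew
                    break
                for e in range(syn_off[i], syn_off[i + 1]):
                    j = syn_nbr[e]
                    step_on = int(np.ceil((ts + syn_delay[e]) / dt - 1e-12))
                    if step_on <= s:
                        step_on = s + 1
                    if step_on < n_steps:
                        ring[step_on % ring_len, j] += 1.0
                        pending += 1
                for e in range(refl_off[i], refl_off[i + 1]):
                    step_on = int(np.ceil((ts + refl_delay[e]) / dt - 1e-12))
                    if step_on <= s:
                        step_on = s + 1
                    if step_on < n_steps:
                        ring[step_on % ring_len, i] += 1.0
                        pending += 1
            else:
                # no spike: consider returning the neuron to the rest pool
                if (vnew - v_rest < 1e-3 and v_rest - vnew < 1e-3
                        and ks0 < 1e-6 and x0 + x1 + x2 + x3 < 1e-4):
                    ok = True
                    for k in range(7):
                        d = G[i, k] - g_rest[k]
                        if d > 1e-5 or d < -1e-5:
                            ok = False
                            break
                    if ok:
                        active[i] = 0
                        n_active -= 1
                        V[i] = v_rest
                        for k in range(7):
                            G[i, k] = g_rest[k]
                        for k in range(4):
                            X[i, k] = 0.0
                        continue
            V[i] = vnew

        steps_done = s + 1
        if abort:
            break
        if stop_mode == 1 and total_spikes >= n:
            status = STATUS_ALL_SPIKED
            t_end = (s + 1) * dt
            break
        if (s & 63) == 0 and pending == 0 and n_active == 0 and sp >= n_stim:
            status = STATUS_QUIESCENT
            t_end = (s + 1) * dt
            break

    if record:
        for i in range(n):
            rec[steps_done, i, 0] = V[i]
            for k in range(7):
                rec[steps_done, i, 1 + k] = G[i, k]
            for k in range(4):
                rec[steps_done, i, 8 + k] = X[i, k]

    out[0] = status
    out[1] = t_end
    out[2] = steps_done
    out[3] = runaway_neuron
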