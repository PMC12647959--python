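"""Compiled integration kernel of the cortical network model.

A single time-stepping loop over (realization, node) with exponential-Euler
gate updates and forward-Euler voltage updates; kept free of Python objects
so numba can compile it. All semantics (noise stream, synaptic update
order, spike detection) are owned here; :mod:`holotus.scnm` is the
user-facing wrapper.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: Order of recorded current traces.
CURRENT_ORDER = ("I_Na", "I_Kd", "I_M", "I_KT", "I_Leak",
                 "I_AMPA", "I_TUS", "I_Noise")

SPIKE_CAP = 512


@njit(cache=True)
def _rates(vi, v_t, tau_max_m):
    u = vi - v_t

    # x / (exp(x/denom) - 1), series-expanded near zero
    def lin_exp(x, denom):
        y = x / denom
        if abs(y) < 1e-7:
            return denom * (1.0 - y / 2.0)
        return x / (np.expm1(y))

    a_m = 0.32 * lin_exp(-(u - 13.0), 4.0)
    b_m = 0.28 * lin_exp(u - 40.0, 5.0)
    a_h = 0.128 * np.exp(-(u - 17.0) / 18.0)
    b_h = 4.0 / (1.0 + np.exp(-(u - 40.0) / 5.0))
    a_n = 0.032 * lin_exp(-(u - 15.0), 5.0)
    b_n = 0.5 * np.exp(-(u - 10.0) / 40.0)
    p_inf = 1.0 / (1.0 + np.exp(-(vi + 35.0) / 10.0))
    tau_p = tau_max_m / (3.3 * np.exp((vi + 35.0) / 20.0)
                         + np.exp(-(vi + 35.0) / 20.0))
    return a_m, b_m, a_h, b_h, a_n, b_n, p_inf, tau_p


@njit(cache=True)
def run_network(n_steps, dt, v, m, h, n_g, p_g, s, i_noise, last_spike,
                adjacency, stim_mask, start, end, drive,
                c_m, g_na0, g_kd0, g_m0, g_leak,
                e_na, e_k, e_leak, v_t, tau_max_m,
                thermal_on, thr_decay, thr_ss,
                q10_kin, q10_gna, q10_gk, g_kt_per_k,
                syn_decay, syn_w, e_ampa, trigger, refractory,
                noise_on, ou_decay, ou_scale, seed,
                spike_times, spike_counts,
                record, v_rec, cur_rec, dt_rec):
    """Integrate the network in place; returns 0 on success or the step
    index at which |V| exceeded 200 mV."""
    np.random.seed(seed)
    R, N = v.shape
    d_temp = 0.0
    v_new = np.empty((R, N))
    crossed = np.empty((R, N), dtype=np.bool_)

    for step in range(1, n_steps + 1):
        t = step * dt
        on = (start <= t - dt) and (t - dt < end)
        if thermal_on:
            ss = thr_ss if on else 0.0
            d_temp = ss + (d_temp - ss) * thr_decay

        for r in range(R):
            for i in range(N):
                vi = v[r, i]
                # heating (and hence Q10 modulation) only at sonicated nodes
                dT = d_temp * stim_mask[i] if thermal_on else 0.0
                phi = q10_kin ** (dT / 10.0)
                g_na = g_na0 * q10_gna ** (dT / 10.0)
                gk_fac = q10_gk ** (dT / 10.0)

                (a_m, b_m, a_h, b_h, a_n, b_n,
                 p_inf, tau_p) = _rates(vi, v_t, tau_max_m)
                inf = a_m / (a_m + b_m)
                m[r, i] = inf + (m[r, i] - inf) * np.exp(
                    -dt * phi * (a_m + b_m))
                inf = a_h / (a_h + b_h)
                h[r, i] = inf + (h[r, i] - inf) * np.exp(
                    -dt * phi * (a_h + b_h))
                inf = a_n / (a_n + b_n)
                n_g[r, i] = inf + (n_g[r, i] - inf) * np.exp(
                    -dt * phi * (a_n + b_n))
                p_g[r, i] = p_inf + (p_g[r, i] - p_inf) * np.exp(
                    -dt * phi / tau_p)

                i_na = g_na * m[r, i] ** 3 * h[r, i] * (vi - e_na)
                i_kd = g_kd0 * gk_fac * n_g[r, i] ** 4 * (vi - e_k)
                i_m = g_m0 * gk_fac * p_g[r, i] * (vi - e_k)
                i_kt = g_kt_per_k * dT * (vi - e_k)
                i_leak = g_leak * (vi - e_leak)
                i_ampa = syn_w * s[r, i] * (vi - e_ampa)
                i_tus = -drive * stim_mask[i] if on else 0.0
                if noise_on:
                    i_noise[r, i] = (i_noise[r, i] * ou_decay
                                     + ou_scale
                                     * np.random.standard_normal())
                total = (i_na + i_kd + i_m + i_kt + i_leak + i_ampa
                         + i_tus + i_noise[r, i])
                vn = vi + dt * (-total) / c_m
                if abs(vn) > 200.0:
                    return step
                v_new[r, i] = vn
                crossed[r, i] = (vi < trigger) and (vn >= trigger) and (
                    t - last_spike[r, i] > refractory)

                if record and r == 0:
                    cur_rec[0, step, i] = i_na
                    cur_rec[1, step, i] = i_kd
                    cur_rec[2, step, i] = i_m
                    cur_rec[3, step, i] = i_kt
                    cur_rec[4, step, i] = i_leak
                    cur_rec[5, step, i] = i_ampa
                    cur_rec[6, step, i] = i_tus
                    cur_rec[7, step, i] = i_noise[r, i]

        # simultaneous synaptic/spike bookkeeping after the voltage sweep
        for r in range(R):
            for i in range(N):
                if crossed[r, i]:
                    last_spike[r, i] = t
                    c = spike_counts[r, i]
                    if c < spike_times.shape[2]:
                        spike_times[r, i, c] = t
                    spike_counts[r, i] = c + 1
                    for j in range(N):
                        s[r, j] += adjacency[j, i]
        for r in range(R):
            for i in range(N):
                s[r, i] *= syn_decay
                v[r, i] = v_new[r, i]

        if record:
            for i in range(N):
                v_rec[step, i] = v[0, i]
            dt_rec[step] = d_temp
    return 0
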