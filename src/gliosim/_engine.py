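"""Fixed-step implicit network integrator (numba-compiled).

The scheme is the classic staggered compartmental update: gating variables
advance by exponential (exact linear) integration using voltage-indexed
lookup tables of steady states and decay factors, then the voltage step is
solved implicitly (backward Euler, the first-order backward-difference
formula) as one symmetric tree-structured linear system per network step,
eliminated exactly by Hines ordering (parents precede children).  Synaptic
receptor states and the SIC gate are linear ODEs per step and use their
closed-form updates; the astrocyte subsystem is four slow states advanced
explicitly at the same step.

Everything is deterministic: there is no randomness anywhere in the model,
so repeated runs with identical settings agree bit-for-bit.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from . import channels as chan

#: channel column order of the conductance matrix
CHANNEL_ORDER = ("Na", "Ca", "K_DR", "K_A", "K_C", "K_AHP", "leak")
#: gate column order of the gating matrix
GATE_ORDER = ("m", "h", "n", "a", "b", "s", "c", "q")

V_TAB_MIN = -130.0
V_TAB_MAX = 80.0
V_TAB_STEP = 0.01


def build_gate_tables(dt_ms: float):
    """Voltage-indexed steady-state and decay-factor tables for the 7
    voltage-dependent gates (q is chi-dependent and handled analytically)."""
    v = np.arange(V_TAB_MIN, V_TAB_MAX + V_TAB_STEP / 2, V_TAB_STEP)
    gates = GATE_ORDER[:7]
    xinf = np.empty((7, v.size))
    dec = np.empty((7, v.size))
    for i, g in enumerate(gates):
        a, b = chan.gate_rates(g, v, 0.0)
        r = a + b
        xinf[i] = a / r
        dec[i] = np.exp(-dt_ms * r)
    return v[0], 1.0 / V_TAB_STEP, np.ascontiguousarray(xinf), np.ascontiguousarray(dec)


# astro parameter-vector layout
AP_LAYOUT = ("v1", "v2", "v3", "k3", "d1", "d2", "d3", "d5", "a2", "c0", "c1",
             "ip3_rest", "tau_ip3", "r_glu", "k_glu", "thr_nm", "sigma_max",
             "clamp_um", "drain_tau_s", "rec_tau_s", "y_on", "y_off")


@njit(cache=True, fastmath=True)
def run_network(parent, gax, gax_sum, cap, area, gdens, inj_ua,
                vmin, dvinv, xinf_tab, dec_tab,
                e_na, e_ca, e_k, e_leak, chi_sat, phi, chi_dec, chi_tau,
                q_alpha_scale, q_alpha_max, q_beta,
                v, gates, chi,
                syn_pre, syn_post, syn_gampa, syn_gnmda,
                glu_gmax, glu_vhalf, glu_kp,
                ampa_alpha, ampa_beta, nmda_alpha, nmda_beta,
                mg_fac, mg_gamma, e_syn, r_ampa, r_nmda,
                sic_post, sic_g, sic_dec, sic_gain, sic_clamp_h,
                sic_sub_rev, sic_erev, h,
                astro_on, astro_clamp, ap, astate,
                sense_syn, dt, n_steps, rec_stride,
                v_rec, glu_rec, h_rec, astro_rec, sigma_rec):
    n = v.shape[0]
    nsyn = syn_pre.shape[0]
    nsic = sic_post.shape[0]
    ntab = xinf_tab.shape[1]
    d = np.empty(n)
    rhs = np.empty(n)
    sigma = 0.0
    dt_s = dt * 1e-3

    for step in range(n_steps):
        # ---- record ----
        if step % rec_stride == 0:
            j = step // rec_stride
            if j < v_rec.shape[0]:
                ok = True
                for i in range(n):
                    v_rec[j, i] = v[i]
                    if not np.isfinite(v[i]) or abs(v[i]) > 500.0:
                        ok = False
                for k in range(nsyn):
                    vp = v[syn_pre[k]]
                    glu_rec[j, k] = glu_gmax[k] / (1.0 + np.exp(-(vp - glu_vhalf[k]) / glu_kp[k]))
                for k in range(nsic):
                    h_rec[j, k] = h[k]
                if astro_rec.shape[1] >= 6:
                    astro_rec[j, 0] = astate[0]
                    astro_rec[j, 1] = astate[1]
                    astro_rec[j, 2] = astate[2]
                    astro_rec[j, 3] = astate[3]
                    astro_rec[j, 4] = sigma
                    astro_rec[j, 5] = astate[5]
                sigma_rec[j] = sigma
                if not ok:
                    return j

        # ---- gating variables (exponential update from tables) ----
        for i in range(n):
            x = (v[i] - vmin) * dvinv
            if x < 0.0:
                x = 0.0
            elif x > ntab - 2:
                x = float(ntab - 2)
            i0 = int(x)
            f = x - i0
            for g in range(7):
                xi = xinf_tab[g, i0] * (1.0 - f) + xinf_tab[g, i0 + 1] * f
                dc = dec_tab[g, i0] * (1.0 - f) + dec_tab[g, i0 + 1] * f
                gates[i, g] = xi + (gates[i, g] - xi) * dc
            aq = q_alpha_scale * chi[i]
            if aq > q_alpha_max:
                aq = q_alpha_max
            rq = aq + q_beta
            qi = aq / rq
            gates[i, 7] = qi + (gates[i, 7] - qi) * np.exp(-dt * rq)
            # Ca pool from the updated s gate at the pre-step voltage
            s_ = gates[i, 5]
            if gdens[i, 1] > 0.0:
                ica_dens = gdens[i, 1] * s_ * s_ * (v[i] - e_ca) / area[i]
                chi_inf = -phi[i] * ica_dens * chi_tau[i]
            else:
                chi_inf = 0.0
            chi[i] = chi_inf + (chi[i] - chi_inf) * chi_dec[i]

        # ---- synaptic receptor states ----
        for k in range(nsyn):
            vp = v[syn_pre[k]]
            t_glu = glu_gmax[k] / (1.0 + np.exp(-(vp - glu_vhalf[k]) / glu_kp[k]))
            ra = ampa_alpha * t_glu
            rr = ra + ampa_beta
            rinf = ra / rr
            r_ampa[k] = rinf + (r_ampa[k] - rinf) * np.exp(-dt * rr)
            rn = nmda_alpha * t_glu
            rr = rn + nmda_beta
            rinf = rn / rr
            r_nmda[k] = rinf + (r_nmda[k] - rinf) * np.exp(-dt * rr)

        # ---- astrocyte and release machinery ----
        if astro_on == 1:
            if astro_clamp == 1:
                astate[0] = ap[17]
                sigma = 0.0
            else:
                ca = astate[0]
                ip3 = astate[1]
                w = astate[2]
                ca_er = (ap[9] - ca) / ap[10]
                m_inf = ip3 / (ip3 + ap[4])
                n_inf = ca / (ca + ap[7])
                act = m_inf * n_inf * w
                j_chan = ap[10] * ap[0] * act * act * act * (ca_er - ca)
                j_leak = ap[10] * ap[1] * (ca_er - ca)
                j_pump = ap[2] * ca * ca / (ca * ca + ap[3] * ap[3])
                glu_s = 0.0
                if sense_syn >= 0:
                    vp = v[syn_pre[sense_syn]]
                    glu_s = glu_gmax[sense_syn] / (
                        1.0 + np.exp(-(vp - glu_vhalf[sense_syn]) / glu_kp[sense_syn]))
                q2 = ap[5] * (ip3 + ap[4]) / (ip3 + ap[6])
                dw = ap[8] * (q2 * (1.0 - w) - w * ca)
                dip3 = (ap[11] - ip3) / ap[12] + ap[13] * glu_s / (glu_s + ap[14])
                dca = j_chan + j_leak - j_pump
                astate[0] = ca + dt_s * dca
                if astate[0] < 0.0:
                    astate[0] = 0.0
                astate[1] = ip3 + dt_s * dip3
                astate[2] = w + dt_s * dw
                if astate[2] < 0.0:
                    astate[2] = 0.0
                elif astate[2] > 1.0:
                    astate[2] = 1.0
                # docked-vesicle pool with on/off hysteresis
                gate_open = astate[0] * 1e3 > ap[15]
                y = astate[3]
                if astate[4] > 0.5:  # releasing
                    y += dt_s * (-y / ap[18] + (1.0 - y) / ap[19])
                    if y < ap[21] or not gate_open:
                        astate[4] = 0.0
                else:
                    y += dt_s * (1.0 - y) / ap[19]
                    if gate_open and y >= ap[20]:
                        astate[4] = 1.0
                        astate[5] += 1.0
                if y < 0.0:
                    y = 0.0
                elif y > 1.0:
                    y = 1.0
                astate[3] = y
                sigma = ap[16] if astate[4] > 0.5 else 0.0

        # ---- SIC gate (closed-form linear update) ----
        for k in range(nsic):
            h[k] = h[k] * sic_dec + sigma * sic_gain

        # ---- implicit voltage step (backward Euler on the tree) ----
        for i in range(n):
            m_ = gates[i, 0]
            h_ = gates[i, 1]
            n_ = gates[i, 2]
            a_ = gates[i, 3]
            b_ = gates[i, 4]
            s_ = gates[i, 5]
            c_ = gates[i, 6]
            q_ = gates[i, 7]
            g_na = gdens[i, 0] * m_ * m_ * h_
            g_ca = gdens[i, 1] * s_ * s_
            g_kdr = gdens[i, 2] * n_
            g_ka = gdens[i, 3] * a_ * b_
            sat = chi[i] / chi_sat
            if sat > 1.0:
                sat = 1.0
            g_kc = gdens[i, 4] * c_ * sat
            g_kahp = gdens[i, 5] * q_
            g_l = gdens[i, 6]
            g_k = g_kdr + g_ka + g_kc + g_kahp
            cdt = cap[i] / dt
            d[i] = cdt + g_na + g_ca + g_k + g_l + gax_sum[i]
            rhs[i] = cdt * v[i] + g_na * e_na + g_ca * e_ca + g_k * e_k \
                + g_l * e_leak + inj_ua[i]

        for k in range(nsyn):
            p = syn_post[k]
            blk = 1.0 / (1.0 + np.exp(-mg_gamma * v[p]) * mg_fac)
            g = syn_gampa[k] * r_ampa[k] + syn_gnmda[k] * r_nmda[k] * blk
            d[p] += g
            rhs[p] += g * e_syn

        for k in range(nsic):
            hk = h[k]
            if sic_clamp_h == 1 and hk > 1.0:
                hk = 1.0
            g = sic_g[k] * hk
            p = sic_post[k]
            d[p] += g
            if sic_sub_rev == 1:
                rhs[p] += g * sic_erev

        # Hines elimination (children have larger indices than parents)
        for i in range(n - 1, 0, -1):
            p = parent[i]
            if p >= 0:
                f = gax[i] / d[i]
                d[p] -= f * gax[i]
                rhs[p] += f * rhs[i]
        for i in range(n):
            p = parent[i]
            if p < 0:
                v[i] = rhs[i] / d[i]
            else:
                v[i] = (rhs[i] + gax[i] * v[p]) / d[i]

    return -1
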