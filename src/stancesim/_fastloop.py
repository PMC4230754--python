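"""Compiled inner loop of the closed-loop simulation.

This module is the compiled twin of the reference per-step loop in
``engine.run_simulation``: it advances the whole coupled system — muscle
fibres, pendulum, spindles (with their mechanical-embedding filters),
Golgi tendon organs, afferent gamma encoders, motor-unit activation
filters and the spinal network — in batches of ``BATCH`` engine steps per
call.  Batching is sound because every spike travels through a conduction
+ transmission delay of at least ``BATCH`` steps, so nothing emitted
inside a batch can act within the same batch; all event scheduling and
random-number replenishment stays in Python at batch boundaries.

A conformance test checks the compiled loop against the pure-Python
reference on short runs.
"""
from __future__ import annotations

import math

import numpy as np

try:
    import numba as _numba
    HAVE_NUMBA = True
    _njit = _numba.njit(cache=True, fastmath=False)
except Exception:                                  # pragma: no cover
    HAVE_NUMBA = False

    def _njit(f):
        return f

BATCH = 10          # engine steps per kernel call; <= the minimum synaptic
#                     delay in steps (transmission alone is 0.5 ms = 10)

# muscle constant layout (per muscle row)
#  0 sin_a0  1 l0  2 lt0  3 ct  4 kt  5 lr  6 k_pe  7 eps  8 pe_denom
#  9 b_pe  10 mass_norm  11 f0
# 12..16 length poly c4..c0 (Horner order)   17..21 arm poly c4..c0
# 22 s_beta 23 s_omega 24 s_rho 25 s_vmax 26 s_cv0 27 s_cv1 28 s_av0
# 29 s_av1 30 s_av2 31 s_bv
# 32 f_beta 33 f_omega 34 f_rho 35 f_vmax 36 f_cv0 37 f_cv1 38 f_av0
# 39 f_av1 40 f_av2 41 f_bv


@_njit
def _fibre_accel(lf, vf, l_mtu, a_s, a_f, mc):
    s = mc[0] / lf
    if s >= 1.0:
        return np.nan, np.nan
    cos_a = math.sqrt(1.0 - s * s)
    x = ((l_mtu - lf * mc[1] * cos_a) / mc[2] - mc[5]) / mc[4]
    if x > 0.0:
        f_t = mc[3] * mc[4] * (x + math.log1p(math.exp(-x)))
    else:
        f_t = mc[3] * mc[4] * math.log1p(math.exp(x))
    f_pe = (math.exp(mc[6] * (lf - 1.0) / mc[7]) - 1.0) / mc[8] + mc[9] * vf
    f_ce = 0.0
    if a_s > 0.0:
        flv = math.exp(-abs((lf ** mc[22] - 1.0) / mc[23]) ** mc[24])
        if vf <= 0.0:
            fvv = (mc[25] - vf) / (mc[25] + vf * (mc[26] + mc[27] * lf))
        else:
            fvv = (mc[31] - vf * (mc[28] + mc[29] * lf
                                  + mc[30] * lf * lf)) / (mc[31] + vf)
        if fvv < 0.0:
            fvv = 0.0
        f_ce += a_s * flv * fvv
    if a_f > 0.0:
        flv = math.exp(-abs((lf ** mc[32] - 1.0) / mc[33]) ** mc[34])
        if vf <= 0.0:
            fvv = (mc[35] - vf) / (mc[35] + vf * (mc[36] + mc[37] * lf))
        else:
            fvv = (mc[41] - vf * (mc[38] + mc[39] * lf
                                  + mc[40] * lf * lf)) / (mc[41] + vf)
        if fvv < 0.0:
            fvv = 0.0
        f_ce += a_f * flv * fvv
    return (f_t / cos_a - f_ce - f_pe) / mc[10], f_t


@_njit
def run_batch(
        step0, k, dt, lock_steps, fall_thr, imposed_none,
        # events due inside this batch
        ev_sub, ev_start, ev_ch, ev_w,
        # motor-unit spike arrivals inside this batch
        arr_sub, arr_mu,
        # fusimotor values per substep
        gs_arr, gd_arr,
        # pendulum state [theta, omega, t_ankle] and body constants
        pend, mgh, inertia, k_pas, b_pas, ref, height, m_g,
        # muscles
        mconst, lf_arr, vf_arr, ften_arr,
        # activation filters
        act_x1, act_x2, act_a11, act_a12, act_a21, act_a22, act_imp,
        act_amp, act_c, act_group, act_tot,
        # spindle input filters
        sf_y, sf_yd, sf_a11, sf_a12, sf_a21, sf_a22, sf_tau,
        # spindles
        sp_const, sp_shared, sp_T, sp_Td, sp_f, sp_decay, g_pri, g_sec,
        # GTOs
        gto_b, gto_a, gto_w, gto_rmax, gto_fhalf, gto_nfull,
        # afferent encoder
        aff_thr, aff_r0, aff_int, aff_tgt, aff_seg, receptor,
        # network: channels
        n_exc, ch_won, ch_r, ch_gmax, ch_neuron, ch_comp,
        alpha_e, beta_e, alpha_i, beta_i, dtms,
        g_exc_d, g_exc_s, g_inh_s,
        # network: neurons
        na_off, h_off, kf_off, refrac_until,
        nm, nh, nn, nq, e_am, e_bm, e_ah, e_bh, e_an, e_bn, e_q,
        g_ls, g_ld, g_c, c_s_inv, c_d_inv, g_na, g_kf, g_ks,
        delta_q, v_th, v_s, v_d, e_na, e_k, e_exc, e_inh,
        na_steps, h_steps, kf_steps, refrac_steps,
        # outputs
        out_series, fn_sub, fn_id, fa_sub, fa_id):
    """Advance ``k`` engine steps; returns (n_mn_fired_total encoded in
    counts) via the buffers: (n_neuron_spikes, n_afferent_spikes,
    fall_substep or -1)."""
    n_mus = mconst.shape[0]
    n_aff = aff_thr.shape[0]
    n_ch = ch_won.shape[0]
    n_nrn = v_s.shape[0]
    half = 0.5 * dt
    n_fn = 0
    n_fa = 0
    fall_sub = -1
    ln_sr_off = sp_shared[5]
    occl = sp_shared[6]
    w_sr = sp_shared[7]
    w_pr = sp_shared[8]
    sec_base_off = sp_shared[9]
    a_pow = sp_shared[0]
    c_len = sp_shared[1]
    c_sho = sp_shared[2]
    off_r = sp_shared[3]
    off_pr = sp_shared[4]
    for j in range(k):
        step = step0 + j
        # -- transmitter events due now
        for e in range(ev_sub.shape[0]):
            if ev_sub[e] == j:
                w = ev_w[e]
                for c in range(ev_start[e], ev_start[e + 1]):
                    ch_won[ev_ch[c]] += w
        # -- motor arrivals -> activation filter impulses
        for e in range(arr_sub.shape[0]):
            if arr_sub[e] == j:
                mu = arr_mu[e]
                act_x2[mu] += act_imp[mu]
        # -- activation filters (exact LTI update) and per-muscle sums
        for i in range(act_x1.shape[0]):
            x1 = act_a11[i] * act_x1[i] + act_a12[i] * act_x2[i]
            act_x2[i] = act_a21[i] * act_x1[i] + act_a22[i] * act_x2[i]
            act_x1[i] = x1
        for g in range(8):
            act_tot[g] = 0.0
        for i in range(act_x1.shape[0]):
            u = act_x1[i]
            if u < 0.0:
                u = 0.0
            act_tot[act_group[i]] += act_amp[i] * math.tanh(act_c[i] * u)
        # -- muscles
        theta_deg = math.degrees(pend[0])
        torque = 0.0
        for mi in range(n_mus):
            mc = mconst[mi]
            acc_p = 0.0
            for ci in range(12, 17):
                acc_p = acc_p * theta_deg + mc[ci]
            l_mtu = acc_p / 100.0
            tot = act_tot[8 + 2 * mi]
            if tot > 0.0:
                a_s = act_tot[2 * mi] / tot
                a_f = act_tot[2 * mi + 1] / tot
            else:
                a_s = 0.0
                a_f = 0.0
            lf = lf_arr[mi]
            vf = vf_arr[mi]
            k1v, f_t = _fibre_accel(lf, vf, l_mtu, a_s, a_f, mc)
            v2 = vf + half * k1v
            k2v, _t2 = _fibre_accel(lf + half * vf, v2, l_mtu, a_s, a_f, mc)
            v3 = vf + half * k2v
            k3v, _t3 = _fibre_accel(lf + half * v2, v3, l_mtu, a_s, a_f, mc)
            v4 = vf + dt * k3v
            k4v, _t4 = _fibre_accel(lf + dt * v3, v4, l_mtu, a_s, a_f, mc)
            lf_arr[mi] = lf + dt * (vf + 2 * v2 + 2 * v3 + v4) / 6.0
            vf_arr[mi] = vf + dt * (k1v + 2 * k2v + 2 * k3v + k4v) / 6.0
            f_n = f_t * mc[11]
            ften_arr[mi] = f_n
            acc_p = 0.0
            for ci in range(17, 22):
                acc_p = acc_p * theta_deg + mc[ci]
            torque += 2.0 * (acc_p / 100.0) * f_n
        # -- pendulum
        if imposed_none and step >= lock_steps:
            th = pend[0]
            om = pend[1]
            k1t = om
            k1o = (mgh * math.sin(th)
                   - (k_pas * (th - ref) + b_pas * om - torque)) / inertia
            k2t = om + 0.5 * dt * k1o
            th2 = th + 0.5 * dt * k1t
            k2o = (mgh * math.sin(th2)
                   - (k_pas * (th2 - ref) + b_pas * k2t - torque)) / inertia
            k3t = om + 0.5 * dt * k2o
            th3 = th + 0.5 * dt * k2t
            k3o = (mgh * math.sin(th3)
                   - (k_pas * (th3 - ref) + b_pas * k3t - torque)) / inertia
            k4t = om + dt * k3o
            th4 = th + dt * k3t
            k4o = (mgh * math.sin(th4)
                   - (k_pas * (th4 - ref) + b_pas * k4t - torque)) / inertia
            th += dt * (k1t + 2 * k2t + 2 * k3t + k4t) / 6.0
            om += dt * (k1o + 2 * k2o + 2 * k3o + k4o) / 6.0
            pend[0] = th
            pend[1] = om
            pend[2] = k_pas * (th - ref) + b_pas * om - torque
            if fall_sub < 0 and abs(th) > fall_thr:
                fall_sub = j
        elif imposed_none:
            pend[2] = k_pas * (pend[0] - ref) - torque
        # -- receptors
        gs = gs_arr[j]
        gd = gd_arr[j]
        for mi in range(n_mus):
            # spindle input filter (second-order critically damped)
            tau = sf_tau[mi]
            dy = sf_y[mi] - lf_arr[mi]
            y = lf_arr[mi] + sf_a11[mi] * dy + sf_a12[mi] * sf_yd[mi]
            sf_yd[mi] = sf_a21[mi] * dy + sf_a22[mi] * sf_yd[mi]
            sf_y[mi] = y
            acc_s = (lf_arr[mi] - y) / (tau * tau) - 2.0 * sf_yd[mi] / tau
            lf_s = y
            vf_s = sf_yd[mi]
            # intrafusal fibres
            for fi in range(3):
                k_sr = sp_const[mi, fi, 0]
                k_pr = sp_const[mi, fi, 1]
                mass = sp_const[mi, fi, 2]
                beta0 = sp_const[mi, fi, 3]
                beta_fus = sp_const[mi, fi, 4]
                gamma_fus = sp_const[mi, fi, 5]
                tau_f = sp_const[mi, fi, 6]
                freq_p = sp_const[mi, fi, 7]
                p_pow = sp_const[mi, fi, 8]
                gme = gd if fi == 0 else gs
                if gme < 0.0:
                    gme = 0.0
                gpow = gme ** p_pow
                inf = gpow / (gpow + freq_p)
                if tau_f > 0.0:
                    f = inf + (sp_f[mi, fi] - inf) * sp_decay[mi, fi]
                else:
                    f = inf
                sp_f[mi, fi] = f
                beta = beta0 + beta_fus * f
                gam = gamma_fus * f
                ksr_m = k_sr / mass
                spring_base = lf_s - off_pr
                macc = mass * acc_s
                t0 = sp_T[mi, fi]
                td0 = sp_Td[mi, fi]

                v_pr = vf_s - td0 / k_sr
                c = c_len if v_pr > 0 else c_sho
                av = abs(v_pr) ** a_pow
                fr = av if v_pr > 0 else -av
                x = lf_s - t0 / k_sr
                k1d = ksr_m * (c * beta * fr * (x - off_r)
                               + k_pr * (spring_base - t0 / k_sr)
                               + macc + gam - t0)
                d2 = td0 + half * k1d
                t_ = t0 + half * td0
                v_pr = vf_s - d2 / k_sr
                c = c_len if v_pr > 0 else c_sho
                av = abs(v_pr) ** a_pow
                fr = av if v_pr > 0 else -av
                x = lf_s - t_ / k_sr
                k2d = ksr_m * (c * beta * fr * (x - off_r)
                               + k_pr * (spring_base - t_ / k_sr)
                               + macc + gam - t_)
                d3 = td0 + half * k2d
                t_ = t0 + half * d2
                v_pr = vf_s - d3 / k_sr
                c = c_len if v_pr > 0 else c_sho
                av = abs(v_pr) ** a_pow
                fr = av if v_pr > 0 else -av
                x = lf_s - t_ / k_sr
                k3d = ksr_m * (c * beta * fr * (x - off_r)
                               + k_pr * (spring_base - t_ / k_sr)
                               + macc + gam - t_)
                d4 = td0 + dt * k3d
                t_ = t0 + dt * d3
                v_pr = vf_s - d4 / k_sr
                c = c_len if v_pr > 0 else c_sho
                av = abs(v_pr) ** a_pow
                fr = av if v_pr > 0 else -av
                x = lf_s - t_ / k_sr
                k4d = ksr_m * (c * beta * fr * (x - off_r)
                               + k_pr * (spring_base - t_ / k_sr)
                               + macc + gam - t_)
                sp_T[mi, fi] = t0 + dt * (td0 + 2 * d2 + 2 * d3 + d4) / 6.0
                sp_Td[mi, fi] = td0 + dt * (k1d + 2 * k2d + 2 * k3d
                                            + k4d) / 6.0
            # afferent potentials
            x1 = sp_T[mi, 0] / sp_const[mi, 0, 0] - ln_sr_off
            x2 = sp_T[mi, 1] / sp_const[mi, 1, 0] - ln_sr_off
            x3 = sp_T[mi, 2] / sp_const[mi, 2, 0] - ln_sr_off
            b1 = g_pri * x1
            stat = g_pri * (x2 + x3)
            if b1 >= stat:
                ia = b1 + occl * stat
            else:
                ia = stat + occl * b1
            base = lf_s - sec_base_off
            ii = g_sec * (w_sr * (x2 + x3)
                          + w_pr * (2.0 * base
                                    - (sp_T[mi, 1] + sp_T[mi, 2])
                                    / sp_const[mi, 1, 0]))
            receptor[3 * mi] = ia if ia > 0.0 else 0.0
            receptor[3 * mi + 1] = ii if ii > 0.0 else 0.0
            # GTO: static law + direct-form II filter
            xg = ften_arr[mi] / gto_nfull
            u = gto_rmax * xg / (xg + gto_fhalf)
            w0 = u - gto_a[1] * gto_w[mi, 0] - gto_a[2] * gto_w[mi, 1] \
                - gto_a[3] * gto_w[mi, 2]
            yg = gto_b[0] * w0 + gto_b[1] * gto_w[mi, 0] \
                + gto_b[2] * gto_w[mi, 1] + gto_b[3] * gto_w[mi, 2]
            gto_w[mi, 2] = gto_w[mi, 1]
            gto_w[mi, 1] = gto_w[mi, 0]
            gto_w[mi, 0] = w0
            receptor[3 * mi + 2] = yg if yg > 0.0 else 0.0
        # -- afferent gamma encoders
        for a in range(n_aff):
            r = receptor[aff_seg[a]] - aff_thr[a]
            if r >= 0.0:
                aff_int[a] += (aff_r0[a] + r) * dt
                if aff_int[a] >= aff_tgt[a]:
                    aff_int[a] -= aff_tgt[a]
                    fa_sub[n_fa] = j
                    fa_id[n_fa] = a
                    n_fa += 1
        # -- network channels
        for i in range(n_nrn):
            g_exc_d[i] = 0.0
            g_exc_s[i] = 0.0
            g_inh_s[i] = 0.0
        for c in range(n_ch):
            if c < n_exc:
                alpha = alpha_e
                beta = beta_e
            else:
                alpha = alpha_i
                beta = beta_i
            w = ch_won[c]
            if w < 0.0:
                w = 0.0
            aw = alpha * w
            rate = aw + beta
            r_inf = aw / rate
            r = r_inf + (ch_r[c] - r_inf) * math.exp(-rate * dtms)
            ch_r[c] = r
            g = ch_gmax[c] * r
            tgt = ch_neuron[c]
            comp = ch_comp[c]
            if comp == 0:
                g_exc_d[tgt] += g
            elif comp == 1:
                g_exc_s[tgt] += g
            else:
                g_inh_s[tgt] += g
        # -- neurons
        for i in range(n_nrn):
            mi_ = nm[i]
            if na_off[i] > step:
                mi_ = 1.0 + (mi_ - 1.0) * e_am
            else:
                mi_ = mi_ * e_bm
            nm[i] = mi_
            hi = nh[i]
            if h_off[i] > step:
                hi = hi * e_ah
            else:
                hi = 1.0 + (hi - 1.0) * e_bh
            nh[i] = hi
            ni = nn[i]
            if kf_off[i] > step:
                ni = 1.0 + (ni - 1.0) * e_an
            else:
                ni = ni * e_bn
            nn[i] = ni
            qi = nq[i] * e_q[i]
            nq[i] = qi
            g_na_eff = g_na[i] * (mi_ * mi_ * mi_) * hi
            n2 = ni * ni
            g_kf_eff = g_kf[i] * n2 * n2
            g_ks_eff = g_ks[i] * qi
            ged = g_exc_d[i]
            ges = g_exc_s[i]
            gis = g_inh_s[i]
            gsum_s = (g_ls[i] + g_c[i] + g_na_eff + g_kf_eff + g_ks_eff
                      + gis + ges)
            b_s = (g_na_eff * e_na + (g_kf_eff + g_ks_eff) * e_k
                   + gis * e_inh + ges * e_exc)
            gsum_d = g_ld[i] + g_c[i] + ged
            b_d = ged * e_exc
            cis = c_s_inv[i]
            cid = c_d_inv[i]
            gc = g_c[i]
            vs = v_s[i]
            vd = v_d[i]
            k1s = (b_s - gsum_s * vs + gc * vd) * cis
            k1d = (b_d - gsum_d * vd + gc * vs) * cid
            a2 = vs + 0.5 * dtms * k1s
            b2 = vd + 0.5 * dtms * k1d
            k2s = (b_s - gsum_s * a2 + gc * b2) * cis
            k2d = (b_d - gsum_d * b2 + gc * a2) * cid
            a3 = vs + 0.5 * dtms * k2s
            b3 = vd + 0.5 * dtms * k2d
            k3s = (b_s - gsum_s * a3 + gc * b3) * cis
            k3d = (b_d - gsum_d * b3 + gc * a3) * cid
            a4 = vs + dtms * k3s
            b4 = vd + dtms * k3d
            k4s = (b_s - gsum_s * a4 + gc * b4) * cis
            k4d = (b_d - gsum_d * b4 + gc * a4) * cid
            vs = vs + dtms * (k1s + 2.0 * k2s + 2.0 * k3s + k4s) / 6.0
            vd = vd + dtms * (k1d + 2.0 * k2d + 2.0 * k3d + k4d) / 6.0
            v_s[i] = vs
            v_d[i] = vd
            if vs >= v_th[i] and refrac_until[i] <= step:
                na_off[i] = step + na_steps
                h_off[i] = step + h_steps
                kf_off[i] = step + kf_steps
                refrac_until[i] = step + refrac_steps
                nq[i] = nq[i] + delta_q[i] * (1.0 - nq[i])
                fn_sub[n_fn] = j
                fn_id[n_fn] = i
                n_fn += 1
        # -- per-substep series outputs
        out_series[0, j] = pend[0]
        out_series[1, j] = pend[1]
        out_series[2, j] = torque
        out_series[3, j] = pend[2]
        for mi in range(n_mus):
            out_series[4 + mi, j] = lf_arr[mi]
            out_series[8 + mi, j] = vf_arr[mi]
            out_series[12 + mi, j] = ften_arr[mi]
            tot = act_tot[8 + 2 * mi]
            out_series[16 + mi, j] = act_tot[2 * mi] / tot if tot > 0 else 0.0
            out_series[20 + mi, j] = act_tot[2 * mi + 1] / tot \
                if tot > 0 else 0.0
        for si in range(12):
            out_series[24 + si, j] = receptor[si]
    return n_fn, n_fa, fall_sub
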