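"""Compiled stepping kernel for the coupled CRU / mitochondria lattice.

One call advances the full model state from its current time to ``t_end``
with the hybrid scheme: explicit Euler for every continuous variable and
per-step stochastic channel sampling (LCC, RyR, mPTP) with exact
exponential per-step transition probabilities ``1 - exp(-rate*dt)``.
The step size adapts globally: ``dt_upstroke`` while |dV/dt| exceeds the
upstroke criterion, ``dt_normal`` otherwise.

Randomness is counter-based: every draw hashes (seed, step, site, salt)
through a splitmix64 finalizer, so trajectories are bit-reproducible for a
given seed, independent of iteration order, and resumable from snapshots.

Gate and current formulas are jit-compiled from :mod:`mitoca.sarcolemma`
so the Python-facing API and the kernel share one definition.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from . import sarcolemma as _sl
from .params import PARAM_INDEX as _PI

# jit-compiled shared formulas
_sodium_rates = njit(cache=True, fastmath=True)(_sl.sodium_gate_rates)
_slow_targets = njit(cache=True, fastmath=True)(_sl.slow_gate_targets)
_lcc_gate = njit(cache=True, fastmath=True)(_sl.lcc_gate_target)
_det_currents = njit(cache=True, fastmath=True)(_sl.deterministic_currents)
_ncx_fv = njit(cache=True, fastmath=True)(_sl.ncx_voltage_factor)

# ---- parameter vector indices (compile-time constants) --------------------
RY_N = _PI["ryr.n_per_cluster"]; RY_KB = _PI["ryr.k_base"]; RY_KU = _PI["ryr.k_u"]
RY_KC = _PI["ryr.k_close"]; RY_KREC = _PI["ryr.k_recover"]; RY_KMAX = _PI["ryr.k12_max"]
RY_DKC = _PI["ryr.dk_camk_max"]; RY_KMC = _PI["ryr.km_cam_ryr"]; RY_HC = _PI["ryr.h_cam_ryr"]
RY_DKR = _PI["ryr.dk_ros_max"]; RY_KMR = _PI["ryr.km_ros_ryr"]; RY_HR = _PI["ryr.h_ros_ryr"]
RY_GREL = _PI["ryr.g_rel"]; RY_ADYAD = _PI["ryr.a_dyad"]
SE_VUP = _PI["serca.v_up"]; SE_KI = _PI["serca.k_i"]; SE_KD = _PI["serca.kd_ros"]
SE_H = _PI["serca.h_ros_serca"]; SE_KM_ATP = _PI["serca.km_up_atp"]
SE_KIUP = _PI["serca.ki_up"]; SE_KIUPP = _PI["serca.ki_up_prime"]
SE_PLBM = _PI["serca.plb_max"]; SE_PLBK = _PI["serca.plb_k"]; SE_PLBH = _PI["serca.plb_h"]
LC_N = _PI["lcc.n_per_cru"]; LC_RO = _PI["lcc.r_open"]; LC_VH = _PI["lcc.v_half_act"]
LC_KA = _PI["lcc.k_act"]; LC_RC = _PI["lcc.r_close"]; LC_KCA = _PI["lcc.k_ca_close"]
LC_AMP = _PI["lcc.flux_amp"]; LC_CAMK = _PI["lcc.camk_avail"]
CO_VS = _PI["compartments.v_sub"]; CO_VN = _PI["compartments.v_nsr"]; CO_VJ = _PI["compartments.v_jsr"]
CO_GSI = _PI["compartments.g_sub_cyt"]; CO_GTR = _PI["compartments.g_tr"]
CO_GLK = _PI["compartments.g_leak"]; CO_DC = _PI["compartments.d_cyt"]; CO_DN = _PI["compartments.d_nsr"]
CO_BIB = _PI["compartments.buf_cyt_b"]; CO_BIK = _PI["compartments.buf_cyt_k"]
CO_BSB = _PI["compartments.buf_sub_b"]; CO_BSK = _PI["compartments.buf_sub_k"]
CO_BJB = _PI["compartments.buf_jsr_b"]; CO_BJK = _PI["compartments.buf_jsr_k"]
MP_A0 = _PI["mptp.alpha0"]; MP_H = _PI["mptp.h_mptp"]; MP_CA0 = _PI["mptp.ca0"]
MP_K1O = _PI["mptp.kc1o0"]; MP_KO1 = _PI["mptp.koc1"]; MP_K10 = _PI["mptp.kc1c0"]
MP_ALPHA = _PI["mptp.alpha_mptp"]
MI_VMCU = _PI["mito.v_mcu"]; MI_KMCU = _PI["mito.k_mcu"]; MI_VNCX = _PI["mito.v_mncx"]
MI_KNCX = _PI["mito.k_mncx"]; MI_GPTP = _PI["mito.g_ptp_rel"]; MI_AMCU = _PI["mito.alpha_mcu"]
MI_SNCX = _PI["mito.mncx_scale"]; MI_VM = _PI["mito.v_mito"]
MI_PPOL = _PI["mito.psi_polarized"]; MI_PDEP = _PI["mito.psi_depolarized"]
MI_TDEP = _PI["mito.tau_psi_depol"]; MI_TREP = _PI["mito.tau_psi_repol"]
MI_FLOOR = _PI["mito.psi_mcu_floor"]
SG_EPOL = _PI["signaling.ros_emit_polarized"]; SG_EDEP = _PI["signaling.ros_emit_depolarized"]
SG_KSC = _PI["signaling.k_ros_scav"]; SG_DR = _PI["signaling.d_ros"]
SG_CG = _PI["signaling.camk_growth"]; SG_CF = _PI["signaling.camk_floor"]
SG_CM = _PI["signaling.camk_max"]; SG_KRC = _PI["signaling.k_ros_camk"]
SG_HRC = _PI["signaling.h_ros_camk"]; SG_WCA = _PI["signaling.w_ca_camk"]
SG_KCA = _PI["signaling.k_ca_camk"]; SG_AREST = _PI["signaling.atp_rest"]
SG_POOL = _PI["signaling.adenine_pool"]; SG_TATP = _PI["signaling.tau_atp"]
SG_FEXP = _PI["signaling.atp_frac_exp"]
MB_CM = _PI["membrane.cm"]; MB_CONV = _PI["membrane.flux_conv"]
MB_VNCX = _PI["membrane.v_ncx"]; MB_KNCX = _PI["membrane.k_ncx"]
ST_AMP = _PI["stimulus.amplitude"]; ST_DUR = _PI["stimulus.duration"]; ST_PCL = _PI["stimulus.period"]

# scalar-state layout
SC_V = 0
SC_GATE0 = 1          # 11 gates: m h j hl xr xs xtf ytf xts yts flcc
SC_CAMK = 12
SC_ATP = 13
SC_T = 14
SC_DVDT = 15
NSC = 16

NCOL = 14  # t V ci cjsr cnsr jup jrel cam popen dpsi ros camkii atp frac_prod

# flags layout
FL_STIM = 0
FL_SERCA_REDOX = 1
NFLAGS = 2

# clamp slots: ros, camkii, atp, ca_mito, ca_cyt, mptp_closed
CL_ROS, CL_CAMK, CL_ATP, CL_CAM, CL_CACYT, CL_PTP = 0, 1, 2, 3, 4, 5

_U1 = np.uint64(0x9E3779B97F4A7C15)
_U2 = np.uint64(0xBF58476D1CE4E5B9)
_U3 = np.uint64(0x94D049BB133111EB)
_U4 = np.uint64(0xD6E8FEB86659FD93)


@njit(cache=True, fastmath=True)
def _u01(seed, step, site, salt):
    """Counter-based uniform in [0, 1): splitmix64 finalizer over
    (seed, step, site, salt)."""
    z = (
        np.uint64(seed) * _U4
        + np.uint64(step) * _U1
        + np.uint64(site) * _U2
        + np.uint64(salt) * _U3
    )
    z = (z ^ (z >> np.uint64(30))) * _U2
    z = (z ^ (z >> np.uint64(27))) * _U3
    z = z ^ (z >> np.uint64(31))
    return (z >> np.uint64(11)) * (1.0 / 9007199254740992.0)


@njit(cache=True, fastmath=True)
def _binom(n, p, u):
    """Binomial sample by CDF inversion from one uniform; cheap fast path
    when n*p is tiny (at most one event)."""
    if n <= 0 or p <= 0.0:
        return 0
    if p >= 1.0:
        return n
    mean = n * p
    if mean < 1e-4:
        return 1 if u < mean else 0
    q = 1.0 - p
    pmf = np.exp(n * np.log(q))
    if u < pmf:
        return 0
    cdf = pmf
    r = p / q
    k = 0
    while cdf < u and k < n:
        k += 1
        pmf *= r * (n - k + 1) / k
        cdf += pmf
    return k


@njit(cache=True, fastmath=True)
def _powh(x, h):
    if h == 2.0:
        return x * x
    return x**h


@njit(cache=True, fastmath=True)
def run_chunk(
    sc, cp, cs, ci, cnsr, cjsr, ros,
    nryr, nrefr, nlcc, cam, dpsi, pstate,
    cru_mito, nbrs, P, flags,
    clamp_on, clamp_val, clamp_t0,
    seed, step0,
    dt_norm, dt_up, v_thresh,
    t_end, out_interval, next_out,
    out, out_n,
    lap_ci, lap_nsr, lap_ros, dcam,
):
    nc = ci.shape[0]
    nm = cam.shape[0]
    block = nc // nm
    n_ryr = int(P[RY_N])
    n_lcc = int(P[LC_N])
    kbu = P[RY_KB] * P[RY_KU]
    # a mitochondrion produces ATP once its pore is shut and psi has
    # recovered a quarter of the way back to the polarized level
    psi_mid = P[MI_PDEP] + 0.25 * (P[MI_PPOL] - P[MI_PDEP])
    step = step0
    t = sc[SC_T]

    while t < t_end - 1e-6:
        dt = dt_up if abs(sc[SC_DVDT]) > v_thresh else dt_norm
        v = sc[SC_V]
        camkii = sc[SC_CAMK]
        atp = sc[SC_ATP]

        # --- per-step scalars -------------------------------------------
        i_sti = 0.0
        if flags[FL_STIM] != 0 and (t % P[ST_PCL]) < P[ST_DUR]:
            i_sti = P[ST_AMP]

        lcc_act = 1.0 / (1.0 + np.exp(-(v - P[LC_VH]) / P[LC_KA]))
        avail = 1.0 + P[LC_CAMK] * camkii
        k_lcc_open = P[LC_RO] * lcc_act * avail * sc[SC_GATE0 + 10]
        p_lcc_open = -np.expm1(-k_lcc_open * dt)
        p_lcc_base_close = P[LC_RC]
        j_unit = P[LC_AMP] * (60.0 - v) / 140.0
        if j_unit < 0.0:
            j_unit = 0.0
        fv_ncx = _ncx_fv(v)

        akh = _powh(camkii, P[RY_HC])
        dk_camk = P[RY_DKC] * akh / (akh + _powh(P[RY_KMC], P[RY_HC]))
        adp = P[SG_POOL] - atp
        if adp < 0.0:
            adp = 0.0
        f_atp = 1.0 / (
            1.0 + adp / P[SE_KIUPP] + (1.0 + adp / P[SE_KIUP]) * P[SE_KM_ATP] / atp
        )
        plbh = _powh(camkii, P[SE_PLBH])
        k_eff = P[SE_KI] - P[SE_PLBM] * plbh / (plbh + _powh(P[SE_PLBK], P[SE_PLBH]))
        k_eff2 = k_eff * k_eff
        serca_pref = P[SE_VUP] * f_atp
        kdh = _powh(P[SE_KD], P[SE_H])
        kmrh = _powh(P[RY_KMR], P[RY_HR])
        p_ryr_close = -np.expm1(-P[RY_KC] * dt)
        p_ryr_rec = -np.expm1(-P[RY_KREC] * dt)

        # --- laplacians of cytosolic Ca, NSR Ca, ROS --------------------
        for i in range(nc):
            aci = 0.0
            ans = 0.0
            aro = 0.0
            deg = 0.0
            for k in range(6):
                j = nbrs[i, k]
                if j >= 0:
                    aci += ci[j]
                    ans += cnsr[j]
                    aro += ros[j]
                    deg += 1.0
            lap_ci[i] = aci - deg * ci[i]
            lap_nsr[i] = ans - deg * cnsr[i]
            lap_ros[i] = aro - deg * ros[i]

        # --- CRU pass ----------------------------------------------------
        s_ci = 0.0; s_cs = 0.0; s_jup = 0.0; s_jrel = 0.0
        s_jl = 0.0; s_jncx = 0.0; s_ros = 0.0; s_cjsr = 0.0; s_cnsr = 0.0
        for i in range(nc):
            mi = cru_mito[i]
            cpi_old = cp[i]

            # LCC transitions (gating senses last step's dyadic Ca)
            no = nlcc[i]
            opened = 0
            if p_lcc_open > 0.0 and no < n_lcc:
                opened = _binom(n_lcc - no, p_lcc_open, _u01(seed, step, i, 3))
            closed = 0
            if no > 0:
                k_cl = p_lcc_base_close + P[LC_KCA] * cpi_old
                closed = _binom(no, -np.expm1(-k_cl * dt), _u01(seed, step, i, 4))
            no = no + opened - closed
            nlcc[i] = no

            # RyR transitions
            rh = _powh(ros[i], P[RY_HR])
            dk_ros = P[RY_DKR] * rh / (rh + kmrh)
            k12 = kbu * (1.0 + dk_camk + dk_ros) * cpi_old * cpi_old
            if k12 > P[RY_KMAX]:
                k12 = P[RY_KMAX]
            nro = nryr[i]
            nrf = nrefr[i]
            n_closed = n_ryr - nro - nrf
            if n_closed > 0:
                nro += _binom(
                    n_closed, -np.expm1(-k12 * dt), _u01(seed, step, i, 1)
                )
            if nro > 0:
                shut = _binom(nro, p_ryr_close, _u01(seed, step, i, 2))
                nro -= shut
                nrf += shut
            if nrf > 0:
                nrf -= _binom(nrf, p_ryr_rec, _u01(seed, step, i, 6))
            nryr[i] = nro
            nrefr[i] = nrf

            # fluxes (cytosol-volume uM/ms)
            po = nro / n_ryr
            gop = P[RY_GREL] * po
            jl = no * j_unit
            cpi = (cs[i] + P[RY_ADYAD] * (gop * cjsr[i] + jl)) / (
                1.0 + P[RY_ADYAD] * gop
            )
            jrel = gop * (cjsr[i] - cpi)
            jsi = P[CO_GSI] * (cs[i] - ci[i])
            if flags[FL_SERCA_REDOX] != 0:
                rh2 = _powh(ros[i], P[SE_H])
                f_ros = kdh / (kdh + rh2) + 0.75 * rh2 / (rh2 + kdh)
            else:
                f_ros = 1.0
            ci2 = ci[i] * ci[i]
            jup = serca_pref * f_ros * ci2 / (ci2 + k_eff2)
            jtr = P[CO_GTR] * (cnsr[i] - cjsr[i])
            jleak = P[CO_GLK] * (cnsr[i] - ci[i])
            cs2 = cs[i] * cs[i]
            jncx = P[MB_VNCX] * fv_ncx * cs2 / (cs2 + P[MB_KNCX] * P[MB_KNCX])
            jmcu = (
                P[MI_AMCU] * P[MI_VMCU]
                * (P[MI_FLOOR] + (1.0 - P[MI_FLOOR]) * dpsi[mi] / P[MI_PPOL])
                * ci2 / (ci2 + P[MI_KMCU] * P[MI_KMCU])
            )
            jmncx = P[MI_SNCX] * P[MI_VNCX] * cam[mi] / (cam[mi] + P[MI_KNCX])
            jptp = 0.0
            if pstate[mi] == 2:
                jptp = P[MI_GPTP] * (cam[mi] - ci[i])
            dcam[mi] += jmcu - jmncx - jptp

            bs = 1.0 / (1.0 + P[CO_BSB] * P[CO_BSK] / ((P[CO_BSK] + cs[i]) ** 2))
            bi = 1.0 / (1.0 + P[CO_BIB] * P[CO_BIK] / ((P[CO_BIK] + ci[i]) ** 2))
            bj = 1.0 / (1.0 + P[CO_BJB] * P[CO_BJK] / ((P[CO_BJK] + cjsr[i]) ** 2))

            cs[i] += dt * bs * (jrel + jl - jsi - jncx) / P[CO_VS]
            ci_new = ci[i] + dt * bi * (
                jsi - jup + jleak - jmcu + jmncx + jptp + P[CO_DC] * lap_ci[i]
            )
            ci[i] = ci_new if ci_new > 0.0 else 0.0
            cnsr[i] += dt * ((jup - jtr - jleak) / P[CO_VN] + P[CO_DN] * lap_nsr[i])
            cjsr[i] += dt * bj * (jtr - jrel) / P[CO_VJ]
            cp[i] = cpi

            # ROS field
            em = P[SG_EPOL] + (P[SG_EDEP] - P[SG_EPOL]) * (
                (P[MI_PPOL] - dpsi[mi]) / (P[MI_PPOL] - P[MI_PDEP])
            )
            ros_new = ros[i] + dt * (
                em - P[SG_KSC] * ros[i] + P[SG_DR] * lap_ros[i]
            )
            ros[i] = ros_new if ros_new > 0.0 else 0.0

            s_ci += ci[i]; s_cs += cs[i]; s_jup += jup; s_jrel += jrel
            s_jl += jl; s_jncx += jncx; s_ros += ros[i]
            s_cjsr += cjsr[i]; s_cnsr += cnsr[i]

        # --- background Ca influx applied uniformly via submembrane ------
        cs_mean = s_cs / nc
        det = _det_currents(v, sc[SC_GATE0:SC_GATE0 + 11], cs_mean, atp, P)
        j_cab = -det[9] * P[MB_CONV]  # inward background current -> influx
        for i in range(nc):
            bs = 1.0 / (1.0 + P[CO_BSB] * P[CO_BSK] / ((P[CO_BSK] + cs[i]) ** 2))
            cs[i] += dt * bs * j_cab / P[CO_VS]

        # --- mitochondria -------------------------------------------------
        n_open = 0
        n_prod = 0
        ptp_blocked = clamp_on[CL_PTP] > 0.0 and t >= clamp_t0[CL_PTP]
        for mi in range(nm):
            cm_new = cam[mi] + dt * dcam[mi] / (P[MI_VM] * block)
            cam[mi] = cm_new if cm_new > 0.0 else 0.0
            dcam[mi] = 0.0

            if ptp_blocked:
                pstate[mi] = 0
            else:
                st = pstate[mi]
                if st == 0:
                    cah = _powh(cam[mi], P[MP_H])
                    k01 = P[MP_A0] * (
                        1.0 + 199.0 * cah / (cah + _powh(P[MP_CA0], P[MP_H]))
                    )
                    if _u01(seed, step, nc + mi, 5) < -np.expm1(-k01 * dt):
                        pstate[mi] = 1
                elif st == 1:
                    k1o = P[MP_ALPHA] * P[MP_K1O]
                    ktot = P[MP_K10] + k1o
                    u = _u01(seed, step, nc + mi, 5)
                    p_leave = -np.expm1(-ktot * dt)
                    if u < p_leave:
                        if u < p_leave * (k1o / ktot):
                            pstate[mi] = 2
                        else:
                            pstate[mi] = 0
                else:
                    if _u01(seed, step, nc + mi, 5) < -np.expm1(-P[MP_KO1] * dt):
                        pstate[mi] = 1

            if pstate[mi] == 2:
                dpsi[mi] += dt * (P[MI_PDEP] - dpsi[mi]) / P[MI_TDEP]
                n_open += 1
            else:
                dpsi[mi] += dt * (P[MI_PPOL] - dpsi[mi]) / P[MI_TREP]
                if dpsi[mi] >= psi_mid:
                    n_prod += 1

        # --- slow whole-cell variables -----------------------------------
        ci_mean = s_ci / nc
        ros_mean = s_ros / nc
        rch = _powh(ros_mean, P[SG_HRC])
        drive = rch / (rch + _powh(P[SG_KRC], P[SG_HRC]))
        ca2 = ci_mean * ci_mean
        drive += P[SG_WCA] * ca2 / (ca2 + P[SG_KCA] * P[SG_KCA])
        if drive > 1.0:
            drive = 1.0
        a_inf = P[SG_CF] + (P[SG_CM] - P[SG_CF]) * drive
        camkii += dt * P[SG_CG] * camkii * (1.0 - camkii / a_inf)
        if camkii < 0.0:
            camkii = 0.0
        elif camkii > 1.0:
            camkii = 1.0

        frac_prod = n_prod / nm
        atp_t = P[SG_AREST] * frac_prod ** P[SG_FEXP]
        atp += dt * (atp_t - atp) / P[SG_TATP]
        if atp < 1e-3:
            atp = 1e-3
        elif atp > P[SG_POOL]:
            atp = P[SG_POOL]

        # --- membrane voltage and gates ----------------------------------
        i_cal_std = -(s_jl / nc) / P[MB_CONV]
        i_ncx_std = -0.5 * (s_jncx / nc) / P[MB_CONV]
        itot_std = (
            det[0] + det[1] + det[2] + det[3] + det[4] + det[5] + det[6]
            + det[7] + det[8] + det[9] + i_cal_std + i_ncx_std
        )
        dvdt = (-itot_std - i_sti) / P[MB_CM]
        sc[SC_DVDT] = dvdt
        sc[SC_V] = v + dt * dvdt

        am, bm, ah, bh, aj, bj = _sodium_rates(v)
        g0 = SC_GATE0
        sc[g0 + 0] += dt * (am * (1.0 - sc[g0 + 0]) - bm * sc[g0 + 0])
        sc[g0 + 1] += dt * (ah * (1.0 - sc[g0 + 1]) - bh * sc[g0 + 1])
        sc[g0 + 2] += dt * (aj * (1.0 - sc[g0 + 2]) - bj * sc[g0 + 2])
        tg = _slow_targets(v)
        for k in range(7):
            sc[g0 + 3 + k] += dt * (tg[2 * k] - sc[g0 + 3 + k]) / tg[2 * k + 1]
        f_inf, f_tau = _lcc_gate(v, P)
        sc[g0 + 10] += dt * (f_inf - sc[g0 + 10]) / f_tau
        for k in range(11):
            if sc[g0 + k] < 0.0:
                sc[g0 + k] = 0.0
            elif sc[g0 + k] > 1.0:
                sc[g0 + k] = 1.0

        sc[SC_CAMK] = camkii
        sc[SC_ATP] = atp
        t += dt
        step += 1
        sc[SC_T] = t

        # --- clamps (overwrite after every step) --------------------------
        if clamp_on[CL_ROS] > 0.0 and t >= clamp_t0[CL_ROS]:
            for i in range(nc):
                ros[i] = clamp_val[CL_ROS]
        if clamp_on[CL_CAMK] > 0.0 and t >= clamp_t0[CL_CAMK]:
            sc[SC_CAMK] = clamp_val[CL_CAMK]
        if clamp_on[CL_ATP] > 0.0 and t >= clamp_t0[CL_ATP]:
            sc[SC_ATP] = clamp_val[CL_ATP]
        if clamp_on[CL_CAM] > 0.0 and t >= clamp_t0[CL_CAM]:
            for mi in range(nm):
                cam[mi] = clamp_val[CL_CAM]
        if clamp_on[CL_CACYT] > 0.0 and t >= clamp_t0[CL_CACYT]:
            for i in range(nc):
                ci[i] = clamp_val[CL_CACYT]

        # --- record -------------------------------------------------------
        if t >= next_out - 1e-6:
            row = out_n[0]
            if row < out.shape[0]:
                out[row, 0] = t
                out[row, 1] = sc[SC_V]
                out[row, 2] = s_ci / nc
                out[row, 3] = s_cjsr / nc
                out[row, 4] = s_cnsr / nc
                out[row, 5] = s_jup / nc
                out[row, 6] = s_jrel / nc
                cam_s = 0.0
                for mi in range(nm):
                    cam_s += cam[mi]
                out[row, 7] = cam_s / nm
                out[row, 8] = n_open / nm
                dps = 0.0
                for mi in range(nm):
                    dps += dpsi[mi]
                out[row, 9] = dps / nm
                out[row, 10] = s_ros / nc
                out[row, 11] = sc[SC_CAMK]
                out[row, 12] = sc[SC_ATP]
                out[row, 13] = frac_prod
                out_n[0] = row + 1
            next_out += out_interval

        if step % 4096 == 0:
            if not (np.isfinite(sc[SC_V]) and np.isfinite(ci_mean)):
                raise RuntimeError(
                    "numerical instability: V or cytosolic Ca became non-finite"
                )

    return step, next_out
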