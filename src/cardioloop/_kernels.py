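"""Compiled assembly kernel for the coupled residual and its Jacobians.

Mirrors CoupledModel's pure-Python assembly exactly (state layout, row
ordering, branch choices, the exponential cap of the passive chamber law)
but runs as a single njit function over flat parameter arrays.  The
pure-Python path remains the reference implementation; an equivalence test
keeps the two in lockstep.
"""
from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly by the fast path
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        if args and callable(args[0]):
            return args[0]
        return wrap

_ZCAP = 25.0

# state indices (must match solver._NAMES)
_P_AT_L, _Q_VIN_L, _Z_MIT, _Q_VOUT_L, _Z_AOR = 0, 1, 2, 3, 4
_P_V_L, _P_AR_SYS, _Q_AR_SYS, _P_VEN_SYS, _Q_VEN_SYS = 5, 6, 7, 8, 9
_P_AT_R, _Q_VIN_R, _Z_TRI, _Q_VOUT_R, _Z_PUL = 10, 11, 12, 13, 14
_P_V_R, _P_AR_PUL, _Q_AR_PUL, _P_VEN_PUL, _Q_VEN_PUL = 15, 16, 17, 18, 19
_V_AT_L, _V_V_L, _V_AT_R, _V_V_R = 20, 21, 22, 23
_TAU_AT_L, _TAU_V_L, _TAU_AT_R, _TAU_V_R = 24, 25, 26, 27


@njit(cache=True, fastmath=False)
def _chamber_p(V, tau, V_ref, Ea, Eb, wf):
    z = Eb * (V - V_ref)
    if z <= _ZCAP:
        e = np.exp(z)
        val = e - 1.0
    else:
        e = np.exp(_ZCAP)
        val = e * (1.0 + (z - _ZCAP)) - 1.0
    p = Ea * val + wf * tau * (V / V_ref)
    dp_dV = Ea * Eb * e + wf * tau / V_ref
    dp_dtau = wf * (V / V_ref)
    return p, dp_dV, dp_dtau


@njit(cache=True, fastmath=False)
def assemble_kernel(x_now, x_prev, u_now, u_prev, wk, valves, chams,
                    dt, th, want_jac, want_jac_prev, r, J, Jp):
    """Fill residual r (28,) and optionally J/Jp (28,28). Returns status."""
    om = 1.0 - th
    for i in range(28):
        if not (np.isfinite(x_now[i]) and np.isfinite(x_prev[i])):
            return 1
    r[:] = 0.0
    if want_jac:
        J[:, :] = 0.0
    if want_jac_prev:
        Jp[:, :] = 0.0

    # chamber slots: (volume, tau, pressure, closure row, mass row, tau row,
    # inflow, outflow) in order la, lv, ra, rv
    slots = (
        (_V_AT_L, _TAU_AT_L, _P_AT_L, 0, 20, 24, _Q_VEN_PUL, _Q_VIN_L),
        (_V_V_L, _TAU_V_L, _P_V_L, 5, 21, 25, _Q_VIN_L, _Q_VOUT_L),
        (_V_AT_R, _TAU_AT_R, _P_AT_R, 10, 22, 26, _Q_VEN_SYS, _Q_VIN_R),
        (_V_V_R, _TAU_V_R, _P_V_R, 15, 23, 27, _Q_VIN_R, _Q_VOUT_R),
    )
    for s in range(4):
        iV, itau, ip, i_cl, i_ms, i_tau, iin, iout = slots[s]
        V_ref = chams[5 * s]
        Ea = chams[5 * s + 1]
        Eb = chams[5 * s + 2]
        wf = chams[5 * s + 3]
        sigma0 = chams[5 * s + 4]
        if x_now[iV] <= 0.0 or x_prev[iV] <= 0.0:
            return 2
        Pn, dPVn, dPtn = _chamber_p(x_now[iV], x_now[itau], V_ref, Ea, Eb, wf)
        Pp, dPVp, dPtp = _chamber_p(x_prev[iV], x_prev[itau], V_ref, Ea, Eb, wf)
        r[i_cl] = th * (x_now[ip] - Pn) + om * (x_prev[ip] - Pp)
        if want_jac:
            J[i_cl, ip] = th
            J[i_cl, iV] = -th * dPVn
            J[i_cl, itau] = -th * dPtn
        if want_jac_prev:
            Jp[i_cl, ip] = om
            Jp[i_cl, iV] = -om * dPVp
            Jp[i_cl, itau] = -om * dPtp
        # mass balance
        r[i_ms] = ((x_now[iV] - x_prev[iV]) / dt
                   - (th * x_now[iin] + om * x_prev[iin])
                   + (th * x_now[iout] + om * x_prev[iout]))
        if want_jac:
            J[i_ms, iV] = 1.0 / dt
            J[i_ms, iin] = -th
            J[i_ms, iout] = th
        if want_jac_prev:
            Jp[i_ms, iV] = -1.0 / dt
            Jp[i_ms, iin] = -om
            Jp[i_ms, iout] = om
        # active stress ODE
        un = u_now[s]
        up = u_prev[s]
        un_pos = un if un > 0.0 else 0.0
        up_pos = up if up > 0.0 else 0.0
        r[i_tau] = ((x_now[itau] - x_prev[itau]) / dt
                    + th * (abs(un) * x_now[itau] - sigma0 * un_pos)
                    + om * (abs(up) * x_prev[itau] - sigma0 * up_pos))
        if want_jac:
            J[i_tau, itau] = 1.0 / dt + th * abs(un)
        if want_jac_prev:
            Jp[i_tau, itau] = -1.0 / dt + om * abs(up)

    # valve slots: (upstream p, downstream p, flow, zeta, momentum row,
    # state row) in order mit, aor, tri, pul
    vslots = (
        (_P_AT_L, _P_V_L, _Q_VIN_L, _Z_MIT, 1, 2),
        (_P_V_L, _P_AR_SYS, _Q_VOUT_L, _Z_AOR, 3, 4),
        (_P_AT_R, _P_V_R, _Q_VIN_R, _Z_TRI, 11, 12),
        (_P_V_R, _P_AR_PUL, _Q_VOUT_R, _Z_PUL, 13, 14),
    )
    for v in range(4):
        iu, idn, iq, iz, i_mom, i_st = vslots[v]
        A_min = valves[7 * v]
        A_max = valves[7 * v + 1]
        K_vo = valves[7 * v + 2]
        K_vc = valves[7 * v + 3]
        l_eff = valves[7 * v + 4]
        rho = valves[7 * v + 5]
        floor = valves[7 * v + 6]
        span = A_max - A_min
        dp_n = x_now[iu] - x_now[idn]
        dp_p = x_prev[iu] - x_prev[idn]
        A_n_raw = span * x_now[iz] + A_min
        A_p_raw = span * x_prev[iz] + A_min
        A_n = A_n_raw if A_n_raw > floor else floor
        A_p = A_p_raw if A_p_raw > floor else floor
        dA_n = span if A_n_raw > floor else 0.0
        dA_p = span if A_p_raw > floor else 0.0
        q_n = x_now[iq]
        q_p = x_prev[iq]
        rl = rho * l_eff
        inert = rl * (th / A_n + om / A_p)
        dqdt = (q_n - q_p) / dt
        g_n = rho / (2.0 * A_n * A_n) * q_n * abs(q_n) - dp_n
        g_p = rho / (2.0 * A_p * A_p) * q_p * abs(q_p) - dp_p
        r[i_mom] = inert * dqdt + th * g_n + om * g_p
        if want_jac:
            J[i_mom, iq] = inert / dt + th * rho / (A_n * A_n) * abs(q_n)
            J[i_mom, iz] = (th * (-rl * dA_n / (A_n * A_n)) * dqdt
                            + th * (-rho * q_n * abs(q_n) * dA_n / (A_n * A_n * A_n)))
            J[i_mom, iu] = -th
            J[i_mom, idn] = th
        if want_jac_prev:
            Jp[i_mom, iq] = -inert / dt + om * rho / (A_p * A_p) * abs(q_p)
            Jp[i_mom, iz] = (om * (-rl * dA_p / (A_p * A_p)) * dqdt
                             + om * (-rho * q_p * abs(q_p) * dA_p / (A_p * A_p * A_p)))
            Jp[i_mom, iu] = -om
            Jp[i_mom, idn] = om
        # opening state
        z_n = x_now[iz]
        z_p = x_prev[iz]
        if dp_n > 0.0:
            rate_n = (1.0 - z_n) * K_vo * dp_n
            drz_n = -K_vo * dp_n
            drdp_n = (1.0 - z_n) * K_vo
        else:
            rate_n = z_n * K_vc * dp_n
            drz_n = K_vc * dp_n
            drdp_n = z_n * K_vc
        if dp_p > 0.0:
            rate_p = (1.0 - z_p) * K_vo * dp_p
            drz_p = -K_vo * dp_p
            drdp_p = (1.0 - z_p) * K_vo
        else:
            rate_p = z_p * K_vc * dp_p
            drz_p = K_vc * dp_p
            drdp_p = z_p * K_vc
        r[i_st] = (z_n - z_p) / dt - th * rate_n - om * rate_p
        if want_jac:
            J[i_st, iz] = 1.0 / dt - th * drz_n
            J[i_st, iu] = -th * drdp_n
            J[i_st, idn] = th * drdp_n
        if want_jac_prev:
            Jp[i_st, iz] = -1.0 / dt - om * drz_p
            Jp[i_st, iu] = -om * drdp_p
            Jp[i_st, idn] = om * drdp_p

    # windkessels: wk = [C_ar_sys, R_ar_sys, Z_ar_sys, C_ven_sys, R_ven_sys,
    #                    C_ar_pul, R_ar_pul, Z_ar_pul, C_ven_pul, R_ven_pul]
    wkslots = (
        (_P_AR_SYS, _Q_AR_SYS, _Q_VOUT_L, _P_VEN_SYS, 6, 7, 0, 1, 2),
        (_P_AR_PUL, _Q_AR_PUL, _Q_VOUT_R, _P_VEN_PUL, 16, 17, 5, 6, 7),
    )
    for w in range(2):
        ip, iq_ar, iq_v, ipv, i_ms, i_mo, jC, jR, jZ = wkslots[w]
        C = wk[jC]
        R = wk[jR]
        Z = wk[jZ]
        r[i_ms] = (C * ((x_now[ip] - x_prev[ip]) - Z * (x_now[iq_v] - x_prev[iq_v])) / dt
                   - (th * x_now[iq_v] + om * x_prev[iq_v])
                   + (th * x_now[iq_ar] + om * x_prev[iq_ar]))
        g_n = (x_now[ipv] - x_now[ip] + Z * x_now[iq_v]) / R + x_now[iq_ar]
        g_p = (x_prev[ipv] - x_prev[ip] + Z * x_prev[iq_v]) / R + x_prev[iq_ar]
        r[i_mo] = th * g_n + om * g_p
        if want_jac:
            J[i_ms, ip] = C / dt
            J[i_ms, iq_v] = -C * Z / dt - th
            J[i_ms, iq_ar] = th
            J[i_mo, ipv] = th / R
            J[i_mo, ip] = -th / R
            J[i_mo, iq_v] = th * Z / R
            J[i_mo, iq_ar] = th
        if want_jac_prev:
            Jp[i_ms, ip] = -C / dt
            Jp[i_ms, iq_v] = C * Z / dt - om
            Jp[i_ms, iq_ar] = om
            Jp[i_mo, ipv] = om / R
            Jp[i_mo, ip] = -om / R
            Jp[i_mo, iq_v] = om * Z / R
            Jp[i_mo, iq_ar] = om

    wk2slots = (
        (_P_VEN_SYS, _Q_VEN_SYS, _Q_AR_SYS, _P_AT_R, 8, 9, 3, 4),
        (_P_VEN_PUL, _Q_VEN_PUL, _Q_AR_PUL, _P_AT_L, 18, 19, 8, 9),
    )
    for w in range(2):
        ip, iq_ven, iq_in, ipat, i_ms, i_mo, jC, jR = wk2slots[w]
        C = wk[jC]
        R = wk[jR]
        r[i_ms] = (C * (x_now[ip] - x_prev[ip]) / dt
                   - (th * x_now[iq_in] + om * x_prev[iq_in])
                   + (th * x_now[iq_ven] + om * x_prev[iq_ven]))
        g_n = (x_now[ipat] - x_now[ip]) / R + x_now[iq_ven]
        g_p = (x_prev[ipat] - x_prev[ip]) / R + x_prev[iq_ven]
        r[i_mo] = th * g_n + om * g_p
        if want_jac:
            J[i_ms, ip] = C / dt
            J[i_ms, iq_in] = -th
            J[i_ms, iq_ven] = th
            J[i_mo, ipat] = th / R
            J[i_mo, ip] = -th / R
            J[i_mo, iq_ven] = th
        if want_jac_prev:
            Jp[i_ms, ip] = -C / dt
            Jp[i_ms, iq_in] = -om
            Jp[i_ms, iq_ven] = om
            Jp[i_mo, ipat] = om / R
            Jp[i_mo, ip] = -om / R
            Jp[i_mo, iq_ven] = om
    return 0
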