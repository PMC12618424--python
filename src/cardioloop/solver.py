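"""Monolithic implicit solver of the fully coupled 0D closed loop.

The unknowns at each time level are the 20 circulation/valve variables
(atrial and ventricular pressures, valve flows and opening states, arterial
and venous windkessel pressures and flows, left side then right side),
extended by the four chamber volumes and the four active fiber stresses -
28 unknowns in total.  One time step solves the stacked One-Step-theta
residual (windkessel mass/momentum, valve momentum and opening-state,
chamber pressure closure, chamber mass balance, active-stress ODE) with a
damped Newton iteration using the hand-assembled analytic Jacobian.

The cardiac cycle is repeated with initial conditions taken from the last
step of the previous cycle until the periodicity error - the maximum
relative change of the four compartment pressures and the four chamber
volumes across one cycle - drops below eps_cycl.
"""
from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from . import chambers as ch
from .params import ChamberParams, CirculationParams, ValveParams

__all__ = [
    "IDX",
    "NSTATE",
    "SystemState",
    "Trajectory",
    "CycleReport",
    "NonconvergenceError",
    "CoupledModel",
    "periodicity_error",
    "apply_valve_replacement",
    "consistent_initial_state",
    "run_cycles",
    "total_blood_volume",
]

#: state-vector layout: circulation variables in their conventional order,
#: then chamber volumes, then active stresses
_NAMES = (
    "p_at_l", "q_vin_l", "z_mit", "q_vout_l", "z_aor",
    "p_v_l", "p_ar_sys", "q_ar_sys", "p_ven_sys", "q_ven_sys",
    "p_at_r", "q_vin_r", "z_tri", "q_vout_r", "z_pul",
    "p_v_r", "p_ar_pul", "q_ar_pul", "p_ven_pul", "q_ven_pul",
    "V_at_l", "V_v_l", "V_at_r", "V_v_r",
    "tau_at_l", "tau_v_l", "tau_at_r", "tau_v_r",
)
IDX: Dict[str, int] = {n: i for i, n in enumerate(_NAMES)}
NSTATE = len(_NAMES)

#: (chamber key, volume index, tau index, pressure index) in solver order
_CHAMBER_SLOTS = (
    ("la", IDX["V_at_l"], IDX["tau_at_l"], IDX["p_at_l"]),
    ("lv", IDX["V_v_l"], IDX["tau_v_l"], IDX["p_v_l"]),
    ("ra", IDX["V_at_r"], IDX["tau_at_r"], IDX["p_at_r"]),
    ("rv", IDX["V_v_r"], IDX["tau_v_r"], IDX["p_v_r"]),
)

#: (valve key, upstream pressure, downstream pressure, flow, zeta)
_VALVE_SLOTS = (
    ("mit", IDX["p_at_l"], IDX["p_v_l"], IDX["q_vin_l"], IDX["z_mit"]),
    ("aor", IDX["p_v_l"], IDX["p_ar_sys"], IDX["q_vout_l"], IDX["z_aor"]),
    ("tri", IDX["p_at_r"], IDX["p_v_r"], IDX["q_vin_r"], IDX["z_tri"]),
    ("pul", IDX["p_v_r"], IDX["p_ar_pul"], IDX["q_vout_r"], IDX["z_pul"]),
)

#: quantities entering the periodicity criterion (both atrial volumes kept;
#: the literal printed set replaces V_at_l by a second copy of V_at_r)
_PERIODICITY_FIELDS = (
    "p_ar_sys", "p_ar_pul", "p_ven_sys", "p_ven_pul",
    "V_v_l", "V_v_r", "V_at_r", "V_at_l",
)


class NonconvergenceError(RuntimeError):
    """Newton failed to converge; carries the last scaled residual norm."""

    def __init__(self, msg, residual_norm):
        super().__init__(f"{msg} (last scaled residual inf-norm {residual_norm:.3e})")
        self.residual_norm = residual_norm


@dataclass
class SystemState:
    """Full coupled state at one time point (internal mm^3/kPa/s units)."""

    x: np.ndarray
    t: float = 0.0

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        if self.x.shape != (NSTATE,):
            raise ValueError(f"state vector must have {NSTATE} entries")

    def __getitem__(self, name: str) -> float:
        return float(self.x[IDX[name]])

    def as_dict(self) -> Dict[str, float]:
        return {n: float(self.x[i]) for n, i in IDX.items()}

    def copy(self) -> "SystemState":
        return SystemState(self.x.copy(), self.t)


@dataclass
class Trajectory:
    """Uniform-grid trajectory of one cardiac cycle."""

    t: np.ndarray
    X: np.ndarray  # (n_steps + 1, NSTATE)

    def series(self, name: str) -> np.ndarray:
        return self.X[:, IDX[name]]

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])


@dataclass
class CycleReport:
    """Cycle-to-cycle convergence record of a closed-loop run."""

    E_cycl: float
    n_cycles: int
    converged: bool
    history: List[float] = field(default_factory=list)
    snapshots: List[SystemState] = field(default_factory=list)


def periodicity_error(start: SystemState, end: SystemState, literal_printed_set: bool = False) -> float:
    """Maximum relative change of the monitored pressures/volumes over a cycle."""
    fields = list(_PERIODICITY_FIELDS)
    if literal_printed_set:
        fields[fields.index("V_at_l")] = "V_at_r"
    errs = []
    for name in fields:
        a, b = start[name], end[name]
        if a == 0.0:
            raise ZeroDivisionError(f"periodicity reference {name} is zero at cycle start")
        errs.append(abs((b - a) / a))
    return max(errs)


def apply_valve_replacement(circulation: CirculationParams, valve_id: str) -> CirculationParams:
    """Return a copy with the named valve's A_eff_min set to 0 (non-leaky).

    All other parameters are left unaltered; the solver's internal area
    floor keeps 1/A terms finite.  Applying twice is idempotent.
    """
    if valve_id not in circulation.valves:
        raise ValueError(f"unknown valve {valve_id!r}")
    new = copy.deepcopy(circulation)
    new.valves[valve_id] = dataclasses.replace(new.valves[valve_id], A_eff_min=0.0)
    return new


def total_blood_volume(state: SystemState, circulation: CirculationParams) -> float:
    """Conserved total volume: chamber volumes plus compartment stored volumes.

    The 3-element windkessel stores C*(p_ar - Z*q_valve) (its state variable),
    the venous compartment C*p_ven.  The coupled residual conserves this sum
    exactly at every step.
    """
    wk = circulation.windkessel
    s = state
    stored = (
        wk.C_ar_sys * (s["p_ar_sys"] - wk.Z_ar_sys * s["q_vout_l"])
        + wk.C_ven_sys * s["p_ven_sys"]
        + wk.C_ar_pul * (s["p_ar_pul"] - wk.Z_ar_pul * s["q_vout_r"])
        + wk.C_ven_pul * s["p_ven_pul"]
    )
    return stored + s["V_at_l"] + s["V_v_l"] + s["V_at_r"] + s["V_v_r"]


def _row_scales() -> np.ndarray:
    """Characteristic magnitudes used to scale residual rows for the Newton test."""
    # rows are ordered: per side [closure, valve mom, valve state, valve mom,
    # valve state, closure, wk3 mass, wk3 mom, wk2 mass, wk2 mom], chambers, tau
    scales = {
        "closure": 1.0,        # kPa
        "valve_mom": 1.0,      # kPa
        "valve_state": 1.0e2,  # 1/s
        "wk_mass": 1.0e5,      # mm^3/s
        "wk_mom": 1.0e5,       # mm^3/s
        "chamber_mass": 1.0e5, # mm^3/s
        "tau": 1.0e3,          # kPa/s
    }
    kinds = (
        ["closure", "valve_mom", "valve_state", "valve_mom", "valve_state",
         "closure", "wk_mass", "wk_mom", "wk_mass", "wk_mom"] * 2
        + ["chamber_mass"] * 4
        + ["tau"] * 4
    )
    return np.array([scales[k] for k in kinds])


class CoupledModel:
    """Residual assembly and implicit time stepping of the coupled system."""

    def __init__(
        self,
        circulation: CirculationParams,
        chambers: ChamberParams,
        dt: float = 1e-3,
        theta: float = 0.5,
        newton_tol: float = 1e-8,
        newton_maxit: int = 25,
        max_halvings: int = 4,
        use_compiled: Optional[bool] = None,
    ):
        if not 0.0 < theta <= 1.0:
            raise ValueError("theta must lie in (0, 1]")
        if not dt > 0.0:
            raise ValueError("dt must be positive")
        self.circulation = circulation
        self.chambers = chambers
        self.dt = dt
        self.theta = theta
        self.newton_tol = newton_tol
        self.newton_maxit = newton_maxit
        self.max_halvings = max_halvings
        self.scales = _row_scales()
        self.T_cycl = chambers.active["lv"].T_cycl
        from . import _kernels

        self._use_compiled = _kernels.HAVE_NUMBA if use_compiled is None else use_compiled
        wk = circulation.windkessel
        self._wk_pack = np.array([
            wk.C_ar_sys, wk.R_ar_sys, wk.Z_ar_sys, wk.C_ven_sys, wk.R_ven_sys,
            wk.C_ar_pul, wk.R_ar_pul, wk.Z_ar_pul, wk.C_ven_pul, wk.R_ven_pul,
        ])
        vpack = []
        for key in ("mit", "aor", "tri", "pul"):
            vp = circulation.valves[key]
            vpack += [vp.A_eff_min, vp.A_eff_max, vp.K_vo, vp.K_vc, vp.l_eff, vp.rho, vp.area_floor]
        self._valve_pack = np.array(vpack)
        cpack = []
        for key, *_rest in _CHAMBER_SLOTS:
            sp = chambers.surrogate[key]
            cpack += [sp.V_ref, sp.E_pass_a, sp.E_pass_b, sp.wall_factor, chambers.active[key].sigma_0]
        self._cham_pack = np.array(cpack)
        self._rbuf = np.zeros(NSTATE)
        self._Jbuf = np.zeros((NSTATE, NSTATE))
        self._Jpbuf = np.zeros((NSTATE, NSTATE))

    # -- residual & Jacobians -------------------------------------------------

    def activation_table(self, t_grid):
        """Transmembrane potentials u (4, len(t_grid)) in chamber slot order."""
        return np.array(
            [ch.transmembrane_potential(t_grid, self.chambers.active[key]) for key, *_ in _CHAMBER_SLOTS]
        )

    def assemble(self, x_now, x_prev, t_now, t_prev, jac=True, jac_prev=False,
                 u_now=None, u_prev=None):
        """Residual (28,) and optionally the Jacobians w.r.t. x_now and x_prev.

        u_now/u_prev optionally supply precomputed transmembrane potentials
        (4,) in chamber slot order to avoid re-evaluating the activation.
        """
        if self._use_compiled:
            from ._kernels import assemble_kernel

            if u_now is None:
                u_now = self.activation_table(np.array([t_now]))[:, 0]
            if u_prev is None:
                u_prev = self.activation_table(np.array([t_prev]))[:, 0]
            status = assemble_kernel(
                np.asarray(x_now, dtype=float), np.asarray(x_prev, dtype=float),
                np.asarray(u_now, dtype=float), np.asarray(u_prev, dtype=float),
                self._wk_pack, self._valve_pack, self._cham_pack,
                self.dt, self.theta, jac, jac_prev,
                self._rbuf, self._Jbuf, self._Jpbuf,
            )
            if status == 1:
                raise FloatingPointError("non-finite state in residual assembly")
            if status == 2:
                raise ValueError("chamber volume must be strictly positive")
            out = [self._rbuf.copy()]
            if jac:
                out.append(self._Jbuf.copy())
            if jac_prev:
                out.append(self._Jpbuf.copy())
            return out[0] if len(out) == 1 else tuple(out)
        if not (np.all(np.isfinite(x_now)) and np.all(np.isfinite(x_prev))):
            raise FloatingPointError("non-finite state in residual assembly")
        dt, th = self.dt, self.theta
        om = 1.0 - th
        r = np.zeros(NSTATE)
        J = np.zeros((NSTATE, NSTATE)) if jac else None
        Jp = np.zeros((NSTATE, NSTATE)) if jac_prev else None

        # row index bookkeeping: same layout as _row_scales
        rows = {
            "closure_la": 0, "mom_mit": 1, "state_mit": 2, "mom_aor": 3, "state_aor": 4,
            "closure_lv": 5, "wk3_mass_sys": 6, "wk3_mom_sys": 7, "wk2_mass_sys": 8, "wk2_mom_sys": 9,
            "closure_ra": 10, "mom_tri": 11, "state_tri": 12, "mom_pul": 13, "state_pul": 14,
            "closure_rv": 15, "wk3_mass_pul": 16, "wk3_mom_pul": 17, "wk2_mass_pul": 18, "wk2_mom_pul": 19,
            "mass_la": 20, "mass_lv": 21, "mass_ra": 22, "mass_rv": 23,
            "tau_la": 24, "tau_lv": 25, "tau_ra": 26, "tau_rv": 27,
        }

        # chamber pressure closures: th*(p - P(V,tau))_now + om*(...)_prev
        closure_rows = {"la": rows["closure_la"], "lv": rows["closure_lv"],
                        "ra": rows["closure_ra"], "rv": rows["closure_rv"]}
        for key, iV, itau, ip in _CHAMBER_SLOTS:
            sp = self.chambers.surrogate[key]
            i = closure_rows[key]
            Pn, dPVn, dPtn = ch.chamber_pressure_derivs(x_now[iV], x_now[itau], sp)
            Pp, dPVp, dPtp = ch.chamber_pressure_derivs(x_prev[iV], x_prev[itau], sp)
            r[i] = th * (x_now[ip] - Pn) + om * (x_prev[ip] - Pp)
            if jac:
                J[i, ip] = th
                J[i, iV] = -th * dPVn
                J[i, itau] = -th * dPtn
            if jac_prev:
                Jp[i, ip] = om
                Jp[i, iV] = -om * dPVp
                Jp[i, itau] = -om * dPtp

        # valves: momentum + opening-state rows
        mom_rows = {"mit": rows["mom_mit"], "aor": rows["mom_aor"],
                    "tri": rows["mom_tri"], "pul": rows["mom_pul"]}
        state_rows = {"mit": rows["state_mit"], "aor": rows["state_aor"],
                      "tri": rows["state_tri"], "pul": rows["state_pul"]}
        for key, iu, idn, iq, iz in _VALVE_SLOTS:
            vp: ValveParams = self.circulation.valves[key]
            dp_n = x_now[iu] - x_now[idn]
            dp_p = x_prev[iu] - x_prev[idn]
            self._valve_momentum(r, J, Jp, mom_rows[key], vp, x_now, x_prev,
                                 iu, idn, iq, iz, dp_n, dp_p, dt, th, om)
            self._valve_state(r, J, Jp, state_rows[key], vp, x_now, x_prev,
                              iu, idn, iz, dp_n, dp_p, dt, th, om)

        # windkessels
        wk = self.circulation.windkessel
        self._wk3(r, J, Jp, rows["wk3_mass_sys"], rows["wk3_mom_sys"], x_now, x_prev,
                  IDX["p_ar_sys"], IDX["q_ar_sys"], IDX["q_vout_l"], IDX["p_ven_sys"],
                  *wk.arterial("sys"), dt, th, om)
        self._wk3(r, J, Jp, rows["wk3_mass_pul"], rows["wk3_mom_pul"], x_now, x_prev,
                  IDX["p_ar_pul"], IDX["q_ar_pul"], IDX["q_vout_r"], IDX["p_ven_pul"],
                  *wk.arterial("pul"), dt, th, om)
        self._wk2(r, J, Jp, rows["wk2_mass_sys"], rows["wk2_mom_sys"], x_now, x_prev,
                  IDX["p_ven_sys"], IDX["q_ven_sys"], IDX["q_ar_sys"], IDX["p_at_r"],
                  *wk.venous("sys"), dt, th, om)
        self._wk2(r, J, Jp, rows["wk2_mass_pul"], rows["wk2_mom_pul"], x_now, x_prev,
                  IDX["p_ven_pul"], IDX["q_ven_pul"], IDX["q_ar_pul"], IDX["p_at_l"],
                  *wk.venous("pul"), dt, th, om)

        # chamber mass balances: dV/dt - q_in + q_out (theta on flows)
        mass = (
            (rows["mass_la"], IDX["V_at_l"], IDX["q_ven_pul"], IDX["q_vin_l"]),
            (rows["mass_lv"], IDX["V_v_l"], IDX["q_vin_l"], IDX["q_vout_l"]),
            (rows["mass_ra"], IDX["V_at_r"], IDX["q_ven_sys"], IDX["q_vin_r"]),
            (rows["mass_rv"], IDX["V_v_r"], IDX["q_vin_r"], IDX["q_vout_r"]),
        )
        for i, iV, iin, iout in mass:
            r[i] = (
                (x_now[iV] - x_prev[iV]) / dt
                - (th * x_now[iin] + om * x_prev[iin])
                + (th * x_now[iout] + om * x_prev[iout])
            )
            if jac:
                J[i, iV] = 1.0 / dt
                J[i, iin] = -th
                J[i, iout] = th
            if jac_prev:
                Jp[i, iV] = -1.0 / dt
                Jp[i, iin] = -om
                Jp[i, iout] = om

        # active-stress ODEs (driven by time only)
        tau_rows = {"la": rows["tau_la"], "lv": rows["tau_lv"],
                    "ra": rows["tau_ra"], "rv": rows["tau_rv"]}
        for slot, (key, iV, itau, ip) in enumerate(_CHAMBER_SLOTS):
            ap = self.chambers.active[key]
            i = tau_rows[key]
            u_n = u_now[slot] if u_now is not None else ch.transmembrane_potential(t_now, ap)
            u_p = u_prev[slot] if u_prev is not None else ch.transmembrane_potential(t_prev, ap)
            r[i] = (
                (x_now[itau] - x_prev[itau]) / dt
                + th * (abs(u_n) * x_now[itau] - ap.sigma_0 * max(0.0, u_n))
                + om * (abs(u_p) * x_prev[itau] - ap.sigma_0 * max(0.0, u_p))
            )
            if jac:
                J[i, itau] = 1.0 / dt + th * abs(u_n)
            if jac_prev:
                Jp[i, itau] = -1.0 / dt + om * abs(u_p)

        out = [r]
        if jac:
            out.append(J)
        if jac_prev:
            out.append(Jp)
        return out[0] if len(out) == 1 else tuple(out)

    @staticmethod
    def _valve_momentum(r, J, Jp, i, vp, x_now, x_prev, iu, idn, iq, iz, dp_n, dp_p, dt, th, om):
        span = vp.A_eff_max - vp.A_eff_min
        A_n = max(span * x_now[iz] + vp.A_eff_min, vp.area_floor)
        A_p = max(span * x_prev[iz] + vp.A_eff_min, vp.area_floor)
        dA_n = span if span * x_now[iz] + vp.A_eff_min > vp.area_floor else 0.0
        dA_p = span if span * x_prev[iz] + vp.A_eff_min > vp.area_floor else 0.0
        q_n, q_p = x_now[iq], x_prev[iq]
        rl = vp.rho * vp.l_eff
        inert = rl * (th / A_n + om / A_p)
        dqdt = (q_n - q_p) / dt
        g_n = vp.rho / (2.0 * A_n**2) * q_n * abs(q_n) - dp_n
        g_p = vp.rho / (2.0 * A_p**2) * q_p * abs(q_p) - dp_p
        r[i] = inert * dqdt + th * g_n + om * g_p
        if J is not None:
            J[i, iq] = inert / dt + th * vp.rho / A_n**2 * abs(q_n)
            J[i, iz] = th * (-rl * dA_n / A_n**2) * dqdt + th * (-vp.rho * q_n * abs(q_n) * dA_n / A_n**3)
            J[i, iu] = -th
            J[i, idn] = th
        if Jp is not None:
            Jp[i, iq] = -inert / dt + om * vp.rho / A_p**2 * abs(q_p)
            Jp[i, iz] = om * (-rl * dA_p / A_p**2) * dqdt + om * (-vp.rho * q_p * abs(q_p) * dA_p / A_p**3)
            Jp[i, iu] = -om
            Jp[i, idn] = om

    @staticmethod
    def _valve_state(r, J, Jp, i, vp, x_now, x_prev, iu, idn, iz, dp_n, dp_p, dt, th, om):
        z_n, z_p = x_now[iz], x_prev[iz]
        if dp_n > 0.0:
            rate_n = (1.0 - z_n) * vp.K_vo * dp_n
            drz_n, drdp_n = -vp.K_vo * dp_n, (1.0 - z_n) * vp.K_vo
        else:
            rate_n = z_n * vp.K_vc * dp_n
            drz_n, drdp_n = vp.K_vc * dp_n, z_n * vp.K_vc
        if dp_p > 0.0:
            rate_p = (1.0 - z_p) * vp.K_vo * dp_p
            drz_p, drdp_p = -vp.K_vo * dp_p, (1.0 - z_p) * vp.K_vo
        else:
            rate_p = z_p * vp.K_vc * dp_p
            drz_p, drdp_p = vp.K_vc * dp_p, z_p * vp.K_vc
        r[i] = (z_n - z_p) / dt - th * rate_n - om * rate_p
        if J is not None:
            J[i, iz] = 1.0 / dt - th * drz_n
            J[i, iu] = -th * drdp_n
            J[i, idn] = th * drdp_n
        if Jp is not None:
            Jp[i, iz] = -1.0 / dt - om * drz_p
            Jp[i, iu] = -om * drdp_p
            Jp[i, idn] = om * drdp_p

    @staticmethod
    def _wk3(r, J, Jp, i_mass, i_mom, x_now, x_prev, ip, iq_ar, iq_v, ipv, C, R, Z, dt, th, om):
        r[i_mass] = (
            C * ((x_now[ip] - x_prev[ip]) - Z * (x_now[iq_v] - x_prev[iq_v])) / dt
            - (th * x_now[iq_v] + om * x_prev[iq_v])
            + (th * x_now[iq_ar] + om * x_prev[iq_ar])
        )
        g_n = (x_now[ipv] - x_now[ip] + Z * x_now[iq_v]) / R + x_now[iq_ar]
        g_p = (x_prev[ipv] - x_prev[ip] + Z * x_prev[iq_v]) / R + x_prev[iq_ar]
        r[i_mom] = th * g_n + om * g_p
        if J is not None:
            J[i_mass, ip] = C / dt
            J[i_mass, iq_v] = -C * Z / dt - th
            J[i_mass, iq_ar] = th
            J[i_mom, ipv] = th / R
            J[i_mom, ip] = -th / R
            J[i_mom, iq_v] = th * Z / R
            J[i_mom, iq_ar] = th
        if Jp is not None:
            Jp[i_mass, ip] = -C / dt
            Jp[i_mass, iq_v] = C * Z / dt - om
            Jp[i_mass, iq_ar] = om
            Jp[i_mom, ipv] = om / R
            Jp[i_mom, ip] = -om / R
            Jp[i_mom, iq_v] = om * Z / R
            Jp[i_mom, iq_ar] = om

    @staticmethod
    def _wk2(r, J, Jp, i_mass, i_mom, x_now, x_prev, ip, iq_ven, iq_in, ipat, C, R, dt, th, om):
        r[i_mass] = (
            C * (x_now[ip] - x_prev[ip]) / dt
            - (th * x_now[iq_in] + om * x_prev[iq_in])
            + (th * x_now[iq_ven] + om * x_prev[iq_ven])
        )
        g_n = (x_now[ipat] - x_now[ip]) / R + x_now[iq_ven]
        g_p = (x_prev[ipat] - x_prev[ip]) / R + x_prev[iq_ven]
        r[i_mom] = th * g_n + om * g_p
        if J is not None:
            J[i_mass, ip] = C / dt
            J[i_mass, iq_in] = -th
            J[i_mass, iq_ven] = th
            J[i_mom, ipat] = th / R
            J[i_mom, ip] = -th / R
            J[i_mom, iq_ven] = th
        if Jp is not None:
            Jp[i_mass, ip] = -C / dt
            Jp[i_mass, iq_in] = -om
            Jp[i_mass, iq_ven] = om
            Jp[i_mom, ipat] = om / R
            Jp[i_mom, ip] = -om / R
            Jp[i_mom, iq_ven] = om

    # -- time stepping ---------------------------------------------------------

    def scaled_norm(self, r):
        return float(np.max(np.abs(r) / self.scales))

    def newton_step(self, x_prev, t_prev, u_now=None, u_prev=None, x_guess=None):
        """Advance one time step with damped Newton; returns x at t_prev + dt."""
        t_now = t_prev + self.dt
        x = x_prev.copy() if x_guess is None else np.asarray(x_guess, dtype=float).copy()
        try:
            r, J = self.assemble(x, x_prev, t_now, t_prev, u_now=u_now, u_prev=u_prev)
            norm = self.scaled_norm(r)
        except (FloatingPointError, ValueError):
            x = x_prev.copy()  # extrapolated guess left the admissible set
            r, J = self.assemble(x, x_prev, t_now, t_prev, u_now=u_now, u_prev=u_prev)
            norm = self.scaled_norm(r)
        for _ in range(self.newton_maxit):
            if norm < self.newton_tol:
                return x
            dx = np.linalg.solve(J, -r)
            lam = 1.0
            for _h in range(self.max_halvings + 1):
                x_trial = x + lam * dx
                try:
                    r_t, J_t = self.assemble(x_trial, x_prev, t_now, t_prev,
                                             u_now=u_now, u_prev=u_prev)
                    norm_t = self.scaled_norm(r_t)
                except (FloatingPointError, ValueError):
                    r_t = J_t = None
                    norm_t = np.inf
                if norm_t < norm or norm_t < self.newton_tol:
                    break
                lam *= 0.5
            if r_t is None:
                raise NonconvergenceError("Newton step left the admissible set", norm)
            x, r, J, norm = x_trial, r_t, J_t, norm_t
        if norm < self.newton_tol:
            return x
        raise NonconvergenceError("Newton iteration did not converge", norm)

    def run_cycle(self, state: SystemState) -> Trajectory:
        """Integrate one cardiac cycle starting from `state` at its time t."""
        n = int(round(self.T_cycl / self.dt))
        t = state.t + self.dt * np.arange(n + 1)
        U = self.activation_table(t)
        X = np.empty((n + 1, NSTATE))
        X[0] = state.x
        for k in range(n):
            guess = 2.0 * X[k] - X[k - 1] if k >= 1 else None
            X[k + 1] = self.newton_step(X[k], t[k], u_now=U[:, k + 1], u_prev=U[:, k],
                                        x_guess=guess)
        return Trajectory(t=t, X=X)


def run_cycles(
    initial: SystemState,
    circulation: CirculationParams,
    chambers: ChamberParams,
    dt: float = 1e-3,
    theta: float = 0.5,
    eps_cycl: float = 0.04,
    max_cycles: int = 50,
    literal_printed_set: bool = False,
):
    """Repeat the cardiac cycle until the periodicity criterion is met.

    Returns (final-cycle Trajectory, CycleReport).  If max_cycles is reached
    the report carries converged=False but the trajectory is still returned.
    """
    if not eps_cycl > 0.0:
        raise ValueError("eps_cycl must be positive")
    model = CoupledModel(circulation, chambers, dt=dt, theta=theta)
    state = initial.copy()
    report = CycleReport(E_cycl=np.inf, n_cycles=0, converged=False)
    traj = None
    for _ in range(max_cycles):
        report.snapshots.append(state.copy())
        traj = model.run_cycle(state)
        end = SystemState(traj.X[-1], traj.t[-1])
        err = periodicity_error(state, end, literal_printed_set)
        report.history.append(err)
        report.n_cycles += 1
        report.E_cycl = err
        # restart the next cycle at t0 with the end state as initial condition
        state = SystemState(end.x, initial.t)
        if err <= eps_cycl:
            report.converged = True
            break
    return traj, report


def consistent_initial_state(
    circulation: CirculationParams,
    chambers: ChamberParams,
    volumes: Dict[str, float],
    pressures: Optional[Dict[str, float]] = None,
    t0: float = 0.0,
) -> SystemState:
    """Build an algebraically consistent initial state at diastasis.

    Chamber volumes are prescribed (mm^3); chamber pressures follow from the
    surrogate law at tau = 0; valve flows and opening states start closed;
    windkessel pressures come from the initial guesses and the algebraic
    momentum balances determine the compartment flows.  Consistency keeps
    the theta-weighted algebraic rows from ringing.
    """
    guesses = {"p_ar_sys": 10.0, "p_ar_pul": 2.5, "p_ven_sys": 0.8, "p_ven_pul": 1.0}
    if pressures:
        guesses.update(pressures)
    x = np.zeros(NSTATE)
    vol_keys = {"la": "V_at_l", "lv": "V_v_l", "ra": "V_at_r", "rv": "V_v_r"}
    for key, iV, itau, ip in _CHAMBER_SLOTS:
        V = volumes[key]
        x[IDX[vol_keys[key]]] = V
        x[itau] = 0.0
        x[ip] = ch.chamber_pressure(V, 0.0, chambers.surrogate[key])
    for name, val in guesses.items():
        x[IDX[name]] = val
    wk = circulation.windkessel
    # algebraic momentum balances with zero valve flows
    x[IDX["q_ar_sys"]] = (x[IDX["p_ar_sys"]] - x[IDX["p_ven_sys"]]) / wk.R_ar_sys
    x[IDX["q_ar_pul"]] = (x[IDX["p_ar_pul"]] - x[IDX["p_ven_pul"]]) / wk.R_ar_pul
    x[IDX["q_ven_sys"]] = (x[IDX["p_ven_sys"]] - x[IDX["p_at_r"]]) / wk.R_ven_sys
    x[IDX["q_ven_pul"]] = (x[IDX["p_ven_pul"]] - x[IDX["p_at_l"]]) / wk.R_ven_pul
    return SystemState(x, t0)
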