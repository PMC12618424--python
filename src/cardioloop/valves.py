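"""Dynamic Bernoulli valve: pressure-flow law, orifice state, and the
standalone forward problem under a prescribed transvalvular pressure drop.

The pressure-flow relationship across a valve is

    dp = rho / (2 A_eff^2) q |q| + (rho l_eff / A_eff) dq/dt

with the effective orifice area interpolating linearly in the opening state
zeta in [0, 1]:

    A_eff = (A_eff_max - A_eff_min) zeta + A_eff_min

and zeta governed by pressure-driven opening/closing rates

    dzeta/dt = (1 - zeta) K_vo dp   if dp > 0
             =      zeta  K_vc dp   if dp <= 0.

The q|q| form preserves the flow sign, so an incompletely sealing valve
(A_eff_min > 0) produces sustained backward flow under a negative diastolic
gradient - the mechanism behind pulmonary regurgitation.  Inside 1/A terms
the area is floored at max(A_eff_min, 1e-4 mm^2) so that a fully sealing
valve keeps a finite Newton Jacobian.
"""
from __future__ import annotations

import numpy as np

from .params import ValveParams

__all__ = [
    "effective_area",
    "valve_momentum_residual",
    "valve_state_rate",
    "simulate_valve_prescribed_dp",
]


def effective_area(zeta, params: ValveParams):
    """Effective orifice area A_eff(zeta) in mm^2 (linear in zeta)."""
    z = np.asarray(zeta, dtype=float)
    if np.any(z < 0.0) or np.any(z > 1.0):
        raise ValueError("valve state zeta must lie in [0, 1]")
    a = (params.A_eff_max - params.A_eff_min) * z + params.A_eff_min
    return float(a) if np.isscalar(zeta) else a


def floored_area(zeta, params: ValveParams):
    """A_eff floored for use inside 1/A terms."""
    return np.maximum(effective_area(zeta, params), params.area_floor)


def valve_momentum_residual(
    dp_now,
    dp_prev,
    q_now,
    q_prev,
    zeta_now,
    zeta_prev,
    params: ValveParams,
    dt,
    theta=0.5,
):
    """One-Step-theta residual of the Bernoulli pressure-flow law [kPa].

    Zero iff the discrete momentum equation holds.  The inertance
    rho*l_eff/A_eff is theta-averaged between the two time levels.
    """
    if not dt > 0.0:
        raise ValueError(f"dt must be positive, got {dt!r}")
    th, om = theta, 1.0 - theta
    A_now = floored_area(zeta_now, params)
    A_prev = floored_area(zeta_prev, params)
    inert = params.rho * params.l_eff * (th / A_now + om / A_prev)
    g_now = params.rho / (2.0 * A_now**2) * q_now * abs(q_now) - dp_now
    g_prev = params.rho / (2.0 * A_prev**2) * q_prev * abs(q_prev) - dp_prev
    return inert * (q_now - q_prev) / dt + th * g_now + om * g_prev


def valve_state_rate(zeta, dp, params: ValveParams):
    """dzeta/dt [1/s] for opening state zeta under pressure gradient dp."""
    z = np.asarray(zeta, dtype=float)
    if np.any(z < 0.0) or np.any(z > 1.0):
        raise ValueError("valve state zeta must lie in [0, 1]")
    rate = np.where(np.asarray(dp) > 0.0, (1.0 - z) * params.K_vo * dp, z * params.K_vc * dp)
    return float(rate) if np.isscalar(zeta) and np.isscalar(dp) else rate


def _state_rate_coeffs(zeta, dp, params: ValveParams):
    """Linear form dzeta/dt = a*zeta + b of the branch selected by dp."""
    if dp > 0.0:
        return -params.K_vo * dp, params.K_vo * dp
    return params.K_vc * dp, 0.0


def _newton_flow(q_prev, dp_now, dp_prev, A_now, A_prev, params, dt, theta):
    """Solve the scalar implicit momentum update for q_now.

    The discrete residual is strictly increasing in q_now (positive
    inertance/dt plus the q|q| subgradient), so the root is unique.  When
    the orifice is nearly sealed the Bernoulli term becomes stiff (its
    relaxation time 2 l_eff A / |q| drops far below the step); the update
    then falls back to the L-stable implicit-Euler branch, which lands on
    the quasi-steady orifice flow instead of ringing.
    """
    q_scale = max(abs(q_prev), A_now * np.sqrt(2.0 * (abs(dp_now) + 1e-9) / params.rho))
    if q_scale > 0.0 and 2.0 * params.l_eff * A_now / q_scale < 0.5 * dt:
        theta = 1.0
    th, om = theta, 1.0 - theta
    inert = params.rho * params.l_eff * (th / A_now + om / A_prev)
    g_prev = params.rho / (2.0 * A_prev**2) * q_prev * abs(q_prev) - dp_prev
    q = q_prev
    for _ in range(60):
        r = inert * (q - q_prev) / dt + th * (params.rho / (2.0 * A_now**2) * q * abs(q) - dp_now) + om * g_prev
        dr = inert / dt + th * params.rho / A_now**2 * abs(q)
        step = r / dr
        q -= step
        if abs(step) <= 1e-12 * (1.0 + abs(q)):
            return q
    return q


def simulate_valve_prescribed_dp(
    dp_series,
    t_span,
    params: ValveParams,
    dt=1e-3,
    q0=0.0,
    zeta0=0.0,
    theta=0.5,
):
    """Time-march the coupled (q, zeta) valve ODEs with dp prescribed.

    dp_series is a callable dp(t) in kPa (e.g. a spline of measured
    ventricular minus arterial pressure).  Initial conditions default to the
    closed-valve state q = 0, zeta = 0 at t0.  Returns (t, q, zeta).
    This is the forward problem of the valve inverse subproblem.
    """
    t0, t1 = t_span
    if not t1 > t0:
        raise ValueError("empty time span")
    n = int(round((t1 - t0) / dt))
    t = t0 + dt * np.arange(n + 1)
    try:
        dp = np.asarray(dp_series(t), dtype=float)
    except Exception as exc:  # pragma: no cover - message carries context
        raise ValueError(f"dp series not evaluable over [{t0}, {t1}]: {exc}") from exc
    if not np.all(np.isfinite(dp)):
        raise ValueError("dp series contains gaps (non-finite values) over the cycle")
    th, om = theta, 1.0 - theta
    q = np.empty(n + 1)
    zeta = np.empty(n + 1)
    q[0], zeta[0] = q0, zeta0
    for k in range(n):
        a1, b1 = _state_rate_coeffs(zeta[k], dp[k + 1], params)
        a0, b0 = _state_rate_coeffs(zeta[k], dp[k], params)
        rate_prev = a0 * zeta[k] + b0
        z_new = (zeta[k] + dt * (th * b1 + om * rate_prev)) / (1.0 - dt * th * a1)
        zeta[k + 1] = min(1.0, max(0.0, z_new))
        A_now = floored_area(zeta[k + 1], params)
        A_prev = floored_area(zeta[k], params)
        q[k + 1] = _newton_flow(q[k], dp[k + 1], dp[k], A_now, A_prev, params, dt, theta)
    return t, q, zeta
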