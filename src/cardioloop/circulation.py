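"""Windkessel compartments: residuals and the eliminated-flow pressure ODE.

The arterial beds are 3-element windkessels (compliance C, peripheral
resistance R, characteristic impedance Z), the venous beds 2-element
windkessels (C, R).  Each compartment contributes a reduced mass balance
(the ODE carrying C dp/dt) and a reduced momentum balance (the algebraic
relation through R).  Time discretization is One-Step-theta: time
derivatives become difference quotients, every other term is weighted
theta/(1-theta) between the new and old time level.

For the arterial inverse subproblem, the outlet flow variable q_ar can be
eliminated, leaving a single scalar pressure ODE

    C R dp_ar/dt + p_ar - p_ven - (R + Z) q - Z C R dq/dt = 0

driven by the measured venous pressure and semilunar-valve flow.  The
One-Step-theta discretization of that ODE is algebraically identical to the
discretized mass/momentum pair, so both routes produce the same trajectory
to round-off.
"""
from __future__ import annotations

import numpy as np

__all__ = [
    "wk3_residual",
    "wk2_residual",
    "wk3_pressure_ode_step",
    "wk3_pressure_trajectory",
]


def _check_step(dt, *values):
    if not dt > 0.0:
        raise ValueError(f"dt must be positive, got {dt!r}")
    if not np.all(np.isfinite(values)):
        raise FloatingPointError("non-finite state passed to windkessel residual")


def wk3_residual(
    p_ar_now,
    q_ar_now,
    p_ar_prev,
    q_ar_prev,
    q_valve_now,
    q_valve_prev,
    p_ven_now,
    p_ven_prev,
    C,
    R,
    Z,
    dt,
    theta=0.5,
):
    """One-Step-theta residual pair (mass, momentum) of a 3-element windkessel.

    q_valve is the semilunar-valve inflow into the compartment, q_ar the
    outflow toward the venous bed whose pressure is p_ven.  Both residuals
    vanish iff the discrete compartment equations hold.
    """
    _check_step(dt, p_ar_now, q_ar_now, p_ar_prev, q_ar_prev, q_valve_now, q_valve_prev, p_ven_now, p_ven_prev)
    th, om = theta, 1.0 - theta
    r_mass = (
        C * ((p_ar_now - p_ar_prev) - Z * (q_valve_now - q_valve_prev)) / dt
        - (th * q_valve_now + om * q_valve_prev)
        + (th * q_ar_now + om * q_ar_prev)
    )
    g_now = (p_ven_now - p_ar_now + Z * q_valve_now) / R + q_ar_now
    g_prev = (p_ven_prev - p_ar_prev + Z * q_valve_prev) / R + q_ar_prev
    return r_mass, th * g_now + om * g_prev


def wk2_residual(
    p_ven_now,
    q_ven_now,
    p_ven_prev,
    q_ven_prev,
    q_in_now,
    q_in_prev,
    p_at_now,
    p_at_prev,
    C,
    R,
    dt,
    theta=0.5,
):
    """One-Step-theta residual pair (mass, momentum) of a 2-element windkessel.

    q_in is the arterial inflow, q_ven the outflow into the atrium at
    pressure p_at.
    """
    _check_step(dt, p_ven_now, q_ven_now, p_ven_prev, q_ven_prev, q_in_now, q_in_prev, p_at_now, p_at_prev)
    th, om = theta, 1.0 - theta
    r_mass = (
        C * (p_ven_now - p_ven_prev) / dt
        - (th * q_in_now + om * q_in_prev)
        + (th * q_ven_now + om * q_ven_prev)
    )
    g_now = (p_at_now - p_ven_now) / R + q_ven_now
    g_prev = (p_at_prev - p_ven_prev) / R + q_ven_prev
    return r_mass, th * g_now + om * g_prev


def wk3_pressure_ode_step(p_ar_prev, q_out, p_ven, C, R, Z, t_prev, dt, theta=0.5):
    """Advance the eliminated-flow arterial pressure ODE by one step.

    q_out and p_ven are callables evaluable on [t_prev, t_prev + dt] (e.g.
    cubic-spline interpolants of the measurements).  Returns p_ar at
    t_prev + dt.  The dq/dt term uses the same difference quotient as the
    coupled residual, which makes this step algebraically equivalent to the
    discretized mass/momentum pair.
    """
    if not dt > 0.0:
        raise ValueError(f"dt must be positive, got {dt!r}")
    th, om = theta, 1.0 - theta
    t_now = t_prev + dt
    q0, q1 = q_out(t_prev), q_out(t_now)
    pv0, pv1 = p_ven(t_prev), p_ven(t_now)
    crdt = C * R / dt
    rhs = (
        crdt * p_ar_prev
        + Z * C * R * (q1 - q0) / dt
        + th * (pv1 + (R + Z) * q1)
        + om * (pv0 + (R + Z) * q0 - p_ar_prev)
    )
    return rhs / (crdt + th)


def wk3_pressure_trajectory(t_grid, p_ar0, q_out, p_ven, C, R, Z, theta=0.5):
    """Integrate the eliminated-flow ODE over a uniform time grid.

    Vectorized linear recurrence: all forcing samples are evaluated once,
    then the scalar update is rolled forward.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    dt = t_grid[1] - t_grid[0]
    if not np.allclose(np.diff(t_grid), dt):
        raise ValueError("wk3_pressure_trajectory requires a uniform grid")
    th, om = theta, 1.0 - theta
    q = np.asarray(q_out(t_grid), dtype=float)
    pv = np.asarray(p_ven(t_grid), dtype=float)
    crdt = C * R / dt
    denom = crdt + th
    # forcing at each step n -> n+1 (independent of p)
    force = (
        Z * C * R * np.diff(q) / dt
        + th * (pv[1:] + (R + Z) * q[1:])
        + om * (pv[:-1] + (R + Z) * q[:-1])
    )
    a = (crdt - om) / denom
    b = force / denom
    p = np.empty_like(t_grid)
    p[0] = p_ar0
    for n in range(len(b)):
        p[n + 1] = a * p[n] + b[n]
    return p
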