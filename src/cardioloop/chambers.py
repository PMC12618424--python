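"""Active-stress generation and the 0D chamber pressure-volume surrogate.

The contractile machinery of each heart chamber is modelled by a scalar
active fiber stress tau_a(t) driven by a trapezoidal activation function:

    dtau_a/dt = -|u| tau_a + sigma_0 |u|_+

where the "transmembrane potential" u(t) blends the upstroke rate alpha_max
and the (negative) relaxation rate alpha_min through the normalized
activation f_hat(t) in [0, 1].  f_hat ramps linearly from 0 to 1 over a
window of width 1/K ending at c1, stays at 1 until c2 and ramps back to 0
over 1/K, where c1 and c2 are offset from the contraction/relaxation onset
times by alpha_max / (K (alpha_max - alpha_min)).

Chamber pressure follows a 0D surrogate law combining an exponential passive
end-diastolic pressure-volume relation with an elastance-like active term
linear in tau_a:

    p(V, tau) = E_pass_a (exp(E_pass_b (V - V_ref)) - 1)
                + wall_factor * tau * V / V_ref

The surrogate is strictly increasing in both V and tau and C^1 on V > 0, so
the monolithic Newton solver sees a well-conditioned closure, and sigma_0,
alpha_max, alpha_min retain their roles as the identifiable contractility
and rate parameters.  The active pressure vanishing as V -> 0 mimics the
loss of pressure generation of a collapsing chamber and keeps the emptying
dynamics self-limiting.
"""
from __future__ import annotations

import numpy as np

from .params import ActiveStressParams, ChamberSurrogateParams

__all__ = [
    "activation_window",
    "activation",
    "activation_sensitivity",
    "transmembrane_potential",
    "potential_sensitivity",
    "active_stress_rate",
    "chamber_pressure",
    "chamber_pressure_derivs",
    "chamber_mass_residual",
]

# exponent cap for the passive law; beyond it the law continues linearly (C^1)
_ZCAP = 25.0


def activation_window(p: ActiveStressParams):
    """Return (c1, c2), the plateau boundaries of the activation trapezoid."""
    shift = p.alpha_max / (p.K * (p.alpha_max - p.alpha_min))
    return p.t_contr + shift, p.t_relax - shift


def _fhat_raw(s, c1, c2, K):
    """Trapezoid on one unwrapped copy: 0 outside [c1-1/K, c2+1/K]."""
    up = np.clip(K * (s - c1) + 1.0, 0.0, 1.0)
    down = np.clip(-K * (s - c2), -1.0, 0.0)
    return up + down


def _fhat_raw_sens(s, c1, c2, K):
    """df_hat/dc1 and df_hat/dc2 of one unwrapped copy (one-sided at kinks)."""
    on_up = (s > c1 - 1.0 / K) & (s < c1)
    on_down = (s > c2) & (s < c2 + 1.0 / K)
    return np.where(on_up, -K, 0.0), np.where(on_down, K, 0.0)


def _unwrap(t, p: ActiveStressParams):
    """Map t into one period anchored at t_contr; ramps may wrap the boundary."""
    return np.mod(np.asarray(t, dtype=float) - p.t_contr, p.T_cycl) + p.t_contr


def activation(t, p: ActiveStressParams):
    """Normalized activation f_hat(t) in [0, 1], periodic with T_cycl."""
    c1, c2 = activation_window(p)
    s = _unwrap(t, p)
    f = 0.0
    for k in (-1.0, 0.0, 1.0):  # ramps may wrap across the cycle boundary
        f = f + _fhat_raw(s + k * p.T_cycl, c1, c2, p.K)
    return float(f) if np.isscalar(t) else f


def activation_sensitivity(t, p: ActiveStressParams):
    """(f_hat, df/dc1, df/dc2) with periodic extension."""
    c1, c2 = activation_window(p)
    s = _unwrap(t, p)
    f, dc1, dc2 = 0.0, 0.0, 0.0
    for k in (-1.0, 0.0, 1.0):
        f = f + _fhat_raw(s + k * p.T_cycl, c1, c2, p.K)
        d1, d2 = _fhat_raw_sens(s + k * p.T_cycl, c1, c2, p.K)
        dc1, dc2 = dc1 + d1, dc2 + d2
    return f, dc1, dc2


def transmembrane_potential(t, p: ActiveStressParams):
    """u(t) = f_hat * alpha_max + (1 - f_hat) * alpha_min  [1/s]."""
    f = activation(t, p)
    u = f * p.alpha_max + (1.0 - f) * p.alpha_min
    return float(u) if np.isscalar(t) else u


def potential_sensitivity(t, p: ActiveStressParams):
    """u(t) and its partial derivatives w.r.t. alpha_max and alpha_min.

    The rates enter u directly through the blend and indirectly by shifting
    the ramp boundaries c1, c2 of the activation trapezoid.
    """
    f, df_dc1, df_dc2 = activation_sensitivity(t, p)
    f = np.asarray(f, dtype=float)
    spread = p.alpha_max - p.alpha_min
    dc1_damax = -p.alpha_min / (p.K * spread**2)
    dc1_damin = p.alpha_max / (p.K * spread**2)
    # c2 carries the same offset with opposite sign
    df_damax = df_dc1 * dc1_damax + df_dc2 * (-dc1_damax)
    df_damin = df_dc1 * dc1_damin + df_dc2 * (-dc1_damin)
    u = f * p.alpha_max + (1.0 - f) * p.alpha_min
    du_damax = f + spread * df_damax
    du_damin = (1.0 - f) + spread * df_damin
    return u, du_damax, du_damin


def active_stress_rate(tau, u, sigma_0):
    """dtau_a/dt = -|u| tau_a + sigma_0 |u|_+  [kPa/s]."""
    return -np.abs(u) * tau + sigma_0 * np.maximum(0.0, u)


def _passive(z):
    """exp(z) - 1 with C^1 linear continuation beyond _ZCAP, and derivative."""
    z = np.asarray(z, dtype=float)
    zc = np.minimum(z, _ZCAP)
    e = np.exp(zc)
    val = np.where(z <= _ZCAP, e - 1.0, e * (1.0 + (z - _ZCAP)) - 1.0)
    der = np.where(z <= _ZCAP, e, e)
    return val, der


def chamber_pressure(V, tau, sp: ChamberSurrogateParams):
    """Chamber pressure p(V, tau) in kPa; V in mm^3, tau in kPa."""
    if np.any(np.asarray(V) <= 0.0):
        raise ValueError("chamber volume must be strictly positive")
    val, _ = _passive(sp.E_pass_b * (np.asarray(V, dtype=float) - sp.V_ref))
    p = sp.E_pass_a * val + sp.wall_factor * tau * (np.asarray(V, dtype=float) / sp.V_ref)
    return float(p) if np.isscalar(V) and np.isscalar(tau) else p


def chamber_pressure_derivs(V, tau, sp: ChamberSurrogateParams):
    """(p, dp/dV, dp/dtau) of the surrogate law."""
    if np.any(np.asarray(V) <= 0.0):
        raise ValueError("chamber volume must be strictly positive")
    V = np.asarray(V, dtype=float)
    val, der = _passive(sp.E_pass_b * (V - sp.V_ref))
    rel = V / sp.V_ref
    p = sp.E_pass_a * val + sp.wall_factor * tau * rel
    dp_dV = sp.E_pass_a * sp.E_pass_b * der + sp.wall_factor * tau / sp.V_ref
    dp_dtau = sp.wall_factor * rel
    return p, dp_dV, dp_dtau


def chamber_mass_residual(dVdt, q_in, q_out):
    """Mass balance residual dV/dt - q_in + q_out of one chamber [mm^3/s]."""
    return dVdt - q_in + q_out
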