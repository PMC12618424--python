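"""Windkessel residuals, the eliminated-flow pressure ODE, and their
discrete equivalence."""
import numpy as np
import pytest

from cardioloop import circulation as circ

# printed patient-scale magnitudes (internal mm^3/kPa/s units)
C_SYS, R_SYS, Z_SYS = 11302.0, 1.392e-4, 1.308e-5
C_VEN, R_VEN = 339060.0, 1.392e-5


class TestWk3Residual:
    def test_algebraic_steady_state(self):
        q = 8.0e4
        p_ven = 0.6
        p_ar = p_ven + (R_SYS + Z_SYS) * q  # = 12.78 kPa
        assert p_ar == pytest.approx(12.78, abs=5e-3)
        r_mass, r_mom = circ.wk3_residual(
            p_ar, q, p_ar, q, q, q, p_ven, p_ven, C_SYS, R_SYS, Z_SYS, dt=1e-3
        )
        assert r_mass == pytest.approx(0.0, abs=1e-9)
        assert r_mom == pytest.approx(0.0, abs=1e-9)

    def test_zero_flow_equal_pressures(self):
        r_mass, r_mom = circ.wk3_residual(
            1.0, 0.0, 1.0, 0.0, 0.0, 0.0, 1.0, 1.0, C_SYS, R_SYS, Z_SYS, dt=1e-3
        )
        assert r_mass == 0.0 and r_mom == 0.0

    def test_residual_linear_in_unknowns(self, rng):
        # random two-point secant equals the (constant) Jacobian action
        args = dict(C=C_SYS, R=R_SYS, Z=Z_SYS, dt=1e-3, theta=0.5)
        x1 = rng.standard_normal(8)
        x2 = rng.standard_normal(8)
        lam = 0.37
        r1 = np.array(circ.wk3_residual(*x1, **args))
        r2 = np.array(circ.wk3_residual(*x2, **args))
        rmid = np.array(circ.wk3_residual(*(lam * x1 + (1 - lam) * x2), **args))
        assert np.allclose(rmid, lam * r1 + (1 - lam) * r2, rtol=1e-9, atol=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            circ.wk3_residual(1, 0, 1, 0, 0, 0, 1, 1, C_SYS, R_SYS, Z_SYS, dt=0.0)
        with pytest.raises(FloatingPointError):
            circ.wk3_residual(np.nan, 0, 1, 0, 0, 0, 1, 1, C_SYS, R_SYS, Z_SYS, dt=1e-3)


class TestWk2Residual:
    def test_steady_state(self):
        q = 5.0e4
        p_at = 0.5
        p_ven = p_at + R_VEN * q
        r_mass, r_mom = circ.wk2_residual(
            p_ven, q, p_ven, q, q, q, p_at, p_at, C_VEN, R_VEN, dt=1e-3
        )
        assert r_mass == pytest.approx(0.0, abs=1e-9)
        assert r_mom == pytest.approx(0.0, abs=1e-9)

    def test_rc_decay_constant(self):
        # step inflow: p_ven relaxes toward steady value with tau = R_ven C_ven;
        # march the discretized pair and compare against the analytic solution
        dt, theta = 1e-4, 0.5
        q_in, p_at = 6.0e4, 0.5
        tau_rc = R_VEN * C_VEN
        p_inf = p_at + R_VEN * q_in
        p = p_at  # start away from the new steady state
        t_end = 2.0
        n = int(t_end / dt)
        for k in range(n):
            # solve the 2x2 linear step from the residual pair itself
            A = np.zeros((2, 2))
            b = np.zeros(2)
            base = np.array(circ.wk2_residual(0.0, 0.0, p, (p - p_at) / R_VEN, q_in, q_in,
                                              p_at, p_at, C_VEN, R_VEN, dt, theta))
            for j, e in enumerate(np.eye(2)):
                A[:, j] = np.array(circ.wk2_residual(e[0], e[1], p, (p - p_at) / R_VEN,
                                                     q_in, q_in, p_at, p_at,
                                                     C_VEN, R_VEN, dt, theta)) - base
            x = np.linalg.solve(A, -base)
            p = x[0]
        exact = p_inf + (p_at - p_inf) * np.exp(-t_end / tau_rc)
        assert p == pytest.approx(exact, rel=1e-6)


class TestEliminatedFlowOde:
    def test_constant_flow_relaxation(self):
        # analytic: p -> p_ven + (R+Z) q0 with time constant R*C
        q0, p_ven = 8.0e4, 0.6
        dt = 1e-4
        t = np.arange(0, 3.0 + dt / 2, dt)
        p0 = 5.0
        p = circ.wk3_pressure_trajectory(t, p0, lambda s: np.full_like(np.asarray(s, float), q0),
                                         lambda s: np.full_like(np.asarray(s, float), p_ven),
                                         C_SYS, R_SYS, Z_SYS)
        p_inf = p_ven + (R_SYS + Z_SYS) * q0
        exact = p_inf + (p0 - p_inf) * np.exp(-t / (R_SYS * C_SYS))
        assert np.max(np.abs(p - exact) / np.abs(exact)) < 1e-5

    def test_zero_drive_keeps_pressure_constant(self):
        dt = 1e-3
        t = np.arange(0, 0.75 + dt / 2, dt)
        p = circ.wk3_pressure_trajectory(t, 2.0, lambda s: np.zeros_like(np.asarray(s, float)),
                                         lambda s: np.full_like(np.asarray(s, float), 2.0),
                                         C_SYS, R_SYS, Z_SYS)
        assert np.allclose(p, 2.0, atol=1e-12)

    def test_sinusoidal_drive_against_fine_reference(self):
        q = lambda s: 8e4 * (1.0 + 0.5 * np.sin(2 * np.pi * np.asarray(s) / 0.75))
        pv = lambda s: np.full_like(np.asarray(s, float), 0.6)
        t_c = np.arange(0, 0.75 + 5e-4, 1e-3)
        t_f = np.arange(0, 0.75 + 2.5e-6, 5e-6)
        p_c = circ.wk3_pressure_trajectory(t_c, 10.0, q, pv, C_SYS, R_SYS, Z_SYS)
        p_f = circ.wk3_pressure_trajectory(t_f, 10.0, q, pv, C_SYS, R_SYS, Z_SYS)
        err = np.abs(p_c - p_f[::200]).max() / np.abs(p_f).max()
        assert err < 1e-3

    @pytest.mark.parametrize("theta,order", [(0.5, 2.0), (1.0, 1.0)])
    def test_convergence_order(self, theta, order):
        q0, p_ven, p0 = 8.0e4, 0.6, 5.0
        p_inf = p_ven + (R_SYS + Z_SYS) * q0
        errs = []
        dts = [4e-3, 2e-3, 1e-3]
        for dt in dts:
            t = np.arange(0, 1.0 + dt / 2, dt)
            p = circ.wk3_pressure_trajectory(
                t, p0, lambda s: np.full_like(np.asarray(s, float), q0),
                lambda s: np.full_like(np.asarray(s, float), p_ven),
                C_SYS, R_SYS, Z_SYS, theta=theta)
            exact = p_inf + (p0 - p_inf) * np.exp(-t / (R_SYS * C_SYS))
            errs.append(np.abs(p - exact).max())
        rate = np.log2(errs[0] / errs[1]), np.log2(errs[1] / errs[2])
        assert min(rate) > order - 0.25

    def test_equivalent_to_discretized_pair(self):
        # eliminated-flow step vs monolithic (p_ar, q_ar) pair: identical
        dt, theta = 1e-3, 0.5
        T = 0.75
        q = lambda s: 8e4 * np.maximum(0.0, np.sin(2 * np.pi * np.asarray(s) / T)) ** 2
        pv = lambda s: 0.6 + 0.05 * np.cos(2 * np.pi * np.asarray(s) / T)
        t = np.arange(0, T + dt / 2, dt)
        p_elim = circ.wk3_pressure_trajectory(t, 10.0, q, pv, C_SYS, R_SYS, Z_SYS, theta=theta)
        # march the pair, solving the 2x2 linear system from the residuals
        p, q_ar = 10.0, (10.0 - pv(0.0) - Z_SYS * q(0.0)) / R_SYS
        p_pair = [p]
        for k in range(len(t) - 1):
            args = (q(t[k + 1]), q(t[k]), pv(t[k + 1]), pv(t[k]), C_SYS, R_SYS, Z_SYS, dt, theta)
            base = np.array(circ.wk3_residual(0.0, 0.0, p, q_ar, *args))
            A = np.zeros((2, 2))
            for j, e in enumerate(np.eye(2)):
                A[:, j] = np.array(circ.wk3_residual(e[0], e[1], p, q_ar, *args)) - base
            p, q_ar = np.linalg.solve(A, -base)
            p_pair.append(p)
        assert np.max(np.abs(p_elim - np.array(p_pair)) / np.abs(p_elim)) < 1e-8
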