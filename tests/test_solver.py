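"""Monolithic coupled residual, Newton stepping, cycle iteration and the
valve-replacement parameter edit."""
import numpy as np
import pytest

import cardioloop as cl
from cardioloop.solver import IDX, NSTATE, CoupledModel, SystemState, periodicity_error


@pytest.fixture(scope="module")
def model(tof_scenario):
    return CoupledModel(tof_scenario.circulation, tof_scenario.chambers)


def _random_admissible_state(scenario, rng):
    x = scenario.initial_state().x.copy()
    x += rng.standard_normal(NSTATE) * np.maximum(0.05 * np.abs(x), 1e-3)
    for z in ("z_mit", "z_aor", "z_tri", "z_pul"):
        x[IDX[z]] = rng.uniform(0.05, 0.95)
    for q in ("q_vin_l", "q_vout_l", "q_vin_r", "q_vout_r"):
        x[IDX[q]] = rng.uniform(-5e4, 2e5)
    for tau in ("tau_at_l", "tau_v_l", "tau_at_r", "tau_v_r"):
        x[IDX[tau]] = rng.uniform(0.5, 40.0)
    return x


class TestCoupledResidual:
    def test_steady_equilibrium_is_root(self, tof_scenario, model):
        # all flows zero, tau zero, chambers at their reference volumes,
        # every pressure equal to the common (zero) passive pressure, at a
        # time where no chamber is activated
        x = np.zeros(NSTATE)
        for c, name in (("la", "V_at_l"), ("lv", "V_v_l"), ("ra", "V_at_r"), ("rv", "V_v_r")):
            x[IDX[name]] = tof_scenario.chambers.surrogate[c].V_ref
        t_quiet = 0.65  # after all activation ramps have closed
        r = model.assemble(x, x, t_quiet + model.dt, t_quiet, jac=False)
        assert np.max(np.abs(r)) < 1e-12

    def test_jacobian_matches_central_fd(self, tof_scenario, model, rng):
        x_prev = _random_admissible_state(tof_scenario, rng)
        x_now = _random_admissible_state(tof_scenario, rng)
        t_prev, t_now = 0.21, 0.21 + model.dt
        _, J, Jp = model.assemble(x_now, x_prev, t_now, t_prev, jac=True, jac_prev=True)
        for which, x0, Jref in (("now", x_now, J), ("prev", x_prev, Jp)):
            Jfd = np.zeros((NSTATE, NSTATE))
            for j in range(NSTATE):
                h = max(1e-6 * abs(x0[j]), 1e-6)
                xp, xm = x0.copy(), x0.copy()
                xp[j] += h
                xm[j] -= h
                if which == "now":
                    rp = model.assemble(xp, x_prev, t_now, t_prev, jac=False)
                    rm = model.assemble(xm, x_prev, t_now, t_prev, jac=False)
                else:
                    rp = model.assemble(x_now, xp, t_now, t_prev, jac=False)
                    rm = model.assemble(x_now, xm, t_now, t_prev, jac=False)
                Jfd[:, j] = (rp - rm) / (2 * h)
            scale = np.maximum(np.abs(Jref), np.abs(Jfd))
            mask = scale > 1e-6
            rel = np.abs(Jref - Jfd)[mask] / scale[mask]
            assert rel.max() < 1e-5

    def test_compiled_kernel_matches_reference_assembly(self, tof_scenario, rng):
        """The compiled assembly path and the pure-Python reference produce
        bitwise-equal residuals and Jacobians."""
        fast = CoupledModel(tof_scenario.circulation, tof_scenario.chambers, use_compiled=True)
        ref = CoupledModel(tof_scenario.circulation, tof_scenario.chambers, use_compiled=False)
        for _ in range(10):
            x_now = _random_admissible_state(tof_scenario, rng)
            x_prev = _random_admissible_state(tof_scenario, rng)
            r1, J1, Jp1 = fast.assemble(x_now, x_prev, 0.321, 0.32, jac=True, jac_prev=True)
            r2, J2, Jp2 = ref.assemble(x_now, x_prev, 0.321, 0.32, jac=True, jac_prev=True)
            assert np.allclose(r1, r2, rtol=1e-14, atol=1e-14)
            assert np.allclose(J1, J2, rtol=1e-14, atol=1e-14)
            assert np.allclose(Jp1, Jp2, rtol=1e-14, atol=1e-14)

    def test_nonfinite_state_rejected(self, model):
        x = np.zeros(NSTATE)
        x[0] = np.nan
        with pytest.raises(FloatingPointError):
            model.assemble(x, np.zeros(NSTATE), 0.001, 0.0, jac=False)


class TestNewton:
    def test_exact_solution_returns_unchanged(self, tof_scenario, model):
        # advance one step, then re-solve from the converged answer
        x0 = tof_scenario.initial_state().x
        x1 = model.newton_step(x0, 0.0)
        x1b = model.newton_step(x0, 0.0, x_guess=x1)
        assert np.allclose(x1, x1b, rtol=0, atol=1e-12)

    def test_converged_residual_below_tolerance(self, tof_scenario, model):
        x0 = tof_scenario.initial_state().x
        x1 = model.newton_step(x0, 0.0)
        r = model.assemble(x1, x0, model.dt, 0.0, jac=False)
        assert model.scaled_norm(r) < 1e-8

    def test_quadratic_contraction(self, tof_scenario, model):
        # undamped Newton from a mildly perturbed iterate: the scaled norm
        # contracts superlinearly on the final iterations
        x0 = tof_scenario.initial_state().x
        x1 = model.newton_step(x0, 0.0)
        x = x1 * (1 + 1e-3)
        norms = []
        for _ in range(6):
            r, J = model.assemble(x, x0, model.dt, 0.0)
            norms.append(model.scaled_norm(r))
            if norms[-1] < 1e-13:
                break
            x = x + np.linalg.solve(J, -r)
        norms = np.array(norms)
        drops = norms[1:] / norms[:-1]
        assert drops.min() < 1e-3  # at least one near-quadratic drop

    def test_larger_step_recovers_by_halving(self, tof_scenario):
        # a deliberately coarse step still converges via damping
        coarse = CoupledModel(tof_scenario.circulation, tof_scenario.chambers, dt=2e-2)
        x0 = tof_scenario.initial_state().x
        x1 = coarse.newton_step(x0, 0.12)
        assert np.all(np.isfinite(x1))


class TestPeriodicity:
    def test_identical_states(self, tof_scenario):
        s = tof_scenario.initial_state()
        assert periodicity_error(s, s) == 0.0

    def test_uniform_two_percent(self, tof_scenario):
        s = tof_scenario.initial_state()
        e = SystemState(s.x * 1.02, s.t + 0.75)
        assert periodicity_error(s, e) == pytest.approx(0.02)

    def test_max_semantics_single_field(self, tof_scenario):
        s = tof_scenario.initial_state()
        x = s.x.copy()
        x[IDX["V_v_r"]] *= 1.10
        assert periodicity_error(s, SystemState(x, s.t)) == pytest.approx(0.10)

    def test_literal_printed_set_ignores_left_atrium(self, tof_scenario):
        s = tof_scenario.initial_state()
        x = s.x.copy()
        x[IDX["V_at_l"]] *= 1.5
        assert periodicity_error(s, SystemState(x, s.t)) == pytest.approx(0.5)
        assert periodicity_error(s, SystemState(x, s.t), literal_printed_set=True) == 0.0

    def test_zero_reference_rejected(self, tof_scenario):
        s = tof_scenario.initial_state()
        x = s.x.copy()
        x[IDX["p_ar_sys"]] = 0.0
        with pytest.raises(ZeroDivisionError):
            periodicity_error(SystemState(x, 0.0), s)


class TestValveReplacement:
    def test_seals_pulmonary_valve_only(self, tof_scenario):
        circ = tof_scenario.circulation
        new = cl.apply_valve_replacement(circ, "pul")
        assert new.valves["pul"].A_eff_min == 0.0
        assert new.valves["pul"].A_eff_max == circ.valves["pul"].A_eff_max
        assert circ.valves["pul"].A_eff_min == 164.0  # original untouched
        assert new.valves["aor"] == circ.valves["aor"]

    def test_idempotent(self, tof_scenario):
        once = cl.apply_valve_replacement(tof_scenario.circulation, "pul")
        twice = cl.apply_valve_replacement(once, "pul")
        assert once.valves["pul"] == twice.valves["pul"]

    def test_unknown_valve(self, tof_scenario):
        with pytest.raises(ValueError):
            cl.apply_valve_replacement(tof_scenario.circulation, "nope")


class TestClosedLoopPhysics:
    def test_total_volume_conserved_over_cycle(self, tof_scenario, periodic_run):
        traj, _ = periodic_run
        vols = [
            cl.total_blood_volume(SystemState(traj.X[k], traj.t[k]), tof_scenario.circulation)
            for k in range(0, traj.X.shape[0], 25)
        ]
        vols = np.array(vols)
        assert np.max(np.abs(vols - vols[0])) / vols[0] < 1e-8

    def test_periodic_state_chamber_mass_balance(self, periodic_run):
        # cycle-integrated inflow equals outflow per chamber at convergence
        traj, report = periodic_run
        pairs = (
            ("q_ven_pul", "q_vin_l"), ("q_vin_l", "q_vout_l"),
            ("q_ven_sys", "q_vin_r"), ("q_vin_r", "q_vout_r"),
        )
        for qin, qout in pairs:
            vin = np.trapezoid(traj.series(qin), traj.t)
            vout = np.trapezoid(traj.series(qout), traj.t)
            assert abs(vin - vout) / abs(vin) < 5 * report.E_cycl + 0.01

    def test_trajectory_invariant_under_refinement(self, tof_scenario):
        import dataclasses
        fine = dataclasses.replace(tof_scenario, dt=5e-4)
        t1, _ = cl.run_to_periodic(tof_scenario, eps_cycl=0.01, max_cycles=10)
        t2, _ = cl.run_to_periodic(fine, eps_cycl=0.01, max_cycles=10)
        v1 = t1.series("V_v_l")
        v2 = t2.series("V_v_l")[::2]
        assert np.max(np.abs(v1 - v2)) / np.max(v1) < 5e-3
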