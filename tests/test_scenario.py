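"""Synthetic scenarios, measurement synthesis, and the valve-replacement
prediction workflow."""
import numpy as np
import pytest

import cardioloop as cl
from cardioloop.measurements import normalize_time_axis
from cardioloop.scenario import DEFAULT_NOISE, Scenario


class TestScenarioDefinition:
    def test_tof_targets(self, tof_scenario, periodic_run):
        traj, report = periodic_run
        m = cl.trajectory_metrics(traj, tof_scenario.T_cycl)
        assert tof_scenario.T_cycl == pytest.approx(0.75)
        assert m["right"].RF > 40.0
        assert m["right"].EDV > 1.5 * m["left"].EDV

    def test_sealing_the_valve_removes_regurgitation(self, tof_scenario):
        import dataclasses

        sealed = dataclasses.replace(
            tof_scenario, circulation=cl.apply_valve_replacement(tof_scenario.circulation, "pul")
        )
        traj, report = cl.run_to_periodic(sealed, max_cycles=40)
        assert report.converged
        m = cl.trajectory_metrics(traj, sealed.T_cycl)
        assert m["right"].RF < 1.0

    def test_json_roundtrip(self, tof_scenario, tmp_path):
        p = tmp_path / "scenario.json"
        tof_scenario.save(p)
        back = Scenario.load(p)
        assert back.circulation == tof_scenario.circulation
        assert back.chambers == tof_scenario.chambers
        assert back.initial_volumes == tof_scenario.initial_volumes
        assert back.label == tof_scenario.label

    def test_healthy_counterpart_not_regurgitant(self):
        sc = cl.make_healthy_scenario()
        assert sc.circulation.valves["pul"].A_eff_min < 1.0
        traj, report = cl.run_to_periodic(sc, max_cycles=40)
        assert report.converged
        m = cl.trajectory_metrics(traj, sc.T_cycl)
        assert m["right"].RF < 1.0
        assert m["right"].EDV < 1.5 * m["left"].EDV


class TestMeasurementSynthesis:
    def test_zero_noise_matches_trajectory(self, tof_scenario, periodic_run):
        from cardioloop.solver import IDX

        traj, _ = periodic_run
        mset = cl.synthesize_measurements(traj, tof_scenario.T_cycl, noise=None, seed=3)
        t_v, V = mset.get("V_v_r")
        assert len(t_v) == 25
        idx = np.round((t_v - 0.0) / traj.dt).astype(int)
        assert np.allclose(V * 1e3, traj.X[idx, IDX["V_v_r"]])
        t_q, _ = mset.get("q_vout_r")
        assert len(t_q) == 30
        t_p, _ = mset.get("p_ar_sys")
        assert len(t_p) == traj.X.shape[0]  # catheter-rate pressures

    def test_seed_reproducibility(self, tof_scenario, periodic_run):
        traj, _ = periodic_run
        a = cl.synthesize_measurements(traj, tof_scenario.T_cycl, noise=DEFAULT_NOISE, seed=11)
        b = cl.synthesize_measurements(traj, tof_scenario.T_cycl, noise=DEFAULT_NOISE, seed=11)
        c = cl.synthesize_measurements(traj, tof_scenario.T_cycl, noise=DEFAULT_NOISE, seed=12)
        for name in a.series:
            assert np.array_equal(a.get(name)[1], b.get(name)[1])
        assert not np.array_equal(a.get("p_v_l")[1], c.get("p_v_l")[1])

    def test_jitter_roundtrip_through_normalization(self, tof_scenario, periodic_run):
        traj, _ = periodic_run
        jitter = {"source_T_factor": {"V_v_r": 1.07}, "shift": {"V_v_r": 0.06}}
        mset = cl.synthesize_measurements(
            traj, tof_scenario.T_cycl, noise=None, seed=0, jitter=jitter
        )
        fixed = normalize_time_axis(
            mset, target_T_cycl=tof_scenario.T_cycl,
            t0_shift={"V_v_r": 0.06},
        )
        clean = cl.synthesize_measurements(traj, tof_scenario.T_cycl, noise=None, seed=0)
        t1, v1 = fixed.get("V_v_r")
        t0, v0 = clean.get("V_v_r")
        # same volumes observed, cycle re-aligned within interpolation error
        assert np.allclose(np.sort(v1), np.sort(v0))
        spl = fixed.spline("V_v_r", periodic=True)
        assert np.allclose(spl(t0), v0, atol=1.5)


@pytest.fixture(scope="module")
def outcome(tof_scenario, periodic_run):
    traj, _rep = periodic_run
    return cl.predict_replacement_outcome(tof_scenario, preop_traj=traj)


class TestReplacementPrediction:
    def test_regurgitation_eliminated(self, outcome):
        table, post_traj, post_rep = outcome
        assert post_rep.converged
        assert table.predicted_post["right"].RF < 1.0
        assert table.predicted_post["right"].RV == pytest.approx(0.0, abs=0.5)

    def test_reverse_remodeling_directions(self, outcome):
        table, _, _ = outcome
        d = table.deltas()
        assert d["right"]["EDV"] < 0.0  # right ventricle unloads
        assert d["left"]["SV"] > 0.0    # cardiac output rises

    def test_backward_volume_never_increases(self, outcome, tof_scenario, periodic_run):
        table, _, _ = outcome
        pre = table.preoperative["right"].RV
        post = table.predicted_post["right"].RV
        assert post <= pre + 1e-9

    def test_metric_identities(self, outcome):
        table, _, _ = outcome
        for block in (table.preoperative, table.predicted_post):
            for side in ("right", "left"):
                m = block[side]
                assert m.SV == pytest.approx(m.EDV - m.ESV, rel=1e-9)
                assert m.RF == pytest.approx(100.0 * m.RV / (m.FV + m.RV), rel=1e-6)

    def test_transient_snapshots_recorded(self, outcome):
        _, _, post_rep = outcome
        assert len(post_rep.snapshots) == post_rep.n_cycles


class TestTwinExperiments:
    def test_noisy_twin_recovers_robust_parameters(self):
        """Default measurement noise: the arterial resistances and the valve
        orifice areas stay within 10%, as does left-ventricular
        contractility.  Atrial and right-ventricular contractility carry a
        larger noise-induced uncertainty (small volume excursions against
        2 ml volume noise) and are only checked against a loose envelope."""
        rep = cl.run_twin_experiment(seed=0, noise="default")
        r = rep["recovery"]
        assert r["R_ar_sys"] < 0.10 and r["R_ar_pul"] < 0.10
        assert r["A_eff_max_pul"] < 0.10 and r["A_eff_min_pul"] < 0.10
        assert r["A_eff_max_aor"] < 0.10
        assert r["sigma_0_lv"] < 0.10
        assert max(r[f"sigma_0_{c}"] for c in ("lv", "rv", "ra", "la")) < 0.35

    def test_report_lists_subproblems_with_required_series(self, twin_report):
        stages = twin_report["stages"]
        for key in ("windkessel_sys", "windkessel_pul", "valve_pul", "valve_aor",
                    "active_stress"):
            assert stages[key].get("required_series_present") is True
        assert "replacement" in stages


def test_decomposed_matches_monolithic_joint_fit(tof_scenario, periodic_run):
    """Desk-scale equivalence: jointly fitting the pulmonary windkessel and
    pulmonary valve (5 parameters, summed normalized objectives) on the same
    noiseless twin lands on the same parameters as the two decomposed
    subproblem fits, within 2%."""
    import numpy as np
    from scipy.optimize import minimize

    from cardioloop.inverse import fit_arterial_windkessel, fit_valve_eoa
    from cardioloop.inverse.windkessel import windkessel_objective
    from cardioloop.inverse.valve import valve_objective, _measured_inputs

    traj, _ = periodic_run
    mset = cl.synthesize_measurements(traj, tof_scenario.T_cycl, noise=None, seed=1)
    vp = tof_scenario.circulation.valves["pul"]
    res_wk = fit_arterial_windkessel(mset, side="pul")
    res_vl = fit_valve_eoa(mset, valve="pul", params=vp)
    _, (vf, vb), _, _, _ = _measured_inputs(mset, "pul")
    vol_scale = vf**2 + vb**2

    def joint(y):
        R, C, Z, A_max, A_min = np.exp(y)
        f1, _, _ = windkessel_objective([R, C, Z], mset, side="pul")
        f2, _, _ = valve_objective([A_max, A_min], mset, valve="pul", params=vp)
        return f1 + f2 / vol_scale

    y0 = np.log([2e-5, 1e4, 3e-6, 250.0, 100.0])
    res = minimize(joint, y0, method="L-BFGS-B",
                   options={"maxfun": 400, "ftol": 1e-15, "gtol": 1e-12, "eps": 1e-6})
    R, C, Z, A_max, A_min = np.exp(res.x)
    sep = np.array([res_wk.R_ar, res_wk.C_ar, res_wk.Z_ar, res_vl.A_eff_max, res_vl.A_eff_min])
    joint_phi = np.array([R, C, Z, A_max, A_min])
    assert np.all(np.abs(joint_phi - sep) / sep < 0.02)
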