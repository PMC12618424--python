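"""Measurement I/O, splines, time-axis normalization, clinical metrics and
mass-consistency checking."""
import json

import numpy as np
import pytest

from cardioloop import measurements as ms
from cardioloop.measurements import (
    ClinicalMetrics,
    MeasurementFormatError,
    MeasurementSet,
    check_mass_consistency,
    clinical_metrics,
    normalize_time_axis,
    read_measurements,
    spline_series,
    write_measurements,
)


def _simple_set():
    T = 0.75
    t_v = (T / 25) * np.arange(25)
    V = 120.0 + 40.0 * np.sin(2 * np.pi * t_v / T - 0.6)
    t_q = (T / 30) * np.arange(30)
    q = 300.0 * np.sin(2 * np.pi * t_q / T) ** 3
    return MeasurementSet(series={"V_v_r": (t_v, V), "q_vout_r": (t_q, q)}, T_cycl=T)


class TestReadWrite:
    def test_roundtrip(self, tmp_path):
        mset = _simple_set()
        csv, meta = tmp_path / "m.csv", tmp_path / "m.json"
        write_measurements(mset, csv, sidecar=meta)
        back = read_measurements(csv, sidecar=meta)
        assert back.T_cycl == mset.T_cycl
        for name in mset.series:
            t0, y0 = mset.get(name)
            t1, y1 = back.get(name)
            assert np.allclose(t0, t1) and np.allclose(y0, y1)

    def test_minimal_single_series(self, tmp_path):
        p = tmp_path / "min.csv"
        p.write_text("t,q_vout_r\n0.0,1.0\n0.1,2.0\n0.2,0.5\n")
        mset = read_measurements(p)
        assert mset.names() == ["q_vout_r"]

    def test_unit_conversion(self, tmp_path):
        csv, meta = tmp_path / "u.csv", tmp_path / "u.json"
        csv.write_text("t,q_vout_r\n0.0,1000.0\n0.1,2000.0\n")
        meta.write_text(json.dumps({"units": {"q_vout_r": "mm^3/s"}}))
        mset = read_measurements(csv, sidecar=meta)
        _, y = mset.get("q_vout_r")
        assert np.allclose(y, [1.0, 2.0])  # converted to ml/s

    def test_unknown_quantity_and_unit_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("t,banana\n0.0,1.0\n")
        with pytest.raises(MeasurementFormatError):
            read_measurements(p)
        csv, meta = tmp_path / "bu.csv", tmp_path / "bu.json"
        csv.write_text("t,q_vout_r\n0.0,1.0\n")
        meta.write_text(json.dumps({"units": {"q_vout_r": "furlongs"}}))
        with pytest.raises(MeasurementFormatError):
            read_measurements(csv, sidecar=meta)

    def test_duplicate_timestamps_rejected(self):
        with pytest.raises(MeasurementFormatError):
            MeasurementSet(series={"p_v_l": (np.array([0.0, 0.1, 0.1]), np.zeros(3))})

    def test_nonmonotone_time_rejected(self):
        with pytest.raises(MeasurementFormatError):
            MeasurementSet(series={"p_v_l": (np.array([0.0, 0.2, 0.1]), np.zeros(3))})


class TestSpline:
    def test_cubic_exactness(self):
        t = np.linspace(0, 1, 9)
        y = 2.0 - t + 3 * t**2 - 0.5 * t**3
        s = spline_series(t, y)
        tt = np.linspace(0, 1, 101)
        assert np.allclose(s(tt), 2.0 - tt + 3 * tt**2 - 0.5 * tt**3, atol=1e-12)

    def test_periodic_boundary_matches_value_and_slope(self):
        T = 0.75
        t = (T / 30) * np.arange(30)
        y = np.sin(2 * np.pi * t / T) + 0.3 * np.cos(4 * np.pi * t / T)
        s = spline_series(t, y, periodic=True, period=T)
        assert s(0.0) == pytest.approx(s(T), abs=1e-12)
        assert s.derivative()(0.0) == pytest.approx(s.derivative()(T), abs=1e-9)

    def test_derivative_of_sampled_sine(self):
        # 30 samples/cycle: max derivative within 1% of amplitude * omega
        T = 0.75
        om = 2 * np.pi / T
        t = (T / 30) * np.arange(30)
        s = spline_series(t, 5.0 * np.sin(om * t), periodic=True, period=T)
        tt = np.linspace(0, T, 5000)
        assert np.max(s.derivative()(tt)) == pytest.approx(5.0 * om, rel=1e-2)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            spline_series([0, 1, 2], [1, 2, 3])


class TestNormalizeTimeAxis:
    def test_identity_when_already_at_target(self):
        mset = _simple_set()
        out = normalize_time_axis(mset, target_T_cycl=0.75)
        for name in mset.series:
            assert np.allclose(out.get(name)[0], mset.get(name)[0])
            assert np.allclose(out.get(name)[1], mset.get(name)[1])

    def test_proportional_scaling(self):
        t = np.linspace(0.0, 0.8, 17)
        mset = MeasurementSet(series={"p_v_l": (t, np.sin(t))}, T_cycl=0.8)
        out = normalize_time_axis(mset, target_T_cycl=0.75)
        tt, _ = out.get("p_v_l")
        k = np.argmin(np.abs(t - 0.40))
        assert tt[k] == pytest.approx(0.375)

    def test_shift_group_property(self):
        mset = _simple_set()
        fwd = normalize_time_axis(mset, t0_shift={"V_v_r": 0.1})
        back = normalize_time_axis(fwd, t0_shift={"V_v_r": -0.1})
        t0, y0 = mset.get("V_v_r")
        t1, y1 = back.get("V_v_r")
        order = np.argsort(np.mod(t0, 0.75))
        assert np.allclose(np.sort(np.mod(t1, 0.75)), np.sort(np.mod(t0, 0.75)), atol=1e-12)
        assert np.allclose(np.sum(y1), np.sum(y0))


class TestClinicalMetrics:
    @pytest.mark.parametrize(
        "EDV,ESV,FV,RV,SV,EF,RF",
        [
            (192.3, 116.3, 32.9, 43.1, 76.0, 39.5, 56.7),  # dilated right ventricle
            (99.7, 59.3, 39.1, 1.3, 40.4, 40.5, 3.2),      # left ventricle
            (161.1, 113.9, 47.0, 0.2, 47.2, 29.3, 0.42),   # post-replacement right
            (120.2, 74.4, 45.6, 0.2, 45.8, 38.1, 0.44),    # post-replacement left
        ],
    )
    def test_row_internal_arithmetic(self, EDV, ESV, FV, RV, SV, EF, RF):
        m = ClinicalMetrics.from_volumes(EDV, ESV, FV=FV, RV=RV)
        assert m.SV == pytest.approx(SV, abs=0.05)
        assert m.EF == pytest.approx(EF, abs=0.05)
        assert m.RF == pytest.approx(RF, abs=0.05 if RF > 1 else 0.005)

    def test_from_series_with_regurgitant_flow(self):
        T = 0.75
        t = np.linspace(0, T, 751)
        V = 150 + 40 * np.cos(2 * np.pi * t / T)
        q = np.where(t < 0.3, 400 * np.sin(np.pi * t / 0.3), -80.0)
        m = clinical_metrics((t, V), (t, q))
        assert m.EDV == pytest.approx(190, abs=0.1)
        assert m.SV == pytest.approx(80, abs=0.1)
        assert m.RV == pytest.approx(80 * 0.45, rel=0.02)
        assert m.FV == pytest.approx(m.SV - m.RV)
        assert 0.0 <= m.RF <= 100.0

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            ClinicalMetrics(EDV=100, ESV=50, SV=60, EF=60)
        with pytest.raises(ValueError):
            clinical_metrics((np.array([]), np.array([])))


class TestMassConsistency:
    @staticmethod
    def _consistent_pair():
        # volume obtained by integrating -q: dV/dt = -q holds exactly
        T = 0.75
        t = np.linspace(0, T, 400)
        q = 300 * np.sin(2 * np.pi * t / T)
        V = 150 - np.concatenate([[0], np.cumsum(np.diff(t) * 0.5 * (q[1:] + q[:-1]))])
        return T, t, q, V

    def test_self_consistent_data(self):
        T, t, q, V = self._consistent_pair()
        mset = MeasurementSet(series={"V_v_r": (t, V), "q_vout_r": (t, q)}, T_cycl=T)
        rep = check_mass_consistency(mset)
        assert rep["consistent"]
        assert rep["max_rel_discrepancy"] < 0.01

    def test_inflated_volume_factor_recovered(self):
        T, t, q, V = self._consistent_pair()
        mset = MeasurementSet(series={"V_v_r": (t, 1.05 * V), "q_vout_r": (t, q)}, T_cycl=T)
        rep = check_mass_consistency(mset, tolerance=0.02, adjust=True)
        assert rep["factors"]["V_v_r"] == pytest.approx(1 / 1.05, rel=5e-3)
        assert rep["adjusted"] == ["V_v_r"]
        adj = rep["adjusted_set"]
        _, Vadj = adj.get("V_v_r")
        assert np.max(Vadj) - np.min(Vadj) == pytest.approx(np.max(V) - np.min(V), rel=5e-3)
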