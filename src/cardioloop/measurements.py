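"""Measurement data model: time series I/O, splines, time-axis
normalization, consistency checks and clinical metrics.

Measured quantities live in clinical units (kPa, ml/s, ml).  A measurement
set holds named series - catheter pressures, phase-contrast MRI valve flows
(typically 30 samples per cycle) and cine-MRI chamber volumes (25 samples
per cycle) - each on its own time grid within one cardiac cycle.  Because
the series are acquired non-simultaneously, each may need a linear time
rescaling to a common cycle duration and a circular shift so that t = 0
coincides with the onset of atrial contraction.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .units import UNIT_FACTORS

__all__ = [
    "SERIES_NAMES",
    "MeasurementSet",
    "ClinicalMetrics",
    "MeasurementFormatError",
    "read_measurements",
    "write_measurements",
    "spline_series",
    "normalize_time_axis",
    "clinical_metrics",
    "check_mass_consistency",
]

#: canonical series names and their unit class
SERIES_NAMES = {
    "p_v_l": "kPa", "p_v_r": "kPa", "p_ar_sys": "kPa", "p_ar_pul": "kPa",
    "p_at_r": "kPa", "p_at_l": "kPa", "p_ven_pul": "kPa", "p_ven_sys": "kPa",
    "q_vout_l": "ml/s", "q_vout_r": "ml/s", "q_vin_l": "ml/s", "q_vin_r": "ml/s",
    "V_v_l": "ml", "V_v_r": "ml", "V_at_l": "ml", "V_at_r": "ml",
}


class MeasurementFormatError(ValueError):
    """Raised for malformed measurement files or series."""


@dataclass
class MeasurementSet:
    """Named, time-stamped measured series over (at least) one cycle."""

    series: Dict[str, Tuple[np.ndarray, np.ndarray]]
    T_cycl: float = 0.75
    t0_is_atrial_onset: bool = True
    source_T: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        clean = {}
        for name, (t, y) in self.series.items():
            if name not in SERIES_NAMES:
                raise MeasurementFormatError(f"unknown measured quantity {name!r}")
            t = np.asarray(t, dtype=float)
            y = np.asarray(y, dtype=float)
            if t.shape != y.shape or t.ndim != 1:
                raise MeasurementFormatError(f"series {name}: time/value shape mismatch")
            if np.any(np.diff(t) < 0):
                raise MeasurementFormatError(f"series {name}: time axis not monotone")
            if np.any(np.diff(t) == 0):
                raise MeasurementFormatError(f"series {name}: duplicate timestamps")
            clean[name] = (t, y)
        self.series = clean

    def __contains__(self, name):
        return name in self.series

    def get(self, name):
        if name not in self.series:
            raise KeyError(f"series {name!r} not present in this measurement set")
        return self.series[name]

    def spline(self, name, periodic=False):
        t, y = self.get(name)
        return spline_series(t, y, periodic=periodic, period=self.T_cycl)

    def names(self):
        return sorted(self.series)


@dataclass
class ClinicalMetrics:
    """Per-ventricle volumetric function metrics.

    EDV/ESV/SV in ml, EF in %, forward volume FV and retrograde volume RV in
    ml, regurgitation fraction RF in %.  FV is defined as SV - RV so that
    FV + RV equals the stroke volume and RF = 100 RV / (FV + RV).
    """

    EDV: float
    ESV: float
    SV: float
    EF: float
    FV: Optional[float] = None
    RV: Optional[float] = None
    RF: Optional[float] = None

    def __post_init__(self):
        if self.EDV < 0 or self.ESV < 0:
            raise ValueError("volumes must be nonnegative")
        if not np.isclose(self.SV, self.EDV - self.ESV, atol=1e-9, rtol=1e-9):
            raise ValueError("SV must equal EDV - ESV")

    @classmethod
    def from_volumes(cls, EDV, ESV, FV=None, RV=None):
        """Build metrics from printed/tabulated volumes (Table-style rows)."""
        SV = EDV - ESV
        EF = 100.0 * SV / EDV
        RF = None
        if FV is not None and RV is not None:
            RF = 100.0 * RV / (FV + RV)
        return cls(EDV=EDV, ESV=ESV, SV=SV, EF=EF, FV=FV, RV=RV, RF=RF)

    def as_dict(self):
        return {k: (None if v is None else float(v)) for k, v in self.__dict__.items()}


# ---------------------------------------------------------------------------


def read_measurements(path, sidecar=None) -> MeasurementSet:
    """Read a wide-format CSV (column `t` plus any subset of series names).

    Different sampling grids are encoded by NaN gaps.  An optional sidecar
    JSON declares units per series ({"units": {...}, "T_cycl": ...,
    "source_T": {...}}); undeclared series are assumed to be in canonical
    units (kPa, ml/s, ml).
    """
    df = pd.read_csv(path)
    if "t" not in df.columns:
        raise MeasurementFormatError("CSV must contain a 't' column (seconds)")
    meta = {}
    if sidecar is not None:
        with open(sidecar) as fh:
            meta = json.load(fh)
    units = meta.get("units", {})
    series = {}
    for col in df.columns:
        if col == "t":
            continue
        if col not in SERIES_NAMES:
            raise MeasurementFormatError(f"unknown measured quantity {col!r}")
        mask = df[col].notna().to_numpy()
        t = df["t"].to_numpy(dtype=float)[mask]
        y = df[col].to_numpy(dtype=float)[mask]
        unit = units.get(col)
        if unit is not None:
            if unit not in UNIT_FACTORS:
                raise MeasurementFormatError(f"unknown unit {unit!r} for series {col}")
            y = y * UNIT_FACTORS[unit]
        series[col] = (t, y)
    return MeasurementSet(
        series=series,
        T_cycl=float(meta.get("T_cycl", 0.75)),
        source_T={k: float(v) for k, v in meta.get("source_T", {}).items()},
    )


def write_measurements(mset: MeasurementSet, path, sidecar=None) -> None:
    """Write a measurement set as wide-format CSV (+ optional sidecar JSON)."""
    all_t = np.unique(np.concatenate([t for t, _ in mset.series.values()]))
    data = {"t": all_t}
    for name, (t, y) in mset.series.items():
        col = np.full_like(all_t, np.nan)
        col[np.searchsorted(all_t, t)] = y
        data[name] = col
    pd.DataFrame(data).to_csv(path, index=False)
    if sidecar is not None:
        with open(sidecar, "w") as fh:
            json.dump(
                {
                    "T_cycl": mset.T_cycl,
                    "units": {n: SERIES_NAMES[n] for n in mset.series},
                    "source_T": mset.source_T,
                },
                fh,
                indent=2,
            )


def spline_series(t, y, periodic=False, period=None):
    """Cubic-spline interpolant with analytic first derivative.

    With periodic=True the series is closed over one cycle (a wrap sample at
    t[0] + period is appended when absent) and value and slope match at the
    cycle boundaries.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size < 4:
        raise ValueError("spline interpolation requires at least 4 samples")
    if periodic:
        if period is None:
            raise ValueError("periodic splines need the cycle duration")
        if not np.isclose(t[-1] - t[0], period):
            t = np.append(t, t[0] + period)
            y = np.append(y, y[0])
        else:
            y = y.copy()
            y[-1] = y[0]
        return CubicSpline(t, y, bc_type="periodic")
    return CubicSpline(t, y)


def normalize_time_axis(
    mset: MeasurementSet,
    target_T_cycl: Optional[float] = None,
    t0_shift: Optional[Dict[str, float]] = None,
) -> MeasurementSet:
    """Rescale every series to a common cycle duration and re-anchor t0.

    Each series' own cycle duration (mset.source_T, defaulting to
    mset.T_cycl) is mapped linearly onto target_T_cycl; a per-series
    circular shift (seconds, the offset of the atrial-contraction onset in
    that series' own clock) re-anchors t = 0.
    """
    target = target_T_cycl if target_T_cycl is not None else mset.T_cycl
    shifts = t0_shift or {}
    out = {}
    for name, (t, y) in mset.series.items():
        src = mset.source_T.get(name, mset.T_cycl)
        if not src > 0:
            raise ValueError(f"unknown source cycle duration for series {name}")
        scale = target / src
        tt = t * scale
        shift = shifts.get(name, 0.0) * scale
        y = np.asarray(y, dtype=float)
        if shift != 0.0:
            tt = np.mod(tt - shift, target)
            order = np.argsort(tt)
            tt, y = tt[order], y[order]
            keep = np.concatenate([[True], np.diff(tt) > 1e-12])  # wrap duplicates
            tt, y = tt[keep], y[keep]
        out[name] = (tt, y.copy())
    return MeasurementSet(series=out, T_cycl=target, source_T={})


def clinical_metrics(volume_series, flow_series=None, T_cycl=None, n_fine=2000) -> ClinicalMetrics:
    """Compute EDV/ESV/SV/EF (and FV/RV/RF when a valve flow is given).

    volume_series: (t [s], V [ml]) of one ventricle over one cycle.
    flow_series: (t [s], q [ml/s]) through its semilunar valve.  The
    retrograde volume RV integrates the negative flow lobe; FV = SV - RV.
    """
    t, V = volume_series
    t = np.asarray(t, dtype=float)
    V = np.asarray(V, dtype=float)
    if t.size == 0:
        raise ValueError("empty volume series")
    EDV, ESV = float(np.max(V)), float(np.min(V))
    SV = EDV - ESV
    EF = 100.0 * SV / EDV
    FV = RV = RF = None
    if flow_series is not None:
        tq, q = flow_series
        tq = np.asarray(tq, dtype=float)
        q = np.asarray(q, dtype=float)
        if tq.size == 0:
            raise ValueError("empty flow series")
        if tq.size >= 4:
            period = T_cycl if T_cycl is not None else tq[-1] - tq[0]
            spl = spline_series(tq, q, periodic=T_cycl is not None, period=period)
            tf = np.linspace(tq[0], tq[0] + period, n_fine)
            qf = spl(tf)
        else:
            tf, qf = tq, q
        RV = float(abs(np.trapezoid(np.minimum(qf, 0.0), tf)))
        FV = SV - RV
        RF = 100.0 * RV / (FV + RV) if (FV + RV) > 0 else 0.0
    return ClinicalMetrics(EDV=EDV, ESV=ESV, SV=SV, EF=EF, FV=FV, RV=RV, RF=RF)


def check_mass_consistency(mset: MeasurementSet, tolerance=0.05, adjust=False):
    """Compare ventricular volume rates against the measured valve outflow.

    Clinical volume and flow series need not satisfy conservation of mass.
    During ejection (outflow above 5% of its peak, inflow valve closed) the
    volume rate should satisfy dV/dt = -q_out; a least-squares factor
    between -q_out and the spline volume rate over that window quantifies
    the inconsistency (factor 1/1.05 for volumes inflated by 5%).  Returns
    a report dict; with adjust=True, inconsistent volume series are
    rescaled by their factor (flow measurements are trusted, volumes
    adjusted) and the adjusted set is attached.
    """
    pairs = {"V_v_l": "q_vout_l", "V_v_r": "q_vout_r"}
    report = {"checked": [], "adjusted": [], "factors": {}, "max_rel_discrepancy": 0.0}
    new_series = {k: (t.copy(), y.copy()) for k, (t, y) in mset.series.items()}
    for vname, qname in pairs.items():
        if vname not in mset.series or qname not in mset.series:
            continue
        tV, V = mset.get(vname)
        tq, q = mset.get(qname)
        v_spl = spline_series(tV, V, periodic=True, period=mset.T_cycl)
        q_spl = spline_series(tq, q, periodic=True, period=mset.T_cycl)
        tf = np.linspace(max(tV[0], tq[0]), max(tV[0], tq[0]) + mset.T_cycl, 2000)
        qf = q_spl(tf)
        window = qf > 0.05 * np.max(qf)
        dVdt = v_spl.derivative()(tf)[window]
        target = -qf[window]
        denom = float(np.dot(dVdt, dVdt))
        factor = float(np.dot(target, dVdt) / denom) if denom > 0 else np.nan
        rel = abs(1.0 - factor)
        report["checked"].append(vname)
        report["factors"][vname] = factor
        report["max_rel_discrepancy"] = max(report["max_rel_discrepancy"], rel)
        if adjust and np.isfinite(factor) and rel > tolerance:
            new_series[vname] = (tV.copy(), V * factor)
            report["adjusted"].append(vname)
    report["consistent"] = report["max_rel_discrepancy"] <= tolerance
    if adjust:
        report["adjusted_set"] = MeasurementSet(
            series=new_series, T_cycl=mset.T_cycl, source_T=dict(mset.source_T)
        )
    return report
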