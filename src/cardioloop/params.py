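"""Parameter containers for the 0D closed-loop model.

All parameters live in the internal mm^3 / kPa / s unit system.  The JSON
representation uses the same key names as the in-memory dataclasses, so a
config file round-trips losslessly.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Dict

CHAMBERS = ("la", "lv", "ra", "rv")
VALVES = ("mit", "aor", "tri", "pul")


class ParameterError(ValueError):
    """Raised when a parameter set violates its invariants."""


@dataclass
class WindkesselParams:
    """3-element arterial and 2-element venous windkessel parameters.

    Compliances C in mm^3/kPa, resistances R and characteristic impedances Z
    in kPa*s/mm^3, for the systemic ("sys") and pulmonary ("pul")
    circulations.
    """

    C_ar_sys: float
    R_ar_sys: float
    Z_ar_sys: float
    C_ven_sys: float
    R_ven_sys: float
    C_ar_pul: float
    R_ar_pul: float
    Z_ar_pul: float
    C_ven_pul: float
    R_ven_pul: float

    def __post_init__(self):
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not (v > 0.0):
                raise ParameterError(f"{f.name} must be strictly positive, got {v!r}")
        # physiological ordering used to sanity-check fits
        if not self.Z_ar_sys < self.R_ar_sys:
            raise ParameterError("Z_ar_sys must be smaller than R_ar_sys")
        if not self.Z_ar_pul < self.R_ar_pul:
            raise ParameterError("Z_ar_pul must be smaller than R_ar_pul")

    def arterial(self, side: str):
        """Return (C, R, Z) of the arterial 3-element windkessel of `side`."""
        if side not in ("sys", "pul"):
            raise ParameterError(f"unknown circulation side {side!r}")
        return (
            getattr(self, f"C_ar_{side}"),
            getattr(self, f"R_ar_{side}"),
            getattr(self, f"Z_ar_{side}"),
        )

    def venous(self, side: str):
        """Return (C, R) of the venous 2-element windkessel of `side`."""
        if side not in ("sys", "pul"):
            raise ParameterError(f"unknown circulation side {side!r}")
        return getattr(self, f"C_ven_{side}"), getattr(self, f"R_ven_{side}")


@dataclass
class ValveParams:
    """Dynamic Bernoulli valve parameters.

    A_eff_min/A_eff_max are the minimum/maximum effective orifice areas in
    mm^2, K_vo/K_vc the opening/closing rate coefficients in 1/(s*kPa),
    l_eff the effective length in mm over which blood accelerates, and rho
    the blood density in kg/mm^3.
    """

    A_eff_min: float
    A_eff_max: float
    K_vo: float
    K_vc: float
    l_eff: float
    rho: float = 1.0e-6

    #: numerical floor applied inside 1/A terms for fully sealing valves
    AREA_FLOOR: float = field(default=1.0e-4, repr=False)

    def __post_init__(self):
        if self.A_eff_min < 0.0 or self.A_eff_max <= 0.0:
            raise ParameterError("effective orifice areas must satisfy 0 <= A_min, 0 < A_max")
        if self.A_eff_min > self.A_eff_max:
            raise ParameterError("A_eff_min must not exceed A_eff_max")
        for name in ("K_vo", "K_vc", "l_eff", "rho"):
            if not (getattr(self, name) > 0.0):
                raise ParameterError(f"{name} must be strictly positive")

    @property
    def area_floor(self) -> float:
        return max(self.A_eff_min, self.AREA_FLOOR)


@dataclass
class ActiveStressParams:
    """Active-stress generation parameters of one chamber.

    sigma_0 is the peak contractility (kPa), alpha_max/alpha_min the upstroke
    and relaxation rates (1/s, alpha_min < 0), t_contr/t_relax the onset times
    of contraction and relaxation within the cycle (s, relative to t0 = onset
    of atrial contraction), K the dimensionless ramp regularization of the
    activation function and T_cycl the cycle duration (s).
    """

    sigma_0: float
    alpha_max: float
    alpha_min: float
    t_contr: float
    t_relax: float
    K: float = 10.0
    T_cycl: float = 0.75

    def __post_init__(self):
        if not self.sigma_0 > 0.0:
            raise ParameterError("sigma_0 must be > 0")
        if not self.alpha_max > 0.0:
            raise ParameterError("alpha_max must be > 0")
        if not self.alpha_min < 0.0:
            raise ParameterError("alpha_min must be < 0")
        if not (self.t_contr < self.t_relax < self.t_contr + self.T_cycl):
            raise ParameterError("need t_contr < t_relax < t_contr + T_cycl")
        if not self.K > 0.0:
            raise ParameterError("K must be > 0")


@dataclass
class ChamberSurrogateParams:
    """0D pressure-volume surrogate law constants of one chamber.

    V_ref is the unloaded reference volume (mm^3) at which the passive
    pressure vanishes, E_pass_a (kPa) and E_pass_b (1/mm^3) the amplitude and
    exponent of the exponential passive pressure-volume relation, and
    wall_factor the dimensionless factor mapping fiber active stress (kPa) to
    chamber pressure (kPa).
    """

    V_ref: float
    E_pass_a: float
    E_pass_b: float
    wall_factor: float

    def __post_init__(self):
        for f in dataclasses.fields(self):
            if not (getattr(self, f.name) > 0.0):
                raise ParameterError(f"{f.name} must be strictly positive")


@dataclass
class CirculationParams:
    """All 0D vascular and valvular parameters of the closed loop."""

    windkessel: WindkesselParams
    valves: Dict[str, ValveParams]

    def __post_init__(self):
        missing = [v for v in VALVES if v not in self.valves]
        if missing:
            raise ParameterError(f"missing valve parameter blocks: {missing}")


@dataclass
class ChamberParams:
    """Per-chamber active-stress and surrogate pressure-volume parameters."""

    active: Dict[str, ActiveStressParams]
    surrogate: Dict[str, ChamberSurrogateParams]

    def __post_init__(self):
        for group, name in ((self.active, "active"), (self.surrogate, "surrogate")):
            missing = [c for c in CHAMBERS if c not in group]
            if missing:
                raise ParameterError(f"missing {name} chamber blocks: {missing}")


# ---------------------------------------------------------------------------
# JSON (de)serialization


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj) if f.repr}
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    return obj


def params_to_dict(obj) -> dict:
    return _to_jsonable(obj)


def windkessel_from_dict(d: dict) -> WindkesselParams:
    return WindkesselParams(**d)


def valve_from_dict(d: dict) -> ValveParams:
    return ValveParams(**d)


def circulation_from_dict(d: dict) -> CirculationParams:
    return CirculationParams(
        windkessel=WindkesselParams(**d["windkessel"]),
        valves={k: ValveParams(**v) for k, v in d["valves"].items()},
    )


def chambers_from_dict(d: dict) -> ChamberParams:
    return ChamberParams(
        active={k: ActiveStressParams(**v) for k, v in d["active"].items()},
        surrogate={k: ChamberSurrogateParams(**v) for k, v in d["surrogate"].items()},
    )


def save_params(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {"_units": "mm^3 / kPa / s (areas mm^2, rates 1/(s kPa))", **params_to_dict(obj)},
            fh,
            indent=2,
        )


def load_circulation(path) -> CirculationParams:
    with open(path) as fh:
        d = json.load(fh)
    d.pop("_units", None)
    return circulation_from_dict(d)
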