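"""Unit conventions.

The model works internally in a fixed mm^3 / kPa / s system: volumes in mm^3,
flows in mm^3/s, pressures in kPa, resistances in kPa*s/mm^3, compliances in
mm^3/kPa.  Clinical quantities (measurements, metrics) use ml and ml/s; the
conversion happens only at I/O boundaries.
"""

MM3_PER_ML = 1000.0
KPA_PER_MMHG = 0.133322

#: unit strings accepted by the measurement reader, mapped to the factor that
#: converts them to the canonical measurement units (kPa, ml/s, ml, s)
UNIT_FACTORS = {
    "kPa": 1.0,
    "mmHg": KPA_PER_MMHG,
    "ml/s": 1.0,
    "ml s^-1": 1.0,
    "mm^3/s": 1.0 / MM3_PER_ML,
    "mm3/s": 1.0 / MM3_PER_ML,
    "ml": 1.0,
    "mm^3": 1.0 / MM3_PER_ML,
    "mm3": 1.0 / MM3_PER_ML,
    "s": 1.0,
}


def ml_to_mm3(v):
    return v * MM3_PER_ML


def mm3_to_ml(v):
    return v / MM3_PER_ML
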