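"""Identify arterial windkessel parameters from synthetic measurements.

Measurements are synthesized from the converged scenario at the clinical
acquisition rates (catheter-rate pressures, 30 flow samples per cycle).
The arterial subproblem drives the eliminated-flow pressure ODE with the
measured venous pressure and valve flow and matches four features of the
arterial pressure; the venous parameters then follow from the dependency
rules (systemic: R/10 and 30C; pulmonary: R and 2.5C).
"""
import cardioloop as cl
from cardioloop.inverse import fit_arterial_windkessel, venous_from_arterial

scenario = cl.make_tof_scenario()
traj, _ = cl.run_to_periodic(scenario, eps_cycl=1e-3, max_cycles=40)
mset = cl.synthesize_measurements(traj, scenario.T_cycl, noise=None, seed=1)

for side in ("sys", "pul"):
    C_true, R_true, Z_true = scenario.circulation.windkessel.arterial(side)
    res = fit_arterial_windkessel(mset, side=side)
    R_ven, C_ven = venous_from_arterial(side, res.R_ar, res.C_ar)
    print(f"[{side}] objective {res.objective:.2e} after {res.n_evals} evaluations")
    print(f"  R_ar  {res.R_ar:.3e}  (truth {R_true:.3e},  {100*abs(res.R_ar-R_true)/R_true:.2f}% off)")
    print(f"  C_ar  {res.C_ar:.0f}      (truth {C_true:.0f},  {100*abs(res.C_ar-C_true)/C_true:.2f}% off)")
    print(f"  Z_ar  {res.Z_ar:.3e}  (truth {Z_true:.3e},  {100*abs(res.Z_ar-Z_true)/Z_true:.2f}% off)")
    print(f"  derived venous: R_ven {R_ven:.3e}, C_ven {C_ven:.0f}  [mm^3/kPa/s units]")
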