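"""End-to-end synthetic twin experiment.

A ground-truth regurgitant scenario is simulated to its periodic state;
measurements are synthesized at the clinical acquisition rates; every
independently identifiable parameter (arterial windkessels, venous
dependency rules, semilunar-valve orifice areas, per-chamber active-stress
parameters) is then re-identified from those measurements alone, and the
valve-replacement outcome is predicted with the calibrated model.
"""
import json

import cardioloop as cl

report = cl.run_twin_experiment(seed=0, noise="none")

print("stage summary:")
for stage, info in report["stages"].items():
    if stage == "replacement":
        continue
    print(f"  {stage}: " + json.dumps({k: v for k, v in info.items()
                                       if k in ("converged", "objective", "objective_ml2", "E_cycl")},
                                      default=float))
print("\nrecovery error per identified parameter (|fit-truth|/|truth|):")
for name, err in sorted(report["recovery"].items(), key=lambda kv: -kv[1]):
    print(f"  {name:16s} {100*err:6.2f} %")
print(f"\nworst recovery: {100*report['max_recovery_error']:.2f} %")
post = report["stages"]["replacement"]["outcome"]
print(f"predicted postoperative pulmonary RF: "
      f"{post['predicted_postoperative']['right']['RF']:.2f} %")
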