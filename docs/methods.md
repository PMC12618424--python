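# Methods

## Model structure

The closed loop couples, per side of the heart: an atrium, an
atrioventricular valve, a ventricle, a semilunar valve, a 3-element
arterial windkessel (compliance C, peripheral resistance R, characteristic
impedance Z) and a 2-element venous windkessel (C, R).  The state vector
holds 20 circulation variables (chamber and compartment pressures, valve
flows and opening states, compartment flows), the four chamber volumes and
the four active fiber stresses — 28 unknowns.  All internal quantities use
a fixed mm³/kPa/s unit system; millilitres appear only at I/O boundaries
(measurements, metrics).

Valves follow the dynamic Bernoulli law with a pressure-driven opening
state ζ ∈ [0, 1]; the q|q| form preserves the flow sign so that a nonzero
minimum effective orifice area produces sustained diastolic backward flow.
Inside 1/A terms the effective area is floored at max(A_eff,min, 10⁻⁴ mm²)
so a fully sealing valve keeps a finite Jacobian.  Poiseuille-type viscous
losses are neglected; the model is therefore not suitable for strongly
stenotic valves.

### Chamber surrogate

The heart chambers are 0D: each combines an exponential passive
end-diastolic pressure–volume relation, `p_pass = E_a (exp(E_b (V −
V_ref)) − 1)`, with an elastance-like active term linear in the fiber
stress, `p_act = wall_factor · τ_a · V/V_ref`.  The surrogate is strictly
increasing in both V and τ_a, C¹ on V > 0, vanishes at (V_ref, 0), and its
active pressure vanishes as V → 0, which mimics the loss of pressure
generation of a collapsing chamber and keeps emptying self-limiting (a
Laplace-type 1/r law, by contrast, lets a strongly activated atrium pump
itself empty).  `wall_factor` maps peak fiber stress (kPa) to peak chamber
pressure and plays the role the wall geometry plays in a
spatially resolved model; σ₀, α_max, α_min keep their meaning as
contractility and activation rates and remain identifiable from volume
curves.  The passive exponent is capped (linear C¹ continuation beyond
e²⁵) purely as an overflow guard far outside the physiological range.

### Activation

The normalized activation is a trapezoid: linear ramp of width 1/K up to
c₁, plateau to c₂, ramp down over 1/K, with c₁/c₂ offset from the
contraction/relaxation onsets by α_max/(K(α_max − α_min)) and K = 10.  The
function is evaluated periodically (ramps may wrap the cycle boundary —
the atrial upstroke begins before t₀).  Because c₁ and c₂ depend on the
rates, the parameter sensitivities of the activation include the ramp
shifts; the adjoint uses one-sided derivatives at the (measure-zero) kink
points.

## Discretization and solver

One-Step-θ, θ = 0.5 (trapezoidal) by default: time derivatives become
difference quotients, all other terms are θ-weighted between time levels,
including the algebraic rows (windkessel momentum balances, chamber
pressure closures).  θ-weighted algebraic constraints are only safe when
the initial state satisfies them — otherwise the constraint error
oscillates undamped at θ = 0.5 — so the initial-state builder solves the
algebraic relations (chamber pressures from the surrogate law, compartment
flows from the momentum balances) before time stepping begins.

Each step solves the stacked 28-equation residual with a damped Newton
method: analytic Jacobian, ∞-norm convergence test on a diagonally scaled
residual (tolerance 10⁻⁸), at most 25 iterations, up to 4 step halvings,
valve branch selection by the current iterate's Δp sign.  A
numba-compiled kernel mirrors the pure-Python assembly exactly (an
equivalence test keeps them in lockstep) and provides a ~10× speedup; the
Python path remains the readable reference and the fallback.

The per-step linear algebra is dense 28×28.  Default dt = 10⁻³ s (750
steps per 0.75 s cycle).  Total blood volume — chamber volumes plus the
compartment stored volumes C_ar (p_ar − Z_ar q_valve) and C_ven p_ven — is
conserved exactly by construction (the mass-type rows telescope), which
the tests verify to 10⁻⁸ relative over a cycle.

In the standalone valve integrator (the open-loop forward problem of the
valve fit), a nearly sealed orifice makes the Bernoulli term stiff: its
relaxation time 2 l_eff A/|q| can drop far below dt, where the trapezoidal
rule is not L-stable and rings at sustained amplitude.  Such steps fall
back to implicit Euler, which lands on the quasi-steady orifice flow.

### Periodicity

The cycle repeats with initial conditions from the previous cycle's last
step until E_cycl ≤ ε_cycl = 0.04, where E_cycl is the maximum relative
change over one cycle of the four compartment pressures, both ventricular
volumes and both atrial volumes.  (A flag restores the literal published
set, which lists the right atrium twice and omits the left.)  In a
severely regurgitant state the pulmonary-artery pressure at end-diastole
is small, which makes its relative change a demanding periodicity monitor;
the default scenario's initial conditions are placed near the periodic
state so the criterion is met within a few cycles.

## Measurements

Measured series live in clinical units on their own time grids: chamber
volumes at 25 equidistant points per cycle (cine MRI), semilunar-valve
flows at 30 points (phase-contrast MRI), pressures at catheter rate
(1 kHz).  Cubic splines (periodic over the cycle where appropriate)
provide C² interpolants with analytic derivatives.  Time-axis
normalization rescales each series' own cycle duration to a common target
and circularly shifts t₀ to the onset of atrial contraction.  A
mass-consistency check regresses dV/dt against −q_out during ejection and
can rescale volume series to the flow measurement (flows are trusted,
volumes adjusted).

Clinical metrics: EDV = max V, ESV = min V, SV = EDV − ESV,
EF = 100·SV/EDV; the retrograde volume RV integrates the negative flow
lobe, FV is defined as SV − RV so that FV + RV = SV, and
RF = 100·RV/(FV + RV).  This convention reproduces the published
preoperative and postoperative table rows arithmetically.

## Inverse subproblems

**Arterial windkessel.**  The flow variable is eliminated, leaving one
scalar pressure ODE driven by splines of the measured venous pressure and
valve flow, with the measured arterial pressure as initial condition; the
One-Step-θ form of this ODE is algebraically identical to the discretized
mass/momentum pair (verified to 10⁻⁸).  The objective holds four
normalized features: pressure maximum, minimum, end-of-cycle value, and
maximum systolic pressure rate.  Two operational choices matter:

* *Common feature representation.*  The computed pressure can only carry
  the temporal detail that the splined 30-sample flow forcing resolves, so
  the features of both the measured and the computed pressure are read off
  a common cubic-spline representation with half the flow sample count of
  knots (densely sampled series are averaged over a short window around
  each knot).  Comparing features of the raw catheter-rate measurement
  against a flow-band-limited model systematically biases C and Z.
* *Plausibility box.*  The fit runs in log-space (positivity) with R and C
  confined within a factor 50 of an Ohmic/decay-based initial estimate and
  Z/R ≤ 0.35 (characteristic impedance is a small fraction of the
  peripheral resistance; the published values are 0.09 and 0.18).  Without
  the box, noisy feature sets are absorbed by a degenerate family in which
  a near-frozen compliance lets the pressure track Z·q̃.

Venous parameters are not identified; they follow the dependency rules
R_ven = R_ar/10 and C_ven = 30 C_ar (systemic), R_ven = R_ar and
C_ven = 2.5 C_ar (pulmonary).

**Valve orifice areas.**  The valve ODEs are marched under the measured
transvalvular gradient; squared mismatches of cycle-integrated forward and
backward volumes (positive magnitudes; the squares make the sign
convention immaterial) are minimized over log-areas with restarts.  The
opening state at t₀ is warm-started at its periodic value — it depends
only on the measured gradient — because in severe regurgitation the valve
is *open* at end-diastole (the backward jet decelerates against a forward
gradient) and a closed-valve initial condition misrepresents the first
systole.  Atrioventricular valves are not fitted: their maximum areas come
from imaging-based geometric orifice areas, minimum areas are zero/floored.

**Active stress.**  Twelve parameters (σ₀, α_max, α_min for RV, LV, RA,
LA) minimize squared volume mismatches at the measured time points that
fall inside each chamber's contraction/relaxation window
[t_contr − 1/K, t_relax + 2/K], taken periodically (the atrial window
wraps t₀).  The forward problem is the full closed loop; gradients come
from a discrete (discretize-then-differentiate) adjoint — one backward
sweep of the transposed step Jacobians — which matches central finite
differences to ~10⁻⁷ relative and costs about one forward solve.
Optimization is L-BFGS over bounded log-magnitudes (signs fixed by the
physiology: σ₀, α_max > 0, α_min < 0; magnitudes within a factor 5 of the
initial guess), restarted with updated initial conditions every N_f = 15
forward evaluations per the periodicity-gated loop.  Two refinements to
that loop: once the initial conditions are stationary (E_cycl ≤ ε_cycl/2)
the block length is extended tenfold, because restarts then reset the
L-BFGS memory without compensating benefit; and the convergence gate
(f_τ ≤ ε_sc and E_cycl ≤ ε_cycl) additionally requires the descent to have
finished, so a quickly reachable threshold cannot cut the optimization
short.  A stagnation guard stops the loop when the threshold is
unreachable (model-error floor).

The threshold ε_sc = avg_error² × n_points should reflect the data
quality: the reference choice is 0.5 ml over 18 points (4.5 ml²); the
noiseless verification twin uses 0.02 ml (the interpolation-level model
error of the decomposed pipeline), the default-noise twin uses the
volume-noise level (2 ml).  Pushing the objective below the
appropriate floor makes the fit absorb model or measurement error into the
weakly identified parameters.

## Synthetic scenario and twin experiments

The default scenario uses the published patient-scale circulation values
(windkessel and valve parameters, blood density 10⁻⁶ kg/mm³), the
published active-stress parameters and timing (atrial contraction at t₀,
ventricular at t₀ + 0.1425 s, relaxation onsets 0.1425 s/0.4275 s, T_cycl
= 0.75 s), and surrogate constants chosen once so the converged loop shows
a ToF-like state: pulmonary regurgitation fraction ≈ 59%, regurgitant
volume ≈ 39–43 ml/cycle, right ventricular EDV ≈ 180 ml at EF ≈ 37%
against a left EDV ≈ 70 ml, LV systolic pressure ≈ 13.6 kPa, RV systolic
pressure ≈ 3.1–3.5 kPa.  The right-ventricular systolic pressure is set by
the pulmonary windkessel afterload and is therefore lower than the
markedly hypertensive right ventricle seen clinically in this disease;
reproducing that feature would require a residual outflow-tract
obstruction that the scenario deliberately omits.

Measurement synthesis samples the converged cycle at the clinical rates
and adds independent Gaussian noise (defaults: 2% pressures, 3% of peak
for flows, 2 ml volumes); optional per-series cycle-duration jitter and
t₀ shifts exercise the time-axis normalization.  All randomness flows
through one seeded generator.

What the twins show — and their limits.  The noiseless twin recovers every
independently identified parameter within ~2%; a small joint (monolithic)
fit of the pulmonary windkessel + valve reaches the same parameters as the
decomposed subproblems within 2%.  Under the default noise the robustly
identified quantities are the arterial resistances, the orifice areas and
left-ventricular contractility (all within 10%); atrial contractility is
noise-limited (a ±5% change of σ₀ of the left atrium moves the volume
objective by ~9 ml² against a χ² fluctuation of ~47 ml², i.e. its 1σ
identification uncertainty already exceeds 10%), and the atrial rate
parameters more so.  Synthetic twins share the model with the estimator,
so these results bound what real data could give from below: real
measurements add physiological variability, model discrepancy and
non-simultaneous acquisition beyond the emulated effects.

## Valve replacement prediction

The intervention sets the pulmonary A_eff,min to zero (non-leaky
prosthesis), leaves every other parameter unaltered, and reruns the loop
from the preoperative periodic state until a new periodic state is
reached; the cycle-by-cycle snapshots trace the transient adaptation.  The
predicted direction — regurgitation eliminated, right-ventricular EDV
down, left-sided stroke volume and net cardiac output up — is a
consequence of closed-loop mass conservation once the regurgitant shuttle
volume is removed.  Long-term remodeling is outside the model, so
measured postoperative values months later are expected to deviate; the
outcome table accepts an optional user-supplied postoperative block for
display but computes nothing for it.

## Problem sizes and defaults

dt = 1 ms, 750 steps/cycle; periodicity tolerance 0.04 (twin ground truth
generated at 10⁻³); Newton tolerance 10⁻⁸; N_f = 15; twin experiment ≈ 1–2
minutes on one CPU core.  All tolerances above are package defaults and
exposed as arguments.

## Known limitations

* The chamber surrogate is a two-term 0D law: no regional mechanics, no
  fiber fields, no pericardial constraint; passive constants and
  reference volumes are scenario inputs, not identified.
* Timing parameters (t_contr, t_relax, T_cycl) are user inputs, as from
  ECG, and are not identified.
* The windkessel feature objective identifies C to a few percent at
  clinical sampling rates; its bias is dominated by what the 30-sample
  flow spline misses at the systolic upstroke.
* No inductances, no wave propagation, no viscous valve losses, no growth
  or remodeling.
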