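# Methods

## The circuit model

`bgtremor` simulates a system-level loop of six neural populations —
primary motor cortex (M1), thalamus (Thal), dorsal raphe nucleus (DRN),
substantia nigra pars compacta (SNc) and the striatal direct (DP) and
indirect (IP) pathways — together with striatal serotonin (5-HT) and
dopamine (DA) concentrations.  The state is eight-dimensional; firing
rates are in Hz, concentrations in nM.  The dynamics are linear
first-order kinetics (constant external drives, linear inter-area gains,
linear decay) with two exceptions:

* **DA release** is the product `G * 5HT * SNc`: serotonin scales the
  dopamine output of the nigral population.
* **The indirect pathway** carries a pathological oscillation
  `alphaIP * sin(fIP * t) / max(DA, 1e-3)`: dopamine *suppresses* the
  GPe–STN oscillation, so dopamine loss amplifies it.  The `1e-3` nM
  floor guards the denominator; the division form is required for the
  directionality of every simulated effect (lesions that lower DA must
  raise the oscillation, treatments that restore DA must quiet it).

Sign structure of the connections: Thal excites M1; DP excites and IP
inhibits Thal; M1 inhibits DRN (via cortical intermediaries) and SNc
excites it weakly; DRN releases 5-HT and inhibits SNc; DA excites DP and
inhibits IP's oscillatory component.  This yields the serotonergic
compensation chain: a dopaminergic lesion lowers SNc → DA → DP → Thal →
M1, the reduced cortical inhibition raises DRN → 5-HT, and the extra
serotonin partially restores DA.

### Integration

Fixed-step explicit Euler with `dt = 0.1` s over a 300-s horizon is the
default; a classical RK4 stepper is available via
`SimulationConfig(method="rk4")`.  Both steppers are exercised by the
test suite.  The integrator is vectorised over a batch axis so cohorts
and GA populations integrate in one pass.  Any state exceeding `1e9` in
magnitude aborts that batch member with a diagnostic naming the variable
and time; in cohort runs failures are recorded per subject without
aborting the rest.  State variables are not clamped at zero by default
(the equations do not prescribe it); `clamp_nonnegative=True` enables a
floor at zero.

Lesions and drug doses are `Intervention`s: at the first step at or
after the intervention time the named parameter is multiplied by the
given factor, composing multiplicatively with earlier interventions on
the same parameter.  The trajectory before the intervention time is
bit-identical to the unlesioned run.

### Steady states

`steady_state` integrates the healthy model and compares means over
consecutive non-overlapping trailing windows, declaring convergence when
every variable's relative change drops below `1e-4`.  A plain fixed
window cannot reach that tolerance: the sinusoidal IP component leaves a
partial-period residue of order `amplitude x (partial cycle)/window`
(~0.5% for visible oscillation).  The window is therefore stretched from
its 10-s minimum to the sample count in [10 s, 20 s] whose span is
closest to a whole number of forcing periods, which suppresses the
residue by several orders of magnitude.  The same windowing is used
inside the calibration fitness so the two agree.

## Parameter calibration

The published coefficient table is not consistent with the published
reference steady states under these equations: the residuals at the
reference point are large (e.g. the analytic IP mean `a8Ex/tauIP` is
~1.09 Hz against a reference of 1.88 Hz) and the published vector's own
fixed point has negative DA, which under the guarded division term makes
the integration blow up.  The package therefore treats the published
vector as the *search seed*, not the operating point, and recalibrates —
`CALIBRATED_PARAMS` ships the result of `run_ga()` with all defaults
(seed 0) and can be regenerated with `bgtremor calibrate`.

The genetic algorithm is generational: population 30, up to 300
generations, tournament selection (size 3), BLX-0.5 crossover, per-gene
Gaussian mutation, elitism 2.  Genes live in log-space (bounds 0.2x–5x
the published values are symmetric there and positivity is automatic).
Mutation is two-scale: the fine scale starts at 5% of the log-range and
anneals by 0.98 per generation so late generations refine the fit to
sub-percent precision, while 3% of mutations keep the full width; if the
best score stagnates for 15 generations the heavy fraction rises to 30%
until improvement resumes.  These choices were driven by convergence
robustness across seeds; all are exposed on `GAConfig`.

Fitness has three components:

* `meanAPE` — mean absolute percentage error of the simulated steady
  state against the eight reference values (minimised);
* `meanPhys` — half peak-to-peak amplitude of the detrended DA series of
  the healthy model over the trailing 50 s of an 130-s evaluation run
  (minimised);
* `meanPark` — the same amplitude under the mild dopaminergic lesion
  (tauSNc +25%, alphaIP +11%, applied from t = 0) (maximised).

The aggregate is the equal-weight mean of `1 - meanAPE`, `1 - meanPhys`
and the saturating reward `min(meanPark/0.005, 1)`, with the reward
additionally gated by fit quality (`clip(1 - meanAPE/0.05, 0, 1)`): a
model with wrong steady states earns no oscillation credit.  Without
the gate the search reproducibly locks onto oscillation-rich but badly
fitted local optima.  Candidates are evaluated under non-negativity
clamping so that far-from-fit vectors (whose unclamped dynamics diverge)
keep finite, smoothly degrading fitness; a penalty on the fraction of
clamped samples makes the optimum clamp-free, so the winning vector
behaves identically under the unclamped default integrator.  Candidates
that overflow even when clamped rank below every finite candidate,
graded by survival time.  An optional proximity regulariser
(`seed_penalty`) penalises log-distance from the seed vector.

Because the oscillation objectives reward transmission of the IP
rhythm into DA, the calibrated optimum settles at a lower oscillation
frequency than the published `fIP` (the loop attenuates high frequencies
strongly); the steady states are unaffected (the sinusoid averages out)
but the simulated tremor ends up slower than the published ~1 Hz.

## The two-link arm

The arm is a planar shoulder–elbow linkage in a horizontal (gravity-free)
workspace, anchored at the origin: standard rigid-body dynamics
`M(q) q'' + C(q, q') q' = T` with link constants from canonical
human-arm values (upper arm 0.30 m / 1.9 kg, forearm 0.35 m / 1.1 kg,
COM at mid-link, slender-rod inertias); exact constants only scale the
tremor amplitude smoothly and are swappable on `ArmParameters`.  Joint
limits (shoulder [-60°, 150°], elbow [0°, 180°]) are enforced by
clamping the angle and zeroing the outward velocity component.

Torques come from a PD controller `T = Kp(A_des - A_cur) - Kd A'_cur`
with gains Kp = (20, 10) Nm/rad, Kd = (1.5, 1.0) Nm s/rad.  Integration
is classical RK4 at `dt = 0.01` s with the feedback torque re-evaluated
at every stage state, preserving fourth order for the closed loop (the
suite checks the ~16x error reduction under step halving).

The desired angles are an affine image of the scalar M1 trace: the
minimum of the trace over the *whole* experiment maps to the lower joint
limits and the maximum to the upper limits, the same signal driving both
joints; the M1 command is held piecewise-constant (zero-order hold) on
the arm grid.  Absolute endpoint amplitudes in metres therefore depend
directly on this scaling convention — ratios between conditions are the
robust quantity.

**Tremor amplitude** over a window: endpoint samples are centred on the
window mean and projected onto their first principal axis; cycles are
delimited by every second zero-crossing of this signed displacement; the
amplitude is half the mean per-cycle peak-to-peak excursion (a pure
sinusoid of amplitude A reports A).  Fewer than two detected cycles
report 0 with a warning.  The metric is invariant under rigid
translation and rotation and scales linearly with the displacement.

## Cohorts and scenarios

A cohort has `n` subjects (default 20).  Subject *i* receives additive
zero-mean Gaussian noise on every parameter and every initial state
value with SD = `s_i` x the base value, `s_i` evenly spaced from 0.01
(subject 1) to 0.02 (subject `n`); draws that would turn a quantity
non-positive are resampled.  (The even spacing honours the stated
endpoints; a fixed step of 0.0005 cannot reach 0.02 at subject 20.)
Subjects are deterministic given the master seed and index.

Scenario presets, all on a 300-s horizon with condition boundaries at
75/125/175/225 s:

| preset | interventions | conditions |
| --- | --- | --- |
| `snc-lesion` | 75 s: tauSNc x1.25, alphaIP x1.11 | HEALTH, LESION |
| `drn-damage` | tauDRN -> 1.4/1.6/1.8x baseline at 75/125/175 s | HEALTH, DAMAGE1–3 |
| `ssri` | 75 s: tauSNc x1.70, alphaIP x4.33; tau5HT -> 0.8/0.7/0.6x baseline at 125/175/225 s | HEALTH, SNC_DAMAGE, TRMT1–3 |

Damage and dose multipliers are *baseline-relative* (an intervention
composes on the running value, so the scenario builder emits the
incremental ratio).  Per condition the summary reports the DA mean over
the window excluding its first 10 s (so values reflect quasi-steady
behaviour) and the tremor amplitude of the continuously simulated arm
over the same clipped window.  Repeated-measures hypothesis tests are
delegated to pingouin via `repeated_measures_anova` and are not part of
the acceptance surface.

## What the synthetic cohort does and does not capture

The noise model perturbs parameters and initial conditions once per
subject; there is no within-run stochasticity, no measurement noise and
no inter-subject variation of the arm or controller.  Passing cohort
tests therefore demonstrates the deterministic dose–response structure
of the model under small parametric spread — not robustness to
physiological noise sources the model does not represent.  Because the
equations had to be recalibrated (see above), quantitative responses to
*large* parameter changes (deep damage levels, strong lesions) can
deviate from the originally reported values by more than the cohort
spread, and the known deviations are asserted honestly in the acceptance
suite rather than hidden.

## Numerical choices and degenerate inputs

* `EPSILON_DA = 1e-3` nM floors the oscillation denominator.
* Overflow guard `1e9` on every state variable.
* Parameters must be finite and non-negative; zero is allowed so that
  degenerate configurations (zero drives, silenced oscillator, frozen
  couplings) used in analysis remain expressible.
* `duration/dt` must be integral; trajectories have `n+1` samples.
* A constant M1 trace makes the affine angle map undefined and is
  rejected.
* Reference steady states must be nonzero for `meanAPE` to exist.
* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); identical seeds give bit-identical
  trajectories, cohorts and GA runs.

## Problem sizes

Default problem sizes are those of the experiments themselves: 300-s
circuit runs at dt = 0.1 (3000 steps), 300-s arm runs at dt = 0.01
(30 000 steps), 20-subject cohorts and a 30 x 300 GA budget.  Unit tests
use the same operators on shorter horizons and smaller cohorts; the
acceptance suite runs the full sizes.

## Known limitations

* The printed-parameter inconsistency means the package's calibrated
  operating point is *a* solution of an underdetermined inverse problem
  (24 parameters, 8 steady-state constraints plus two scalar oscillation
  objectives), not *the* original one; responses to strong perturbations
  inherit that uncertainty.
* Tremor amplitude in metres is convention-dependent through the
  M1-to-angle scaling (see above).
* No receptor pharmacokinetics, no spiking dynamics, no 3-D kinematics,
  no muscle model.
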