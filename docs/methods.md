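# Methods

`bcisim` simulates a closed-loop intracortical brain–computer interface (BCI)
controlling three-dimensional arm reaches. One simulated reach couples four
components in a loop running at a fixed 30 ms step:

1. a **multiple-submovement controller** that commands position, velocity,
   acceleration and goal trajectories;
2. a **neural encoder** that converts the commanded state into noisy firing
   rates of position-, velocity-, and goal-tuned neurons;
3. a **goal-augmented Extended Kalman Filter (EKF)** that decodes the rates
   back into a 12-dimensional state estimate; and
4. the feedback path: the decoded state is returned to the controller, which
   corrects its commands accordingly.

Performance is scored post-hoc with the **Minimum Attainable Target Radius
(MATR)**: the smallest target radius within which the decoded position dwells
continuously for 1 s.

## Submovement model

Reaching commands are a linear superposition of discrete minimum-jerk
submovements. Submovement *i* with onset `t0`, duration `td` and 3D amplitude
`d` contributes the quintic position profile
`d · (6τ⁵ − 15τ⁴ + 10τ³)`, `τ = (t − t0)/td`, which is zero before onset and
holds at `d` after completion; velocity and acceleration are its analytic
derivatives (zero at both endpoints). The commanded position is the start
position plus the sum of all profiles; the commanded goal is the start
position plus the amplitudes of all submovements launched so far, so it is
piecewise constant and jumps at onsets. Commanded position and goal are
clamped into an axis-aligned workspace box; velocity and acceleration are
left unclamped because they are analytic derivatives of the unclamped
profile and clipping them would produce kinematically inconsistent commands.

## Controller

The controller is a rule-based error-correcting policy with the same
inputs and outputs as a learned submovement predictor (an adapter lets a
learned trigger/planner pair be substituted). At each step it forms the
predicted miss of the *decoded* position once all in-flight submovements
finish,

    error = target − (decoded_pos + (commanded_endpoint − commanded_pos)),

where `commanded_endpoint = start + Σ dᵢ`. Under ideal feedback
(decoded ≡ commanded) this reduces to `target − commanded_endpoint`. A new
submovement launches when the reach starts, and afterwards whenever the
error norm exceeds a 1 cm threshold and at least 0.15 s (the refractory
period) has passed since the last onset. Corrections deliberately undershoot:
the amplitude is 0.9 × error, mirroring the undershoot-then-correct character
of natural reaches, and the duration grows with amplitude
(0.35 s + 0.01 s/cm, clipped to [0.2, 1.5] s). Stop-rule presets:
short reaches (3 s or 30 submovements) and long reaches (30 s or 300
submovements). When the submovement budget is exhausted the simulation stops,
but never before the 2 s minimum the dwell metric needs.

The open-loop baseline (`constant` controller) pins the commanded position
and goal at the target with zero velocity and acceleration; constant
commanded velocities cannot reach a target and are not simulated.

## Neural encoder

Three tuning families are modelled on the commanded state:

* **Cosine (linear) tuning** of position, velocity, or goal:
  `f = f_base (1 + f_depth · p̂ · x)` with preferred direction `p̂` given by
  spherical angles. The same form serves position-only, velocity-only and
  linearly goal-tuned (premotor-like) cells.
* **Joint position+velocity tuning**: the sum of one position and one
  velocity cosine component, with the overall baseline corrected to the mean
  of the two component baselines.
* **Gaussian goal tuning** (parietal-like spatial receptive fields):
  `f = f_min + f_amp · exp(−‖goal − q_pos‖² / (2 q_std²))` with floor 0 Hz,
  amplitude 100 Hz, preferred location uniform in the workspace, and tuning
  widths of 10–40 cm.

Nominal rates pass through a fixed generalized-logistic saturation
`g(x) = 150 / (1 + 9.305 e^{−0.01602 (x+190)})^{6.015}` that maps large
negative nominal rates to ~0 Hz and large positive ones to 150 Hz while
leaving moderate rates nearly unchanged (g(50) ≈ 50 Hz); one curve serves
all neurons. Spiking noise then acts on the saturated rate over each 30 ms
bin: half the neurons emit Poisson counts, the other half a normal
approximation with Fano factor 1 truncated at zero counts; observed rate =
count / bin width.

Mixed "M1" populations are split 50% velocity-only, 37% position+velocity,
13% position-only (largest-remainder rounding; remainder ties resolved in
that order). Preferred directions are area-uniform on the sphere
(cos θ ~ U(−1,1)). Baselines are exponential (mean 10 Hz) and tuning depths
gamma (shape 2, mean 0.1 per cm or per cm/s). The depth default makes a
30 cm or 30 cm/s excursion modulate the rate by ~3× baseline — tens of Hz at
naturalistic reach speeds, consistent with strongly modulated motor-cortical
cells and large enough that a single 30 ms spike count carries usable
kinematic information; with substantially shallower depths the modulation
drowns in Poisson noise and velocity ensembles lose their characteristic
advantage. All of these distributions are configurable (`EnsembleParams`),
and an ensemble serializes to JSON so any run can be replayed exactly.

## Decoder

The EKF state is `[position, velocity, acceleration, goal]` (12-D, cm-based
units). The **trajectory model** `s_{t+1} = A s_t + w`, `w ~ N(0, W)`, is fit
by ridge-stabilized least squares (ridge 1e-8) to a synthetic training set:
controller-driven point-to-point reaches to the task's target set under
ideal feedback, with the goal component equal to the running submovement
endpoint. Two details matter for a well-behaved filter:

* training traces are truncated ~0.33 s after the movement ends, so parked
  samples do not dominate the regression;
* small kinematic variability (std 0.1 cm position, 1 cm/s velocity,
  10 cm/s² acceleration, 0.5 cm goal) is added, standing in for the
  measurement and submovement-decomposition noise of recorded reaches. A
  perfectly noiseless training set yields exactly zero position/velocity
  residuals, i.e. a degenerate `W` whose filter cannot track velocity
  transients at all — closed-loop runs then wind up against the workspace
  boundary.

`W` is the maximum-likelihood covariance of the fit residuals. The
**measurement model is the encoder itself** (the ideal-decoder assumption):
expected rates are the saturated tuning curves at the state mean, with the
Jacobian computed analytically (saturation chain rule; Gaussian goal
gradient). The measurement-noise covariance `R` is diagonal and
state-dependent, re-evaluated at each predicted mean as the generative
variance of a rate estimate from one count bin: `max(rate, 1 Hz)/dt`, scaled
by the Fano factor for normal-noise neurons; the 1 Hz floor prevents silent
neurons from claiming infinite precision. Updates use the Joseph-stabilized
covariance form with symmetrization each step, which keeps the covariance
positive semi-definite through thousands of cycles despite the saturating
nonlinearity.

Initialization: position = known start (per-axis variance 0.001), velocity
and acceleration = 0 (variance 0.001), goal mean = workspace origin (the
target-volume centroid) with per-axis variance 1000 — effectively flat over
the workspace, so the precise prior mean is inconsequential.

## Task geometry

The target volume is a 50 × 30 × 25 cm box centred on the origin; the start
position (0, −25, −37.5) cm lies below and behind it, emulating a reach
outward from an armrest. Commands are clamped to a workspace box
(60 × 50 × 65 cm) containing both. Targets are drawn by stratified random
sampling (ceil(n/3) slabs along the long axis, three draws per slab); the
default 33-target set has start-to-target distances with mean ≈ 48 cm
spanning roughly 28–69 cm. One fixed-seed target set is reused across all
parameter combinations of an analysis.

## Metrics

On the 30 ms grid the MATR is the minimum over admissible window centres of
the within-window maximum of the distance from decoded position to target.
Window membership is closed (samples at exactly ±0.5 s are included; the
half-width in samples is floored when the dwell does not divide the grid).
Admissible centres exclude the first and last half second of the simulation.
MATR-T averages the MATR over targets; MATR-TP additionally averages over
neuron parameter sets, with a Student-t 95% confidence interval across
parameter sets. Movement time for a given radius is the earliest dwell-window
*start* whose window stays inside the radius (the dwell itself is excluded
from the reported time); radii a trace never attains are excluded and
counted. The distance dependence of performance is summarized by an OLS
regression of per-target MATR (averaged over parameter sets) on the target's
distance from the origin, with a two-sided p-value for zero slope.

## Analyses

* **Analysis 1** crosses the number of goal-tuned neurons with the number of
  M1 neurons (each 0–50) on short reaches (3 s / 30 submovements), Gaussian
  and linear goal tuning simulated separately.
* **Analysis 2** compares 50-neuron single-kind populations — position-only,
  velocity-only, linear goal, Gaussian goal at 10/20/30/40 cm widths — on
  long reaches, under the submovement controller and under the constant
  command (except velocity).

Per-parameter-set and per-cell random streams are spawned from a single
`SeedSequence`, so every row of a results table is reproducible in isolation
and a fixed seed makes whole runs bit-identical.

### Problem sizes used by the shipped checks

The test suite reproduces the qualitative findings at reduced scale, chosen
as the smallest conditions under which the orderings are stable: the
neuron-count sweep uses counts {0, 5, 15, 30, 50} with 10 targets × 4
parameter sets at 3 s; the per-type comparison uses 10 targets × 4 parameter
sets with a 12 s movement cap (the type orderings are already asymptotic
there); the distance regression uses the full 33 targets × 24 parameter
sets, where the regression p-values are stable across replication streams. Full-scale grids (51 × 51 cells, 30 parameter sets, 30 s caps) are
available through the library/CLI flags but take hours of CPU time.

## What the generator does and does not emulate

The synthetic ensembles emulate literature-reported tuning *forms*, rate
ranges, and noise models, with population parameters (exponential baselines,
gamma depths, Poisson/normal mix) that are configurable stand-ins for values
the source reports do not print. The simulator assumes stationary tuning, a
decoder with exact knowledge of every tuning curve (no decoder-training
error), rate-based coding in independent 30 ms bins (no spike-train
structure, refractoriness, or inter-neuron correlation), and a controller
strategy fixed across conditions (no user learning or adaptation). Passing
tests therefore demonstrate properties of this model class — e.g. that
velocity ensembles outperform equally sized goal or position ensembles
*under an ideal decoder* — not guarantees about recorded cortical data.

## Known limitations

* The controller is a stated rule-based stand-in for predictors trained on
  human reaching data; its trigger threshold (1 cm) sets a floor on the
  achievable MATR for tuning types that rely on closed-loop re-correction.
* With zero informative neurons the decoded position drifts toward the goal
  prior (the origin) under the fitted trajectory dynamics, so the empty-
  ensemble MATR reflects distance-to-origin rather than distance-to-start.
* The EKF is mildly inconsistent where saturation curvature or the
  truncated-normal noise bias is large; the Joseph form bounds the numerical
  consequences but calibration checks are run with Poisson noise.
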