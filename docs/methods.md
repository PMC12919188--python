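# Methods

## The model

Reactive balance torque at a joint is modelled as a quasi-linear sum of
delayed center-of-mass (CoM) deviation relative to the feet. For one joint
and one horizontal axis the predicted torque is

    tau(t) = k_a0 * a(t - l0)
           + sum_i [ k_di * s_d,i(t - l_i) + k_vi * s_v,i(t - l_i) + k_ai * s_a,i(t - l_i) ]

where `d, v, a` are CoM displacement (m), velocity (m/s) and acceleration
(m/s^2) relative to the feet, and `s_*,i` is the half-wave rectified
positive or negative component of the channel, selected by loop `i`'s
CoM-input gate. The structure comprises:

* one **instantaneous acceleration loop** (`k_a0`, delay `l0` near zero,
  ungated): the intrinsic mechanical response to CoM acceleration and
  deceleration;
* four **sign-gated residual loops**, one per combination of CoM-input sign
  (+/-) and torque-response sign (+/-), each with displacement, velocity and
  acceleration gains sharing a single delay.

That is 2 + 4 x 4 = 18 free parameters. Torque-sign gating is enforced as
sign bounds on the gains during fitting (a loop assigned to the positive
torque response may only produce a nonnegative contribution given its
rectified input's sign); loop outputs are never clipped, so the model stays
linear in its gains at fixed delays and the inner fitting problem stays
convex. Sagittal-plane CoM deviation drives the ankle plantarflexion, knee
flexion and hip flexion models; frontal-plane CoM deviation drives hip
adduction.

## Preprocessing

Trials are averaged pointwise across repetitions of a condition, truncated
to a closed window from 0.25 s before to 1 s after perturbation onset
(1251 samples at 1 kHz; 15 s after onset for sinusoid trials), and the mean
torque over `[onset - 0.25 s, onset)` is subtracted. The background window
excludes the onset sample itself: a zero-delay intrinsic response fires at
onset and would otherwise leak into the background estimate.

For sinusoids with superimposed perturbations, the perturbation response is
isolated by subtracting the matching perturbation-free sinusoid average,
segmenting at the (metadata-supplied) perturbation onsets, grouping by
perturbation direction and accelerating/braking class, re-basing each
segment so onset = 0, and windowing to [-0.25, +1] s. Sinusoid averages are
kept separate per starting direction rather than sign-flipping
opposite-start trials onto one template: the response is deliberately
asymmetric between opposite CoM excursions, so a sign flip is not a symmetry
and would bias the template. Trial-vs-average phase alignment is checked
from the phase of the platform-position Fourier component at the sinusoid
frequency (the maximum-likelihood lag estimator for a sinusoid in white
noise); a lag beyond 10 ms — under 1% of a 0.75 Hz cycle but wide enough
that noise jitter cannot false-alarm — is an error.

Zero-phase (forward-backward) low-pass filtering at a nominal 4th order and
linear-interpolation resampling to 1 kHz are provided for externally
recorded data; the synthetic pipeline generates smooth signals directly at
1 kHz and does not filter them, because filtering does not commute with the
model's half-wave rectification and would perturb exact recovery checks.

Averaged traces whose torque range is below 10 Nm over the analysis window
are excluded as too noisy to score (strict less-than; configurable).

## Staged fitting

Stage 1 fits the acceleration loop alone: a grid search over its delay
(bounds [0, 20] ms, 5 ms step, 1 ms local refinement) with the closed-form
least-squares gain at each candidate. If this loop alone accounts for more
than 95% of the torque variability (strictly greater), fitting stops with
the residual loops zeroed.

Stage 2 fits the four residual loops. At fixed delays the problem is linear
in the gains, so each delay candidate is scored by a convex bound-constrained
least squares (an active-set solver on the normal equations, verified
against `scipy.optimize.lsq_linear`). Delays are searched by seeded
multistart coordinate descent over a deterministic grid (bounds
[40, 250] ms — physiological feedback latencies — at 5 ms, then 1 ms local
refinement). By default the acceleration gain and delay are re-estimated
jointly in stage 2: with residual pathways present, the stage-1-alone
estimate is biased, and the joint solve is what makes exact noiseless
recovery possible. A flag restores the frozen-stage-1 behaviour.

Gain magnitudes are capped at 10x a per-channel scale estimate
(torque range / channel range). If the optimum pins a gain at its cap, the
caps are doubled once and the solve repeated (logged) — a reproducible,
automated replacement for manual bound tuning. Finally, individual gain
terms are removed by greedy backward elimination while removal costs less
than 0.1% of the torque variance (`prune_r2_drop`), so the reported
active-parameter count reflects the pathways the data actually require;
with the default plant this yields roughly 6 active parameters at the ankle
and 8–9 at the other joints, far below the 18-parameter structure.

Fit quality is reported as R^2 (coefficient of determination against the
mean; a zero-variance target is an error) and RMSE normalized by body mass
(Nm/kg). The squared error is minimized over the 1 s post-onset window;
metrics are reported over the full truncated trace. Identical inputs and
seed give bit-identical results.

## Generalization protocols

* **Direction**: models fitted per cardinal direction (sagittal CoM input
  for 90/270 deg, frontal for 0/180 deg) predict the diagonals; the X and Y
  contributions come from the two cardinals bounding the diagonal's quadrant
  (135 deg uses the 180 deg X gains and the 90 deg Y gains), preserving
  left/right and fore/aft asymmetry. Joints with a model on one axis only
  contribute zero on the missing axis (logged).
* **Magnitude**: a 4 x 4 train-by-test matrix per cardinal direction; the
  train = test diagonal reproduces the training metrics exactly.
* **Sinusoid**: ramp-trained gains matched to the movement direction predict
  the continuous sinusoid response over [-0.25, +15] s; for each plane the
  model trained at the starting-direction cardinal is used.
* **Superimposed**: ramp-trained gains matched to the perturbation direction
  (regardless of the background sinusoid's direction) predict the extracted
  superimposed-perturbation responses over [-0.25, +1] s; slow and fast
  superimposed perturbations are matched to the small-slow and small-fast
  training magnitudes.

Summaries report mean +/- sample SD (ddof = 1; 0 with an `n = 1`
annotation for singleton cells) per protocol, joint and role; excluded
cells contribute nothing. A transfer is flagged a good fit when mean
R^2 > 0.7 and mean RMSE < 0.2 Nm/kg.

## The synthetic study generator

The generator emulates the full protocol: ramp-and-hold support-surface
translations in 8 directions x 4 magnitudes — (4.9 cm, 16 cm/s, 1.06 g),
(4.9 cm, 24 cm/s, 1.6 g), (7.7 cm, 16 cm/s, 1.06 g), (12.6 cm, 24 cm/s,
1.6 g) — x 5 repetitions (160 trials); 7.7 cm, 0.75 Hz, 10-cycle sinusoids
in the sagittal and frontal planes; and sinusoids with slow or fast
discrete perturbations superimposed at displacement zero crossings, moving
with (accelerating) or against (braking) the platform — 36 sinusoid-block
trials. Ramp velocity profiles are exact trapezoids; sinusoids carry a
half-cycle raised-cosine on/off taper so the platform does not need an
acceleration impulse at motion onset. Each superimposed trial carries two
perturbations separated by at least six half-cycles (4 s) so one response's
ring-down decays before the next window opens.

The participant is a linearized single inverted pendulum per horizontal
axis: `m*h*dd = m*g*d - tau - b*h*v - m*h*p_acc`, with CoM height
`h = 0.94` m, mass 69 kg, light intrinsic damping `b = 20` N s/m, and
platform acceleration `p_acc` as the disturbance. The stabilizing torque is
the sum of the axis's ground-truth joint models evaluated on the simulated
CoM history (semi-implicit Euler at 1 kHz; the zero-delay acceleration gain
is handled algebraically as added effective mass). The ground-truth gains
place the closed loop in an underdamped regime (natural frequency ~4.3
rad/s, damping ratio ~0.3), so single-direction responses overshoot and
excite both CoM signs — without that overshoot the opposite-sign loops are
unidentifiable from one direction within the 1 s window, and transfer to
symmetric cyclic movement would fail for reasons of experiment design, not
modelling. Displacement-gain totals per axis exceed the gravitational
destabilization `m*g`, and velocity gains exceed the effective negative
damping `K_d * lambda` introduced by the feedback delays. The two restoring
loops carry deliberately asymmetric gains (fore/aft, left/right), and
per-subject variants scale gains with `mass * height`, jitter each gain by
+/-8%, and move delays by one 5 ms grid step.

Measurement noise is additive, seeded, proportional to each channel's range
(default SD 2% of range), and never enters the loop — repetitions of a
condition share one deterministic closed-loop solution and differ only in
their noise draw. A noiseless recording therefore reproduces
`predict_torque(ground truth, recorded CoM)` sample for sample, which is
the oracle behind the exact-recovery checks.

The optional **context-dissociated plant** gives ankle plantarflexion and
hip adduction a large zero-delay intrinsic acceleration gain in the
sinusoid context only (added effective mass, hence unconditionally stable),
emulating the empirical finding that ankle and frontal-plane hip feedback
differ between discrete perturbations and cyclic movement while knee and
hip flexion feedback transfers.

What the generator does **not** emulate: multi-segment body dynamics,
inertial artifacts of a moving platform, marker/force-plate measurement
chains, inverse-dynamics estimation error, stepping responses, or
trial-to-trial motor variability (noise is measurement-only). Passing tests
therefore validate the pipeline — preprocessing, identification,
generalization scoring — under a known-truth plant, not the biomechanical
fidelity of the plant itself.

## Numerical choices

* Delays round to the nearest 1 ms sample (at most 0.5 ms error, far below
  physiological delay scales); delayed signals back-fill their leading gap
  with the first sample, consistent with a quiescent pre-perturbation
  background.
* Windows are closed intervals (inclusive endpoints): 1251 samples for
  [-0.25, +1] s at 1 kHz.
* Grid/coordinate-descent ties break toward the smaller delay; candidate
  scoring uses normal-equation SSE, and the final gains are re-solved on
  the raw regressors for precision.
* Degenerate regressor columns (zero energy over the fit window, e.g. a
  rectified component the condition never excites) are dropped and their
  gains reported as exactly zero, with a logged warning.
* A zero-variance torque target yields the zero model with R^2 reported as
  0 (documented convention for unusable traces); zero-variance targets are
  an error in the standalone R^2 metric.
* Closed-loop divergence (|CoM| > 0.5 m) aborts the simulation and names
  the unstable parameter set.

## Problem sizes in the test suite and acceptance script

Recovery audits fit both cardinals along each joint's axis and compare each
ground-truth loop against the fit from the direction that excites it
directly. The packaged checks use 5 noiseless and 20 noisy seeded
participants (tests), and 3 noiseless / 8 noisy participants plus
two-participant transfer cohorts (acceptance script) — cohort sizes chosen
so the full audit remains a few minutes of desk-scale compute while the
medians it reports are stable.

## Known limitations

* The plant is deliberately minimal; headline human-subject numbers
  (population means of R^2/RMSE) are properties of the synthetic cohort,
  not of human data.
* Sinusoid-context scoring uses the model trained at the starting-direction
  cardinal; other conventions (e.g. blending both signed cardinals) are
  possible and untested.
* Superimposed-response extraction inherits ring-down contamination from
  preceding perturbations when onsets are packed closer than the packaged
  spacing.
* Gain bounds, the bound-escalation rule, and the pruning threshold are
  reproducible stand-ins for the manual bound tuning a human analyst would
  perform; they are configurable but only validated on the synthetic
  conditions above.
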