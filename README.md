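# comfeedback

Delayed center-of-mass (CoM) feedback identification of multi-joint reactive
balance torques, with cross-condition generalization testing.

When standing balance is perturbed — the support surface translates under
the feet — the nervous system generates corrective torques at the ankle,
knee and hip. A compact, physiologically grounded description of this
response models each joint's torque as a quasi-linear sum of *delayed CoM
deviation* relative to the feet:

    tau(t) = k_a0 a(t - l0)  +  sum_i [ k_di s_d,i(t-l_i) + k_vi s_v,i(t-l_i) + k_ai s_a,i(t-l_i) ]

one near-instantaneous acceleration loop (the intrinsic mechanical
response) plus four sign-gated feedback loops, one per combination of
half-wave-rectified CoM-input sign and torque-response sign — 18 free
parameters per joint, of which a fitted model typically needs far fewer.
Because the controller runs continuously on CoM state, it needs no
perturbation detector, which makes it a candidate torque controller for
balance-assisting exoskeletons; the question this package addresses is how
well gains identified from one perturbation condition *generalize* to
others.

The package provides:

* **signals / preprocess** — time-series primitives (zero-phase filtering,
  resampling, nearest-sample delays, half-wave rectification, windowing),
  condition averaging, background-torque removal, low-torque exclusion, and
  extraction of responses to perturbations superimposed on sinusoidal
  movement;
* **model / fitting** — the delayed CoM feedback model and its staged,
  bounded identification: an acceleration-only stage with a 95%
  variance-accounted stopping rule, then sign-constrained least-squares
  gains inside a seeded grid search over physiological delays, with
  parsimony pruning;
* **generalization** — four transfer protocols: cardinal-to-diagonal
  direction transfer via quadrant-matched gains, magnitude transfer,
  transfer from discrete ramps to continuous sinusoidal movement, and to
  discrete perturbations superimposed on that movement; R^2 and
  mass-normalized RMSE scoring with mean +/- SD reporting;
* **synthetic** — a closed-loop inverted-pendulum study generator that
  emulates the full protocol (160 ramp-and-hold trials: 8 directions x 4
  magnitudes x 5 reps; 36 sinusoid-block trials at 7.7 cm / 0.75 Hz) from
  known ground-truth feedback parameters, so every pipeline stage is
  testable end to end with no data download;
* a **CLI** (`comfeedback simulate | fit | generalize | report | run-all`)
  wiring the stages through documented on-disk artifacts.

See `docs/methods.md` for the model, fitting procedure, and the synthetic
plant's assumptions and limitations.

## Worked example

Simulate a participant's medium-magnitude forward/backward perturbations,
fit the ankle plantarflexion model, and compare with the generator's ground
truth:

```python
from comfeedback import (FitConfig, StudyDataset, default_plant,
                         generate_study, study_plan, train_ramp_models)

plant = default_plant(noise_frac=0.02)           # 69 kg simulated participant
plan = study_plan(seed=0, directions=(90.0, 270.0), magnitudes=("medium",),
                  ramp_reps=5, planes=(), superimposed_kinds=())
trials, _ = generate_study(plant, seed=0, plan=plan)
dataset = StudyDataset(trials)

models = train_ramp_models(dataset, FitConfig(), directions=(90.0, 270.0),
                           magnitudes=("medium",))
fit = models[("ankle_pf", 90.0, "medium")]
print("ankle plantarflexion @ 90 deg, medium ramp:")
print(f"  R^2 = {fit.r2_train:.3f}   RMSE = {fit.rmse_per_kg_train:.3f} Nm/kg")
print(f"  stage-1 (acceleration-only) R^2 = {fit.stage1_r2:.2f}")
print(f"  active parameters = {fit.active_parameters} of 18")
truth = plant.models["ramp"]["ankle_pf"].residual_loops[3]
fitted = fit.model.residual_loops[3]
print(f"  (-CoM -> -torque) loop: k_d = {fitted.k_d:.0f} Nm/m "
      f"(truth {truth.k_d:.0f}), delay = {fitted.lambda_s*1000:.0f} ms "
      f"(truth {truth.lambda_s*1000:.0f})")
```

Output:

```
ankle plantarflexion @ 90 deg, medium ramp:
  R^2 = 0.999   RMSE = 0.010 Nm/kg
  stage-1 (acceleration-only) R^2 = 0.11
  active parameters = 6 of 18
  (-CoM -> -torque) loop: k_d = 615 Nm/m (truth 620), delay = 112 ms (truth 110)
```

The fit explains 99.9% of the averaged torque variance at 0.01 Nm/kg error.
The acceleration loop alone explains only 11% at the ankle (its response is
feedback-dominated), so fitting proceeds to the residual loops; the
identified displacement gain and delay of the loop driven by the backward
CoM excursion land within ~1% and 2 ms of the ground truth, and pruning
leaves 6 of the 18 structural parameters active. A full study, all four
transfer protocols and summary tables:

```sh
comfeedback run-all --out report/ --seed 1
```

which writes `results.csv`, per-joint mean +/- SD tables (`summary.txt`),
fitted models, a parameter-count summary, representative-trace figures, and
a reproducibility manifest.

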