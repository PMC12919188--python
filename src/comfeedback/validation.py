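"""Ground-truth recovery harness for the synthetic closed-loop study.

Because the generator embeds known feedback parameters in the loop, the
staged fit can be audited end to end: simulate a participant, average the
repetitions of a training condition, fit each joint, and compare the fitted
gains and delays against the plant's ground truth.

A single perturbation direction mainly excites the feedback loops gated to
the initial CoM excursion sign (platform motion toward the positive axis
pushes the CoM negative relative to the feet, and vice versa); the
opposite-sign loops are identified from the response overshoot and, far more
strongly, from the opposite cardinal direction.  The harness therefore fits
both cardinals along each joint's input axis and audits every ground-truth
loop against the fit from the direction that excites it directly (the
ungated acceleration loop is audited in both).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fitting import FitConfig, fit_model, remove_background_torque
from .generalization import com_state, direction_axis
from .model import CoMFeedbackModel
from .preprocess import StudyDataset
from .synthetic import JOINT_AXES, PlantParams, generate_study, study_plan

__all__ = ["RecoveryReport", "recover_subject", "recovery_cohort"]

#: cardinal direction -> sign of the initial CoM excursion it produces
_INITIAL_COM_SIGN = {90.0: "-", 0.0: "-", 270.0: "+", 180.0: "+"}


@dataclass
class RecoveryReport:
    """Per-parameter recovery errors for one or more participants."""

    gain_rel_errors: list = field(default_factory=list)  # |k^ - k| / |k|
    delay_abs_errors_s: list = field(default_factory=list)
    r2_train: list = field(default_factory=list)

    def extend(self, other: "RecoveryReport") -> None:
        self.gain_rel_errors.extend(other.gain_rel_errors)
        self.delay_abs_errors_s.extend(other.delay_abs_errors_s)
        self.r2_train.extend(other.r2_train)

    @property
    def max_gain_error(self) -> float:
        return float(np.max(self.gain_rel_errors)) if self.gain_rel_errors \
            else np.nan

    @property
    def median_gain_error(self) -> float:
        return float(np.median(self.gain_rel_errors)) \
            if self.gain_rel_errors else np.nan

    @property
    def max_delay_error_s(self) -> float:
        return float(np.max(self.delay_abs_errors_s)) \
            if self.delay_abs_errors_s else np.nan

    @property
    def median_delay_error_s(self) -> float:
        return float(np.median(self.delay_abs_errors_s)) \
            if self.delay_abs_errors_s else np.nan

    @property
    def min_r2(self) -> float:
        return float(np.min(self.r2_train)) if self.r2_train else np.nan


def _audit(truth: CoMFeedbackModel, fitted: CoMFeedbackModel,
           init_sign: str, report: RecoveryReport) -> None:
    for tl, fl in zip(truth.all_loops, fitted.all_loops):
        if not tl.is_active:
            continue
        if tl.com_sign not in ("both", init_sign):
            continue
        for gt, gf in zip(tl.gains, fl.gains):
            if gt != 0.0:
                report.gain_rel_errors.append(abs(gf - gt) / abs(gt))
        report.delay_abs_errors_s.append(abs(fl.lambda_s - tl.lambda_s))


def recover_subject(plant: PlantParams, cfg: FitConfig, seed: int,
                    magnitude: str = "medium", reps: int = 5,
                    joints=None) -> RecoveryReport:
    """Simulate one participant's training conditions and audit the fits.

    Uses ``reps`` repetitions per condition (identical closed loop, seeded
    measurement noise per rep) averaged before fitting, exactly as in the
    analysis pipeline.
    """
    joints = tuple(joints) if joints else tuple(JOINT_AXES)
    axes = {JOINT_AXES[j] for j in joints}
    directions = []
    if "y" in axes:
        directions += [90.0, 270.0]
    if "x" in axes:
        directions += [0.0, 180.0]
    plan = study_plan(seed=seed, directions=tuple(directions),
                      magnitudes=(magnitude,), ramp_reps=reps, planes=(),
                      superimposed_kinds=())
    trials, _ = generate_study(plant, seed=seed, plan=plan)
    ds = StudyDataset(trials)
    report = RecoveryReport()
    for joint in joints:
        axis = JOINT_AXES[joint]
        truth = plant.models["ramp"][joint]
        for direction in directions:
            if direction_axis(direction) != axis:
                continue
            trial = ds.windowed_ramp(direction, magnitude)
            com = com_state(trial, axis)
            tau, _bg = remove_background_torque(trial[f"tau_{joint}_Nm"],
                                                trial.meta.onset_s,
                                                cfg.background_window_s)
            res = fit_model(com, tau, cfg, mass_kg=plant.mass_kg,
                            joint_id=joint, axis=axis)
            report.r2_train.append(res.r2_train)
            _audit(truth, res.model, _INITIAL_COM_SIGN[direction], report)
    return report


def recovery_cohort(n_subjects: int, cfg: FitConfig, seed: int,
                    noise_frac: float, magnitude: str = "medium",
                    reps: int = 5, joints=None) -> RecoveryReport:
    """Recovery over a cohort of seeded random participants."""
    from .synthetic import subject_plant

    rng = np.random.default_rng(seed)
    report = RecoveryReport()
    for _ in range(n_subjects):
        sseed = int(rng.integers(2 ** 31))
        plant = subject_plant(sseed, noise_frac=noise_frac)
        report.extend(recover_subject(plant, cfg, seed=sseed,
                                      magnitude=magnitude,
                                      reps=1 if noise_frac == 0 else reps,
                                      joints=joints))
    return report
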