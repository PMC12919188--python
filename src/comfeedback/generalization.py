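"""Cross-condition transfer of ramp-trained CoM feedback models.

Four protocols, each scoring a model fitted on one training condition against
data from another:

* **direction** -- models fitted per cardinal direction (0/90/180/270) predict
  the diagonal directions; for a diagonal, the frontal-axis (X) and
  sagittal-axis (Y) contributions come from the two cardinals bounding the
  diagonal's quadrant (e.g. 135 deg uses the 180 deg X gains and the 90 deg Y
  gains), which preserves left/right and fore/aft response asymmetry.
* **magnitude** -- models fitted at one ramp magnitude predict the other
  magnitudes in the same cardinal direction.
* **sinusoid** -- ramp-trained models predict the continuous sinusoid response
  in the matching direction, over a [-0.25, +15] s window.
* **superimposed** -- ramp-trained models predict the extracted responses to
  perturbations superimposed on the sinusoid, matched by perturbation
  direction regardless of the background-sinusoid direction.

Fits and predictions are scored by R^2 and body-mass-normalized RMSE
(Nm/kg); averaged traces whose torque range is below 10 Nm are excluded as
too noisy to score.  A transfer is a "good fit" when the average R^2 exceeds
0.7 and the average RMSE stays below 0.2 Nm/kg.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fitting import (FitConfig, FitResult, compute_r2, compute_rmse_per_kg,
                      fit_model, remove_background_torque)
from .model import CoMFeedbackModel, CoMState, predict_torque
from .preprocess import StudyDataset, exclude_low_torque
from .signals import TimeSeriesTrial
from .synthetic import (CARDINAL_DIRECTIONS, DIAGONAL_DIRECTIONS, JOINTS,
                        PLANE_AXIS, PLANE_NEG_DIR, PLANE_POS_DIR,
                        STUDY_MAGNITUDES)

__all__ = [
    "GeneralizationResult",
    "quadrant_sources",
    "direction_axis",
    "com_state",
    "predict_diagonal",
    "train_ramp_models",
    "run_direction_generalization",
    "run_magnitude_generalization",
    "run_context_generalization",
    "aggregate_report",
]

log = logging.getLogger(__name__)

GOOD_FIT_R2 = 0.7
GOOD_FIT_RMSE_PER_KG = 0.2
EXCLUDE_TORQUE_RANGE_NM = 10.0


@dataclass
class GeneralizationResult:
    """One train-condition -> test-condition transfer record for one joint."""

    protocol: str
    joint_id: str
    train_key: dict
    test_key: dict
    role: str  # "train" or "test"
    r2: float | None = None
    rmse_per_kg: float | None = None
    excluded: bool = False
    participant_id: str = ""
    detail: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def quadrant_sources(direction_deg: float) -> tuple[float, float]:
    """Cardinal (X-axis, Y-axis) training directions for a diagonal.

    Each source is the cardinal bounding the diagonal's quadrant on its axis:
    135 -> (180, 90); 45 -> (0, 90); 225 -> (180, 270); 315 -> (0, 270).
    """
    if direction_deg not in DIAGONAL_DIRECTIONS:
        raise ValueError(f"{direction_deg} deg is not a diagonal direction")
    x_source = 0.0 if direction_deg in (45.0, 315.0) else 180.0
    y_source = 90.0 if direction_deg in (45.0, 135.0) else 270.0
    return x_source, y_source


def direction_axis(direction_deg: float) -> str:
    """CoM input axis for a cardinal training direction."""
    if direction_deg in (90.0, 270.0):
        return "y"
    if direction_deg in (0.0, 180.0):
        return "x"
    raise ValueError(f"{direction_deg} deg is not cardinal")


def com_state(trial: TimeSeriesTrial, axis: str) -> CoMState:
    return CoMState(trial[f"com_d_{axis}_m"], trial[f"com_v_{axis}_mps"],
                    trial[f"com_a_{axis}_mps2"])


def predict_diagonal(models_x: dict[str, CoMFeedbackModel | None],
                     models_y: dict[str, CoMFeedbackModel | None],
                     com_x: CoMState, com_y: CoMState) -> dict:
    """Per-joint diagonal prediction as the sum of the two axis models.

    Joints with a model on one axis only (the other cardinal's fit was
    excluded or the joint acts in a single plane) contribute zero on the
    missing axis, which is logged.  A joint with no model on either axis is
    an error.
    """
    out = {}
    for joint in set(models_x) | set(models_y):
        mx, my = models_x.get(joint), models_y.get(joint)
        if mx is None and my is None:
            raise ValueError(f"no axis model available for joint {joint!r}")
        total = np.zeros(len(com_x))
        if mx is not None:
            total = total + predict_torque(mx, com_x).values
        else:
            log.info("joint %s: no X-axis model; frontal term contributes zero",
                     joint)
        if my is not None:
            total = total + predict_torque(my, com_y).values
        else:
            log.info("joint %s: no Y-axis model; sagittal term contributes zero",
                     joint)
        out[joint] = com_x.d.with_values(total)
    return out


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _prepared(trial: TimeSeriesTrial, joint: str,
              background_window_s: float = 0.25):
    """Background-subtracted torque for one joint of a windowed average."""
    return remove_background_torque(trial[f"tau_{joint}_Nm"],
                                    trial.meta.onset_s, background_window_s)[0]


def train_ramp_models(dataset: StudyDataset, cfg: FitConfig,
                      directions=CARDINAL_DIRECTIONS,
                      magnitudes=tuple(STUDY_MAGNITUDES),
                      joints=JOINTS,
                      threshold_nm: float = EXCLUDE_TORQUE_RANGE_NM,
                      ) -> dict[tuple, FitResult | None]:
    """Fit every (joint, cardinal direction, magnitude) training cell.

    The CoM input axis follows the perturbation plane: sagittal CoM for
    90/270 deg, frontal CoM for 0/180 deg.  Cells whose averaged torque range
    is below the exclusion threshold get ``None``.
    """
    out: dict[tuple, FitResult | None] = {}
    for direction in directions:
        axis = direction_axis(direction)
        for mag in magnitudes:
            trial = dataset.windowed_ramp(direction, mag)
            com = com_state(trial, axis)
            for joint in joints:
                if exclude_low_torque(trial, joint, threshold_nm):
                    out[(joint, direction, mag)] = None
                    continue
                tau = _prepared(trial, joint, cfg.background_window_s)
                out[(joint, direction, mag)] = fit_model(
                    com, tau, cfg, mass_kg=dataset.mass_kg,
                    joint_id=joint, axis=axis)
    return out


# ---------------------------------------------------------------------------
# Protocols
# ---------------------------------------------------------------------------

def _score(tau, pred, mass_kg) -> tuple[float, float]:
    return compute_r2(tau, pred), compute_rmse_per_kg(tau, pred, mass_kg)


def run_direction_generalization(dataset: StudyDataset, cfg: FitConfig,
                                 magnitudes=tuple(STUDY_MAGNITUDES),
                                 joints=JOINTS,
                                 threshold_nm: float = EXCLUDE_TORQUE_RANGE_NM,
                                 models: dict | None = None,
                                 ) -> list[GeneralizationResult]:
    """Cardinal-trained models predicting the diagonal directions."""
    models = models if models is not None else train_ramp_models(
        dataset, cfg, magnitudes=magnitudes, joints=joints,
        threshold_nm=threshold_nm)
    pid = next(iter(dataset.ramp.values()))[0].meta.participant_id \
        if dataset.ramp else ""
    results: list[GeneralizationResult] = []
    for (joint, direction, mag), fit in models.items():
        results.append(GeneralizationResult(
            protocol="direction", joint_id=joint,
            train_key={"direction_deg": direction, "magnitude": mag},
            test_key={"direction_deg": direction, "magnitude": mag},
            role="train", participant_id=pid,
            r2=None if fit is None else fit.r2_train,
            rmse_per_kg=None if fit is None else fit.rmse_per_kg_train,
            excluded=fit is None))
    diagonals = sorted({d for (d, _m) in dataset.ramp
                        if d in DIAGONAL_DIRECTIONS})
    for direction in diagonals:
        x_src, y_src = quadrant_sources(direction)
        for mag in magnitudes:
            trial = dataset.windowed_ramp(direction, mag)
            com_x = com_state(trial, "x")
            com_y = com_state(trial, "y")
            mx = {j: (models.get((j, x_src, mag)) or None) for j in joints}
            my = {j: (models.get((j, y_src, mag)) or None) for j in joints}
            mx = {j: (f.model if f else None) for j, f in mx.items()}
            my = {j: (f.model if f else None) for j, f in my.items()}
            preds = predict_diagonal(mx, my, com_x, com_y)
            for joint in joints:
                res = GeneralizationResult(
                    protocol="direction", joint_id=joint,
                    train_key={"x_source": x_src, "y_source": y_src,
                               "magnitude": mag},
                    test_key={"direction_deg": direction, "magnitude": mag},
                    role="test", participant_id=pid)
                if exclude_low_torque(trial, joint, threshold_nm):
                    res.excluded = True
                else:
                    tau = _prepared(trial, joint, cfg.background_window_s)
                    res.r2, res.rmse_per_kg = _score(tau, preds[joint],
                                                     dataset.mass_kg)
                results.append(res)
    return results


def run_magnitude_generalization(dataset: StudyDataset, cfg: FitConfig,
                                 magnitudes=tuple(STUDY_MAGNITUDES),
                                 joints=JOINTS,
                                 threshold_nm: float = EXCLUDE_TORQUE_RANGE_NM,
                                 models: dict | None = None,
                                 ) -> list[GeneralizationResult]:
    """Train at one ramp magnitude, test at all magnitudes (cardinals only).

    The train=test diagonal of the 4x4 matrix is reported with role
    ``"train"`` and reproduces the training metrics exactly.
    """
    models = models if models is not None else train_ramp_models(
        dataset, cfg, magnitudes=magnitudes, joints=joints,
        threshold_nm=threshold_nm)
    pid = next(iter(dataset.ramp.values()))[0].meta.participant_id \
        if dataset.ramp else ""
    results: list[GeneralizationResult] = []
    for direction in CARDINAL_DIRECTIONS:
        axis = direction_axis(direction)
        for test_mag in magnitudes:
            trial = dataset.windowed_ramp(direction, test_mag)
            com = com_state(trial, axis)
            for train_mag in magnitudes:
                for joint in joints:
                    fit = models.get((joint, direction, train_mag))
                    res = GeneralizationResult(
                        protocol="magnitude", joint_id=joint,
                        train_key={"direction_deg": direction,
                                   "magnitude": train_mag},
                        test_key={"direction_deg": direction,
                                  "magnitude": test_mag},
                        role="train" if train_mag == test_mag else "test",
                        participant_id=pid)
                    if fit is None or exclude_low_torque(trial, joint,
                                                         threshold_nm):
                        res.excluded = True
                    elif train_mag == test_mag:
                        res.r2 = fit.r2_train
                        res.rmse_per_kg = fit.rmse_per_kg_train
                    else:
                        tau = _prepared(trial, joint, cfg.background_window_s)
                        pred = predict_torque(fit.model, com)
                        res.r2, res.rmse_per_kg = _score(tau, pred,
                                                         dataset.mass_kg)
                    results.append(res)
    return results


def run_context_generalization(dataset: StudyDataset, cfg: FitConfig,
                               context: str,
                               magnitudes=tuple(STUDY_MAGNITUDES),
                               joints=JOINTS,
                               threshold_nm: float = EXCLUDE_TORQUE_RANGE_NM,
                               models: dict | None = None,
                               sinusoid_post_s: float = 15.0,
                               ) -> list[GeneralizationResult]:
    """Ramp-trained models predicting cyclic-movement responses.

    ``context`` is ``"sinusoid"`` (continuous movement, scored over
    [-0.25, +15] s from platform onset) or ``"superimposed_slow"`` /
    ``"superimposed_fast"`` (extracted responses to perturbations
    superimposed at sinusoid zero crossings, scored over [-0.25, +1] s).
    Training gains are matched to the direction of the movement or
    superimposed perturbation, per training magnitude.
    """
    if context not in ("sinusoid", "superimposed_slow", "superimposed_fast"):
        raise ValueError(f"unknown context {context!r}")
    models = models if models is not None else train_ramp_models(
        dataset, cfg, magnitudes=magnitudes, joints=joints,
        threshold_nm=threshold_nm)
    results: list[GeneralizationResult] = []

    def score_cell(trial, com, joint, fit, train_key, test_key, pid):
        res = GeneralizationResult(
            protocol=context, joint_id=joint, train_key=train_key,
            test_key=test_key, role="test", participant_id=pid)
        if fit is None or exclude_low_torque(trial, joint, threshold_nm):
            res.excluded = True
        else:
            tau = _prepared(trial, joint, cfg.background_window_s)
            pred = predict_torque(fit.model, com)
            res.r2, res.rmse_per_kg = _score(tau, pred, dataset.mass_kg)
        results.append(res)

    if context == "sinusoid":
        for (plane, start_dir) in sorted(dataset.sinusoid_only):
            trial = dataset.windowed_sinusoid(plane, start_dir,
                                              post_s=sinusoid_post_s)
            com = com_state(trial, PLANE_AXIS[plane])
            pid = trial.meta.participant_id
            for mag in magnitudes:
                for joint in joints:
                    fit = models.get((joint, start_dir, mag))
                    score_cell(trial, com, joint, fit,
                               {"direction_deg": start_dir, "magnitude": mag},
                               {"plane": plane, "start_direction_deg": start_dir},
                               pid)
    else:
        sup = context.rsplit("_", 1)[-1]  # "slow" | "fast"
        matched_mag = {"slow": "small_slow", "fast": "small_fast"}[sup]
        groups = dataset.superimposed_averages(sup)
        for (plane, pert_dir, cls), avg in sorted(groups.items()):
            trial = avg.trial
            com = com_state(trial, PLANE_AXIS[plane])
            pid = trial.meta.participant_id
            for mag in magnitudes:
                for joint in joints:
                    fit = models.get((joint, pert_dir, mag))
                    score_cell(trial, com, joint, fit,
                               {"direction_deg": pert_dir, "magnitude": mag},
                               {"plane": plane, "direction_deg": pert_dir,
                                "cls": cls, "matched_magnitude": matched_mag},
                               pid)
    return results


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def aggregate_report(results: list[GeneralizationResult],
                     good_fit_r2: float = GOOD_FIT_R2,
                     good_fit_rmse: float = GOOD_FIT_RMSE_PER_KG,
                     ) -> pd.DataFrame:
    """Mean +/- SD summary per (protocol, joint, role).

    Excluded cells contribute nothing.  SD is the sample standard deviation
    (ddof=1), reported as 0 for singleton cells (flagged by ``n``).  The
    good-fit flag requires mean R^2 above ``good_fit_r2`` and mean RMSE below
    ``good_fit_rmse`` Nm/kg.
    """
    rows = []
    for r in results:
        if r.excluded:
            continue
        rows.append(dict(protocol=r.protocol, joint_id=r.joint_id, role=r.role,
                         r2=r.r2, rmse_per_kg=r.rmse_per_kg))
    if not rows:
        return pd.DataFrame(columns=["protocol", "joint_id", "role", "n",
                                     "r2_mean", "r2_sd", "rmse_mean",
                                     "rmse_sd", "good_fit"])
    df = pd.DataFrame(rows)
    g = df.groupby(["protocol", "joint_id", "role"], sort=True)
    out = g.agg(n=("r2", "size"), r2_mean=("r2", "mean"),
                r2_sd=("r2", lambda s: s.std(ddof=1) if len(s) > 1 else 0.0),
                rmse_mean=("rmse_per_kg", "mean"),
                rmse_sd=("rmse_per_kg",
                         lambda s: s.std(ddof=1) if len(s) > 1 else 0.0),
                ).reset_index()
    out["good_fit"] = (out["r2_mean"] > good_fit_r2) & \
                      (out["rmse_mean"] < good_fit_rmse)
    return out
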