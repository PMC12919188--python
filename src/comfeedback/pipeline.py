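"""End-to-end study pipeline: simulate -> preprocess -> fit -> generalize -> report.

The :class:`StudyConfig` document collects every protocol constant with its
study default (perturbation magnitudes, sinusoid spec, exclusion threshold of
10 Nm, good-fit thresholds R^2 > 0.7 / RMSE < 0.2 Nm/kg, stage-1 stop at
95% variance accounted), so any deviation from the study conditions is
explicit in one place.  It round-trips losslessly through YAML and is
schema-validated on load.

``run_pipeline`` executes all stages for a cohort of seeded synthetic
participants and writes the report bundle: fitted models (JSON), per-transfer
results (CSV), mean +/- SD summary tables per protocol, a parameter-count
summary, representative-trace figures, and a reproducibility manifest
(config hash, seeds, package versions).  Trials are kept in memory between
stages by default; with ``write_trials`` enabled the simulated study is also
written to disk in the documented CSV/JSON trial format so each stage can be
re-run standalone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import pydantic
import yaml

from . import io as cio
from .fitting import FitConfig
from .generalization import (aggregate_report, run_context_generalization,
                             run_direction_generalization,
                             run_magnitude_generalization, train_ramp_models)
from .preprocess import StudyDataset
from .synthetic import (CARDINAL_DIRECTIONS, DIAGONAL_DIRECTIONS, JOINTS,
                        STUDY_MAGNITUDES, default_plant, generate_study,
                        study_plan, subject_plant)

__all__ = ["StudyConfig", "run_pipeline"]

log = logging.getLogger(__name__)


class FitSettings(pydantic.BaseModel):
    """YAML-facing mirror of :class:`comfeedback.fitting.FitConfig`."""

    lambda_bounds_accel: tuple[float, float] = (0.0, 0.020)
    lambda_bounds_residual: tuple[float, float] = (0.040, 0.250)
    lambda_grid_step: float = pydantic.Field(0.005, gt=0)
    lambda_refine_step: float = pydantic.Field(0.001, gt=0)
    gain_cap_factor: float = pydantic.Field(10.0, gt=0)
    stage1_r2_stop: float = pydantic.Field(0.95, gt=0, lt=1)
    fit_window_post_s: float = pydantic.Field(1.0, gt=0)
    background_window_s: float = pydantic.Field(0.25, gt=0)
    multistart_count: int = pydantic.Field(4, ge=1)
    refit_accel_in_stage2: bool = True
    seed: int = 0

    def to_fit_config(self) -> FitConfig:
        return FitConfig(**self.model_dump())


class ProtocolSettings(pydantic.BaseModel):
    directions: list[float] = list(CARDINAL_DIRECTIONS + DIAGONAL_DIRECTIONS)
    magnitudes: list[str] = list(STUDY_MAGNITUDES)
    ramp_reps: int = pydantic.Field(5, ge=1)
    sinusoid_reps: int = pydantic.Field(6, ge=1)
    planes: list[str] = ["sagittal", "frontal"]
    superimposed_kinds: list[str] = ["none", "slow", "fast"]

    @pydantic.field_validator("magnitudes")
    @classmethod
    def _known_magnitudes(cls, v):
        unknown = set(v) - set(STUDY_MAGNITUDES)
        if unknown:
            raise ValueError(f"unknown magnitudes {sorted(unknown)}")
        return v


class PlantSettings(pydantic.BaseModel):
    n_subjects: int = pydantic.Field(1, ge=1)
    noise_frac: float = pydantic.Field(0.02, ge=0)
    context_dissociated: bool = False
    randomize_subjects: bool = True  # False: one canonical average participant


class ThresholdSettings(pydantic.BaseModel):
    exclusion_torque_range_nm: float = pydantic.Field(10.0, gt=0)
    good_fit_r2: float = 0.7
    good_fit_rmse_per_kg: float = 0.2


class StudyConfig(pydantic.BaseModel):
    """Validated, YAML-round-trippable configuration of one pipeline run."""

    seed: int = 0
    plant: PlantSettings = PlantSettings()
    protocol: ProtocolSettings = ProtocolSettings()
    fit: FitSettings = FitSettings()
    thresholds: ThresholdSettings = ThresholdSettings()
    protocols: list[str] = ["direction", "magnitude", "sinusoid",
                            "superimposed_slow", "superimposed_fast"]
    write_trials: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.model_dump(), sort_keys=True, default=str)
            .encode()).hexdigest()[:16]


def _parameter_count_summary(all_models: list[dict]) -> pd.DataFrame:
    rows = []
    for models in all_models:
        for (joint, direction, mag), fit in models.items():
            if fit is not None:
                rows.append(dict(joint_id=joint, direction_deg=direction,
                                 magnitude=mag,
                                 active_parameters=fit.active_parameters))
    if not rows:
        return pd.DataFrame()
    df = pd.DataFrame(rows)
    return df.groupby("joint_id")["active_parameters"].agg(
        ["mean", "std", "min", "max", "count"]).reset_index()


def _representative_figure(ds: StudyDataset, models: dict, out_path: Path,
                           cfg: FitConfig) -> None:
    """Trained vs predicted torque traces for one direction per joint."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .generalization import com_state, direction_axis
    from .fitting import remove_background_torque
    from .model import predict_torque

    fig, axes = plt.subplots(2, 2, figsize=(9, 6), sharex=True)
    for ax, joint in zip(axes.ravel(), JOINTS):
        direction = 90.0 if joint != "hip_add" else 0.0
        fit = models.get((joint, direction, "medium"))
        if fit is None:
            ax.set_title(f"{joint} (excluded)")
            continue
        trial = ds.windowed_ramp(direction, "medium")
        com = com_state(trial, direction_axis(direction))
        tau, _ = remove_background_torque(trial[f"tau_{joint}_Nm"],
                                          trial.meta.onset_s,
                                          cfg.background_window_s)
        t = tau.times() - trial.meta.onset_s
        ax.plot(t, tau.values, lw=1.2, label="measured")
        ax.plot(t, predict_torque(fit.model, com).values, "k--", lw=1.0,
                label="CoM feedback model")
        ax.axvline(0.0, color="0.6", ls=":")
        ax.set_title(f"{joint} @ {direction:g} deg (R2={fit.r2_train:.3f})")
    axes[0, 0].legend(frameon=False, fontsize=8)
    for ax in axes[-1]:
        ax.set_xlabel("time from onset (s)")
    for ax in axes[:, 0]:
        ax.set_ylabel("torque (Nm)")
    fig.tight_layout()
    fig.savefig(out_path, dpi=110)
    plt.close(fig)


def run_pipeline(config: StudyConfig, out_dir: str | Path) -> Path:
    """Execute all stages and write the report bundle to ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fit_cfg = config.fit.to_fit_config()
    thr = config.thresholds
    magnitudes = tuple(config.protocol.magnitudes)
    cardinals = tuple(d for d in config.protocol.directions
                      if d in CARDINAL_DIRECTIONS)
    have_diagonals = any(d in DIAGONAL_DIRECTIONS
                         for d in config.protocol.directions)

    subject_seeds = [config.seed + 1000 * i
                     for i in range(config.plant.n_subjects)]
    all_results, all_models = [], []
    for i, sseed in enumerate(subject_seeds):
        log.info("simulating participant %d/%d (seed %d)", i + 1,
                 len(subject_seeds), sseed)
        if config.plant.randomize_subjects:
            plant = subject_plant(sseed, noise_frac=config.plant.noise_frac,
                                  context_dissociated=config.plant.context_dissociated)
        else:
            plant = default_plant(noise_frac=config.plant.noise_frac,
                                  context_dissociated=config.plant.context_dissociated)
            plant.participant_id = f"sim{sseed:04d}"
        plan = study_plan(
            seed=sseed, directions=tuple(config.protocol.directions),
            magnitudes=magnitudes, ramp_reps=config.protocol.ramp_reps,
            planes=tuple(config.protocol.planes),
            superimposed_kinds=tuple(config.protocol.superimposed_kinds),
            sinusoid_reps=config.protocol.sinusoid_reps)
        trials, manifest = generate_study(plant, seed=sseed, plan=plan)
        if config.write_trials:
            cio.write_study(trials, manifest,
                            out_dir / "trials" / plant.participant_id)
        ds = StudyDataset(trials)

        log.info("fitting training conditions")
        models = train_ramp_models(
            ds, fit_cfg, directions=cardinals, magnitudes=magnitudes,
            threshold_nm=thr.exclusion_torque_range_nm)
        all_models.append(models)
        cio.save_models(models,
                        out_dir / "models" / f"{plant.participant_id}.json")

        for protocol in config.protocols:
            log.info("protocol: %s", protocol)
            if protocol == "direction":
                if not have_diagonals:
                    log.warning("no diagonal directions in protocol; skipping "
                                "direction generalization tests")
                    continue
                res = run_direction_generalization(
                    ds, fit_cfg, magnitudes=magnitudes, models=models,
                    threshold_nm=thr.exclusion_torque_range_nm)
            elif protocol == "magnitude":
                res = run_magnitude_generalization(
                    ds, fit_cfg, magnitudes=magnitudes, models=models,
                    threshold_nm=thr.exclusion_torque_range_nm)
            else:
                res = run_context_generalization(
                    ds, fit_cfg, protocol, magnitudes=magnitudes,
                    models=models,
                    threshold_nm=thr.exclusion_torque_range_nm)
            all_results.extend(res)

        if i == 0:
            try:
                _representative_figure(ds, models,
                                       out_dir / "representative_traces.png",
                                       fit_cfg)
            except Exception as e:  # plotting must never sink the run
                log.warning("figure generation failed: %s", e)

    results_df = cio.results_to_frame(all_results)
    results_df.to_csv(out_dir / "results.csv", index=False)
    summary = aggregate_report(all_results, good_fit_r2=thr.good_fit_r2,
                               good_fit_rmse=thr.good_fit_rmse_per_kg)
    summary.to_csv(out_dir / "summary.csv", index=False)
    (out_dir / "summary.txt").write_text(summary.to_string(index=False) + "\n")
    pc = _parameter_count_summary(all_models)
    pc.to_csv(out_dir / "parameter_counts.csv", index=False)

    import scipy

    manifest_doc = {
        "config": config.model_dump(),
        "config_hash": config.config_hash(),
        "subject_seeds": subject_seeds,
        "versions": {"numpy": np.__version__, "scipy": scipy.__version__,
                     "pandas": pd.__version__},
        "finished_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (out_dir / "run_manifest.json").write_text(
        json.dumps(manifest_doc, indent=1, default=str))
    log.info("report bundle written to %s", out_dir)
    return out_dir
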