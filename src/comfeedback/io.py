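"""On-disk formats: trial CSV + JSON sidecar, model JSON, results tables.

A trial is stored as one wide CSV (column ``time_s`` plus one column per
channel, e.g. ``com_d_x_m``, ``com_v_x_mps``, ``com_a_x_mps2``,
``tau_ankle_pf_Nm``) with a ``<stem>.meta.json`` sidecar holding the trial
metadata.  Channel names follow ``<quantity>_<axis-or-joint>_<unit>`` and are
part of the contract.  Fitted models serialize to a single JSON document per
training run; generalization results flatten to a CSV table.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .fitting import FitResult
from .model import CoMFeedbackModel
from .signals import TimeSeries, TimeSeriesTrial, TrialMeta

__all__ = [
    "write_trial",
    "read_trial",
    "write_study",
    "read_study",
    "save_models",
    "load_models",
    "results_to_frame",
]


def write_trial(trial: TimeSeriesTrial, path: str | Path) -> Path:
    """Write one trial as ``<path>.csv`` + ``<path>.meta.json``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ref = next(iter(trial.channels.values()))
    df = pd.DataFrame({"time_s": ref.times()})
    for name, ch in trial.channels.items():
        df[name] = ch.values
    csv_path = path.with_suffix(".csv")
    df.to_csv(csv_path, index=False, float_format="%.9g")
    meta = trial.meta.to_dict()
    meta["dt"] = trial.dt
    meta["t0"] = trial.t0
    path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=1))
    return csv_path


def read_trial(path: str | Path) -> TimeSeriesTrial:
    path = Path(path)
    df = pd.read_csv(path.with_suffix(".csv"))
    meta_d = json.loads(path.with_suffix(".meta.json").read_text())
    t = df["time_s"].to_numpy()
    t0 = float(meta_d.pop("t0", t[0]))
    dt = float(meta_d.pop("dt", t[1] - t[0]))
    meta = TrialMeta.from_dict(meta_d)
    chans = {c: TimeSeries(t0=t0, dt=dt, values=df[c].to_numpy(),
                           units=c.rsplit("_", 1)[-1])
             for c in df.columns if c != "time_s"}
    return TimeSeriesTrial(chans, meta)


def write_study(trials: list[TimeSeriesTrial], manifest: pd.DataFrame,
                out_dir: str | Path) -> Path:
    """Write all trials plus ``manifest.csv`` into a directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    names = []
    for i, tr in enumerate(trials):
        name = f"trial_{i:04d}"
        write_trial(tr, out_dir / name)
        names.append(name)
    manifest = manifest.copy()
    manifest["file"] = [f"{n}.csv" for n in names]
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return out_dir


def read_study(in_dir: str | Path) -> tuple[list[TimeSeriesTrial], pd.DataFrame]:
    in_dir = Path(in_dir)
    manifest = pd.read_csv(in_dir / "manifest.csv")
    trials = [read_trial(in_dir / Path(f).stem) for f in manifest["file"]]
    return trials, manifest


def _fit_record(key: tuple, fit: FitResult | None) -> dict:
    joint, direction, magnitude = key
    rec = {"joint_id": joint, "direction_deg": direction,
           "magnitude": magnitude, "excluded": fit is None}
    if fit is not None:
        rec.update(model=fit.model.to_dict(), r2_train=fit.r2_train,
                   rmse_per_kg_train=fit.rmse_per_kg_train,
                   stage1_r2=fit.stage1_r2,
                   stopped_after_stage1=fit.stopped_after_stage1,
                   active_parameters=fit.active_parameters,
                   diagnostics=fit.diagnostics)
    return rec


def save_models(models: dict[tuple, FitResult | None], path: str | Path) -> Path:
    """Serialize a training run (dict of (joint, direction, magnitude) cells)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    recs = [_fit_record(k, v) for k, v in sorted(models.items(),
                                                 key=lambda kv: str(kv[0]))]
    path.write_text(json.dumps(recs, indent=1))
    return path


def load_models(path: str | Path) -> dict[tuple, FitResult | None]:
    recs = json.loads(Path(path).read_text())
    out: dict[tuple, FitResult | None] = {}
    for rec in recs:
        key = (rec["joint_id"], float(rec["direction_deg"]), rec["magnitude"])
        if rec.get("excluded", False):
            out[key] = None
        else:
            out[key] = FitResult(
                model=CoMFeedbackModel.from_dict(rec["model"]),
                r2_train=rec["r2_train"],
                rmse_per_kg_train=rec["rmse_per_kg_train"],
                stage1_r2=rec["stage1_r2"],
                stopped_after_stage1=rec["stopped_after_stage1"],
                active_parameters=rec["active_parameters"],
                diagnostics=rec.get("diagnostics", {}))
    return out


def results_to_frame(results) -> pd.DataFrame:
    """Flatten GeneralizationResult records to a table."""
    rows = []
    for r in results:
        row = dict(protocol=r.protocol, joint_id=r.joint_id, role=r.role,
                   participant_id=r.participant_id, excluded=r.excluded,
                   r2=np.nan if r.r2 is None else r.r2,
                   rmse_per_kg=np.nan if r.rmse_per_kg is None else r.rmse_per_kg)
        for k, v in r.train_key.items():
            row[f"train_{k}"] = v
        for k, v in r.test_key.items():
            row[f"test_{k}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
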