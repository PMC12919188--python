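"""Condition averaging, exclusion, and superimposed-response extraction.

Raw trials are averaged within each condition (perturbation direction x
magnitude, or sinusoid plane x starting direction), truncated around the
perturbation onset, and background-referenced before model fitting.  For
sinusoids with superimposed perturbations, the balance-correcting response to
each superimposed perturbation is isolated by subtracting the matching
perturbation-free sinusoid average, segmenting at the known perturbation
onsets, and re-basing each segment so its onset is time zero.

Trials are averaged separately per sinusoid starting direction (rather than
sign-flipping opposite-start trials onto one template): the feedback response
is deliberately asymmetric between opposite CoM excursions, so a sign flip is
not a symmetry of the response.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .signals import TimeSeries, TimeSeriesTrial, TrialMeta, truncate_window

__all__ = [
    "ConditionAverage",
    "condition_key",
    "average_condition",
    "extract_superimposed_response",
    "exclude_low_torque",
    "StudyDataset",
]

log = logging.getLogger(__name__)


def condition_key(meta: TrialMeta) -> tuple:
    """Hashable condition identity of a trial (everything but the rep)."""
    return (meta.condition_label, meta.direction_deg, meta.plane,
            meta.start_direction_deg, meta.magnitude_label)


@dataclass
class ConditionAverage:
    """Pointwise mean of the repetitions of one condition."""

    key: tuple
    trial: TimeSeriesTrial
    n_trials: int
    excluded_reps: list = field(default_factory=list)


def average_condition(trials: list[TimeSeriesTrial]) -> ConditionAverage:
    """Channel-wise pointwise mean across repetitions of one condition.

    All trials must share the condition key, time base, and onset.
    """
    if not trials:
        raise ValueError("need at least one trial")
    ref = trials[0]
    key = condition_key(ref.meta)
    for tr in trials[1:]:
        if condition_key(tr.meta) != key:
            raise ValueError(f"mixed condition keys: {condition_key(tr.meta)} "
                             f"vs {key}")
        if (abs(tr.t0 - ref.t0) > 1e-9 or abs(tr.dt - ref.dt) > 1e-12
                or len(tr) != len(ref)
                or abs(tr.meta.onset_s - ref.meta.onset_s) > 1e-9):
            raise ValueError("trials are not aligned on a shared time base")
    chans = {}
    for name, ch in ref.channels.items():
        acc = np.zeros(len(ch))
        for tr in trials:
            acc += tr[name].values
        chans[name] = ch.with_values(acc / len(trials))
    meta = replace(ref.meta, rep_index=-1)
    return ConditionAverage(key=key, trial=TimeSeriesTrial(chans, meta),
                            n_trials=len(trials))


def _phase_lag_s(a: np.ndarray, b: np.ndarray, freq: float,
                 dt: float) -> float:
    """Time lag of ``a`` relative to ``b`` at one frequency.

    Estimated from the phase difference of the complex Fourier component at
    ``freq`` -- the maximum-likelihood lag estimator for a sinusoid in white
    noise, and far more robust than locating the (flat) peak of the broadband
    cross-correlation.  Returns 0 when either signal has no energy at
    ``freq``.
    """
    n = min(a.size, b.size)
    w = 2 * np.pi * freq
    ph = np.exp(-1j * w * dt * np.arange(n))
    ca = complex(a[:n] @ ph)
    cb = complex(b[:n] @ ph)
    scale = max(np.abs(ca), np.abs(cb))
    if scale <= 0 or min(np.abs(ca), np.abs(cb)) < 1e-6 * scale:
        return 0.0
    dphi = np.angle(ca / cb)
    return float(dphi / w)


def extract_superimposed_response(pert_trial: TimeSeriesTrial,
                                  sinusoid_only_avg: ConditionAverage,
                                  pre_s: float = 0.25, post_s: float = 1.0,
                                  max_phase_lag_s: float = 0.010,
                                  ) -> list[TimeSeriesTrial]:
    """Isolate the responses to perturbations superimposed on a sinusoid.

    Subtracts the matching perturbation-free sinusoid average channel-wise,
    segments the difference at each superimposed-perturbation onset (from
    trial metadata), and re-bases every segment so its onset is time zero,
    truncated to ``[-pre_s, +post_s]``.  Segment metadata carries the
    perturbation direction, magnitude label, and accelerating/braking class.

    A phase mismatch between trial and average (cross-correlation lag of the
    platform-position channel beyond ``max_phase_lag_s``, default 10 ms --
    under 1% of a 0.75 Hz cycle, but wide enough that measurement-noise
    jitter of the correlation peak does not false-alarm) is an error.
    """
    avg = sinusoid_only_avg.trial
    m, am = pert_trial.meta, avg.meta
    if m.plane != am.plane or m.start_direction_deg != am.start_direction_deg:
        raise ValueError("sinusoid average does not match the trial's plane or "
                         "starting direction")
    if len(pert_trial) != len(avg) or abs(pert_trial.dt - avg.dt) > 1e-12:
        raise ValueError("trial and average are not on the same grid")
    axis = "y" if m.plane == "sagittal" else "x"
    pchan = f"plat_pos_{axis}_m"
    freq = float(m.extra.get("sinusoid", {}).get("frequency", 0.75))
    # align on the prefix before the first superimposed perturbation, where
    # trial and average should agree up to noise
    events = m.extra.get("superimposed_events", [])
    stop = len(pert_trial)
    if events:
        first = min(ev["onset_s"] for ev in events)
        one_cycle = int(round(1.0 / (freq * pert_trial.dt)))
        stop = max(one_cycle,
                   int(round((first - pert_trial.t0) / pert_trial.dt)))
    lag_s = _phase_lag_s(pert_trial[pchan].values[:stop],
                         avg[pchan].values[:stop], freq, pert_trial.dt)
    if abs(lag_s) > max(pert_trial.dt, max_phase_lag_s):
        raise ValueError(f"phase mismatch between trial and sinusoid average: "
                         f"lag {lag_s * 1000:.1f} ms")

    diff = {name: ch.with_values(ch.values - avg[name].values)
            for name, ch in pert_trial.channels.items()}
    events = m.extra.get("superimposed_events", [])
    segments = []
    dt = pert_trial.dt
    for ev in events:
        i_on = int(round((ev["onset_s"] - pert_trial.t0) / dt))
        i0 = i_on - int(round(pre_s / dt))
        i1 = i_on + int(round(post_s / dt))
        if i0 < 0 or i1 >= len(pert_trial):
            raise ValueError("superimposed-response window exceeds the record")
        chans = {name: TimeSeries(t0=-pre_s, dt=dt,
                                  values=ch.values[i0:i1 + 1], units=ch.units)
                 for name, ch in diff.items()}
        meta = TrialMeta(
            participant_id=m.participant_id, mass_kg=m.mass_kg,
            condition_label=f"superimposed_{ev['cls']}",
            direction_deg=ev["direction_deg"], plane=m.plane,
            start_direction_deg=m.start_direction_deg,
            magnitude_label=ev["magnitude_label"], onset_s=0.0,
            rep_index=m.rep_index,
            extra={"cls": ev["cls"], "crossing": ev.get("crossing")})
        segments.append(TimeSeriesTrial(chans, meta))
    return segments


def exclude_low_torque(avg: ConditionAverage | TimeSeriesTrial, joint_id: str,
                       threshold_nm: float = 10.0) -> bool:
    """True iff the joint's torque range over the record is below threshold.

    A range exactly at the threshold is retained (strict less-than); the
    default 10 Nm marks traces with too little signal to fit.
    """
    trial = avg.trial if isinstance(avg, ConditionAverage) else avg
    tau = trial[f"tau_{joint_id}_Nm"]
    return bool(np.ptp(tau.values) < threshold_nm)


class StudyDataset:
    """One participant's trials grouped by condition, with cached averages.

    Provides the averaged, windowed inputs the fitting and generalization
    stages consume: ramp-condition averages, perturbation-free sinusoid
    averages per (plane, starting direction), and averaged extracted
    responses to superimposed perturbations grouped by (plane, perturbation
    direction, accelerating/braking class).
    """

    def __init__(self, trials: list[TimeSeriesTrial]):
        self.ramp: dict[tuple, list[TimeSeriesTrial]] = {}
        self.sinusoid_only: dict[tuple, list[TimeSeriesTrial]] = {}
        self.superimposed: dict[str, list[TimeSeriesTrial]] = {}
        self.mass_kg = trials[0].meta.mass_kg if trials else 70.0
        for tr in trials:
            m = tr.meta
            if m.condition_label.startswith("ramp"):
                self.ramp.setdefault(
                    (m.direction_deg, m.magnitude_label), []).append(tr)
            elif m.condition_label.endswith("none"):
                self.sinusoid_only.setdefault(
                    (m.plane, m.start_direction_deg), []).append(tr)
            else:
                sup = m.condition_label.rsplit("_", 1)[-1]
                self.superimposed.setdefault(sup, []).append(tr)
        self._cache: dict = {}

    # -- averages -----------------------------------------------------------
    def ramp_average(self, direction_deg: float, magnitude: str,
                     ) -> ConditionAverage:
        key = ("ramp", direction_deg, magnitude)
        if key not in self._cache:
            trials = self.ramp.get((direction_deg, magnitude))
            if not trials:
                raise KeyError(f"no ramp trials at {direction_deg} deg, "
                               f"{magnitude}")
            self._cache[key] = average_condition(trials)
        return self._cache[key]

    def sinusoid_average(self, plane: str, start_direction_deg: float,
                         ) -> ConditionAverage:
        key = ("sin", plane, start_direction_deg)
        if key not in self._cache:
            trials = self.sinusoid_only.get((plane, start_direction_deg))
            if not trials:
                raise KeyError(f"no sinusoid trials for {plane} starting at "
                               f"{start_direction_deg} deg")
            self._cache[key] = average_condition(trials)
        return self._cache[key]

    def superimposed_averages(self, sup: str, pre_s: float = 0.25,
                              post_s: float = 1.0,
                              ) -> dict[tuple, ConditionAverage]:
        """Averaged extracted responses keyed by (plane, direction, class)."""
        key = ("sup", sup, pre_s, post_s)
        if key not in self._cache:
            groups: dict[tuple, list[TimeSeriesTrial]] = {}
            for tr in self.superimposed.get(sup, []):
                avg = self.sinusoid_average(tr.meta.plane,
                                            tr.meta.start_direction_deg)
                for seg in extract_superimposed_response(tr, avg, pre_s, post_s):
                    gk = (seg.meta.plane, seg.meta.direction_deg,
                          seg.meta.extra["cls"])
                    groups.setdefault(gk, []).append(seg)
            out = {}
            for gk, segs in groups.items():
                # segments within a group can come from different reps /
                # starting directions; align on the shared re-based grid
                ref = segs[0]
                chans = {name: ch.with_values(
                    np.mean([s[name].values for s in segs], axis=0))
                    for name, ch in ref.channels.items()}
                meta = replace(ref.meta, rep_index=-1)
                out[gk] = ConditionAverage(
                    key=gk, trial=TimeSeriesTrial(chans, meta),
                    n_trials=len(segs))
            self._cache[key] = out
        return self._cache[key]

    # -- windowed views -----------------------------------------------------
    def windowed_ramp(self, direction_deg: float, magnitude: str,
                      pre_s: float = 0.25, post_s: float = 1.0,
                      ) -> TimeSeriesTrial:
        return truncate_window(self.ramp_average(direction_deg, magnitude).trial,
                               pre_s, post_s)

    def windowed_sinusoid(self, plane: str, start_direction_deg: float,
                          pre_s: float = 0.25, post_s: float = 15.0,
                          ) -> TimeSeriesTrial:
        return truncate_window(
            self.sinusoid_average(plane, start_direction_deg).trial,
            pre_s, post_s)
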