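"""Uniformly sampled time-series primitives.

All continuous signals in the pipeline (platform kinematics, center-of-mass
displacement/velocity/acceleration, joint torques) are carried as
:class:`TimeSeries` objects on a uniform grid.  A perturbation trial is a
:class:`TimeSeriesTrial`: a set of channels on a shared time base plus trial
metadata (participant mass, condition label, perturbation onset, ...).

Conventions
-----------
* Windows are closed intervals: truncating to ``[-0.25, +1.0]`` s at 1 kHz
  yields 1251 samples (inclusive endpoints).
* ``delay_signal`` rounds a requested lag to the nearest integer number of
  samples and back-fills the leading gap with the signal's first value,
  consistent with a quiescent pre-perturbation background.
* ``lowpass_filter`` is zero-phase (forward-backward second-order sections);
  the ``order`` argument is the nominal combined order, so ``order=4`` applies
  a 2nd-order Butterworth forward and backward.  Zero-phase filtering avoids
  introducing artificial lag that would bias fitted feedback delays.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy import signal as _sps

__all__ = [
    "TimeSeries",
    "TrialMeta",
    "TimeSeriesTrial",
    "lowpass_filter",
    "resample_linear",
    "delay_signal",
    "halfwave_split",
    "truncate_window",
]


@dataclass(frozen=True)
class TimeSeries:
    """A uniformly sampled real signal.

    Parameters
    ----------
    t0 : float
        Time of the first sample (s).
    dt : float
        Sample interval (s); must be positive.
    values : numpy.ndarray
        Sample values; stored as a float64 copy.
    units : str
        Free-text unit label (e.g. ``"m"``, ``"Nm"``).
    """

    t0: float
    dt: float
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if v.ndim != 1:
            raise ValueError("TimeSeries values must be one-dimensional")
        if not np.all(np.isfinite(v)):
            raise ValueError("TimeSeries values must be finite")

    def __len__(self) -> int:
        return self.values.size

    @property
    def fs(self) -> float:
        """Sampling rate (Hz)."""
        return 1.0 / self.dt

    @property
    def t_end(self) -> float:
        return self.t0 + (len(self) - 1) * self.dt

    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(len(self))

    def index_of(self, t: float) -> int:
        """Nearest-sample index of time ``t`` (must lie inside the record)."""
        i = int(round((t - self.t0) / self.dt))
        if i < 0 or i >= len(self):
            raise ValueError(f"time {t} s outside record [{self.t0}, {self.t_end}] s")
        return i

    def with_values(self, values: np.ndarray) -> "TimeSeries":
        return replace(self, values=np.asarray(values, dtype=float))


@dataclass
class TrialMeta:
    """Metadata attached to a trial.

    ``direction_deg`` is the platform translation heading (0 = rightward,
    90 = anterior); sinusoid trials use ``plane`` (``"sagittal"`` along the
    90-270 axis, ``"frontal"`` along 0-180) plus ``start_direction_deg``.
    ``onset_s`` marks perturbation onset (or platform motion onset for pure
    sinusoid trials).  ``extra`` carries protocol-specific fields such as the
    list of superimposed-perturbation onsets.
    """

    participant_id: str = "anon"
    mass_kg: float = 70.0
    condition_label: str = ""
    direction_deg: float | None = None
    plane: str | None = None
    start_direction_deg: float | None = None
    magnitude_label: str | None = None
    onset_s: float = 0.0
    rep_index: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mass_kg <= 0:
            raise ValueError("mass_kg must be positive")

    def to_dict(self) -> dict:
        d = {
            "participant_id": self.participant_id,
            "mass_kg": self.mass_kg,
            "condition_label": self.condition_label,
            "direction_deg": self.direction_deg,
            "plane": self.plane,
            "start_direction_deg": self.start_direction_deg,
            "magnitude_label": self.magnitude_label,
            "onset_s": self.onset_s,
            "rep_index": self.rep_index,
            "extra": dict(self.extra),
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "TrialMeta":
        return cls(**{k: d.get(k) for k in (
            "participant_id", "mass_kg", "condition_label", "direction_deg",
            "plane", "start_direction_deg", "magnitude_label", "onset_s",
            "rep_index") if d.get(k) is not None},
            extra=dict(d.get("extra", {})))


class TimeSeriesTrial:
    """Named channels on a shared time base plus trial metadata."""

    def __init__(self, channels: Mapping[str, TimeSeries], meta: TrialMeta):
        channels = dict(channels)
        if not channels:
            raise ValueError("trial needs at least one channel")
        ref = next(iter(channels.values()))
        for name, ch in channels.items():
            if (abs(ch.t0 - ref.t0) > 1e-9 or abs(ch.dt - ref.dt) > 1e-12
                    or len(ch) != len(ref)):
                raise ValueError(f"channel {name!r} not on the shared time base")
        if not (ref.t0 - 1e-9 <= meta.onset_s <= ref.t_end + 1e-9):
            raise ValueError("onset_s lies outside the recorded interval")
        self.channels: dict[str, TimeSeries] = channels
        self.meta = meta

    @property
    def t0(self) -> float:
        return next(iter(self.channels.values())).t0

    @property
    def dt(self) -> float:
        return next(iter(self.channels.values())).dt

    def __len__(self) -> int:
        return len(next(iter(self.channels.values())))

    def __getitem__(self, name: str) -> TimeSeries:
        return self.channels[name]

    def map_channels(self, fn) -> "TimeSeriesTrial":
        """Apply ``fn(name, TimeSeries) -> TimeSeries`` to every channel."""
        return TimeSeriesTrial({k: fn(k, v) for k, v in self.channels.items()},
                               self.meta)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def lowpass_filter(x: TimeSeries, cutoff_hz: float, order: int = 4) -> TimeSeries:
    """Zero-phase Butterworth low-pass filter.

    ``order`` is the nominal combined order; the filter is applied as
    forward-backward second-order sections of order ``order // 2``, so the
    effective magnitude response is the squared Butterworth response and the
    phase response is identically zero.
    """
    if len(x) < 2:
        raise ValueError("filtering needs at least 2 samples")
    if order < 2 or order % 2:
        raise ValueError("order must be a positive even integer")
    nyq = 0.5 * x.fs
    if not 0 < cutoff_hz < nyq:
        raise ValueError(f"cutoff {cutoff_hz} Hz must lie in (0, {nyq}) Hz")
    sos = _sps.butter(order // 2, cutoff_hz / nyq, output="sos")
    y = _sps.sosfiltfilt(sos, x.values)
    return x.with_values(y)


def resample_linear(x: TimeSeries, target_hz: float) -> TimeSeries:
    """Resample by linear interpolation onto a grid at ``target_hz``.

    The new grid starts at ``x.t0`` and covers the original span; the first
    sample is always preserved, and the last whenever the span is an integer
    number of new intervals.
    """
    if target_hz <= 0:
        raise ValueError("target_hz must be positive")
    if len(x) < 2:
        raise ValueError("resampling needs at least 2 samples")
    new_dt = 1.0 / target_hz
    n_new = int(np.floor((x.t_end - x.t0) / new_dt + 1e-9)) + 1
    if n_new < 1:
        raise ValueError("empty target grid")
    t_new = x.t0 + new_dt * np.arange(n_new)
    y = np.interp(t_new, x.times(), x.values)
    return TimeSeries(t0=x.t0, dt=new_dt, values=y, units=x.units)


def delay_signal(x: TimeSeries, lambda_s: float) -> TimeSeries:
    """Delay by ``lambda_s`` seconds, rounded to the nearest sample.

    ``y(t) = x(t - lambda)``; the leading gap is back-filled with ``x[0]``
    (the pre-perturbation background).  Output keeps the time base.
    """
    if lambda_s < 0:
        raise ValueError("lambda_s must be nonnegative")
    lag = int(round(lambda_s / x.dt))
    if lag >= len(x):
        raise ValueError(f"delay of {lag} samples exceeds record length {len(x)}")
    if lag == 0:
        return x
    y = np.empty_like(x.values)
    y[:lag] = x.values[0]
    y[lag:] = x.values[: len(x) - lag]
    return x.with_values(y)


def halfwave_split(x: TimeSeries) -> tuple[TimeSeries, TimeSeries]:
    """Half-wave rectification: ``(max(x, 0), min(x, 0))``; pos + neg == x."""
    pos = np.maximum(x.values, 0.0)
    neg = np.minimum(x.values, 0.0)
    return x.with_values(pos), x.with_values(neg)


def truncate_window(trial: TimeSeriesTrial, pre_s: float, post_s: float) -> TimeSeriesTrial:
    """Cut all channels to the closed window ``[onset - pre_s, onset + post_s]``.

    The onset is re-expressed on the new time base (time zero stays absolute:
    the new ``t0`` is ``onset - pre_s``).  At 1 kHz, ``pre_s=0.25`` and
    ``post_s=1.0`` yield 1251 samples.
    """
    dt = trial.dt
    i_on = int(round((trial.meta.onset_s - trial.t0) / dt))
    i0 = i_on - int(round(pre_s / dt))
    i1 = i_on + int(round(post_s / dt))
    if i0 < 0 or i1 >= len(trial) or i1 < i0:
        raise ValueError("truncation window exceeds the record")
    new_t0 = trial.t0 + i0 * dt

    def cut(_name: str, ch: TimeSeries) -> TimeSeries:
        return TimeSeries(t0=new_t0, dt=dt, values=ch.values[i0:i1 + 1],
                          units=ch.units)

    out = trial.map_channels(cut)
    return out
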