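"""Shared fixtures: simulated trials and analytic CoM states.

Simulation-backed fixtures are session-scoped; everything is generated
programmatically from seeded ground truth.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from comfeedback.model import CoMState
from comfeedback.signals import TimeSeries, TrialMeta
from comfeedback.synthetic import (RAMP_HOLD_S, RAMP_ONSET_S,
                                   PerturbationSpec, default_plant,
                                   make_ramp_profile, simulate_trial)


def sim_ramp(plant, direction_deg: float, magnitude: str, seed=None,
             dt: float = 0.001):
    """Simulate one ramp-and-hold trial of the study protocol."""
    spec = PerturbationSpec.from_label(magnitude, direction_deg)
    pos, vel, acc = make_ramp_profile(spec, dt, RAMP_HOLD_S)
    th = math.radians(direction_deg)
    profiles = {}
    for axis, c in (("x", math.cos(th)), ("y", math.sin(th))):
        if abs(c) > 1e-12:
            profiles[axis] = (c * pos, c * vel, c * acc)
    meta = TrialMeta(mass_kg=plant.mass_kg, direction_deg=direction_deg,
                     magnitude_label=magnitude,
                     condition_label=f"ramp_{direction_deg:g}_{magnitude}",
                     onset_s=RAMP_ONSET_S)
    return simulate_trial(profiles, plant, meta, context="ramp", dt=dt,
                          seed=seed)


def analytic_com_state(n: int = 1251, dt: float = 0.001,
                       t0: float = -0.25) -> CoMState:
    """Smooth CoM state with both displacement signs: damped oscillation.

    d(t) = A e^(-bt) sin(w t) for t >= 0 (zero before), with v and a the
    exact analytic derivatives -- no simulation involved.
    """
    t = t0 + dt * np.arange(n)
    A, b, w = 0.05, 1.2, 2 * np.pi * 0.9
    tp = np.maximum(t, 0.0)
    e = np.exp(-b * tp)
    s, c = np.sin(w * tp), np.cos(w * tp)
    d = A * e * s
    v = A * e * (w * c - b * s)
    a = A * e * ((b * b - w * w) * s - 2 * b * w * c)
    mask = t < 0
    for arr in (d, v, a):
        arr[mask] = 0.0
    return CoMState(
        d=TimeSeries(t0, dt, d, "m"),
        v=TimeSeries(t0, dt, v, "mps"),
        a=TimeSeries(t0, dt, a, "mps2"),
    )


@pytest.fixture(scope="session")
def noiseless_plant():
    return default_plant(noise_frac=0.0)


@pytest.fixture(scope="session")
def ramp_trial(noiseless_plant):
    """Noiseless medium 90-deg ramp trial (shared, do not mutate)."""
    return sim_ramp(noiseless_plant, 90.0, "medium")


@pytest.fixture(scope="session")
def com_oscillation():
    return analytic_com_state()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
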