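"""Synthetic closed-loop balance study generator.

Emulates the full support-surface translation protocol -- ramp-and-hold
perturbations in 8 directions x 4 magnitudes x 5 repetitions (160 trials),
continuous 0.75 Hz / 7.7 cm sinusoids in the sagittal and frontal planes, and
sinusoids with discrete perturbations superimposed at displacement zero
crossings (36 sinusoid-block trials) -- on a simulated standing participant.

The participant is a linearized single inverted pendulum per horizontal axis:
CoM deviation ``d`` relative to the feet obeys

    m*h * dd(t) = m*g * d(t) - tau(t) - b*h * v(t) - m*h * p_acc(t)

where ``p_acc`` is platform acceleration and ``tau`` the summed torque of the
axis's ground-truth joint feedback models (ankle plantarflexion, knee flexion
and hip flexion act on the sagittal axis; hip adduction on the frontal axis).
Each joint's torque is produced by a known delayed CoM feedback model
evaluated on the simulated CoM history, so the closed loop embeds the exact
model structure the fitting stage estimates, and a noiseless recording
reproduces ``predict_torque(ground_truth, recorded CoM)`` sample for sample.
Measurement noise is additive, seeded, and proportional to each channel's
range; it never enters the loop, so repetitions of a condition differ only in
their noise draw.

Ground-truth parameter sets are optionally context-dependent ("ramp" vs
"sinusoid" blocks), which reproduces the empirical dissociation in which
ankle and frontal-plane hip feedback differs between discrete perturbations
and cyclic movement while knee/hip flexion feedback transfers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .model import CoMFeedbackModel, FeedbackLoop
from .signals import TimeSeries, TimeSeriesTrial, TrialMeta

__all__ = [
    "PerturbationSpec",
    "SinusoidSpec",
    "PlantParams",
    "STUDY_MAGNITUDES",
    "JOINTS",
    "JOINT_AXES",
    "CARDINAL_DIRECTIONS",
    "DIAGONAL_DIRECTIONS",
    "make_ramp_profile",
    "make_sinusoid_profile",
    "simulate_trial",
    "default_plant",
    "subject_plant",
    "study_plan",
    "generate_study",
]

G = 9.81

#: joints and the horizontal axis of their CoM input
JOINT_AXES = {"ankle_pf": "y", "knee_flex": "y", "hip_flex": "y",
              "hip_add": "x"}
JOINTS = tuple(JOINT_AXES)

CARDINAL_DIRECTIONS = (0.0, 90.0, 180.0, 270.0)
DIAGONAL_DIRECTIONS = (45.0, 135.0, 225.0, 315.0)

#: the study's ramp magnitudes: displacement (m), peak velocity (m/s),
#: peak acceleration (g)
STUDY_MAGNITUDES = {
    "small_slow": (0.049, 0.16, 1.06),
    "small_fast": (0.049, 0.24, 1.6),
    "medium": (0.077, 0.16, 1.06),
    "large": (0.126, 0.24, 1.6),
}

PLANE_AXIS = {"sagittal": "y", "frontal": "x"}
#: cardinal heading of motion toward the positive axis of each plane
PLANE_POS_DIR = {"sagittal": 90.0, "frontal": 0.0}
PLANE_NEG_DIR = {"sagittal": 270.0, "frontal": 180.0}


@dataclass(frozen=True)
class PerturbationSpec:
    """Ramp-and-hold perturbation magnitude (trapezoidal velocity profile)."""

    displacement: float  # m
    peak_velocity: float  # m/s
    peak_acceleration: float  # g units
    direction_deg: float = 90.0
    label: str = ""

    def __post_init__(self) -> None:
        a_si = self.peak_acceleration * G
        if self.displacement < 0 or self.peak_velocity < 0:
            raise ValueError("displacement and velocity must be nonnegative")
        if self.displacement > 0:
            if a_si <= 0 or self.peak_velocity <= 0:
                raise ValueError("moving ramp needs positive velocity/acceleration")
            if self.displacement < self.peak_velocity ** 2 / a_si - 1e-12:
                raise ValueError(
                    "infeasible trapezoid: displacement < v^2 / a")

    @classmethod
    def from_label(cls, label: str, direction_deg: float = 90.0) -> "PerturbationSpec":
        d, v, a = STUDY_MAGNITUDES[label]
        return cls(d, v, a, direction_deg=direction_deg, label=label)


@dataclass(frozen=True)
class SinusoidSpec:
    """Continuous sinusoidal platform motion, optionally with superimposed ramps.

    ``superimposed`` lists ``(PerturbationSpec, zero-crossing index, class)``
    with class ``"accelerating"`` (same direction as the ongoing platform
    motion) or ``"braking"`` (opposing it); onsets sit exactly at displacement
    zero crossings ``k / (2 f)``.
    """

    amplitude: float = 0.077  # m
    frequency: float = 0.75  # Hz
    cycles: int = 10
    plane: str = "sagittal"
    start_sign: int = 1  # +1: first motion toward the positive axis
    superimposed: tuple = ()

    def __post_init__(self) -> None:
        if self.plane not in PLANE_AXIS:
            raise ValueError("plane must be 'sagittal' or 'frontal'")
        if self.start_sign not in (1, -1):
            raise ValueError("start_sign must be +1 or -1")
        ks = [k for _, k, _ in self.superimposed]
        if any(not 1 <= k <= 2 * self.cycles - 1 for k in ks):
            raise ValueError("zero-crossing index outside the sinusoid")
        for _, _, cls in self.superimposed:
            if cls not in ("accelerating", "braking"):
                raise ValueError(f"bad superimposed class {cls!r}")

    @property
    def start_direction_deg(self) -> float:
        return (PLANE_POS_DIR if self.start_sign > 0 else PLANE_NEG_DIR)[self.plane]

    def zero_crossing_times(self) -> np.ndarray:
        k = np.arange(1, 2 * self.cycles)
        return k / (2.0 * self.frequency)


@dataclass
class PlantParams:
    """Simulated participant: pendulum parameters plus ground-truth models.

    ``models`` maps context ("ramp", "sinusoid") -> joint id -> ground-truth
    :class:`CoMFeedbackModel`.  ``noise_frac`` scales per-channel measurement
    noise as a fraction of the channel's range within the trial.
    """

    mass_kg: float = 69.0
    com_height_m: float = 0.94
    damping_Ns_m: float = 20.0
    noise_frac: float = 0.02
    models: dict = field(default_factory=dict)
    divergence_limit_m: float = 0.5
    participant_id: str = "sim"

    def joint_models(self, context: str) -> dict[str, CoMFeedbackModel]:
        if context not in self.models:
            raise KeyError(f"no ground-truth models for context {context!r}")
        return self.models[context]


# ---------------------------------------------------------------------------
# Ground-truth model sets
# ---------------------------------------------------------------------------

def _loop(cs: str, ts: str, k_d=0.0, k_v=0.0, lam=0.0) -> FeedbackLoop:
    return FeedbackLoop(k_d=k_d, k_v=k_v, lambda_s=lam, com_sign=cs,
                        torque_sign=ts)


def _truth_model(joint: str, k_a: float, lam_a: float,
                 pos: tuple[float, float, float],
                 neg: tuple[float, float, float]) -> CoMFeedbackModel:
    kd_p, kv_p, lam_p = pos
    kd_n, kv_n, lam_n = neg
    return CoMFeedbackModel(
        joint_id=joint, axis=JOINT_AXES[joint],
        accel_loop=FeedbackLoop(k_a=k_a, lambda_s=lam_a),
        residual_loops=(
            _loop("+", "+", kd_p, kv_p, lam_p),
            _loop("+", "-"),
            _loop("-", "+"),
            _loop("-", "-", kd_n, kv_n, lam_n),
        ))


# Base gains (Nm per m / Nm s per m) for a 69 kg, 0.94 m CoM-height subject.
# Restoring feedback lives in the (+CoM -> +torque) and (-CoM -> -torque)
# loops with deliberate left/right--fore/aft asymmetry; totals per axis exceed
# the gravitational destabilization m*g and leave the closed loop underdamped
# so perturbation responses overshoot and excite both CoM signs.
_BASE_TRUTH = {
    "ankle_pf": dict(k_a=0.0, lam_a=0.0,
                     pos=(700.0, 130.0, 0.100), neg=(620.0, 115.0, 0.110)),
    "knee_flex": dict(k_a=5.0, lam_a=0.005,
                      pos=(420.0, 85.0, 0.120), neg=(380.0, 75.0, 0.130)),
    "hip_flex": dict(k_a=15.0, lam_a=0.005,
                     pos=(620.0, 115.0, 0.095), neg=(560.0, 100.0, 0.105)),
    "hip_add": dict(k_a=8.0, lam_a=0.010,
                    pos=(1800.0, 340.0, 0.100), neg=(1600.0, 300.0, 0.110)),
}

#: joints whose feedback changes between discrete-perturbation and cyclic
#: movement contexts in the dissociated plant
CONTEXT_DEPENDENT_JOINTS = ("ankle_pf", "hip_add")
#: extra intrinsic acceleration gain those joints acquire in the cyclic context
_SINUSOID_ACCEL_GAIN = {"ankle_pf": 80.0, "hip_add": 120.0}


def _base_models() -> dict[str, CoMFeedbackModel]:
    return {j: _truth_model(j, **kw) for j, kw in _BASE_TRUTH.items()}


def default_plant(mass_kg: float = 69.0, com_height_m: float = 0.94,
                  noise_frac: float = 0.02,
                  context_dissociated: bool = False) -> PlantParams:
    """Plant with the base ground-truth models.

    With ``context_dissociated=True`` the ankle and hip-adduction models of
    the sinusoid context acquire a large intrinsic acceleration gain, so
    ramp-trained fits for those joints do not transfer to cyclic movement.
    """
    ramp = _base_models()
    if context_dissociated:
        sinus = {}
        for j, m in ramp.items():
            if j in CONTEXT_DEPENDENT_JOINTS:
                # zero-delay intrinsic gain: acts as added effective mass in
                # the loop, so the dissociated plant stays stable
                sinus[j] = replace(m, accel_loop=FeedbackLoop(
                    k_a=_SINUSOID_ACCEL_GAIN[j], lambda_s=0.0))
            else:
                sinus[j] = m
    else:
        sinus = dict(ramp)
    return PlantParams(mass_kg=mass_kg, com_height_m=com_height_m,
                       noise_frac=noise_frac,
                       models={"ramp": ramp, "sinusoid": sinus})


def subject_plant(seed: int, noise_frac: float = 0.02,
                  context_dissociated: bool = False) -> PlantParams:
    """Seeded random participant: body parameters and jittered ground truth.

    Gains scale with ``mass * CoM height`` (so the closed-loop dynamics stay
    in the same regime across subjects) times a per-gain multiplicative
    jitter; delays move by a whole 5 ms grid step at random, staying within
    the physiological search bounds.
    """
    rng = np.random.default_rng(seed)
    mass = float(np.clip(rng.normal(69.0, 11.0), 50.0, 95.0))
    height = float(np.clip(rng.normal(0.94, 0.06), 0.80, 1.10))
    scale = (mass * height) / (69.0 * 0.94)

    def jitter_gain(g: float) -> float:
        return g * scale * rng.uniform(0.92, 1.08) if g else 0.0

    def jitter_delay(lam: float, lo: float, hi: float) -> float:
        if lam == 0.0:
            return lam
        step = 0.005 * rng.integers(-1, 2)
        return float(np.clip(lam + step, lo, hi))

    plant = PlantParams(mass_kg=mass, com_height_m=height,
                        noise_frac=noise_frac,
                        participant_id=f"sim{seed:04d}")
    ramp = {}
    for j, m in _base_models().items():
        al = m.accel_loop
        al = replace(al, k_a=jitter_gain(al.k_a),
                     lambda_s=jitter_delay(al.lambda_s, 0.0, 0.020))
        loops = tuple(
            replace(lp, k_d=jitter_gain(lp.k_d), k_v=jitter_gain(lp.k_v),
                    k_a=jitter_gain(lp.k_a),
                    lambda_s=jitter_delay(lp.lambda_s, 0.040, 0.250))
            for lp in m.residual_loops)
        ramp[j] = replace(m, accel_loop=al, residual_loops=loops)
    # the cyclic-movement context shares the jittered ramp models; with
    # dissociation the designated joints additionally gain a zero-delay
    # intrinsic acceleration term (scaled like the other gains)
    sinus = dict(ramp)
    if context_dissociated:
        for j in CONTEXT_DEPENDENT_JOINTS:
            sinus[j] = replace(ramp[j], accel_loop=FeedbackLoop(
                k_a=jitter_gain(_SINUSOID_ACCEL_GAIN[j]), lambda_s=0.0))
    plant.models = {"ramp": ramp, "sinusoid": sinus}
    return plant


# ---------------------------------------------------------------------------
# Platform profiles
# ---------------------------------------------------------------------------

def make_ramp_profile(spec: PerturbationSpec, dt: float = 0.001,
                      hold_s: float = 1.5) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Trapezoidal-velocity ramp-and-hold: (pos, vel, acc) sampled arrays.

    Accelerate at the peak acceleration to the peak velocity, cruise,
    decelerate to rest at the target displacement, hold for ``hold_s``.
    Velocity and acceleration are the analytic derivatives evaluated on the
    grid.
    """
    if spec.displacement == 0.0:
        n = int(round(hold_s / dt)) + 1
        z = np.zeros(n)
        return z, z.copy(), z.copy()
    A = spec.peak_acceleration * G
    V = spec.peak_velocity
    D = spec.displacement
    t_a = V / A
    t_c = (D - V * V / A) / V
    t_move = 2 * t_a + t_c
    n = int(round((t_move + hold_s) / dt)) + 1
    t = dt * np.arange(n)
    pos = np.empty(n)
    vel = np.empty(n)
    acc = np.empty(n)
    m1 = t < t_a
    m2 = (t >= t_a) & (t < t_a + t_c)
    m3 = (t >= t_a + t_c) & (t < t_move)
    m4 = t >= t_move
    pos[m1] = 0.5 * A * t[m1] ** 2
    vel[m1] = A * t[m1]
    acc[m1] = A
    pos[m2] = 0.5 * A * t_a ** 2 + V * (t[m2] - t_a)
    vel[m2] = V
    acc[m2] = 0.0
    td = t[m3] - (t_a + t_c)
    pos[m3] = 0.5 * A * t_a ** 2 + V * t_c + V * td - 0.5 * A * td ** 2
    vel[m3] = V - A * td
    acc[m3] = -A
    pos[m4] = D
    vel[m4] = 0.0
    acc[m4] = 0.0
    return pos, vel, acc


def make_sinusoid_profile(spec: SinusoidSpec, dt: float = 0.001,
                          tail_s: float = 0.0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sinusoidal platform motion with raised-cosine on/off taper.

    ``p(t) = s * e(t) * A * sin(2 pi f t)`` over ``cycles / f`` seconds, where
    the envelope ``e`` rises from 0 to 1 over the first half cycle and falls
    back over the last (avoiding the acceleration impulse a hard start would
    need); derivatives are analytic.  Superimposed ramps from the spec are
    added at their zero-crossing onsets with sign set by the accelerating /
    braking class.  ``tail_s`` appends a quiescent hold after the motion.
    """
    f, A, s = spec.frequency, spec.amplitude, float(spec.start_sign)
    w = 2 * math.pi * f
    T = spec.cycles / f
    T_h = 1.0 / (2 * f)  # half cycle: taper span
    n = int(round((T + tail_s) / dt)) + 1
    t = dt * np.arange(n)

    e = np.ones(n)
    de = np.zeros(n)
    d2e = np.zeros(n)
    wh = math.pi / T_h
    m_on = t < T_h
    e[m_on] = 0.5 * (1 - np.cos(wh * t[m_on]))
    de[m_on] = 0.5 * wh * np.sin(wh * t[m_on])
    d2e[m_on] = 0.5 * wh ** 2 * np.cos(wh * t[m_on])
    m_off = (t > T - T_h) & (t <= T)
    toff = T - t[m_off]
    e[m_off] = 0.5 * (1 - np.cos(wh * toff))
    de[m_off] = -0.5 * wh * np.sin(wh * toff)
    d2e[m_off] = 0.5 * wh ** 2 * np.cos(wh * toff)
    m_tail = t > T
    e[m_tail] = 0.0

    sin_, cos_ = np.sin(w * t), np.cos(w * t)
    pos = s * A * e * sin_
    vel = s * A * (de * sin_ + e * w * cos_)
    acc = s * A * (d2e * sin_ + 2 * de * w * cos_ - e * w ** 2 * sin_)
    pos[m_tail] = 0.0
    vel[m_tail] = 0.0
    acc[m_tail] = 0.0

    # superimposed ramps at zero crossings
    spans = []
    for pspec, k, cls in spec.superimposed:
        t_on = k / (2.0 * f)
        i_on = int(round(t_on / dt))
        v_sign = s * (1.0 if k % 2 == 0 else -1.0)  # platform velocity sign at crossing
        sign = v_sign if cls == "accelerating" else -v_sign
        rp, rv, ra = make_ramp_profile(pspec, dt, hold_s=0.0)
        spans.append((i_on, i_on + rp.size))
        end = min(n, i_on + rp.size)
        m = end - i_on
        pos[i_on:end] += sign * rp[:m]
        vel[i_on:end] += sign * rv[:m]
        acc[i_on:end] += sign * ra[:m]
        if end < n:
            pos[end:] += sign * rp[-1]
    spans.sort()
    for (a0, a1), (b0, _b1) in zip(spans, spans[1:]):
        if b0 < a1:
            raise ValueError("superimposed perturbations overlap")
    return pos, vel, acc


# ---------------------------------------------------------------------------
# Closed-loop simulation
# ---------------------------------------------------------------------------

def _axis_terms(models: list[CoMFeedbackModel], dt: float):
    """Flatten active model terms for the integrator.

    Returns ``(delayed_terms, accel0, n_joints)`` where ``delayed_terms`` is a
    list of ``(joint_idx, chan_idx, lag, gain, gate)`` with lag >= 1 sample
    and ``accel0[j]`` the summed zero-lag ungated acceleration gain of joint
    ``j`` (solved algebraically).
    """
    delayed = []
    accel0 = [0.0] * len(models)
    for j, m in enumerate(models):
        for lp in m.all_loops:
            if not lp.is_active:
                continue
            lag = int(round(lp.lambda_s / dt))
            gate = 0 if lp.com_sign == "both" else (1 if lp.com_sign == "+" else -1)
            for ci, g in enumerate(lp.gains):
                if g == 0.0:
                    continue
                if lag == 0:
                    if gate != 0 or ci != 2:
                        raise ValueError(
                            "zero-delay feedback is only supported for the "
                            "ungated acceleration loop")
                    accel0[j] += g
                else:
                    delayed.append((j, ci, lag, g, gate))
    return delayed, accel0


def _integrate_axis(p_acc: np.ndarray, dt: float, plant: PlantParams,
                    models: list[CoMFeedbackModel]):
    """Fixed-step closed-loop integration of one horizontal axis.

    Semi-implicit Euler at the sample rate; torque terms read the delayed CoM
    history with the same nearest-sample convention as ``delay_signal``.
    Returns ``(d, v, a, taus)`` with ``taus`` one torque array per model.
    """
    m, h, b = plant.mass_kg, plant.com_height_m, plant.damping_Ns_m
    delayed, accel0 = _axis_terms(models, dt)
    c0 = sum(accel0)
    n = p_acc.size
    nj = len(models)
    d = [0.0] * n
    v = [0.0] * n
    a = [0.0] * n
    taus = [[0.0] * n for _ in range(nj)]
    chans = (d, v, a)
    mg, mh, bh = m * G, m * h, b * h
    lim = plant.divergence_limit_m
    for t in range(n):
        dt_ = d[t]
        if abs(dt_) > lim:
            raise RuntimeError(
                f"closed-loop divergence: |CoM| > {lim} m at t={t * dt:.3f} s "
                f"(unstable ground-truth parameter set)")
        tau_del = 0.0
        for j, ci, lag, g, gate in delayed:
            idx = t - lag
            x = chans[ci][idx] if idx >= 0 else 0.0
            if gate == 1:
                if x < 0.0:
                    continue
            elif gate == -1:
                if x > 0.0:
                    continue
            c = g * x
            taus[j][t] += c
            tau_del += c
        a_t = (mg * dt_ - tau_del - bh * v[t] - mh * p_acc[t]) / (mh + c0)
        a[t] = a_t
        for j in range(nj):
            if accel0[j] != 0.0:
                taus[j][t] += accel0[j] * a_t
        if t + 1 < n:
            v[t + 1] = v[t] + a_t * dt
            d[t + 1] = d[t] + v[t + 1] * dt
    return (np.asarray(d), np.asarray(v), np.asarray(a),
            [np.asarray(x) for x in taus])


def simulate_trial(profiles: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
                   plant: PlantParams, meta: TrialMeta, context: str = "ramp",
                   dt: float = 0.001, seed: int | None = None,
                   ) -> TimeSeriesTrial:
    """Simulate one trial given per-axis platform profiles.

    ``profiles`` maps axis (``"x"``/``"y"``) to (pos, vel, acc) arrays on a
    shared grid starting at the perturbation onset; a quiescent lead-in of
    ``meta.onset_s`` seconds is prepended so delayed feedback has settled
    history.  With ``seed`` given, seeded Gaussian measurement noise with SD
    ``noise_frac`` x channel range is added to every recorded channel.
    """
    n_prof = max(p[0].size for p in profiles.values())
    n_pre = int(round(meta.onset_s / dt))
    n = n_pre + n_prof
    models = plant.joint_models(context)
    joint_ids = list(models)

    channels: dict[str, np.ndarray] = {}
    tau_total: dict[str, np.ndarray] = {j: np.zeros(n) for j in joint_ids}
    for axis in ("x", "y"):
        pa = np.zeros(n)
        pp = np.zeros(n)
        pv = np.zeros(n)
        if axis in profiles:
            pos, vel, acc = profiles[axis]
            pp[n_pre:n_pre + pos.size] = pos
            pv[n_pre:n_pre + vel.size] = vel
            pa[n_pre:n_pre + acc.size] = acc
            if pos.size and n_pre + pos.size < n:
                pp[n_pre + pos.size:] = pos[-1]
        ax_joints = [j for j in joint_ids if models[j].axis == axis]
        dd, vv, aa, taus = _integrate_axis(pa, dt, plant,
                                           [models[j] for j in ax_joints])
        channels[f"plat_pos_{axis}_m"] = pp
        channels[f"plat_vel_{axis}_mps"] = pv
        channels[f"plat_acc_{axis}_mps2"] = pa
        channels[f"com_d_{axis}_m"] = dd
        channels[f"com_v_{axis}_mps"] = vv
        channels[f"com_a_{axis}_mps2"] = aa
        for j, tau in zip(ax_joints, taus):
            tau_total[j] += tau
    for j in joint_ids:
        channels[f"tau_{j}_Nm"] = tau_total[j]

    if seed is not None and plant.noise_frac > 0:
        rng = np.random.default_rng(seed)
        for name, arr in channels.items():
            sd = plant.noise_frac * float(np.ptp(arr))
            if sd > 0:
                channels[name] = arr + rng.normal(0.0, sd, size=arr.size)

    ts = {name: TimeSeries(t0=0.0, dt=dt, values=arr,
                           units=name.rsplit("_", 1)[-1])
          for name, arr in channels.items()}
    return TimeSeriesTrial(ts, meta)


# ---------------------------------------------------------------------------
# Full study protocol
# ---------------------------------------------------------------------------

RAMP_ONSET_S = 0.5
RAMP_HOLD_S = 1.5
SINUSOID_TAIL_S = 2.0
SUPERIMPOSED_PER_TRIAL = 2
_SUP_SPECS = {"slow": "small_slow", "fast": "small_fast"}


def _superimposed_pattern(spec_label: str, rng: np.random.Generator,
                          cycles: int = 10) -> tuple:
    """Two well-separated superimposed perturbations with random classes."""
    k1 = int(rng.integers(2, 8))
    k2 = int(k1 + 6 + rng.integers(0, 5))
    k2 = min(k2, 2 * cycles - 2)
    out = []
    for k in (k1, k2):
        cls = "accelerating" if rng.random() < 0.5 else "braking"
        out.append((PerturbationSpec.from_label(spec_label), k, cls))
    return tuple(out)


def study_plan(seed: int = 0,
               directions=CARDINAL_DIRECTIONS + DIAGONAL_DIRECTIONS,
               magnitudes=tuple(STUDY_MAGNITUDES),
               ramp_reps: int = 5,
               planes=("sagittal", "frontal"),
               superimposed_kinds=("none", "slow", "fast"),
               sinusoid_reps: int = 6) -> list[dict]:
    """Enumerate every trial of the protocol (no simulation).

    The default protocol yields 160 ramp-and-hold trials (8 directions x 4
    magnitudes x 5 reps) and 36 sinusoid-block trials (2 planes x {none,
    slow, fast} superimposed x 6 reps, starting in either direction half the
    time each).
    """
    rng = np.random.default_rng(seed)
    plan: list[dict] = []
    for direction in directions:
        for mag in magnitudes:
            for rep in range(ramp_reps):
                plan.append(dict(kind="ramp", direction_deg=direction,
                                 magnitude_label=mag, rep_index=rep))
    for plane in planes:
        for sup in superimposed_kinds:
            for rep in range(sinusoid_reps):
                start_sign = 1 if rep < (sinusoid_reps + 1) // 2 else -1
                entry = dict(kind="sinusoid", plane=plane, superimposed=sup,
                             start_sign=start_sign, rep_index=rep)
                if sup != "none":
                    entry["pattern"] = _superimposed_pattern(
                        _SUP_SPECS[sup], rng)
                plan.append(entry)
    return plan


def _sinusoid_meta_extra(spec: SinusoidSpec, onset_s: float) -> dict:
    events = []
    for pspec, k, cls in spec.superimposed:
        t_on = k / (2.0 * spec.frequency)
        v_sign = spec.start_sign * (1 if k % 2 == 0 else -1)
        sign = v_sign if cls == "accelerating" else -v_sign
        direction = (PLANE_POS_DIR if sign > 0 else PLANE_NEG_DIR)[spec.plane]
        events.append(dict(onset_s=onset_s + t_on, crossing=k, cls=cls,
                           direction_deg=direction,
                           magnitude_label=pspec.label))
    return {"superimposed_events": events,
            "sinusoid": {"amplitude": spec.amplitude,
                         "frequency": spec.frequency,
                         "cycles": spec.cycles,
                         "start_sign": spec.start_sign}}


def generate_study(plant: PlantParams, seed: int = 0, dt: float = 0.001,
                   plan: list[dict] | None = None,
                   ) -> tuple[list[TimeSeriesTrial], pd.DataFrame]:
    """Simulate the full protocol; returns (trials, manifest).

    The closed loop is deterministic per condition, so each unique condition
    is integrated once and repetitions differ only in their seeded
    measurement-noise draw.
    """
    plan = study_plan(seed) if plan is None else plan
    trials: list[TimeSeriesTrial] = []
    rows = []
    cache: dict[tuple, TimeSeriesTrial] = {}
    for idx, entry in enumerate(plan):
        trial_seed = None if plant.noise_frac == 0 else int(
            np.random.default_rng([seed, idx]).integers(2 ** 31))
        if entry["kind"] == "ramp":
            direction, mag = entry["direction_deg"], entry["magnitude_label"]
            key = ("ramp", direction, mag)
            if key not in cache:
                spec = PerturbationSpec.from_label(mag, direction)
                pos, vel, acc = make_ramp_profile(spec, dt, RAMP_HOLD_S)
                th = math.radians(direction)
                profiles = {}
                for axis, c in (("x", math.cos(th)), ("y", math.sin(th))):
                    if abs(c) > 1e-12:
                        profiles[axis] = (c * pos, c * vel, c * acc)
                meta0 = TrialMeta(participant_id=plant.participant_id,
                                  mass_kg=plant.mass_kg,
                                  condition_label=f"ramp_{direction:g}_{mag}",
                                  direction_deg=direction, magnitude_label=mag,
                                  onset_s=RAMP_ONSET_S)
                cache[key] = simulate_trial(profiles, plant, meta0,
                                            context="ramp", dt=dt, seed=None)
            base = cache[key]
            meta = replace(base.meta, rep_index=entry["rep_index"])
        else:
            plane, sup = entry["plane"], entry["superimposed"]
            pattern = entry.get("pattern", ())
            key = ("sin", plane, sup, entry["start_sign"], entry["rep_index"]
                   if sup != "none" else 0)
            if key not in cache:
                spec = SinusoidSpec(plane=plane, start_sign=entry["start_sign"],
                                    superimposed=pattern)
                pos, vel, acc = make_sinusoid_profile(spec, dt,
                                                      tail_s=SINUSOID_TAIL_S)
                axis = PLANE_AXIS[plane]
                meta0 = TrialMeta(participant_id=plant.participant_id,
                                  mass_kg=plant.mass_kg,
                                  condition_label=f"sin_{plane}_{sup}",
                                  plane=plane,
                                  start_direction_deg=spec.start_direction_deg,
                                  magnitude_label=f"sin_{sup}",
                                  onset_s=RAMP_ONSET_S,
                                  extra=_sinusoid_meta_extra(spec, RAMP_ONSET_S))
                cache[key] = simulate_trial({axis: (pos, vel, acc)}, plant,
                                            meta0, context="sinusoid", dt=dt,
                                            seed=None)
            base = cache[key]
            meta = replace(base.meta, rep_index=entry["rep_index"])

        if trial_seed is not None:
            rng = np.random.default_rng(trial_seed)
            noisy = {}
            for name, ch in base.channels.items():
                sd = plant.noise_frac * float(np.ptp(ch.values))
                noisy[name] = ch.with_values(
                    ch.values + rng.normal(0.0, sd, size=len(ch))
                    if sd > 0 else ch.values)
            trial = TimeSeriesTrial(noisy, meta)
        else:
            trial = TimeSeriesTrial(dict(base.channels), meta)
        trials.append(trial)
        rows.append(dict(trial_index=idx, kind=entry["kind"],
                         condition_label=trial.meta.condition_label,
                         direction_deg=trial.meta.direction_deg,
                         plane=trial.meta.plane,
                         magnitude_label=trial.meta.magnitude_label,
                         start_direction_deg=trial.meta.start_direction_deg,
                         rep_index=trial.meta.rep_index,
                         onset_s=trial.meta.onset_s,
                         n_samples=len(trial)))
    return trials, pd.DataFrame(rows)
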