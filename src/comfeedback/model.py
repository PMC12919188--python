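"""Delayed center-of-mass (CoM) feedback torque model.

A joint's reactive torque is modelled as a quasi-linear sum of delayed CoM
deviation relative to the feet.  The structure comprises

* one *instantaneous acceleration loop*: an acceleration gain ``k_a`` and a
  short delay acting on the full (unrectified) CoM acceleration.  It captures
  the intrinsic mechanical response to both acceleration and deceleration of
  the CoM; and
* four *sign-gated residual loops*, one per combination of CoM-input sign
  (half-wave rectified positive / negative component) and torque-response
  sign (the loop reconstructs the positive or the negative part of the
  torque).  Each residual loop has displacement, velocity and acceleration
  gains ``k_d, k_v, k_a`` sharing a single delay ``lambda``.

The full structure exposes 18 independent parameters: 2 for the acceleration
loop and 4 loops x (3 gains + 1 delay).  The torque-sign gating is enforced
through sign bounds on the gains during fitting (a loop assigned to the
positive torque response may only produce a nonnegative contribution given
the sign of its rectified input), never by clipping the loop output, which
would break linearity in the gains.

The model is quasi-linear: linear in its gains at fixed delays, nonlinear
only through the half-wave rectification of its inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .signals import TimeSeries, delay_signal, halfwave_split

__all__ = [
    "CoMState",
    "FeedbackLoop",
    "CoMFeedbackModel",
    "RESIDUAL_LOOP_ROLES",
    "loop_output",
    "predict_torque",
    "count_active_parameters",
]

#: residual-loop roles as (com_sign, torque_sign) pairs, in canonical order
RESIDUAL_LOOP_ROLES: tuple[tuple[str, str], ...] = (
    ("+", "+"), ("+", "-"), ("-", "+"), ("-", "-"),
)

_CHANNELS = ("d", "v", "a")


@dataclass(frozen=True)
class CoMState:
    """CoM deviation relative to the feet along one horizontal axis."""

    d: TimeSeries  # displacement (m)
    v: TimeSeries  # velocity (m/s)
    a: TimeSeries  # acceleration (m/s^2)

    def __post_init__(self) -> None:
        for ch in (self.v, self.a):
            if (abs(ch.t0 - self.d.t0) > 1e-9 or abs(ch.dt - self.d.dt) > 1e-12
                    or len(ch) != len(self.d)):
                raise ValueError("CoMState channels must share a time base")

    def __len__(self) -> int:
        return len(self.d)

    @property
    def dt(self) -> float:
        return self.d.dt

    def channel(self, name: str) -> TimeSeries:
        return getattr(self, name)


@dataclass(frozen=True)
class FeedbackLoop:
    """One feedback pathway from delayed CoM deviation to torque.

    ``com_sign`` selects the half-wave component of each CoM channel fed to
    the loop (``"+"``, ``"-"``, or ``"both"`` for the unrectified signal).
    ``torque_sign`` records which part of the torque response the loop is
    assigned to reconstruct (``"+"``, ``"-"``, or ``"none"`` for the ungated
    acceleration loop); it constrains gain signs during fitting.
    """

    k_d: float = 0.0  # Nm per m
    k_v: float = 0.0  # Nm s per m
    k_a: float = 0.0  # Nm s^2 per m
    lambda_s: float = 0.0  # delay (s)
    com_sign: str = "both"
    torque_sign: str = "none"

    def __post_init__(self) -> None:
        if self.com_sign not in ("+", "-", "both"):
            raise ValueError(f"bad com_sign {self.com_sign!r}")
        if self.torque_sign not in ("+", "-", "none"):
            raise ValueError(f"bad torque_sign {self.torque_sign!r}")
        if self.lambda_s < 0:
            raise ValueError("lambda_s must be nonnegative")

    @property
    def gains(self) -> tuple[float, float, float]:
        return (self.k_d, self.k_v, self.k_a)

    @property
    def is_active(self) -> bool:
        return any(g != 0.0 for g in self.gains)

    def gated_channel(self, com: CoMState, name: str) -> TimeSeries:
        """The loop's input for CoM channel ``name`` (rectified per com_sign)."""
        ch = com.channel(name)
        if self.com_sign == "both":
            return ch
        pos, neg = halfwave_split(ch)
        return pos if self.com_sign == "+" else neg

    def to_dict(self) -> dict:
        return {"k_d": self.k_d, "k_v": self.k_v, "k_a": self.k_a,
                "lambda_s": self.lambda_s, "com_sign": self.com_sign,
                "torque_sign": self.torque_sign}

    @classmethod
    def from_dict(cls, d: dict) -> "FeedbackLoop":
        return cls(**d)


@dataclass(frozen=True)
class CoMFeedbackModel:
    """Full delayed CoM feedback model for one joint and one horizontal axis.

    ``axis`` names the CoM input plane: ``"y"`` (sagittal) for ankle
    plantarflexion, knee flexion and hip flexion; ``"x"`` (frontal) for hip
    adduction.  ``accel_loop`` must be ungated (``com_sign="both"``,
    ``torque_sign="none"``) with only ``k_a`` free; ``residual_loops`` holds
    exactly four loops, one per (com_sign, torque_sign) combination.
    """

    joint_id: str
    axis: str
    accel_loop: FeedbackLoop = field(
        default_factory=lambda: FeedbackLoop(com_sign="both", torque_sign="none"))
    residual_loops: tuple[FeedbackLoop, ...] = field(
        default_factory=lambda: tuple(
            FeedbackLoop(com_sign=cs, torque_sign=ts)
            for cs, ts in RESIDUAL_LOOP_ROLES))
    train_condition: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.axis not in ("x", "y"):
            raise ValueError("axis must be 'x' or 'y'")
        al = self.accel_loop
        if al.com_sign != "both" or al.torque_sign != "none":
            raise ValueError("acceleration loop must be ungated")
        if al.k_d != 0.0 or al.k_v != 0.0:
            raise ValueError("acceleration loop has only k_a and lambda free")
        loops = tuple(self.residual_loops)
        object.__setattr__(self, "residual_loops", loops)
        roles = tuple((lp.com_sign, lp.torque_sign) for lp in loops)
        if roles != RESIDUAL_LOOP_ROLES:
            raise ValueError(
                f"residual loops must cover roles {RESIDUAL_LOOP_ROLES} in order,"
                f" got {roles}")

    @property
    def all_loops(self) -> tuple[FeedbackLoop, ...]:
        return (self.accel_loop,) + self.residual_loops

    def scaled(self, c: float) -> "CoMFeedbackModel":
        """All gains scaled by ``c`` (delays unchanged)."""
        sc = lambda lp: replace(lp, k_d=c * lp.k_d, k_v=c * lp.k_v, k_a=c * lp.k_a)
        return replace(self, accel_loop=sc(self.accel_loop),
                       residual_loops=tuple(sc(lp) for lp in self.residual_loops))

    def to_dict(self) -> dict:
        return {"joint_id": self.joint_id, "axis": self.axis,
                "accel_loop": self.accel_loop.to_dict(),
                "residual_loops": [lp.to_dict() for lp in self.residual_loops],
                "train_condition": dict(self.train_condition)}

    @classmethod
    def from_dict(cls, d: dict) -> "CoMFeedbackModel":
        return cls(joint_id=d["joint_id"], axis=d["axis"],
                   accel_loop=FeedbackLoop.from_dict(d["accel_loop"]),
                   residual_loops=tuple(FeedbackLoop.from_dict(x)
                                        for x in d["residual_loops"]),
                   train_condition=dict(d.get("train_condition", {})))


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def loop_output(loop: FeedbackLoop, com: CoMState) -> TimeSeries:
    """Torque contribution of one loop.

    ``tau(t) = k_d s_d(t-l) + k_v s_v(t-l) + k_a s_a(t-l)`` where ``s_*`` is
    the (possibly rectified) CoM channel and ``l`` the loop delay, applied by
    nearest-sample shift with background back-fill.
    """
    out = np.zeros(len(com))
    for gain, name in zip(loop.gains, _CHANNELS):
        if gain == 0.0:
            continue
        s = loop.gated_channel(com, name)
        out += gain * delay_signal(s, loop.lambda_s).values
    return TimeSeries(t0=com.d.t0, dt=com.dt, values=out, units="Nm")


def predict_torque(model: CoMFeedbackModel, com: CoMState) -> TimeSeries:
    """Predicted joint torque: acceleration loop plus all four residual loops."""
    out = np.zeros(len(com))
    for lp in model.all_loops:
        if lp.is_active:
            out += loop_output(lp, com).values
    return TimeSeries(t0=com.d.t0, dt=com.dt, values=out, units="Nm")


def count_active_parameters(model: CoMFeedbackModel) -> int:
    """Number of free parameters in use.

    Each loop with at least one nonzero gain contributes its nonzero gains
    plus one delay; all-zero loops contribute nothing.  The full structure
    with every gain nonzero counts 18; an acceleration-only model counts 2.
    """
    n = 0
    for lp in model.all_loops:
        if lp.is_active:
            n += sum(1 for g in lp.gains if g != 0.0) + 1
    return n
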