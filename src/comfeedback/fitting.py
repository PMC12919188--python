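"""Staged, bounded identification of a delayed CoM feedback model.

The fit runs on one condition's averaged, truncated, background-subtracted
torque trace together with the matching CoM state:

1. *Stage 1* fits the instantaneous acceleration loop alone: a grid search
   over the short acceleration delay with a closed-form (bound-clipped)
   acceleration gain at each candidate.  If this loop alone accounts for more
   than ``stage1_r2_stop`` (default 95%) of the torque variability, fitting
   ends with the residual loops zeroed.
2. *Stage 2* fits the four sign-gated residual loops.  At fixed delays the
   problem is linear in the gains, so each candidate delay combination is
   scored by a convex bound-constrained least-squares solve; delays are
   searched by seeded multistart coordinate descent over a deterministic grid
   (default 5 ms step) followed by a 1 ms local refinement.  By default the
   acceleration gain and delay are re-estimated jointly in stage 2 (the
   stage-1 estimate is biased when residual pathways are present); set
   ``refit_accel_in_stage2=False`` to freeze the stage-1 loop instead.

Torque-sign gating is enforced through sign bounds on the gains: a loop
assigned to the positive torque response may only produce a nonnegative
contribution given the sign of its rectified input.  Gain magnitudes are
capped at ``gain_cap_factor`` times a per-channel scale estimate
(range of torque / range of channel).  If the optimum pins a gain at its cap
the caps are doubled once and the solve repeated (logged) -- an automated,
reproducible stand-in for manual bound tuning.  Loops whose removal does not
degrade the fit are zeroed, so the reported active-parameter count reflects
the pathways the data actually require.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import lsq_linear

from .model import (RESIDUAL_LOOP_ROLES, CoMFeedbackModel, CoMState,
                    FeedbackLoop, count_active_parameters, loop_output,
                    predict_torque)
from .signals import TimeSeries

__all__ = [
    "FitConfig",
    "FitResult",
    "remove_background_torque",
    "compute_r2",
    "compute_rmse_per_kg",
    "fit_gains_at_fixed_delays",
    "fit_acceleration_loop",
    "fit_model",
]

log = logging.getLogger(__name__)

_CHANNELS = ("d", "v", "a")


@dataclass
class FitConfig:
    """Tunable parameters of the staged fit.

    Delay bounds default to a near-instantaneous window [0, 20] ms for the
    acceleration loop and a physiological feedback-latency window
    [40, 250] ms for the residual loops; both are searched on a
    ``lambda_grid_step`` (5 ms) grid with 1 ms local refinement.
    """

    lambda_bounds_accel: tuple[float, float] = (0.0, 0.020)
    lambda_bounds_residual: tuple[float, float] = (0.040, 0.250)
    lambda_grid_step: float = 0.005
    lambda_refine_step: float = 0.001
    gain_cap_factor: float = 10.0
    stage1_r2_stop: float = 0.95
    fit_window_post_s: float = 1.0
    background_window_s: float = 0.25
    multistart_count: int = 4
    max_passes: int = 6
    refit_accel_in_stage2: bool = True
    prune_r2_drop: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi in (self.lambda_bounds_accel, self.lambda_bounds_residual):
            if not (0 <= lo < hi):
                raise ValueError("delay bounds must satisfy 0 <= lo < hi")
        if not 0 < self.stage1_r2_stop < 1:
            raise ValueError("stage1_r2_stop must lie in (0, 1)")
        if self.lambda_grid_step <= 0 or self.multistart_count < 1:
            raise ValueError("bad search configuration")


@dataclass
class FitResult:
    """Outcome of :func:`fit_model` for one joint/condition."""

    model: CoMFeedbackModel
    r2_train: float
    rmse_per_kg_train: float
    stage1_r2: float
    stopped_after_stage1: bool
    active_parameters: int
    diagnostics: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Metrics and background removal
# ---------------------------------------------------------------------------

def _values(x) -> np.ndarray:
    return x.values if isinstance(x, TimeSeries) else np.asarray(x, dtype=float)


def remove_background_torque(tau: TimeSeries, onset_s: float,
                             background_window_s: float = 0.25,
                             ) -> tuple[TimeSeries, float]:
    """Subtract the mean torque over ``[onset - window, onset)`` from the trace.

    The onset sample itself is excluded: a zero-delay intrinsic response
    fires at onset and must not leak into the background estimate.
    """
    i_on = tau.index_of(onset_s)
    n_bg = int(round(background_window_s / tau.dt))
    i0 = i_on - n_bg
    if i0 < 0 or i_on < i0:
        raise ValueError("background window falls outside the record")
    seg = tau.values[i0:i_on]
    if seg.size == 0:
        raise ValueError("empty background window")
    background = float(np.mean(seg))
    return tau.with_values(tau.values - background), background


def compute_r2(tau, tau_hat) -> float:
    """Coefficient of determination ``1 - SSE / SST`` against the mean."""
    y, yh = _values(tau), _values(tau_hat)
    if y.shape != yh.shape:
        raise ValueError("traces must have equal length")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst <= 0.0:
        raise ValueError("zero-variance target: R^2 undefined (unusable trial)")
    sse = float(np.sum((y - yh) ** 2))
    return 1.0 - sse / sst


def compute_rmse_per_kg(tau, tau_hat, mass_kg: float) -> float:
    """Root-mean-square error normalized by body mass (Nm/kg)."""
    if mass_kg <= 0:
        raise ValueError("mass_kg must be positive")
    y, yh = _values(tau), _values(tau_hat)
    if y.shape != yh.shape:
        raise ValueError("traces must have equal length")
    return float(np.sqrt(np.mean((y - yh) ** 2))) / mass_kg


# ---------------------------------------------------------------------------
# Regressor machinery
# ---------------------------------------------------------------------------

def _rect(values: np.ndarray, com_sign: str) -> np.ndarray:
    if com_sign == "both":
        return values
    if com_sign == "+":
        return np.maximum(values, 0.0)
    return np.minimum(values, 0.0)


def _shift(values: np.ndarray, lag: int) -> np.ndarray:
    # nearest-sample delay with first-value back-fill; mirrors delay_signal
    if lag == 0:
        return values
    out = np.empty_like(values)
    out[:lag] = values[0]
    out[lag:] = values[:values.size - lag]
    return out


def _gain_sign(com_sign: str, torque_sign: str) -> int:
    """Required gain sign for a residual loop (0 = unconstrained)."""
    if torque_sign == "none":
        return 0
    s_in = 1 if com_sign == "+" else -1
    s_out = 1 if torque_sign == "+" else -1
    return s_in * s_out


class _Regressors:
    """Pre-rectified CoM channels with a shifted-column cache."""

    def __init__(self, com: CoMState, tau_fit: np.ndarray, fit_slice: slice,
                 cap_factor: float):
        self.com = com
        self.n = len(com)
        self.fit_slice = fit_slice
        self.dt = com.dt
        self.rect: dict[tuple[str, str], np.ndarray] = {}
        for cs in ("+", "-", "both"):
            for ch in _CHANNELS:
                self.rect[(cs, ch)] = _rect(com.channel(ch).values, cs)
        tau_range = float(np.ptp(tau_fit))
        self.caps: dict[str, float] = {}
        for ch in _CHANNELS:
            ch_range = float(np.ptp(com.channel(ch).values))
            if ch_range <= 0 or tau_range <= 0:
                self.caps[ch] = np.inf
            else:
                self.caps[ch] = cap_factor * tau_range / ch_range
        self._cache: dict[tuple[str, str, int], np.ndarray] = {}

    def lag(self, lambda_s: float) -> int:
        return int(round(lambda_s / self.dt))

    def col(self, com_sign: str, ch: str, lag: int) -> np.ndarray:
        """One delayed, rectified channel restricted to the fit window."""
        key = (com_sign, ch, lag)
        out = self._cache.get(key)
        if out is None:
            out = _shift(self.rect[(com_sign, ch)], lag)[self.fit_slice]
            self._cache[key] = out
        return out

    def columns(self, loop: FeedbackLoop, channels=None) -> np.ndarray:
        """(n, k) matrix of delayed, rectified channels for one loop (full length)."""
        channels = channels or _CHANNELS
        lag = self.lag(loop.lambda_s)
        cols = [
            _shift(self.rect[(loop.com_sign, ch)], lag) for ch in channels
        ]
        return np.column_stack(cols)


def _box_qp(G: np.ndarray, c: np.ndarray, lo: np.ndarray, hi: np.ndarray,
            max_iter: int = 80) -> tuple[np.ndarray, bool]:
    """Box-constrained least squares on the normal equations.

    Active-set iteration: solve the free subsystem, clamp violated variables
    to their bounds, release clamped variables whose KKT multiplier has the
    wrong sign.  Returns ``(g, converged)``; the caller falls back to a dense
    solver when the iteration fails to certify optimality.
    """
    n = c.size
    scale = max(float(np.max(np.abs(c))), 1.0)
    tiny = 1e-12 * scale
    val = np.zeros(n)
    free = np.ones(n, dtype=bool)
    g = np.zeros(n)
    for _ in range(max_iter):
        g = val.copy()
        if free.any():
            idx = np.where(free)[0]
            rhs = c[idx] - G[np.ix_(idx, ~free)] @ val[~free]
            sub = G[np.ix_(idx, idx)]
            try:
                g[idx] = np.linalg.solve(sub, rhs)
            except np.linalg.LinAlgError:
                g[idx] = np.linalg.lstsq(sub, rhs, rcond=None)[0]
        vlo = free & (g < lo - 1e-12 * (1 + np.abs(lo)))
        vhi = free & (g > hi + 1e-12 * (1 + np.abs(hi)))
        if vlo.any() or vhi.any():
            val[vlo] = lo[vlo]
            val[vhi] = hi[vhi]
            free &= ~(vlo | vhi)
            continue
        grad = G @ g - c
        rel = (~free) & (((val <= lo + 1e-30) & (grad < -tiny))
                         | ((val >= hi - 1e-30) & (grad > tiny)))
        if rel.any():
            free |= rel
            val[rel] = 0.0
            continue
        return np.clip(g, lo, hi), True
    return np.clip(g, lo, hi), False


def fit_gains_at_fixed_delays(com: CoMState, tau: TimeSeries,
                              loops: list[FeedbackLoop],
                              gain_bounds: dict[str, float] | None = None,
                              fit_slice: slice | None = None,
                              cap_scale: float = 1.0,
                              _reg: "_Regressors | None" = None,
                              ) -> tuple[list[FeedbackLoop], float]:
    """Bound-constrained least-squares gains at fixed delays.

    ``loops`` supplies each loop's delay and gating; the returned loops carry
    the optimal gains.  Columns with (numerically) zero energy over the fit
    window are dropped and their gains set to zero with a logged warning.
    The inner problem is convex, so the solution is a global optimum of the
    gain subproblem.  Returns ``(fitted_loops, sse)`` over the fit window.
    """
    fit_slice = fit_slice if fit_slice is not None else slice(0, len(tau))
    y = tau.values[fit_slice]
    reg = _reg if _reg is not None else _Regressors(
        com, y, fit_slice, cap_factor=10.0)

    blocks, lo, hi, col_loop, col_chan = [], [], [], [], []
    for i, lp in enumerate(loops):
        channels = ("a",) if lp.torque_sign == "none" else _CHANNELS
        cols = reg.columns(lp, channels)[fit_slice]
        sgn = _gain_sign(lp.com_sign, lp.torque_sign)
        for j, ch in enumerate(channels):
            cap = gain_bounds.get(ch, reg.caps[ch]) if gain_bounds else reg.caps[ch]
            cap = cap * cap_scale
            blocks.append(cols[:, j])
            col_loop.append(i)
            col_chan.append(ch)
            if sgn > 0:
                lo.append(0.0), hi.append(cap)
            elif sgn < 0:
                lo.append(-cap), hi.append(0.0)
            else:
                lo.append(-cap), hi.append(cap)

    A = np.column_stack(blocks)
    lo, hi = np.asarray(lo), np.asarray(hi)
    norms = np.linalg.norm(A, axis=0)
    ok = norms > 1e-12 * max(np.max(norms), 1.0)
    if not np.all(ok):
        log.warning("dropping %d degenerate regressor column(s)",
                    int(np.sum(~ok)))
    gains = np.zeros(A.shape[1])
    if np.any(ok):
        Aok = A[:, ok]
        g, *_ = np.linalg.lstsq(Aok, y, rcond=None)
        slack = 1e-9 * (1.0 + np.abs(g))
        if np.all(g >= lo[ok] - slack) and np.all(g <= hi[ok] + slack):
            gains[ok] = np.clip(g, lo[ok], hi[ok])
        else:
            res = lsq_linear(Aok, y, bounds=(lo[ok], hi[ok]),
                             tol=1e-12, lsmr_tol="auto")
            gains[ok] = res.x
    sse = float(np.sum((y - A @ gains) ** 2))

    fitted = []
    for i, lp in enumerate(loops):
        kw = {"k_d": 0.0, "k_v": 0.0, "k_a": 0.0}
        for g, li, ch in zip(gains, col_loop, col_chan):
            if li == i:
                kw[f"k_{ch}"] = float(g)
        fitted.append(FeedbackLoop(lambda_s=lp.lambda_s, com_sign=lp.com_sign,
                                   torque_sign=lp.torque_sign, **kw))
    return fitted, sse


# ---------------------------------------------------------------------------
# Stage 1: acceleration loop
# ---------------------------------------------------------------------------

def _grid(bounds: tuple[float, float], step: float) -> np.ndarray:
    lo, hi = bounds
    return np.arange(lo, hi + 1e-12, step)


def fit_acceleration_loop(com: CoMState, tau: TimeSeries, cfg: FitConfig,
                          fit_slice: slice | None = None,
                          ) -> tuple[FeedbackLoop, float]:
    """Grid-search the acceleration delay with a closed-form gain at each step.

    Returns the (loop, R^2) maximizing R^2 over the acceleration delay grid
    (refined to ``lambda_refine_step``).  A zero-variance target yields a
    zero-gain loop with R^2 reported as 0 (convention for unusable traces).
    """
    fit_slice = fit_slice if fit_slice is not None else slice(0, len(tau))
    y = tau.values[fit_slice]
    sst = float(np.sum((y - y.mean()) ** 2))
    a_full = com.a.values
    dt = com.dt

    def sse_at(lam: float) -> tuple[float, float]:
        x = _shift(a_full, int(round(lam / dt)))[fit_slice]
        xx = float(x @ x)
        if xx <= 0 or sst <= 0:
            return 0.0, float(y @ y)
        k = float(x @ y) / xx
        return k, float(np.sum((y - k * x) ** 2))

    if sst <= 0.0:
        return FeedbackLoop(com_sign="both", torque_sign="none",
                            lambda_s=cfg.lambda_bounds_accel[0]), 0.0

    grid = _grid(cfg.lambda_bounds_accel, cfg.lambda_grid_step)
    best = min(((sse, lam, k) for lam in grid
                for k, sse in [sse_at(lam)]), key=lambda t: (t[0], t[1]))
    # local refinement at the fine step around the best coarse delay
    lo = max(cfg.lambda_bounds_accel[0], best[1] - cfg.lambda_grid_step)
    hi = min(cfg.lambda_bounds_accel[1], best[1] + cfg.lambda_grid_step)
    fine = np.arange(lo, hi + 1e-12, cfg.lambda_refine_step)
    best = min(((sse, lam, k) for lam in fine
                for k, sse in [sse_at(lam)]), key=lambda t: (t[0], t[1]))
    sse, lam, k = best
    r2 = 1.0 - sse / sst
    return FeedbackLoop(k_a=k, lambda_s=float(lam), com_sign="both",
                        torque_sign="none"), r2


# ---------------------------------------------------------------------------
# Stage 2: residual loops via multistart coordinate descent on delays
# ---------------------------------------------------------------------------

def _make_loops(delays: np.ndarray, accel_delay: float | None) -> list[FeedbackLoop]:
    loops = []
    if accel_delay is not None:
        loops.append(FeedbackLoop(com_sign="both", torque_sign="none",
                                  lambda_s=float(accel_delay)))
    for (cs, ts), lam in zip(RESIDUAL_LOOP_ROLES, delays):
        loops.append(FeedbackLoop(com_sign=cs, torque_sign=ts,
                                  lambda_s=float(lam)))
    return loops


def fit_model(com: CoMState, tau: TimeSeries, cfg: FitConfig,
              mass_kg: float = 70.0, joint_id: str = "joint",
              axis: str = "y") -> FitResult:
    """Full staged fit of one joint's delayed CoM feedback model.

    ``tau`` must already be averaged, truncated and background-subtracted;
    the squared error is minimized over the post-onset fit window
    ``[onset, onset + fit_window_post_s]`` (onset taken as time 0 of the
    window convention, i.e. ``background_window_s`` after the trace start),
    while the reported metrics cover the whole trace.  Identical inputs and
    seed give bit-identical results.
    """
    n = len(tau)
    i_on = int(round(cfg.background_window_s / tau.dt))
    i_end = min(n - 1, i_on + int(round(cfg.fit_window_post_s / tau.dt)))
    fit_slice = slice(i_on, i_end + 1)
    y = tau.values[fit_slice]
    sst = float(np.sum((y - y.mean()) ** 2))

    accel_loop, stage1_r2 = fit_acceleration_loop(com, tau, cfg, fit_slice)
    zero_residuals = tuple(FeedbackLoop(com_sign=cs, torque_sign=ts)
                           for cs, ts in RESIDUAL_LOOP_ROLES)

    def finalize(model: CoMFeedbackModel, stopped: bool) -> FitResult:
        pred = predict_torque(model, com)
        try:
            r2 = compute_r2(tau, pred)
        except ValueError:
            r2 = 0.0
        rmse = compute_rmse_per_kg(tau, pred, mass_kg)
        shares = {}
        denom = float(pred.values @ pred.values)
        for name, lp in zip(("accel",) + RESIDUAL_LOOP_ROLES, model.all_loops):
            if lp.is_active and denom > 0:
                out = loop_output(lp, com).values
                shares[str(name)] = float(out @ pred.values) / denom
        return FitResult(model=model, r2_train=r2, rmse_per_kg_train=rmse,
                         stage1_r2=stage1_r2, stopped_after_stage1=stopped,
                         active_parameters=count_active_parameters(model),
                         diagnostics={"loop_shares": shares})

    if sst <= 0.0:
        log.warning("zero-variance torque target for %s: returning zero model",
                    joint_id)
        model = CoMFeedbackModel(joint_id=joint_id, axis=axis,
                                 residual_loops=zero_residuals)
        return finalize(model, stopped=True)

    if stage1_r2 > cfg.stage1_r2_stop:
        model = CoMFeedbackModel(joint_id=joint_id, axis=axis,
                                 accel_loop=accel_loop,
                                 residual_loops=zero_residuals)
        return finalize(model, stopped=True)

    reg = _Regressors(com, y, fit_slice, cfg.gain_cap_factor)
    rng = np.random.default_rng(cfg.seed)
    res_grid = _grid(cfg.lambda_bounds_residual, cfg.lambda_grid_step)
    acc_grid = _grid(cfg.lambda_bounds_accel, cfg.lambda_grid_step)
    refit_accel = cfg.refit_accel_in_stage2

    if refit_accel:
        target = tau
    else:
        target = tau.with_values(tau.values - loop_output(accel_loop, com).values)

    cap_scale = 1.0
    y_t = target.values[fit_slice]
    yy = float(y_t @ y_t)

    def solve_fast(delays: np.ndarray, accel_delay: float | None,
                   scale: float) -> float:
        """SSE of the bound-constrained gain fit at one delay candidate."""
        cols, lo, hi = [], [], []
        if accel_delay is not None:
            cols.append(reg.col("both", "a", reg.lag(accel_delay)))
            cap = reg.caps["a"] * scale
            lo.append(-cap), hi.append(cap)
        for (cs, ts), lam in zip(RESIDUAL_LOOP_ROLES, delays):
            lag = reg.lag(lam)
            sgn = _gain_sign(cs, ts)
            for ch in _CHANNELS:
                cols.append(reg.col(cs, ch, lag))
                cap = reg.caps[ch] * scale
                if sgn > 0:
                    lo.append(0.0), hi.append(cap)
                else:
                    lo.append(-cap), hi.append(0.0)
        A = np.column_stack(cols)
        G = A.T @ A
        c = A.T @ y_t
        diag = np.diag(G)
        ok = diag > 1e-24 * max(float(diag.max()), 1.0)
        g = np.zeros(c.size)
        if ok.any():
            idx = np.where(ok)[0]
            sub, converged = _box_qp(G[np.ix_(idx, idx)], c[idx],
                                     np.asarray(lo)[idx], np.asarray(hi)[idx])
            if not converged:
                log.debug("active-set solver fell back to lsq_linear")
                res = lsq_linear(A[:, idx], y_t,
                                 bounds=(np.asarray(lo)[idx], np.asarray(hi)[idx]),
                                 tol=1e-12, lsmr_tol="auto")
                sub = res.x
            g[idx] = sub
        return max(yy - 2.0 * float(g @ c) + float(g @ (G @ g)), 0.0)

    def solve(delays: np.ndarray, accel_delay: float | None,
              scale: float) -> tuple[list[FeedbackLoop], float]:
        loops = _make_loops(delays, accel_delay)
        return fit_gains_at_fixed_delays(com, target, loops, fit_slice=fit_slice,
                                         cap_scale=scale, _reg=reg)

    def descend(delays: np.ndarray, accel_delay: float | None,
                grids: list[np.ndarray], scale: float,
                ) -> tuple[np.ndarray, float | None, float]:
        delays = delays.copy()
        best_sse = solve_fast(delays, accel_delay, scale)
        for _ in range(cfg.max_passes):
            improved = False
            coords = list(range(len(delays))) + ([-1] if accel_delay is not None else [])
            for ci in coords:
                grid = grids[ci] if ci >= 0 else grids[-1]
                cur = delays[ci] if ci >= 0 else accel_delay
                for lam in grid:
                    if lam == cur:
                        continue
                    if ci >= 0:
                        trial = delays.copy(); trial[ci] = lam
                        sse = solve_fast(trial, accel_delay, scale)
                        if sse < best_sse - 1e-12 * max(best_sse, 1.0):
                            delays, best_sse, improved = trial, sse, True
                    else:
                        sse = solve_fast(delays, lam, scale)
                        if sse < best_sse - 1e-12 * max(best_sse, 1.0):
                            accel_delay, best_sse, improved = lam, sse, True
            if not improved:
                break
        return delays, accel_delay, best_sse

    # multistart: two spread heuristics plus seeded random delay combinations
    lo, hi = cfg.lambda_bounds_residual
    starts: list[np.ndarray] = [
        np.array([lo + 0.25 * (hi - lo)] * 4),
        np.array([lo + 0.6 * (hi - lo)] * 4),
    ]
    while len(starts) < cfg.multistart_count:
        starts.append(rng.choice(res_grid, size=4))
    # snap heuristic starts to the grid
    starts = [res_grid[np.argmin(np.abs(res_grid[None, :] - s[:, None]), axis=1)]
              for s in starts]

    acc0 = accel_loop.lambda_s if refit_accel else None
    coarse_grids = [res_grid] * 4 + [acc_grid]
    best = None
    for s in starts[: cfg.multistart_count]:
        d, ad, sse = descend(s, acc0, coarse_grids, cap_scale)
        if best is None or sse < best[2] - 1e-12 * max(best[2], 1.0):
            best = (d, ad, sse)
    d_best, ad_best, sse_best = best

    # 1 ms refinement around the best coarse solution
    def fine_grid(center: float, bounds: tuple[float, float]) -> np.ndarray:
        lo_f = max(bounds[0], center - cfg.lambda_grid_step)
        hi_f = min(bounds[1], center + cfg.lambda_grid_step)
        return np.arange(lo_f, hi_f + 1e-12, cfg.lambda_refine_step)

    fine_grids = [fine_grid(lam, cfg.lambda_bounds_residual) for lam in d_best]
    fine_grids.append(fine_grid(ad_best if ad_best is not None else 0.0,
                                cfg.lambda_bounds_accel))
    d_best, ad_best, sse_best = descend(d_best, ad_best, fine_grids, cap_scale)

    loops, sse_best = solve(d_best, ad_best, cap_scale)

    # escalate bounds once if the optimum pins a gain at its cap
    def at_cap(lps: list[FeedbackLoop], scale: float) -> bool:
        for lp in lps:
            for g, ch in zip(lp.gains, _CHANNELS):
                cap = reg.caps[ch] * scale
                if np.isfinite(cap) and cap > 0 and abs(abs(g) - cap) <= 1e-9 * cap:
                    return True
        return False

    if at_cap(loops, cap_scale):
        log.warning("gain at bound for %s: doubling gain caps and refitting",
                    joint_id)
        cap_scale = 2.0
        d_best, ad_best, sse_best = descend(d_best, ad_best, fine_grids, cap_scale)
        loops, sse_best = solve(d_best, ad_best, cap_scale)

    # Greedy backward elimination of individual gain terms: a term (one gain
    # of one loop) is zeroed when removing it costs less than
    # cfg.prune_r2_drop of the torque variance, so the reported
    # active-parameter count reflects the pathways the data require.
    def prune(loops_in: list[FeedbackLoop]) -> tuple[list[FeedbackLoop], float]:
        specs = []  # (loop_idx, com_sign, ch, lag, lo, hi)
        for li, lp in enumerate(loops_in):
            channels = ("a",) if lp.torque_sign == "none" else _CHANNELS
            sgn = _gain_sign(lp.com_sign, lp.torque_sign)
            lag = reg.lag(lp.lambda_s)
            for ch in channels:
                if getattr(lp, f"k_{ch}") == 0.0:
                    continue
                cap = reg.caps[ch] * cap_scale
                if sgn > 0:
                    b = (0.0, cap)
                elif sgn < 0:
                    b = (-cap, 0.0)
                else:
                    b = (-cap, cap)
                specs.append((li, lp.com_sign, ch, lag, b[0], b[1]))

        def solve_subset(subset):
            if not subset:
                return np.zeros(0), yy
            A = np.column_stack([reg.col(cs, ch, lag)
                                 for (_li, cs, ch, lag, _lo, _hi) in subset])
            G = A.T @ A
            c = A.T @ y_t
            lo_b = np.array([s[4] for s in subset])
            hi_b = np.array([s[5] for s in subset])
            g, converged = _box_qp(G, c, lo_b, hi_b)
            if not converged:
                res = lsq_linear(A, y_t, bounds=(lo_b, hi_b), tol=1e-12,
                                 lsmr_tol="auto")
                g = res.x
            return g, max(yy - 2.0 * float(g @ c) + float(g @ (G @ g)), 0.0)

        subset = list(specs)
        gains, sse_cur = solve_subset(subset)
        tol = cfg.prune_r2_drop * max(sst, 1e-30)
        while len(subset) > 1:
            best = None
            for i in range(len(subset)):
                _g, sse_i = solve_subset(subset[:i] + subset[i + 1:])
                inc = sse_i - sse_cur
                if best is None or inc < best[1]:
                    best = (i, inc, sse_i)
            if best is None or best[1] > tol:
                break
            subset.pop(best[0])
            gains, sse_cur = solve_subset(subset)
        out = []
        for li, lp in enumerate(loops_in):
            kw = {"k_d": 0.0, "k_v": 0.0, "k_a": 0.0}
            for g, (lj, _cs, ch, _lag, _lo, _hi) in zip(gains, subset):
                if lj == li:
                    kw[f"k_{ch}"] = float(g)
            out.append(FeedbackLoop(lambda_s=lp.lambda_s, com_sign=lp.com_sign,
                                    torque_sign=lp.torque_sign, **kw))
        return out, sse_cur

    loops, sse_best = prune(loops)

    if refit_accel:
        final_accel, residual_loops = loops[0], tuple(loops[1:])
    else:
        final_accel, residual_loops = accel_loop, tuple(loops)

    # fall back to the zero model if stage 2 found no improvement over it
    if sse_best >= sst and stage1_r2 <= 0.0:
        log.warning("no feasible improvement over the zero model for %s", joint_id)
        model = CoMFeedbackModel(joint_id=joint_id, axis=axis,
                                 residual_loops=zero_residuals)
        return finalize(model, stopped=False)

    model = CoMFeedbackModel(joint_id=joint_id, axis=axis,
                             accel_loop=final_accel,
                             residual_loops=residual_loops)
    return finalize(model, stopped=False)
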