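"""Staged constrained fitting: metrics, gain solves, delay search, recovery."""

import numpy as np
import pytest

from comfeedback.fitting import (FitConfig, compute_r2, compute_rmse_per_kg,
                                 fit_acceleration_loop, fit_model,
                                 fit_gains_at_fixed_delays,
                                 remove_background_torque)
from comfeedback.fitting import _box_qp
from comfeedback.model import (CoMFeedbackModel, FeedbackLoop,
                               RESIDUAL_LOOP_ROLES, predict_torque)
from comfeedback.signals import TimeSeries

from conftest import analytic_com_state

FIT_SLICE = slice(250, 1251)  # post-onset window of the standard 1251-sample trace


def ts(values, t0=0.0, dt=0.001):
    return TimeSeries(t0, dt, np.asarray(values, float), "Nm")


class TestBackgroundRemoval:
    def test_constant_trace_goes_to_zero(self):
        tau = ts(np.full(1000, 4.2), t0=-0.25)
        out, bg = remove_background_torque(tau, 0.0, 0.25)
        assert bg == pytest.approx(4.2)
        assert np.allclose(out.values, 0.0)

    def test_zero_background_leaves_trace_unchanged(self):
        v = np.concatenate([np.zeros(250), np.ones(750)])
        tau = ts(v, t0=-0.25)
        out, bg = remove_background_torque(tau, 0.0, 0.25)
        assert bg == 0.0
        assert np.array_equal(out.values, v)

    def test_toy_arithmetic(self):
        # pre-onset samples {3.0, 3.4} -> mean 3.2; onset sample excluded
        tau = ts([3.0, 3.4, 9.0, 5.0, 1.0], dt=1.0, t0=0.0)
        out, bg = remove_background_torque(tau, 2.0, 2.0)
        assert bg == pytest.approx(3.2)
        assert np.allclose(out.values, [-0.2, 0.2, 5.8, 1.8, -2.2])

    def test_window_outside_record_rejected(self):
        with pytest.raises(ValueError):
            remove_background_torque(ts([1.0, 2.0]), 0.0, 0.25)


class TestMetrics:
    def test_r2_perfect_and_mean_predictions(self):
        tau = ts([0, 1, 2, 3.0])
        assert compute_r2(tau, tau) == pytest.approx(1.0)
        mean = ts(np.full(4, 1.5))
        assert compute_r2(tau, mean) == pytest.approx(0.0)

    def test_r2_hand_arithmetic(self):
        assert compute_r2(ts([0, 1, 2, 3.0]),
                          ts([0, 1, 2, 2.0])) == pytest.approx(0.8)

    def test_r2_zero_variance_target_is_an_error(self):
        with pytest.raises(ValueError):
            compute_r2(ts([2.0, 2.0, 2.0]), ts([1.0, 2.0, 3.0]))

    def test_rmse_per_kg(self):
        tau = ts(np.zeros(8))
        assert compute_rmse_per_kg(tau, tau, 70.0) == 0.0
        assert compute_rmse_per_kg(tau, ts(np.full(8, 7.0)),
                                   70.0) == pytest.approx(0.1)
        assert compute_rmse_per_kg(ts([3.0, -4.0]), ts([0.0, 0.0]),
                                   70.0) == pytest.approx(np.sqrt(12.5) / 70)

    def test_rmse_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError):
            compute_rmse_per_kg(ts([1.0]), ts([1.0]), 0.0)


class TestGainSolve:
    def test_recovers_pure_acceleration_pathway(self, com_oscillation):
        lam = 0.045
        loops = [FeedbackLoop(com_sign="both", torque_sign="none",
                              lambda_s=lam)]
        truth = FeedbackLoop(k_a=10.0, lambda_s=lam)
        from comfeedback.model import loop_output
        tau = loop_output(truth, com_oscillation)
        fitted, sse = fit_gains_at_fixed_delays(com_oscillation, tau, loops,
                                                fit_slice=FIT_SLICE)
        assert fitted[0].k_a == pytest.approx(10.0, rel=1e-9)
        assert sse == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_target_gives_zero_gains(self, com_oscillation):
        # target uncorrelated-by-construction: residual after projecting
        # noise onto the regressor space
        rng = np.random.default_rng(3)
        loops = [FeedbackLoop(com_sign="both", torque_sign="none",
                              lambda_s=0.01)]
        from comfeedback.fitting import _shift
        a = com_oscillation.a.values
        col = _shift(a, 10)
        noise = rng.normal(size=a.size)
        resid = noise - col * (col @ noise) / (col @ col)
        fitted, _ = fit_gains_at_fixed_delays(
            com_oscillation, ts(resid, t0=-0.25),
            loops, fit_slice=slice(0, len(a)))
        assert fitted[0].k_a == pytest.approx(0.0, abs=1e-9)

    def test_active_upper_bound_clamps_gain(self, com_oscillation):
        lam = 0.045
        from comfeedback.model import loop_output
        truth = FeedbackLoop(k_a=10.0, lambda_s=lam)
        tau = loop_output(truth, com_oscillation)
        loops = [FeedbackLoop(com_sign="both", torque_sign="none",
                              lambda_s=lam)]
        fitted, _ = fit_gains_at_fixed_delays(com_oscillation, tau, loops,
                                              gain_bounds={"a": 5.0},
                                              fit_slice=FIT_SLICE)
        assert fitted[0].k_a == pytest.approx(5.0, rel=1e-9)

    def test_matches_dense_brute_force_on_three_parameter_toy(self,
                                                              com_oscillation):
        # single (+,+) loop: three sign-bounded gains at a fixed delay
        lam = 0.060
        truth = FeedbackLoop(k_d=3.0, k_v=1.2, k_a=0.4, lambda_s=lam,
                             com_sign="+", torque_sign="+")
        from comfeedback.model import loop_output
        tau = loop_output(truth, com_oscillation)
        loops = [FeedbackLoop(com_sign="+", torque_sign="+", lambda_s=lam)]
        fitted, sse = fit_gains_at_fixed_delays(com_oscillation, tau, loops,
                                                fit_slice=FIT_SLICE)
        # brute force over a dense gain grid around the search region
        from comfeedback.fitting import _rect, _shift
        y = tau.values[FIT_SLICE]
        cols = [_shift(_rect(com_oscillation.channel(ch).values, "+"), 60)[FIT_SLICE]
                for ch in "dva"]
        A = np.column_stack(cols)
        grids = [np.linspace(0, 6, 61), np.linspace(0, 2.4, 49),
                 np.linspace(0, 0.8, 41)]
        best, best_sse = None, np.inf
        for g0 in grids[0]:
            r0 = y - g0 * A[:, 0]
            for g1 in grids[1]:
                r1 = r0 - g1 * A[:, 1]
                for g2 in grids[2]:
                    sse_b = float(np.sum((r1 - g2 * A[:, 2]) ** 2))
                    if sse_b < best_sse:
                        best, best_sse = (g0, g1, g2), sse_b
        step = (grids[0][1] - grids[0][0], grids[1][1] - grids[1][0],
                grids[2][1] - grids[2][0])
        for got, bf, st_ in zip(fitted[0].gains, best, step):
            assert abs(got - bf) <= st_ / 2 + 1e-12
        assert sse <= best_sse + 1e-9

    def test_degenerate_column_zeroed(self, com_oscillation):
        # a "-" gated loop on an everywhere-positive trace has zero columns
        from comfeedback.model import loop_output
        pos_only = analytic_com_state()
        truth = FeedbackLoop(k_a=2.0, lambda_s=0.0)
        tau = loop_output(truth, pos_only)
        dead = FeedbackLoop(com_sign="-", torque_sign="-", lambda_s=0.05)
        live = FeedbackLoop(com_sign="both", torque_sign="none", lambda_s=0.0)
        com = CoMStateAllPositive()
        fitted, _ = fit_gains_at_fixed_delays(com, loop_output(truth, com),
                                              [live, dead],
                                              fit_slice=slice(0, len(com)))
        assert fitted[1].gains == (0.0, 0.0, 0.0)
        assert fitted[0].k_a == pytest.approx(2.0)


def CoMStateAllPositive():
    from comfeedback.model import CoMState
    n, dt = 800, 0.001
    t = dt * np.arange(n)
    base = 1.0 + 0.5 * np.sin(2 * np.pi * 1.3 * t)
    return CoMState(TimeSeries(0, dt, 0.05 * base, "m"),
                    TimeSeries(0, dt, 0.2 * np.roll(base, 7), "mps"),
                    TimeSeries(0, dt, 2.0 * np.roll(base, 13), "mps2"))


class TestAccelerationLoop:
    def test_recovers_gain_and_delay(self, com_oscillation):
        from comfeedback.model import loop_output
        truth = FeedbackLoop(k_a=8.0, lambda_s=0.005)
        tau = loop_output(truth, com_oscillation)
        loop, r2 = fit_acceleration_loop(com_oscillation, tau, FitConfig(),
                                         FIT_SLICE)
        assert loop.k_a == pytest.approx(8.0, rel=1e-6)
        assert abs(loop.lambda_s - 0.005) <= 0.001 + 1e-12
        assert r2 > 0.999999

    def test_pure_noise_gives_near_zero_r2(self, com_oscillation, rng):
        tau = ts(rng.normal(size=1251), t0=-0.25)
        _loop, r2 = fit_acceleration_loop(com_oscillation, tau, FitConfig(),
                                          FIT_SLICE)
        assert r2 < 0.1

    def test_zero_variance_target_convention(self, com_oscillation):
        tau = ts(np.zeros(1251), t0=-0.25)
        loop, r2 = fit_acceleration_loop(com_oscillation, tau, FitConfig(),
                                         FIT_SLICE)
        assert loop.k_a == 0.0
        assert r2 == 0.0


def make_truth(k_a=0.0, lam_a=0.005, pos=None, neg=None) -> CoMFeedbackModel:
    loops = []
    for cs, tsn in RESIDUAL_LOOP_ROLES:
        if cs == "+" and tsn == "+" and pos:
            loops.append(FeedbackLoop(k_d=pos[0], k_v=pos[1],
                                      lambda_s=pos[2], com_sign=cs,
                                      torque_sign=tsn))
        elif cs == "-" and tsn == "-" and neg:
            loops.append(FeedbackLoop(k_d=neg[0], k_v=neg[1],
                                      lambda_s=neg[2], com_sign=cs,
                                      torque_sign=tsn))
        else:
            loops.append(FeedbackLoop(com_sign=cs, torque_sign=tsn))
    return CoMFeedbackModel(joint_id="toy", axis="y",
                            accel_loop=FeedbackLoop(k_a=k_a, lambda_s=lam_a),
                            residual_loops=tuple(loops))


class TestFitModel:
    def test_acceleration_only_truth_stops_after_stage1(self, com_oscillation,
                                                        rng):
        truth = make_truth(k_a=12.0, lam_a=0.005)
        tau = predict_torque(truth, com_oscillation)
        noise = rng.normal(0, 0.01 * np.ptp(tau.values), len(tau))
        res = fit_model(com_oscillation, tau.with_values(tau.values + noise),
                        FitConfig())
        assert res.stopped_after_stage1
        assert res.active_parameters == 2
        assert res.stage1_r2 > 0.95
        assert res.model.accel_loop.k_a == pytest.approx(12.0, rel=0.02)

    def test_three_loop_noiseless_recovery(self, com_oscillation):
        truth = make_truth(k_a=2.0, lam_a=0.005,
                           pos=(40.0, 9.0, 0.095), neg=(35.0, 7.0, 0.110))
        tau = predict_torque(truth, com_oscillation)
        res = fit_model(com_oscillation, tau, FitConfig())
        assert not res.stopped_after_stage1
        assert res.r2_train > 0.999
        for tl, fl in zip(truth.all_loops, res.model.all_loops):
            if not tl.is_active:
                continue
            for gt, gf in zip(tl.gains, fl.gains):
                if gt:
                    assert gf == pytest.approx(gt, rel=0.01)
            assert abs(fl.lambda_s - tl.lambda_s) <= 0.005 + 1e-12

    def test_stage1_threshold_strictly_honored(self, com_oscillation):
        # acceleration pathway explains ~96% by construction: small residual
        truth = make_truth(k_a=10.0, lam_a=0.005)
        tau_a = predict_torque(truth, com_oscillation).values
        resid_truth = make_truth(pos=(1.5, 0.3, 0.1), neg=(1.2, 0.2, 0.12))
        tau_r = predict_torque(resid_truth, com_oscillation).values
        sst = np.sum((tau_a - tau_a.mean()) ** 2)
        scale = np.sqrt(0.03 * sst / max(np.sum(tau_r ** 2), 1e-30))
        tau = ts(tau_a + scale * tau_r, t0=-0.25)
        res = fit_model(com_oscillation, tau, FitConfig())
        assert res.stage1_r2 > 0.95
        assert res.stopped_after_stage1
        assert all(not lp.is_active for lp in res.model.residual_loops)

    def test_stage2_runs_when_acceleration_explains_less_than_95(self,
                                                                 com_oscillation):
        truth = make_truth(k_a=2.0, lam_a=0.005,
                           pos=(40.0, 9.0, 0.095), neg=(35.0, 7.0, 0.110))
        tau = predict_torque(truth, com_oscillation)
        res = fit_model(com_oscillation, tau, FitConfig())
        assert res.stage1_r2 <= 0.95
        assert not res.stopped_after_stage1
        assert any(lp.is_active for lp in res.model.residual_loops)

    def test_stage2_never_below_stage1(self, com_oscillation, rng):
        truth = make_truth(k_a=3.0, lam_a=0.01, pos=(40.0, 9.0, 0.095))
        tau = predict_torque(truth, com_oscillation)
        noisy = tau.with_values(tau.values
                                + rng.normal(0, 0.05 * np.ptp(tau.values),
                                             len(tau)))
        res = fit_model(com_oscillation, noisy, FitConfig())
        assert res.r2_train >= res.stage1_r2 - 1e-9

    def test_determinism_bit_identical(self, com_oscillation, rng):
        truth = make_truth(k_a=3.0, lam_a=0.01,
                           pos=(40.0, 9.0, 0.095), neg=(35.0, 7.0, 0.110))
        tau = predict_torque(truth, com_oscillation)
        noisy = tau.with_values(tau.values
                                + rng.normal(0, 0.02 * np.ptp(tau.values),
                                             len(tau)))
        cfg = FitConfig(seed=42)
        r1 = fit_model(com_oscillation, noisy, cfg)
        r2 = fit_model(com_oscillation, noisy, cfg)
        assert r1.model == r2.model
        assert r1.r2_train == r2.r2_train

    def test_zero_variance_target_returns_zero_model(self, com_oscillation):
        tau = ts(np.zeros(1251), t0=-0.25)
        res = fit_model(com_oscillation, tau, FitConfig())
        assert res.active_parameters == 0
        assert res.r2_train == 0.0


class TestBoxQP:
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_scipy_reference(self, seed):
        from scipy.optimize import lsq_linear
        rng = np.random.default_rng(seed)
        n, k = 120, 7
        A = rng.normal(size=(n, k))
        y = rng.normal(size=n)
        lo = np.where(rng.random(k) < 0.5, 0.0, -2.0)
        hi = lo + 2.0
        G, c = A.T @ A, A.T @ y
        g, ok = _box_qp(G, c, lo, hi)
        assert ok
        ref = lsq_linear(A, y, bounds=(lo, hi), tol=1e-14).x
        sse = np.sum((y - A @ g) ** 2)
        sse_ref = np.sum((y - A @ ref) ** 2)
        assert sse <= sse_ref + 1e-9
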