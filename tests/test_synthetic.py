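"""Study generator: platform profiles, closed-loop plant, protocol counts."""

import numpy as np
import pytest

from comfeedback.model import CoMState, predict_torque
from comfeedback.signals import TrialMeta
from comfeedback.synthetic import (JOINT_AXES, STUDY_MAGNITUDES,
                                   PerturbationSpec, PlantParams, SinusoidSpec,
                                   default_plant, generate_study,
                                   make_ramp_profile, make_sinusoid_profile,
                                   simulate_trial, study_plan, subject_plant)

from conftest import sim_ramp

G = 9.81


class TestPerturbationSpec:
    @pytest.mark.parametrize("label", list(STUDY_MAGNITUDES))
    def test_study_magnitudes_are_feasible(self, label):
        spec = PerturbationSpec.from_label(label)
        assert spec.displacement >= spec.peak_velocity ** 2 / \
            (spec.peak_acceleration * G)

    def test_infeasible_trapezoid_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            PerturbationSpec(displacement=0.001, peak_velocity=0.24,
                             peak_acceleration=1.6)


class TestRampProfile:
    def test_large_spec_reaches_target_displacement_and_velocity(self):
        pos, vel, _acc = make_ramp_profile(
            PerturbationSpec.from_label("large"), 0.001, 1.0)
        assert pos[-1] == pytest.approx(0.126, abs=1e-9)
        assert np.max(np.abs(vel)) == pytest.approx(0.24, abs=1e-9)

    def test_zero_displacement_gives_zero_profile(self):
        pos, vel, acc = make_ramp_profile(
            PerturbationSpec(0.0, 0.0, 0.0), 0.001, 0.5)
        assert not pos.any() and not vel.any() and not acc.any()

    def test_small_slow_cruise_duration_closed_form(self):
        spec = PerturbationSpec.from_label("small_slow")
        A, V, D = spec.peak_acceleration * G, spec.peak_velocity, \
            spec.displacement
        t_cruise = (D - V * V / A) / V
        dt = 0.001
        _pos, vel, _acc = make_ramp_profile(spec, dt, 0.5)
        n_at_peak = int(np.sum(np.isclose(vel, V)))
        assert n_at_peak * dt == pytest.approx(t_cruise, abs=2 * dt)

    def test_kinematic_consistency(self):
        dt = 0.001
        pos, vel, acc = make_ramp_profile(
            PerturbationSpec.from_label("medium"), dt, 0.5)
        dvel = np.gradient(pos, dt)
        # O(dt) agreement away from the profile corners
        assert np.percentile(np.abs(dvel - vel), 95) < 0.02
        dacc = np.gradient(vel, dt)
        assert np.median(np.abs(dacc - acc)) < 0.1


class TestSinusoidProfile:
    def test_peak_amplitude_and_cycle_count(self):
        spec = SinusoidSpec()
        pos, _v, _a = make_sinusoid_profile(spec, 0.001)
        assert np.max(np.abs(pos)) == pytest.approx(0.077, rel=1e-3)
        # 10 cycles -> 19 interior zero crossings at k/(2f)
        crossings = spec.zero_crossing_times()
        assert crossings.size == 19
        assert np.allclose(np.diff(crossings), 1 / (2 * 0.75))
        # crossings are exact in continuous time; on the 1 ms grid the
        # nearest sample sits within half a sample of zero (|p| <= A w dt/2)
        tol = 0.077 * 2 * np.pi * 0.75 * 0.001 / 2 * 1.01
        for t in crossings:
            assert abs(pos[int(round(t / 0.001))]) <= tol

    def test_taper_starts_and_ends_at_rest(self):
        pos, vel, acc = make_sinusoid_profile(SinusoidSpec(), 0.001)
        assert abs(acc[0]) < 1e-6 and abs(vel[0]) < 1e-6
        assert abs(vel[-1]) < 1e-3

    def test_kinematic_consistency(self):
        dt = 0.001
        pos, vel, acc = make_sinusoid_profile(SinusoidSpec(), dt)
        assert np.percentile(np.abs(np.gradient(pos, dt) - vel), 99) < 0.01
        assert np.percentile(np.abs(np.gradient(vel, dt) - acc), 99) < 0.1

    def test_accelerating_injection_follows_platform_motion(self):
        p = PerturbationSpec.from_label("small_fast")
        base, _, _ = make_sinusoid_profile(SinusoidSpec(), 0.001)
        # crossing k=2: platform moving toward +; accelerating adds +ramp
        acc_spec = SinusoidSpec(superimposed=((p, 2, "accelerating"),))
        brk_spec = SinusoidSpec(superimposed=((p, 2, "braking"),))
        pos_a, _, _ = make_sinusoid_profile(acc_spec, 0.001)
        pos_b, _, _ = make_sinusoid_profile(brk_spec, 0.001)
        i = int(round(2 / (2 * 0.75) / 0.001)) + 400
        assert pos_a[i] - base[i] > 0
        assert pos_b[i] - base[i] < 0

    def test_overlapping_superimposed_rejected(self):
        p = PerturbationSpec.from_label("small_fast")
        spec = SinusoidSpec(superimposed=((p, 4, "accelerating"),
                                          (p, 4, "braking")))
        with pytest.raises(ValueError, match="overlap"):
            make_sinusoid_profile(spec, 0.001)


class TestSimulateTrial:
    def test_zero_platform_motion_stays_at_baseline(self, noiseless_plant):
        n = 1500
        z = np.zeros(n)
        meta = TrialMeta(mass_kg=69.0, onset_s=0.5, condition_label="ramp_0_z")
        tr = simulate_trial({"y": (z, z, z)}, noiseless_plant, meta)
        for name, ch in tr.channels.items():
            assert not ch.values.any(), name

    def test_noiseless_torque_matches_model_prediction(self, ramp_trial,
                                                       noiseless_plant):
        """Closed-loop self-consistency: the key identifiability oracle."""
        com = CoMState(ramp_trial["com_d_y_m"], ramp_trial["com_v_y_mps"],
                       ramp_trial["com_a_y_mps2"])
        for joint in ("ankle_pf", "knee_flex", "hip_flex"):
            truth = noiseless_plant.models["ramp"][joint]
            pred = predict_torque(truth, com)
            assert np.allclose(pred.values,
                               ramp_trial[f"tau_{joint}_Nm"].values,
                               atol=1e-9)

    def test_identical_seeds_give_identical_trials(self):
        plant = default_plant(noise_frac=0.02)
        a = sim_ramp(plant, 90.0, "small_slow", seed=77)
        b = sim_ramp(plant, 90.0, "small_slow", seed=77)
        for name in a.channels:
            assert np.array_equal(a[name].values, b[name].values)

    def test_unstable_plant_raises_divergence_error(self):
        plant = default_plant(noise_frac=0.0)
        # gut the stabilizing gains: gravity wins and the CoM runs away
        weak = {j: m.scaled(0.01) for j, m in plant.models["ramp"].items()}
        bad = PlantParams(models={"ramp": weak})
        with pytest.raises(RuntimeError, match="divergence"):
            sim_ramp(bad, 90.0, "large")

    def test_direction_decomposes_into_axes(self, noiseless_plant):
        tr = sim_ramp(noiseless_plant, 45.0, "medium")
        c = np.cos(np.radians(45.0))
        assert np.max(np.abs(tr["plat_pos_x_m"].values)) == \
            pytest.approx(0.077 * c, rel=1e-6)
        assert np.allclose(tr["plat_pos_x_m"].values,
                           tr["plat_pos_y_m"].values)


class TestSubjectPlant:
    def test_deterministic_given_seed(self):
        a = subject_plant(3)
        b = subject_plant(3)
        assert a.mass_kg == b.mass_kg
        assert a.models["ramp"]["ankle_pf"] == b.models["ramp"]["ankle_pf"]

    def test_subjects_differ(self):
        assert subject_plant(3).models["ramp"]["ankle_pf"] != \
            subject_plant(4).models["ramp"]["ankle_pf"]

    def test_context_dissociation_only_touches_designated_joints(self):
        p = subject_plant(5, context_dissociated=True)
        assert p.models["sinusoid"]["knee_flex"] == p.models["ramp"]["knee_flex"]
        assert p.models["sinusoid"]["hip_flex"] == p.models["ramp"]["hip_flex"]
        assert p.models["sinusoid"]["ankle_pf"] != p.models["ramp"]["ankle_pf"]
        assert p.models["sinusoid"]["hip_add"] != p.models["ramp"]["hip_add"]


class TestStudyPlan:
    def test_protocol_counts(self):
        plan = study_plan(0)
        ramps = [e for e in plan if e["kind"] == "ramp"]
        sins = [e for e in plan if e["kind"] == "sinusoid"]
        assert len(ramps) == 160
        assert len(sins) == 36
        # 8 directions x 4 magnitudes x 5 reps
        assert len({(e["direction_deg"], e["magnitude_label"])
                    for e in ramps}) == 32
        # each sinusoid condition starts in either direction 3 times
        sag_none = [e for e in sins if e["plane"] == "sagittal"
                    and e["superimposed"] == "none"]
        assert sum(e["start_sign"] == 1 for e in sag_none) == 3
        assert sum(e["start_sign"] == -1 for e in sag_none) == 3

    def test_superimposed_onsets_at_zero_crossings(self):
        plan = study_plan(1)
        f = 0.75
        for e in plan:
            for _spec, k, _cls in e.get("pattern", ()):
                t = k / (2 * f)
                assert t == pytest.approx(round(t * 2 * f) / (2 * f))
                assert 1 <= k <= 18

    def test_generate_study_respects_plan_and_seeds(self, noiseless_plant):
        plan = study_plan(0, directions=(90.0,), magnitudes=("small_slow",),
                         ramp_reps=2, planes=("sagittal",),
                         superimposed_kinds=("none",), sinusoid_reps=2)
        trials, manifest = generate_study(noiseless_plant, seed=9, plan=plan)
        assert len(trials) == 4
        assert list(manifest["kind"]) == ["ramp", "ramp", "sinusoid",
                                          "sinusoid"]
        # noiseless repetitions of one condition are identical
        assert np.array_equal(trials[0]["tau_ankle_pf_Nm"].values,
                              trials[1]["tau_ankle_pf_Nm"].values)
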