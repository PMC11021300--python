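import numpy as np
import pytest

from extrot.cohort import sample_cohort, scenario_preset
from extrot.engine import (CalibrationError, CalibrationState, EngineConfig,
                           TrialRecord, estimate_slope, execute_extended_trial,
                           experiment_mode, first_accuracy_calibration,
                           run_participant, set_rotation_speed,
                           update_unreliable)

from conftest import make_profile


def itrial(angle, rt, correct=True):
    return TrialRecord(0, 1, "internal", 0, angle, False, "internal", False,
                       rt, correct, False, False)


class TestEstimateSlope:
    def test_exact_linear_fit(self):
        trials = [itrial(60, 1120), itrial(120, 1240), itrial(180, 1360)]
        assert estimate_slope(trials) == pytest.approx(2.0, abs=1e-12)

    def test_incorrect_trials_excluded(self):
        trials = [itrial(60, 1120), itrial(120, 1240), itrial(180, 1360),
                  itrial(60, 9000, correct=False), itrial(180, 50, correct=False)]
        assert estimate_slope(trials) == pytest.approx(2.0, abs=1e-12)

    def test_noisy_recovery_within_se(self, rng):
        angles = rng.choice([60, 120, 180], size=500)
        rts = 800.0 + 3.0 * angles + rng.normal(0, 200, size=500)
        trials = [itrial(int(a), float(r)) for a, r in zip(angles, rts)]
        se = 200.0 / np.sqrt(np.sum((angles - angles.mean()) ** 2))
        assert abs(estimate_slope(trials) - 3.0) < 3 * se

    def test_insufficient_data(self):
        with pytest.raises(CalibrationError):
            estimate_slope([itrial(60, 1120)])

    def test_single_angle(self):
        with pytest.raises(CalibrationError):
            estimate_slope([itrial(60, 1120), itrial(60, 1130)])


class TestSetRotationSpeed:
    def test_paper_worked_example(self):
        cfg = EngineConfig(speed_cap=1000.0)
        assert set_rotation_speed(2.0, cfg) == pytest.approx(10.0)

    def test_cap_arithmetic(self):
        cfg = EngineConfig(speed_cap=750.0)
        assert set_rotation_speed(0.5, cfg) == pytest.approx(15.0)

    def test_floor_case(self):
        cfg = EngineConfig(speed_cap=750.0)
        assert set_rotation_speed(-3.0, cfg) == pytest.approx(15.0)

    def test_never_exceeds_cap(self, rng):
        cfg = EngineConfig(speed_cap=1000.0)
        for slope in rng.uniform(-5, 10, size=200):
            assert set_rotation_speed(float(slope), cfg) <= 20.0 + 1e-12


class TestUnreliableUpdates:
    def test_paper_worked_example_plus_two(self):
        assert update_unreliable(0, 4, 3) == 2

    def test_paper_worked_example_total_four(self):
        assert update_unreliable(2, 4, 3) == 4

    def test_no_removal_by_default(self):
        assert update_unreliable(4, 1, 5) == 4

    def test_symmetric_variant(self):
        assert update_unreliable(4, 1, 3, symmetric=True) == 0

    def test_even_and_monotone(self, rng):
        for _ in range(200):
            c = 2 * int(rng.integers(0, 5))
            ei, ee = int(rng.integers(0, 10)), int(rng.integers(0, 10))
            out = update_unreliable(c, ei, ee)
            assert out % 2 == 0 and out >= c


class TestFirstAccuracyCalibration:
    def test_no_difference(self):
        assert first_accuracy_calibration(0.9, 0.9, 0.9, 48) == 0

    def test_spec_arithmetic(self):
        assert first_accuracy_calibration(42 / 48, 44 / 48, 46 / 48, 48) == 6

    def test_extended_worse_adds_nothing(self):
        assert first_accuracy_calibration(1.0, 1.0, 0.5, 48) == 0


class TestExecuteExtendedTrial:
    def test_deterministic_kinematics(self, rng):
        p = make_profile(a_man=400.0)
        state = CalibrationState(slope_hat=2.0, speed=10.0, lockout=0.0)
        rec = execute_extended_trial(p, state, 180, False, rng)
        assert rec.rt == pytest.approx(760.0) and rec.rotated

    def test_lockout_additivity(self, rng):
        p = make_profile(a_man=400.0)
        state = CalibrationState(slope_hat=2.0, speed=10.0, lockout=511.0)
        rec = execute_extended_trial(p, state, 180, False, rng)
        assert rec.rt == pytest.approx(1271.0)

    def test_unreliable_guess_rate(self, rng):
        p = make_profile()
        state = CalibrationState(slope_hat=2.0, speed=10.0)
        correct = [execute_extended_trial(p, state, 120, True, rng).correct
                   for _ in range(10_000)]
        assert abs(np.mean(correct) - 0.5) < 3 * np.sqrt(0.25 / 10_000)

    def test_timeout_semantics(self, rng):
        p = make_profile(a_man=11_999.0)
        state = CalibrationState(slope_hat=2.0, speed=10.0)
        rec = execute_extended_trial(p, state, 180, False, rng)
        assert rec.rt == 12_000.0 and rec.timeout and not rec.correct


class TestRunParticipant:
    def test_block_structure(self):
        prof = make_profile()
        cfg = experiment_mode("exp1", practice_enabled=False)
        recs = run_participant(prof, cfg, 0)
        blocks = {}
        for r in recs:
            blocks.setdefault(r.block, []).append(r)
        assert sorted(blocks) == list(range(1, 14))
        assert all(len(v) == 48 for v in blocks.values())
        roles = {b: {r.role for r in v} for b, v in blocks.items()}
        for b in (1, 3, 5, 7, 9):
            assert roles[b] == {"internal"}
        for b in (2, 4, 6, 8):
            assert roles[b] == {"extended"}
        for b in (10, 11, 12, 13):
            assert roles[b] == {"choice"}

    def test_determinism(self):
        prof = make_profile(sigma_rt=300.0, eps0_int=0.05)
        cfg = experiment_mode("exp1")
        assert run_participant(prof, cfg, 7) == run_participant(prof, cfg, 7)

    def test_noiseless_no_unreliables(self):
        prof = make_profile()
        cfg = experiment_mode("exp1", practice_enabled=False)
        recs = run_participant(prof, cfg, 0)
        assert not any(r.unreliable for r in recs)

    def test_exp2_matched_lockout_identity(self):
        # lockout 511 = a_int - a_man -> internal and extended RTs coincide
        prof = make_profile(a_int=1911.0, a_man=1400.0, b_int=2.0)
        cfg = experiment_mode("exp2", practice_enabled=False)
        recs = run_participant(prof, cfg, 0)
        by_angle = {}
        for r in recs:
            if r.block in (7, 8):
                by_angle.setdefault((r.block, r.angle), set()).add(r.rt)
        for angle in (60, 120, 180):
            assert by_angle[(7, angle)] == by_angle[(8, angle)]
        b7 = np.mean([r.rt for r in recs if r.block == 7])
        b8 = np.mean([r.rt for r in recs if r.block == 8])
        assert b7 == b8

    def test_exp1_constant_intercept_gap(self):
        prof = make_profile(a_int=1911.0, a_man=1400.0, b_int=2.0)
        cfg = experiment_mode("exp1", practice_enabled=False)
        recs = run_participant(prof, cfg, 0)
        rt = {(r.block, r.angle): r.rt for r in recs if r.block in (7, 8)}
        gaps = [rt[(8, a)] - rt[(7, a)] for a in (60, 120, 180)]
        assert all(g == pytest.approx(1400.0 - 1911.0) for g in gaps)

    def test_slope_exact_after_block1(self):
        prof = make_profile(b_int=3.0)
        cfg = experiment_mode("exp1", practice_enabled=False)
        recs = run_participant(prof, cfg, 0)
        b1 = [r for r in recs if r.block == 1]
        assert estimate_slope(b1) == pytest.approx(3.0, abs=1e-10)

    def test_practice_at_least_24(self):
        prof = make_profile(eps0_int=0.1)
        cfg = experiment_mode("exp1", practice_enabled=True)
        recs = run_participant(prof, cfg, 3)
        practice = [r for r in recs if r.role == "practice"]
        assert len(practice) >= 24
        # repeat-on-error: errors among the final-16 section are re-run
        n_errors = sum(1 for r in practice[8:] if not r.correct)
        assert len(practice) == 24 + n_errors

    def test_unreliable_counts_even_nondecreasing(self):
        cfg = experiment_mode("exp1", practice_enabled=False)
        prof = make_profile(sigma_rt=400.0, eps0_int=0.05, eps1_int=0.0004,
                            eps_man=0.02)
        recs = run_participant(prof, cfg, 0)
        counts = [sum(1 for r in recs if r.block == b and r.unreliable)
                  for b in (2, 4, 6, 8)]
        assert all(c % 2 == 0 for c in counts)

    def test_speed_cap_enforced_in_rts(self):
        # slope below the cap threshold: rotation runs at the cap
        prof = make_profile(b_int=0.5, a_man=400.0)
        cfg = experiment_mode("exp2", practice_enabled=False)
        recs = run_participant(prof, cfg, 0)
        for r in recs:
            if r.block == 8 and not r.unreliable:
                expected = 511.0 + r.angle / 0.75 + 400.0
                assert r.rt == pytest.approx(expected)


def test_engine_config_validation():
    with pytest.raises(ValueError):
        EngineConfig(calibration_block_roles=("e", "i"))
    with pytest.raises(ValueError):
        EngineConfig(tick=0.0)
    with pytest.raises(ValueError):
        experiment_mode("exp9")
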