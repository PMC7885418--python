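import math

import numpy as np
import pytest

from emgdecode import fitts, metrics, synth


class StraightMover:
    """Scripted controller: head for the target center at full speed,
    clamp at the center, ignore the EMG entirely."""

    def __init__(self, target, rate=200.0, speed=540.0):
        self.goal = np.asarray(target.center, float)
        self.pos = np.zeros(2)
        self.rate = rate
        self.speed = speed

    def warmup(self, sample):
        pass

    def velocity(self, sample):
        delta = self.goal - self.pos
        dist = float(np.linalg.norm(delta))
        if dist == 0:
            return np.zeros(2)
        step = min(dist, self.speed / self.rate)
        v = delta / dist * step * self.rate
        self.pos = self.pos + v / self.rate
        return v


class VelocityScript:
    """Scripted controller replaying a fixed velocity sequence."""

    def __init__(self, velocities):
        self.seq = list(velocities)
        self.k = 0

    def warmup(self, sample):
        pass

    def velocity(self, sample):
        v = self.seq[self.k] if self.k < len(self.seq) else np.zeros(2)
        self.k += 1
        return np.asarray(v, float)


class ZeroController:
    def warmup(self, sample):
        pass

    def velocity(self, sample):
        return np.zeros(2)


@pytest.fixture
def quiet_user():
    return fitts.SimulatedUser()


class TestTargetSet:
    def test_forty_targets(self):
        assert len(fitts.make_target_set()) == 40

    def test_radii(self):
        radii = {t.radius for t in fitts.make_target_set()}
        assert radii == {60.0, 85.0}
        assert fitts.DEFAULT_RADII[1] == math.ceil(math.sqrt(2) * 60)

    def test_six_distinct_difficulty_values(self):
        ids = {
            round(metrics.index_of_difficulty(t.distance, t.diameter), 9)
            for t in fitts.make_target_set()
        }
        assert len(ids) == 6

    def test_difficulty_range_matches_published(self):
        ids = [
            metrics.index_of_difficulty(t.distance, t.diameter)
            for t in fitts.make_target_set()
        ]
        assert min(ids) == pytest.approx(1.17, abs=0.005)
        assert max(ids) == pytest.approx(2.38, abs=0.005)

    def test_no_target_on_axes(self):
        for t in fitts.make_target_set():
            assert abs(t.center[0]) > 1.0 and abs(t.center[1]) > 1.0

    def test_quadrant_balance(self):
        centers = {t.center for t in fitts.make_target_set()}
        quads = [0, 0, 0, 0]
        for x, y in centers:
            quads[(x < 0) + 2 * (y < 0)] += 1
        assert quads == [5, 5, 5, 5]

    def test_axis_angle_rejected(self):
        with pytest.raises(ValueError):
            fitts.make_target_set(angles=(0.0, 30.0, 45.0, 60.0, 75.0))


class TestVelocityMappings:
    def test_zero_command_zero_speed(self):
        np.testing.assert_array_equal(fitts.regressor_velocity([0.0, 0.0]), [0.0, 0.0])

    def test_unit_norm_gives_full_speed(self):
        v = fitts.regressor_velocity([3 / 5, 4 / 5])
        assert np.linalg.norm(v) == pytest.approx(540.0)

    def test_linearity(self):
        np.testing.assert_allclose(fitts.regressor_velocity([0.5, 0.0]), [270.0, 0.0])

    def test_wrong_dof_count_rejected(self):
        with pytest.raises(ValueError):
            fitts.regressor_velocity([1.0])

    def test_rest_class_stops(self):
        np.testing.assert_array_equal(fitts.lda_velocity(0, 1.0), [0.0, 0.0])

    def test_wrist_extension_moves_right(self):
        np.testing.assert_allclose(fitts.lda_velocity(2, 1.0), [540.0, 0.0])

    def test_compound_class_moves_diagonally(self):
        v = fitts.lda_velocity(8, 1.0)
        np.testing.assert_allclose(v, 540.0 * np.array([1, 1]) / math.sqrt(2))
        assert np.linalg.norm(v) == pytest.approx(540.0)

    def test_speed_scales_with_pc(self):
        v = fitts.lda_velocity(1, 0.25)
        assert np.linalg.norm(v) == pytest.approx(135.0)


class TestRunTrial:
    def test_straight_run_completion_time(self, profile, quiet_user):
        # D = 270 px at 540 px/s -> 0.5 s travel + 0.3 s dwell
        target = fitts.TargetSpec(center=(270 / math.sqrt(2), 270 / math.sqrt(2)),
                                  radius=2.0)
        log = fitts.run_trial(
            StraightMover(target), target, quiet_user, profile,
            np.random.default_rng(0),
        )
        assert log.success
        assert log.completion_time == pytest.approx(0.8, abs=0.01)

    def test_zero_controller_fails_at_timeout(self, profile, quiet_user):
        target = fitts.TargetSpec(center=(200.0, 200.0), radius=60.0)
        log = fitts.run_trial(
            ZeroController(), target, quiet_user, profile, np.random.default_rng(0)
        )
        assert not log.success
        assert log.completion_time is None
        assert len(log.trajectory) - 1 == 20 * 200

    def test_enter_exit_reenter_counts_one_overshoot(self, profile, quiet_user):
        target = fitts.TargetSpec(center=(10.0, 10.0), radius=4.0)
        inward = np.array([10.0, 10.0]) * 20.0  # reaches center in 1/20 s
        outward = np.array([200.0, 200.0])
        seq = (
            [inward / 2] * 20  # enter and sit at center after ~10 samples
            + [outward] * 12   # leave the target
            + [-outward] * 12  # come back
            + [np.zeros(2)] * 400  # dwell
        )
        log = fitts.run_trial(
            VelocityScript(seq), target, quiet_user, profile,
            np.random.default_rng(0),
        )
        assert log.success
        assert log.overshoots == 1

    def test_trajectory_starts_at_origin(self, profile, quiet_user):
        target = fitts.TargetSpec(center=(100.0, 100.0), radius=60.0)
        log = fitts.run_trial(
            StraightMover(target), target, quiet_user, profile,
            np.random.default_rng(1),
        )
        np.testing.assert_array_equal(log.trajectory[0], [0.0, 0.0])

    def test_success_requires_sixty_consecutive_inside_samples(self, profile, quiet_user):
        target = fitts.TargetSpec(center=(100.0, 100.0), radius=60.0)
        log = fitts.run_trial(
            StraightMover(target), target, quiet_user, profile,
            np.random.default_rng(2),
        )
        assert log.success
        tail = log.trajectory[-60:]
        d = np.hypot(tail[:, 0] - 100.0, tail[:, 1] - 100.0)
        assert np.all(d < target.radius)

    def test_clock_matches_sample_count(self, profile, quiet_user):
        target = fitts.TargetSpec(center=(150.0, 80.0), radius=40.0)
        log = fitts.run_trial(
            StraightMover(target), target, quiet_user, profile,
            np.random.default_rng(3),
        )
        assert log.success
        assert log.completion_time == (len(log.trajectory) - 1) / 200.0


class TestSimulatedUser:
    def test_stop_band_at_center(self):
        user = fitts.SimulatedUser()
        target = fitts.TargetSpec(center=(100.0, 0.1), radius=60.0)
        intent = user.intent(target, np.array([100.0, 0.1]), 1.0,
                             np.random.default_rng(0))
        assert np.linalg.norm(intent) <= 0.05

    def test_relaxes_inside_target(self):
        user = fitts.SimulatedUser()
        target = fitts.TargetSpec(center=(100.0, 50.0), radius=60.0)
        far = user.intent(target, np.zeros(2), 1.0, np.random.default_rng(0))
        near = user.intent(target, np.array([95.0, 45.0]), 1.0,
                           np.random.default_rng(0))
        assert np.linalg.norm(near) < 0.2 * np.linalg.norm(far)

    def test_noise_free_proportional_loop_is_straight(self):
        """Ideal proportional controller + noiseless user: path efficiency
        is essentially perfect."""
        user = fitts.SimulatedUser()
        target = fitts.TargetSpec(center=(300.0, 200.0), radius=30.0)
        cursor = np.zeros(2)
        path = 0.0
        rng = np.random.default_rng(0)
        for k in range(4000):
            intent = user.intent(target, cursor, k / 200.0, rng)
            v = 540.0 * intent  # ideal decoder
            step = v / 200.0
            path += float(np.linalg.norm(step))
            cursor = cursor + step
            if np.linalg.norm(cursor - target.center) < 1.0:
                break
        assert path <= 1.01 * np.linalg.norm(target.center)

    def test_reaction_delay_outputs_zero(self):
        user = fitts.SimulatedUser(reaction_seconds=0.5)
        target = fitts.TargetSpec(center=(100.0, 100.0), radius=60.0)
        intent = user.intent(target, np.zeros(2), 0.3, np.random.default_rng(0))
        np.testing.assert_array_equal(intent, [0.0, 0.0])

    def test_reproducible_with_fixed_seed(self, profile):
        target = fitts.TargetSpec(center=(120.0, 90.0), radius=60.0)
        user = fitts.SimulatedUser(direction_noise_sd=0.2, magnitude_noise_sd=0.05)
        a = fitts.run_trial(StraightMover(target), target, user, profile,
                            np.random.default_rng(5))
        user2 = fitts.SimulatedUser(direction_noise_sd=0.2, magnitude_noise_sd=0.05)
        b = fitts.run_trial(StraightMover(target), target, user2, profile,
                            np.random.default_rng(5))
        np.testing.assert_array_equal(a.trajectory, b.trajectory)


class TestRunSession:
    def _session(self, seed, profile):
        targets = fitts.make_target_set()

        class PerTargetMover:
            """Fresh straight mover per trial; state reset via warmup calls."""

            def __init__(self):
                self.mover = None

            def warmup(self, sample):
                self.mover = None

            def velocity(self, sample):
                if self.mover is None:
                    self.mover = StraightMover(self.current)
                return self.mover.velocity(sample)

        ctrl = PerTargetMover()
        user = fitts.SimulatedUser()
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(targets))
        logs = [None] * len(targets)
        for idx in order:
            ctrl.current = targets[idx]
            ctrl.mover = None
            logs[idx] = fitts.run_trial(ctrl, targets[idx], user, profile, rng)
        return logs

    def test_forty_logs_all_from_origin(self, profile):
        logs = self._session(0, profile)
        assert len(logs) == 40
        for log in logs:
            np.testing.assert_array_equal(log.trajectory[0], [0.0, 0.0])

    def test_run_session_order_depends_on_seed(self, profile):
        targets = fitts.make_target_set()[:4]
        user = fitts.SimulatedUser()
        logs_a = fitts.run_session(ZeroController(), targets, user, profile,
                                   seed=1, timeout=0.5, inter_trial_rest=0.1)
        logs_b = fitts.run_session(ZeroController(), targets, user, profile,
                                   seed=2, timeout=0.5, inter_trial_rest=0.1)
        assert len(logs_a) == len(logs_b) == 4
        # seed changes the rng stream; all logs still map back to their targets
        for la, lb, t in zip(logs_a, logs_b, targets):
            assert la.target is t and lb.target is t
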