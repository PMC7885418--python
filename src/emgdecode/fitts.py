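"""Closed-loop virtual target-acquisition test.

Simulates the cursor task: circular targets off the coordinate axes, a
3 s planning hold, velocity control at 200 Hz, 0.3 s dwell for success,
20 s timeout, and trajectory logging.  A scripted simulated user closes
the loop: it forms a continuous 2-DoF intent from the cursor-to-target
geometry, the synthetic-EMG model turns that intent into voltages, and
the controller under test maps voltages back to cursor velocity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .envelope import NormalizationStats, StreamingEnvelope
from .lda import WINDOW_SAMPLES, LdaModel, ProportionalityTables, classify, feature_vector, proportionality
from .network import NetParams, forward
from .synth import CLASS_ENCODINGS, EmgSimulator, SubjectProfile

FULL_SPEED = 540.0  # px/s at unit command magnitude
SAMPLING_RATE = 200.0
DEFAULT_RADII = (60, int(math.ceil(math.sqrt(2) * 60)))
DEFAULT_DISTANCES = (213.0, 350.0, 505.0)
DEFAULT_ANGLES = (15.0, 30.0, 45.0, 60.0, 75.0)


@dataclass(frozen=True)
class TargetSpec:
    center: tuple[float, float]
    radius: float

    @property
    def distance(self) -> float:
        return math.hypot(*self.center)

    @property
    def diameter(self) -> float:
        return 2.0 * self.radius


@dataclass
class TrialLog:
    target: TargetSpec
    trajectory: np.ndarray  # (n, 2) positions at 200 Hz from control grant
    success: bool
    completion_time: float | None  # seconds from control grant (success only)
    overshoots: int

    @property
    def path_length(self) -> float:
        if len(self.trajectory) < 2:
            return 0.0
        return float(np.linalg.norm(np.diff(self.trajectory, axis=0), axis=1).sum())


def make_target_set(distances=DEFAULT_DISTANCES, radii=DEFAULT_RADII,
                    angles=DEFAULT_ANGLES) -> list[TargetSpec]:
    """The 40-target layout: 5 centers per quadrant (distances cycled
    over off-axis angles) crossed with 2 radii."""
    targets = []
    for q in range(4):
        for k, angle in enumerate(angles):
            theta = math.radians(angle + 90.0 * q)
            if abs(math.cos(theta)) < 1e-9 or abs(math.sin(theta)) < 1e-9:
                raise ValueError("target angle lies on a coordinate axis")
            d = distances[k % len(distances)]
            center = (d * math.cos(theta), d * math.sin(theta))
            for r in radii:
                targets.append(TargetSpec(center=center, radius=float(r)))
    return targets


def regressor_velocity(y_hat) -> np.ndarray:
    """Continuous-controller velocity: command scaled to 540 px/s at
    unit Euclidean norm (x from DoF 1, y from DoF 2)."""
    y_hat = np.asarray(y_hat, float)
    if y_hat.shape != (2,):
        raise ValueError("velocity mapping requires a 2-DoF command")
    return FULL_SPEED * y_hat


def lda_velocity(m: int, pc: float) -> np.ndarray:
    """Class-based velocity: unit direction from the ternary encoding of
    class ``m`` (axes for 1-DoF, diagonals for 2-DoF), speed 540*pc."""
    if m == 0:
        return np.zeros(2)
    enc = np.asarray(CLASS_ENCODINGS[m], float)
    direction = enc / np.linalg.norm(enc)
    return FULL_SPEED * pc * direction


class SimulatedUser:
    """Scripted intent generator standing in for the human subject.

    Aims from the cursor to the target center; the magnitude ramps down
    within ``ramp_px`` of the center (stop band at the center itself) and
    both direction and magnitude are perturbed with Gaussian noise.
    """

    def __init__(self, direction_noise_sd: float = 0.0,
                 magnitude_noise_sd: float = 0.0,
                 reaction_seconds: float = 0.0,
                 ramp_px: float = 150.0,
                 max_intent: float = 0.5,
                 smoothing: float = 0.0,
                 relax_inside: float = 0.1):
        self.direction_noise_sd = direction_noise_sd
        self.magnitude_noise_sd = magnitude_noise_sd
        self.reaction_seconds = reaction_seconds
        self.ramp_px = ramp_px
        self.max_intent = max_intent
        self.smoothing = smoothing  # EMA weight on the previous intent
        self.relax_inside = relax_inside  # effort multiplier once in-target
        self._prev = np.zeros(2)

    def reset(self):
        self._prev = np.zeros(2)

    def intent(self, target: TargetSpec, cursor: np.ndarray,
               t_seconds: float, rng: np.random.Generator) -> np.ndarray:
        if t_seconds < self.reaction_seconds:
            return np.zeros(2)
        delta = np.asarray(target.center, float) - cursor
        dist = float(np.linalg.norm(delta))
        if dist < 1e-9:
            self._prev = (self.smoothing * self._prev)
            return self._prev.copy()
        angle = math.atan2(delta[1], delta[0])
        if self.direction_noise_sd > 0:
            angle += self.direction_noise_sd * rng.standard_normal()
        mag = self.max_intent * min(1.0, dist / self.ramp_px)
        if dist < target.radius:
            mag *= self.relax_inside  # hold still while dwelling
        if self.magnitude_noise_sd > 0:
            mag += self.magnitude_noise_sd * rng.standard_normal()
        mag = float(np.clip(mag, 0.0, 1.0))
        vec = mag * np.array([math.cos(angle), math.sin(angle)])
        vec = self.smoothing * self._prev + (1.0 - self.smoothing) * vec
        self._prev = np.clip(vec, -1.0, 1.0)
        return self._prev.copy()


class RegressorController:
    """Envelope streaming + network forward pass -> velocity."""

    def __init__(self, params: NetParams, stats: NormalizationStats,
                 filter_length: int):
        self.params = params
        self.stream = StreamingEnvelope(stats, filter_length)

    def reset(self):
        self.stream.reset()

    def velocity(self, sample: np.ndarray) -> np.ndarray:
        env = self.stream.step(sample)
        _, y_hat = forward(self.params, env)
        return regressor_velocity(y_hat)


class LdaController:
    """Trailing-window feature classification recomputed every sample."""

    def __init__(self, model: LdaModel, tables: ProportionalityTables,
                 n_channels: int, window: int = WINDOW_SAMPLES):
        self.model = model
        self.tables = tables
        self.window = window
        self.n_channels = n_channels
        self._buf = np.zeros((n_channels, window))
        self._count = 0

    def reset(self):
        self._buf[:] = 0.0
        self._count = 0

    def velocity(self, sample: np.ndarray) -> np.ndarray:
        self._buf[:, :-1] = self._buf[:, 1:]
        self._buf[:, -1] = sample
        self._count += 1
        if self._count < self.window:
            return np.zeros(2)
        vec = feature_vector(self._buf)
        m = classify(self.model, vec)
        if m == 0:
            return np.zeros(2)
        pc = proportionality(vec[0::4], m, self.tables)
        return lda_velocity(m, pc)


def run_trial(controller, target: TargetSpec, subject_sim: SimulatedUser,
              profile: SubjectProfile, rng: np.random.Generator,
              timeout: float = 20.0, hold: float = 3.0, dwell: float = 0.3,
              rate: float = SAMPLING_RATE,
              emg_source: EmgSimulator | None = None) -> TrialLog:
    """Run one target acquisition attempt through the full loop.

    During the hold phase the cursor is frozen at the origin while rest
    EMG keeps flowing through the controller's filters.  Success occurs
    at the first instant the cursor has been strictly inside the target
    for ``dwell * rate`` consecutive samples; an overshoot is counted
    each time the cursor exits the boundary before dwell completion.
    """
    dt = 1.0 / rate
    dwell_samples = int(round(dwell * rate))
    max_samples = int(round(timeout * rate))
    cursor = np.zeros(2)
    trajectory = [cursor.copy()]
    if emg_source is None:
        emg_source = EmgSimulator(profile, rng, sampling_rate=rate)

    if hasattr(subject_sim, "reset"):
        subject_sim.reset()
    # rest EMG keeps flowing during the hold; scripted controllers without
    # filter state may expose `warmup` as a no-op instead
    feed = getattr(controller, "warmup", controller.velocity)
    for _ in range(int(round(hold * rate))):
        feed(emg_source.sample(np.zeros(2)))

    inside_run = 0
    was_inside = False
    overshoots = 0
    success = False
    completion = None

    for k in range(1, max_samples + 1):
        t = (k - 1) * dt
        intent = subject_sim.intent(target, cursor, t, rng)
        sample = emg_source.sample(intent)
        v = controller.velocity(sample)
        cursor = cursor + v * dt
        trajectory.append(cursor.copy())
        inside = float(np.hypot(cursor[0] - target.center[0],
                                cursor[1] - target.center[1])) < target.radius
        if inside:
            inside_run += 1
            was_inside = True
            if inside_run >= dwell_samples:
                success = True
                completion = k * dt
                break
        else:
            if was_inside and inside_run > 0:
                overshoots += 1
            inside_run = 0
    return TrialLog(
        target=target,
        trajectory=np.asarray(trajectory),
        success=success,
        completion_time=completion,
        overshoots=overshoots,
    )


def run_session(controller, target_set, subject_sim: SimulatedUser,
                profile: SubjectProfile, seed: int,
                inter_trial_rest: float = 5.0,
                rate: float = SAMPLING_RATE, **trial_kwargs) -> list[TrialLog]:
    """Attempt every target exactly once, in seed-randomized order, with
    rest-intent EMG streamed between trials to keep filter states hot."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(target_set))
    logs = [None] * len(target_set)
    feed = getattr(controller, "warmup", controller.velocity)
    emg_source = EmgSimulator(profile, rng, sampling_rate=rate)
    for idx in order:
        for _ in range(int(round(inter_trial_rest * rate))):
            feed(emg_source.sample(np.zeros(2)))
        logs[idx] = run_trial(
            controller, target_set[idx], subject_sim, profile, rng,
            rate=rate, emg_source=emg_source, **trial_kwargs,
        )
    return logs
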