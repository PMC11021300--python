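"""Block-schedule execution with adaptive performance calibration.

Runs one simulated participant through the full paradigm: optional practice,
nine forced-strategy calibration blocks alternating internal (mental rotation)
and extended (keyboard rotation), and four free-choice blocks. Two yoking
mechanisms tie extended performance to the participant's own internal
performance:

* speed yoking — at the end of every internal block an OLS slope
  (Angle -> RT, correct trials only, cumulative) is re-estimated and the
  on-screen rotation speed is set to its inverse, capped at a maximum speed;
* reliability yoking — for every error committed more in the preceding
  internal than in the preceding extended block, two "unreliable" trials
  (rotation fails, forcing a guess) are added to the next extended block.

Experiment-2 mode additionally imposes a lockout window: rotation starts only
after a continuous key press of fixed duration, and lowers the speed cap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .cohort import (
    ANGLE_SET,
    DEADLINE_MS,
    ChoicePolicy,
    ParticipantProfile,
    choose_strategy,
    internal_response,
    perceived_rt_delta,
)

__all__ = [
    "EngineConfig",
    "CalibrationState",
    "TrialRecord",
    "CalibrationError",
    "EngineError",
    "estimate_slope",
    "set_rotation_speed",
    "update_unreliable",
    "first_accuracy_calibration",
    "execute_extended_trial",
    "run_participant",
    "experiment_mode",
    "SLOPE_FLOOR",
]

SLOPE_FLOOR = 0.1  # ms per degree; guards against non-positive OLS slopes


class CalibrationError(RuntimeError):
    """Raised when a slope cannot be estimated from the available trials."""


class EngineError(RuntimeError):
    """Calibration failure annotated with participant/block context."""


@dataclass(frozen=True)
class EngineConfig:
    """Schedule and calibration constants of one experiment mode."""

    trials_per_block: int = 48
    calibration_block_roles: tuple = ("i", "e", "i", "e", "i", "e", "i", "e", "i")
    n_choice_blocks: int = 4
    tick: float = 20.0            # rotation update interval, ms
    speed_cap: float = 1000.0     # degrees per second
    lockout: float = 0.0          # ms
    deadline: float = DEADLINE_MS
    angle_set: tuple = ANGLE_SET
    practice_enabled: bool = True
    slope_floor: float = SLOPE_FLOOR
    symmetric_unreliable: bool = False  # allow error deficits to remove trials

    def __post_init__(self):
        ok = (
            self.trials_per_block >= 1
            and self.calibration_block_roles
            and self.calibration_block_roles[0] == "i"
            and self.calibration_block_roles[-1] == "i"
            and all(r in ("i", "e") for r in self.calibration_block_roles)
            and self.tick > 0
            and self.speed_cap > 0
            and self.lockout >= 0
            and self.deadline > 0
            and self.slope_floor > 0
        )
        if not ok:
            raise ValueError("invalid EngineConfig")


def experiment_mode(name: str, **overrides) -> EngineConfig:
    """Engine constants of the two experiment modes.

    ``exp1``: speed cap 1000 deg/s, no lockout. ``exp2``: cap 750 deg/s and a
    511-ms lockout window before rotation onset.
    """
    presets = {"exp1": (1000.0, 0.0), "exp2": (750.0, 511.0)}
    if name not in presets:
        raise ValueError(f"unknown experiment mode {name!r}")
    cap, lockout = presets[name]
    return EngineConfig(speed_cap=cap, lockout=lockout, **overrides)


@dataclass
class CalibrationState:
    """Mutable calibration parameters carried across blocks."""

    slope_hat: Optional[float] = None   # ms per degree
    speed: float = 0.0                  # degrees per tick
    unreliable_count: int = 0
    lockout: float = 0.0

    def __post_init__(self):
        if self.unreliable_count < 0 or self.unreliable_count % 2:
            raise ValueError("unreliable_count must be even and >= 0")


@dataclass(frozen=True)
class TrialRecord:
    """One executed trial."""

    participant: int
    block: int            # 0 = practice, 1-9 calibration, 10-13 choice
    role: str             # practice | internal | extended | choice
    trial: int            # index within block, 0-based
    angle: int
    mirrored: bool
    strategy_used: str    # internal | extended
    rotated: bool
    rt: float
    correct: bool
    timeout: bool
    unreliable: bool


def estimate_slope(internal_trials: Sequence[TrialRecord]) -> float:
    """OLS slope of RT on angle over all correct internal trials given.

    The engine calls this cumulatively: trials from every internal block run
    so far are passed in together. Incorrect trials carry no information about
    rotation speed and are excluded.
    """
    pts = [(t.angle, t.rt) for t in internal_trials if t.correct]
    if len(pts) < 2:
        raise CalibrationError("need >= 2 correct internal trials")
    a = np.array([p[0] for p in pts], dtype=float)
    r = np.array([p[1] for p in pts], dtype=float)
    if np.ptp(a) == 0.0:
        raise CalibrationError("correct trials span a single angle")
    a_c = a - a.mean()
    return float(np.dot(a_c, r) / np.dot(a_c, a_c))


def set_rotation_speed(slope_hat: float, config: EngineConfig) -> float:
    """Degrees of rotation applied per update tick for a given slope estimate.

    The target speed is the inverse of the slope (so that rotating through an
    angle takes as long as mentally rotating it), floored at ``slope_floor``
    and capped at ``speed_cap``.
    """
    if not np.isfinite(slope_hat):
        raise ValueError("slope_hat must be finite")
    speed_deg_per_ms = min(1.0 / max(slope_hat, config.slope_floor),
                           config.speed_cap / 1000.0)
    return speed_deg_per_ms * config.tick


def update_unreliable(count_prev: int, errors_internal_prev: int,
                      errors_extended_prev: int, *,
                      symmetric: bool = False) -> int:
    """Unreliable-trial count for the next extended block.

    Two trials are added per error committed more in the preceding internal
    than in the preceding extended block; deficits never remove trials unless
    ``symmetric`` is set (non-default variant).
    """
    if min(count_prev, errors_internal_prev, errors_extended_prev) < 0:
        raise ValueError("counts must be >= 0")
    diff = errors_internal_prev - errors_extended_prev
    if not symmetric:
        diff = max(0, diff)
    return max(0, count_prev + 2 * diff)


def first_accuracy_calibration(acc_block1: float, acc_block3: float,
                               acc_block2: float, trials_per_block: int) -> int:
    """Unreliable count for Block 4, the first accuracy-calibrated block.

    Because two internal blocks precede it, the mean accuracy of Blocks 1 and
    3 is used on the internal side; error counts are reconstructed as
    ``round(trials * (1 - accuracy))``.
    """
    for acc in (acc_block1, acc_block3, acc_block2):
        if not 0.0 <= acc <= 1.0:
            raise ValueError("accuracies must be in [0, 1]")
    err_int = round(trials_per_block * (1.0 - (acc_block1 + acc_block3) / 2.0))
    err_ext = round(trials_per_block * (1.0 - acc_block2))
    return update_unreliable(0, err_int, err_ext)


def _finish(rt: float, correct: bool, deadline: float) -> tuple:
    """Apply deadline semantics: (rt, correct, timeout)."""
    rt = max(rt, 1.0)
    if rt >= deadline:
        return deadline, False, True
    return float(rt), bool(correct), False


def execute_extended_trial(profile: ParticipantProfile, state: CalibrationState,
                           angle: int, unreliable: bool,
                           rng: np.random.Generator,
                           config: EngineConfig = EngineConfig()) -> TrialRecord:
    """One keyboard-rotation trial (participant/block/trial indices zeroed).

    Reliable trial: rt = lockout + time to rotate through ``angle`` at the
    calibrated speed + motor/decision intercept ``a_man`` + noise; correct
    with probability 1 - ``eps_man``. Unreliable trial: the stimulus vanishes
    at the first key press, the answer is a coin-flip guess, and rt is lockout
    plus a guess-time draw (the motor/decision intercept plus noise).
    """
    if state.speed <= 0:
        raise ValueError("rotation speed must be positive")
    if angle not in config.angle_set:
        raise ValueError(f"angle must be one of {config.angle_set}, got {angle}")
    noise = rng.normal(0.0, profile.sigma_rt) if profile.sigma_rt > 0 else 0.0
    if unreliable:
        rt = state.lockout + profile.a_man + noise
        correct = rng.random() < 0.5
    else:
        rotation_time = angle / state.speed * config.tick
        rt = state.lockout + rotation_time + profile.a_man + noise
        correct = rng.random() >= profile.eps_man
    rt, correct, timeout = _finish(rt, correct, config.deadline)
    return TrialRecord(0, 0, "extended", 0, angle, False, "extended", True,
                       rt, correct, timeout, unreliable)


def _draw_angle_mirror(config, rng):
    angle = int(config.angle_set[rng.integers(len(config.angle_set))])
    return angle, bool(rng.random() < 0.5)


def _block_angles(config, rng) -> list:
    """Angle sequence of one block: counterbalanced over the angle set when
    the block length divides evenly, then shuffled; extra trials drawn
    uniformly at random."""
    k = len(config.angle_set)
    reps, extra = divmod(config.trials_per_block, k)
    angles = [int(a) for a in config.angle_set for _ in range(reps)]
    angles += [int(config.angle_set[i])
               for i in rng.integers(k, size=extra)]
    rng.shuffle(angles)
    return angles


def _internal_record(profile, angle, mirrored, rng, config, *, pid, block, role,
                     trial, strategy="internal"):
    rt, correct = internal_response(profile, angle, rng)
    rt, correct, timeout = _finish(rt, correct, config.deadline)
    return TrialRecord(pid, block, role, trial, angle, mirrored, strategy,
                       False, rt, correct, timeout, False)


def _run_practice(profile, config, rng, pid) -> list:
    """At least 24 practice trials; the final 16 repeat on error."""
    records = []
    trial = 0
    for _ in range(24 - 16):
        angle, mirrored = _draw_angle_mirror(config, rng)
        records.append(_internal_record(profile, angle, mirrored, rng, config,
                                        pid=pid, block=0, role="practice",
                                        trial=trial))
        trial += 1
    queue = [_draw_angle_mirror(config, rng) for _ in range(16)]
    guard = 0
    while queue and guard < 1000:
        angle, mirrored = queue.pop(0)
        rec = _internal_record(profile, angle, mirrored, rng, config,
                               pid=pid, block=0, role="practice", trial=trial)
        records.append(rec)
        trial += 1
        guard += 1
        if not rec.correct:
            queue.append((angle, mirrored))
    return records


def run_participant(profile: ParticipantProfile, config: EngineConfig,
                    rng, participant_id: int = 0) -> list:
    """Full session of one participant: practice, calibration, choice blocks.

    Returns the trial records in execution order. The rotation speed is
    re-derived from the cumulative slope estimate at the end of every internal
    block; unreliable counts are updated before each extended block (Block 4
    from the reconstructed accuracies of Blocks 1-3) and once more, from
    Blocks 9 and 8, before the choice section, where calibration is frozen.
    """
    rng = np.random.default_rng(rng)
    state = CalibrationState(lockout=config.lockout)
    records: list = []
    if config.practice_enabled:
        records.extend(_run_practice(profile, config, rng, participant_id))

    internal_pool: list = []          # all internal calibration records so far
    block_stats: dict = {}            # block -> (n_errors, accuracy)
    tpb = config.trials_per_block

    def block_errors(recs):
        return sum(1 for r in recs if not r.correct)

    # ---- calibration section -------------------------------------------
    n_cal = len(config.calibration_block_roles)
    for b, role in enumerate(config.calibration_block_roles, start=1):
        block_recs = []
        angles = _block_angles(config, rng)
        if role == "i":
            for trial in range(tpb):
                angle, mirrored = angles[trial], bool(rng.random() < 0.5)
                block_recs.append(_internal_record(
                    profile, angle, mirrored, rng, config, pid=participant_id,
                    block=b, role="internal", trial=trial))
            internal_pool.extend(block_recs)
            try:
                state.slope_hat = estimate_slope(internal_pool)
            except CalibrationError as exc:
                if state.slope_hat is None:
                    raise EngineError(
                        f"participant {participant_id}, block {b}: {exc}"
                    ) from exc
                # keep the previous estimate
            state.speed = set_rotation_speed(state.slope_hat, config)
        else:
            if b == 4:
                state.unreliable_count = first_accuracy_calibration(
                    block_stats[1][1], block_stats[3][1], block_stats[2][1], tpb)
            elif b > 4:
                state.unreliable_count = update_unreliable(
                    state.unreliable_count,
                    block_stats[b - 1][0], block_stats[b - 2][0],
                    symmetric=config.symmetric_unreliable)
            slots = set(rng.choice(tpb, size=min(state.unreliable_count, tpb),
                                   replace=False).tolist())
            for trial in range(tpb):
                rec = execute_extended_trial(profile, state, angles[trial],
                                             trial in slots, rng, config)
                block_recs.append(replace(rec, participant=participant_id,
                                          block=b, trial=trial,
                                          mirrored=bool(rng.random() < 0.5)))
        err = block_errors(block_recs)
        block_stats[b] = (err, 1.0 - err / tpb)
        records.extend(block_recs)

    # ---- choice section -------------------------------------------------
    state.unreliable_count = update_unreliable(
        state.unreliable_count,
        block_stats[n_cal][0], block_stats[n_cal - 1][0],
        symmetric=config.symmetric_unreliable)

    # Perceived deltas (internal - extended). The RT input is the
    # steady-state experienced difference implied by the profile under the
    # final calibration: with the rotation speed converged to the true slope,
    # the expected RT difference at the mean angle reduces to the intercept
    # gap minus the lockout (plus any speed-cap shortfall). Using this
    # expectation rather than one noisy block-pair realisation keeps the
    # choice input independent of the measurement noise in the analysed
    # block-7/8 difference. The accuracy input is the realised accuracy
    # difference of the final yoked block pair.
    mean_angle = float(np.mean(config.angle_set))
    speed_ms = min(1.0 / max(profile.b_int, config.slope_floor),
                   config.speed_cap / 1000.0)  # degrees per ms
    expected_internal = profile.a_int + profile.b_int * mean_angle
    expected_extended = config.lockout + mean_angle / speed_ms + profile.a_man
    true_delta_rt = expected_internal - expected_extended
    last_ext = n_cal - 1              # block 8 under the default schedule
    acc_delta = block_stats[last_ext - 1][1] - block_stats[last_ext][1]
    delta_rt = perceived_rt_delta(profile, true_delta_rt)

    previous = None
    for cb in range(config.n_choice_blocks):
        b = n_cal + 1 + cb
        slots = set(rng.choice(tpb, size=min(state.unreliable_count, tpb),
                               replace=False).tolist())
        angles = _block_angles(config, rng)
        for trial in range(tpb):
            angle, mirrored = angles[trial], bool(rng.random() < 0.5)
            strategy = choose_strategy(profile.policy, delta_rt, acc_delta,
                                       angle, previous, rng)
            if strategy == "internal":
                rec = _internal_record(profile, angle, mirrored, rng, config,
                                       pid=participant_id, block=b,
                                       role="choice", trial=trial)
            else:
                rec = execute_extended_trial(profile, state, angle,
                                             trial in slots, rng, config)
                rec = replace(rec, participant=participant_id, block=b,
                              role="choice", trial=trial, mirrored=mirrored)
            records.append(rec)
            previous = strategy
    return records
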