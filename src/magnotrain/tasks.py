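"""Engines for the training and assessment tasks.

Four procedures are modelled:

* **Digit counting** — 10 levels; presentation time shrinks linearly
  from 560 ms (level 1) to 190 ms (level 10); level +1 after a correct
  answer, -1 after a wrong one, and the session stops outright after
  four cumulative mistakes.
* **Dot counting** — sequential dots to be traced and counted; level 1
  shows 7-9 dots in 9 s; the child advances on >= 80 % correct in a
  block, each level adds dots and shrinks the inter-dot interval by
  25 % relative to the previous level.
* **RDK with feedback** — the same weighted staircase as the threshold
  test, plus a feedback flag per trial, stopping after a total of four
  wrong choices.
* **Saccade-cycle scoring** — a leftward saccade followed by the next
  rightward one counts as a cycle; performance is cycles per minute.

Responders are callables ``(level, rng) -> bool`` (digit/dot tasks); a
deterministic sequence can be wrapped with :func:`sequence_responder`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, List, NamedTuple, Optional, Sequence, Tuple

import numpy as np

from .staircase import (
    StaircaseConfig,
    StaircaseState,
    attenuation_to_coherence,
    update,
)

__all__ = [
    "DigitTaskConfig",
    "DotTaskConfig",
    "SaccadeEvent",
    "SaccadeEventLog",
    "TaskTrial",
    "digit_schedule",
    "run_digit_session",
    "dot_schedule",
    "run_dot_session",
    "run_rdk_training",
    "count_cycles",
    "sequence_responder",
]


@dataclass(frozen=True)
class DigitTaskConfig:
    n_levels: int = 10
    presentation_ms_first: float = 560.0
    presentation_ms_last: float = 190.0
    max_mistakes: int = 4
    max_trials: int = 200
    # No quantitative font sizes are specified; carried as metadata only.
    font_size_schedule: Tuple[float, ...] = tuple(range(10, 0, -1))

    def __post_init__(self) -> None:
        if self.presentation_ms_first <= self.presentation_ms_last:
            raise ValueError("presentation schedule must be strictly decreasing")
        if self.n_levels < 2 or self.max_mistakes < 1 or self.max_trials < 1:
            raise ValueError("invalid digit task configuration")


def digit_schedule(level: int, config: DigitTaskConfig = DigitTaskConfig()) -> float:
    """Presentation time (ms) at a level: linear between the endpoints."""
    if not 1 <= level <= config.n_levels:
        raise ValueError(f"level must be in [1, {config.n_levels}], got {level}")
    first, last = config.presentation_ms_first, config.presentation_ms_last
    return first - (level - 1) * (first - last) / (config.n_levels - 1)


class TaskTrial(NamedTuple):
    trial: int
    level: int
    correct: bool
    cumulative_mistakes: int
    stimulus: dict


@dataclass
class SessionLog:
    trials: List[TaskTrial] = field(default_factory=list)
    terminated_by: str = "max_trials"

    @property
    def levels_visited(self) -> List[int]:
        return [t.level for t in self.trials]

    @property
    def mistakes(self) -> int:
        return sum(not t.correct for t in self.trials)


def run_digit_session(
    responder: Callable[[int, np.random.Generator], bool],
    config: DigitTaskConfig = DigitTaskConfig(),
    rng: Optional[np.random.Generator] = None,
) -> SessionLog:
    """Level +1 on correct (cap), -1 on wrong (floor 1); stop at 4 mistakes."""
    rng = rng if rng is not None else np.random.default_rng()
    log = SessionLog()
    level, mistakes = 1, 0
    for trial in range(config.max_trials):
        correct = bool(responder(level, rng))
        if not correct:
            mistakes += 1
        log.trials.append(
            TaskTrial(
                trial=trial,
                level=level,
                correct=correct,
                cumulative_mistakes=mistakes,
                stimulus={"presentation_ms": digit_schedule(level, config)},
            )
        )
        if mistakes >= config.max_mistakes:
            log.terminated_by = "mistakes"
            return log
        level = min(level + 1, config.n_levels) if correct else max(level - 1, 1)
    return log


@dataclass(frozen=True)
class DotTaskConfig:
    level1_dot_min: int = 7
    level1_dot_max: int = 9
    level1_duration_s: float = 9.0
    advance_criterion: float = 0.80
    interval_decay: float = 0.75
    dots_increment_per_level: int = 2
    trials_per_level: int = 10
    max_levels: int = 10
    max_blocks: int = 30

    def __post_init__(self) -> None:
        if not 0.0 < self.advance_criterion <= 1.0:
            raise ValueError("advance_criterion must be in (0, 1]")
        if not 0.0 < self.interval_decay < 1.0:
            raise ValueError("interval_decay must be in (0, 1)")
        if self.trials_per_level < 5:
            raise ValueError("trials_per_level must be >= 5")
        if not 1 <= self.level1_dot_min <= self.level1_dot_max:
            raise ValueError("invalid level-1 dot range")


def dot_schedule(
    level: int,
    config: DotTaskConfig = DotTaskConfig(),
    n_dots_level1: Optional[int] = None,
) -> Tuple[int, float]:
    """(n_dots, inter-dot interval in s) at a level.

    The level-1 interval divides the 9 s window among the level-1 dots;
    each further level multiplies the interval by 0.75 and adds
    ``dots_increment_per_level`` dots. ``n_dots_level1`` defaults to the
    top of the level-1 range.
    """
    if level < 1:
        raise ValueError("level must be >= 1")
    base = n_dots_level1 if n_dots_level1 is not None else config.level1_dot_max
    if not config.level1_dot_min <= base <= config.level1_dot_max:
        raise ValueError("n_dots_level1 outside the configured level-1 range")
    interval1 = config.level1_duration_s / base
    interval = interval1 * config.interval_decay ** (level - 1)
    n_dots = base + (level - 1) * config.dots_increment_per_level
    return n_dots, interval


def run_dot_session(
    responder: Callable[[int, np.random.Generator], bool],
    config: DotTaskConfig = DotTaskConfig(),
    rng: Optional[np.random.Generator] = None,
) -> SessionLog:
    """Blocks of ``trials_per_level``; advance iff proportion correct >= 0.80.

    Each trial draws its own level-1 dot count from the 7-9 range;
    auditory feedback is recorded per trial (always on, as in the task).
    """
    rng = rng if rng is not None else np.random.default_rng()
    log = SessionLog()
    level = 1
    trial_index = 0
    for _ in range(config.max_blocks):
        n_correct = 0
        for _ in range(config.trials_per_level):
            base = int(
                rng.integers(config.level1_dot_min, config.level1_dot_max + 1)
            )
            n_dots, interval = dot_schedule(level, config, base)
            correct = bool(responder(level, rng))
            n_correct += correct
            log.trials.append(
                TaskTrial(
                    trial=trial_index,
                    level=level,
                    correct=correct,
                    cumulative_mistakes=log.mistakes + (not correct),
                    stimulus={
                        "n_dots": n_dots,
                        "inter_dot_interval_s": interval,
                        "auditory_feedback": True,
                    },
                )
            )
            trial_index += 1
        if n_correct / config.trials_per_level >= config.advance_criterion:
            if level >= config.max_levels:
                log.terminated_by = "max_level"
                return log
            level += 1
    log.terminated_by = "max_blocks"
    return log


def run_rdk_training(
    observer,
    config: StaircaseConfig = StaircaseConfig(),
    rng: Optional[np.random.Generator] = None,
    max_wrong: int = 4,
) -> SessionLog:
    """Staircase dynamics with feedback, stopping after 4 wrong choices.

    The feedback flag marks the trials on which the error noise would
    have sounded (i.e. wrong choices).
    """
    rng = rng if rng is not None else np.random.default_rng()
    respond = getattr(observer, "respond", observer)
    log = SessionLog()
    state = StaircaseState.fresh(config)
    wrong = 0
    for trial in range(config.max_trials):
        coherence = attenuation_to_coherence(state.attenuation_db)
        correct = bool(respond(coherence, rng))
        if not correct:
            wrong += 1
        log.trials.append(
            TaskTrial(
                trial=trial,
                level=0,
                correct=correct,
                cumulative_mistakes=wrong,
                stimulus={
                    "coherence_pct": coherence,
                    "attenuation_db": state.attenuation_db,
                    "feedback": not correct,
                },
            )
        )
        update(state, correct, config)
        if wrong >= max_wrong:
            log.terminated_by = "wrong_choices"
            return log
    return log


class SaccadeEvent(NamedTuple):
    timestamp_s: float
    direction: str  # {"left", "right"}


@dataclass(frozen=True)
class SaccadeEventLog:
    events: Tuple[SaccadeEvent, ...]
    duration_s: float

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("session duration must be positive")
        last = 0.0
        for ev in self.events:
            if ev.direction not in ("left", "right"):
                raise ValueError(f"bad direction {ev.direction!r}")
            if ev.timestamp_s < last or ev.timestamp_s > self.duration_s:
                raise ValueError("timestamps must be non-decreasing within duration")
            last = ev.timestamp_s

    @classmethod
    def from_directions(
        cls, directions: Iterable[str], duration_s: float
    ) -> "SaccadeEventLog":
        dirs = list(directions)
        n = len(dirs)
        times = [duration_s * (i + 1) / (n + 1) for i in range(n)]
        return cls(
            events=tuple(SaccadeEvent(t, d) for t, d in zip(times, dirs)),
            duration_s=duration_s,
        )


def count_cycles(log: SaccadeEventLog) -> float:
    """Cycles per minute: a left saccade closed by the next right saccade.

    Strict left-then-right consumption — an unmatched trailing left is
    not a cycle; a right saccade with no pending left is ignored.
    """
    cycles = 0
    pending_left = False
    for ev in log.events:
        if ev.direction == "left":
            pending_left = True
        elif pending_left:
            cycles += 1
            pending_left = False
    return cycles / (log.duration_s / 60.0)


def sequence_responder(pattern: Sequence[bool]) -> Callable:
    """Responder replaying a fixed correct/wrong sequence (then repeating)."""
    seq = list(pattern)
    state = {"i": 0}

    def respond(level, rng):
        value = seq[state["i"] % len(seq)]
        state["i"] += 1
        return bool(value)

    return respond
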