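"""Weighted up-down adaptive staircase in dB attenuation space.

The coherent-motion threshold test adjusts stimulus strength trial by
trial: a correct answer makes the task *harder* by attenuating coherence
1 dB further, a wrong answer makes it *easier* by backing off 3 dB. With
asymmetric steps ``d`` (down, after correct) and ``u`` (up, after wrong)
the track drifts towards the level where ``p * d = (1 - p) * u``, i.e.
``p = u / (u + d)`` — for the 1/3 dB pair this is the 75 %-correct point,
which is exactly how the threshold is defined.

Attenuation is expressed on an amplitude dB scale relative to 100 %
coherence: ``coherence = 100 * 10 ** (-A / 20)``. The convention only
fixes the geometry of the steps; the 75 % equilibrium is invariant to it.

The run terminates once the step direction has reversed a fixed number
of times (default 8); the threshold estimate is the mean coherence of
the reversal points after discarding the earliest ones.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, List, NamedTuple, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "StaircaseConfig",
    "StaircaseState",
    "StaircaseResult",
    "StaircaseTerminatedError",
    "TrialRecord",
    "attenuation_to_coherence",
    "coherence_to_attenuation",
    "update",
    "count_reversals",
    "run_staircase",
    "estimate_threshold",
    "equilibrium_p_correct",
]


class StaircaseTerminatedError(RuntimeError):
    """Raised on an attempt to update a staircase that has already stopped."""


def attenuation_to_coherence(attenuation_db: float) -> float:
    """Map dB attenuation to percent coherence: ``100 * 10**(-A/20)``.

    Strictly decreasing; 0 dB is 100 % coherence (no attenuation).
    """
    if attenuation_db < 0:
        raise ValueError(f"attenuation must be >= 0 dB, got {attenuation_db}")
    return 100.0 * 10.0 ** (-attenuation_db / 20.0)


def coherence_to_attenuation(coherence_pct: float) -> float:
    """Inverse of :func:`attenuation_to_coherence`."""
    if not 0.0 < coherence_pct <= 100.0:
        raise ValueError(f"coherence must lie in (0, 100], got {coherence_pct}")
    return -20.0 * math.log10(coherence_pct / 100.0)


@dataclass(frozen=True)
class StaircaseConfig:
    """Step sizes and stopping rules for the weighted up-down track.

    Defaults encode the test protocol: 1 dB harder after a correct
    response, 3 dB easier after a wrong one, stop at 8 reversals. The
    trial cap only guards against pathological simulated observers.
    """

    down_step_db: float = 1.0
    up_step_db: float = 3.0
    stop_reversals: int = 8
    start_attenuation_db: float = 0.0
    max_trials: int = 500
    min_attenuation_db: float = 0.0
    max_attenuation_db: float = 40.0

    def __post_init__(self) -> None:
        if self.down_step_db <= 0 or self.up_step_db <= 0:
            raise ValueError("step sizes must be positive")
        if self.stop_reversals < 1:
            raise ValueError("stop_reversals must be >= 1")
        if self.max_trials <= 0:
            raise ValueError("max_trials must be positive")
        if not (
            self.min_attenuation_db
            <= self.start_attenuation_db
            <= self.max_attenuation_db
        ):
            raise ValueError("start attenuation must lie within [min, max]")


class TrialRecord(NamedTuple):
    trial: int
    attenuation_db: float
    coherence_pct: float
    correct: bool
    reversal: bool


@dataclass
class StaircaseState:
    """Mutable trial-by-trial track state."""

    attenuation_db: float
    trial_log: List[TrialRecord] = field(default_factory=list)
    reversal_log: List[Tuple[int, float]] = field(default_factory=list)
    last_step_direction: str = "none"  # {"none", "down", "up"}
    terminated: bool = False

    @classmethod
    def fresh(cls, config: StaircaseConfig) -> "StaircaseState":
        return cls(attenuation_db=config.start_attenuation_db)


def update(
    state: StaircaseState, correct: bool, config: StaircaseConfig
) -> StaircaseState:
    """Apply one response to the track (in place; returns the state).

    A correct response steps *down* (harder: attenuation increases by
    ``down_step_db``), a wrong one steps *up* (easier). The new level is
    clamped to ``[min, max]``; a clamped step still counts as a step in
    the attempted direction for reversal bookkeeping. A reversal is
    logged — at the stimulus level of the reversing trial — whenever the
    applied direction differs from the previous one; the first response
    only sets the direction.
    """
    if state.terminated:
        raise StaircaseTerminatedError("staircase has already terminated")

    presented = state.attenuation_db
    direction = "down" if correct else "up"
    is_reversal = state.last_step_direction not in ("none", direction)

    index = len(state.trial_log)
    state.trial_log.append(
        TrialRecord(
            trial=index,
            attenuation_db=presented,
            coherence_pct=attenuation_to_coherence(presented),
            correct=correct,
            reversal=is_reversal,
        )
    )
    if is_reversal:
        state.reversal_log.append((index, presented))

    step = config.down_step_db if correct else -config.up_step_db
    state.attenuation_db = float(
        np.clip(
            presented + step, config.min_attenuation_db, config.max_attenuation_db
        )
    )
    state.last_step_direction = direction
    return state


def count_reversals(responses: Sequence[bool]) -> int:
    """Number of direction changes implied by a correct/wrong sequence."""
    return sum(1 for a, b in zip(responses, responses[1:]) if a != b)


@dataclass(frozen=True)
class StaircaseResult:
    threshold_coherence_pct: float
    reversals: Tuple[Tuple[int, float], ...]
    n_trials: int
    terminated_by: str  # {"reversals", "max_trials"}
    trial_log: Tuple[TrialRecord, ...]
    seed: Optional[int] = None

    def to_summary_json(self) -> str:
        return json.dumps(
            {
                "threshold_coherence_pct": self.threshold_coherence_pct,
                "n_trials": self.n_trials,
                "n_reversals": len(self.reversals),
                "terminated_by": self.terminated_by,
                "seed": self.seed,
            }
        )


def estimate_threshold(result: StaircaseResult, discard: int = 2) -> float:
    """Threshold from reversal levels after discarding the first ``discard``.

    The weighted track equilibrates at its 75 %-correct level, so
    averaging the late reversal levels estimates that point; the early
    reversals are dropped because they still carry the starting level.
    Reversals are averaged on the dB scale the steps are applied on
    (equivalently, the geometric mean of the reversal coherences) —
    averaging raw coherences instead would inflate the estimate, since
    coherence is convex in attenuation and the 1/3 dB sawtooth swings
    several dB around its equilibrium.
    """
    if discard < 0:
        raise ValueError("discard must be >= 0")
    if len(result.reversals) <= discard:
        raise ValueError(
            f"need more than {discard} reversals, have {len(result.reversals)}"
        )
    mean_attenuation = float(
        np.mean([att for _, att in result.reversals[discard:]])
    )
    return attenuation_to_coherence(mean_attenuation)


def run_staircase(
    observer,
    config: StaircaseConfig = StaircaseConfig(),
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    discard: int = 2,
) -> StaircaseResult:
    """Run one adaptive track against a responder.

    ``observer`` must expose ``respond(coherence_pct, rng) -> bool`` (a
    plain callable with that signature also works). The run stops at
    ``stop_reversals`` reversals, or at ``max_trials`` as a safety cap.
    Identical (observer, config, seed) triples give identical logs.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    respond: Callable[[float, np.random.Generator], bool] = getattr(
        observer, "respond", observer
    )

    state = StaircaseState.fresh(config)
    while (
        len(state.reversal_log) < config.stop_reversals
        and len(state.trial_log) < config.max_trials
    ):
        coherence = attenuation_to_coherence(state.attenuation_db)
        correct = bool(respond(coherence, rng))
        update(state, correct, config)
    state.terminated = True

    terminated_by = (
        "reversals"
        if len(state.reversal_log) >= config.stop_reversals
        else "max_trials"
    )
    result = StaircaseResult(
        threshold_coherence_pct=float("nan"),
        reversals=tuple(state.reversal_log),
        n_trials=len(state.trial_log),
        terminated_by=terminated_by,
        trial_log=tuple(state.trial_log),
        seed=seed,
    )
    threshold = _threshold_with_fallback(result, discard)
    return StaircaseResult(
        threshold_coherence_pct=threshold,
        reversals=result.reversals,
        n_trials=result.n_trials,
        terminated_by=result.terminated_by,
        trial_log=result.trial_log,
        seed=seed,
    )


def _threshold_with_fallback(result: StaircaseResult, discard: int) -> float:
    # A capped run may hold too few reversals for the discard rule; fall
    # back to all reversals, then to the mean presented coherence.
    if len(result.reversals) > discard:
        return estimate_threshold(result, discard)
    if result.reversals:
        return estimate_threshold(result, 0)
    return float(np.mean([t.coherence_pct for t in result.trial_log]))


def equilibrium_p_correct(config: StaircaseConfig = StaircaseConfig()) -> float:
    """Percent-correct targeted by the step asymmetry: ``u / (u + d)``."""
    return config.up_step_db / (config.up_step_db + config.down_step_db)


def trial_log_to_rows(result: StaircaseResult) -> List[dict]:
    """Trial log as plain dict rows (CSV-ready)."""
    return [
        {
            "trial": t.trial,
            "attenuation_db": t.attenuation_db,
            "coherence_pct": t.coherence_pct,
            "correct": int(t.correct),
            "reversal_flag": int(t.reversal),
        }
        for t in result.trial_log
    ]
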