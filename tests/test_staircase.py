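"""Unit and property tests for the weighted up-down staircase."""

import math

import numpy as np
import pytest

from magnotrain.observers import PsychometricObserver
from magnotrain.staircase import (
    StaircaseConfig,
    StaircaseState,
    StaircaseTerminatedError,
    attenuation_to_coherence,
    coherence_to_attenuation,
    count_reversals,
    estimate_threshold,
    run_staircase,
    update,
)


@pytest.mark.parametrize(
    "attenuation, coherence",
    [(0.0, 100.0), (20.0, 10.0), (6.0206, 50.0)],
)
def test_attenuation_to_coherence_closed_form(attenuation, coherence):
    assert attenuation_to_coherence(attenuation) == pytest.approx(
        coherence, abs=0.01
    )


def test_attenuation_coherence_round_trip_and_monotonicity():
    grid = np.linspace(0, 40, 41)
    cohs = [attenuation_to_coherence(a) for a in grid]
    assert all(a > b for a, b in zip(cohs, cohs[1:]))
    for a in grid:
        assert coherence_to_attenuation(attenuation_to_coherence(a)) == pytest.approx(a)
    with pytest.raises(ValueError):
        attenuation_to_coherence(-1.0)
    with pytest.raises(ValueError):
        coherence_to_attenuation(0.0)


class TestUpdate:
    config = StaircaseConfig()

    def _state(self, attenuation):
        return StaircaseState(attenuation_db=attenuation)

    def test_correct_steps_down_one_db(self):
        state = update(self._state(10.0), True, self.config)
        assert state.attenuation_db == pytest.approx(11.0)  # harder: less coherence

    def test_wrong_steps_up_three_db(self):
        state = update(self._state(10.0), False, self.config)
        assert state.attenuation_db == pytest.approx(7.0)

    def test_wrong_at_ceiling_clamps(self):
        state = update(self._state(0.0), False, self.config)
        assert state.attenuation_db == 0.0

    def test_clamped_step_counts_for_reversal_direction(self):
        state = self._state(0.0)
        update(state, False, self.config)  # clamped, but direction = up
        update(state, True, self.config)  # down after up -> reversal
        assert len(state.reversal_log) == 1

    def test_update_after_termination_raises(self):
        state = self._state(5.0)
        state.terminated = True
        with pytest.raises(StaircaseTerminatedError):
            update(state, True, self.config)


class TestReversals:
    @pytest.mark.parametrize(
        "responses, expected",
        [([True, False], 1), ([True, True, True], 0), ([], 0), ([True], 0)],
    )
    def test_simple_sequences(self, responses, expected):
        assert count_reversals(responses) == expected

    @pytest.mark.parametrize("n", [2, 5, 10])
    def test_alternating_sequence(self, n):
        responses = [i % 2 == 0 for i in range(n)]
        assert count_reversals(responses) == n - 1

    def test_matches_enumeration_oracle_and_state_log(self, rng):
        config = StaircaseConfig(max_attenuation_db=1e9)  # no clamping
        for _ in range(20):
            responses = list(rng.random(30) < 0.5)
            # independent oracle: explicit enumeration of direction changes
            dirs = ["down" if r else "up" for r in responses]
            expected = sum(d1 != d2 for d1, d2 in zip(dirs, dirs[1:]))
            assert count_reversals(responses) == expected
            state = StaircaseState(attenuation_db=500.0)
            for r in responses:
                update(state, r, config)
            assert len(state.reversal_log) == expected

    def test_reversal_logged_at_presented_level(self):
        config = StaircaseConfig()
        state = StaircaseState.fresh(config)
        for r in [True, True, True, False]:
            update(state, r, config)
        # track 0 -> 1 -> 2 -> 3; the wrong answer at 3 dB is the reversal
        assert state.reversal_log == [(3, 3.0)]


class TestRunStaircase:
    def test_stops_at_exactly_eight_reversals(self):
        observer = PsychometricObserver(alpha75=40.0)
        for seed in range(20):
            result = run_staircase(observer, seed=seed)
            assert result.terminated_by == "reversals"
            assert len(result.reversals) == 8

    def test_deterministic_threshold_observer_oscillates(self):
        # correct iff coherence > 50 %: the track must ping-pong around
        # the 50 % level and stop on reversals
        respond = lambda coherence, rng: coherence > 50.0  # noqa: E731
        result = run_staircase(respond, seed=0)
        assert result.terminated_by == "reversals"
        revs = [attenuation_to_coherence(a) for _, a in result.reversals]
        assert min(revs) < 50.0 < max(revs) or max(revs) > 45.0

    def test_same_seed_identical_trial_log(self):
        observer = PsychometricObserver(alpha75=30.0)
        a = run_staircase(observer, seed=99)
        b = run_staircase(observer, seed=99)
        assert a.trial_log == b.trial_log
        assert a.threshold_coherence_pct == b.threshold_coherence_pct

    def test_max_trials_safety_cap(self):
        # an always-correct responder never reverses
        result = run_staircase(
            lambda c, rng: True, StaircaseConfig(max_trials=50), seed=0
        )
        assert result.terminated_by == "max_trials"
        assert result.n_trials == 50
        assert len(result.reversals) == 0


class TestEstimateThreshold:
    def _result_with_reversals(self, coherences):
        from magnotrain.staircase import StaircaseResult

        reversals = tuple(
            (i, coherence_to_attenuation(c)) for i, c in enumerate(coherences)
        )
        return StaircaseResult(
            threshold_coherence_pct=float("nan"),
            reversals=reversals,
            n_trials=len(coherences),
            terminated_by="reversals",
            trial_log=(),
        )

    def test_constant_reversals(self):
        result = self._result_with_reversals([40.0] * 8)
        assert estimate_threshold(result) == pytest.approx(40.0)

    def test_alternating_reversals_geometric_mean(self):
        result = self._result_with_reversals([30.0, 50.0] * 4)
        assert estimate_threshold(result, discard=2) == pytest.approx(math.sqrt(30.0 * 50.0))

    def test_too_few_reversals_raises(self):
        result = self._result_with_reversals([40.0, 41.0])
        with pytest.raises(ValueError):
            estimate_threshold(result, discard=2)


def test_equilibrium_percent_correct_is_75():
    """Long-run proportion correct of the 1-down/3-up track is 75 %.

    Zero net drift forces #correct * 1 dB = #wrong * 3 dB, i.e. an
    empirical percent-correct of u/(u+d) = 0.75 in steady state.
    """
    observer = PsychometricObserver(alpha75=30.0)
    config = StaircaseConfig(stop_reversals=10**9, max_trials=300)
    correct = []
    for seed in range(50):
        result = run_staircase(observer, config, seed=seed)
        correct.extend(t.correct for t in result.trial_log[120:])
    assert np.mean(correct) == pytest.approx(0.75, abs=0.02)


def test_threshold_monotone_in_observer_sensitivity():
    """A more sensitive observer never yields a higher mean threshold."""
    means = []
    for alpha in (20.0, 35.0, 50.0):
        observer = PsychometricObserver(alpha75=alpha, slope=4.0)
        estimates = [
            run_staircase(observer, seed=s).threshold_coherence_pct
            for s in range(60)
        ]
        means.append(np.mean(estimates))
    assert means[0] < means[1] < means[2]
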