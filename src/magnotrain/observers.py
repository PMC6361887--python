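"""Simulated participants for the two-panel coherent-motion task.

Two kinds of observer are provided. :class:`PsychometricObserver` has a
closed-form Weibull psychometric function under 2AFC, parameterised
directly by its 75 %-correct coherence so that staircase estimates can
be checked against a known truth. :class:`MechanisticObserver` carries
no psychometric function at all: it inspects generated dot-motion
geometry through angular noise and compares a resultant-vector statistic
between panels, so its psychometric curve *emerges* from the stimulus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "PsychometricObserver",
    "MechanisticObserver",
    "MechanisticRDKResponder",
    "CalibrationError",
    "calibrate_alpha75",
    "observer_from_spec",
]


class CalibrationError(RuntimeError):
    """Raised when the 75 %-point search cannot bracket its target."""


@dataclass(frozen=True)
class PsychometricObserver:
    """2AFC Weibull observer anchored at its 75 %-correct point.

    p(c) = 0.5 + (0.5 - lapse) * (1 - exp(-(c / scale)**slope))

    with the scale solved analytically so that ``p(alpha75) = 0.75``
    exactly. ``guess`` is fixed at 0.5 (two panels, forced choice).

    Parameters
    ----------
    alpha75 : coherence (%) at which the observer is 75 % correct.
    slope : Weibull steepness (dimensionless), default 2.0.
    lapse : stimulus-independent error probability in [0, 0.06].
    """

    alpha75: float
    slope: float = 2.0
    lapse: float = 0.02
    guess: float = field(default=0.5, init=False)

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha75 <= 100.0:
            raise ValueError(f"alpha75 must be in (0, 100], got {self.alpha75}")
        if self.slope <= 0:
            raise ValueError("slope must be positive")
        if not 0.0 <= self.lapse <= 0.06:
            raise ValueError("lapse must lie in [0, 0.06]")

    @property
    def scale(self) -> float:
        # Solve 0.75 = 0.5 + (0.5 - lapse) * (1 - exp(-(alpha75/scale)**slope))
        inner = 1.0 - 0.25 / (0.5 - self.lapse)
        return self.alpha75 / (-math.log(inner)) ** (1.0 / self.slope)

    def p_correct(self, coherence_pct: float) -> float:
        if not 0.0 <= coherence_pct <= 100.0:
            raise ValueError(f"coherence must be in [0, 100], got {coherence_pct}")
        if coherence_pct == 0.0:
            return self.guess
        return self.guess + (self.guess - self.lapse) * (
            1.0 - math.exp(-((coherence_pct / self.scale) ** self.slope))
        )

    def respond(self, coherence_pct: float, rng: np.random.Generator) -> bool:
        """One Bernoulli trial at the given coherence."""
        return bool(rng.random() < self.p_correct(coherence_pct))


@dataclass(frozen=True)
class MechanisticObserver:
    """Observer that reads the dot geometry itself.

    Each perceived dot displacement is corrupted by angular noise
    ~ Normal(0, ``direction_noise_sd`` radians); the panel with the
    larger mean resultant length of the perceived unit displacement
    vectors is chosen.
    """

    direction_noise_sd: float
    integration: str = "resultant-vector"

    def __post_init__(self) -> None:
        if self.direction_noise_sd < 0:
            raise ValueError("direction_noise_sd must be >= 0")
        if self.integration != "resultant-vector":
            raise ValueError(f"unknown integration statistic: {self.integration}")


class MechanisticRDKResponder:
    """Adapter making a MechanisticObserver usable by the staircase.

    ``respond(coherence, rng)`` generates a fresh two-panel trial at the
    requested coherence and scores whether the chosen panel is the
    signal panel.
    """

    def __init__(self, observer: MechanisticObserver, rdk_params) -> None:
        self.observer = observer
        self.rdk_params = rdk_params

    def respond(self, coherence_pct: float, rng: np.random.Generator) -> bool:
        from . import rdk  # local import avoids a cycle at module load

        params = self.rdk_params.with_coherence(coherence_pct)
        trial = rdk.generate_trial(params, rng)
        chosen = rdk.decide_panel(trial, self.observer, rng)
        return chosen == params.signal_panel


def _empirical_p(responder, coherence: float, n: int, rng) -> float:
    return float(np.mean([responder.respond(coherence, rng) for _ in range(n)]))


def calibrate_alpha75(
    observer: MechanisticObserver,
    rdk_params,
    rng: np.random.Generator,
    target: float = 0.75,
    n_trials_per_probe: int = 2000,
    n_iter: int = 12,
    lo: float = 0.5,
    hi: float = 100.0,
) -> float:
    """Monte-Carlo bisection for the mechanistic observer's 75 %-point.

    Probes empirical percent-correct on freshly generated trials at each
    candidate coherence and bisects on the (noisy but monotone) curve.
    Raises :class:`CalibrationError` if the bracket does not straddle
    the target.
    """
    responder = MechanisticRDKResponder(observer, rdk_params)
    p_lo = _empirical_p(responder, lo, n_trials_per_probe, rng)
    p_hi = _empirical_p(responder, hi, n_trials_per_probe, rng)
    if p_lo >= target:
        # Near-noiseless observer: already above target at the smallest
        # probed coherence.
        return lo
    if p_hi < target:
        raise CalibrationError(
            f"target {target} not bracketed: p({lo})={p_lo:.3f}, p({hi})={p_hi:.3f}"
        )
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        p_mid = _empirical_p(responder, mid, n_trials_per_probe, rng)
        if p_mid < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def observer_from_spec(spec: dict):
    """Build an observer from a serialisable config mapping.

    ``{kind: psychometric, alpha75, slope, lapse}`` or
    ``{kind: mechanistic, direction_noise_sd}``.
    """
    kind = spec.get("kind")
    if kind == "psychometric":
        return PsychometricObserver(
            alpha75=float(spec["alpha75"]),
            slope=float(spec.get("slope", 2.0)),
            lapse=float(spec.get("lapse", 0.02)),
        )
    if kind == "mechanistic":
        return MechanisticObserver(
            direction_noise_sd=float(spec["direction_noise_sd"])
        )
    raise ValueError(f"unknown observer kind: {kind!r}")
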