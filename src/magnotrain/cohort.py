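"""Synthetic two-group longitudinal cohort generator.

Emulates the study design: 13 experimental and 11 control boys aged
9-11, assessed four times (pre, after the 6th session, after the 12th
session, one-month follow-up) on seven measures — coherent-motion
threshold (% coherence), saccade cycles/min, reading accuracy,
comprehension, and visual / phonological / pragmatic error counts.

The generative model per child and measure is

    value(child, session) = traj[group][session] + b_child + e_session

with ``b_child ~ N(0, between_sd)`` drawn once per child and
``e_session ~ N(0, within_sd)`` drawn per session; error counts replace
the Gaussian value by a Poisson draw whose rate is the (floored) latent
value. Coherent-motion thresholds can instead be produced
*mechanistically*: the latent value becomes the child-session 75 %-point
of a simulated observer and the recorded threshold is the estimate from
an actual staircase run against that observer.

The default scenario encodes the published within-group mean changes as
trajectory deltas over plausible baselines; it is a scenario, not data.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .observers import PsychometricObserver
from .staircase import StaircaseConfig, run_staircase

__all__ = [
    "SESSIONS",
    "MEASURES",
    "COUNT_MEASURES",
    "CohortConfig",
    "default_config",
    "null_config",
    "generate_cohort",
    "screen_inclusion",
    "summarize_by_group_session",
]

SESSIONS: Tuple[str, ...] = ("pre", "mid", "post", "followup")
GROUPS: Tuple[str, ...] = ("experimental", "control")
MEASURES: Tuple[str, ...] = (
    "rdk_threshold",
    "saccade_cycles_per_min",
    "reading_accuracy",
    "comprehension",
    "visual_errors",
    "phonological_errors",
    "pragmatic_errors",
)
COUNT_MEASURES = frozenset(
    {"visual_errors", "phonological_errors", "pragmatic_errors"}
)

Trajectories = Dict[str, Dict[str, Tuple[float, float, float, float]]]


@dataclass(frozen=True)
class CohortConfig:
    n_experimental: int = 13
    n_control: int = 11
    sessions: Tuple[str, ...] = SESSIONS
    trajectories: Trajectories = field(default_factory=dict)
    between_sd: Dict[str, float] = field(default_factory=dict)
    within_sd: Dict[str, float] = field(default_factory=dict)
    rdk_mode: str = "parametric"  # {"parametric", "mechanistic"}
    enforce_inclusion: bool = True
    apra_cutoff: float = 71.0
    rdk_cutoff: float = 34.0
    age_mean: float = 9.76
    age_sd: float = 0.59
    age_range: Tuple[float, float] = (9.0, 11.0)
    observer_slope: float = 2.0
    observer_lapse: float = 0.02
    staircase: StaircaseConfig = field(default_factory=StaircaseConfig)

    def __post_init__(self) -> None:
        if self.n_experimental < 2 or self.n_control < 2:
            raise ValueError("each group needs at least 2 children")
        if self.rdk_mode not in ("parametric", "mechanistic"):
            raise ValueError(f"unknown rdk_mode {self.rdk_mode!r}")
        k = len(self.sessions)
        for measure in MEASURES:
            if measure not in self.trajectories:
                raise ValueError(f"missing trajectory for measure {measure!r}")
            for group in GROUPS:
                traj = self.trajectories[measure].get(group)
                if traj is None or len(traj) != k:
                    raise ValueError(
                        f"trajectory for {measure!r}/{group!r} must have "
                        f"{k} entries"
                    )
            for name, table in (
                ("between_sd", self.between_sd),
                ("within_sd", self.within_sd),
            ):
                if measure not in table:
                    raise ValueError(f"missing {name} for measure {measure!r}")
                if table[measure] < 0:
                    raise ValueError(f"{name}[{measure!r}] must be >= 0")


def _flat(value: float) -> Dict[str, Tuple[float, float, float, float]]:
    return {g: (value,) * 4 for g in GROUPS}


# Baselines are plausible scale anchors; the experimental deltas are the
# published within-group mean changes (pre -> mid/post/follow-up).
_DEFAULT_TRAJECTORIES: Trajectories = {
    "rdk_threshold": {
        "experimental": (45.0, 30.846, 26.615, 27.923),
        "control": (45.0, 45.0, 45.0, 45.0),
    },
    "saccade_cycles_per_min": {
        "experimental": (60.0, 102.077, 118.231, 120.769),
        "control": (60.0, 60.0, 60.0, 60.0),
    },
    "reading_accuracy": {
        "experimental": (55.0, 68.58, 75.07, 76.822),
        "control": (55.0, 56.0, 57.0, 57.5),
    },
    "comprehension": {
        "experimental": (40.0, 45.774, 54.541, 57.252),
        "control": (40.0, 45.774, 54.541, 57.252),
    },
    "visual_errors": {
        "experimental": (12.0, 10.5, 8.5, 8.0),
        "control": (12.0, 12.0, 12.0, 12.0),
    },
    "phonological_errors": {
        "experimental": (8.0, 9.0, 10.5, 10.5),
        "control": (8.0, 7.5, 7.0, 7.0),
    },
    "pragmatic_errors": _flat(4.0),
}

# Back-derived from the published test statistics (see docs/methods.md).
_DEFAULT_BETWEEN_SD = {
    "rdk_threshold": 8.0,
    "saccade_cycles_per_min": 12.0,
    "reading_accuracy": 12.0,
    "comprehension": 8.0,
    "visual_errors": 3.0,
    "phonological_errors": 2.5,
    "pragmatic_errors": 1.5,
}
_DEFAULT_WITHIN_SD = {
    "rdk_threshold": 10.0,
    "saccade_cycles_per_min": 12.0,
    "reading_accuracy": 6.0,
    "comprehension": 6.5,
    "visual_errors": 1.0,
    "phonological_errors": 1.0,
    "pragmatic_errors": 0.5,
}


def default_config(**overrides) -> CohortConfig:
    """The study-shaped scenario: published deltas over plausible baselines."""
    base = dict(
        trajectories=copy.deepcopy(_DEFAULT_TRAJECTORIES),
        between_sd=dict(_DEFAULT_BETWEEN_SD),
        within_sd=dict(_DEFAULT_WITHIN_SD),
    )
    base.update(overrides)
    return CohortConfig(**base)


def null_config(**overrides) -> CohortConfig:
    """Flat trajectories (group baselines only): no effect of anything.

    Inclusion enforcement is off so the null stays exactly Gaussian.
    """
    traj = {
        m: _flat(_DEFAULT_TRAJECTORIES[m]["experimental"][0]) for m in MEASURES
    }
    base = dict(
        trajectories=traj,
        between_sd=dict(_DEFAULT_BETWEEN_SD),
        within_sd=dict(_DEFAULT_WITHIN_SD),
        enforce_inclusion=False,
    )
    base.update(overrides)
    return CohortConfig(**base)


def _draw_age(config: CohortConfig, rng: np.random.Generator) -> float:
    lo, hi = config.age_range
    for _ in range(100):
        age = rng.normal(config.age_mean, config.age_sd)
        if lo <= age <= hi:
            return float(age)
    return float(np.clip(rng.normal(config.age_mean, config.age_sd), lo, hi))


def _measure_rdk_mechanistic(
    latent_alpha75: float, config: CohortConfig, rng: np.random.Generator
) -> float:
    observer = PsychometricObserver(
        alpha75=float(np.clip(latent_alpha75, 1.0, 95.0)),
        slope=config.observer_slope,
        lapse=config.observer_lapse,
    )
    result = run_staircase(observer, config.staircase, rng=rng)
    return result.threshold_coherence_pct


def generate_cohort(
    config: CohortConfig,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Generate the long-format cohort table.

    Returns a DataFrame with columns ``participant_id, group, age,
    session, measure, value`` and exactly
    ``n_participants * n_sessions * n_measures`` rows. Fully
    reproducible from the seed.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    rows = []
    pid = 0
    for group, n in (("experimental", config.n_experimental),
                     ("control", config.n_control)):
        for _ in range(n):
            pid += 1
            rows.extend(_draw_child(f"P{pid:03d}", group, config, rng))
    return pd.DataFrame(rows)


def _draw_child(
    participant: str,
    group: str,
    config: CohortConfig,
    rng: np.random.Generator,
    max_tries: int = 200,
) -> list:
    """Draw one child's full session x measure block.

    With ``enforce_inclusion`` the whole block is redrawn until the
    *observed* baseline meets the enrolment screen (reading score below
    the APRA cut-off, motion threshold above the RDK cut-off) — the
    in-silico analogue of only enrolling eligible children. Acceptance
    depends on the pre-session draws alone, so later sessions keep
    their marginal distributions.
    """
    age = _draw_age(config, rng)
    for _ in range(max_tries):
        offsets = {m: rng.normal(0.0, config.between_sd[m]) for m in MEASURES}
        rows = []
        baseline = {}
        for s_idx, session in enumerate(config.sessions):
            for measure in MEASURES:
                latent = (
                    config.trajectories[measure][group][s_idx]
                    + offsets[measure]
                    + rng.normal(0.0, config.within_sd[measure])
                )
                value = _realise(measure, latent, config, rng)
                if s_idx == 0:
                    baseline[measure] = value
                rows.append(
                    {
                        "participant_id": participant,
                        "group": group,
                        "age": age,
                        "session": session,
                        "measure": measure,
                        "value": value,
                    }
                )
        if not config.enforce_inclusion:
            return rows
        if (
            baseline["reading_accuracy"] < config.apra_cutoff
            and baseline["rdk_threshold"] > config.rdk_cutoff
        ):
            return rows
    raise RuntimeError(
        "could not draw an inclusion-eligible child; check trajectories "
        "against the cut-offs"
    )


def _realise(
    measure: str, latent: float, config: CohortConfig, rng: np.random.Generator
) -> float:
    if measure in COUNT_MEASURES:
        rate = max(latent, 0.05)
        return float(rng.poisson(rate))
    if measure == "rdk_threshold":
        if config.rdk_mode == "mechanistic":
            return _measure_rdk_mechanistic(latent, config, rng)
        return float(np.clip(latent, 1.0, 100.0))
    if measure == "saccade_cycles_per_min":
        return float(max(latent, 0.0))
    return float(latent)


def screen_inclusion(
    table: pd.DataFrame,
    apra_cutoff: float = 71.0,
    rdk_cutoff: float = 34.0,
    baseline_session: str = "pre",
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Apply the study's screen: baseline reading score strictly below the
    APRA cut-off AND baseline motion threshold strictly above the
    threshold cut-off. Returns (eligible rows, {kept, dropped}).
    """
    base = table[table["session"] == baseline_session]
    wide = base.pivot_table(
        index="participant_id", columns="measure", values="value", aggfunc="first"
    )
    needed = {"reading_accuracy", "rdk_threshold"}
    if base.empty or not needed.issubset(wide.columns) or wide[list(needed)].isna().any().any():
        raise ValueError(
            "baseline session must provide reading_accuracy and rdk_threshold "
            "for every participant"
        )
    eligible_ids = wide.index[
        (wide["reading_accuracy"] < apra_cutoff)
        & (wide["rdk_threshold"] > rdk_cutoff)
    ]
    kept = table[table["participant_id"].isin(eligible_ids)]
    n_all = table["participant_id"].nunique()
    report = {"kept": int(len(eligible_ids)), "dropped": int(n_all - len(eligible_ids))}
    return kept.reset_index(drop=True), report


def summarize_by_group_session(table: pd.DataFrame) -> pd.DataFrame:
    """Mean and SEM (sd/sqrt(n), ddof=1) per group x session x measure.

    Mirrors the shape of the study's figures; SEM is NaN for n = 1.
    """
    def _sem(x: pd.Series) -> float:
        if len(x) < 2:
            return float("nan")
        return float(x.std(ddof=1) / np.sqrt(len(x)))

    out = (
        table.groupby(["group", "session", "measure"], sort=False)["value"]
        .agg(mean="mean", sem=_sem, n="count")
        .reset_index()
    )
    return out
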