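"""Two-panel random-dot-kinematogram trial generation.

Two panels of moving dots are shown side by side; one panel carries a
proportion of dots (the coherence) drifting in a common left/right
direction among uniformly random noise dots, the other panel is pure
noise, and the task is to say which panel contains the coherent cloud.

Coordinate convention: origin top-left, x rightward, y downward, panel
units normalised so positions live in [0, width) x [0, height) with
toroidal wrap-around. Signal-dot identities are re-drawn every frame
("different rule"), which prevents single-dot tracking. The decision
statistic for mechanistic observers is the mean resultant length of all
dot displacement unit vectors pooled over frames: 1 for perfect
coherence, approaching 0 like n**-0.5 for pure noise.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np

from .observers import MechanisticObserver

__all__ = [
    "RDKParams",
    "RDKTrialData",
    "generate_trial",
    "panel_coherence_statistic",
    "decide_panel",
    "n_signal_dots",
    "trial_to_rows",
]

PANELS = ("left", "right")
DIRECTIONS = ("left", "right")


@dataclass(frozen=True)
class RDKParams:
    n_dots_per_panel: int = 100
    n_frames: int = 20
    dot_step: float = 0.03
    coherence: float = 50.0
    signal_direction: str = "right"
    signal_panel: str = "left"
    panel_width: float = 1.0
    panel_height: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.coherence <= 100.0:
            raise ValueError(f"coherence must be in [0, 100], got {self.coherence}")
        if self.n_dots_per_panel < 1:
            raise ValueError("need at least one dot per panel")
        if self.n_frames < 2:
            raise ValueError("need at least two frames")
        if self.signal_direction not in DIRECTIONS:
            raise ValueError(f"signal_direction must be one of {DIRECTIONS}")
        if self.signal_panel not in PANELS:
            raise ValueError(f"signal_panel must be one of {PANELS}")
        if self.dot_step <= 0 or self.panel_width <= 0 or self.panel_height <= 0:
            raise ValueError("dot_step and panel dimensions must be positive")

    def with_coherence(self, coherence: float) -> "RDKParams":
        return dataclasses.replace(self, coherence=coherence)


def n_signal_dots(coherence: float, n_dots: int) -> int:
    """Half-up rounding of coherence/100 * n_dots."""
    return int(math.floor(coherence / 100.0 * n_dots + 0.5))


@dataclass(frozen=True)
class RDKTrialData:
    """Per-panel dot positions, displacements and signal masks.

    Arrays are shaped (n_frames, n_dots, 2) for positions/displacements
    and (n_frames, n_dots) for the boolean signal masks; frame ``f``'s
    displacement carries its dots to frame ``f + 1`` (the final frame's
    displacement is the motion shown on that frame).
    """

    params: RDKParams
    positions: Dict[str, np.ndarray]
    displacements: Dict[str, np.ndarray]
    signal_mask: Dict[str, np.ndarray]


def generate_trial(params: RDKParams, rng: np.random.Generator) -> RDKTrialData:
    """Generate one two-panel trial.

    The signal panel contains exactly ``n_signal_dots`` coherently
    moving dots per frame (identities re-drawn each frame); every other
    dot, and every dot of the noise panel, takes an independent uniform
    heading. Positions wrap toroidally.
    """
    n = params.n_dots_per_panel
    n_sig = n_signal_dots(params.coherence, n)
    signal_heading = 0.0 if params.signal_direction == "right" else math.pi
    extent = np.array([params.panel_width, params.panel_height])

    positions: Dict[str, np.ndarray] = {}
    displacements: Dict[str, np.ndarray] = {}
    signal_mask: Dict[str, np.ndarray] = {}
    nf = params.n_frames
    for panel in PANELS:
        start = rng.uniform(0.0, 1.0, size=(n, 2)) * extent
        headings = rng.uniform(0.0, 2.0 * math.pi, size=(nf, n))
        mask = np.zeros((nf, n), dtype=bool)
        if panel == params.signal_panel and n_sig > 0:
            # fresh signal-dot identities every frame: smallest n_sig of
            # i.i.d. uniforms per row is a uniform subset without replacement
            order = rng.random((nf, n)).argpartition(n_sig - 1, axis=1)
            np.put_along_axis(mask, order[:, :n_sig], True, axis=1)
            headings[mask] = signal_heading
        disp = params.dot_step * np.stack(
            (np.cos(headings), np.sin(headings)), axis=-1
        )
        travel = np.concatenate(
            (np.zeros((1, n, 2)), np.cumsum(disp[:-1], axis=0))
        )
        positions[panel] = np.mod(start[None] + travel, extent)
        displacements[panel] = disp
        signal_mask[panel] = mask
    return RDKTrialData(
        params=params,
        positions=positions,
        displacements=displacements,
        signal_mask=signal_mask,
    )


def panel_coherence_statistic(trial: RDKTrialData, panel: str) -> float:
    """Mean resultant length of displacement unit vectors, pooled over frames."""
    disp = trial.displacements[panel].reshape(-1, 2)
    return _resultant_length(disp)


def _resultant_length(disp: np.ndarray) -> float:
    norms = np.linalg.norm(disp, axis=1)
    units = disp / norms[:, None]
    return float(np.linalg.norm(units.mean(axis=0)))


def decide_panel(
    trial: RDKTrialData,
    observer: MechanisticObserver,
    rng: np.random.Generator,
) -> str:
    """Pick the panel the mechanistic observer perceives as more coherent.

    Each dot heading is perturbed by angular noise before the resultant
    statistic; an exact tie is broken by a fair coin.
    """
    stats = {}
    for panel in PANELS:
        disp = trial.displacements[panel].reshape(-1, 2)
        theta = np.arctan2(disp[:, 1], disp[:, 0])
        if observer.direction_noise_sd > 0:
            theta = theta + rng.normal(0.0, observer.direction_noise_sd, theta.shape)
        units = np.column_stack((np.cos(theta), np.sin(theta)))
        stats[panel] = float(np.linalg.norm(units.mean(axis=0)))
    if stats["left"] > stats["right"]:
        return "left"
    if stats["right"] > stats["left"]:
        return "right"
    return "left" if rng.random() < 0.5 else "right"


def trial_to_rows(trial: RDKTrialData) -> List[dict]:
    """Flatten a trial to CSV-ready rows (frame, panel, dot, x, y, dx, dy, is_signal)."""
    rows = []
    for panel in PANELS:
        pos = trial.positions[panel]
        disp = trial.displacements[panel]
        mask = trial.signal_mask[panel]
        n_frames, n, _ = pos.shape
        for f in range(n_frames):
            for d in range(n):
                rows.append(
                    {
                        "frame": f,
                        "panel": panel,
                        "dot_id": d,
                        "x": pos[f, d, 0],
                        "y": pos[f, d, 1],
                        "dx": disp[f, d, 0],
                        "dy": disp[f, d, 1],
                        "is_signal": int(mask[f, d]),
                    }
                )
    return rows
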