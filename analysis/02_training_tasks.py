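"""Exercise the four training-task engines.

Prints the digit-counting presentation schedule, the dot-counting
level schedule, a feedback-staircase session and saccade-cycle scoring
for simulated responders; writes the schedules and one session log of
each kind under results/.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from magnotrain.observers import PsychometricObserver
from magnotrain.tasks import (
    DigitTaskConfig,
    DotTaskConfig,
    SaccadeEventLog,
    count_cycles,
    digit_schedule,
    dot_schedule,
    run_digit_session,
    run_dot_session,
    run_rdk_training,
)

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0


def main() -> None:
    OUT.mkdir(exist_ok=True)
    rng = np.random.default_rng(SEED)

    digit = pd.DataFrame(
        {"level": range(1, 11),
         "presentation_ms": [digit_schedule(lvl) for lvl in range(1, 11)]}
    )
    dots = pd.DataFrame(
        [(lvl, *dot_schedule(lvl)) for lvl in range(1, 8)],
        columns=["level", "n_dots", "inter_dot_interval_s"],
    )
    digit.to_csv(OUT / "digit_schedule.csv", index=False)
    dots.to_csv(OUT / "dot_schedule.csv", index=False)
    print("digit schedule: 560 ms at level 1 ->",
          f"{digit_schedule(10):.0f} ms at level 10 (linear)")
    print("dot task: interval ratio between levels =",
          f"{dots.inter_dot_interval_s[1] / dots.inter_dot_interval_s[0]:.2f}")

    # sessions for a mid-ability responder (p correct = 0.75 per trial)
    responder = lambda level, r: bool(r.random() < 0.75)  # noqa: E731
    digit_log = run_digit_session(responder, DigitTaskConfig(), rng)
    dot_log = run_dot_session(responder, DotTaskConfig(max_blocks=8), rng)
    rdk_log = run_rdk_training(PsychometricObserver(alpha75=40.0), rng=rng)
    for name, log in (("digit", digit_log), ("dot", dot_log), ("rdk_training", rdk_log)):
        pd.DataFrame(
            [{"trial": t.trial, "level": t.level, "correct": t.correct,
              "cumulative_mistakes": t.cumulative_mistakes} for t in log.trials]
        ).to_csv(OUT / f"session_{name}.csv", index=False)
        print(f"{name} session: {len(log.trials)} trials, "
              f"max level {max(t.level for t in log.trials)}, "
              f"terminated by {log.terminated_by}")

    log = SaccadeEventLog.from_directions(
        ["left", "right"] * 40 + ["left"], duration_s=60.0
    )
    print(f"saccade scoring: 81 alternating saccades in 60 s -> "
          f"{count_cycles(log):.0f} cycles/min")


if __name__ == "__main__":
    main()
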