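"""Run the mixed repeated-measures analysis on the generated cohort.

Reads results/cohort.csv (run 03_generate_cohort.py first), applies the
enrolment screen, and for every outcome measure fits the 2-group x
4-session split-plot ANOVA with Mauchly's test and Greenhouse-Geisser
correction, pairwise within-group paired t-tests and per-session
between-group t-tests. Writes results/anova_report.json and prints the
effect lines in the conventional F[df1, df2] style.
"""

import sys
from pathlib import Path

from magnotrain import io as mio
from magnotrain.cohort import MEASURES, screen_inclusion
from magnotrain.pipeline import analyse_measure

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort_path = OUT / "cohort.csv"
    if not cohort_path.exists():
        sys.exit("results/cohort.csv not found - run 03_generate_cohort.py first")
    table, _ = screen_inclusion(mio.read_cohort_csv(cohort_path))

    report = {}
    for measure in MEASURES:
        report[measure] = analyse_measure(table, measure)
        print(f"\n{measure}")
        for line in report[measure]["text"]:
            print(" ", line)
        first_pair = report[measure]["pairwise_within"][0]
        print(f"  experimental pre vs mid: mean difference "
              f"{first_pair['mean_difference']:+.2f}, p = {first_pair['p']:.4f}")
    mio.write_json(report, OUT / "anova_report.json")
    print("\nwrote results/anova_report.json")


if __name__ == "__main__":
    main()
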