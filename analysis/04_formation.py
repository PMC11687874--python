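"""Initial→final stance transitions and stance-formation cohorts.

Reports the 3x3 transition matrix with margins, the per-row
retention/shift percentages, and the neutral-to-pro / neutral-to-anti /
remaining-neutral cohort assignments with change months.

    python analysis/04_formation.py [--timelines results/timelines.csv]
"""

import argparse
from pathlib import Path

from stanceform import formation as fm
from stanceform import timeline as tl


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--timelines", type=Path, default=Path("results/timelines.csv"))
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    timelines = tl.read_timelines(args.timelines)
    matrix = fm.transition_matrix(timelines)
    stats = fm.retention_and_shift_stats(matrix)
    assigns = fm.assign_cohorts(timelines)
    counts = fm.cohort_counts(assigns)

    args.out_dir.mkdir(parents=True, exist_ok=True)
    fm.write_transition_matrix(matrix, args.out_dir / "transition_matrix.csv")
    fm.write_cohorts(assigns, args.out_dir / "cohorts.csv")
    stats.to_csv(args.out_dir / "retention_stats.csv")

    print("initial -> final transition matrix (with margins):")
    print(matrix.with_margins().to_string())
    print("\nretention / shift percentages:")
    print(stats[["total", "to_pro", "to_neutral", "to_anti", "retention"]].to_string())
    print("\ncohorts:", counts)
    print(f"tables -> {args.out_dir}/transition_matrix.csv, cohorts.csv, retention_stats.csv")


if __name__ == "__main__":
    main()
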