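"""Aggregate the stream into per-user stance timelines.

Majority vote per 10-day period, pro > neutral > anti tie priority,
carry-forward/backfill fill, and the >=4-active-months filter.  Writes the
timelines plus two per-period stance-count views: the all-users
observed-only counts and the active-user filled counts.

    python analysis/02_aggregate_timelines.py [--stream scratch/stream.jsonl]
"""

import argparse
from pathlib import Path

from stanceform import synthetic_data as sd
from stanceform import timeline as tl


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--stream", type=Path, default=Path("scratch/stream.jsonl"))
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    ap.add_argument("--min-active-months", type=int, default=4)
    args = ap.parse_args()

    events = sd.read_stream(args.stream)
    calendar = tl.PeriodCalendar.default_study_window()
    timelines = tl.build_timelines(events, calendar, args.min_active_months)
    args.out_dir.mkdir(parents=True, exist_ok=True)
    tl.write_timelines(timelines, args.out_dir / "timelines.csv")
    tl.stance_distribution(timelines).to_csv(args.out_dir / "stance_counts_filled.csv")
    tl.observed_stance_distribution(events, calendar).to_csv(
        args.out_dir / "stance_counts_observed.csv"
    )

    dist = tl.stance_distribution(timelines)
    print(f"{len(timelines)} active users (of {len({e.user_id for e in events})} posters)")
    print("filled per-period stance counts (first/last period):")
    print(f"  period 0 : {dist.iloc[0].to_dict()}")
    print(f"  period 14: {dist.iloc[-1].to_dict()}")
    print(f"tables -> {args.out_dir}/timelines.csv, stance_counts_*.csv")


if __name__ == "__main__":
    main()
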