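"""Information-sharing enrichment around stance changes.

For each month with stance changers, compares what the neutral-to-pro and
neutral-to-anti cohorts referred to (accounts, URL domains, headline
tokens) inside their 4-period change windows against the remaining-neutral
users, via per-item chi-squared tests at 5% and a top-30 ranking.

    python analysis/05_sharing.py [--stream ...] [--timelines ...]
"""

import argparse
from pathlib import Path

import pandas as pd

from stanceform import formation as fm
from stanceform import sharing as sh
from stanceform import synthetic_data as sd
from stanceform import timeline as tl


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--stream", type=Path, default=Path("scratch/stream.jsonl"))
    ap.add_argument("--timelines", type=Path, default=Path("results/timelines.csv"))
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    ap.add_argument("--top", type=int, default=30)
    ap.add_argument("--alpha", type=float, default=0.05)
    args = ap.parse_args()

    events = sd.read_stream(args.stream)
    calendar = tl.PeriodCalendar.default_study_window()
    timelines = tl.read_timelines(args.timelines)
    assigns = fm.assign_cohorts(timelines)

    frames = []
    for group in (fm.NEUTRAL_TO_PRO, fm.NEUTRAL_TO_ANTI):
        months = sorted(
            {a.change_month for a in assigns.values() if a.cohort == group and a.change_month}
        )
        for month in months:
            for kind in ("account", "url", "token"):
                table = sh.enrichment_table(
                    events, assigns, month, kind, calendar, group=group,
                    n=args.top, alpha=args.alpha,
                )
                if table.empty:
                    continue
                table.insert(0, "month", month)
                table.insert(0, "item_kind", kind)
                table.insert(0, "cohort", group)
                frames.append(table)
    args.out_dir.mkdir(parents=True, exist_ok=True)
    out = args.out_dir / "enrichment.csv"
    if frames:
        combined = pd.concat(frames, ignore_index=True)
        combined.to_csv(out, index=False)
        print(f"{len(combined)} enriched (cohort, month, item) rows -> {out}")
        for group in (fm.NEUTRAL_TO_PRO, fm.NEUTRAL_TO_ANTI):
            sub = combined[(combined.cohort == group) & (combined.item_kind == "url")]
            if not sub.empty:
                top = sub.sort_values("group_users_referring", ascending=False).head(5)
                print(f"\ntop enriched domains for {group}:")
                print(
                    top[["month", "item", "group_users_referring", "p_value"]]
                    .to_string(index=False)
                )
    else:
        pd.DataFrame().to_csv(out)
        print("no significant enrichment found (small cohorts this run)")


if __name__ == "__main__":
    main()
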