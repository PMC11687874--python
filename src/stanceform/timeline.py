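"""Period calendar and per-user stance timelines.

A study window of ``n_months`` calendar months is cut into three periods per
month — days 1–10, 11–20, and 21 to the end of the month — giving 15 periods
for the default five-month window.  A user's stance in a period is the
majority vote over their labeled tweets in that period (ties broken by a
fixed priority, pro > neutral > anti by default); periods without posts are
filled from the last observed stance, or backfilled from the first observed
stance for leading gaps.  Only *active* users — those posting in at least
four distinct calendar months — enter the longitudinal analyses.
"""

from __future__ import annotations

import calendar as _calendar
import datetime as _dt
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from stanceform._stances import STANCES, check_stance

#: Timestamps in the stream are Japan Standard Time; period boundaries are
#: calendar dates in this zone.
JST = _dt.timezone(_dt.timedelta(hours=9), name="JST")

OBSERVED = "observed"
CARRIED = "carried_forward"
BACKFILLED = "backfilled"
PROVENANCE_CODES = {OBSERVED: "o", CARRIED: "c", BACKFILLED: "b"}
_CODE_TO_PROVENANCE = {v: k for k, v in PROVENANCE_CODES.items()}


class CalendarRangeError(ValueError):
    """A date falls outside the calendar window."""


class DegenerateAgreementError(ValueError):
    """Fleiss' kappa is undefined: chance agreement is exactly 1."""


@dataclass(frozen=True)
class PeriodCalendar:
    """Three ten-day-ish periods per month over a multi-month window.

    Parameters
    ----------
    start_year, start_month:
        First calendar month of the window.
    n_months:
        Number of months; the window has ``3 * n_months`` periods.
    """

    start_year: int
    start_month: int
    n_months: int = 5

    @classmethod
    def default_study_window(cls) -> "PeriodCalendar":
        """June–October 2021, the five months the default stream emulates."""
        return cls(2021, 6, 5)

    @property
    def n_periods(self) -> int:
        return 3 * self.n_months

    def month_tuple(self, month_offset: int) -> tuple[int, int]:
        """(year, month) for a 0-based month offset into the window."""
        if not 0 <= month_offset < self.n_months:
            raise CalendarRangeError(f"month offset {month_offset} outside 0..{self.n_months - 1}")
        m = self.start_month - 1 + month_offset
        return self.start_year + m // 12, m % 12 + 1

    def period_bounds(self, period: int) -> tuple[_dt.date, _dt.date]:
        """First and last calendar day of a period (inclusive)."""
        if not 0 <= period < self.n_periods:
            raise CalendarRangeError(f"period {period} outside 0..{self.n_periods - 1}")
        year, month = self.month_tuple(period // 3)
        sub = period % 3
        last_dom = _calendar.monthrange(year, month)[1]
        starts = (1, 11, 21)
        ends = (10, 20, last_dom)
        return (_dt.date(year, month, starts[sub]), _dt.date(year, month, ends[sub]))

    @property
    def periods(self) -> list[tuple[int, _dt.date, _dt.date]]:
        return [(p, *self.period_bounds(p)) for p in range(self.n_periods)]

    def month_of_period(self, period: int) -> int:
        if not 0 <= period < self.n_periods:
            raise CalendarRangeError(f"period {period} outside 0..{self.n_periods - 1}")
        return period // 3

    def periods_of_month(self, month_offset: int) -> tuple[int, int, int]:
        if not 0 <= month_offset < self.n_months:
            raise CalendarRangeError(f"month offset {month_offset} outside 0..{self.n_months - 1}")
        return (3 * month_offset, 3 * month_offset + 1, 3 * month_offset + 2)


def period_index(when: _dt.date | _dt.datetime, calendar: PeriodCalendar) -> int:
    """Index of the unique period covering a date.

    Datetimes are reduced to their calendar date (in their own zone; the
    stream writes JST timestamps).  Raises :class:`CalendarRangeError` for
    dates outside the window.
    """
    if isinstance(when, _dt.datetime):
        when = when.date()
    month_offset = (when.year - calendar.start_year) * 12 + (when.month - calendar.start_month)
    if not 0 <= month_offset < calendar.n_months:
        raise CalendarRangeError(f"{when.isoformat()} outside calendar window")
    sub = 0 if when.day <= 10 else (1 if when.day <= 20 else 2)
    return 3 * month_offset + sub


def majority_stance(labels: Iterable[str], priority: Sequence[str] = STANCES) -> str:
    """Plurality stance of a non-empty label multiset.

    Ties are resolved by ``priority`` (first match wins); the default order
    pro > neutral > anti mirrors the per-class precision of the upstream
    classifier.  An empty multiset raises ``ValueError`` — the caller decides
    whether to carry forward or backfill.
    """
    counts = Counter(check_stance(s) for s in labels)
    if not counts:
        raise ValueError("majority_stance: empty label multiset (no observation)")
    best = max(counts.values())
    for stance in priority:
        if counts.get(stance, 0) == best:
            return stance
    raise AssertionError("priority order does not cover the observed labels")


@dataclass(frozen=True)
class StanceTimeline:
    """One stance per period for an active user, with fill provenance."""

    user_id: str
    stances: tuple[str, ...]
    provenance: tuple[str, ...]
    months_active: int = 0

    def __post_init__(self) -> None:
        if len(self.stances) != len(self.provenance):
            raise ValueError("stances and provenance must be parallel")

    @property
    def n_periods(self) -> int:
        return len(self.stances)

    @property
    def initial(self) -> str:
        return self.stances[0]

    @property
    def final(self) -> str:
        return self.stances[-1]


def fill_timeline(
    observed: Mapping[int, str], n_periods: int, user_id: str = "", months_active: int = 0
) -> StanceTimeline:
    """Complete a partial period→stance map into a full timeline.

    Gaps after the first observation take the most recent observed stance
    (``carried_forward``); gaps before it take the first observed stance
    (``backfilled``).
    """
    if not observed:
        raise ValueError("fill_timeline: user has zero observed periods; exclude upstream")
    if not all(0 <= p < n_periods for p in observed):
        raise ValueError("observed period index outside 0..n_periods-1")
    first = min(observed)
    stances: list[str] = []
    provenance: list[str] = []
    current = check_stance(observed[first])
    for p in range(n_periods):
        if p in observed:
            current = check_stance(observed[p])
            stances.append(current)
            provenance.append(OBSERVED)
        elif p < first:
            stances.append(observed[first])
            provenance.append(BACKFILLED)
        else:
            stances.append(current)
            provenance.append(CARRIED)
    return StanceTimeline(user_id, tuple(stances), tuple(provenance), months_active)


def _event_label(event) -> str | None:
    # Tweets carrying only class probabilities are labeled through the
    # precision-oriented anti threshold before aggregation.
    if event.stance_label is not None:
        return event.stance_label
    if event.stance_probs is not None:
        from stanceform.reaction_features import apply_anti_threshold

        return apply_anti_threshold(event.stance_probs)
    return None


def _months_posted(events, calendar: PeriodCalendar) -> dict[str, set[int]]:
    months: dict[str, set[int]] = defaultdict(set)
    for ev in events:
        p = period_index(ev.timestamp, calendar)
        months[ev.user_id].add(calendar.month_of_period(p))
    return months


def active_users(events, calendar: PeriodCalendar, min_months: int = 4) -> set[str]:
    """Users posting in at least ``min_months`` distinct calendar months."""
    return {u for u, m in _months_posted(events, calendar).items() if len(m) >= min_months}


def build_timelines(
    events,
    calendar: PeriodCalendar,
    min_active_months: int = 4,
    priority: Sequence[str] = STANCES,
) -> dict[str, StanceTimeline]:
    """Aggregate a stream into per-active-user filled stance timelines.

    Order-independent: any permutation of the stream yields the same result.
    """
    per_user_period: dict[str, dict[int, list[str]]] = defaultdict(lambda: defaultdict(list))
    months: dict[str, set[int]] = defaultdict(set)
    for ev in events:
        p = period_index(ev.timestamp, calendar)
        months[ev.user_id].add(calendar.month_of_period(p))
        label = _event_label(ev)
        if label is not None:
            per_user_period[ev.user_id][p].append(label)
    out: dict[str, StanceTimeline] = {}
    for user in sorted(per_user_period):
        if len(months[user]) < min_active_months:
            continue
        observed = {
            p: majority_stance(labels, priority)
            for p, labels in per_user_period[user].items()
        }
        if not observed:
            continue
        out[user] = fill_timeline(observed, calendar.n_periods, user, len(months[user]))
    return out


def stance_distribution(timelines: Mapping[str, StanceTimeline]) -> pd.DataFrame:
    """Per-period counts of each stance over filled timelines.

    Rows are periods, columns the three stances; every row sums to the
    number of timelines.
    """
    if not timelines:
        return pd.DataFrame(columns=list(STANCES), dtype=int)
    n_periods = next(iter(timelines.values())).n_periods
    counts = np.zeros((n_periods, 3), dtype=int)
    idx = {s: i for i, s in enumerate(STANCES)}
    for tl in timelines.values():
        for p, s in enumerate(tl.stances):
            counts[p, idx[s]] += 1
    return pd.DataFrame(counts, columns=list(STANCES))


def observed_stance_distribution(events, calendar: PeriodCalendar,
                                 priority: Sequence[str] = STANCES) -> pd.DataFrame:
    """Per-period stance counts over users observed in that period only.

    No fill, no activity filter — the all-users view of the stream.
    """
    per_period_user: dict[int, dict[str, list[str]]] = defaultdict(lambda: defaultdict(list))
    for ev in events:
        label = _event_label(ev)
        if label is None:
            continue
        per_period_user[period_index(ev.timestamp, calendar)][ev.user_id].append(label)
    counts = np.zeros((calendar.n_periods, 3), dtype=int)
    idx = {s: i for i, s in enumerate(STANCES)}
    for p, users in per_period_user.items():
        for labels in users.values():
            counts[p, idx[majority_stance(labels, priority)]] += 1
    return pd.DataFrame(counts, columns=list(STANCES))


def fleiss_kappa(counts) -> float:
    """Fleiss' kappa for an items × 3-category tally table.

    Each row must sum to the (constant) number of raters.  Used as an
    annotation-QC statistic; raises :class:`DegenerateAgreementError` when
    expected chance agreement is exactly 1 (all ratings in one category).
    """
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need at least 2 items and 2 categories")
    row_sums = table.sum(axis=1)
    if not np.all(row_sums == row_sums[0]):
        raise ValueError("rows must all sum to the rater count")
    if row_sums[0] < 2:
        raise ValueError("need at least 2 raters")
    p_cat = table.sum(axis=0) / table.sum()
    if np.isclose((p_cat**2).sum(), 1.0):
        raise DegenerateAgreementError("chance agreement is 1; kappa undefined")
    from statsmodels.stats.inter_rater import fleiss_kappa as _sm_fleiss

    return float(_sm_fleiss(table, method="fleiss"))


# ---------------------------------------------------------------------------
# CSV round trip: user_id, p00..p14 stances, v00..v14 provenance codes.

def timelines_to_frame(timelines: Mapping[str, StanceTimeline]) -> pd.DataFrame:
    rows = []
    for user in sorted(timelines):
        tl = timelines[user]
        row: dict[str, object] = {"user_id": user, "months_active": tl.months_active}
        for p, s in enumerate(tl.stances):
            row[f"p{p:02d}"] = s
        for p, v in enumerate(tl.provenance):
            row[f"v{p:02d}"] = PROVENANCE_CODES[v]
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_timelines(frame: pd.DataFrame) -> dict[str, StanceTimeline]:
    p_cols = sorted(c for c in frame.columns if c.startswith("p") and c[1:].isdigit())
    out = {}
    for _, row in frame.iterrows():
        stances = tuple(row[c] for c in p_cols)
        prov = tuple(_CODE_TO_PROVENANCE[row["v" + c[1:]]] for c in p_cols)
        out[row["user_id"]] = StanceTimeline(
            row["user_id"], stances, prov, int(row.get("months_active", 0))
        )
    return out


def write_timelines(timelines: Mapping[str, StanceTimeline], path) -> None:
    timelines_to_frame(timelines).to_csv(path, index=False)


def read_timelines(path) -> dict[str, StanceTimeline]:
    return frame_to_timelines(pd.read_csv(path))
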