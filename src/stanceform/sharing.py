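"""Information-sharing enrichment around stance changes.

For each calendar month, users who changed stance that month (neutral-to-pro
or neutral-to-anti) are compared against users who stayed neutral.  Sharing
is observed inside a per-user window — the change period plus the three
periods before it for changers, the literal month for the reference group —
with per-user dedupe (one user referring to the same item many times counts
once).  Items (referred accounts, URL domains, or headline tokens) are kept
when a 2×2 chi-squared test of independence between the two user groups is
significant at alpha, then ranked by distinct cohort users, top-N.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from stanceform.formation import (
    NEUTRAL_TO_ANTI,
    NEUTRAL_TO_PRO,
    REMAINING_NEUTRAL,
    CohortAssignment,
)
from stanceform.timeline import PeriodCalendar, period_index

ITEM_KINDS = ("account", "url", "token")
REFERRAL_REACTIONS = ("retweet", "quote", "reply")


def whitespace_tokenizer(text: str) -> list[str]:
    """Lower-cased whitespace tokenization; the desk-scale default.

    Any ``str -> list[str]`` callable (e.g. a Japanese morphological
    tokenizer restricted to nouns) can replace it.
    """
    return text.lower().split()


def tokenize_headlines(
    texts: Iterable[str], tokenizer: Callable[[str], list[str]] = whitespace_tokenizer
) -> list[str]:
    """Token multiset over headline texts; tokenizer failures are skipped
    with a warning (per-user dedupe happens in collect_referrals)."""
    tokens: list[str] = []
    for text in texts:
        try:
            tokens.extend(tokenizer(text))
        except Exception as exc:  # noqa: BLE001 - contract: skip and warn
            warnings.warn(f"tokenizer failed on {text!r}: {exc}", stacklevel=2)
    return tokens


@dataclass
class GroupIncidence:
    """Binary user×item incidence for one group in one month's analysis."""

    users: set = field(default_factory=set)  # all group members (totals)
    items_by_user: dict = field(default_factory=dict)  # user -> set(items)

    def n_users(self) -> int:
        return len(self.users)

    def item_counts(self) -> dict:
        counts: dict = defaultdict(int)
        for items in self.items_by_user.values():
            for item in items:
                counts[item] += 1
        return dict(counts)


def _window_periods(assignment: CohortAssignment, month: int, calendar: PeriodCalendar,
                    symmetric_reference: bool) -> list[int]:
    if assignment.cohort in (NEUTRAL_TO_PRO, NEUTRAL_TO_ANTI):
        cp = assignment.change_period
        return [p for p in range(cp - 3, cp + 1) if p >= 0]
    periods = list(calendar.periods_of_month(month))
    if symmetric_reference and periods[0] - 1 >= 0:
        periods.insert(0, periods[0] - 1)
    return periods


def _items_of(ev, item_kind: str, tokenizer) -> list[str]:
    if item_kind == "account":
        if ev.reaction is not None and ev.reaction.type in REFERRAL_REACTIONS:
            return [ev.reaction.target_user_id]
        return []
    if item_kind == "url":
        return [ev.shared_url.domain] if ev.shared_url is not None else []
    if item_kind == "token":
        if ev.shared_url is not None and ev.shared_url.headline_text:
            return tokenize_headlines([ev.shared_url.headline_text], tokenizer)
        return []
    raise ValueError(f"unknown item_kind {item_kind!r} (expected one of {ITEM_KINDS})")


def collect_referrals(
    events,
    assignments: Mapping[str, CohortAssignment],
    month: int,
    item_kind: str,
    calendar: PeriodCalendar,
    tokenizer: Callable[[str], list[str]] = whitespace_tokenizer,
    symmetric_reference: bool = False,
) -> dict[str, GroupIncidence]:
    """Per-group binary user×item incidence for one month's comparison.

    Groups are the users whose stance changed in ``month`` (neutral-to-pro,
    neutral-to-anti; window = change period + 3 prior periods) and all
    remaining-neutral users (window = the literal month, or month plus one
    prior period with ``symmetric_reference``).  Incidence is binary per
    (user, item) inside the window — repeats never count twice.
    """
    if item_kind not in ITEM_KINDS:
        raise ValueError(f"unknown item_kind {item_kind!r}")
    window_of: dict[str, frozenset[int]] = {}
    groups = {
        NEUTRAL_TO_PRO: GroupIncidence(),
        NEUTRAL_TO_ANTI: GroupIncidence(),
        REMAINING_NEUTRAL: GroupIncidence(),
    }
    for user, a in assignments.items():
        if a.cohort in (NEUTRAL_TO_PRO, NEUTRAL_TO_ANTI):
            if a.change_month != month:
                continue
        elif a.cohort != REMAINING_NEUTRAL:
            continue
        groups[a.cohort].users.add(user)
        window_of[user] = frozenset(
            _window_periods(a, month, calendar, symmetric_reference)
        )
    for ev in events:
        window = window_of.get(ev.user_id)
        if window is None:
            continue
        if period_index(ev.timestamp, calendar) not in window:
            continue
        items = _items_of(ev, item_kind, tokenizer)
        if not items:
            continue
        group = groups[assignments[ev.user_id].cohort]
        bag = group.items_by_user.setdefault(ev.user_id, set())
        bag.update(items)
    return groups


def top_items(incidence: GroupIncidence, n: int) -> list[str]:
    """Items ranked by distinct referring users, descending; ties broken
    lexicographically by item id."""
    if n < 1:
        raise ValueError("n must be >= 1")
    counts = incidence.item_counts()
    return sorted(counts, key=lambda item: (-counts[item], item))[:n]


def chi2_independence(table, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-squared test of independence on a 2×2 count table.

    Returns ``(statistic, p_value)`` with 1 degree of freedom; Yates
    continuity correction is off by default.  A zero row or column margin
    raises ``ValueError``.
    """
    a = np.asarray(table, dtype=float)
    if a.shape != (2, 2) or np.any(a < 0):
        raise ValueError("expected a nonnegative 2x2 table")
    if np.any(a.sum(axis=0) == 0) or np.any(a.sum(axis=1) == 0):
        raise ValueError("chi-squared undefined: zero margin")
    res = stats.chi2_contingency(a, correction=yates)
    return float(res.statistic), float(res.pvalue)


def enrichment_table(
    events,
    assignments: Mapping[str, CohortAssignment],
    month: int,
    item_kind: str,
    calendar: PeriodCalendar,
    group: str = NEUTRAL_TO_PRO,
    reference: str = REMAINING_NEUTRAL,
    n: int | None = 30,
    alpha: float = 0.05,
    yates: bool = False,
    bh_correct: bool = False,
    catalog: Mapping[str, str] | None = None,
    tokenizer: Callable[[str], list[str]] = whitespace_tokenizer,
    symmetric_reference: bool = False,
) -> pd.DataFrame:
    """Significantly over/under-shared items for a cohort vs a reference.

    Per item, the 2×2 table is (group users referring / not) × (reference
    users referring / not); items with p < alpha survive and the top ``n``
    by distinct group users are returned (``n=None`` keeps all).
    ``bh_correct`` applies Benjamini–Hochberg before the alpha filter (off
    by default: the study design tests each item at 5% uncorrected).
    ``catalog`` joins an attribute/category annotation per item.
    """
    incidences = collect_referrals(
        events, assignments, month, item_kind, calendar, tokenizer, symmetric_reference
    )
    if group not in incidences or reference not in incidences:
        raise ValueError(f"group and reference must be in {sorted(incidences)}")
    g, ref = incidences[group], incidences[reference]
    if g.n_users() == 0:
        warnings.warn(f"empty cohort {group!r} for month {month}", stacklevel=2)
        return _empty_enrichment()
    g_counts, r_counts = g.item_counts(), ref.item_counts()
    items = sorted(set(g_counts) | set(r_counts))
    rows = []
    for item in items:
        a = g_counts.get(item, 0)
        c = r_counts.get(item, 0)
        table = [[a, g.n_users() - a], [c, ref.n_users() - c]]
        try:
            chi2, p = chi2_independence(table, yates=yates)
        except ValueError:
            chi2, p = float("nan"), float("nan")
        rows.append(
            {
                "item": item,
                "group_users_referring": a,
                "group_users_total": g.n_users(),
                "reference_users_referring": c,
                "reference_users_total": ref.n_users(),
                "chi2": chi2,
                "p_value": p,
            }
        )
    frame = pd.DataFrame(rows)
    if frame.empty:
        return _empty_enrichment()
    if bh_correct:
        from statsmodels.stats.multitest import multipletests

        ok = frame["p_value"].notna()
        adjusted = frame["p_value"].copy()
        if ok.any():
            adjusted.loc[ok] = multipletests(frame.loc[ok, "p_value"], method="fdr_bh")[1]
        frame["p_value_adj"] = adjusted
        frame["significant"] = frame["p_value_adj"] < alpha
    else:
        frame["significant"] = frame["p_value"] < alpha
    if alpha >= 1.0:
        # filter disabled: keep even items with undefined p (zero margins)
        frame["significant"] = True
    kept = frame[frame["significant"]].copy()
    kept = kept.sort_values(
        ["group_users_referring", "item"], ascending=[False, True], kind="mergesort"
    )
    if n is not None:
        kept = kept.head(n)
    kept = kept.reset_index(drop=True)
    kept["rank"] = np.arange(1, len(kept) + 1)
    kept["annotation"] = (
        kept["item"].map(catalog).astype(object) if catalog is not None else None
    )
    return kept


def _empty_enrichment() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "item", "group_users_referring", "group_users_total",
            "reference_users_referring", "reference_users_total",
            "chi2", "p_value", "significant", "rank", "annotation",
        ]
    )
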