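"""Shared fixtures: a default calendar and a compact event factory."""

from __future__ import annotations

import datetime as dt

import pytest

from stanceform.synthetic_data import Reaction, SharedUrl, TweetEvent
from stanceform.timeline import JST, PeriodCalendar

_COUNTER = {"n": 0}


def make_event(
    user: str,
    when: str,
    label: str | None = "neutral",
    retweet_of: str | None = None,
    reply_to: str | None = None,
    quote_of: str | None = None,
    url: tuple[str, str] | None = None,
    headline: str = "",
    probs=None,
) -> TweetEvent:
    """Build a TweetEvent from shorthand: ``when`` is 'YYYY-MM-DD[ HH:MM]'."""
    _COUNTER["n"] += 1
    if " " in when:
        ts = dt.datetime.strptime(when, "%Y-%m-%d %H:%M").replace(tzinfo=JST)
    else:
        ts = dt.datetime.strptime(when, "%Y-%m-%d").replace(hour=12, tzinfo=JST)
    reaction = None
    for target, rtype in ((retweet_of, "retweet"), (reply_to, "reply"), (quote_of, "quote")):
        if target is not None:
            reaction = Reaction(rtype, target, f"t_of_{target}")
    shared = None
    if url is not None:
        domain, category = url
        shared = SharedUrl(domain, category, headline)
    return TweetEvent(
        tweet_id=f"t{_COUNTER['n']:06d}",
        user_id=user,
        timestamp=ts,
        stance_label=label,
        stance_probs=probs,
        reaction=reaction,
        shared_url=shared,
    )


@pytest.fixture
def calendar() -> PeriodCalendar:
    return PeriodCalendar.default_study_window()


@pytest.fixture
def event_factory():
    return make_event
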