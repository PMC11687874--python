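"""Synthetic tweet/reaction/link streams with the structure the analysis assumes.

The real corpus (five months of Japanese vaccine-related tweets) is
proprietary, so every downstream stage is exercised against a generative
stand-in.  The generator states a small world and sticks to it:

- each user carries a *latent* monthly stance following a row-stochastic
  monthly hazard matrix (predominantly neutral→pro drift, anti a small
  minority);
- emitted tweet labels equal the latent stance up to a uniform label-noise
  flip;
- reactions (retweet/quote/reply) choose their target with probability
  proportional to ``homophily_matrix[stance_u, stance_v]`` times the
  target's popularity (a Zipf-like weight, emulating hub-dominated retweet
  graphs), so pro–anti edges are sparse, neutral users mostly touch pro
  users, and each stance group condenses around a few influencer accounts;
- shared URLs draw a site category from a per-stance preference (anti users
  lean on video hosting and BBS/blog sites), with headline text assembled
  from small per-stance token pools.

Ground-truth latent trajectories are returned (and written) separately from
the event stream so they can never leak into pipeline inputs.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from stanceform._stances import ANTI, NEUTRAL, PRO, STANCES
from stanceform.timeline import JST, PeriodCalendar

# Account-attribute taxonomy for referred accounts (profile-derived labels).
ACCOUNT_ATTRIBUTES = (
    "Government",
    "Politician",
    "Medical worker",
    "Researcher",
    "Mass media",
    "Web news",
    "Business person",
    "Influencer",
    "Professional writer",
    "Artist",
    "Uncategorized",
    "No info",
)

# Site-category taxonomy for shared external links.
SITE_CATEGORIES = (
    "Government",
    "Politician",
    "Healthcare institution",
    "Pharmaceutical",
    "Academic organization",
    "Mass media",
    "COVID-info",
    "Web news",
    "SNS",
    "Video hosting",
    "BBS, Blog",
    "Uncategorized",
)

REACTION_TYPES = ("retweet", "quote", "reply")

# Stated-world defaults (see docs/methods.md for the rationale of each number).
_DEFAULT_INITIAL = (0.46, 0.46, 0.08)
_DEFAULT_HAZARDS = (
    (0.939, 0.060, 0.001),  # pro row: mostly stable, leaks to neutral
    (0.150, 0.845, 0.005),  # neutral row: strong drift to pro, trickle to anti
    (0.020, 0.080, 0.900),  # anti row: a sticky echo chamber
)
_DEFAULT_HOMOPHILY = (
    (1.000, 0.030, 0.002),
    (0.030, 1.000, 0.006),
    (0.002, 0.006, 1.000),
)

# Per-stance categorical preference over SITE_CATEGORIES (rows sum to 1).
_DEFAULT_SITE_PREFS = {
    PRO:     (0.08, 0.02, 0.04, 0.02, 0.04, 0.24, 0.04, 0.32, 0.05, 0.06, 0.04, 0.05),
    NEUTRAL: (0.08, 0.02, 0.04, 0.02, 0.05, 0.26, 0.05, 0.26, 0.06, 0.06, 0.05, 0.05),
    ANTI:    (0.02, 0.02, 0.02, 0.01, 0.03, 0.05, 0.03, 0.07, 0.08, 0.30, 0.30, 0.07),
}

# Per-stance preference over ACCOUNT_ATTRIBUTES for the accounts a stance
# group tends to react to (medical workers for pro/neutral; unclear or
# unknown occupations for anti).
_DEFAULT_ATTRIBUTE_PREFS = {
    PRO:     (0.06, 0.04, 0.22, 0.06, 0.14, 0.10, 0.08, 0.06, 0.06, 0.10, 0.04, 0.04),
    NEUTRAL: (0.08, 0.04, 0.20, 0.06, 0.18, 0.12, 0.06, 0.06, 0.06, 0.06, 0.04, 0.04),
    ANTI:    (0.02, 0.04, 0.08, 0.06, 0.04, 0.06, 0.10, 0.08, 0.06, 0.02, 0.20, 0.24),
}

# Headline token pools; category token + stance tokens drive the
# headline-token enrichment analyses.
_STANCE_TOKENS = {
    PRO: ("reservation", "venue", "dose", "coupon", "moderna", "pfizer", "effective"),
    NEUTRAL: ("report", "coverage", "survey", "schedule", "update", "ministry"),
    ANTI: ("death", "danger", "side-effects", "conceal", "israel", "developer"),
}


def _slug(category: str) -> str:
    return category.lower().replace(",", "").replace(" ", "-")


class StreamFormatError(ValueError):
    """A serialized stream record is malformed (reports line and field)."""


@dataclass(frozen=True)
class Reaction:
    type: str
    target_user_id: str
    target_tweet_id: str


@dataclass(frozen=True)
class ReferredAccount:
    account_id: str
    attribute: str


@dataclass(frozen=True)
class SharedUrl:
    domain: str
    category: str
    headline_text: str


@dataclass(frozen=True)
class TweetEvent:
    """One post: stance label plus optional reaction / account / URL payload."""

    tweet_id: str
    user_id: str
    timestamp: _dt.datetime
    stance_label: str | None = None
    stance_probs: tuple[float, float, float] | None = None
    reaction: Reaction | None = None
    referred_account: ReferredAccount | None = None
    shared_url: SharedUrl | None = None

    def __post_init__(self) -> None:
        if self.reaction is not None and self.reaction.target_user_id == self.user_id:
            raise ValueError("reaction target must differ from the posting user")
        if self.stance_probs is not None:
            if abs(sum(self.stance_probs) - 1.0) > 1e-9:
                raise ValueError("stance_probs must sum to 1 within 1e-9")


@dataclass
class SimConfig:
    """Parameters of the synthetic stream; defaults are the stated world."""

    n_users: int = 2000
    n_months: int = 5
    posting_rate: float = 2.0
    initial_stance_probs: tuple[float, float, float] = _DEFAULT_INITIAL
    monthly_transition_hazards: tuple[tuple[float, ...], ...] = _DEFAULT_HAZARDS
    homophily_matrix: tuple[tuple[float, ...], ...] = _DEFAULT_HOMOPHILY
    label_noise: float = 0.05
    attribute_catalog: tuple[str, ...] = ACCOUNT_ATTRIBUTES
    site_catalog: tuple[str, ...] = SITE_CATEGORIES
    stance_site_preferences: dict = field(default_factory=lambda: dict(_DEFAULT_SITE_PREFS))
    stance_attribute_preferences: dict = field(
        default_factory=lambda: dict(_DEFAULT_ATTRIBUTE_PREFS)
    )
    reaction_prob: float = 0.8
    share_prob: float = 0.15
    reaction_type_probs: tuple[float, float, float] = (0.70, 0.15, 0.15)
    #: Zipf exponent of the per-user popularity weights that concentrate
    #: reactions on a few hub accounts per stance group (0 = uniform).
    popularity_exponent: float = 2.5
    #: Per-stance multiplier on posting_rate; the anti minority is vocal.
    stance_activity: tuple[float, float, float] = (1.0, 1.0, 2.5)
    start_year: int = 2021
    start_month: int = 6
    seed: int = 0

    def calendar(self) -> PeriodCalendar:
        return PeriodCalendar(self.start_year, self.start_month, self.n_months)

    def validate(self) -> "SimConfig":
        if self.n_users <= 0:
            raise ValueError("n_users must be positive")
        if self.n_months <= 0:
            raise ValueError("n_months must be positive")
        if not 0.0 <= self.label_noise <= 1.0:
            raise ValueError("label_noise must lie in [0, 1]")
        p0 = np.asarray(self.initial_stance_probs, dtype=float)
        if p0.shape != (3,) or np.any(p0 < 0) or abs(p0.sum() - 1.0) > 1e-12:
            raise ValueError("initial_stance_probs must be a 3-simplex (sum 1 within 1e-12)")
        H = np.asarray(self.monthly_transition_hazards, dtype=float)
        if H.shape != (3, 3) or np.any(H < 0):
            raise ValueError("monthly_transition_hazards must be a nonnegative 3x3 matrix")
        if np.any(np.abs(H.sum(axis=1) - 1.0) > 1e-12):
            raise ValueError("monthly_transition_hazards rows must sum to 1 within 1e-12")
        M = np.asarray(self.homophily_matrix, dtype=float)
        if M.shape != (3, 3) or np.any(M < 0) or not np.allclose(M, M.T):
            raise ValueError("homophily_matrix must be symmetric with nonnegative entries")
        for prefs in (self.stance_site_preferences, self.stance_attribute_preferences):
            for stance, row in prefs.items():
                r = np.asarray(row, dtype=float)
                if np.any(r < 0) or abs(r.sum() - 1.0) > 1e-9:
                    raise ValueError(f"preference row for {stance!r} must be a simplex")
        q = np.asarray(self.reaction_type_probs, dtype=float)
        if q.shape != (3,) or np.any(q < 0) or abs(q.sum() - 1.0) > 1e-9:
            raise ValueError("reaction_type_probs must be a 3-simplex")
        if self.popularity_exponent < 0:
            raise ValueError("popularity_exponent must be >= 0")
        act = np.asarray(self.stance_activity, dtype=float)
        if act.shape != (3,) or np.any(act <= 0):
            raise ValueError("stance_activity must be three positive multipliers")
        return self


@dataclass(frozen=True)
class SimResult:
    """Event stream plus the sidecar ground truth (never interleaved)."""

    events: list[TweetEvent]
    truth: pd.DataFrame  # columns: user_id, month, latent_stance


def _sample_categorical(rng: np.random.Generator, probs: np.ndarray) -> int:
    # Single inverse-CDF draw; avoids rng.choice's permutation overhead.
    return int(np.searchsorted(np.cumsum(probs), rng.random(), side="right"))


def simulate_latent(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Latent stance index per (user, month); month 0 drawn from the initial
    distribution, each later month one step of the monthly hazard chain."""
    H = np.asarray(config.monthly_transition_hazards, dtype=float)
    latent = np.empty((config.n_users, config.n_months), dtype=np.int64)
    latent[:, 0] = rng.choice(3, size=config.n_users, p=np.asarray(config.initial_stance_probs))
    for m in range(1, config.n_months):
        prev = latent[:, m - 1]
        nxt = prev.copy()
        for s in range(3):
            mask = prev == s
            n = int(mask.sum())
            if n:
                nxt[mask] = rng.choice(3, size=n, p=H[s])
        latent[:, m] = nxt
    return latent


def simulate_stream(config: SimConfig) -> SimResult:
    """Generate the event stream and its ground-truth sidecar.

    Bit-reproducible under a fixed seed: a single PCG64 generator is consumed
    in a fixed (period-major, user-major) order.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    cal = config.calendar()
    latent = simulate_latent(config, rng)
    users = [f"u{i:05d}" for i in range(config.n_users)]
    site_prefs = {s: np.asarray(config.stance_site_preferences[s], float) for s in STANCES}
    attr_prefs = {s: np.asarray(config.stance_attribute_preferences[s], float) for s in STANCES}
    # Fixed per-user account attribute, drawn from the preference of the
    # user's initial latent stance (attributes are profile-derived, static).
    user_attr = [
        config.attribute_catalog[_sample_categorical(rng, attr_prefs[STANCES[latent[i, 0]]])]
        for i in range(config.n_users)
    ]
    # Three candidate domains per category.
    domains = {
        cat: [f"{_slug(cat)}{j}.example.jp" for j in range(3)] for cat in config.site_catalog
    }
    homophily = np.asarray(config.homophily_matrix, dtype=float)
    type_cum = np.cumsum(config.reaction_type_probs)
    activity = np.asarray(config.stance_activity, dtype=float)
    # Popularity: Zipf weights over a random rank order *within* each
    # initial stance group, so every group owns a few hub accounts that
    # attract most of its reactions (hub-dominated retweet graphs) and the
    # groups' total popularity masses are comparable regardless of size.
    pop = np.empty(config.n_users, dtype=float)
    for s in range(3):
        group = np.flatnonzero(latent[:, 0] == s)
        ranks = rng.permutation(len(group))
        pop[group] = (1.0 + ranks) ** -config.popularity_exponent

    events: list[TweetEvent] = []
    last_tweet_of: dict[str, str] = {}
    counter = 0
    for period in range(cal.n_periods):
        month = period // 3
        stances_now = latent[:, month]
        members = [np.flatnonzero(stances_now == s) for s in range(3)]
        pop_cum = [np.cumsum(pop[m]) if len(m) else np.empty(0) for m in members]
        pop_sum = [c[-1] if len(c) else 0.0 for c in pop_cum]
        first_day, last_day = cal.period_bounds(period)
        n_days = (last_day - first_day).days + 1
        n_posts = rng.poisson(config.posting_rate * activity[latent[:, month]])
        for i in range(config.n_users):
            s_u = int(stances_now[i])
            for _ in range(int(n_posts[i])):
                day = int(rng.integers(n_days))
                secs = int(rng.integers(86400))
                ts = _dt.datetime.combine(
                    first_day + _dt.timedelta(days=day),
                    _dt.time(secs // 3600, (secs % 3600) // 60, secs % 60),
                    tzinfo=JST,
                )
                label = STANCES[s_u]
                if config.label_noise > 0 and rng.random() < config.label_noise:
                    others = [s for s in range(3) if s != s_u]
                    label = STANCES[others[int(rng.integers(2))]]
                reaction = None
                referred = None
                if rng.random() < config.reaction_prob:
                    # group weight = homophily x total popularity of the
                    # group (own popularity excluded from the own group)
                    sizes = np.array(
                        [pop_sum[g] - (pop[i] if g == s_u else 0.0) for g in range(3)]
                    )
                    weights = homophily[s_u] * np.maximum(sizes, 0.0)
                    total = weights.sum()
                    if total > 0:
                        g = _sample_categorical(rng, weights / total)
                        pool = members[g]
                        target_idx = i
                        for _try in range(50):  # popularity draw, reject self
                            j = int(
                                np.searchsorted(
                                    pop_cum[g], rng.random() * pop_sum[g], side="right"
                                )
                            )
                            j = min(j, len(pool) - 1)
                            if int(pool[j]) != i:
                                target_idx = int(pool[j])
                                break
                        if target_idx != i:
                            target = users[target_idx]
                            rtype = REACTION_TYPES[
                                int(np.searchsorted(type_cum, rng.random(), side="right"))
                            ]
                            reaction = Reaction(
                                rtype, target, last_tweet_of.get(target, f"t_seed_{target}")
                            )
                            referred = ReferredAccount(target, user_attr[target_idx])
                shared = None
                if rng.random() < config.share_prob:
                    cat = config.site_catalog[_sample_categorical(rng, site_prefs[STANCES[s_u]])]
                    domain = domains[cat][int(rng.integers(3))]
                    pool = _STANCE_TOKENS.get(STANCES[s_u], _STANCE_TOKENS[NEUTRAL])
                    toks = rng.choice(len(pool), size=2, replace=False)
                    headline = f"{_slug(cat)} vaccine {pool[int(toks[0])]} {pool[int(toks[1])]}"
                    shared = SharedUrl(domain, cat, headline)
                tweet_id = f"t{counter:08d}"
                counter += 1
                events.append(
                    TweetEvent(
                        tweet_id=tweet_id,
                        user_id=users[i],
                        timestamp=ts,
                        stance_label=label,
                        reaction=reaction,
                        referred_account=referred,
                        shared_url=shared,
                    )
                )
                last_tweet_of[users[i]] = tweet_id
    truth = pd.DataFrame(
        {
            "user_id": np.repeat(users, config.n_months),
            "month": np.tile(np.arange(config.n_months), config.n_users),
            "latent_stance": [STANCES[s] for s in latent.ravel()],
        }
    )
    return SimResult(events, truth)


# ---------------------------------------------------------------------------
# JSON Lines serialization (lossless, byte-stable)

def _event_to_obj(ev: TweetEvent) -> dict:
    obj: dict = {
        "tweet_id": ev.tweet_id,
        "user_id": ev.user_id,
        "timestamp": ev.timestamp.isoformat(),
    }
    if ev.stance_label is not None:
        obj["stance_label"] = ev.stance_label
    if ev.stance_probs is not None:
        obj["stance_probs"] = list(ev.stance_probs)
    if ev.reaction is not None:
        obj["reaction"] = {
            "type": ev.reaction.type,
            "target_user_id": ev.reaction.target_user_id,
            "target_tweet_id": ev.reaction.target_tweet_id,
        }
    if ev.referred_account is not None:
        obj["referred_account"] = {
            "account_id": ev.referred_account.account_id,
            "attribute": ev.referred_account.attribute,
        }
    if ev.shared_url is not None:
        obj["shared_url"] = {
            "domain": ev.shared_url.domain,
            "category": ev.shared_url.category,
            "headline_text": ev.shared_url.headline_text,
        }
    return obj


def _require(obj: dict, key: str, lineno: int):
    if key not in obj:
        raise StreamFormatError(f"line {lineno}: missing field '{key}'")
    return obj[key]


def _obj_to_event(obj: dict, lineno: int) -> TweetEvent:
    raw_ts = _require(obj, "timestamp", lineno)
    try:
        ts = _dt.datetime.fromisoformat(raw_ts)
    except ValueError as exc:
        raise StreamFormatError(f"line {lineno}: field 'timestamp' not ISO-8601: {exc}") from exc
    reaction = referred = shared = None
    if "reaction" in obj:
        r = obj["reaction"]
        for key in ("type", "target_user_id", "target_tweet_id"):
            if key not in r:
                raise StreamFormatError(f"line {lineno}: field 'reaction.{key}' missing")
        if r["type"] not in REACTION_TYPES:
            raise StreamFormatError(f"line {lineno}: field 'reaction.type' invalid: {r['type']!r}")
        reaction = Reaction(r["type"], r["target_user_id"], r["target_tweet_id"])
    if "referred_account" in obj:
        a = obj["referred_account"]
        for key in ("account_id", "attribute"):
            if key not in a:
                raise StreamFormatError(f"line {lineno}: field 'referred_account.{key}' missing")
        referred = ReferredAccount(a["account_id"], a["attribute"])
    if "shared_url" in obj:
        u = obj["shared_url"]
        for key in ("domain", "category", "headline_text"):
            if key not in u:
                raise StreamFormatError(f"line {lineno}: field 'shared_url.{key}' missing")
        shared = SharedUrl(u["domain"], u["category"], u["headline_text"])
    label = obj.get("stance_label")
    if label is not None and label not in STANCES:
        raise StreamFormatError(f"line {lineno}: field 'stance_label' invalid: {label!r}")
    probs = obj.get("stance_probs")
    try:
        return TweetEvent(
            tweet_id=_require(obj, "tweet_id", lineno),
            user_id=_require(obj, "user_id", lineno),
            timestamp=ts,
            stance_label=label,
            stance_probs=tuple(probs) if probs is not None else None,
            reaction=reaction,
            referred_account=referred,
            shared_url=shared,
        )
    except ValueError as exc:
        raise StreamFormatError(f"line {lineno}: {exc}") from exc


def write_stream(events: Iterable[TweetEvent], path) -> None:
    """Write events as UTF-8 JSON Lines with a fixed key order."""
    with open(path, "w", encoding="utf-8") as fh:
        for ev in events:
            fh.write(json.dumps(_event_to_obj(ev), ensure_ascii=False, separators=(",", ":")))
            fh.write("\n")


def read_stream(path) -> list[TweetEvent]:
    """Read a JSON-Lines stream; malformed records raise
    :class:`StreamFormatError` naming the line number and field."""
    events = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise StreamFormatError(f"line {lineno}: invalid JSON: {exc}") from exc
            if not isinstance(obj, dict):
                raise StreamFormatError(f"line {lineno}: record is not an object")
            events.append(_obj_to_event(obj, lineno))
    return events


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, index=False)


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path)


def events_to_frame(events: Sequence[TweetEvent]) -> pd.DataFrame:
    """Flat CSV-ready view with a fixed column order (lossy for nesting)."""
    rows = []
    for ev in events:
        rows.append(
            {
                "tweet_id": ev.tweet_id,
                "user_id": ev.user_id,
                "timestamp": ev.timestamp.isoformat(),
                "stance_label": ev.stance_label,
                "reaction_type": ev.reaction.type if ev.reaction else None,
                "target_user_id": ev.reaction.target_user_id if ev.reaction else None,
                "referred_account": ev.referred_account.account_id if ev.referred_account else None,
                "account_attribute": ev.referred_account.attribute if ev.referred_account else None,
                "url_domain": ev.shared_url.domain if ev.shared_url else None,
                "url_category": ev.shared_url.category if ev.shared_url else None,
                "headline_text": ev.shared_url.headline_text if ev.shared_url else None,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "tweet_id", "user_id", "timestamp", "stance_label", "reaction_type",
            "target_user_id", "referred_account", "account_attribute",
            "url_domain", "url_category", "headline_text",
        ],
    )
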