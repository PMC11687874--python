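"""Sharing windows, dedupe, chi-squared enrichment, tokenization."""

from __future__ import annotations

import numpy as np
import pytest

from stanceform import formation as fm
from stanceform import sharing as sh


def assignment(user, cohort, change_period=None):
    cm = None if change_period is None else change_period // 3
    return fm.CohortAssignment(user, cohort, change_period, cm)


@pytest.fixture
def cohort_setup():
    """One neutral-to-anti changer (change at period 7, month 2) and two
    remaining-neutral users."""
    return {
        "chg": assignment("chg", fm.NEUTRAL_TO_ANTI, change_period=7),
        "ref1": assignment("ref1", fm.REMAINING_NEUTRAL),
        "ref2": assignment("ref2", fm.REMAINING_NEUTRAL),
    }


class TestChi2:
    def test_matches_direct_formula_on_random_tables(self):
        """|scipy Pearson - direct sum((O-E)^2/E)| < 1e-9 on 100 tables."""
        rng = np.random.default_rng(0)
        for _ in range(100):
            t = rng.integers(1, 200, size=(2, 2)).astype(float)
            row, col, n = t.sum(1), t.sum(0), t.sum()
            expected = np.outer(row, col) / n
            direct = ((t - expected) ** 2 / expected).sum()
            stat, p = sh.chi2_independence(t)
            assert abs(stat - direct) < 1e-9
            assert 0.0 <= p <= 1.0

    def test_perfect_independence(self):
        stat, p = sh.chi2_independence([[50, 50], [50, 50]])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            sh.chi2_independence([[0, 0], [10, 10]])

    def test_row_swap_preserves_statistic(self):
        t = [[30, 70], [10, 90]]
        assert sh.chi2_independence(t)[0] == pytest.approx(
            sh.chi2_independence(t[::-1])[0]
        )


class TestTopItems:
    def test_tie_broken_lexicographically(self):
        inc = sh.GroupIncidence(
            users={"u1", "u2", "u3", "u4", "u5"},
            items_by_user={
                "u1": {"A", "B"}, "u2": {"A", "C"}, "u3": {"A", "B"},
                "u4": {"A", "C"}, "u5": {"A", "B", "C"},
            },
        )
        assert sh.top_items(inc, 2) == ["A", "B"]
        assert sh.top_items(inc, 99) == ["A", "B", "C"]
        assert sh.top_items(sh.GroupIncidence(), 5) == []


class TestCollect:
    def test_repeated_referrals_count_once(self, calendar, event_factory, cohort_setup):
        events = [
            event_factory("chg", "2021-08-15", reply_to="acctX") for _ in range(5)
        ]
        groups = sh.collect_referrals(events, cohort_setup, 2, "account", calendar)
        assert groups[fm.NEUTRAL_TO_ANTI].items_by_user == {"chg": {"acctX"}}

    def test_changer_window_is_change_period_plus_three_prior(
        self, calendar, event_factory, cohort_setup
    ):
        # change_period 7 covers periods 4..7 = 2021-07-11 .. 2021-08-20
        inside = [
            event_factory("chg", "2021-07-15", retweet_of="in1"),  # period 4
            event_factory("chg", "2021-08-15", retweet_of="in2"),  # period 7
        ]
        outside = [
            event_factory("chg", "2021-07-05", retweet_of="out1"),  # period 3
            event_factory("chg", "2021-08-25", retweet_of="out2"),  # period 8
        ]
        groups = sh.collect_referrals(inside + outside, cohort_setup, 2, "account", calendar)
        assert groups[fm.NEUTRAL_TO_ANTI].items_by_user["chg"] == {"in1", "in2"}

    def test_reference_window_is_literal_month(self, calendar, event_factory, cohort_setup):
        events = [
            event_factory("ref1", "2021-08-15", retweet_of="inA"),
            event_factory("ref1", "2021-07-28", retweet_of="outA"),  # prior month
        ]
        groups = sh.collect_referrals(events, cohort_setup, 2, "account", calendar)
        assert groups[fm.REMAINING_NEUTRAL].items_by_user["ref1"] == {"inA"}
        # symmetric flag additionally admits the period before the month
        groups = sh.collect_referrals(
            events, cohort_setup, 2, "account", calendar, symmetric_reference=True
        )
        assert groups[fm.REMAINING_NEUTRAL].items_by_user["ref1"] == {"inA", "outA"}

    def test_user_without_referrals_still_counts_in_totals(
        self, calendar, event_factory, cohort_setup
    ):
        groups = sh.collect_referrals([], cohort_setup, 2, "account", calendar)
        assert groups[fm.REMAINING_NEUTRAL].n_users() == 2
        assert groups[fm.REMAINING_NEUTRAL].item_counts() == {}


def _enrichment_stream(event_factory, n_chg=12, n_ref=30):
    """Changers share video domains heavily; reference users share news."""
    assignments = {}
    events = []
    for i in range(n_chg):
        u = f"chg{i}"
        assignments[u] = assignment(u, fm.NEUTRAL_TO_ANTI, change_period=7)
        events.append(
            event_factory(u, "2021-08-15", url=("rumble0.example.jp", "Video hosting"),
                          headline="vaccine danger death")
        )
        events.append(
            event_factory(u, "2021-08-16", url=("news0.example.jp", "Web news"),
                          headline="vaccine coverage report")
        )
    for i in range(n_ref):
        u = f"ref{i}"
        assignments[u] = assignment(u, fm.REMAINING_NEUTRAL)
        events.append(
            event_factory(u, "2021-08-15", url=("news0.example.jp", "Web news"),
                          headline="vaccine coverage report")
        )
        if i < 2:
            events.append(
                event_factory(u, "2021-08-16", url=("rumble0.example.jp", "Video hosting"),
                              headline="vaccine danger death")
            )
    return events, assignments


class TestEnrichment:
    def test_planted_video_domain_enriched(self, calendar, event_factory):
        events, assignments = _enrichment_stream(event_factory)
        table = sh.enrichment_table(
            events, assignments, 2, "url", calendar, group=fm.NEUTRAL_TO_ANTI,
            catalog={"rumble0.example.jp": "Video hosting"},
        )
        assert table["item"].tolist() == ["rumble0.example.jp"]
        assert table["annotation"].tolist() == ["Video hosting"]
        assert (table["p_value"] < 0.05).all()

    def test_equally_shared_item_excluded(self, calendar, event_factory):
        events, assignments = _enrichment_stream(event_factory)
        table = sh.enrichment_table(
            events, assignments, 2, "url", calendar, group=fm.NEUTRAL_TO_ANTI
        )
        assert "news0.example.jp" not in table["item"].tolist()

    def test_alpha_one_reduces_to_unfiltered_ranking(self, calendar, event_factory):
        events, assignments = _enrichment_stream(event_factory)
        table = sh.enrichment_table(
            events, assignments, 2, "url", calendar, group=fm.NEUTRAL_TO_ANTI, alpha=1.01
        )
        assert set(table["item"]) == {"rumble0.example.jp", "news0.example.jp"}
        # ranked by distinct cohort users referring
        assert table["rank"].tolist() == [1, 2]

    def test_duplicating_stream_changes_nothing(self, calendar, event_factory):
        events, assignments = _enrichment_stream(event_factory)
        once = sh.enrichment_table(
            events, assignments, 2, "url", calendar, group=fm.NEUTRAL_TO_ANTI
        )
        twice = sh.enrichment_table(
            events + events, assignments, 2, "url", calendar, group=fm.NEUTRAL_TO_ANTI
        )
        assert once.equals(twice)

    def test_group_reference_swap_selects_same_items(self, calendar, event_factory):
        events, assignments = _enrichment_stream(event_factory)
        ab = sh.enrichment_table(
            events, assignments, 2, "url", calendar,
            group=fm.NEUTRAL_TO_ANTI, reference=fm.REMAINING_NEUTRAL, n=None,
        )
        ba = sh.enrichment_table(
            events, assignments, 2, "url", calendar,
            group=fm.REMAINING_NEUTRAL, reference=fm.NEUTRAL_TO_ANTI, n=None,
        )
        assert set(ab["item"]) == set(ba["item"])
        merged = ab.merge(ba, on="item", suffixes=("_ab", "_ba"))
        np.testing.assert_allclose(merged["chi2_ab"], merged["chi2_ba"], atol=1e-9)

    def test_empty_cohort_warns_and_returns_empty(self, calendar, event_factory):
        _, assignments = _enrichment_stream(event_factory)
        with pytest.warns(UserWarning, match="empty cohort"):
            table = sh.enrichment_table(
                [], assignments, 0, "url", calendar, group=fm.NEUTRAL_TO_PRO
            )
        assert table.empty

    def test_token_enrichment_dedupes_per_user(self, calendar, event_factory):
        events, assignments = _enrichment_stream(event_factory)
        table = sh.enrichment_table(
            events, assignments, 2, "token", calendar, group=fm.NEUTRAL_TO_ANTI
        )
        danger = table[table["item"] == "danger"]
        assert not danger.empty
        # 12 changers each shared "danger" once (binary incidence)
        assert danger["group_users_referring"].iloc[0] == 12


class TestTokenize:
    def test_whitespace_default(self):
        assert sh.tokenize_headlines(["Vaccine Reservation opens"]) == [
            "vaccine", "reservation", "opens",
        ]
        assert sh.tokenize_headlines([""]) == []

    def test_failing_tokenizer_skipped_with_warning(self):
        def boom(text):
            raise RuntimeError("no dictionary")

        with pytest.warns(UserWarning, match="tokenizer failed"):
            assert sh.tokenize_headlines(["x"], tokenizer=boom) == []
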