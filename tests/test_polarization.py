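"""Retweet graphs, Louvain stance communities, modified RWC."""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from stanceform import polarization as pol
from stanceform import synthetic_data as sd
from stanceform import timeline as tl


def timeline_all(user, stance, n=15):
    return tl.StanceTimeline(user, (stance,) * n, ("observed",) * n)


def planted_two_block(rng, n_per=15, p_in=0.5, p_out=0.05):
    """Two stance blocks with dense intra- and sparse inter-block edges."""
    g = nx.Graph()
    pro = [f"p{i}" for i in range(n_per)]
    anti = [f"a{i}" for i in range(n_per)]
    for side in (pro, anti):
        for u, v in itertools.combinations(side, 2):
            if rng.random() < p_in:
                g.add_edge(u, v, weight=1)
    for u in pro:
        for v in anti:
            if rng.random() < p_out:
                g.add_edge(u, v, weight=1)
    for node in g.nodes:
        g.nodes[node]["stance"] = "pro" if node.startswith("p") else "anti"
    return g, [u for u in pro if u in g], [u for u in anti if u in g]


class TestGraphConstruction:
    def test_repeated_retweets_accumulate_weight(self, calendar, event_factory):
        tls = {"A": timeline_all("A", "pro"), "B": timeline_all("B", "pro")}
        events = [
            event_factory("A", "2021-07-05", retweet_of="B"),
            event_factory("A", "2021-07-08", retweet_of="B"),
        ]
        g = pol.build_retweet_graph(events, 3, calendar, tls)
        assert g.number_of_edges() == 1
        assert g["A"]["B"]["weight"] == 2
        assert g.nodes["A"]["stance"] == "pro"

    def test_self_retweet_rejected_at_event_level(self, event_factory):
        with pytest.raises(ValueError, match="differ"):
            event_factory("A", "2021-07-05", retweet_of="A")

    def test_other_periods_and_non_retweets_excluded(self, calendar, event_factory):
        tls = {"A": timeline_all("A", "pro"), "B": timeline_all("B", "anti")}
        events = [
            event_factory("A", "2021-06-05", retweet_of="B"),  # other period
            event_factory("A", "2021-07-05", reply_to="B"),  # not a retweet
        ]
        g = pol.build_retweet_graph(events, 3, calendar, tls)
        assert g.number_of_edges() == 0

    def test_min_degree_filter_removes_leaves_once(self, calendar, event_factory):
        tls = {f"leaf{i}": timeline_all(f"leaf{i}", "neutral") for i in range(40)}
        tls["hub"] = timeline_all("hub", "pro")
        events = [
            event_factory(f"leaf{i}", "2021-06-05", retweet_of="hub") for i in range(40)
        ]
        g = pol.build_retweet_graph(events, 0, calendar, tls, min_degree=30)
        assert set(g.nodes) == {"hub"}

    def test_empty_period_gives_empty_graph(self, calendar):
        g = pol.build_retweet_graph([], 5, calendar, {})
        assert g.number_of_nodes() == 0


class TestCommunities:
    def test_three_blocks_labeled_by_stance(self, calendar, event_factory):
        rng = np.random.default_rng(0)
        g = nx.Graph()
        for stance, prefix in (("pro", "p"), ("anti", "a"), ("neutral", "n")):
            nodes = [f"{prefix}{i}" for i in range(12)]
            for u, v in itertools.combinations(nodes, 2):
                if rng.random() < 0.7:
                    g.add_edge(u, v)
            for node in nodes:
                g.nodes[node]["stance"] = stance
        comms = pol.detect_communities(g, seed=1)
        assert sorted(comms.community_stances.values()) == ["anti", "neutral", "pro"]

    def test_stance_tie_resolves_to_neutral(self):
        assert pol.label_majority_stance({"pro": 10, "neutral": 10, "anti": 0}) == "neutral"
        assert pol.label_majority_stance({"pro": 5, "anti": 5}) == "neutral"
        assert pol.label_majority_stance({"anti": 3, "pro": 2}) == "anti"

    def test_resolution_two_recovers_planted_blocks(self):
        """Louvain at resolution 2 recovers a planted 3-block partition
        (adjusted Rand >= 0.9 on average over 10 seeds)."""
        rng = np.random.default_rng(123)
        g = nx.Graph()
        truth = {}
        for b, prefix in enumerate("xyz"):
            nodes = [f"{prefix}{i}" for i in range(30)]
            for node in nodes:
                truth[node] = b
                g.add_node(node, stance="neutral")
            for u, v in itertools.combinations(nodes, 2):
                if rng.random() < 0.5:
                    g.add_edge(u, v)
        for u, v in itertools.combinations(g.nodes, 2):
            if truth[u] != truth[v] and rng.random() < 0.02:
                g.add_edge(u, v)
        nodes = sorted(g.nodes)
        scores = []
        for seed in range(10):
            comms = pol.detect_communities(g, resolution=2.0, seed=seed)
            scores.append(
                adjusted_rand_score(
                    [truth[n] for n in nodes], [comms.partition[n] for n in nodes]
                )
            )
        assert np.mean(scores) >= 0.9


class TestRwc:
    def test_two_cliques_no_cross_edges_is_one(self):
        g = nx.Graph()
        pro = [f"p{i}" for i in range(20)]
        anti = [f"a{i}" for i in range(20)]
        for side, stance in ((pro, "pro"), (anti, "anti")):
            for u, v in itertools.combinations(side, 2):
                g.add_edge(u, v)
        res = pol.rwc_between(g, pro, anti, k=5, method="exact")
        assert res.rwc == pytest.approx(1.0)
        np.testing.assert_allclose(res.p_matrix, np.eye(2), atol=1e-12)

    def test_p_matrix_rows_sum_to_one(self):
        g, pro, anti = planted_two_block(np.random.default_rng(1))
        res = pol.rwc_between(g, pro, anti, k=3, method="exact")
        np.testing.assert_allclose(res.p_matrix.sum(axis=1), [1.0, 1.0], atol=1e-9)
        assert -1.0 <= res.rwc <= 1.0

    def test_label_swap_symmetry(self):
        g, pro, anti = planted_two_block(np.random.default_rng(2))
        a = pol.rwc_between(g, pro, anti, k=3, method="exact")
        b = pol.rwc_between(g, anti, pro, k=3, method="exact")
        assert a.rwc == pytest.approx(b.rwc, abs=1e-12)

    def test_monte_carlo_matches_exact_within_3_se(self):
        rng = np.random.default_rng(3)
        g, pro, anti = planted_two_block(rng, n_per=15, p_in=0.45, p_out=0.1)
        exact = pol.rwc_between(g, pro, anti, k=3, method="exact")
        mc = pol.rwc_between(g, pro, anti, k=3, method="monte_carlo", n_walks=30_000, seed=9)
        assert abs(mc.rwc - exact.rwc) < 3 * mc.rwc_se

    def test_monte_carlo_se_shrinks_with_walks(self):
        g, pro, anti = planted_two_block(np.random.default_rng(4))
        se = [
            pol.rwc_between(g, pro, anti, k=3, method="monte_carlo", n_walks=n, seed=1).rwc_se
            for n in (1_000, 16_000)
        ]
        # O(n^-1/2): 16x walks ~ 4x smaller standard error
        assert se[1] < se[0] / 2.5

    def test_more_inter_block_edges_lower_rwc(self):
        """Controversy decreases as the planted blocks mix (3-point sweep)."""
        values = []
        for p_out in (0.01, 0.1, 0.4):
            vals = []
            for seed in range(5):
                g, pro, anti = planted_two_block(
                    np.random.default_rng(seed), n_per=15, p_in=0.5, p_out=p_out
                )
                vals.append(pol.rwc_between(g, pro, anti, k=3, method="exact").rwc)
            values.append(np.mean(vals))
        assert values[0] > values[1] > values[2]

    def test_disconnected_start_side_signaled(self):
        g = nx.Graph()
        # a0 is the anti absorbing node (highest degree); a1 is isolated, so
        # walks starting from it can never be absorbed
        g.add_edges_from([("p0", "p1"), ("p1", "p2"), ("p0", "p2"), ("p0", "a0")])
        g.add_node("a1")
        with pytest.raises(pol.DisconnectedGraphError):
            pol.rwc_between(g, ["p0", "p1", "p2"], ["a0", "a1"], k=1, method="exact")

    def test_missing_side_is_undefined(self):
        g = nx.Graph()
        g.add_edge("n0", "n1")
        g.nodes["n0"]["stance"] = g.nodes["n1"]["stance"] = "neutral"
        comms = pol.detect_communities(g, seed=0)
        with pytest.raises(pol.RwcUndefinedError):
            pol.modified_rwc(g, comms, k=1)


class TestSeries:
    def test_all_neutral_stream_every_period_undefined(self, calendar, event_factory):
        users = [f"u{i}" for i in range(6)]
        tls = {u: timeline_all(u, "neutral") for u in users}
        events = [
            event_factory(u, f"2021-{m:02d}-05", retweet_of=users[(i + 1) % 6])
            for i, u in enumerate(users)
            for m in (6, 7, 8, 9, 10)
        ]
        series = pol.rwc_series(events, tls, calendar, k=1)
        assert (series["status"] != "ok").all()
        assert series["rwc"].isna().all()

    def test_exact_series_deterministic(self, calendar):
        cfg = sd.SimConfig(n_users=250, seed=6)
        res = sd.simulate_stream(cfg)
        tls = tl.build_timelines(res.events, calendar)
        s1 = pol.rwc_series(res.events, tls, calendar, k=5, seed=3)
        s2 = pol.rwc_series(res.events, tls, calendar, k=5, seed=3)
        assert s1.equals(s2)
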