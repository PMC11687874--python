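"""Per-period retweet graphs and the modified Random Walk Controversy (RWC).

Polarization between the pro- and anti-vaccine sides of a period's
undirected retweet graph is scored with a random-walk measure adapted to a
three-community setting: walks start on the pro or anti side and are
absorbed at the ``k`` highest-degree nodes of either side, while the neutral
community remains traversable but never absorbing.  With ``P_xy`` the
probability that a walk starting on side ``x`` is absorbed on side ``y``
(conditional on absorption),

    rwc = P_pp * P_aa - P_pa * P_ap            (in [-1, 1])

``1`` means walks never cross sides (maximal controversy); ``0`` means the
sides are indistinguishable to a random walker.  Communities come from the
Louvain method at resolution 2; the three largest are stance-labeled by a
majority vote of their members, ties going to neutral.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from stanceform._stances import ANTI, NEUTRAL, PRO, STANCES
from stanceform.timeline import PeriodCalendar, StanceTimeline, period_index


class RwcUndefinedError(ValueError):
    """RWC cannot be computed (no pro or anti community / no start nodes)."""


class DisconnectedGraphError(RwcUndefinedError):
    """A start side has no path to any absorbing node."""


def build_retweet_graph(
    events,
    period: int,
    calendar: PeriodCalendar,
    timelines: Mapping[str, StanceTimeline],
    min_degree: int = 1,
    reaction_types: Sequence[str] = ("retweet",),
) -> nx.Graph:
    """Undirected reaction graph for one period, nodes stance-labeled.

    An edge joins two users when either reacted (by default: retweeted) to
    the other inside the period; its ``weight`` is the reaction count.
    Self-reactions are dropped, as are endpoints without a timeline (users
    failing the activity filter).  Nodes with degree below ``min_degree``
    are removed once, not iteratively; the default 1 keeps everything, 30 is
    the depiction preset for "actively sharing" users.
    """
    g = nx.Graph(period=period)
    wanted = set(reaction_types)
    for ev in events:
        if ev.reaction is None or ev.reaction.type not in wanted:
            continue
        if period_index(ev.timestamp, calendar) != period:
            continue
        u, v = ev.user_id, ev.reaction.target_user_id
        if u == v or u not in timelines or v not in timelines:
            continue
        if g.has_edge(u, v):
            g[u][v]["weight"] += 1
        else:
            g.add_edge(u, v, weight=1)
    for node in g.nodes:
        g.nodes[node]["stance"] = timelines[node].stances[period]
    if min_degree > 1:
        drop = [n for n, d in g.degree() if d < min_degree]
        g.remove_nodes_from(drop)
    return g


def label_majority_stance(stance_counts: Mapping[str, int]) -> str:
    """Majority stance of a community; any tie resolves to neutral
    (conservative: never manufactures a pro/anti side out of a tie)."""
    if not stance_counts:
        return NEUTRAL
    best = max(stance_counts.values())
    winners = [s for s in STANCES if stance_counts.get(s, 0) == best]
    return winners[0] if len(winners) == 1 else NEUTRAL


@dataclass(frozen=True)
class CommunityResult:
    partition: dict  # node -> community id (0 = largest)
    sizes: tuple[int, ...]
    community_stances: dict  # community id -> stance, three largest only

    def members(self, cid: int) -> list:
        return sorted(n for n, c in self.partition.items() if c == cid)

    def side_nodes(self, stance: str) -> list:
        for cid, s in self.community_stances.items():
            if s == stance:
                return self.members(cid)
        return []


def detect_communities(graph: nx.Graph, resolution: float = 2.0, seed=None) -> CommunityResult:
    """Louvain partition (default resolution 2) with stance labels on the
    three largest communities."""
    if graph.number_of_nodes() == 0:
        raise ValueError("detect_communities: empty graph")
    comms = nx.algorithms.community.louvain_communities(
        graph, resolution=resolution, seed=seed
    )
    # Deterministic ordering: by size desc, then smallest member id.
    comms = sorted(comms, key=lambda c: (-len(c), min(c)))
    partition = {node: cid for cid, comm in enumerate(comms) for node in comm}
    stances = {}
    for cid, comm in enumerate(comms[:3]):
        counts = Counter(graph.nodes[n]["stance"] for n in comm)
        stances[cid] = label_majority_stance(counts)
    return CommunityResult(partition, tuple(len(c) for c in comms), stances)


@dataclass(frozen=True)
class RwcResult:
    """Absorption probabilities between sides and the controversy score."""

    p_matrix: np.ndarray  # rows: start side (pro, anti); cols: absorbing side
    rwc: float
    k: int
    method: str  # "exact" | "monte_carlo"
    n_walks: int | None = None
    seed: int | None = None
    rwc_se: float | None = None  # Monte-Carlo standard error of rwc
    reachable_fraction: tuple[float, float] = (1.0, 1.0)


def _absorbing_nodes(graph: nx.Graph, side_nodes: Sequence, k: int) -> list:
    # k highest-degree nodes of the side; ties broken by ascending node id
    ranked = sorted(side_nodes, key=lambda n: (-graph.degree(n), n))
    return ranked[:k]


def _neighbor_structure(graph: nx.Graph, nodes: list, weighted: bool):
    index = {n: i for i, n in enumerate(nodes)}
    a = nx.to_scipy_sparse_array(
        graph, nodelist=nodes, weight="weight" if weighted else None, format="csr"
    ).astype(float)
    return index, a


def rwc_between(
    graph: nx.Graph,
    pro_nodes: Sequence,
    anti_nodes: Sequence,
    k: int = 10,
    method: str = "exact",
    n_walks: int = 100_000,
    seed: int | None = None,
    weighted: bool = False,
    max_steps: int = 100_000,
) -> RwcResult:
    """RWC between two explicit node sides on an arbitrary graph.

    ``pro_nodes``/``anti_nodes`` are the two community node sets; every other
    node (e.g. a neutral community) is traversable but never absorbing.
    Walks start uniformly at random from the non-absorbing nodes of the
    start side and hop to a uniformly random neighbor (degree-weighted by
    edge weight when ``weighted``).  ``method="exact"`` solves the absorbing
    Markov chain linear system; ``"monte_carlo"`` samples ``n_walks`` walks
    per side.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    pro_nodes, anti_nodes = list(pro_nodes), list(anti_nodes)
    if set(pro_nodes) & set(anti_nodes):
        raise ValueError("pro and anti sides must be disjoint")
    if not pro_nodes or not anti_nodes:
        raise RwcUndefinedError("both a pro and an anti side are required")
    absorb_pro = _absorbing_nodes(graph, pro_nodes, k)
    absorb_anti = _absorbing_nodes(graph, anti_nodes, k)
    absorbing = set(absorb_pro) | set(absorb_anti)
    starts = [
        [n for n in side if n not in absorbing] for side in (pro_nodes, anti_nodes)
    ]
    for side_name, pool in zip((PRO, ANTI), starts):
        if not pool:
            raise RwcUndefinedError(
                f"no non-absorbing start nodes on the {side_name} side (k too large?)"
            )
    nodes = sorted(graph.nodes())
    index, adj = _neighbor_structure(graph, nodes, weighted)
    n = len(nodes)
    absorb_side = np.full(n, -1, dtype=np.int64)
    for node in absorb_pro:
        absorb_side[index[node]] = 0
    for node in absorb_anti:
        absorb_side[index[node]] = 1
    start_idx = [np.array([index[u] for u in pool], dtype=np.int64) for pool in starts]

    if method == "exact":
        p_matrix, reach = _rwc_exact(adj, absorb_side, start_idx)
        result_walks, se = None, None
    elif method == "monte_carlo":
        p_matrix, reach, se = _rwc_monte_carlo(
            adj, absorb_side, start_idx, n_walks, seed, max_steps
        )
        result_walks = n_walks
    else:
        raise ValueError(f"unknown method {method!r}")
    rwc = float(p_matrix[0, 0] * p_matrix[1, 1] - p_matrix[0, 1] * p_matrix[1, 0])
    return RwcResult(
        p_matrix=p_matrix, rwc=rwc, k=k, method=method, n_walks=result_walks,
        seed=seed, rwc_se=se, reachable_fraction=reach,
    )


def _rwc_exact(adj: sp.csr_array, absorb_side: np.ndarray, start_idx):
    n = adj.shape[0]
    # Nodes in connected components without any absorbing node can never be
    # absorbed; they get zero mass (and would make I - Q singular).
    n_comp, comp = sp.csgraph.connected_components(adj, directed=False)
    good_comps = np.zeros(n_comp, dtype=bool)
    good_comps[comp[absorb_side >= 0]] = True
    solvable = good_comps[comp] & (absorb_side < 0)
    transient = np.flatnonzero(solvable)
    pos = np.full(n, -1, dtype=np.int64)
    pos[transient] = np.arange(len(transient))
    deg = np.asarray(adj.sum(axis=1)).ravel()
    deg_safe = np.where(deg > 0, deg, 1.0)
    # Row-normalized transitions restricted to transient rows.
    p_full = (sp.diags(1.0 / deg_safe) @ adj).tocsr()
    q = p_full[transient][:, transient]
    r_pro = np.asarray(p_full[transient][:, absorb_side == 0].sum(axis=1)).ravel()
    r_anti = np.asarray(p_full[transient][:, absorb_side == 1].sum(axis=1)).ravel()
    rhs = np.column_stack([r_pro, r_anti])
    lhs = sp.eye(len(transient), format="csc") - q.tocsc()
    x_solved = spla.spsolve(lhs, rhs)
    x_solved = np.asarray(x_solved).reshape(rhs.shape)
    x = np.zeros((n, 2))
    x[transient] = x_solved
    p_matrix = np.zeros((2, 2))
    reach = [1.0, 1.0]
    for side in (0, 1):
        mass = x[start_idx[side]]  # (n_start, 2) absorption masses
        total = mass.sum(axis=1)
        reachable = total > 1e-9
        reach[side] = float(reachable.mean())
        if not reachable.any():
            raise DisconnectedGraphError(
                f"start side {('pro', 'anti')[side]} cannot reach any absorbing node"
            )
        # Pooled conditioning: uniform start over the pool, condition the
        # walk on eventual absorption (matches the Monte-Carlo estimator).
        p_matrix[side] = mass.sum(axis=0) / total.sum()
    return p_matrix, (reach[0], reach[1])


def _rwc_monte_carlo(adj: sp.csr_array, absorb_side, start_idx, n_walks, seed, max_steps):
    rng = np.random.default_rng(seed)
    indptr, indices = adj.indptr, adj.indices
    deg = np.diff(indptr)
    weighted = not np.allclose(adj.data, 1.0)
    if weighted:
        # per-node cumulative weights for weighted neighbor sampling
        cumw = np.copy(adj.data)
        for i in range(len(deg)):
            if deg[i]:
                cumw[indptr[i]:indptr[i + 1]] = np.cumsum(adj.data[indptr[i]:indptr[i + 1]])
    p_matrix = np.zeros((2, 2))
    reach = [1.0, 1.0]
    absorbed_counts = np.zeros((2, 2), dtype=np.int64)
    for side in (0, 1):
        cur = rng.choice(start_idx[side], size=n_walks, replace=True)
        active = np.ones(n_walks, dtype=bool)
        # walks starting on zero-degree nodes can never be absorbed
        active &= deg[cur] > 0
        for _ in range(max_steps):
            if not active.any():
                break
            idx = np.flatnonzero(active)
            c = cur[idx]
            if weighted:
                row_tot = cumw[indptr[c] + deg[c] - 1]
                r = rng.random(len(c)) * row_tot
                offs = np.empty(len(c), dtype=np.int64)
                for ii, node in enumerate(c):  # pragma: no cover - weighted path
                    offs[ii] = np.searchsorted(
                        cumw[indptr[node]:indptr[node] + deg[node]], r[ii], side="left"
                    )
                nxt = indices[indptr[c] + offs]
            else:
                nxt = indices[indptr[c] + rng.integers(0, deg[c])]
            cur[idx] = nxt
            landed = absorb_side[nxt] >= 0
            if landed.any():
                li = idx[landed]
                sides = absorb_side[cur[li]]
                absorbed_counts[side, 0] += int((sides == 0).sum())
                absorbed_counts[side, 1] += int((sides == 1).sum())
                active[li] = False
            dead = deg[cur[idx]] == 0
            if dead.any():
                active[idx[dead]] = False
        total = absorbed_counts[side].sum()
        reach[side] = float(total / n_walks)
        if total == 0:
            raise DisconnectedGraphError(
                f"start side {('pro', 'anti')[side]} produced no absorbed walks"
            )
        p_matrix[side] = absorbed_counts[side] / total
    # rows sum to 1, so rwc = P_pp + P_aa - 1 and its variance is the sum of
    # the two binomial variances
    var = 0.0
    for side in (0, 1):
        p = p_matrix[side, side]
        var += p * (1 - p) / absorbed_counts[side].sum()
    return p_matrix, (reach[0], reach[1]), float(np.sqrt(var))


def modified_rwc(
    graph: nx.Graph,
    communities: CommunityResult,
    k: int = 10,
    method: str = "exact",
    n_walks: int = 100_000,
    seed: int | None = None,
    weighted: bool = False,
) -> RwcResult:
    """RWC between the pro- and anti-labeled communities of a partition.

    Raises :class:`RwcUndefinedError` when the three largest communities do
    not include both a pro- and an anti-labeled one.
    """
    pro_nodes = communities.side_nodes(PRO)
    anti_nodes = communities.side_nodes(ANTI)
    if not pro_nodes or not anti_nodes:
        raise RwcUndefinedError("partition lacks a pro- or anti-labeled community")
    return rwc_between(
        graph, pro_nodes, anti_nodes, k=k, method=method, n_walks=n_walks,
        seed=seed, weighted=weighted,
    )


def rwc_series(
    events,
    timelines: Mapping[str, StanceTimeline],
    calendar: PeriodCalendar,
    k: int = 10,
    resolution: float = 2.0,
    method: str = "exact",
    n_walks: int = 100_000,
    seed: int | None = None,
    min_degree: int = 1,
) -> pd.DataFrame:
    """One RWC per period; undefined periods are recorded, not fatal.

    Returns a frame with columns ``period, rwc, p_pp, p_aa, n_nodes,
    n_edges, status`` where status is ``ok`` or the failure reason.
    """
    rows = []
    for period in range(calendar.n_periods):
        g = build_retweet_graph(events, period, calendar, timelines, min_degree=min_degree)
        row = {
            "period": period,
            "n_nodes": g.number_of_nodes(),
            "n_edges": g.number_of_edges(),
            "rwc": np.nan,
            "p_pp": np.nan,
            "p_aa": np.nan,
            "status": "ok",
        }
        try:
            if g.number_of_nodes() == 0:
                raise RwcUndefinedError("empty graph")
            comms = detect_communities(g, resolution=resolution, seed=seed)
            res = modified_rwc(g, comms, k=k, method=method, n_walks=n_walks, seed=seed)
            row.update(rwc=res.rwc, p_pp=res.p_matrix[0, 0], p_aa=res.p_matrix[1, 1])
        except RwcUndefinedError as exc:
            row["status"] = f"undefined: {exc}"
        rows.append(row)
    return pd.DataFrame(rows)


def write_graph(graph: nx.Graph, path, partition: Mapping | None = None) -> None:
    """Whitespace edge list plus a ``.nodes`` sidecar (node, stance, community)."""
    nx.write_weighted_edgelist(graph, path)
    with open(str(path) + ".nodes", "w", encoding="utf-8") as fh:
        for node in sorted(graph.nodes()):
            comm = partition.get(node, -1) if partition else -1
            fh.write(f"{node} {graph.nodes[node].get('stance', '?')} {comm}\n")
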