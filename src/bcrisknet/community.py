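"""Newman modularity and Louvain-style greedy modularity maximization.

Modularity of a partition C of an undirected unweighted graph with m edges:

    Q = sum_c [ e_c / m  -  (d_c / 2m)^2 ]

where e_c counts intra-community edges and d_c the total degree of community
c.  Q lies in [-1, 1]; the single-community partition always scores 0.

``louvain`` runs the classic two-phase heuristic (greedy local moves until no
gain, then community aggregation, repeated) from several seeded random node
orders and keeps the best partition.  ``brute_force_best_partition``
enumerates all set partitions of graphs with at most 12 nodes and is the
exact oracle the heuristic is tested against.

Isolated nodes are legal: each becomes its own community and contributes
nothing to either modularity term.
"""

from __future__ import annotations

import itertools
import math
import random
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd
from sklearn.base import BaseEstimator

from .graphs import WOMAN_PREFIX

__all__ = [
    "Partition",
    "CommunityProfile",
    "modularity",
    "louvain",
    "LouvainCommunities",
    "brute_force_best_partition",
    "summarize_communities",
]


class UndefinedModularityError(ValueError):
    """Modularity is undefined on an edgeless graph."""


@dataclass
class Partition:
    """A node -> community-label mapping together with its modularity Q."""

    membership: dict
    q: float

    def communities(self) -> dict:
        out: dict = {}
        for node, c in self.membership.items():
            out.setdefault(c, set()).add(node)
        return out

    def n_communities(self) -> int:
        return len(set(self.membership.values()))

    def relabeled(self) -> "Partition":
        """Canonical labels 0..k-1 in order of first appearance."""
        seen: dict = {}
        new = {}
        for node in self.membership:
            c = self.membership[node]
            if c not in seen:
                seen[c] = len(seen)
            new[node] = seen[c]
        return Partition(new, self.q)


@dataclass
class CommunityProfile:
    """Per-community summary: women count and the characteristics it absorbed."""

    label: object
    n_women: int
    characteristics: list
    women: list = field(default_factory=list)


def modularity(graph: nx.Graph, membership: dict, resolution: float = 1.0) -> float:
    """Newman modularity of ``membership`` on ``graph`` (unweighted)."""
    m = graph.number_of_edges()
    if m == 0:
        raise UndefinedModularityError("modularity is undefined on an edgeless graph")
    uncovered = [n for n in graph.nodes if n not in membership]
    if uncovered:
        raise ValueError(f"partition misses {len(uncovered)} nodes, e.g. {uncovered[0]!r}")
    e = {}
    d = {}
    for node in graph.nodes:
        d[membership[node]] = d.get(membership[node], 0) + graph.degree(node)
    for u, v in graph.edges:
        if membership[u] == membership[v]:
            e[membership[u]] = e.get(membership[u], 0) + 1
    q = 0.0
    for c, dc in d.items():
        q += e.get(c, 0) / m - resolution * (dc / (2.0 * m)) ** 2
    return q


# ---------------------------------------------------------------------------
# Louvain


def _one_level(adj, degree, m2, membership, order, rng, resolution):
    """Greedy local moves until no move improves Q. Returns True if anything moved."""
    comm_tot = {}
    for node, c in membership.items():
        comm_tot[c] = comm_tot.get(c, 0.0) + degree[node]
    improved = False
    moved = True
    while moved:
        moved = False
        rng.shuffle(order)
        for node in order:
            c_old = membership[node]
            ki = degree[node]
            # weights from node to each neighbouring community
            links = {}
            for nbr, w in adj[node].items():
                if nbr != node:
                    links[membership[nbr]] = links.get(membership[nbr], 0.0) + w
            comm_tot[c_old] -= ki
            best_c, best_gain = c_old, links.get(c_old, 0.0) - resolution * comm_tot[c_old] * ki / m2
            for c, kin in links.items():
                if c == c_old:
                    continue
                gain = kin - resolution * comm_tot[c] * ki / m2
                if gain > best_gain + 1e-12:
                    best_gain, best_c = gain, c
            comm_tot[best_c] = comm_tot.get(best_c, 0.0) + ki
            if best_c != c_old:
                membership[node] = best_c
                moved = True
                improved = True
    return improved


def _aggregate(adj, membership):
    """Collapse communities into super-nodes; self-loops keep intra weight."""
    new_adj: dict = {}
    for u, nbrs in adj.items():
        cu = membership[u]
        row = new_adj.setdefault(cu, {})
        for v, w in nbrs.items():
            cv = membership[v]
            row[cv] = row.get(cv, 0.0) + w
    return new_adj


def _build_adj(graph):
    # adjacency with weights; undirected edges appear in both rows,
    # self-loops (from aggregation) count their weight twice in the degree.
    adj = {n: {} for n in graph.nodes}
    for u, v in graph.edges:
        adj[u][v] = adj[u].get(v, 0.0) + 1.0
        if u != v:
            adj[v][u] = adj[v].get(u, 0.0) + 1.0
        else:
            adj[u][v] += 1.0
    return adj


def _multilevel(base_adj, m2, rng, resolution, init=None):
    """One full local-move + aggregation cascade.

    ``init`` seeds the first level's membership (defaults to singletons);
    passing a previous partition restarts the cascade from it at original
    node granularity, which un-sticks nodes frozen inside aggregated
    super-nodes.
    """
    adj = base_adj
    if init is None:
        membership = {n: i for i, n in enumerate(adj)}
    else:
        membership = dict(init)
    current = None
    prev_q = None
    while True:
        degree = {n: sum(nbrs.values()) for n, nbrs in adj.items()}
        order = list(adj)
        improved = _one_level(adj, degree, m2, membership, order, rng, resolution)
        q = _partition_quality(adj, degree, m2, membership, resolution)
        if prev_q is not None:
            # the heuristic only accepts gain moves, so Q must not decrease
            assert q >= prev_q - 1e-9, "Louvain pass decreased modularity"
        prev_q = q
        if current is None:
            current = dict(membership)
        else:
            current = {n: membership[current[n]] for n in current}
        if not improved:
            break
        adj = _aggregate(adj, membership)
        membership = {n: i for i, n in enumerate(adj)}
        if len(adj) == 1:
            break
    return current, prev_q


def _louvain_once(graph, rng, resolution):
    base_adj = _build_adj(graph)
    m2 = 2.0 * graph.number_of_edges()
    membership, q = _multilevel(base_adj, m2, rng, resolution)
    # repeat whole cascades from the found partition until no move (at any
    # granularity) increases Q; guards against nodes trapped by aggregation
    while True:
        membership2, q2 = _multilevel(base_adj, m2, rng, resolution, init=membership)
        if q2 <= q + 1e-12:
            break
        membership, q = membership2, q2
    return membership, q


def _partition_quality(adj, degree, m2, membership, resolution):
    if m2 == 0:
        return 0.0
    intra = {}
    tot = {}
    for n, nbrs in adj.items():
        c = membership[n]
        tot[c] = tot.get(c, 0.0) + degree[n]
        for v, w in nbrs.items():
            if membership[v] == c:
                intra[c] = intra.get(c, 0.0) + w  # counts both directions
    q = 0.0
    for c in tot:
        q += intra.get(c, 0.0) / m2 - resolution * (tot[c] / m2) ** 2
    return q


def louvain(
    graph: nx.Graph,
    seed: int = 0,
    restarts: int = 10,
    resolution: float = 1.0,
) -> Partition:
    """Best-of-``restarts`` Louvain partition of an undirected simple graph.

    Each restart shuffles the node order with its own stream derived from
    ``seed``; ties in local moves break toward the first best-gain community
    encountered under that order, which makes the result reproducible for a
    given seed.  The reported Q is recomputed from the returned membership
    with :func:`modularity`.
    """
    if graph.number_of_edges() == 0:
        raise UndefinedModularityError("cannot detect communities on an edgeless graph")
    best = None
    for r in range(restarts):
        rng = random.Random(1000003 * int(seed) + r)
        membership, _ = _louvain_once(graph, rng, resolution)
        q = modularity(graph, membership, resolution=1.0)
        if best is None or q > best.q + 1e-12:
            best = Partition(dict(membership), q)
    return best.relabeled()


class LouvainCommunities(BaseEstimator):
    """Clustering estimator detecting modularity communities on a graph.

    Parameters
    ----------
    seed : int
        Base seed for the shuffled node orders.
    restarts : int
        Independent restarts; the max-Q partition is kept.
    resolution : float
        Resolution of the modularity gain used in local moves (Q itself is
        always reported at resolution 1).

    Attributes
    ----------
    partition_ : Partition
    labels_ : dict  node -> community label
    modularity_ : float
    """

    def __init__(self, seed: int = 0, restarts: int = 10, resolution: float = 1.0):
        self.seed = seed
        self.restarts = restarts
        self.resolution = resolution

    def fit(self, X: nx.Graph, y=None):
        self.partition_ = louvain(
            X, seed=self.seed, restarts=self.restarts, resolution=self.resolution
        )
        self.labels_ = self.partition_.membership
        self.modularity_ = self.partition_.q
        return self

    def fit_predict(self, X: nx.Graph, y=None) -> dict:
        return self.fit(X).labels_


# ---------------------------------------------------------------------------
# exact oracle


def _set_partitions(items):
    """All set partitions, as lists of blocks (restricted-growth enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in _set_partitions(rest):
        for i in range(len(smaller)):
            yield smaller[:i] + [smaller[i] + [first]] + smaller[i + 1:]
        yield [[first]] + smaller


def brute_force_best_partition(graph: nx.Graph, max_nodes: int = 12) -> Partition:
    """Exact maximum-modularity partition by enumerating all set partitions.

    Refuses graphs above ``max_nodes`` (Bell numbers explode).  Ties in Q
    (within 1e-12) break toward fewer communities.
    """
    n = graph.number_of_nodes()
    if n > max_nodes:
        raise ValueError(
            f"brute force limited to {max_nodes} nodes, graph has {n}"
        )
    if graph.number_of_edges() == 0:
        raise UndefinedModularityError("modularity is undefined on an edgeless graph")
    nodes = list(graph.nodes)
    best_q = -math.inf
    best_blocks = None
    for blocks in _set_partitions(nodes):
        membership = {n: i for i, block in enumerate(blocks) for n in block}
        q = modularity(graph, membership)
        if q > best_q + 1e-12 or (
            abs(q - best_q) <= 1e-12
            and best_blocks is not None
            and len(blocks) < len(best_blocks)
        ):
            best_q = q
            best_blocks = blocks
    membership = {n: i for i, block in enumerate(best_blocks) for n in block}
    return Partition(membership, best_q).relabeled()


def summarize_communities(graph: nx.Graph, partition: Partition) -> list:
    """Per-community women counts and absorbed characteristic nodes."""
    profiles = []
    for label, members in sorted(
        partition.communities().items(), key=lambda kv: str(kv[0])
    ):
        women = sorted(
            str(n)[len(WOMAN_PREFIX):]
            for n in members
            if graph.nodes[n].get("kind") == "woman"
        )
        chars = sorted(
            str(n) for n in members if graph.nodes[n].get("kind") == "characteristic"
        )
        profiles.append(
            CommunityProfile(
                label=label, n_women=len(women), characteristics=chars, women=women
            )
        )
    return profiles


def partition_to_frame(graph: nx.Graph, partition: Partition) -> pd.DataFrame:
    """Flat (node, kind, community) frame for CSV export."""
    rows = [
        {
            "node": n,
            "kind": graph.nodes[n].get("kind", ""),
            "community": partition.membership[n],
        }
        for n in graph.nodes
    ]
    return pd.DataFrame(rows)
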