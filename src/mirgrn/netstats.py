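"""Centrality, random-walk community detection, and cross-group comparison.

Graphs are treated as undirected and unweighted: the reported centralities
(degree and within-component normalized closeness) ignore the regulatory
direction of miRNA-target edges.  Community detection implements the
random-walk agglomerative method: node distances derive from t-step random
walk profiles, adjacent communities are merged greedily by the Ward-style
criterion, and the partition maximizing modularity along the merge sequence
is reported.  Network comparison operates on the shared (miRNA family,
reference gene) interaction namespace via Jaccard similarity; the
intersection itself is the list of conserved interactions (exact pairwise
network alignment).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np


def degree_centrality(g: nx.Graph) -> dict[str, int]:
    """Node degree: number of incident edges (all edge kinds counted)."""
    return {n: int(d) for n, d in g.degree()}


def closeness_centrality(g: nx.Graph) -> dict[str, float]:
    """Within-component closeness: c(v) = (r-1) / sum of distances to the
    r-1 reachable nodes; isolated nodes get 0."""
    return {n: float(c) for n, c in nx.closeness_centrality(g, wf_improved=False).items()}


def modularity(g: nx.Graph, partition: dict) -> float:
    """Newman modularity Q = (1/2m) sum_ij (A_ij - k_i k_j / 2m) [c_i = c_j]."""
    m = g.number_of_edges()
    if m == 0:
        raise ValueError("modularity undefined for an edgeless graph")
    missing = set(g.nodes) - set(partition)
    if missing:
        raise ValueError(f"partition does not cover nodes: {sorted(missing)[:3]}")
    q = 0.0
    two_m = 2.0 * m
    for c in set(partition.values()):
        nodes = [n for n in g.nodes if partition[n] == c]
        internal = sum(1 for a, b in g.edges(nodes) if partition[a] == c and partition[b] == c)
        deg_sum = sum(g.degree(n) for n in nodes)
        q += internal / m - (deg_sum / two_m) ** 2
    return q


@dataclass
class CommunityPartition:
    membership: dict           # node -> community id at the chosen cut
    merges: list               # ordered (community_a, community_b) merges
    q_per_cut: list            # modularity after 0, 1, 2, ... merges
    chosen_cut: int            # merge count of the reported partition

    @property
    def n_communities(self) -> int:
        return len(set(self.membership.values()))


def walktrap_communities(g: nx.Graph, t: int = 4) -> CommunityPartition:
    """Random-walk agglomerative community detection.

    With transition matrix P = D^-1 A, the distance between nodes i, j is
    r_ij = sqrt( sum_k (P^t_ik - P^t_jk)^2 / d(k) ); communities start as
    singletons and the adjacent pair minimizing the Ward-style merge cost
    delta sigma = (1/n) * |C1||C2|/(|C1|+|C2|) * r_C1C2^2 is merged at each
    step, where a community's walk profile is the mean of its members'.
    Merges never cross connected components (non-adjacent pairs are never
    considered); the reported cut maximizes modularity over the merge
    sequence.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    nodes = list(g.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    a = nx.to_numpy_array(g, nodelist=nodes, dtype=float)
    deg = a.sum(axis=1)
    walkers = deg > 0
    inv_d = np.where(walkers, 1.0 / np.where(deg > 0, deg, 1.0), 0.0)

    p = a * inv_d[:, None]
    pt = np.linalg.matrix_power(p, t) if walkers.any() else p

    # community state: id -> (member indices, profile, size)
    comm_members = {i: [i] for i in range(n)}
    comm_profile = {i: pt[i].copy() for i in range(n)}
    adjacency = {i: set() for i in range(n)}
    for u, v in g.edges:
        iu, iv = idx[u], idx[v]
        if iu != iv:
            adjacency[iu].add(iv)
            adjacency[iv].add(iu)

    w = np.where(walkers, inv_d, 0.0)   # 1/d(k) weights; isolates excluded

    def merge_cost(c1: int, c2: int) -> float:
        diff = comm_profile[c1] - comm_profile[c2]
        r2 = float(np.sum(diff * diff * w))
        s1, s2 = len(comm_members[c1]), len(comm_members[c2])
        return (s1 * s2 / (s1 + s2)) * r2 / n

    def current_partition() -> dict:
        return {nodes[i]: cid for cid, members in comm_members.items() for i in members}

    merges: list[tuple[int, int]] = []
    has_edges = g.number_of_edges() > 0
    q_per_cut = [modularity(g, current_partition())] if has_edges else [0.0]
    best_q, best_cut, best_partition = q_per_cut[0], 0, current_partition()

    while True:
        candidates = [
            (merge_cost(c1, c2), c1, c2)
            for c1 in comm_members
            for c2 in adjacency[c1]
            if c1 < c2
        ]
        if not candidates:
            break
        _, c1, c2 = min(candidates, key=lambda x: (x[0], x[1], x[2]))
        s1, s2 = len(comm_members[c1]), len(comm_members[c2])
        comm_profile[c1] = (s1 * comm_profile[c1] + s2 * comm_profile[c2]) / (s1 + s2)
        comm_members[c1].extend(comm_members[c2])
        del comm_profile[c2], comm_members[c2]
        adjacency[c1] = (adjacency[c1] | adjacency[c2]) - {c1, c2}
        for other in adjacency[c2]:
            adjacency[other].discard(c2)
            if other != c1:
                adjacency[other].add(c1)
        del adjacency[c2]
        merges.append((c1, c2))
        part = current_partition()
        q = modularity(g, part) if has_edges else 0.0
        q_per_cut.append(q)
        if q > best_q + 1e-12:
            best_q, best_cut, best_partition = q, len(merges), part

    # relabel communities densely and deterministically
    order = {}
    membership = {}
    for node in nodes:
        cid = best_partition[node]
        if cid not in order:
            order[cid] = len(order)
        membership[node] = order[cid]
    return CommunityPartition(membership, merges, q_per_cut, best_cut)


@dataclass
class NetworkComparison:
    group_a: str
    group_b: str
    jaccard: float
    conserved_count: int
    conserved: list = field(default_factory=list)   # the aligned interactions


def jaccard_similarity(
    edges_a: set, edges_b: set, *, group_a: str = "A", group_b: str = "B"
) -> NetworkComparison:
    """Jaccard similarity and conserved-interaction count of two interaction
    sets in the shared (family, reference gene) namespace."""
    inter = edges_a & edges_b
    union = edges_a | edges_b
    j = len(inter) / len(union) if union else 1.0
    return NetworkComparison(group_a, group_b, j, len(inter), sorted(inter))
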