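"""Signed community detection on weighted co-occurrence networks.

The partition quality is the signed modularity

    Q = (w+ / (w+ + w-)) * Q+  -  (w- / (w+ + w-)) * Q-

where Q+ and Q- are ordinary (weighted, resolution-gamma) modularities of
the positive- and negative-edge subgraphs and w+/w- their total weight.
Within-cluster positive edges raise Q; within-cluster negative edges lower
it, so positive and negative links carry equal importance when
gamma_pos = gamma_neg = 1.  Optimization is spin-glass-style simulated
annealing with restarts, the number of clusters unconstrained; an exact
enumeration oracle is provided for small graphs.

Cluster indices are 1-based and ordered by prevalence: cluster 1 carries the
largest total relative reads (falls back to node count when no abundances
are supplied), ties broken by the smallest member id.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .errors import DataError
from .otutable import OtuTable

__all__ = [
    "ClusterPartition",
    "signed_modularity",
    "spinglass_cluster",
    "exhaustive_best_partition",
    "cluster_abundances",
    "order_clusters",
]


@dataclass
class ClusterPartition:
    membership: dict  # node -> 1-based cluster index, ordered by prevalence
    modularity: float
    abundances: pd.DataFrame | None = None  # samples x clusters summed rel. reads

    @property
    def n_clusters(self) -> int:
        return max(self.membership.values()) if self.membership else 0

    def members(self, cluster: int) -> list:
        return [n for n, c in self.membership.items() if c == cluster]


class _EdgeData:
    """Edge arrays and strength vectors for fast Q evaluation."""

    def __init__(self, network: nx.Graph):
        self.nodes = list(network.nodes)
        index = {n: i for i, n in enumerate(self.nodes)}
        self.p = len(self.nodes)
        ei, ej, ew = [], [], []
        for u, v, d in network.edges(data=True):
            if u == v:
                continue
            ei.append(index[u])
            ej.append(index[v])
            ew.append(float(d.get("weight", 1.0)))
        self.ei = np.array(ei, dtype=np.intp)
        self.ej = np.array(ej, dtype=np.intp)
        self.ew = np.array(ew, dtype=float)
        pos = self.ew > 0
        neg = self.ew < 0
        self.wp = self.ew[pos]
        self.wn = -self.ew[neg]
        self.pi, self.pj = self.ei[pos], self.ej[pos]
        self.ni, self.nj = self.ei[neg], self.ej[neg]
        self.s_pos = np.bincount(self.pi, self.wp, self.p) + np.bincount(
            self.pj, self.wp, self.p
        )
        self.s_neg = np.bincount(self.ni, self.wn, self.p) + np.bincount(
            self.nj, self.wn, self.p
        )
        self.w_pos = float(self.wp.sum())
        self.w_neg = float(self.wn.sum())

    @property
    def n_edges(self) -> int:
        return len(self.ew)


def _q_of(labels: np.ndarray, ed: _EdgeData, gp: float, gn: float) -> float:
    total = ed.w_pos + ed.w_neg
    if total == 0:
        return 0.0
    k = int(labels.max()) + 1
    q_pos = q_neg = 0.0
    if ed.w_pos > 0:
        within = labels[ed.pi] == labels[ed.pj]
        in_pos = np.bincount(labels[ed.pi[within]], ed.wp[within], k)
        d_pos = np.bincount(labels, ed.s_pos, k)
        q_pos = float(in_pos.sum() / ed.w_pos - gp * ((d_pos / (2 * ed.w_pos)) ** 2).sum())
    if ed.w_neg > 0:
        within = labels[ed.ni] == labels[ed.nj]
        in_neg = np.bincount(labels[ed.ni[within]], ed.wn[within], k)
        d_neg = np.bincount(labels, ed.s_neg, k)
        q_neg = float(in_neg.sum() / ed.w_neg - gn * ((d_neg / (2 * ed.w_neg)) ** 2).sum())
    return (ed.w_pos * q_pos - ed.w_neg * q_neg) / total


def signed_modularity(
    network: nx.Graph,
    membership: dict,
    gamma_pos: float = 1.0,
    gamma_neg: float = 1.0,
) -> float:
    """Q of a given partition; every network node must be assigned."""
    ed = _EdgeData(network)
    missing = [n for n in ed.nodes if n not in membership]
    if missing:
        raise DataError(f"partition missing nodes: {missing[:5]}")
    uniq = {c: i for i, c in enumerate(sorted(set(membership[n] for n in ed.nodes)))}
    labels = np.array([uniq[membership[n]] for n in ed.nodes], dtype=np.intp)
    return _q_of(labels, ed, gamma_pos, gamma_neg)


def _relabel(labels: np.ndarray) -> np.ndarray:
    _, out = np.unique(labels, return_inverse=True)
    return out.astype(np.intp)


class _MoveState:
    """Incremental signed-modularity state for single-node moves.

    Keeps per-cluster strength sums and the within-cluster edge totals so
    the Q change of moving one node costs O(degree) instead of O(edges).
    """

    def __init__(self, ed: _EdgeData, labels: np.ndarray,
                 gp: float, gn: float):
        self.ed = ed
        self.gp, self.gn = gp, gn
        self.total = ed.w_pos + ed.w_neg
        # adjacency lists split by sign
        self.nbr: list = [[] for _ in range(ed.p)]
        for i, j, w in zip(ed.ei, ed.ej, ed.ew):
            self.nbr[i].append((int(j), float(w)))
            self.nbr[j].append((int(i), float(w)))
        self.reset(labels)

    def reset(self, labels: np.ndarray) -> None:
        ed = self.ed
        self.labels = _relabel(labels)
        k = int(self.labels.max()) + 1 if ed.p else 0
        size = max(2 * k + 2, 8)
        self.d_pos = np.zeros(size)
        self.d_neg = np.zeros(size)
        np.add.at(self.d_pos, self.labels, ed.s_pos)
        np.add.at(self.d_neg, self.labels, ed.s_neg)
        within_p = self.labels[ed.pi] == self.labels[ed.pj]
        within_n = self.labels[ed.ni] == self.labels[ed.nj]
        self.in_pos = float(ed.wp[within_p].sum())
        self.in_neg = float(ed.wn[within_n].sum())

    def q(self) -> float:
        if self.total == 0:
            return 0.0
        pos = self.in_pos
        neg = self.in_neg
        if self.ed.w_pos > 0:
            pos -= self.gp * float((self.d_pos**2).sum()) / (4 * self.ed.w_pos)
        if self.ed.w_neg > 0:
            neg -= self.gn * float((self.d_neg**2).sum()) / (4 * self.ed.w_neg)
        return (pos - neg) / self.total

    def _links_to(self, i: int, n_clusters: int):
        """Summed positive/negative weight from node i into each cluster."""
        kp = np.zeros(n_clusters)
        kn = np.zeros(n_clusters)
        lab = self.labels
        for j, w in self.nbr[i]:
            if w > 0:
                kp[lab[j]] += w
            else:
                kn[lab[j]] -= w
        return kp, kn

    def delta_q(self, i: int, kp, kn, target: int) -> float:
        """Q change of moving node i to ``target`` (may be an empty slot)."""
        ed, lab = self.ed, self.labels
        a = lab[i]
        if target == a:
            return 0.0
        sp, sn = ed.s_pos[i], ed.s_neg[i]
        d_in = (kp[target] - kp[a]) - (kn[target] - kn[a])
        dq = d_in
        if ed.w_pos > 0:
            d_sq = 2 * sp * sp + 2 * sp * (self.d_pos[target] - (self.d_pos[a] - sp) - sp)
            dq -= self.gp * d_sq / (4 * ed.w_pos)
        if ed.w_neg > 0:
            d_sq = 2 * sn * sn + 2 * sn * (self.d_neg[target] - (self.d_neg[a] - sn) - sn)
            dq += self.gn * d_sq / (4 * ed.w_neg)
        return dq / self.total if self.total else 0.0

    def apply(self, i: int, kp, kn, target: int) -> None:
        ed, lab = self.ed, self.labels
        a = lab[i]
        self.in_pos += kp[target] - kp[a]
        self.in_neg += kn[target] - kn[a]
        self.d_pos[a] -= ed.s_pos[i]
        self.d_neg[a] -= ed.s_neg[i]
        self.d_pos[target] += ed.s_pos[i]
        self.d_neg[target] += ed.s_neg[i]
        lab[i] = target
        if target >= len(self.d_pos) - 1:
            self.d_pos = np.append(self.d_pos, np.zeros(8))
            self.d_neg = np.append(self.d_neg, np.zeros(8))

    def n_slots(self) -> int:
        return int(self.labels.max()) + 2  # existing clusters + one empty


def _local_opt(labels, ed: _EdgeData, gp, gn, rng):
    """Greedy single-node moves (to any existing cluster or a fresh one)
    until no move improves Q."""
    st = _MoveState(ed, labels, gp, gn)
    best_q = st.q()
    improved = True
    while improved:
        improved = False
        for i in rng.permutation(ed.p):
            n_slots = st.n_slots()
            kp, kn = st._links_to(i, n_slots)
            deltas = np.array([st.delta_q(i, kp, kn, c) for c in range(n_slots)])
            c = int(np.argmax(deltas))
            if deltas[c] > 1e-12:
                st.apply(i, kp, kn, c)
                best_q += deltas[c]
                improved = True
    return _relabel(st.labels), st.q()


def _anneal_once(ed: _EdgeData, gp, gn, rng, t0, cooling, n_temps, sweeps):
    labels = _relabel(rng.integers(0, max(2, ed.p // 2 + 1), size=ed.p))
    st = _MoveState(ed, labels, gp, gn)
    q = st.q()
    best_labels, best_q = st.labels.copy(), q
    t = t0
    for _ in range(n_temps):
        for _ in range(sweeps * ed.p):
            i = rng.integers(ed.p)
            n_slots = st.n_slots()
            new = int(rng.integers(n_slots))
            if new == st.labels[i]:
                continue
            kp, kn = st._links_to(i, n_slots)
            dq = st.delta_q(i, kp, kn, new)
            if dq >= 0 or rng.random() < np.exp(dq / t):
                st.apply(i, kp, kn, new)
                q += dq
                if q > best_q:
                    best_q, best_labels = q, _relabel(st.labels)
        t *= cooling
    return best_labels, best_q


def spinglass_cluster(
    network: nx.Graph,
    gamma_pos: float = 1.0,
    gamma_neg: float = 1.0,
    n_restarts: int = 5,
    t0: float = 1.0,
    cooling: float = 0.9,
    n_temps: int = 30,
    sweeps: int = 2,
    seed: int = 0,
    otu_weights: pd.Series | None = None,
) -> ClusterPartition:
    """Simulated-annealing signed clustering, best of ``n_restarts`` kept.

    Each restart anneals from a random labelling with geometric cooling and
    finishes with a greedy local pass.  ``otu_weights`` (total relative reads
    per node) orders the clusters by prevalence.  Seeded and reproducible.
    """
    if network.number_of_nodes() == 0:
        raise DataError("empty network")
    ed = _EdgeData(network)
    rng = np.random.default_rng(seed)
    if ed.n_edges == 0:
        membership = {n: i + 1 for i, n in enumerate(ed.nodes)}
        part = ClusterPartition(membership=membership, modularity=0.0)
        return order_clusters(part, otu_weights)

    best_labels, best_q = None, -np.inf
    for _ in range(max(1, n_restarts)):
        labels, _ = _anneal_once(ed, gamma_pos, gamma_neg, rng, t0, cooling,
                                 n_temps, sweeps)
        labels, q = _local_opt(labels, ed, gamma_pos, gamma_neg, rng)
        if q > best_q:
            best_q, best_labels = q, labels

    membership = {n: int(c) + 1 for n, c in zip(ed.nodes, best_labels)}
    part = ClusterPartition(membership=membership, modularity=float(best_q))
    return order_clusters(part, otu_weights)


def exhaustive_best_partition(
    network: nx.Graph, gamma_pos: float = 1.0, gamma_neg: float = 1.0
) -> tuple[dict, float]:
    """Exact optimum by enumerating all set partitions (small graphs only)."""
    ed = _EdgeData(network)
    if ed.p > 12:
        raise DataError("exhaustive search limited to <= 12 nodes")
    best_q, best = -np.inf, None

    def rec(prefix: list):
        nonlocal best_q, best
        if len(prefix) == ed.p:
            labels = np.array(prefix, dtype=np.intp)
            q = _q_of(labels, ed, gamma_pos, gamma_neg)
            if q > best_q:
                best_q, best = q, labels.copy()
            return
        m = max(prefix) if prefix else -1
        for c in range(m + 2):
            rec(prefix + [c])

    rec([])
    membership = {n: int(c) + 1 for n, c in zip(ed.nodes, best)}
    return membership, float(best_q)


def order_clusters(
    partition: ClusterPartition, otu_weights: pd.Series | None
) -> ClusterPartition:
    """Renumber clusters 1..k by descending prevalence (total relative reads;
    node count if no weights), ties by smallest member id."""
    clusters = sorted(set(partition.membership.values()))
    keys = []
    for c in clusters:
        members = sorted(str(n) for n, cc in partition.membership.items() if cc == c)
        if otu_weights is not None:
            w = float(
                sum(
                    otu_weights.get(n, 0.0)
                    for n, cc in partition.membership.items()
                    if cc == c
                )
            )
        else:
            w = float(len(members))
        keys.append((-w, members[0], c))
    order = [c for _, _, c in sorted(keys)]
    remap = {c: i + 1 for i, c in enumerate(order)}
    return ClusterPartition(
        membership={n: remap[c] for n, c in partition.membership.items()},
        modularity=partition.modularity,
        abundances=None,
    )


def cluster_abundances(partition: ClusterPartition, table: OtuTable) -> pd.DataFrame:
    """Per-sample relative reads summed within clusters (columns = cluster 1..k)."""
    missing = [o for o in partition.membership if o not in set(table.otu_ids)]
    if missing:
        raise DataError(f"partition OTUs missing from table: {missing[:5]}")
    rel = table.relative()
    cols = {}
    for c in range(1, partition.n_clusters + 1):
        members = partition.members(c)
        cols[c] = rel[members].sum(axis=1)
    return pd.DataFrame(cols)
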