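"""Degree-preserving rewiring null models and empirical p-values.

Rewiring uses repeated double edge swaps, which keep every node's degree
exactly while randomizing the wiring; the original multiset of signed edge
weights is then randomly permuted onto the new edge set, so the weight
distribution is preserved too.  Empirical p-values follow the one-tailed
convention "proportion of randomized statistics smaller than the observed";
ties count as not smaller, and the complementary tail is reported alongside
so callers can test either direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .clustering import cluster_abundances, signed_modularity, spinglass_cluster
from .errors import DataError
from .otutable import OtuTable

logger = logging.getLogger(__name__)

__all__ = [
    "RewiredEnsemble",
    "rewire_preserving_degrees",
    "null_modularity_test",
    "null_coupling_correlation_test",
]

DEFAULT_N_SWAPS_PER_EDGE = 10
DEFAULT_R = 1000


@dataclass
class RewiredEnsemble:
    observed: float
    values: np.ndarray  # per-replicate statistic
    R: int
    p_lower: float  # proportion of replicates strictly smaller than observed
    p_upper: float  # 1 - p_lower (ties counted in the upper tail)
    seed: int
    warning: str | None = field(default=None)

    @classmethod
    def from_values(cls, observed, values, seed, warning=None):
        values = np.asarray(values, dtype=float)
        R = len(values)
        p_lower = float((values < observed).sum() / R)
        return cls(
            observed=float(observed),
            values=values,
            R=R,
            p_lower=p_lower,
            p_upper=1.0 - p_lower,
            seed=seed,
            warning=warning,
        )


def rewire_preserving_degrees(
    network: nx.Graph,
    n_swaps_per_edge: int = DEFAULT_N_SWAPS_PER_EDGE,
    seed: int = 0,
) -> nx.Graph:
    """Double-edge-swap rewiring with the weight multiset permuted onto the
    new edges.  Degree sequence is preserved exactly; simple graph guaranteed.
    Networks too small to swap are returned as annotated copies."""
    m = network.number_of_edges()
    out = nx.Graph()
    out.add_nodes_from(network.nodes)
    out.add_edges_from(network.edges(data=True))
    if m < 2:
        out.graph["rewire_warning"] = "too few edges to swap"
        logger.warning("rewire: %d edge(s), returning copy", m)
        return out
    rng = np.random.default_rng(seed)
    nswap = n_swaps_per_edge * m
    try:
        nx.double_edge_swap(
            out, nswap=nswap, max_tries=100 * nswap, seed=int(rng.integers(2**31))
        )
    except nx.NetworkXError as exc:  # e.g. all swaps blocked
        out.graph["rewire_warning"] = str(exc)
        logger.warning("rewire: %s", exc)
    weights = [d["weight"] for _, _, d in network.edges(data=True)]
    perm = rng.permutation(len(weights))
    for (u, v), k in zip(out.edges(), perm):
        out[u][v]["weight"] = weights[k]
    return out


def _check_degrees(original: nx.Graph, rewired: nx.Graph) -> None:
    do = dict(original.degree())
    dr = dict(rewired.degree())
    if do != dr:
        raise DataError("rewiring changed the degree sequence")


def null_modularity_test(
    network: nx.Graph,
    R: int = DEFAULT_R,
    seed: int = 0,
    n_swaps_per_edge: int = DEFAULT_N_SWAPS_PER_EDGE,
    cluster_kwargs: dict | None = None,
) -> RewiredEnsemble:
    """Observed signed modularity against R rewired replicates.

    Each replicate is rewired, re-clustered from scratch, and its Q recorded;
    p_lower is the proportion of replicate Qs strictly below the observed.
    """
    if R < 1:
        raise DataError("R must be >= 1")
    kwargs = dict(cluster_kwargs or {})
    part = spinglass_cluster(network, seed=seed, **kwargs)
    observed = part.modularity
    values = []
    for r in range(R):
        rw = rewire_preserving_degrees(network, n_swaps_per_edge, seed=seed + 1 + r)
        _check_degrees(network, rw)
        values.append(spinglass_cluster(rw, seed=seed + 1 + r, **kwargs).modularity)
    return RewiredEnsemble.from_values(observed, values, seed)


def null_coupling_correlation_test(
    prok_network: nx.Graph,
    fungal_network: nx.Graph,
    prok_table: OtuTable,
    fungal_table: OtuTable,
    R: int = DEFAULT_R,
    seed: int = 0,
    n_swaps_per_edge: int = DEFAULT_N_SWAPS_PER_EDGE,
    family_alpha: float = 0.05,
    denominator: str = "clusters",
    grouping=None,
    cluster_kwargs: dict | None = None,
) -> RewiredEnsemble:
    """Count of significant prokaryote-fungal cluster correlations against
    rewired replicates (both networks rewired, clusters re-detected,
    abundances and the Bonferroni-corrected correlation count recomputed)."""
    from .coupling import count_significant_cross_correlations

    if R < 1:
        raise DataError("R must be >= 1")
    kwargs = dict(cluster_kwargs or {})

    def statistic(pn, fn, s):
        pw = prok_table.relative().sum(axis=0)
        fw = fungal_table.relative().sum(axis=0)
        pp = spinglass_cluster(pn, seed=s, otu_weights=pw, **kwargs)
        fp = spinglass_cluster(fn, seed=s, otu_weights=fw, **kwargs)
        pa = cluster_abundances(pp, prok_table)
        fa = cluster_abundances(fp, fungal_table)
        return count_significant_cross_correlations(
            pa, fa, grouping=grouping, family_alpha=family_alpha,
            denominator=denominator,
        )

    observed = statistic(prok_network, fungal_network, seed)
    values = []
    for r in range(R):
        s = seed + 1 + r
        pn = rewire_preserving_degrees(prok_network, n_swaps_per_edge, seed=s)
        fn = rewire_preserving_degrees(fungal_network, n_swaps_per_edge, seed=s + 10_000_019)
        _check_degrees(prok_network, pn)
        _check_degrees(fungal_network, fn)
        values.append(statistic(pn, fn, s))
    return RewiredEnsemble.from_values(observed, values, seed)
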