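"""Signed co-occurrence network inference from clr-transformed counts.

Neighborhood selection fits, per OTU, an L1-penalized regression of its clr
abundance on all other OTUs; the union ("or" rule) of the two directed
coefficients defines an undirected edge whose weight is the coefficient of
larger magnitude, sign kept.  The penalty is chosen by stability selection
(StARS): over subsamples of the data, edge-selection frequencies theta give
per-edge instabilities 2*theta*(1-theta); the mean instability curve is
monotonized along the path and the densest penalty whose monotonized
instability stays below the threshold is selected, with a final refit on the
full data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.linear_model import lasso_path

from .errors import DataError

logger = logging.getLogger(__name__)

__all__ = [
    "StarsPath",
    "mb_neighborhood_selection",
    "stars_select",
    "lambda_max",
    "write_edge_list",
]

DEFAULT_BETA_THRESHOLD = 0.05
DEFAULT_N_LAMBDA = 20
DEFAULT_N_SUBSAMPLES = 999
DEFAULT_SUBSAMPLE_FRACTION = 0.8
LAMBDA_MIN_RATIO = 0.01


@dataclass
class StarsPath:
    """Stability-selection diagnostics along the penalty path."""

    lambdas: np.ndarray  # descending penalties
    densities: np.ndarray  # full-data edge density per lambda
    instability: np.ndarray  # D(lambda), mean per-edge instability
    monotonized: np.ndarray  # running max of D as lambda decreases
    selected_lambda: float
    beta_threshold: float
    n_subsamples: int
    threshold_met: bool
    edge_frequencies: dict = field(default_factory=dict, repr=False)


def _as_matrix(clr) -> tuple[np.ndarray, list]:
    if isinstance(clr, pd.DataFrame):
        return clr.to_numpy(dtype=float), list(clr.columns)
    arr = np.asarray(clr, dtype=float)
    return arr, list(range(arr.shape[1]))


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center/scale columns; constant columns become all-zero (isolated)."""
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    ok = sd > 0
    Z = np.zeros_like(X)
    Z[:, ok] = (X[:, ok] - mu[ok]) / sd[ok]
    return Z, ok


def lambda_max(clr) -> float:
    """Smallest penalty shrinking every neighborhood to zero: the largest
    absolute pairwise correlation (on standardized columns, the MB grid top)."""
    X, _ = _as_matrix(clr)
    Z, _ = _standardize(X)
    n = Z.shape[0]
    G = np.abs(Z.T @ Z) / n
    np.fill_diagonal(G, 0.0)
    return float(G.max())


def _neighborhood_coefs(Z: np.ndarray, lambdas: np.ndarray) -> np.ndarray:
    """Lasso coefficients for every node along the penalty path.

    Returns array (n_lambda, p, p): coefs[l, j, i] = effect of node i in the
    regression of node j.  Penalties on the sklearn scale (objective
    (1/2n)||y - Xb||^2 + lambda ||b||_1) over standardized columns.
    """
    n, p = Z.shape
    out = np.zeros((len(lambdas), p, p))
    order = np.argsort(lambdas)[::-1]
    lams_desc = lambdas[order]
    for j in range(p):
        if not Z[:, j].any():
            continue
        others = np.delete(np.arange(p), j)
        _, coefs, _ = lasso_path(Z[:, others], Z[:, j], alphas=lams_desc,
                                 max_iter=2000)
        # coefs: (n_features, n_alphas) in the order given
        for li, lam_i in enumerate(order):
            out[lam_i, j, others] = coefs[:, li]
    return out


def _symmetrize(coefs_jp: np.ndarray, nodes: list) -> nx.Graph:
    """Union rule: edge if either directed coefficient is nonzero; weight is
    the larger-magnitude coefficient with its sign."""
    p = coefs_jp.shape[0]
    g = nx.Graph()
    g.add_nodes_from(nodes)
    a, b = coefs_jp, coefs_jp.T
    mag = np.where(np.abs(a) >= np.abs(b), a, b)
    sel = (a != 0) | (b != 0)
    ii, jj = np.nonzero(np.triu(sel, k=1))
    for i, j in zip(ii, jj):
        g.add_edge(nodes[i], nodes[j], weight=float(mag[i, j]))
    return g


def mb_neighborhood_selection(clr, lam: float) -> nx.Graph:
    """Neighborhood-selection network at a single penalty.

    At ``lam == 0`` with n > p, each neighborhood is the ordinary
    least-squares partial regression.  Constant clr columns are isolated with
    a warning.
    """
    X, nodes = _as_matrix(clr)
    n, p = X.shape
    if n < 4:
        raise DataError("need >= 4 samples for neighborhood selection")
    if lam < 0:
        raise DataError("lambda must be >= 0")
    Z, ok = _standardize(X)
    if not ok.all():
        logger.warning("isolating %d constant clr columns", int((~ok).sum()))
    if lam == 0:
        if n <= p:
            raise DataError("lambda = 0 requires n > p")
        coefs = np.zeros((p, p))
        for j in range(p):
            if not ok[j]:
                continue
            others = np.delete(np.arange(p), j)
            beta, *_ = np.linalg.lstsq(Z[:, others], Z[:, j], rcond=None)
            coefs[j, others] = beta
        coefs[np.abs(coefs) < 1e-12] = 0.0
        return _symmetrize(coefs, nodes)
    coefs = _neighborhood_coefs(Z, np.array([lam]))[0]
    return _symmetrize(coefs, nodes)


def _edge_indicator(coefs_jp: np.ndarray) -> np.ndarray:
    sel = (coefs_jp != 0) | (coefs_jp.T != 0)
    return np.triu(sel, k=1)


def stars_select(
    clr,
    n_lambda: int = DEFAULT_N_LAMBDA,
    beta_threshold: float = DEFAULT_BETA_THRESHOLD,
    n_subsamples: int = DEFAULT_N_SUBSAMPLES,
    subsample_fraction: float = DEFAULT_SUBSAMPLE_FRACTION,
    seed: int = 0,
) -> tuple[StarsPath, nx.Graph]:
    """StARS penalty selection for the neighborhood-selection network.

    The grid is ``n_lambda`` log-spaced penalties from lambda_max down to
    1% of it.  Per subsample (fraction drawn without replacement) the full
    path is fit; D(lambda) averages per-edge instabilities over all p(p-1)/2
    possible edges.  Selection takes the smallest penalty whose monotonized
    D stays <= the threshold (the densest stable graph); if none qualifies
    the sparsest penalty is returned with ``threshold_met=False``.
    """
    if n_subsamples < 2:
        raise DataError("n_subsamples must be >= 2")
    if not 0 < subsample_fraction < 1:
        raise DataError("subsample_fraction must be in (0, 1)")
    X, nodes = _as_matrix(clr)
    n, p = X.shape
    lmax = lambda_max(clr)
    if lmax <= 0:
        raise DataError("degenerate data: lambda_max = 0")
    lambdas = np.geomspace(lmax, LAMBDA_MIN_RATIO * lmax, n_lambda)

    rng = np.random.default_rng(seed)
    b = max(4, int(np.floor(subsample_fraction * n)))
    freq = np.zeros((n_lambda, p, p))
    for _ in range(n_subsamples):
        idx = rng.choice(n, size=b, replace=False)
        Z, _ = _standardize(X[idx])
        coefs = _neighborhood_coefs(Z, lambdas)
        for li in range(n_lambda):
            freq[li] += _edge_indicator(coefs[li])
    freq /= n_subsamples

    n_pairs = p * (p - 1) / 2
    inst = np.array(
        [(2 * freq[li] * (1 - freq[li])).sum() / n_pairs for li in range(n_lambda)]
    )
    mono = np.maximum.accumulate(inst)
    feasible = np.nonzero(mono <= beta_threshold)[0]
    if len(feasible):
        sel_idx = int(feasible[-1])  # smallest feasible penalty = densest
        met = True
    else:
        sel_idx = 0
        met = False
        logger.warning("StARS: no penalty met threshold %g; returning sparsest",
                       beta_threshold)

    Zfull, _ = _standardize(X)
    coefs_full = _neighborhood_coefs(Zfull, lambdas)
    densities = np.array(
        [_edge_indicator(coefs_full[li]).sum() / n_pairs for li in range(n_lambda)]
    )
    network = _symmetrize(coefs_full[sel_idx], nodes)
    path = StarsPath(
        lambdas=lambdas,
        densities=densities,
        instability=inst,
        monotonized=mono,
        selected_lambda=float(lambdas[sel_idx]),
        beta_threshold=beta_threshold,
        n_subsamples=n_subsamples,
        threshold_met=met,
    )
    return path, network


def write_edge_list(network: nx.Graph, path) -> None:
    rows = [
        {"node_i": u, "node_j": v, "weight": d["weight"]}
        for u, v, d in network.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["node_i", "node_j", "weight"]).to_csv(
        path, sep="\t", index=False
    )
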