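"""Weighted co-expression hypergraph construction.

Genes are nodes and samples are hyperedges.  A gene belongs to a sample's
hyperedge when its standardized expression in that sample is extreme enough
(|z| >= tau); the hyperedge weight summarizes how strongly the member genes
co-vary, either as the mean of |Pearson correlation|^beta over member pairs
(the soft-thresholded scheme) or as the mean pairwise mutual information.

The correlation entering a hyperedge weight is always the global correlation
of the two genes across *all* samples; hyperedges differ because their member
sets differ.  With ``tau = 0`` every gene joins every hyperedge, all weights
coincide and the resulting network carries no contrast — the thresholded
membership (default ``tau = 1``) is what makes the hypergraph informative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class WeightedHypergraph:
    """Binary incidence structure plus per-hyperedge weights.

    ``incidence`` is the genes x hyperedges 0/1 matrix H with
    ``incidence[v, e] = 1`` iff gene v belongs to hyperedge e.  Every
    hyperedge has at least two member genes and every node belongs to at
    least one hyperedge; construction enforces both.
    """

    incidence: np.ndarray
    edge_weights: np.ndarray
    node_ids: list[str]
    edge_ids: list[str]

    def __post_init__(self) -> None:
        self.incidence = np.asarray(self.incidence, dtype=float)
        self.edge_weights = np.asarray(self.edge_weights, dtype=float)
        n, m = self.incidence.shape
        if len(self.node_ids) != n or len(self.edge_ids) != m:
            raise ValueError("incidence shape does not match identifiers")
        if self.edge_weights.shape != (m,):
            raise ValueError("one weight per hyperedge required")
        if not set(np.unique(self.incidence)) <= {0.0, 1.0}:
            raise ValueError("incidence matrix must be binary")
        if (self.incidence.sum(axis=0) < 2).any():
            raise ValueError("every hyperedge must contain at least 2 nodes")
        if (self.incidence.sum(axis=1) < 1).any():
            raise ValueError("every node must belong to at least 1 hyperedge")
        if not np.all(np.isfinite(self.edge_weights)) or (self.edge_weights < 0).any():
            raise ValueError("edge weights must be finite and nonnegative")

    @property
    def n_nodes(self) -> int:
        return self.incidence.shape[0]

    @property
    def n_edges(self) -> int:
        return self.incidence.shape[1]

    def edge_members(self, e: int) -> np.ndarray:
        """Indices of the genes in hyperedge ``e``."""
        return np.where(self.incidence[:, e] > 0)[0]


@dataclass
class HyperedgeWeightReport:
    """Correlation-based vs mutual-information-based hyperedge weights."""

    corr_weights: np.ndarray
    mi_weights: np.ndarray
    spearman_rho: float  # NaN when either weight vector is constant
    spearman_p: float


def build_incidence(Z: ExpressionMatrix, tau: float = 1.0) -> WeightedHypergraph:
    """Threshold standardized expression into hypergraph membership.

    Gene v joins the hyperedge of sample s iff ``|z_vs| >= tau``.  Hyperedges
    with fewer than two members are dropped with a warning, and genes left in
    no surviving hyperedge are dropped with a warning.  Weights are
    initialized to 1.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    H = (np.abs(Z.values) >= tau).astype(float)
    edge_ok = H.sum(axis=0) >= 2
    if not edge_ok.all():
        dropped = [e for e, ok in zip(Z.sample_ids, edge_ok) if not ok]
        logger.warning("dropping %d hyperedges with < 2 members: %s", len(dropped), dropped)
    if not edge_ok.any():
        raise ValueError(f"all hyperedges dropped at tau={tau}; choose a smaller tau")
    H = H[:, edge_ok]
    edge_ids = [e for e, ok in zip(Z.sample_ids, edge_ok) if ok]
    node_ok = H.sum(axis=1) >= 1
    if not node_ok.all():
        dropped_nodes = [g for g, ok in zip(Z.gene_ids, node_ok) if not ok]
        logger.warning("dropping %d isolated genes: %s", len(dropped_nodes), dropped_nodes)
    H = H[node_ok]
    node_ids = [g for g, ok in zip(Z.gene_ids, node_ok) if ok]
    return WeightedHypergraph(H, np.ones(H.shape[1]), node_ids, edge_ids)


def _align_rows(X: ExpressionMatrix, hg: WeightedHypergraph) -> np.ndarray:
    """Rows of X matching the hypergraph nodes, in node order."""
    index = {g: i for i, g in enumerate(X.gene_ids)}
    missing = [g for g in hg.node_ids if g not in index]
    if missing:
        raise ValueError(f"hypergraph nodes absent from expression matrix: {missing}")
    return X.values[[index[g] for g in hg.node_ids]]


def abs_correlation(X: ExpressionMatrix, method: str = "pearson") -> np.ndarray:
    """Genes x genes |correlation| across all samples."""
    if method == "pearson":
        C = np.corrcoef(X.values)
    elif method == "spearman":
        ranks = stats.rankdata(X.values, axis=1)
        C = np.corrcoef(ranks)
    else:
        raise ValueError(f"unknown correlation method: {method!r}")
    return np.abs(C)


def _mean_pair_value(S: np.ndarray, hg: WeightedHypergraph) -> np.ndarray:
    """Per-hyperedge mean of a symmetric pair score over member gene pairs.

    S must be symmetric with a constant diagonal equal to ``S[0, 0]``'s
    self-score; the diagonal is excluded analytically.
    """
    weights = np.empty(hg.n_edges)
    for e in range(hg.n_edges):
        members = hg.edge_members(e)
        m = members.size
        if m < 2:
            raise ValueError(f"hyperedge {hg.edge_ids[e]} has no gene pairs")
        block = S[np.ix_(members, members)]
        weights[e] = (block.sum() - np.trace(block)) / (m * (m - 1))
    return weights


def hyperedge_weights_corr(
    X: ExpressionMatrix,
    hg: WeightedHypergraph,
    beta: int = 1,
    method: str = "pearson",
    corr: np.ndarray | None = None,
) -> WeightedHypergraph:
    """Soft-thresholded correlation weights: mean of |corr|^beta over pairs.

    ``corr`` may pass a precomputed |correlation| matrix (aligned to
    ``hg.node_ids``) so that a scan over beta computes it only once.
    Weights land in [0, 1].
    """
    if beta < 1 or int(beta) != beta:
        raise ValueError("beta must be a positive integer")
    if corr is None:
        rows = _align_rows(X, hg)
        corr = abs_correlation(
            ExpressionMatrix(rows, list(hg.node_ids), list(X.sample_ids)), method
        )
    W = _mean_pair_value(corr**beta, hg)
    return replace(hg, edge_weights=W)


def _bin_labels(values: np.ndarray, bins: int) -> np.ndarray:
    """Equal-width bin index per entry of a 1-D array."""
    lo, hi = values.min(), values.max()
    if hi == lo:
        raise ValueError("constant gene values: equal-width binning undefined")
    edges = np.linspace(lo, hi, bins + 1)
    return np.clip(np.digitize(values, edges[1:-1]), 0, bins - 1)


def pairwise_mutual_information(values: np.ndarray, bins: int = 8) -> np.ndarray:
    """Plug-in mutual information (nats) for every row pair of ``values``.

    Each row is discretized into ``bins`` equal-width bins across samples;
    the MI of a pair is computed from the joint contingency table.
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    G, n = values.shape
    labels = np.stack([_bin_labels(values[i], bins) for i in range(G)])
    # indicator tensor: for each gene a bins x n one-hot matrix
    ind = np.zeros((G, bins, n))
    rows = np.repeat(np.arange(G), n)
    ind[rows, labels.ravel(), np.tile(np.arange(n), G)] = 1.0
    flat = ind.reshape(G * bins, n)
    joint = (flat @ flat.T).reshape(G, bins, G, bins) / n
    marg = ind.sum(axis=2) / n  # G x bins
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = joint / (marg[:, :, None, None] * marg[None, None, :, :])
        term = np.where(joint > 0, joint * np.log(ratio), 0.0)
    mi = term.sum(axis=(1, 3))
    return np.maximum(mi, 0.0)


def hyperedge_weights_mi(
    X: ExpressionMatrix, hg: WeightedHypergraph, bins: int = 8
) -> np.ndarray:
    """Mean pairwise mutual information per hyperedge (nats, >= 0)."""
    rows = _align_rows(X, hg)
    mi = pairwise_mutual_information(rows, bins)
    return _mean_pair_value(mi, hg)


def compare_weight_schemes(
    X: ExpressionMatrix,
    hg: WeightedHypergraph,
    beta: int = 1,
    bins: int = 8,
) -> HyperedgeWeightReport:
    """Spearman agreement between correlation- and MI-based hyperedge weights."""
    if hg.n_edges < 5:
        raise ValueError("weight-scheme comparison needs at least 5 hyperedges")
    corr_w = hyperedge_weights_corr(X, hg, beta).edge_weights
    mi_w = hyperedge_weights_mi(X, hg, bins)
    if np.ptp(corr_w) == 0 or np.ptp(mi_w) == 0:
        rho, p = float("nan"), float("nan")
    else:
        rho, p = stats.spearmanr(corr_w, mi_w)
    return HyperedgeWeightReport(corr_w, mi_w, float(rho), float(p))


def node_hyperdegrees(hg: WeightedHypergraph) -> np.ndarray:
    """Weighted hyperdegree d(v) = sum_e W_e h(v, e); the diagonal of Dv."""
    return hg.incidence @ hg.edge_weights


def edge_degrees(hg: WeightedHypergraph) -> np.ndarray:
    """Edge degree delta(e) = number of member genes; the diagonal of De."""
    return hg.incidence.sum(axis=0)


def toy_hypergraph() -> WeightedHypergraph:
    """The 7-node, 4-hyperedge textbook example used throughout the tests.

    e1 = {v1, v2, v3}, e2 = {v3, v5}, e3 = {v5, v6}, e4 = {v4, v7},
    with weights W = (3, 2, 2, 2).  The hypergraph has two connected
    components: {v1, v2, v3, v5, v6} and {v4, v7}.
    """
    H = np.zeros((7, 4))
    for e, members in enumerate([(0, 1, 2), (2, 4), (4, 5), (3, 6)]):
        H[list(members), e] = 1.0
    return WeightedHypergraph(
        H,
        np.array([3.0, 2.0, 2.0, 2.0]),
        [f"v{i}" for i in range(1, 8)],
        [f"e{j}" for j in range(1, 5)],
    )


def write_hypergraph(hg: WeightedHypergraph, edge_list_path: str | Path, weights_path: str | Path) -> None:
    """Serialize as a TSV edge list (edge_id, node_id) plus a weights TSV."""
    rows = [
        {"edge_id": hg.edge_ids[e], "node_id": hg.node_ids[v]}
        for e in range(hg.n_edges)
        for v in hg.edge_members(e)
    ]
    pd.DataFrame(rows).to_csv(edge_list_path, sep="\t", index=False)
    pd.DataFrame(
        {"edge_id": hg.edge_ids, "weight": hg.edge_weights}
    ).to_csv(weights_path, sep="\t", index=False, float_format="%.17g")


def read_hypergraph(edge_list_path: str | Path, weights_path: str | Path) -> WeightedHypergraph:
    """Inverse of :func:`write_hypergraph`; preserves first-seen ordering."""
    edges = pd.read_csv(edge_list_path, sep="\t", dtype=str)
    weights = pd.read_csv(weights_path, sep="\t", dtype={"edge_id": str})
    edge_ids = list(weights["edge_id"])
    node_ids = list(dict.fromkeys(edges["node_id"]))
    node_index = {g: i for i, g in enumerate(node_ids)}
    edge_index = {e: j for j, e in enumerate(edge_ids)}
    H = np.zeros((len(node_ids), len(edge_ids)))
    for e, v in zip(edges["edge_id"], edges["node_id"]):
        H[node_index[v], edge_index[e]] = 1.0
    return WeightedHypergraph(H, weights["weight"].to_numpy(float), node_ids, edge_ids)
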