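"""Soft-threshold selection by scale-free topology of the hyperdegree distribution.

The soft threshold beta is the exponent applied to |correlation| inside the
hyperedge weight aggregation.  Raising beta suppresses weak correlations, and
the resulting node hyperdegree distribution is scanned for approximate
scale-free behaviour: a power-law degree distribution is linear on log-log
axes, so the signed R^2 of a log-log regression of degree density on degree
serves as the fit index.  Following common practice the smallest beta whose
signed R^2 reaches 0.8 is selected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .hypergraph import build_incidence, hyperedge_weights_corr, node_hyperdegrees, abs_correlation
from .io import ExpressionMatrix, standardize

logger = logging.getLogger(__name__)


@dataclass
class SoftThresholdScan:
    """Scale-free fit index and mean hyperdegree per candidate beta."""

    betas: list[int]
    r_squared: np.ndarray  # signed; NaN where undefined
    mean_degree: np.ndarray
    chosen_beta: int | None = None
    below_cut: bool = False
    tau: float = 1.0
    n_bins: int = 10


def scale_free_fit(degrees: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the log-log degree-density regression.

    Degrees are split into ``n_bins`` equal-count (quantile) bins; each
    nonempty bin contributes its mean degree and an empirical density
    (bin count / (n * bin width)).  Least squares of log10 density on
    log10 mean degree gives R^2, and the sign flag ``-sign(slope)`` makes
    the index positive only when density falls with degree (the scale-free
    direction).  Returns NaN when fewer than 3 distinct nonempty bins exist.
    """
    degrees = np.asarray(degrees, dtype=float)
    if degrees.size < 10:
        raise ValueError("scale_free_fit needs at least 10 degrees")
    if n_bins < 3:
        raise ValueError("n_bins must be >= 3")
    if (degrees <= 0).any():
        raise ValueError("degrees must be strictly positive")
    edges = np.unique(np.quantile(degrees, np.linspace(0, 1, n_bins + 1)))
    if edges.size < 4:  # < 3 distinct bins
        return float("nan")
    counts, _ = np.histogram(degrees, bins=edges)
    widths = np.diff(edges)
    keep = (counts > 0) & (widths > 0)
    if keep.sum() < 3:
        return float("nan")
    # mean degree within each kept bin
    idx = np.clip(np.digitize(degrees, edges[1:-1]), 0, edges.size - 2)
    k_mean = np.array([degrees[idx == b].mean() for b in np.where(keep)[0]])
    density = counts[keep] / (degrees.size * widths[keep])
    x = np.log10(k_mean)
    y = np.log10(density)
    if np.ptp(x) == 0:
        return float("nan")
    slope, _ = np.polyfit(x, y, 1)
    r = np.corrcoef(x, y)[0, 1]
    r2 = float(r * r)
    return -np.sign(slope) * r2 if slope != 0 else 0.0


def scan_beta(
    X: ExpressionMatrix,
    tau: float = 1.0,
    betas: list[int] | None = None,
    n_bins: int = 10,
) -> SoftThresholdScan:
    """Scan candidate soft thresholds on a complete expression matrix.

    The incidence is built once (tau fixed) from the standardized matrix and
    the |correlation| matrix is computed once; only the exponent varies
    across the scan.
    """
    betas = list(betas) if betas is not None else list(range(1, 13))
    if not betas:
        raise ValueError("betas must be non-empty")
    Z = standardize(X)
    hg = build_incidence(Z, tau)
    rows_X = ExpressionMatrix(
        X.values[[X.gene_ids.index(g) for g in hg.node_ids]],
        list(hg.node_ids),
        list(X.sample_ids),
    )
    corr = abs_correlation(rows_X)
    r2 = np.empty(len(betas))
    mean_deg = np.empty(len(betas))
    for i, beta in enumerate(betas):
        weighted = hyperedge_weights_corr(rows_X, hg, beta=beta, corr=corr)
        d = node_hyperdegrees(weighted)
        r2[i] = scale_free_fit(d, n_bins)
        mean_deg[i] = d.mean()
    return SoftThresholdScan(betas, r2, mean_deg, tau=tau, n_bins=n_bins)


def pick_beta(scan: SoftThresholdScan, r2_cut: float = 0.8) -> int:
    """Select the smallest beta with signed R^2 >= ``r2_cut`` (inclusive).

    When no beta qualifies, fall back to the beta maximizing signed R^2 and
    mark the scan ``below_cut``.  The choice is recorded on the scan.
    """
    r2 = scan.r_squared
    if np.isnan(r2).all():
        raise ValueError("scale-free fit undefined for every candidate beta")
    qualifying = [i for i, v in enumerate(r2) if not np.isnan(v) and v >= r2_cut]
    if qualifying:
        i = qualifying[0]
        scan.below_cut = False
    else:
        i = int(np.nanargmax(r2))
        scan.below_cut = True
        logger.warning(
            "no beta reaches signed R^2 >= %.3g; falling back to beta=%d (R^2=%.3f)",
            r2_cut, scan.betas[i], r2[i],
        )
    scan.chosen_beta = scan.betas[i]
    return scan.chosen_beta
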