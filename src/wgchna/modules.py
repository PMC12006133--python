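"""Module detection: hierarchical clustering of dissTOM, dynamic cutting,
eigengene computation and merging of similar modules.

Genes are clustered by average-linkage agglomeration on the TOM
dissimilarity.  The dendrogram is cut at a quantile of the merge heights
controlled by ``deepSplit`` (deeper splits cut lower), clusters below
``minClusterSize`` are relabelled as unassigned ("grey", label 0), and
modules whose eigengenes correlate above the merge threshold are iteratively
fused.  The module eigengene is the first principal component of the
standardized module submatrix, sign-oriented against the module mean profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .io import ExpressionMatrix, standardize
from .laplacian import DissTOM

logger = logging.getLogger(__name__)

#: deterministic module palette; label 0 is always grey
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue", "darkred",
    "darkgreen", "darkturquoise", "darkgrey", "orange", "darkorange", "white",
    "skyblue", "saddlebrown", "steelblue", "paleturquoise", "violet",
]

#: deepSplit level -> fraction of the dendrogram height range at which to cut
#: (deeper split cuts lower, refining modules)
DEEPSPLIT_QUANTILE = {0: 0.95, 1: 0.90, 2: 0.85, 3: 0.80}


@dataclass
class DetectionConfig:
    """Knobs of the module detection stage (defaults follow WGCNA practice)."""

    min_cluster_size: int = 50
    deep_split: int = 2
    merge_similarity: float = 0.8
    linkage: str = "average"

    def __post_init__(self) -> None:
        if self.deep_split not in DEEPSPLIT_QUANTILE:
            raise ValueError("deep_split must be in {0, 1, 2, 3}")
        if self.min_cluster_size < 1:
            raise ValueError("min_cluster_size must be >= 1")


@dataclass
class ModuleAssignment:
    """Gene -> module labels (0 = grey/unassigned) plus eigengenes."""

    gene_ids: list[str]
    labels: np.ndarray
    eigengenes: pd.DataFrame | None = None  # samples x ME<label> columns

    @property
    def module_sizes(self) -> dict[int, int]:
        values, counts = np.unique(self.labels, return_counts=True)
        return {int(v): int(c) for v, c in zip(values, counts)}

    @property
    def n_modules(self) -> int:
        """Number of non-grey modules."""
        return int(len([v for v in set(self.labels.tolist()) if v != 0]))

    def colors(self) -> list[str]:
        out = []
        for lab in self.labels:
            if lab == 0:
                out.append("grey")
            else:
                out.append(MODULE_COLORS[(int(lab) - 1) % len(MODULE_COLORS)])
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene_id": self.gene_ids, "module_label": self.labels, "module_color": self.colors()}
        )


def hierarchical_cluster(diss: DissTOM, method: str = "average") -> np.ndarray:
    """Average-linkage dendrogram (SciPy linkage matrix) of a dissimilarity."""
    D = diss.diss
    if not np.all(np.isfinite(D)):
        raise ValueError("dissimilarity contains non-finite entries")
    condensed = squareform(D, checks=False)
    return linkage(condensed, method=method)


def cut_tree_dynamic(
    dend: np.ndarray, cfg: DetectionConfig, n_leaves: int | None = None
) -> np.ndarray:
    """Static-height dynamic cut with minimum module size and grey fallback.

    The tree is cut at the height interpolating the fraction
    ``DEEPSPLIT_QUANTILE[deep_split]`` of the way through the merge-height
    range [min height, max height].  Interpolating the *range* (rather than
    taking a quantile of the merge-height distribution) keeps the cut robust
    to how many merges are internal to modules: with K tight modules only
    K - 1 merges sit above module level, a vanishing fraction of all merges,
    so any count-based quantile would land inside modules and shatter them.
    Clusters smaller than ``min_cluster_size`` become grey (0); survivors are
    renumbered 1, 2, ... by decreasing size (ties broken by the smallest
    member index, which makes the labelling deterministic).
    """
    heights = dend[:, 2]
    q = DEEPSPLIT_QUANTILE[cfg.deep_split]
    cut = float(heights.min() + q * (heights.max() - heights.min()))
    raw = fcluster(dend, t=cut, criterion="distance")
    labels = np.zeros(raw.shape[0], dtype=int)
    clusters = []
    for value in np.unique(raw):
        members = np.where(raw == value)[0]
        if members.size >= cfg.min_cluster_size:
            clusters.append(members)
    if not clusters:
        logger.warning("cut_tree_dynamic: no cluster reaches min size %d; all grey",
                       cfg.min_cluster_size)
        return labels
    clusters.sort(key=lambda m: (-m.size, m.min()))
    for new_label, members in enumerate(clusters, start=1):
        labels[members] = new_label
    return labels


def _standardized_submatrix(X: ExpressionMatrix, member_idx: np.ndarray) -> np.ndarray:
    sub = ExpressionMatrix(
        X.values[member_idx],
        [X.gene_ids[i] for i in member_idx],
        list(X.sample_ids),
    )
    return standardize(sub).values


def module_eigengenes(X: ExpressionMatrix, labels: np.ndarray) -> pd.DataFrame:
    """First principal component per non-grey module, one score per sample.

    Each eigengene is the leading right singular vector of the standardized
    module submatrix (unit norm), sign-oriented so that its correlation with
    the module's mean standardized profile is >= 0.  A singleton module's
    eigengene degenerates to the gene's own standardized profile (normalized).
    """
    if np.isnan(X.values).any():
        raise ValueError("eigengenes require a complete expression matrix")
    module_labels = sorted(v for v in set(labels.tolist()) if v != 0)
    if not module_labels:
        raise ValueError("no non-grey modules present")
    columns = {}
    for lab in module_labels:
        members = np.where(labels == lab)[0]
        Zm = _standardized_submatrix(X, members)
        _, _, vt = np.linalg.svd(Zm, full_matrices=False)
        me = vt[0]
        mean_profile = Zm.mean(axis=0)
        orient = me @ mean_profile
        if orient < 0:
            me = -me
        columns[f"ME{lab}"] = me
    return pd.DataFrame(columns, index=X.sample_ids)


def merge_similar_modules(
    X: ExpressionMatrix,
    labels: np.ndarray,
    merge_similarity: float = 0.8,
) -> np.ndarray:
    """Iteratively fuse module pairs whose eigengene correlation exceeds the cut.

    At each round the pair with the highest eigengene Pearson correlation
    strictly above ``merge_similarity`` is merged (the larger module's label
    wins; size ties go to the smaller label) and eigengenes are recomputed.
    The loop terminates because each merge reduces the module count by one.
    """
    labels = labels.copy()
    while True:
        module_labels = sorted(v for v in set(labels.tolist()) if v != 0)
        if len(module_labels) < 2:
            return labels
        ME = module_eigengenes(X, labels)
        corr = np.corrcoef(ME.to_numpy().T)
        np.fill_diagonal(corr, -np.inf)
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        if corr[i, j] <= merge_similarity:
            return labels
        a, b = module_labels[i], module_labels[j]
        size_a, size_b = int((labels == a).sum()), int((labels == b).sum())
        if size_a > size_b or (size_a == size_b and a < b):
            keep, absorb = a, b
        else:
            keep, absorb = b, a
        logger.info("merging module %d into %d (eigengene corr %.3f)", absorb, keep, corr[i, j])
        labels[labels == absorb] = keep


def renumber_by_size(labels: np.ndarray) -> np.ndarray:
    """Canonical labelling: modules 1, 2, ... by decreasing size; grey stays 0."""
    out = np.zeros_like(labels)
    module_labels = [v for v in set(labels.tolist()) if v != 0]
    sized = sorted(
        module_labels,
        key=lambda v: (-int((labels == v).sum()), int(np.where(labels == v)[0].min())),
    )
    for new, old in enumerate(sized, start=1):
        out[labels == old] = new
    return out


def detect_modules(
    X: ExpressionMatrix,
    diss: DissTOM,
    cfg: DetectionConfig | None = None,
) -> ModuleAssignment:
    """Cluster -> cut -> merge -> renumber, returning the final assignment.

    ``X`` must contain exactly the genes of ``diss`` (same order) and be
    complete; it supplies the expression profiles for eigengene computation.
    """
    cfg = cfg or DetectionConfig()
    if list(X.gene_ids) != list(diss.node_ids):
        raise ValueError("expression matrix and dissTOM gene sets differ")
    dend = hierarchical_cluster(diss, cfg.linkage)
    labels = cut_tree_dynamic(dend, cfg)
    if labels.max() > 0:
        labels = merge_similar_modules(X, labels, cfg.merge_similarity)
        labels = renumber_by_size(labels)
        eigengenes = module_eigengenes(X, labels)
    else:
        eigengenes = None
    assignment = ModuleAssignment(list(X.gene_ids), labels, eigengenes)
    logger.info(
        "detected %d modules (sizes %s); %d genes grey",
        assignment.n_modules,
        {k: v for k, v in assignment.module_sizes.items() if k != 0},
        assignment.module_sizes.get(0, 0),
    )
    return assignment
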