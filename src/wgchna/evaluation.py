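"""Clustering quality metrics.

Internal indices (silhouette, Calinski-Harabasz, Davies-Bouldin) score a
partition against a feature representation of the genes — by default each
gene's row of the TOM matrix, since that is the similarity structure the
clustering was computed on.  External indices (adjusted Rand, adjusted
mutual information) compare a partition to a reference labelling, both
corrected for chance.  Grey (unassigned, label 0) genes are excluded from
internal indices: they are non-clusters by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn import metrics as skm


@dataclass
class ClusteringMetrics:
    """Bundle of internal/external indices; NaN marks an undefined value."""

    si: float = float("nan")
    chi: float = float("nan")
    dbi: float = float("nan")
    ami: float = float("nan")
    ari: float = float("nan")
    feature_space: str = ""

    def to_dict(self) -> dict[str, float]:
        return {"SI": self.si, "CHI": self.chi, "DBI": self.dbi,
                "AMI": self.ami, "ARI": self.ari}


def internal_metrics(
    features: np.ndarray,
    labels: np.ndarray,
    feature_space: str = "tom_rows",
    exclude_grey: bool = True,
) -> ClusteringMetrics:
    """Silhouette, Calinski-Harabasz and Davies-Bouldin on feature rows.

    Euclidean distances on ``features`` rows.  With fewer than two clusters
    after grey exclusion, all three indices are NaN.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if exclude_grey:
        mask = labels != 0
        features, labels = features[mask], labels[mask]
    if len(set(labels.tolist())) < 2 or features.shape[0] < 3:
        return ClusteringMetrics(feature_space=feature_space)
    return ClusteringMetrics(
        si=float(skm.silhouette_score(features, labels, metric="euclidean")),
        chi=float(skm.calinski_harabasz_score(features, labels)),
        dbi=float(skm.davies_bouldin_score(features, labels)),
        feature_space=feature_space,
    )


def external_metrics(
    labels_a: np.ndarray, labels_b: np.ndarray, exclude_grey: bool = False
) -> ClusteringMetrics:
    """Adjusted Rand index and adjusted mutual information between partitions.

    ARI uses the permutation-model contingency formula; AMI uses max-entropy
    normalization with expected-MI correction.  With ``exclude_grey`` genes
    labelled 0 in either partition are dropped before scoring (grey is a
    non-cluster, not a cluster of its own); the default keeps every gene,
    treating grey as one more class.  When both partitions are a single
    cluster, the pair is scored 1 if the labellings are identical as
    partitions and NaN otherwise.
    """
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise ValueError("labelings must cover the same gene set")
    if exclude_grey:
        mask = (labels_a != 0) & (labels_b != 0)
        labels_a, labels_b = labels_a[mask], labels_b[mask]
        if labels_a.size == 0:
            return ClusteringMetrics()
    if len(set(labels_a.tolist())) == 1 and len(set(labels_b.tolist())) == 1:
        return ClusteringMetrics(ami=1.0, ari=1.0)
    return ClusteringMetrics(
        ari=float(skm.adjusted_rand_score(labels_a, labels_b)),
        ami=float(skm.adjusted_mutual_info_score(labels_a, labels_b, average_method="max")),
    )
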