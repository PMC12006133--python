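"""Independent brute-force reference implementations used only by the tests.

Every function here recomputes a quantity from its definition with explicit
loops (or an unrelated library code path), so agreement with the production
code is a genuine dual-route check.
"""

import math

import numpy as np


def naive_edge_weights_corr(values, incidence, beta):
    """Mean |Pearson corr|^beta over unordered gene pairs within each edge."""
    n_genes, _ = values.shape
    n_edges = incidence.shape[1]
    weights = np.empty(n_edges)
    for e in range(n_edges):
        members = [v for v in range(n_genes) if incidence[v, e] > 0]
        total, count = 0.0, 0
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                r = np.corrcoef(values[members[a]], values[members[b]])[0, 1]
                total += abs(r) ** beta
                count += 1
        weights[e] = total / count
    return weights


def naive_laplacians(incidence, edge_weights):
    """Explicit-loop hypergraph Laplacians and affinity."""
    n, m = incidence.shape
    d = np.zeros(n)
    delta = np.zeros(m)
    for v in range(n):
        for e in range(m):
            d[v] += edge_weights[e] * incidence[v, e]
    for e in range(m):
        delta[e] = sum(incidence[v, e] for v in range(n))
    S = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            for e in range(m):
                S[i, j] += incidence[i, e] * edge_weights[e] * incidence[j, e] / delta[e]
    L = np.diag(d) - S
    A_full = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            A_full[i, j] = S[i, j] / math.sqrt(d[i] * d[j])
    Ln = np.eye(n) - A_full
    A = A_full.copy()
    np.fill_diagonal(A, 0.0)
    return L, Ln, A, d


def naive_tom(A):
    """Triple-loop topological overlap of a zero-diagonal affinity matrix."""
    n = A.shape[0]
    d = A.sum(axis=1)
    T = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(A[i, k] * A[k, j] for k in range(n) if k not in (i, j))
            T[i, j] = (A[i, j] + shared) / (min(d[i], d[j]) + 1.0 - A[i, j])
    return np.clip(T, 0.0, 1.0)


def naive_mi_matrix(values, bins):
    """Pairwise plug-in mutual information via explicit contingency tables."""
    G, n = values.shape
    labels = []
    for g in range(G):
        lo, hi = values[g].min(), values[g].max()
        edges = np.linspace(lo, hi, bins + 1)
        labels.append(np.clip(np.digitize(values[g], edges[1:-1]), 0, bins - 1))
    mi = np.zeros((G, G))
    for i in range(G):
        for j in range(G):
            table = np.zeros((bins, bins))
            for s in range(n):
                table[labels[i][s], labels[j][s]] += 1
            P = table / n
            pi, pj = P.sum(axis=1), P.sum(axis=0)
            total = 0.0
            for a in range(bins):
                for b in range(bins):
                    if P[a, b] > 0:
                        total += P[a, b] * math.log(P[a, b] / (pi[a] * pj[b]))
            mi[i, j] = max(total, 0.0)
    return mi


def naive_average_linkage_cophenetic(D):
    """O(n^3) agglomerative average linkage; returns the cophenetic matrix.

    The inter-cluster distance is recomputed from the original matrix as the
    mean over all cross-pairs (the definition of average linkage), so no
    update formula is shared with the implementation under test.
    """
    n = D.shape[0]
    clusters = {i: [i] for i in range(n)}
    coph = np.zeros((n, n))
    next_id = n
    while len(clusters) > 1:
        ids = sorted(clusters)
        best = None
        for x in range(len(ids)):
            for y in range(x + 1, len(ids)):
                a, b = ids[x], ids[y]
                h = np.mean([D[i, j] for i in clusters[a] for j in clusters[b]])
                if best is None or h < best[0]:
                    best = (h, a, b)
        h, a, b = best
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i, j] = coph[j, i] = h
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return coph


def naive_ari(labels_a, labels_b):
    """Pair-counting adjusted Rand index over all O(n^2) pairs."""
    n = len(labels_a)
    a = b = ab = 0
    pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            pairs += 1
            same_a = labels_a[i] == labels_a[j]
            same_b = labels_b[i] == labels_b[j]
            a += same_a
            b += same_b
            ab += same_a and same_b
    expected = a * b / pairs
    max_index = (a + b) / 2.0
    if max_index == expected:
        return 1.0
    return (ab - expected) / (max_index - expected)


def naive_silhouette(X, labels):
    """Mean silhouette from the definition, Euclidean distances."""
    n = X.shape[0]
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    uniq = sorted(set(labels.tolist()))
    scores = []
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            scores.append(0.0)
            continue
        a = np.mean([D[i, j] for j in own])
        b = min(
            np.mean([D[i, j] for j in range(n) if labels[j] == lab])
            for lab in uniq
            if lab != labels[i]
        )
        scores.append((b - a) / max(a, b))
    return float(np.mean(scores))


def naive_calinski_harabasz(X, labels):
    n, _ = X.shape
    uniq = sorted(set(labels.tolist()))
    k = len(uniq)
    overall = X.mean(axis=0)
    between = within = 0.0
    for lab in uniq:
        members = X[np.asarray(labels) == lab]
        centroid = members.mean(axis=0)
        between += len(members) * ((centroid - overall) ** 2).sum()
        within += ((members - centroid) ** 2).sum()
    return float((between / (k - 1)) / (within / (n - k)))


def naive_davies_bouldin(X, labels):
    uniq = sorted(set(labels.tolist()))
    centroids = {lab: X[np.asarray(labels) == lab].mean(axis=0) for lab in uniq}
    scatter = {
        lab: np.mean(
            np.sqrt(((X[np.asarray(labels) == lab] - centroids[lab]) ** 2).sum(-1))
        )
        for lab in uniq
    }
    total = 0.0
    for lab in uniq:
        worst = 0.0
        for other in uniq:
            if other == lab:
                continue
            gap = np.sqrt(((centroids[lab] - centroids[other]) ** 2).sum())
            worst = max(worst, (scatter[lab] + scatter[other]) / gap)
        total += worst
    return float(total / len(uniq))
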