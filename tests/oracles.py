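"""Independent brute-force oracles used by unit and acceptance tests.

Everything here is deliberately naive (enumeration, pairwise loops, direct
formula evaluation) and shares no code with the implementation paths it
checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from dermseg.clustering import kmeans


def exhaustive_two_cluster_optimum(X: np.ndarray) -> float:
    """Minimal within-cluster sum of squares over all 2-partitions."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    best = math.inf
    for bits in range(1, 2**n - 1):
        labels = [(bits >> i) & 1 for i in range(n)]
        wcss = 0.0
        for cluster in (0, 1):
            members = X[[i for i in range(n) if labels[i] == cluster]]
            wcss += ((members - members.mean(axis=0)) ** 2).sum()
        best = min(best, wcss)
    return best


def best_of_pairs_kmeans(X: np.ndarray) -> float:
    """Best K-means inertia over all distinct-point-pair initializations."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    best = math.inf
    for i, j in itertools.combinations(range(X.shape[0]), 2):
        if np.array_equal(X[i], X[j]):
            continue
        res = kmeans(X, K=2, init_centroids=np.stack([X[i], X[j]]))
        best = min(best, res.inertia)
    return best


def mann_whitney_auc(score: np.ndarray, gt: np.ndarray) -> float:
    """P(score_lesion > score_skin) + 0.5 * P(tie) over all pixel pairs."""
    s = np.asarray(score, dtype=float).ravel()
    g = np.asarray(gt).astype(bool).ravel()
    pos, neg = s[g], s[~g]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (pos.size * neg.size)


def brute_force_infer(D: float, size: float, rulebase, c_lo: int = 2, c_hi: int = 40) -> int:
    """Max-min Mamdani inference by direct loops over rules and candidates."""

    def mu(x, fs):
        return math.exp(-((x - fs.center) ** 2) / (2.0 * fs.spread**2))

    sets = {
        "distance": {s.label: s for s in rulebase.distance_sets},
        "size": {s.label: s for s in rulebase.size_sets},
        "cluster": {s.label: s for s in rulebase.cluster_sets},
    }
    best_c, best_q = c_lo, -1.0
    for c in range(c_lo, c_hi + 1):
        q = 0.0
        for dlab, slab, clab in rulebase.rules:
            strength = min(mu(D, sets["distance"][dlab]), mu(size, sets["size"][slab]))
            q = max(q, min(strength, mu(c, sets["cluster"][clab])))
        if q > best_q:
            best_c, best_q = c, q
    return best_c
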