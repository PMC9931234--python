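"""Independent Ward oracles used by unit and acceptance tests.

``greedy_ward_k2`` re-runs agglomerative Ward from scratch, O(n^3),
using the within-cluster sum-of-squares merge increment
``|A||B|/(|A|+|B|) * (mean_A - mean_B)^2`` directly — no linkage-matrix
machinery — and returns the final 2-cluster partition. Any library cut
that matches neither the exhaustive optimum nor this independent greedy
path indicates an implementation bug rather than a greedy limitation.
"""

import numpy as np


def wcss(x, labels):
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels)
    return sum(
        float(np.sum((x[labels == u] - x[labels == u].mean()) ** 2))
        for u in np.unique(labels)
    )


def best_bipartition_wcss(x):
    """Exhaustive minimum WCSS over all 2-partitions (n <= ~16)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    best = np.inf
    for bits in range(1, 2 ** (n - 1)):
        labels = np.array([(bits >> i) & 1 for i in range(n)])
        best = min(best, wcss(x, labels))
    return best


def greedy_ward_k2(x):
    """Independent bottom-up Ward agglomeration; returns the k=2 labels."""
    x = np.asarray(x, dtype=float)
    clusters = [[i] for i in range(x.size)]
    while len(clusters) > 2:
        best_cost, best_pair = np.inf, None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                xa, xb = x[clusters[a]], x[clusters[b]]
                na, nb = xa.size, xb.size
                cost = na * nb / (na + nb) * (xa.mean() - xb.mean()) ** 2
                if cost < best_cost:
                    best_cost, best_pair = cost, (a, b)
        a, b = best_pair
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    labels = np.zeros(x.size, dtype=int)
    labels[clusters[1]] = 1
    return labels
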