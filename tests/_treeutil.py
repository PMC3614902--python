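"""Shared helper: random additive distance matrices from random trees."""

import numpy as np


def random_additive_matrix(rng, n_leaves):
    """Random binary tree by sequential cluster joins.

    Returns (labels, distance matrix, nontrivial clades of the tree); the
    matrix is exactly additive on the generating tree.
    """
    labels = [f"t{i}" for i in range(n_leaves)]
    acc = {lab: 0.0 for lab in labels}
    clusters = [[lab] for lab in labels]
    dist = np.zeros((n_leaves, n_leaves))
    idx = {lab: i for i, lab in enumerate(labels)}
    clades = []
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        la, lb = rng.uniform(0.1, 1.0), rng.uniform(0.1, 1.0)
        A, B = clusters[i], clusters[j]
        for a in A:
            for b in B:
                dist[idx[a], idx[b]] = dist[idx[b], idx[a]] = acc[a] + la + acc[b] + lb
        for a in A:
            acc[a] += la
        for b in B:
            acc[b] += lb
        merged = A + B
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
        if 1 < len(merged) < n_leaves - 1:
            clades.append(frozenset(merged))
    return labels, dist, clades
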