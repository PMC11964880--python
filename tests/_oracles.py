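"""Independent brute-force oracles used to cross-check the implementation."""

import numpy as np


def lloyd_oracle(points, init_centers, max_iter=100, tol=1e-4):
    """Naive Lloyd k-means, written independently of the package.

    Loops over centers explicitly; empty clusters keep their previous
    center.  Same convergence contract as the implementation: stop when
    the largest center movement falls below ``tol``, with one final
    assignment against the converged centers.
    """
    centers = [np.array(c, dtype=float) for c in init_centers]
    k = len(centers)
    n = len(points)
    labels = np.zeros(n, dtype=int)

    def assign():
        dists = np.empty((n, k))
        for j in range(k):
            diff = points - centers[j]
            dists[:, j] = np.einsum("ij,ij->i", diff, diff)
        return dists.argmin(axis=1)

    for _ in range(max_iter):
        labels = assign()
        shift = 0.0
        new_centers = []
        for j in range(k):
            members = points[labels == j]
            c_new = members.mean(axis=0) if len(members) else centers[j]
            shift = max(shift, float(np.linalg.norm(c_new - centers[j])))
            new_centers.append(c_new)
        centers = new_centers
        if shift < tol:
            labels = assign()
            break
    return np.stack(centers), labels


def relabel_to_match(labels_ref, labels_other, k):
    """Best label permutation mapping other -> ref (greedy on overlap)."""
    mapping = {}
    used = set()
    pairs = []
    for j in range(k):
        for m in range(k):
            pairs.append((int(np.sum((labels_other == j) & (labels_ref == m))), j, m))
    for _, j, m in sorted(pairs, reverse=True):
        if j not in mapping and m not in used:
            mapping[j] = m
            used.add(m)
    out = np.full_like(labels_other, -1)
    for j, m in mapping.items():
        out[labels_other == j] = m
    return out
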