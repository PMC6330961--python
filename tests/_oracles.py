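"""Independent brute-force oracles used only by the tests.

These deliberately share no code with the package: the alignment oracle is
a plain-Python dynamic program, the dihedral oracle sums math.cos terms one
angle at a time, the medoid oracle enumerates all candidates, and the Gini
oracle evaluates every possible stump split directly.
"""

import math


def sw_score_naive(a: str, b: str, sub: dict, gap_open: int = 9,
                   gap_extend: int = 1) -> int:
    """Affine-gap Smith-Waterman score; a length-k gap costs open + k*ext.

    ``sub`` maps (residue, residue) -> score.
    """
    n, m = len(a), len(b)
    NEG = -10**9
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i - 1][j] - gap_open - gap_extend,
                          E[i - 1][j] - gap_extend)
            F[i][j] = max(H[i][j - 1] - gap_open - gap_extend,
                          F[i][j - 1] - gap_extend)
            H[i][j] = max(0,
                          H[i - 1][j - 1] + sub[(a[i - 1], b[j - 1])],
                          E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def loop_distance_naive(dihedrals_i, dihedrals_j) -> float:
    """Sum of 2(1-cos(delta)) over phi and psi, one residue at a time."""
    total = 0.0
    for (phi_i, psi_i), (phi_j, psi_j) in zip(dihedrals_i, dihedrals_j):
        total += 2.0 * (1.0 - math.cos(math.radians(phi_i - phi_j)))
        total += 2.0 * (1.0 - math.cos(math.radians(psi_i - psi_j)))
    return total


def medoid_naive(dihedral_lists):
    """Index of the member minimizing the summed distance to all members."""
    best_idx, best_sum = None, None
    for i, di in enumerate(dihedral_lists):
        s = sum(loop_distance_naive(di, dj) for dj in dihedral_lists)
        if best_sum is None or s < best_sum:
            best_idx, best_sum = i, s
    return best_idx


def gini(labels) -> float:
    n = len(labels)
    if n == 0:
        return 0.0
    freqs = {}
    for l in labels:
        freqs[l] = freqs.get(l, 0) + 1
    return 1.0 - sum((c / n) ** 2 for c in freqs.values())


def stump_gini_reductions(X, y):
    """Best node-size-weighted Gini impurity reduction per feature.

    For binary features the only split is 0 vs 1; returns a list of the
    weighted impurity decrease each feature achieves at the root.
    """
    n = len(y)
    parent = gini(y)
    out = []
    for j in range(len(X[0])):
        left = [y[i] for i in range(n) if X[i][j] == 0]
        right = [y[i] for i in range(n) if X[i][j] == 1]
        if not left or not right:
            out.append(0.0)
            continue
        child = (len(left) / n) * gini(left) + (len(right) / n) * gini(right)
        out.append(parent - child)
    return out
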