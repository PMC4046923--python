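"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's dynamic-programming machinery:
the local-alignment oracle enumerates every monotone matching of
residue positions directly, the entropy oracle is a plain double loop,
and the graph oracles recompute distances from scratch.
"""

from itertools import combinations

import numpy as np


def local_align_oracle(seq_a, seq_b, score, gap_open, gap_extend):
    """Optimal local alignment score by exhaustive enumeration.

    Every local alignment corresponds to a non-empty monotone matching
    of positions (i_1 < ... < i_k) -> (j_1 < ... < j_k): matched pairs
    are substitution columns, unmatched residues between consecutive
    matched pairs sit in one deletion run and one insertion run, whose
    minimal affine cost is open + len * extend each (first gap position
    costs open + extend).  Unmatched prefixes/suffixes are free (local
    alignment).  The score of the empty alignment is 0.
    """
    la, lb = len(seq_a), len(seq_b)
    S = np.asarray(score)
    a = np.asarray(seq_a)
    b = np.asarray(seq_b)

    def gap_cost(g):
        return gap_open + gap_extend * g if g > 0 else 0

    best = 0
    for k in range(1, min(la, lb) + 1):
        combos_b = [np.array(c) for c in combinations(range(lb), k)]
        if not combos_b:
            continue
        cb = np.stack(combos_b)  # (nb, k)
        # internal gap costs on the b side depend only on the combo
        gb = np.zeros(len(cb))
        if k > 1:
            gaps = np.diff(cb, axis=1) - 1
            gb = np.where(gaps > 0, gap_open + gap_extend * gaps, 0).sum(axis=1)
        for ca in combinations(range(la), k):
            ca = np.array(ca)
            ga = 0
            if k > 1:
                d = np.diff(ca) - 1
                ga = np.where(d > 0, gap_open + gap_extend * d, 0).sum()
            subst = np.zeros(len(cb))
            for t in range(k):
                subst += S[a[ca[t]], b[cb[:, t]]]
            total = subst - ga - gb
            m = total.max()
            if m > best:
                best = m
    return int(best)


def relative_entropy_oracle(q, c1, c2):
    """Brute-force double loop for sum q log2(q / (c1 c2))."""
    h = 0.0
    for i in range(q.shape[0]):
        for j in range(q.shape[1]):
            if q[i, j] > 0:
                h += q[i, j] * np.log2(q[i, j] / (c1[i] * c2[j]))
    return h


def pair_counts_oracle(rows, weights=None):
    """Weighted residue-pair counts within the columns of a gapless
    block (pairs between different sequences, both orders halved)."""
    n = len(rows)
    width = len(rows[0])
    if weights is None:
        weights = [1.0] * n
    counts = {}
    for col in range(width):
        for i in range(n):
            for j in range(i + 1, n):
                a, b = rows[i][col], rows[j][col]
                w = weights[i] * weights[j]
                counts[(a, b)] = counts.get((a, b), 0.0) + 0.5 * w
                counts[(b, a)] = counts.get((b, a), 0.0) + 0.5 * w
    return counts


def diameter_oracle(nodes, edges):
    """Graph diameter by Floyd-Warshall from scratch."""
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    INF = 10 ** 9
    d = [[0 if i == j else INF for j in range(n)] for i in range(n)]
    for a, b in edges:
        d[idx[a]][idx[b]] = 1
        d[idx[b]][idx[a]] = 1
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i][k] + d[k][j] < d[i][j]:
                    d[i][j] = d[i][k] + d[k][j]
    return max(max(row) for row in d)
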