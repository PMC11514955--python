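"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation paths they check: exact tests
are computed by exhaustive enumeration, AUC by pairwise concordance
counting, and the interaction null by iterating every label permutation.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np


def fisher_two_sided_oracle(table) -> float:
    """Two-sided Fisher p by enumerating all tables with fixed margins."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = prob(x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(1.0, total)


def mann_whitney_exact_oracle(x, y) -> float:
    """Two-sided exact Mann-Whitney p by enumerating all group assignments."""
    x = list(x)
    y = list(y)
    pooled = x + y
    n, m = len(x), len(y)

    def u_stat(xs, ys):
        return sum(1.0 if xi > yi else 0.5 if xi == yi else 0.0
                   for xi in xs for yi in ys)

    u_obs = u_stat(x, y)
    mu = n * m / 2.0
    count = 0
    total = 0
    idx = range(n + m)
    for combo in itertools.combinations(idx, n):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in idx if i not in combo]
        if abs(u_stat(xs, ys) - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
        total += 1
    return count / total


def auc_concordance_oracle(scores, labels) -> float:
    """AUC as the fraction of concordant positive/negative pairs."""
    s = np.asarray(scores, dtype=float)
    yv = np.asarray(labels).astype(int)
    pos = s[yv == 1]
    neg = s[yv == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            wins += 1.0 if p > q else 0.5 if p == q else 0.0
    return wins / (len(pos) * len(neg))


def interaction_exhaustive_oracle(codes, edges, n_classes):
    """Exact permutation null for pairwise adjacency counts on a tiny ROI.

    Returns dicts pair -> (observed, z_exact, p_exact) over all distinct
    label permutations (feasible for <= 8 cells).
    """
    codes = np.asarray(codes)
    edges = np.asarray(edges)

    def pair_counts(lab):
        out = np.zeros(n_classes * n_classes)
        for i, j in edges:
            lo, hi = sorted((lab[i], lab[j]))
            out[lo * n_classes + hi] += 1
        return out

    obs = pair_counts(codes)
    perms = set(itertools.permutations(codes.tolist()))
    nulls = np.array([pair_counts(np.array(p)) for p in sorted(perms)])
    mean = nulls.mean(axis=0)
    sd = nulls.std(axis=0)
    present = sorted(set(codes.tolist()))
    result = {}
    for i in present:
        for j in present:
            if j < i:
                continue
            flat = i * n_classes + j
            z = 0.0 if sd[flat] == 0 else (obs[flat] - mean[flat]) / sd[flat]
            dev = np.abs(nulls[:, flat] - mean[flat])
            p = float(np.mean(dev >= abs(obs[flat] - mean[flat]) - 1e-12))
            result[(i, j)] = (obs[flat], z, p)
    return result
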