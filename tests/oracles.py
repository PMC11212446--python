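"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as plain scalar loops, deliberately sharing no
code path with the package: neighbour-consistency values, rank-based AUROC,
and paired bootstrap counts are recomputed from first principles.
"""

from __future__ import annotations

import math

import numpy as np

EPS = 1e-7


def _clamp(x: float) -> float:
    return min(max(x, EPS), 1.0 - EPS)


def brute_force_ncr(V, Z, k: int, divergence: str) -> float:
    """Neighbour-consistency loss via explicit per-sample loops."""
    V = [list(map(float, row)) for row in np.atleast_2d(V)]
    Z = [float(z) for z in np.ravel(Z)]
    m = len(Z)
    total = 0.0
    for i in range(m):
        ni = math.sqrt(sum(x * x for x in V[i]))
        sims = []
        for j in range(m):
            if j == i:
                continue
            nj = math.sqrt(sum(x * x for x in V[j]))
            if ni < 1e-12 or nj < 1e-12:
                s = 0.0
            else:
                s = sum(a * b for a, b in zip(V[i], V[j])) / (ni * nj)
            sims.append((max(s, 0.0), j))
        sims.sort(key=lambda t: (-t[0], t[1]))  # ties broken by lower index
        top = sims[:k]
        ssum = sum(s for s, _ in top)
        if ssum <= 0.0:
            continue  # sample contributes 0
        q1 = sum(s / ssum * (1.0 / (1.0 + math.exp(-Z[j]))) for s, j in top)
        q0 = sum(s / ssum * (1.0 - 1.0 / (1.0 + math.exp(-Z[j]))) for s, j in top)
        pi = 1.0 / (1.0 + math.exp(-Z[i]))
        P = [_clamp(1.0 - pi), _clamp(pi)]
        Q = [_clamp(q0), _clamp(q1)]
        if divergence == "kl":
            d = sum(p * (math.log(p) - math.log(q)) for p, q in zip(P, Q))
        elif divergence == "js":
            M = [_clamp((p + q) / 2.0) for p, q in zip(P, Q)]
            d = 0.5 * sum(p * (math.log(p) - math.log(mm)) for p, mm in zip(P, M))
            d += 0.5 * sum(q * (math.log(q) - math.log(mm)) for q, mm in zip(Q, M))
        elif divergence == "mae":
            d = 0.5 * (abs((1.0 - pi) - q0) + abs(pi - q1))
        else:
            raise ValueError(divergence)
        total += d
    return total / m


def pairwise_auroc(labels, scores) -> float:
    """AUROC by exhaustive positive-negative pair enumeration (ties count 1/2)."""
    labels = np.ravel(labels)
    scores = np.ravel(scores)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1.0
            elif sp == sn:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def percentile_bootstrap_ci(labels, scores, indices, level: float = 0.95):
    """Percentile CI over given resample rows using the pair-enumeration AUROC."""
    labels = np.ravel(labels)
    scores = np.ravel(scores)
    stats = sorted(pairwise_auroc(labels[row], scores[row]) for row in indices)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(np.array(stats), [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi)


def paired_bootstrap_p(labels, scores_a, scores_b, indices) -> float:
    """Fraction of resamples on which A fails to beat B (ties half)."""
    labels = np.ravel(labels)
    a = np.ravel(scores_a)
    b = np.ravel(scores_b)
    total = 0.0
    for row in indices:
        ma = pairwise_auroc(labels[row], a[row])
        mb = pairwise_auroc(labels[row], b[row])
        if ma < mb:
            total += 1.0
        elif ma == mb:
            total += 0.5
    return total / len(indices)
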