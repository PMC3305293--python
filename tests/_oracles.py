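"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by the most direct method available —
exhaustive dynamic programming, literal enumeration, hand-transcribed
formulas — sharing no code with the implementation paths it checks.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np


def local_affine_dp_score(
    read: str,
    ref: str,
    match: int = 10,
    mismatch: int = 20,
    gap_open: int = 20,
    gap_extend: int = 5,
) -> int:
    """Exhaustive local-alignment optimum (Gotoh), plain Python.

    A 1-base gap costs gap_open + gap_extend, matching the aligner's
    convention.
    """
    n, m = len(read), len(ref)
    NEG = -(10**9)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    D = [[NEG] * (m + 1) for _ in range(n + 1)]
    I = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            D[i][j] = max(H[i][j - 1] - gap_open - gap_extend, D[i][j - 1] - gap_extend)
            I[i][j] = max(H[i - 1][j] - gap_open - gap_extend, I[i - 1][j] - gap_extend)
            s = match if read[i - 1] == ref[j - 1] else -mismatch
            H[i][j] = max(0, H[i - 1][j - 1] + s, D[i][j], I[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best


def fisher_p_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by literal enumeration with exact rationals.

    All tables with the observed margins are listed; their hypergeometric
    probabilities are exact Fractions, so the "no more probable than
    observed" comparison needs no tolerance.
    """
    n = a + b + c + d
    if n == 0:
        return 1.0
    row1, col1 = a + b, a + c

    def table_prob(k: int) -> Fraction:
        # P(X = k) for X ~ Hypergeom(n, row1, col1)
        return Fraction(
            math.comb(row1, k) * math.comb(n - row1, col1 - k), math.comb(n, col1)
        )

    k_min = max(0, col1 - (n - row1))
    k_max = min(row1, col1)
    p_obs = table_prob(a)
    total = sum(
        (p for k in range(k_min, k_max + 1) if (p := table_prob(k)) <= p_obs),
        Fraction(0),
    )
    return float(total)


def classify_allele_sets(ao: frozenset, lm: frozenset) -> tuple[str, str | None]:
    """Brute-force group-specificity decision over two present-allele sets.

    Written as flat case analysis (membership tests only) rather than the
    implementation's set arithmetic.
    """
    if len(ao) == 0 or len(lm) == 0:
        return "uncallable", None
    some_private = any(x not in lm for x in ao) or any(x not in ao for x in lm)
    if not some_private:
        return "not_group_specific", None
    if len(ao) == 1 and len(lm) == 1:
        return "group_exclusive", "fixed_divergent"
    ao_poly_private = len(ao) >= 2 and any(x not in lm for x in ao)
    lm_poly_private = len(lm) >= 2 and any(x not in ao for x in lm)
    if ao_poly_private and not lm_poly_private:
        return "group_exclusive", "polymorphic_in_AO"
    if lm_poly_private and not ao_poly_private:
        return "group_exclusive", "polymorphic_in_LM"
    if len(ao) >= len(lm):
        return "group_exclusive", "polymorphic_in_AO"
    return "group_exclusive", "polymorphic_in_LM"


def bh_stepup(p: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up written directly from its definition:
    q_(i) = min over j >= i of p_(j) * m / j, capped at 1."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = min(running, 1.0)
    return q


def moderated_t_rederivation(x1, x2, d0: float, s0_sq: float):
    """High-precision recomputation of the moderated t statistic for one
    contig from its two group vectors (longdouble arithmetic)."""
    x1 = np.asarray(x1, dtype=np.longdouble)
    x2 = np.asarray(x2, dtype=np.longdouble)
    n1, n2 = len(x1), len(x2)
    dg = n1 + n2 - 2
    ss = ((x1 - x1.mean()) ** 2).sum() + ((x2 - x2.mean()) ** 2).sum()
    s2 = ss / dg
    if math.isinf(d0):
        s_tilde_sq = np.longdouble(s0_sq)
    else:
        s_tilde_sq = (d0 * s0_sq + dg * s2) / (d0 + dg)
    se = np.sqrt(s_tilde_sq * (np.longdouble(1) / n1 + np.longdouble(1) / n2))
    return float((x1.mean() - x2.mean()) / se)


def centroid_linkage_bruteforce(points: np.ndarray):
    """Agglomerative centroid clustering by literal recomputation.

    Each step merges the pair of clusters with the smallest Euclidean
    distance between centroids (centroid = mean of member points); returns
    the scipy-style merge list [(id_a, id_b, height, size), ...].
    """
    clusters = {i: [i] for i in range(len(points))}
    centroids = {i: points[i].astype(float) for i in range(len(points))}
    merges = []
    next_id = len(points)
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if a >= b:
                    continue
                dist = float(np.linalg.norm(centroids[a] - centroids[b]))
                if best is None or dist < best[0]:
                    best = (dist, a, b)
        dist, a, b = best
        members = clusters.pop(a) + clusters.pop(b)
        clusters[next_id] = members
        centroids[next_id] = points[members].mean(axis=0)
        del centroids[a], centroids[b]
        merges.append((a, b, dist, len(members)))
        next_id += 1
    return merges
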