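"""Independent brute-force oracles kept deliberately separate from the package."""
from __future__ import annotations

import math

import numpy as np


def auroc_pairwise(scores, labels) -> float:
    """O(n^2) Mann-Whitney pair counting; ties count 1/2."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def conformal_quantile_enumerated(s_nc, alpha) -> float:
    """k-th smallest with k = ceil((N+1)(1-alpha)) capped at N, via exact fractions."""
    from fractions import Fraction

    s = sorted(float(x) for x in s_nc)
    n = len(s)
    k = math.ceil(Fraction(n + 1) * (1 - Fraction(alpha).limit_denominator(10**6)))
    k = min(max(k, 1), n)
    return s[k - 1]


def mean_cosine_brute(shift, group) -> float:
    """Mean of per-row cosines via explicit dot products."""
    shift = np.asarray(shift, float)
    vals = []
    for row in np.asarray(group, float):
        ns, nr = np.linalg.norm(shift), np.linalg.norm(row)
        if ns == 0 or nr == 0:
            vals.append(0.0)
        else:
            vals.append(float(shift @ row) / (ns * nr))
    return float(np.mean(vals))


def marker_pass_by_rank(type_means, candidate_means, percentile) -> np.ndarray:
    """Strict-exceeds-the-linear-interpolated-percentile rule, recomputed directly."""
    cut = np.percentile(np.asarray(type_means, float), percentile, method="linear")
    return np.asarray(candidate_means, float) > cut
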