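"""Karlin-Altschul statistics for local alignment scores.

For an ungapped local alignment of two random sequences under a
substitution score ``s(i,j)`` with letter frequencies ``p_i``, the
expected number of alignments scoring at least S in a search space of
size m*n is

    E = K * m * n * exp(-lambda * S)

where ``lambda`` is the unique positive root of

    sum_ij p_i p_j exp(lambda * s(i,j)) = 1

and ``K`` is computed by the standard series for integer (lattice)
scores: with span delta = gcd of attainable scores, relative entropy
H = lambda * sum_ij p_i p_j s_ij exp(lambda * s_ij), and

    sigma = sum_{k>=1} (1/k) * [ P(S_k >= 0) + E(exp(lambda*S_k); S_k < 0) ]

(S_k the k-step random walk of scores),

    K = delta * lambda * exp(-2*sigma) / (H * (1 - exp(-lambda*delta))).

Both parameters are deterministic functions of the scoring scheme and
composition and are cached per scheme. Uniform base composition
(p = 1/4) is the default: at the decision cutoffs used here (1e-10 on
<=130 bp probes) the pass/fail outcome is insensitive to composition.
"""

from __future__ import annotations

from functools import lru_cache
from math import exp, gcd

import numpy as np
from scipy.optimize import brentq

__all__ = ["karlin_params", "evalue"]


def _score_distribution(match: int, mismatch: int, p: float = 0.25) -> dict[int, float]:
    """Distribution of the per-column score for i.i.d. uniform bases."""
    return {match: 4 * p * p, mismatch: 12 * p * p}


@lru_cache(maxsize=32)
def karlin_params(match: int = 1, mismatch: int = -2) -> tuple[float, float, float]:
    """Return (lambda, K, H) for a match/mismatch scheme under uniform
    composition.

    Raises ``ValueError`` if the expected score is non-negative (no
    positive lambda exists, the scheme is invalid for local statistics).
    """
    dist = _score_distribution(match, mismatch)
    scores = np.array(sorted(dist), dtype=float)
    probs = np.array([dist[int(s)] for s in scores])
    mean = float(np.dot(scores, probs))
    if mean >= 0 or scores.max() <= 0:
        raise ValueError("invalid scoring scheme: expected score must be negative "
                         "with a positive score attainable")

    def f(lam: float) -> float:
        return float(np.dot(probs, np.exp(lam * scores))) - 1.0

    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
    lam = float(brentq(f, 1e-9, hi, xtol=1e-12))

    H = lam * float(np.dot(probs, scores * np.exp(lam * scores)))

    delta = 0
    for s in dist:
        delta = gcd(delta, abs(int(s)))

    # sigma by convolving the walk's score distribution k steps out
    lo_s, hi_s = int(scores.min()), int(scores.max())
    step = np.zeros(hi_s - lo_s + 1)
    for s, pr in dist.items():
        step[int(s) - lo_s] = pr
    walk = np.array([1.0])  # S_0 = 0
    offset = 0  # walk[i] = P(S_k = offset + i)
    sigma = 0.0
    for k in range(1, 400):
        walk = np.convolve(walk, step)
        offset += lo_s
        idx = np.arange(len(walk)) + offset
        neg = idx < 0
        term = float(walk[~neg].sum() + np.dot(walk[neg], np.exp(lam * idx[neg])))
        sigma += term / k
        if term / k < 1e-9:
            break

    K = delta * lam * exp(-2.0 * sigma) / (H * (1.0 - exp(-lam * delta)))
    return lam, K, H


def evalue(score: float, m: int, n: int, match: int = 1, mismatch: int = -2) -> float:
    """Karlin-Altschul e-value of a local alignment *score* between
    sequences of lengths *m* and *n*."""
    lam, K, _ = karlin_params(match, mismatch)
    return K * m * n * exp(-lam * score)
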