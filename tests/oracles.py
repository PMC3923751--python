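"""Independent brute-force oracles used to pin expected values.

These deliberately share no code with the package's dynamic programming
or statistics: path probabilities are enumerated exhaustively, the
hypergeometric tail is summed with exact rational arithmetic.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb

import numpy as np

from dismotif.motifhmm import MotifHMM, encode, _Compiled


def enumerate_paths(h: MotifHMM, seq: str):
    """Yield (path, log-prob) over all emitting-state paths of length L."""
    c = _Compiled(h)
    x = encode(seq)
    L, K = len(x), h.K
    for path in itertools.product(range(K), repeat=L):
        lp = c.log_init[path[0]] + c.log_emis[path[0], x[0]]
        for t in range(1, L):
            lp += c.logA[path[t - 1], path[t]] + c.log_emis[path[t], x[t]]
        lp += c.log_end[path[-1]]
        if np.isfinite(lp):
            yield path, lp


def brute_force_loglik(h: MotifHMM, seq: str) -> float:
    tot = -np.inf
    for _, lp in enumerate_paths(h, seq):
        tot = np.logaddexp(tot, lp)
    return float(tot)


def brute_force_viterbi(h: MotifHMM, seq: str) -> tuple[tuple, float]:
    best, best_lp = None, -np.inf
    for path, lp in enumerate_paths(h, seq):
        if lp > best_lp:
            best, best_lp = path, lp
    return best, float(best_lp)


def brute_force_begin_end(h: MotifHMM, seq: str) -> tuple[np.ndarray, np.ndarray]:
    """Posterior P(first match at t) and P(last match at t) by enumeration."""
    L = len(seq)
    tot = brute_force_loglik(h, seq)
    begin = np.zeros(L)
    end = np.zeros(L)
    m1, mW = 1, h.W
    for path, lp in enumerate_paths(h, seq):
        p = np.exp(lp - tot)
        for t, s in enumerate(path):
            if s == m1:
                begin[t] += p
            if s == mW:
                end[t] += p
    return begin, end


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k), X ~ Hypergeometric(N, K, n), exact rational sum."""
    total = Fraction(0)
    denom = comb(N, n)
    for j in range(k, min(n, K) + 1):
        if n - j <= N - K:
            total += Fraction(comb(K, j) * comb(N - K, n - j), denom)
    return float(total)


def hand_metrics(cm: np.ndarray):
    """Cell-by-cell precision/recall/accuracy computation."""
    M = cm.shape[0]
    prec, rec = np.zeros(M), np.zeros(M)
    for c in range(M):
        tp = cm[c, c]
        fp = sum(cm[r, c] for r in range(M) if r != c)
        fn = sum(cm[c, r] for r in range(M) if r != c)
        prec[c] = tp / (tp + fp) if tp + fp else 0.0
        rec[c] = tp / (tp + fn) if tp + fn else 0.0
    acc = sum(cm[c, c] for c in range(M)) / cm.sum() if cm.sum() else 0.0
    return prec, rec, float(acc)
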