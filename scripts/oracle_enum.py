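"""Exhaustive path-enumeration log-likelihood, independent of the
package's dynamic programming (used by acceptance.py as a cross-check)."""

from __future__ import annotations

import itertools

import numpy as np

from dismotif.motifhmm import MotifHMM, encode, _Compiled


def brute_force_loglik(h: MotifHMM, seq: str) -> float:
    c = _Compiled(h)
    x = encode(seq)
    L, K = len(x), h.K
    tot = -np.inf
    for path in itertools.product(range(K), repeat=L):
        lp = c.log_init[path[0]] + c.log_emis[path[0], x[0]]
        for t in range(1, L):
            lp += c.logA[path[t - 1], path[t]] + c.log_emis[path[t], x[t]]
        lp += c.log_end[path[-1]]
        tot = np.logaddexp(tot, lp)
    return float(tot)
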