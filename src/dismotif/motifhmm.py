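"""Profile motif HMM with a one-occurrence-per-sequence (OOPS) topology.

Architecture (emitting states only, silent Begin/End collapsed into the
transition graph)::

    N-flank --> M1 --> ... --> MW --> C-flank --> (terminal)
      |self     \\->I1->/  (inserts between consecutive matches)

* ``N`` and ``C`` are background flank states with self-loops; their
  emission distributions are pinned to the background ``bg``.
* ``M1..MW`` are match states with trainable emissions.
* ``I1..I(W-1)`` are insert states (background emissions) allowing the
  motif to stretch; delete states are omitted (short motifs with defined
  positions).
* Every path passes the match block exactly once, realizing OOPS.

All dynamic programming is in log space.  The recursions are vectorized
over a padded batch of sequences, exploiting the sparse predecessor
structure of the topology (every state has at most two predecessors), so
a Baum-Welch iteration over hundreds of sequences costs a handful of
numpy passes per sequence position.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .seqdata import ALPHABET, AA_INDEX

NEG_INF = -np.inf


# ---------------------------------------------------------------------------
# topology helpers

def n_states(W: int) -> int:
    """Emitting-state count: N-flank + W matches + (W-1) inserts + C-flank."""
    return 2 * W + 1


def state_names(W: int) -> list[str]:
    return (["Nflank"] + [f"M{i}" for i in range(1, W + 1)]
            + [f"I{i}" for i in range(1, W)] + ["Cflank"])


def transition_support(W: int) -> np.ndarray:
    """Boolean (K, K+1) mask of structurally allowed transitions; the last
    column is the transition to the terminal (end of sequence)."""
    K = n_states(W)
    sup = np.zeros((K, K + 1), dtype=bool)
    N, C, END = 0, K - 1, K
    sup[N, N] = True
    sup[N, 1] = True                      # N -> M1
    for k in range(1, W):                 # Mk (state k), k = 1..W-1
        sup[k, k + 1] = True              # Mk -> M(k+1)
        ins = W + k                       # insert I_k
        sup[k, ins] = True                # Mk -> Ik
        sup[ins, ins] = True              # Ik -> Ik
        sup[ins, k + 1] = True            # Ik -> M(k+1)
    sup[W, C] = True                      # MW -> C
    sup[W, END] = True                    # MW -> end (motif at sequence end)
    sup[C, C] = True
    sup[C, END] = True
    return sup


@dataclass
class NullModel:
    """HMMER-null1-style background: i.i.d. residues from ``bg`` with a
    geometric length distribution of extension probability ``ext``."""

    bg: np.ndarray
    ext: float

    def __post_init__(self) -> None:
        self.bg = np.asarray(self.bg, dtype=float)
        if not np.isclose(self.bg.sum(), 1.0):
            raise ValueError("null background must sum to 1")
        if not 0.0 < self.ext < 1.0:
            raise ValueError("extension probability must be in (0, 1)")


def null_log_likelihood(n: NullModel, seq: str) -> float:
    """log P(seq | null) = sum_i log bg(x_i) + L log(ext) + log(1 - ext)."""
    if len(seq) == 0:
        raise ValueError("cannot score an empty sequence")
    idx = encode(seq)
    with np.errstate(divide="ignore"):
        logbg = np.log(n.bg)
    return float(logbg[idx].sum() + len(seq) * np.log(n.ext) + np.log1p(-n.ext))


def mean_length_to_ext(mean_length: float) -> float:
    """Geometric extension probability whose expected length matches."""
    return mean_length / (mean_length + 1.0)


@dataclass
class MotifHMM:
    """A width-W profile motif HMM (see module docstring for topology).

    ``init`` is the initial distribution over emitting states (support:
    N-flank and M1); ``trans`` is (K, K+1) with the terminal transition in
    the last column; ``match_emis`` is (W, 20); flank and insert states
    emit ``bg``.
    """

    W: int
    init: np.ndarray
    trans: np.ndarray
    match_emis: np.ndarray
    bg: np.ndarray
    null: NullModel
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.init = np.asarray(self.init, dtype=float)
        self.trans = np.asarray(self.trans, dtype=float)
        self.match_emis = np.asarray(self.match_emis, dtype=float)
        self.bg = np.asarray(self.bg, dtype=float)
        self.validate()

    # -- structure ---------------------------------------------------------
    @property
    def K(self) -> int:
        return n_states(self.W)

    @property
    def states(self) -> list[str]:
        return state_names(self.W)

    @property
    def match_slice(self) -> slice:
        return slice(1, self.W + 1)

    def validate(self, atol: float = 1e-9) -> None:
        W, K = self.W, self.K
        if W < 1:
            raise ValueError("motif width must be >= 1")
        if self.init.shape != (K,) or self.trans.shape != (K, K + 1):
            raise ValueError("parameter shapes inconsistent with W")
        if self.match_emis.shape != (W, len(ALPHABET)):
            raise ValueError("match emission table must be (W, 20)")
        sup = transition_support(W)
        if np.any(self.trans[~sup] != 0.0):
            raise ValueError("transition mass on a structurally forbidden edge")
        if (self.init < 0).any() or (self.trans < 0).any() or (self.match_emis < 0).any():
            raise ValueError("negative probability")
        if abs(self.init.sum() - 1.0) > atol:
            raise ValueError("initial distribution does not sum to 1")
        rows = self.trans.sum(axis=1)
        if np.max(np.abs(rows - 1.0)) > atol:
            raise ValueError("a transition row does not sum to 1")
        if np.max(np.abs(self.match_emis.sum(axis=1) - 1.0)) > atol:
            raise ValueError("a match emission row does not sum to 1")

    def emission_matrix(self) -> np.ndarray:
        """Full (K, 20) emission table (flanks/inserts pinned to bg)."""
        E = np.tile(self.bg, (self.K, 1))
        E[self.match_slice] = self.match_emis
        return E

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "W": self.W,
            "states": self.states,
            "init": self.init.tolist(),
            "trans": self.trans.tolist(),
            "match_emis": self.match_emis.tolist(),
            "bg": self.bg.tolist(),
            "null": {"bg": self.null.bg.tolist(), "ext": self.null.ext},
            "meta": self.meta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MotifHMM":
        return cls(W=d["W"], init=np.array(d["init"]), trans=np.array(d["trans"]),
                   match_emis=np.array(d["match_emis"]), bg=np.array(d["bg"]),
                   null=NullModel(np.array(d["null"]["bg"]), d["null"]["ext"]),
                   meta=d.get("meta", {}))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_json(cls, path) -> "MotifHMM":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    # -- sampling ----------------------------------------------------------
    def sample(self, rng: np.random.Generator) -> str:
        """Draw one sequence from the model (always contains W matches)."""
        E = self.emission_matrix()
        out = []
        state = int(rng.choice(self.K, p=self.init))
        while True:
            out.append(ALPHABET[int(rng.choice(20, p=E[state]))])
            nxt = int(rng.choice(self.K + 1, p=self.trans[state]))
            if nxt == self.K:
                return "".join(out)
            state = nxt


def build_hmm(W: int, bg: np.ndarray, rng: np.random.Generator,
              mean_length: float = 100.0, init_peak: float = 0.5,
              meta: dict | None = None) -> MotifHMM:
    """A randomly initialized width-W motif HMM.

    Each match column starts as the background mixed with weight
    ``init_peak`` on one uniformly chosen residue — a strong random
    perturbation that spreads EM restarts across motif space far better
    than small jitter around the background.  Flank self-loops are set
    so the expected flank length matches ``(mean_length - W) / 2``.
    """
    if W < 1:
        raise ValueError("motif width must be >= 1")
    bg = np.asarray(bg, dtype=float)
    K = n_states(W)
    mu = max((mean_length - W) / 2.0, 1.0)
    p = mu / (mu + 1.0)

    init = np.zeros(K)
    init[0], init[1] = p, 1.0 - p
    trans = np.zeros((K, K + 1))
    N, C, END = 0, K - 1, K
    trans[N, N], trans[N, 1] = p, 1.0 - p
    for k in range(1, W):
        ins = W + k
        trans[k, k + 1], trans[k, ins] = 0.95, 0.05
        trans[ins, ins], trans[ins, k + 1] = 0.3, 0.7
    trans[W, C], trans[W, END] = p, 1.0 - p
    trans[C, C], trans[C, END] = p, 1.0 - p

    match = np.tile(bg * (1.0 - init_peak), (W, 1))
    match[np.arange(W), rng.integers(20, size=W)] += init_peak
    match /= match.sum(axis=1, keepdims=True)

    null = NullModel(bg.copy(), mean_length_to_ext(mean_length))
    return MotifHMM(W, init, trans, match, bg, null, meta=dict(meta or {}))


# ---------------------------------------------------------------------------
# encoding and batching

def encode(seq: str) -> np.ndarray:
    try:
        return np.fromiter((AA_INDEX[c] for c in seq), dtype=np.int64, count=len(seq))
    except KeyError as e:
        raise ValueError(f"non-canonical residue {e.args[0]!r}") from None


class Batch:
    """Padded integer batch of sequences for vectorized DP."""

    def __init__(self, seqs: Sequence[str]):
        if not seqs:
            raise ValueError("empty sequence batch")
        self.n = len(seqs)
        self.lengths = np.array([len(s) for s in seqs], dtype=np.int64)
        if (self.lengths == 0).any():
            raise ValueError("empty sequence in batch")
        self.Lmax = int(self.lengths.max())
        self.X = np.zeros((self.n, self.Lmax), dtype=np.int64)
        for i, s in enumerate(seqs):
            self.X[i, : len(s)] = encode(s)
        self.valid = np.arange(self.Lmax)[None, :] < self.lengths[:, None]


class _Compiled:
    """Log parameters plus sparse predecessor/successor index tables."""

    def __init__(self, h: MotifHMM):
        self.h = h
        K = h.K
        with np.errstate(divide="ignore"):
            self.log_init = np.log(h.init)
            logT = np.log(h.trans)
            self.log_emis = np.log(h.emission_matrix())
        self.logA = logT[:, :K]
        self.log_end = logT[:, K]
        sup = transition_support(h.W)[:, :K]
        # predecessors of each state, padded to the max in-degree
        preds = [np.nonzero(sup[:, j])[0] for j in range(K)]
        P = max(len(p) for p in preds)
        self.pred_idx = np.zeros((K, P), dtype=np.int64)
        self.pred_w = np.full((K, P), NEG_INF)
        for j, p in enumerate(preds):
            self.pred_idx[j, : len(p)] = p
            self.pred_w[j, : len(p)] = self.logA[p, j]
        # successors of each state
        succs = [np.nonzero(sup[i, :])[0] for i in range(K)]
        S = max(len(s) for s in succs)
        self.succ_idx = np.zeros((K, S), dtype=np.int64)
        self.succ_w = np.full((K, S), NEG_INF)
        for i, s in enumerate(succs):
            self.succ_idx[i, : len(s)] = s
            self.succ_w[i, : len(s)] = self.logA[i, s]
        self.edges = [(int(i), int(j)) for i in range(K) for j in np.nonzero(sup[i])[0]]


def _forward(c: _Compiled, b: Batch) -> tuple[np.ndarray, np.ndarray]:
    """Batched forward pass; returns (log-likelihoods (n,), alpha (n,L,K))."""
    n, L, K = b.n, b.Lmax, c.h.K
    E = c.log_emis[:, b.X].transpose(1, 2, 0)          # (n, L, K)
    alpha = np.empty((n, L, K))
    alpha[:, 0] = c.log_init + E[:, 0]
    for t in range(1, L):
        cand = alpha[:, t - 1][:, c.pred_idx] + c.pred_w  # (n, K, P)
        alpha[:, t] = np.logaddexp.reduce(cand, axis=2) + E[:, t]
    last = alpha[np.arange(n), b.lengths - 1]          # (n, K)
    with np.errstate(invalid="ignore"):
        ll = np.logaddexp.reduce(last + c.log_end, axis=1)
    return ll, alpha


def _backward(c: _Compiled, b: Batch) -> np.ndarray:
    n, L, K = b.n, b.Lmax, c.h.K
    E = c.log_emis[:, b.X].transpose(1, 2, 0)
    beta = np.full((n, L, K), NEG_INF)
    beta[np.arange(n), b.lengths - 1] = c.log_end
    for t in range(L - 2, -1, -1):
        nxt = beta[:, t + 1] + E[:, t + 1]             # (n, K)
        cand = nxt[:, c.succ_idx] + c.succ_w           # (n, K, S)
        val = np.logaddexp.reduce(cand, axis=2)
        live = t < b.lengths - 1
        beta[live, t] = val[live]
    return beta


def forward_batch(h: MotifHMM, seqs: Sequence[str]) -> np.ndarray:
    """Log-likelihoods of many sequences under ``h``."""
    _check_lengths(h, seqs)
    ll, _ = _forward(_Compiled(h), Batch(seqs))
    return ll


def log_likelihood(h: MotifHMM, seq: str) -> float:
    """log P(seq | h), summed over all state paths (forward algorithm)."""
    _check_lengths(h, [seq])
    ll, _ = _forward(_Compiled(h), Batch([seq]))
    return float(ll[0])


def _check_lengths(h: MotifHMM, seqs: Sequence[str]) -> None:
    for s in seqs:
        if len(s) < h.W:
            raise ValueError(f"sequence shorter than motif width {h.W}")


def viterbi(h: MotifHMM, seq: str) -> tuple[list[int], float]:
    """Most probable state path (emitting-state indices) and its log-prob."""
    _check_lengths(h, [seq])
    c = _Compiled(h)
    x = encode(seq)
    L, K = len(x), h.K
    delta = np.empty((L, K))
    back = np.zeros((L, K), dtype=np.int64)
    delta[0] = c.log_init + c.log_emis[:, x[0]]
    for t in range(1, L):
        cand = delta[t - 1][c.pred_idx] + c.pred_w     # (K, P)
        best = np.argmax(cand, axis=1)
        delta[t] = cand[np.arange(K), best] + c.log_emis[:, x[t]]
        back[t] = c.pred_idx[np.arange(K), best]
    final = delta[L - 1] + c.log_end
    state = int(np.argmax(final))
    logp = float(final[state])
    path = [state]
    for t in range(L - 1, 0, -1):
        state = int(back[t, state])
        path.append(state)
    path.reverse()
    return path, logp


def match_positions(h: MotifHMM, path: Sequence[int]) -> list[int]:
    """Positions of the path aligned to match states (0-based)."""
    lo, hi = 1, h.W + 1
    return [t for t, s in enumerate(path) if lo <= s < hi]


def posterior_begin_end(h: MotifHMM, seq: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-position posterior of the motif Begin (first match emitted at
    that position) and End (last match emitted at that position).

    Under OOPS each path enters M1 and leaves MW exactly once, so each
    vector sums to 1 over positions.
    """
    _check_lengths(h, [seq])
    c = _Compiled(h)
    b = Batch([seq])
    ll, alpha = _forward(c, b)
    beta = _backward(c, b)
    gamma = alpha[0] + beta[0] - ll[0]                 # (L, K)
    begin = np.exp(gamma[:, 1])
    end = np.exp(gamma[:, h.W])
    return begin, end


def posterior_states(h: MotifHMM, seq: str) -> np.ndarray:
    """(L, K) posterior state marginals (rows sum to 1)."""
    _check_lengths(h, [seq])
    c = _Compiled(h)
    b = Batch([seq])
    ll, alpha = _forward(c, b)
    beta = _backward(c, b)
    return np.exp(alpha[0] + beta[0] - ll[0])


# ---------------------------------------------------------------------------
# expected sufficient statistics (the E step shared by MLE and MMIE training)

class EStats:
    """Expected counts from one weighted E pass."""

    __slots__ = ("init", "trans", "emis", "total_ll", "ll")

    def __init__(self, init, trans, emis, total_ll, ll):
        self.init = init          # (K,)
        self.trans = trans        # (K, K+1) incl. terminal column
        self.emis = emis          # (W, 20) match-state emission counts
        self.total_ll = total_ll  # weighted sum of per-sequence log-liks
        self.ll = ll              # per-sequence log-likelihoods


def expected_counts(h: MotifHMM, seqs: Sequence[str],
                    weights: np.ndarray | None = None) -> EStats:
    """Forward-backward expected counts, optionally per-sequence weighted."""
    _check_lengths(h, seqs)
    c = _Compiled(h)
    b = Batch(seqs)
    w = np.ones(b.n) if weights is None else np.asarray(weights, dtype=float)
    ll, alpha = _forward(c, b)
    beta = _backward(c, b)
    if not np.all(np.isfinite(ll)):
        raise FloatingPointError("non-finite sequence log-likelihood in E step")
    K, W = h.K, h.W
    E = c.log_emis[:, b.X].transpose(1, 2, 0)

    loggamma = alpha + beta - ll[:, None, None]
    gamma0 = np.exp(loggamma[:, 0, :])                 # (n, K)
    init = gamma0.T @ w

    emis = np.zeros((W, 20))
    flat_x = b.X.ravel()
    for j in range(1, W + 1):
        probs = np.exp(loggamma[:, :, j]) * w[:, None]
        emis[j - 1] = np.bincount(flat_x, weights=probs.ravel(), minlength=20)

    trans = np.zeros((K, K + 1))
    if b.Lmax > 1:
        for (i, j) in c.edges:
            if j == K:
                continue
            xi = np.exp(alpha[:, :-1, i] + c.logA[i, j] + E[:, 1:, j]
                        + beta[:, 1:, j] - ll[:, None])
            trans[i, j] = float((xi.sum(axis=1) * w).sum())
    last = alpha[np.arange(b.n), b.lengths - 1]
    endp = np.exp(last + c.log_end - ll[:, None])
    trans[:, K] = endp.T @ w
    return EStats(init, trans, emis, float((ll * w).sum()), ll)
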