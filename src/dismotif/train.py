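"""Generative (MLE / Baum-Welch) and discriminative (MMIE / extended
Baum-Welch) training of motif HMMs.

The discriminative objective is the binary one-vs-all conditional
log-likelihood

    F(lambda) = sum_{x in pos} log P(pos | x) + sum_{x in neg} log P(neg | x),
    P(pos | x) = pi_p L_lambda(x) / (pi_p L_lambda(x) + pi_n L_0(x)),

where ``L_lambda`` is the motif HMM and ``L_0`` a fixed null model
standing in for all competing classes.  Extended Baum-Welch re-estimates
every parameter group (a transition row, a match emission row, the
initial distribution) as

    theta'_i = (num_i - den_i + D theta_i) / (sum_j (num_j - den_j) + D)

with numerator counts from the positive set, denominator counts weighted
by the posterior P(pos | x) over positives plus (optionally
under-sampled) negatives, and D chosen per group so that every updated
entry stays above a floor.

When the negative pool dwarfs the positive set, a fresh uniform
under-sample of ``|pos|`` negatives is drawn at *every* iteration, so no
negative sequence is permanently discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .motifhmm import (MotifHMM, NullModel, build_hmm, EStats, expected_counts,
                       forward_batch, null_log_likelihood, transition_support,
                       mean_length_to_ext)
from .seqdata import ALPHABET, AA_INDEX


@dataclass
class TrainingConfig:
    """Hyperparameters of the discovery pipeline.

    Defaults follow the method's reference settings: width-4 motifs,
    10 random initializations, at most 50 (extended) Baum-Welch
    iterations, 20% simulated-evolution mutation rate, 10 motifs per
    class via Viterbi masking, linear SVM with error/margin trade-off
    0.01.
    """

    W: int = 4
    n_init: int = 10
    max_iter: int = 50
    mutation_rate: float = 0.2
    n_motifs_per_class: int = 10
    seed: int = 0
    structure: str = "flat"            # "flat" | "tree"
    undersample: bool = True
    tol: float = 1e-3                  # Baum-Welch log-likelihood tolerance
    eps: float = 1e-6                  # probability floor
    ebw_c: float = 2.0                 # D-smoothing multiplier
    ebw_update: str = "all"            # "all" | "emissions"
    n_folds: int = 10
    svm_c: float = 0.01
    matrix: str = "BLOSUM62"
    oversample_parents: str = "pool"
    mask_negatives: bool = False
    early_stop_patience: int = 3

    def __post_init__(self) -> None:
        if min(self.W, self.n_init, self.n_motifs_per_class, self.n_folds) < 1:
            raise ValueError("counts must be >= 1")
        if self.max_iter < 0:
            raise ValueError("max_iter must be >= 0")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be in [0, 1]")
        if self.structure not in ("flat", "tree"):
            raise ValueError("structure must be 'flat' or 'tree'")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "TrainingConfig":
        import yaml
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


def estimate_null(seqs: Sequence[str], pseudocount: float = 1.0) -> NullModel:
    """Background model from training data: residue frequencies plus a
    geometric length term matching the mean training length."""
    counts = np.full(20, pseudocount)
    total_len = 0
    for s in seqs:
        for ch in s:
            counts[AA_INDEX[ch]] += 1
        total_len += len(s)
    bg = counts / counts.sum()
    mean_len = total_len / max(len(seqs), 1)
    return NullModel(bg, mean_length_to_ext(mean_len))


# ---------------------------------------------------------------------------
# generative training

def _normalize_floor(p: np.ndarray, support: np.ndarray, eps: float) -> np.ndarray:
    out = np.zeros_like(p)
    s = p[support].sum()
    if s <= 0:
        raise ValueError("cannot normalize an all-zero distribution")
    out[support] = p[support] / s
    out[support] = np.maximum(out[support], eps)
    out[support] /= out[support].sum()
    return out


def _mstep(h: MotifHMM, st: EStats, eps: float, update: str = "all") -> MotifHMM:
    sup = transition_support(h.W)
    init = h.init.copy()
    trans = h.trans.copy()
    emis = h.match_emis.copy()
    if update == "all":
        isup = np.zeros(h.K, dtype=bool)
        isup[[0, 1]] = True
        if st.init.sum() > 0:
            init = _normalize_floor(st.init, isup, eps)
        for i in range(h.K):
            row = st.trans[i]
            if row.sum() > 0:
                trans[i] = _normalize_floor(row, sup[i], eps)
    for j in range(h.W):
        row = st.emis[j]
        if row.sum() > 0:
            emis[j] = _normalize_floor(row, np.ones(20, dtype=bool), eps)
    return MotifHMM(h.W, init, trans, emis, h.bg, h.null, meta=dict(h.meta))


def baum_welch(h: MotifHMM, seqs: Sequence[str], max_iter: int = 50,
               tol: float = 1e-3, eps: float = 1e-6,
               update: str = "all") -> MotifHMM:
    """EM re-estimation; the summed log-likelihood is non-decreasing.

    Stops after ``max_iter`` iterations or when the improvement falls
    below ``tol``.  The per-iteration log-likelihood trace is stored in
    ``meta["ll_trace"]``.
    """
    if not seqs:
        raise ValueError("empty training set")
    trace: list[float] = []
    for _ in range(max_iter):
        st = expected_counts(h, seqs)
        trace.append(st.total_ll)
        h = _mstep(h, st, eps, update=update)
        if len(trace) >= 2 and trace[-1] - trace[-2] < tol:
            break
    h.meta["ll_trace"] = trace
    h.meta["final_ll"] = trace[-1] if trace else float(forward_batch(h, seqs).sum())
    return h


def best_of_inits(seqs: Sequence[str], cfg: TrainingConfig,
                  rng: np.random.Generator,
                  null: NullModel | None = None) -> MotifHMM:
    """Run Baum-Welch from ``cfg.n_init`` random initializations and keep
    the highest-likelihood model."""
    if not seqs:
        raise ValueError("empty training set")
    if null is None:
        null = estimate_null(seqs)
    mean_len = float(np.mean([len(s) for s in seqs]))
    best: MotifHMM | None = None
    for i in range(cfg.n_init):
        h0 = build_hmm(cfg.W, null.bg, rng, mean_length=mean_len,
                       meta={"init_index": i})
        h0.null = null
        h = baum_welch(h0, seqs, max_iter=cfg.max_iter, tol=cfg.tol, eps=cfg.eps)
        if best is None or h.meta["final_ll"] > best.meta["final_ll"]:
            best = h
    return best


# ---------------------------------------------------------------------------
# discriminative training

@dataclass
class MMIEState:
    """State of one one-vs-all MMIE problem."""

    lambda_pos: MotifHMM
    competing: NullModel
    priors: np.ndarray = field(default_factory=lambda: np.array([0.5, 0.5]))
    trace: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.priors = np.asarray(self.priors, dtype=float)
        if not np.isclose(self.priors.sum(), 1.0):
            raise ValueError("class priors must sum to 1")


def _log_posterior_margin(st: MMIEState, seqs: Sequence[str]) -> np.ndarray:
    """log [pi_p L_lambda(x)] - log [pi_n L_0(x)] per sequence."""
    lp = forward_batch(st.lambda_pos, seqs) + np.log(st.priors[0])
    ln = np.array([null_log_likelihood(st.competing, s) for s in seqs]) \
        + np.log(st.priors[1])
    return lp - ln


def mmie_objective(st: MMIEState, pos: Sequence[str], neg: Sequence[str]) -> float:
    """Conditional log-likelihood of the correct labels (<= 0)."""
    if not pos:
        raise ValueError("positive set must be non-empty")
    total = float(-np.logaddexp(0.0, -_log_posterior_margin(st, pos)).sum())
    if neg:
        total += float(-np.logaddexp(0.0, _log_posterior_margin(st, neg)).sum())
    return total


def undersample_negatives(neg: Sequence[str], n_pos: int,
                          rng: np.random.Generator) -> list:
    """Uniform sample of min(|neg|, n_pos) negatives without replacement;
    a fresh draw on every call."""
    if n_pos < 1:
        raise ValueError("n_pos must be >= 1")
    neg = list(neg)
    if len(neg) <= n_pos:
        return neg
    idx = rng.choice(len(neg), size=n_pos, replace=False)
    return [neg[i] for i in idx]


def _ebw_row(theta: np.ndarray, num: np.ndarray, den: np.ndarray,
             support: np.ndarray, c: float, eps: float) -> np.ndarray:
    """One extended-Baum-Welch distribution update with D-smoothing.

    D = c * max(D_min, 1) where D_min is the smallest value keeping every
    updated entry on the support at or above the floor; doubled further
    if the denominator is non-positive.
    """
    g = num - den
    G = float(g[support].sum())
    cands = [0.0]
    for i in np.nonzero(support)[0]:
        slack = theta[i] - eps
        if slack > 0:
            cands.append((eps * G - g[i]) / slack)
    D = c * max(max(cands), 1.0)
    for _ in range(200):
        tot = G + D
        if tot > 0:
            new = np.zeros_like(theta)
            new[support] = (g[support] + D * theta[support]) / tot
            if new[support].min() >= 0.5 * eps:
                break
        D *= 2.0
    else:  # pragma: no cover - defensive
        raise FloatingPointError("EBW smoothing failed to stabilize")
    new[support] = np.maximum(new[support], eps)
    new[support] /= new[support].sum()
    return new


def ebw_step(h: MotifHMM, num: EStats, den: EStats, cfg: TrainingConfig) -> MotifHMM:
    """Apply one extended-Baum-Welch update to every parameter group."""
    sup = transition_support(h.W)
    init = h.init.copy()
    trans = h.trans.copy()
    emis = h.match_emis.copy()
    full = np.ones(20, dtype=bool)
    for j in range(h.W):
        emis[j] = _ebw_row(h.match_emis[j], num.emis[j], den.emis[j],
                           full, cfg.ebw_c, cfg.eps)
    if cfg.ebw_update == "all":
        isup = np.zeros(h.K, dtype=bool)
        isup[[0, 1]] = True
        init = _ebw_row(h.init, num.init, den.init, isup, cfg.ebw_c, cfg.eps)
        for i in range(h.K):
            trans[i] = _ebw_row(h.trans[i], num.trans[i], den.trans[i],
                                sup[i], cfg.ebw_c, cfg.eps)
    return MotifHMM(h.W, init, trans, emis, h.bg, h.null, meta=dict(h.meta))


def extended_baum_welch(st: MMIEState, pos: Sequence[str],
                        neg_full: Sequence[str], cfg: TrainingConfig,
                        rng: np.random.Generator) -> MMIEState:
    """Discriminative refinement of ``st.lambda_pos``.

    Per iteration: draw the negative subset (all negatives when
    ``cfg.undersample`` is off), accumulate numerator statistics on the
    positives and posterior-weighted denominator statistics on positives
    plus drawn negatives, and apply the smoothed EBW update.  The MMIE
    objective on the *full* (non-subsampled) data is traced every
    iteration; training stops early after ``early_stop_patience``
    consecutive decreases and the iterate with the highest full-data
    objective is returned.
    """
    if not pos:
        raise ValueError("positive set must be non-empty")
    pos = list(pos)
    neg_full = list(neg_full)
    h = st.lambda_pos
    trace = [mmie_objective(MMIEState(h, st.competing, st.priors), pos, neg_full)]
    best_h, best_obj = h, trace[0]
    decreases = 0
    for _ in range(cfg.max_iter):
        if cfg.undersample and neg_full:
            neg = undersample_negatives(neg_full, len(pos), rng)
        else:
            neg = neg_full
        num = expected_counts(h, pos)
        both = pos + neg
        margins = _log_posterior_margin(MMIEState(h, st.competing, st.priors), both)
        w = 1.0 / (1.0 + np.exp(-margins))             # P(pos | x)
        den = expected_counts(h, both, weights=w)
        if not (np.isfinite(num.total_ll) and np.isfinite(den.total_ll)):
            raise FloatingPointError("non-finite EBW statistics")
        h = ebw_step(h, num, den, cfg)
        obj = mmie_objective(MMIEState(h, st.competing, st.priors), pos, neg_full)
        trace.append(obj)
        if obj > best_obj:
            best_h, best_obj = h, obj
        decreases = decreases + 1 if trace[-1] < trace[-2] else 0
        if decreases >= cfg.early_stop_patience:
            break
    out = MMIEState(best_h, st.competing, st.priors, trace)
    out.lambda_pos.meta["mmie_trace"] = trace
    return out
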