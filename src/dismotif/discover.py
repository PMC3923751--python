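"""Motif-discovery pipeline: negative-set construction, per-class
training, Viterbi masking for non-redundant motifs, and posterior-decoding
instance retrieval.

For each class the pipeline trains a motif, masks the residues its
Viterbi paths assign to match states with random amino acids, and
repeats — by default 10 times — so successive motifs cannot rediscover
the same signal.  Training mode selects the method variant:

========  =============================================================
mode      training
========  =============================================================
gen       Baum-Welch (MLE) on the positive class only
disc      gen, then extended Baum-Welch against the full negative set
genM      gen after simulated-evolution balancing of the dataset
discM     disc after balancing
discMU    discM with per-iteration random under-sampling of negatives
========  =============================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqdata import ALPHABET, Dataset, LabeledSequence, CompartmentTree, relabel
from .simevo import SubstitutionModel, balance_dataset
from .motifhmm import MotifHMM, viterbi, match_positions, posterior_begin_end
from .train import (TrainingConfig, MMIEState, best_of_inits, estimate_null,
                    extended_baum_welch)
from ._rng import rng_for

MODES = ("gen", "disc", "genM", "discM", "discMU")


@dataclass(frozen=True)
class MotifInstance:
    """A scored motif occurrence; coordinates 0-based half-open."""

    motif_id: str
    seq_id: str
    start: int
    end: int
    score: float

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError("invalid instance coordinates")
        if not 0.0 <= self.score <= 1.0 + 1e-9:
            raise ValueError("instance score must be a probability product")

    def overlap(self, start: int, end: int) -> int:
        return max(0, min(self.end, end) - max(self.start, start))


@dataclass
class MotifSet:
    """Discovered motifs per class, in discovery order."""

    motifs: dict[str, list[MotifHMM]] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def all_motifs(self) -> list[tuple[str, MotifHMM]]:
        """(motif_id, model) pairs in a stable order."""
        out = []
        for cls in self.motifs:
            for r, h in enumerate(self.motifs[cls]):
                out.append((f"{cls}:{r}", h))
        return out

    def to_json(self, path) -> None:
        import json
        bundle = {
            "meta": self.meta,
            "motifs": {c: [h.to_dict() for h in hs] for c, hs in self.motifs.items()},
        }
        with open(path, "w") as fh:
            json.dump(bundle, fh)

    @classmethod
    def from_json(cls, path) -> "MotifSet":
        import json
        with open(path) as fh:
            bundle = json.load(fh)
        return cls({c: [MotifHMM.from_dict(d) for d in hs]
                    for c, hs in bundle["motifs"].items()}, bundle.get("meta", {}))


def negative_set(d: Dataset, cls: str, structure: str = "flat",
                 tree: CompartmentTree | None = None) -> list[LabeledSequence]:
    """Negative training sequences for one-vs-all training of ``cls``.

    flat: every sequence not labeled ``cls``.  tree: sequences of the
    sibling classes under the positive class's parent node (at the top
    level this is the other branches of the root).
    """
    if cls not in d.classes:
        raise KeyError(f"unknown class {cls!r}")
    if structure == "flat":
        return [s for s in d if s.label != cls]
    if structure != "tree":
        raise ValueError("structure must be 'flat' or 'tree'")
    if tree is None:
        raise ValueError("tree structure requires a CompartmentTree")
    # nearest ancestor with other leaves: a class alone under its parent
    # competes with the other branches one level up (root level at worst)
    sibs: set[str] = set()
    for node in reversed(tree.ancestors_of_leaf(cls)):
        sibs = set(tree.leaves(node)) - {cls}
        if sibs:
            break
    return [s for s in d if s.label in sibs]


def mask_instances(seqs: list[LabeledSequence], h: MotifHMM,
                   rng: np.random.Generator) -> list[LabeledSequence]:
    """Redraw the residues each sequence's Viterbi path assigns to match
    states, uniformly over the amino-acid alphabet.  Under OOPS every
    path visits all W match states, so exactly W positions are redrawn
    per sequence (a redraw may coincide with the original residue)."""
    out = []
    for s in seqs:
        path, _ = viterbi(h, s.residues)
        residues = list(s.residues)
        for t in match_positions(h, path):
            residues[t] = ALPHABET[int(rng.integers(20))]
        out.append(relabel(s, residues="".join(residues)))
    return out


def _train_one(pos: list[str], neg: list[str], cfg: TrainingConfig, mode: str,
               rng: np.random.Generator) -> MotifHMM:
    null = estimate_null(pos + neg if neg else pos)
    h = best_of_inits(pos, cfg, rng, null=null)
    if mode in ("disc", "discM", "discMU"):
        local = TrainingConfig(**{**cfg.to_dict(),
                                  "undersample": mode == "discMU"})
        st = MMIEState(h, null)
        st = extended_baum_welch(st, pos, neg, local, rng)
        h = st.lambda_pos
    return h


def balance_for_mode(d: Dataset, cfg: TrainingConfig, mode: str,
                     model: SubstitutionModel | None = None) -> Dataset:
    """The training dataset a mode actually sees: balanced by simulated
    evolution for genM/discM/discMU, unchanged for gen/disc."""
    if mode not in ("genM", "discM", "discMU"):
        return d
    if model is None:
        model = SubstitutionModel.load(cfg.matrix)
    return balance_dataset(d, cfg.mutation_rate, model,
                           rng_for(cfg.seed, "oversample"),
                           parents=cfg.oversample_parents)


def discover_motifs(d: Dataset, cfg: TrainingConfig, mode: str = "discMU",
                    tree: CompartmentTree | None = None,
                    model: SubstitutionModel | None = None,
                    classes: list[str] | None = None,
                    prebalanced: bool = False) -> MotifSet:
    """Run the full per-class discovery loop.

    For balanced modes (genM/discM/discMU) the dataset is first grown by
    simulated evolution (skipped when ``prebalanced``, for callers that
    already applied :func:`balance_for_mode`); held-out evaluation must
    always be done on original sequences only.  Per class,
    ``cfg.n_motifs_per_class`` motifs are trained, each followed by
    Viterbi masking of the positive (and optionally negative) training
    sequences.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if cfg.structure == "tree" and tree is not None:
        tree.validate(d.classes)
    work = d if prebalanced else balance_for_mode(d, cfg, mode, model)
    ms = MotifSet(meta={"mode": mode, "structure": cfg.structure,
                        "config": cfg.to_dict()})
    for cls in (classes or d.classes):
        rng = rng_for(cfg.seed, "discover", cls)
        pos = work.by_class(cls)
        neg = negative_set(work, cls, cfg.structure, tree)
        motifs: list[MotifHMM] = []
        for round_ in range(cfg.n_motifs_per_class):
            h = _train_one([s.residues for s in pos],
                           [s.residues for s in neg], cfg, mode, rng)
            h.meta.update({"class": cls, "round": round_, "mode": mode})
            motifs.append(h)
            if round_ + 1 < cfg.n_motifs_per_class:
                pos = mask_instances(pos, h, rng)
                if cfg.mask_negatives:
                    neg = mask_instances(neg, h, rng)
        ms.motifs[cls] = motifs
    return ms


def scan_instances(motif_id: str, h: MotifHMM, seqs: list[LabeledSequence],
                   floor: float = 1e-12) -> list[MotifInstance]:
    """All candidate instances of one motif: every position whose Begin
    posterior exceeds ``floor``, paired with the nearest downstream End
    position, scored by the product of the two posteriors."""
    out: list[MotifInstance] = []
    for s in seqs:
        if len(s.residues) < h.W:
            continue
        begin, end = posterior_begin_end(h, s.residues)
        ends = np.nonzero(end > floor)[0]
        for b in np.nonzero(begin > floor)[0]:
            nxt = ends[ends >= b + h.W - 1]
            if nxt.size == 0:
                continue
            e = int(nxt[0])
            score = min(float(begin[b] * end[e]), 1.0)
            out.append(MotifInstance(motif_id, s.id, int(b), e + 1, score))
    return out


def top_instances(motifs: list[tuple[str, MotifHMM]] | list[MotifHMM],
                  seqs: list[LabeledSequence], k: int,
                  floor: float = 1e-12) -> list[MotifInstance]:
    """Globally ranked top-k instances across all motifs and sequences.

    Ranking is by score descending; ties break deterministically by
    (seq_id, start, motif_id).  If fewer than ``k`` candidates exist they
    are all returned (with a warning).
    """
    import warnings
    if k < 1:
        raise ValueError("k must be >= 1")
    if motifs and not isinstance(motifs[0], tuple):
        motifs = [(f"m{i}", h) for i, h in enumerate(motifs)]
    cands: list[MotifInstance] = []
    for mid, h in motifs:
        cands.extend(scan_instances(mid, h, seqs, floor))
    cands.sort(key=lambda x: (-x.score, x.seq_id, x.start, x.motif_id))
    if len(cands) < k:
        warnings.warn(f"only {len(cands)} candidate instances for k={k}")
        return cands
    return cands[:k]


def write_instances(instances: list[MotifInstance], path) -> None:
    """TSV report, 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        fh.write("motif_id\tseq_id\tstart\tend\tscore\n")
        for x in instances:
            fh.write(f"{x.motif_id}\t{x.seq_id}\t{x.start + 1}\t{x.end}\t{x.score:.6g}\n")
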