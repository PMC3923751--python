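"""Localization prediction from motif features.

Each sequence is converted into a feature vector of log-likelihood
ratios, one per discovered motif:

    f_m(x) = log P(x | lambda_m) - log P(x | null_m)

A linear soft-margin SVM (error/margin trade-off C = 0.01) classifies
the vectors, either flat (one-vs-rest over all classes) or
hierarchically (one classifier per internal tree node with top-down
routing).  Evaluation is stratified 10-fold cross-validation in which
motifs are re-discovered on each training fold, so no test sequence (nor
any simulated mutant of it) ever influences the motifs or the
classifier; only original sequences are scored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from .seqdata import Dataset, LabeledSequence, CompartmentTree
from .motifhmm import MotifHMM, forward_batch, null_log_likelihood
from .train import TrainingConfig
from .discover import MotifSet, discover_motifs, balance_for_mode
from ._rng import rng_for


def llr_feature(h: MotifHMM, seq: str) -> float:
    """Log-likelihood ratio of one sequence under one motif model."""
    return float(forward_batch(h, [seq])[0] - null_log_likelihood(h.null, seq))


def featurize(ms: MotifSet, seqs: list[LabeledSequence]) -> tuple[list[str], np.ndarray]:
    """LLR feature matrix (rows follow ``seqs``; columns are motif ids in
    the MotifSet's stable order)."""
    pairs = ms.all_motifs()
    residues = [s.residues for s in seqs]
    X = np.empty((len(seqs), len(pairs)))
    for j, (_, h) in enumerate(pairs):
        nll = np.array([null_log_likelihood(h.null, r) for r in residues])
        X[:, j] = forward_batch(h, residues) - nll
    return [mid for mid, _ in pairs], X


def write_features(motif_ids: list[str], X: np.ndarray,
                   seqs: list[LabeledSequence], path) -> None:
    """Feature matrix as TSV: rows are sequence ids, columns motif ids."""
    import pandas as pd
    pd.DataFrame(X, index=[s.id for s in seqs], columns=motif_ids) \
        .to_csv(path, sep="\t", index_label="seq_id")


@dataclass
class Metrics:
    precision: np.ndarray
    recall: np.ndarray
    accuracy: float
    flagged: list = field(default_factory=list)

    def __iter__(self):
        return iter((self.precision, self.recall, self.accuracy))


def metrics(confusion: np.ndarray) -> Metrics:
    """Per-class precision and recall plus overall accuracy.

    ``confusion[i, j]`` counts true class i predicted as class j.  A
    class never predicted (or absent) gets precision (recall) 0 and is
    flagged.
    """
    cm = np.asarray(confusion)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1] or (cm < 0).any():
        raise ValueError("confusion matrix must be square and non-negative")
    tp = np.diag(cm).astype(float)
    pred = cm.sum(axis=0).astype(float)
    true = cm.sum(axis=1).astype(float)
    flagged = []
    with np.errstate(divide="ignore", invalid="ignore"):
        prec = np.where(pred > 0, tp / np.where(pred > 0, pred, 1), 0.0)
        rec = np.where(true > 0, tp / np.where(true > 0, true, 1), 0.0)
    for i in np.nonzero(pred == 0)[0]:
        flagged.append(("precision", int(i)))
    for i in np.nonzero(true == 0)[0]:
        flagged.append(("recall", int(i)))
    total = cm.sum()
    acc = float(tp.sum() / total) if total > 0 else 0.0
    return Metrics(prec, rec, acc, flagged)


@dataclass
class PredictionResult:
    """Pooled cross-validation outcome."""

    classes: list[str]
    confusion: np.ndarray
    precision: dict[str, float]
    recall: dict[str, float]
    accuracy: float
    fold_of: dict[str, int]
    per_fold_accuracy: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "classes": self.classes,
            "confusion": self.confusion.tolist(),
            "precision": self.precision,
            "recall": self.recall,
            "accuracy": self.accuracy,
            "per_fold_accuracy": self.per_fold_accuracy,
        }


def _fit_flat(X: np.ndarray, y: list[str], c: float, seed: int) -> LinearSVC:
    clf = LinearSVC(C=c, random_state=seed)
    clf.fit(X, y)
    return clf


class _TreeRouter:
    """One linear SVM per internal node; prediction routes top-down to the
    child with the highest decision score until reaching a leaf."""

    def __init__(self, tree: CompartmentTree, c: float, seed: int):
        self.tree = tree
        self.c = c
        self.seed = seed
        self.node_clf: dict[str, LinearSVC] = {}
        self.node_children: dict[str, list[tuple[str, set[str]]]] = {}

    def fit(self, X: np.ndarray, y: list[str]) -> "_TreeRouter":
        for node in self.tree.internal_nodes():
            children = [(ch["name"], set(self.tree.leaves(ch)))
                        for ch in node["children"]]
            self.node_children[node["name"]] = children
            idx, targets = [], []
            for i, label in enumerate(y):
                for name, leaves in children:
                    if label in leaves:
                        idx.append(i)
                        targets.append(name)
                        break
            if len(set(targets)) >= 2:
                self.node_clf[node["name"]] = _fit_flat(X[idx], targets,
                                                        self.c, self.seed)
            elif targets:
                self.node_clf[node["name"]] = targets[0]  # degenerate node
        return self

    def predict(self, X: np.ndarray) -> list[str]:
        out = []
        for i in range(X.shape[0]):
            node = self.tree.root
            while node.get("children"):
                clf = self.node_clf.get(node["name"])
                if clf is None:
                    break
                if isinstance(clf, str):
                    choice = clf
                else:
                    choice = clf.predict(X[i: i + 1])[0]
                node = next(ch for ch in node["children"] if ch["name"] == choice)
            out.append(node["name"])
        return out


def crossval_predict(d: Dataset, cfg: TrainingConfig, mode: str = "discMU",
                     tree: CompartmentTree | None = None) -> PredictionResult:
    """Stratified k-fold cross-validated localization prediction.

    Per fold: discover motifs (mode-dependent, with any simulated-
    evolution balancing confined to the training fold), featurize train
    and test originals, fit the SVM(s), and predict the held-out fold.
    Folds are pooled into one confusion matrix (micro-accuracy).
    """
    originals = d.originals()
    ids = [s.id for s in originals]
    labels = [s.label for s in originals]
    sizes = originals.sizes
    smallest = min(v for v in sizes.values() if v > 0)
    if smallest < 2:
        warnings.warn("a class has fewer than 2 members; its folds degenerate")
    skf = StratifiedKFold(n_splits=cfg.n_folds, shuffle=True, random_state=cfg.seed)
    classes = list(originals.classes)
    cls_index = {c: i for i, c in enumerate(classes)}
    confusion = np.zeros((len(classes), len(classes)), dtype=int)
    fold_of: dict[str, int] = {}
    per_fold_acc: list[float] = []

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        splits = list(skf.split(np.zeros(len(ids)), labels))

    for fold, (tr_idx, te_idx) in enumerate(splits):
        train_seqs = [originals.sequences[i] for i in tr_idx]
        test_seqs = [originals.sequences[i] for i in te_idx]
        for s in test_seqs:
            fold_of[s.id] = fold
        fold_classes = [c for c in classes
                        if any(s.label == c for s in train_seqs)]
        train_d = Dataset(train_seqs, fold_classes)
        fold_cfg = TrainingConfig(**{**cfg.to_dict(), "seed": cfg.seed + 1000 * (fold + 1)})
        # balancing (and hence every simulated mutant) is confined to the
        # training fold; the SVM trains on the balanced fold's features so
        # minority classes carry weight, but only originals are scored
        work = balance_for_mode(train_d, fold_cfg, mode)
        ms = discover_motifs(work, fold_cfg, mode=mode, prebalanced=True,
                             tree=tree if cfg.structure == "tree" else None)
        _, X_tr = featurize(ms, work.sequences)
        _, X_te = featurize(ms, test_seqs)
        y_tr = [s.label for s in work.sequences]
        if cfg.structure == "tree":
            if tree is None:
                raise ValueError("tree structure requires a CompartmentTree")
            router = _TreeRouter(tree, cfg.svm_c, cfg.seed).fit(X_tr, y_tr)
            y_pred = router.predict(X_te)
        else:
            clf = _fit_flat(X_tr, y_tr, cfg.svm_c, cfg.seed)
            y_pred = list(clf.predict(X_te))
        hits = 0
        for s, p in zip(test_seqs, y_pred):
            confusion[cls_index[s.label], cls_index[p]] += 1
            hits += int(p == s.label)
        per_fold_acc.append(hits / len(test_seqs))

    m = metrics(confusion)
    return PredictionResult(
        classes=classes,
        confusion=confusion,
        precision={c: float(m.precision[i]) for c, i in cls_index.items()},
        recall={c: float(m.recall[i]) for c, i in cls_index.items()},
        accuracy=m.accuracy,
        fold_of=fold_of,
        per_fold_accuracy=per_fold_acc,
    )


def rank_motifs_backward(X: np.ndarray, y: list[str], motif_ids: list[str],
                         svm_c: float = 0.01, seed: int = 0,
                         test_fraction: float = 0.25) -> list[str]:
    """One-step backward feature selection over motifs.

    For every motif, the classifier is refit without that motif's
    feature and the held-out accuracy recorded; motifs are ranked by
    ascending accuracy-after-removal (rank 1 = biggest drop = most
    discriminative), ties broken by motif id.
    """
    if len(motif_ids) < 2:
        raise ValueError("need at least 2 motifs to rank")
    y = np.asarray(y)
    n_splits = max(2, int(round(1.0 / test_fraction)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        tr, te = next(iter(skf.split(X, y)))
    accs = []
    for j, mid in enumerate(motif_ids):
        keep = [k for k in range(X.shape[1]) if k != j]
        clf = _fit_flat(X[np.ix_(tr, keep)], list(y[tr]), svm_c, seed)
        acc = float(np.mean(clf.predict(X[np.ix_(te, keep)]) == y[te]))
        accs.append((acc, mid))
    accs.sort(key=lambda t: (t[0], t[1]))
    return [mid for _, mid in accs]
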