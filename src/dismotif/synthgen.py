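"""Synthetic planted-motif benchmark generator.

Every generated sequence consists of i.i.d. background residues with
exactly one motif occurrence (OOPS) sampled from its class's position
weight matrix at a uniformly random position.  Class sizes can mirror
the severely skewed nine-compartment distribution of curated yeast
localization data (shares from 0.83% for secreted proteins up to 37.58%
for nuclear ones), so minority-class behaviour of the discovery and
classification pipeline is testable at desk scale without downloads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seqdata import ALPHABET, Dataset, LabeledSequence

#: Nine-compartment class sizes of the curated single-localization
#: (dataset I) and multi-localization (dataset II) yeast benchmarks.
COMPARTMENT_COUNTS_I = {
    "Cytosol": 190, "ER": 84, "Golgi": 25, "Vacuole": 30,
    "Mitochondria": 312, "Nuclear": 454, "Peroxisome": 17,
    "Membrane": 86, "Secreted": 10,
}
COMPARTMENT_COUNTS_II = {
    "Cytosol": 453, "ER": 156, "Golgi": 77, "Vacuole": 43,
    "Mitochondria": 345, "Nuclear": 647, "Peroxisome": 24,
    "Membrane": 126, "Secreted": 18,
}


def degenerate_pwm(W: int, rng: np.random.Generator,
                   defined_prob: float = 0.7) -> np.ndarray:
    """A width-W PWM with one preferred residue per column (probability
    ``defined_prob``) and the rest spread uniformly — mimicking short
    linear motifs whose defined positions tolerate few substitutions."""
    pwm = np.full((W, 20), (1.0 - defined_prob) / 19.0)
    for j in range(W):
        pwm[j, int(rng.integers(20))] = defined_prob
    return pwm


@dataclass
class PlantSpec:
    """Specification of a planted-motif dataset."""

    class_pwms: dict[str, np.ndarray]
    class_sizes: dict[str, int]
    bg: np.ndarray = field(default_factory=lambda: np.full(20, 0.05))
    length_range: tuple[int, int] = (50, 200)
    seed: int = 0

    def __post_init__(self) -> None:
        self.bg = np.asarray(self.bg, dtype=float)
        if not np.isclose(self.bg.sum(), 1.0):
            raise ValueError("background must sum to 1")
        for c, pwm in self.class_pwms.items():
            pwm = np.asarray(pwm, dtype=float)
            if not np.allclose(pwm.sum(axis=1), 1.0):
                raise ValueError(f"PWM columns for class {c!r} must sum to 1")
            self.class_pwms[c] = pwm
        if set(self.class_pwms) != set(self.class_sizes):
            raise ValueError("class_pwms and class_sizes must cover the same classes")
        if any(v < 1 for v in self.class_sizes.values()):
            raise ValueError("class sizes must be >= 1")
        ws = {p.shape[0] for p in self.class_pwms.values()}
        if len(ws) != 1:
            raise ValueError("all class PWMs must share one width")
        self.W = ws.pop()
        if self.length_range[0] < self.W:
            raise ValueError("minimum sequence length must be >= motif width")


def generate(spec: PlantSpec) -> tuple[Dataset, pd.DataFrame]:
    """Generate the dataset and its ground-truth planted-instance table
    (columns seq_id, label, start, end; 0-based half-open)."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_range
    records: list[LabeledSequence] = []
    truth_rows = []
    for cls in spec.class_sizes:
        pwm = spec.class_pwms[cls]
        W = pwm.shape[0]
        for i in range(spec.class_sizes[cls]):
            L = int(rng.integers(lo, hi + 1))
            idx = rng.choice(20, size=L, p=spec.bg)
            start = int(rng.integers(L - W + 1))
            for j in range(W):
                idx[start + j] = rng.choice(20, p=pwm[j])
            sid = f"{cls}_{i}"
            records.append(LabeledSequence(sid, "".join(ALPHABET[k] for k in idx), cls))
            truth_rows.append({"seq_id": sid, "label": cls,
                               "start": start, "end": start + W})
    truth = pd.DataFrame(truth_rows, columns=["seq_id", "label", "start", "end"])
    return Dataset(records, list(spec.class_sizes)), truth


def scaled_skew_sizes(n: int, counts: dict[str, int] | None = None) -> dict[str, int]:
    """Class sizes mirroring a reference skew, scaled to about ``n``
    sequences (each class at least 1; rounded shares)."""
    counts = counts or COMPARTMENT_COUNTS_I
    total = sum(counts.values())
    return {c: max(1, int(np.floor(n * k / total + 0.5))) for c, k in counts.items()}


def yeast_skew_spec(n: int = 200, W: int = 4, seed: int = 0,
                     length_range: tuple[int, int] = (50, 200),
                     defined_prob: float = 0.7) -> PlantSpec:
    """The standard imbalanced benchmark: nine classes with the curated
    yeast compartment skew scaled to ``n`` sequences, one degenerate
    width-``W`` PWM per class, uniform background."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x707]))
    sizes = scaled_skew_sizes(n)
    pwms = {c: degenerate_pwm(W, rng, defined_prob) for c in sizes}
    return PlantSpec(pwms, sizes, length_range=length_range, seed=seed)


def write_truth(truth: pd.DataFrame, path) -> None:
    """Truth table as TSV with 1-based inclusive coordinates."""
    out = truth.copy()
    out["start"] = out["start"] + 1
    out.to_csv(path, sep="\t", index=False)
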