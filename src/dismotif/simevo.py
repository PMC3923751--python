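"""Over-sampling by simulated evolution.

Minority classes are grown to the size of the largest class by adding
mutated copies of randomly chosen class members.  A mutated copy differs
from its parent at exactly ``m = round(rate * L)`` positions (minimum 1
when ``rate > 0``); each mutated residue is replaced by its best
substitute under a BLOSUM substitution matrix — the off-diagonal row
maximum, i.e. the most exchangeable amino acid.  The default matrix is
BLOSUM62, balancing conservation of any embedded motif signal against
diversity of the generated sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

from .seqdata import ALPHABET, Dataset, LabeledSequence


@dataclass
class SubstitutionModel:
    """A 20x20 substitution score matrix plus its precomputed
    best-substitute map (argmax of each row excluding the diagonal,
    ties broken alphabetically)."""

    name: str
    matrix: np.ndarray                      # (20, 20) float, ALPHABET order
    best: dict[str, str] = field(init=False)

    def __post_init__(self) -> None:
        if self.matrix.shape != (20, 20):
            raise ValueError("substitution matrix must be 20x20 over the canonical alphabet")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("substitution matrix must be symmetric")
        best = {}
        for i, r in enumerate(ALPHABET):
            row = self.matrix[i].copy()
            row[i] = -np.inf
            # argmax returns the first (alphabetically smallest) index on ties
            best[r] = ALPHABET[int(np.argmax(row))]
        self.best = best

    @classmethod
    def load(cls, name: str = "BLOSUM62") -> "SubstitutionModel":
        """Load a named matrix (BLOSUM45/62/80, PAM...) from biopython's
        bundled NCBI-format collection, restricted to the 20 canonical
        amino acids."""
        m = substitution_matrices.load(name)
        idx = [m.alphabet.index(a) for a in ALPHABET]
        arr = np.asarray(m)[np.ix_(idx, idx)].astype(float)
        return cls(name, arr)

    @classmethod
    def from_file(cls, path: str, name: str | None = None) -> "SubstitutionModel":
        """Read a matrix in NCBI text format."""
        m = substitution_matrices.read(path)
        idx = [m.alphabet.index(a) for a in ALPHABET]
        arr = np.asarray(m)[np.ix_(idx, idx)].astype(float)
        return cls(name or str(path), arr)


def best_substitute(residue: str, model: SubstitutionModel) -> str:
    """The highest-scoring replacement for ``residue`` (never itself)."""
    if residue not in model.best:
        raise ValueError(f"residue {residue!r} is not a canonical amino acid")
    return model.best[residue]


def n_mutations(rate: float, length: int) -> int:
    """Number of positions to mutate: round-half-up of rate*L, at least 1
    whenever rate > 0 and the sequence is non-empty."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"rate must be in [0, 1], got {rate}")
    if rate == 0.0 or length == 0:
        return 0
    m = int(np.floor(rate * length + 0.5))
    return max(m, 1)


def mutate_sequence(seq: str, rate: float, model: SubstitutionModel,
                    rng: np.random.Generator) -> str:
    """Mutate ``seq`` at exactly ``n_mutations(rate, len(seq))`` distinct
    positions, replacing each with its best substitute."""
    m = n_mutations(rate, len(seq))
    if m == 0:
        return seq
    positions = rng.choice(len(seq), size=m, replace=False)
    out = list(seq)
    for p in positions:
        out[p] = best_substitute(out[p], model)
    return "".join(out)


def balance_dataset(d: Dataset, rate: float = 0.2,
                    model: SubstitutionModel | None = None,
                    rng: np.random.Generator | None = None,
                    parents: str = "pool") -> Dataset:
    """Grow every class to the size of the largest class by simulated
    evolution.

    For each deficit slot a parent is drawn uniformly from the class's
    current pool (originals plus previously generated mutants; pass
    ``parents="originals"`` to restrict parents to original records) and
    a mutated copy is appended with ``origin="simulated"``.  Original
    records are never modified or removed.
    """
    if model is None:
        model = SubstitutionModel.load("BLOSUM62")
    if rng is None:
        rng = np.random.default_rng()
    if parents not in ("pool", "originals"):
        raise ValueError("parents must be 'pool' or 'originals'")
    sizes = d.sizes
    if any(v == 0 for v in sizes.values()):
        empty = [c for c, v in sizes.items() if v == 0]
        raise ValueError(f"cannot balance dataset with empty classes: {empty}")
    target = max(sizes.values())

    new_records: list[LabeledSequence] = list(d.sequences)
    for cls in d.classes:
        pool = [s for s in d.sequences if s.label == cls]
        originals = list(pool)
        k = 0
        while len(pool) < target:
            source = pool if parents == "pool" else originals
            parent = source[int(rng.integers(len(source)))]
            child = mutate_sequence(parent.residues, rate, model, rng)
            k += 1
            rec = LabeledSequence(f"{parent.id}|sim{k}", child, cls, origin="simulated")
            pool.append(rec)
            new_records.append(rec)
    return Dataset(new_records, list(d.classes))
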