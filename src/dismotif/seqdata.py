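"""Domain types and I/O for labeled protein sequence datasets.

A :class:`Dataset` is a flat list of :class:`LabeledSequence` records
(protein sequence + compartment label) together with an ordered list of
class names.  Classes may be organised in a user-supplied rooted
:class:`CompartmentTree` whose leaves are exactly the dataset's classes;
the tree drives hierarchical (one-vs-siblings) negative-set construction
and top-down classification.

Coordinates are 0-based half-open everywhere inside the package; TSV
reports written for human consumption are 1-based inclusive.

A sequence annotated with several compartments is represented as one
record per label.  Because record ids must be unique within a dataset,
duplicated ids read from a label table are disambiguated by suffixing
``|<label>``.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 canonical amino acids, alphabetically ordered.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(ALPHABET)}


@dataclass(frozen=True)
class LabeledSequence:
    """A protein sequence with its compartment label.

    ``origin`` records provenance: ``"original"`` for input records,
    ``"simulated"`` for records created by simulated evolution.
    """

    id: str
    residues: str
    label: str
    origin: str = "original"

    def __post_init__(self) -> None:
        if self.origin not in ("original", "simulated"):
            raise ValueError(f"origin must be 'original' or 'simulated', got {self.origin!r}")

    def validate_alphabet(self) -> None:
        bad = set(self.residues) - set(ALPHABET)
        if bad:
            raise ValueError(
                f"record {self.id!r} contains non-canonical residues: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Dataset:
    """An ordered collection of labeled sequences."""

    sequences: list[LabeledSequence]
    classes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.classes:
            seen: list[str] = []
            for s in self.sequences:
                if s.label not in seen:
                    seen.append(s.label)
            self.classes = seen
        labels = {s.label for s in self.sequences}
        missing = labels - set(self.classes)
        if missing:
            raise ValueError(f"labels not in class list: {sorted(missing)}")
        ids = [s.id for s in self.sequences]
        dup = [i for i, c in Counter(ids).items() if c > 1]
        if dup:
            raise ValueError(f"duplicate sequence ids: {dup[:5]}")

    @property
    def sizes(self) -> dict[str, int]:
        counts = Counter(s.label for s in self.sequences)
        return {c: counts.get(c, 0) for c in self.classes}

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self):
        return iter(self.sequences)

    def by_class(self, cls: str) -> list[LabeledSequence]:
        if cls not in self.classes:
            raise KeyError(f"unknown class {cls!r}")
        return [s for s in self.sequences if s.label == cls]

    def originals(self) -> "Dataset":
        return Dataset([s for s in self.sequences if s.origin == "original"],
                       list(self.classes))

    def subset(self, ids: Iterable[str]) -> "Dataset":
        keep = set(ids)
        return Dataset([s for s in self.sequences if s.id in keep], list(self.classes))


def class_sizes(d: Dataset) -> dict[str, int]:
    """Per-class sequence counts (in class order)."""
    return d.sizes


def class_percentages(d: Dataset) -> dict[str, float]:
    """Per-class shares as percentages of the dataset size."""
    n = len(d)
    return {c: 100.0 * k / n for c, k in d.sizes.items()} if n else {}


def read_dataset(fasta_path: str | Path, labels_path: str | Path,
                 strict: bool = False) -> Dataset:
    """Read a FASTA file and a tab-separated label table into a Dataset.

    The label table has a header line ``id<TAB>compartment``; every id in
    it must be present in the FASTA.  An id occurring with several labels
    yields one record per label with ``|<label>`` appended to the id.

    Records containing non-canonical residues (B, Z, X, U, ...) are
    rejected with a warning by default; with ``strict=True`` they raise.
    """
    import warnings

    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    rows: list[tuple[str, str]] = []
    with open(labels_path) as fh:
        header = fh.readline()
        if not header.lower().startswith("id"):
            raise ValueError("label table must start with an 'id<TAB>compartment' header")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"malformed label row: {line!r}")
            rows.append((parts[0], parts[1]))

    missing = [i for i, _ in rows if i not in seqs]
    if missing:
        raise ValueError(f"label-table ids missing from FASTA: {missing[:5]}")

    id_counts = Counter(i for i, _ in rows)
    records: list[LabeledSequence] = []
    classes: list[str] = []
    for sid, label in rows:
        residues = seqs[sid]
        rid = sid if id_counts[sid] == 1 else f"{sid}|{label}"
        rec = LabeledSequence(rid, residues, label)
        try:
            rec.validate_alphabet()
        except ValueError as e:
            if strict:
                raise
            warnings.warn(str(e) + " -- record skipped")
            continue
        records.append(rec)
        if label not in classes:
            classes.append(label)
    return Dataset(records, classes)


def write_dataset(d: Dataset, fasta_path: str | Path, labels_path: str | Path) -> None:
    """Write a Dataset back to FASTA + label TSV (inverse of read_dataset)."""
    recs = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in d]
    SeqIO.write(recs, str(fasta_path), "fasta-2line")
    with open(labels_path, "w") as fh:
        fh.write("id\tcompartment\n")
        for s in d:
            fh.write(f"{s.id}\t{s.label}\n")


@dataclass
class CompartmentTree:
    """A rooted tree over compartments; leaves are exactly the classes.

    Nodes are dicts ``{"name": str, "children": [...]}``; a node without
    (or with an empty) ``children`` list is a leaf.
    """

    root: dict

    @classmethod
    def from_json(cls, path: str | Path) -> "CompartmentTree":
        with open(path) as fh:
            return cls(json.load(fh))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CompartmentTree":
        import yaml
        with open(path) as fh:
            return cls(yaml.safe_load(fh))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.root, fh, indent=2)

    def _walk(self, node=None):
        node = self.root if node is None else node
        yield node
        for c in node.get("children", []) or []:
            yield from self._walk(c)

    def leaves(self, node=None) -> list[str]:
        node = self.root if node is None else node
        if not node.get("children"):
            return [node["name"]]
        out: list[str] = []
        for c in node["children"]:
            out.extend(self.leaves(c))
        return out

    def internal_nodes(self) -> list[dict]:
        return [n for n in self._walk() if n.get("children")]

    def ancestors_of_leaf(self, cls: str) -> list[dict]:
        """Internal nodes on the root-to-leaf path, root first."""
        path: list[dict] = []

        def rec(node, trail):
            if not node.get("children"):
                return node["name"] == cls
            for c in node["children"]:
                if rec(c, trail + [node]):
                    if not path:
                        path.extend(trail + [node])
                    return True
            return False

        if not rec(self.root, []):
            raise KeyError(f"class {cls!r} is not a leaf of the tree")
        return path

    def parent_of_leaf(self, cls: str) -> dict:
        """The internal node whose child subtree contains ``cls`` as a leaf
        of a direct child (i.e. the parent in the leaf-to-root path)."""
        def rec(node):
            for c in node.get("children", []) or []:
                if not c.get("children") and c["name"] == cls:
                    return node
                found = rec(c)
                if found is not None:
                    return found
            return None
        found = rec(self.root)
        if found is None:
            raise KeyError(f"class {cls!r} is not a leaf of the tree")
        return found

    def validate(self, classes: Iterable[str]) -> None:
        leaves = self.leaves()
        if sorted(leaves) != sorted(set(leaves)):
            raise ValueError("tree leaves are not unique")
        if sorted(leaves) != sorted(classes):
            raise ValueError(
                f"tree leaves {sorted(leaves)} do not match dataset classes {sorted(classes)}"
            )

    @classmethod
    def example_nine_compartments(cls) -> "CompartmentTree":
        """A synthetic example tree grouping the nine yeast compartments by
        a plausible sorting route (secretory pathway vs. intracellular).
        Shipped for documentation and testing; real analyses should supply
        a biologically curated tree."""
        return cls({
            "name": "root",
            "children": [
                {"name": "secretory", "children": [
                    {"name": "ER"}, {"name": "Golgi"}, {"name": "Vacuole"},
                    {"name": "Membrane"}, {"name": "Secreted"},
                ]},
                {"name": "intracellular", "children": [
                    {"name": "Cytosol"}, {"name": "Nuclear"},
                    {"name": "Mitochondria"}, {"name": "Peroxisome"},
                ]},
            ],
        })


def relabel(seq: LabeledSequence, **kw) -> LabeledSequence:
    """Return a copy of ``seq`` with fields replaced."""
    return replace(seq, **kw)
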