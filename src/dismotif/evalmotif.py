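"""Motif evaluation: known-motif recovery, conservation scoring, and
statistical significance.

A known motif counts as *recovered* when, retrieving the global top
``4 * n_known`` instances of the found motifs, at least one third of the
known instances are each overlapped by a found instance over at least
half the motif width.  Conservation uses per-residue states parsed from
a ClustalW-style annotation line (``*`` identical, ``:`` strong, ``.``
weak, space none); an instance is conserved when every site is strong or
identical.  Significance: an upper-tail hypergeometric test for
conservation enrichment, and a Monte-Carlo null of random motifs
(random positions, matched instance counts and widths) for recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from .discover import MotifInstance

CONSERVATION_CHARS = {"*": "identical", ":": "strong", ".": "weak", " ": "none"}


@dataclass(frozen=True)
class KnownMotif:
    """A catalogued motif with its known instance coordinates
    (0-based half-open)."""

    id: str
    source: str                       # e.g. "MinimotifMiner" | "InterPro"
    instances: tuple                  # of (seq_id, start, end)

    def __post_init__(self) -> None:
        for (sid, s, e) in self.instances:
            if not 0 <= s < e:
                raise ValueError(f"bad instance coordinates for {self.id}: {(sid, s, e)}")


def read_known_motifs(path) -> list[KnownMotif]:
    """TSV with header ``motif_id source seq_id start end`` (1-based
    inclusive on disk)."""
    by_id: dict[str, tuple[str, list]] = {}
    with open(path) as fh:
        header = fh.readline().split()
        if header[:2] != ["motif_id", "source"]:
            raise ValueError("known-motif table must have a motif_id/source header")
        for line in fh:
            if not line.strip():
                continue
            mid, source, sid, start, end = line.split("\t")
            by_id.setdefault(mid, (source, []))[1].append(
                (sid, int(start) - 1, int(end)))
    return [KnownMotif(mid, src, tuple(inst)) for mid, (src, inst) in by_id.items()]


def is_recovered(km: KnownMotif, found: list[MotifInstance], W: int) -> bool:
    """True iff >= ceil(n/3) known instances each overlap a found instance
    by at least W/2 residues."""
    if not km.instances:
        raise ValueError("known motif has no instances")
    need = math.ceil(len(km.instances) / 3)
    hit = 0
    for (sid, s, e) in km.instances:
        for f in found:
            if f.seq_id == sid and f.overlap(s, e) >= W / 2:
                hit += 1
                break
    return hit >= need


def conserved_fraction(instances: list[MotifInstance],
                       tracks: dict[str, str]) -> float:
    """Percentage of instances whose sites are all strong/identical.

    ``tracks`` maps seq_id to a per-residue state string over
    {none, weak, strong, identical} encoded as ``' .:*'`` or the state
    names' initials; here we accept the ClustalW characters directly.
    """
    if not instances:
        return 0.0
    conserved = 0
    for x in instances:
        if x.seq_id not in tracks:
            raise KeyError(f"no conservation track for sequence {x.seq_id!r}")
        track = tracks[x.seq_id]
        if x.end > len(track):
            raise ValueError(f"instance {x} outside conservation track")
        if all(ch in "*:" for ch in track[x.start: x.end]):
            conserved += 1
    return 100.0 * conserved / len(instances)


def hypergeom_pvalue(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N population, K marked,
    n drawn): the chance of seeing at least ``k`` conserved instances
    among ``n`` found ones if conservation were as frequent as in the
    background (``K`` of ``N``)."""
    if not (0 <= k <= n <= N and k <= K <= N):
        raise ValueError(f"inconsistent hypergeometric counts k={k} n={n} K={K} N={N}")
    return float(hypergeom.sf(k - 1, N, K, n))


def random_instances(seqs: list, counts_widths: list[tuple[int, int]],
                     rng: np.random.Generator) -> list[MotifInstance]:
    """Instance sets of 'random motifs': for each (count, width) pair,
    ``count`` uniformly placed width-``width`` windows in random
    sequences."""
    out = []
    usable = [(s.id, len(s.residues)) for s in seqs]
    for m, (count, width) in enumerate(counts_widths):
        fits = [(sid, L) for sid, L in usable if L >= width]
        if not fits:
            continue
        for _ in range(count):
            sid, L = fits[int(rng.integers(len(fits)))]
            start = int(rng.integers(L - width + 1))
            out.append(MotifInstance(f"rand{m}", sid, start, start + width, 1.0))
    return out


def recovery_pvalue(observed: int, known_list: list[KnownMotif], seqs: list,
                    trials: int, rng: np.random.Generator, W: int = 4,
                    instances_per_known: int = 4) -> float:
    """Monte-Carlo p-value for recovering ``observed`` known motifs.

    Each trial replaces the found instances by random-motif instance
    sets (per known motif, ``instances_per_known * n_known`` random
    windows of width W) and counts recovered motifs; the estimator is
    (1 + #{trials >= observed}) / (trials + 1).
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    as_extreme = 0
    for _ in range(trials):
        score = 0
        for km in known_list:
            n_found = instances_per_known * len(km.instances)
            rand = random_instances(seqs, [(n_found, W)], rng)
            score += int(is_recovered(km, rand, W))
        if score >= observed:
            as_extreme += 1
    return (1 + as_extreme) / (trials + 1)


def parse_conservation_aln(path) -> dict[str, str]:
    """Per-sequence conservation tracks from a ClustalW alignment.

    The consensus annotation line assigns each alignment column one of
    ``* : .`` or space; each sequence's track keeps the columns where it
    has a residue (gaps dropped), so track length equals the ungapped
    sequence length.
    """
    from Bio import AlignIO
    aln = AlignIO.read(str(path), "clustal")
    consensus = aln.column_annotations["clustal_consensus"]
    tracks: dict[str, str] = {}
    for rec in aln:
        track = [c for res, c in zip(str(rec.seq), consensus) if res != "-"]
        tracks[rec.id] = "".join(track)
    return tracks


def read_conservation_tsv(path) -> dict[str, str]:
    """Tracks from a two-column TSV ``seq_id<TAB>states`` where states is a
    string over ``' .:*'``."""
    tracks = {}
    with open(path) as fh:
        fh.readline()
        for line in fh:
            if not line.rstrip("\n"):
                continue
            sid, states = line.rstrip("\n").split("\t")
            tracks[sid] = states
    return tracks
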