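import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from dismotif.seqdata import Dataset, LabeledSequence
from dismotif.simevo import SubstitutionModel
from dismotif.motifhmm import build_hmm


@pytest.fixture(scope="session")
def blosum62() -> SubstitutionModel:
    return SubstitutionModel.load("BLOSUM62")


@pytest.fixture()
def tiny_dataset() -> Dataset:
    return Dataset([
        LabeledSequence("s1", "ACDEFGHIKLMNP", "a"),
        LabeledSequence("s2", "MNPQRSTVWYACD", "a"),
        LabeledSequence("s3", "QRSTVWYACDEFG", "a"),
        LabeledSequence("s4", "GHIKLMNPQRSTV", "b"),
    ])


def random_motif_hmm(W: int, rng: np.random.Generator, mean_length: float = 8.0):
    """A fully random (but valid) motif HMM for property tests."""
    from dismotif.motifhmm import transition_support
    h = build_hmm(W, rng.dirichlet(np.ones(20)), rng, mean_length=mean_length)
    sup = transition_support(W)
    trans = np.zeros_like(h.trans)
    for i in range(h.K):
        idx = np.nonzero(sup[i])[0]
        trans[i, idx] = rng.dirichlet(np.ones(len(idx)))
    h.trans = trans
    init = np.zeros(h.K)
    init[[0, 1]] = rng.dirichlet(np.ones(2))
    h.init = init
    h.match_emis = np.vstack([rng.dirichlet(np.ones(20) * 0.5) for _ in range(W)])
    h.validate()
    return h
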