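import numpy as np
import pytest

from embalign import PairwiseAlignment, ProteinSequence

AA = "ARNDCQEGHILKMFPSTWYV"


@pytest.fixture
def example_alignments():
    """Two alignments of the peptides P=RKD and Q=DNN used throughout the
    distance-metric worked examples."""
    a1 = PairwiseAlignment("-RKD", "DN-N")
    a2 = PairwiseAlignment("RKD-", "D-NN")
    return a1, a2


def random_sequence(rng, min_len=1, max_len=6, sid="s") -> ProteinSequence:
    n = int(rng.integers(min_len, max_len + 1))
    return ProteinSequence(sid, "".join(rng.choice(list(AA), n)))


def random_alignment(p: str, q: str, rng) -> PairwiseAlignment:
    """A uniform-ish random alignment of two strings: a random monotone path
    of diagonal / gap-in-Q / gap-in-P moves."""
    i = j = 0
    pa, qa = [], []
    while i < len(p) or j < len(q):
        moves = []
        if i < len(p) and j < len(q):
            moves.append("D")
        if i < len(p):
            moves.append("X")
        if j < len(q):
            moves.append("Y")
        mv = moves[int(rng.integers(len(moves)))]
        if mv == "D":
            pa.append(p[i]); qa.append(q[j]); i += 1; j += 1
        elif mv == "X":
            pa.append(p[i]); qa.append("-"); i += 1
        else:
            pa.append("-"); qa.append(q[j]); j += 1
    return PairwiseAlignment("".join(pa), "".join(qa))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
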