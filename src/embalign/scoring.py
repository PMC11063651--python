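"""Substitution scoring: cosine similarity, the embedding-based E-score, and
BLOSUM lookup, unified behind a single positional scoring contract.

The E-score between residue i of P and residue j of Q is the cosine
similarity of their per-residue embedding vectors,

    E-score(i, j) = CosSim(E(P)_i, E(Q)_j),

which lies in [-1, 1] and, for contextual embeddings, changes with the
surrounding sequence.  A BLOSUM model scores (i, j) by looking up the letter
pair (P[i], Q[j]) in a fixed matrix.  Either kind of model carries its own
affine gap parameters: BLOSUM models default to the NCBI BLAST values
(open -11, extend -1); E-score models default to (open -0.25, extend -0.01),
matched to the [-1, 1] score scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .embeddings import EmbeddingMatrix
from .io_formats import ProteinSequence, SubstitutionMatrix

BLOSUM_GAP_OPEN = -11.0
BLOSUM_GAP_EXTEND = -1.0
ESCORE_GAP_OPEN = -0.25
ESCORE_GAP_EXTEND = -0.01


def cosine_similarity(a, b) -> float:
    """Cosine of the angle between two vectors, clamped to [-1, 1].

    Raises on zero vectors (the angle is undefined) and on length mismatch.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"vector shapes differ: {a.shape} vs {b.shape}")
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine similarity undefined for a zero vector")
    # identical (or exactly opposite) vectors hit the endpoints exactly,
    # bypassing round-off in the dot/norm quotient
    if np.array_equal(a, b):
        return 1.0
    if np.array_equal(a, -b):
        return -1.0
    return float(np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0))


def escore(p_emb: EmbeddingMatrix, q_emb: EmbeddingMatrix,
           i: int, j: int) -> float:
    """E-score of residue i of P against residue j of Q (1-based)."""
    if p_emb.dimension != q_emb.dimension:
        raise ValueError(
            f"embedding dimensions differ: {p_emb.dimension} vs "
            f"{q_emb.dimension}"
        )
    return cosine_similarity(p_emb.row(i), q_emb.row(j))


def escore_matrix(p_emb: EmbeddingMatrix, q_emb: EmbeddingMatrix) -> np.ndarray:
    """All-pairs E-scores as an m x m' matrix, entry (i-1, j-1) being
    E-score(i, j).  Vectorized; identical to the scalar definition."""
    if p_emb.dimension != q_emb.dimension:
        raise ValueError(
            f"embedding dimensions differ: {p_emb.dimension} vs "
            f"{q_emb.dimension}"
        )
    p = p_emb.values / np.linalg.norm(p_emb.values, axis=1, keepdims=True)
    q = q_emb.values / np.linalg.norm(q_emb.values, axis=1, keepdims=True)
    return np.clip(p @ q.T, -1.0, 1.0)


@dataclass(frozen=True)
class ScoringModel:
    """Positional substitution scorer for a fixed pair of sequences, plus
    affine gap parameters.  ``score_at(i, j)`` (1-based) must be defined for
    all 1 <= i <= len(P), 1 <= j <= len(Q)."""

    score_at: Callable[[int, int], float]
    gap_open: float
    gap_extend: float
    label: str
    p_len: int
    q_len: int


def make_blosum_model(matrix: SubstitutionMatrix, p: ProteinSequence,
                      q: ProteinSequence,
                      gap_open: float = BLOSUM_GAP_OPEN,
                      gap_extend: float = BLOSUM_GAP_EXTEND) -> ScoringModel:
    """Fixed-matrix scorer: score_at(i, j) = matrix(P[i], Q[j]).

    Every residue letter occurring in P or Q must be covered by the matrix
    (its own B/Z/X rows are used for ambiguity codes when present; no
    substitution values are invented)."""
    for seq in (p, q):
        for ch in set(seq.residues):
            if (ch, ch) not in matrix.scores:
                raise KeyError(
                    f"residue {ch!r} of {seq.id!r} is not covered by "
                    f"matrix {matrix.name}"
                )

    def score_at(i: int, j: int) -> float:
        return matrix.score(p[i], q[j])

    return ScoringModel(score_at, float(gap_open), float(gap_extend),
                        matrix.name, len(p), len(q))


def make_matrix_model(scores: np.ndarray, label: str,
                      gap_open: float, gap_extend: float) -> ScoringModel:
    """Scorer backed by a precomputed positions-by-positions score array
    (entry (i-1, j-1) scores the pair (i, j))."""
    scores = np.asarray(scores, dtype=np.float64)

    def score_at(i: int, j: int) -> float:
        return float(scores[i - 1, j - 1])

    return ScoringModel(score_at, float(gap_open), float(gap_extend),
                        label, scores.shape[0], scores.shape[1])


def make_escore_model(p_emb: EmbeddingMatrix, q_emb: EmbeddingMatrix,
                      gap_open: float = ESCORE_GAP_OPEN,
                      gap_extend: float = ESCORE_GAP_EXTEND) -> ScoringModel:
    """E-score scorer over two embedded sequences.  The full cosine matrix is
    precomputed once; score_at is a lookup."""
    mat = escore_matrix(p_emb, q_emb)
    label = f"escore:{p_emb.model_name}"
    return make_matrix_model(mat, label, gap_open, gap_extend)
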