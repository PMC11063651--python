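"""Affine-gap pairwise alignment over any positional scoring model.

The aligner is the Gotoh three-state dynamic program (states: residue pair,
gap in the Q row, gap in the P row).  A gap run of length k costs
``gap_open + k * gap_extend`` — the opening penalty is charged once per run
and every gap symbol, including the first, pays the extension penalty,
matching the NCBI BLAST convention for "-11 open / -1 extend".

Two modes are supported: ``global`` charges every gap, ``semiglobal``
(global alignment without end-gap penalties) makes leading and trailing gap
runs in either row free, which is appropriate when two domain sequences are
expected to align end to end but may overhang.

Traceback is deterministic: at equal score the residue-pair state is
preferred over a gap in the Q row, which is preferred over a gap in the P
row, and extending an open gap is preferred over opening a new one.  Ties
encountered during traceback are reported on the result.

``brute_force_align`` enumerates every alignment of two short sequences and
is the correctness oracle for the dynamic program.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import GAP, PairwiseAlignment, ProteinSequence
from .scoring import ScoringModel

NEG_INF = float("-inf")

_M, _X, _Y = 0, 1, 2  # residue pair / gap in Q row / gap in P row


@dataclass(frozen=True)
class AlignmentResult:
    alignment: PairwiseAlignment
    score: float
    mode: str
    scoring_label: str
    tied: bool = False  # traceback met at least one equal-score choice


def _check_mode(mode: str) -> None:
    if mode not in ("global", "semiglobal"):
        raise ValueError(f"mode must be 'global' or 'semiglobal', got {mode!r}")


def _fill(n: int, m: int, model: ScoringModel, mode: str):
    go, ge = model.gap_open, model.gap_extend
    M = np.full((n + 1, m + 1), NEG_INF)
    X = np.full((n + 1, m + 1), NEG_INF)
    Y = np.full((n + 1, m + 1), NEG_INF)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = 0.0 if mode == "semiglobal" else go + i * ge
    for j in range(1, m + 1):
        Y[0, j] = 0.0 if mode == "semiglobal" else go + j * ge
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = model.score_at(i, j)
            M[i, j] = s + max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            X[i, j] = max(M[i - 1, j] + go + ge, X[i - 1, j] + ge,
                          Y[i - 1, j] + go + ge)
            Y[i, j] = max(M[i, j - 1] + go + ge, Y[i, j - 1] + ge,
                          X[i, j - 1] + go + ge)
    return M, X, Y


def _best_state(M, X, Y, i, j):
    vals = (M[i, j], X[i, j], Y[i, j])
    best = max(vals)
    state = vals.index(best)  # prefers M over X over Y
    tied = sum(v == best for v in vals if v != NEG_INF) > 1
    return state, best, tied


def align(p: ProteinSequence, q: ProteinSequence, model: ScoringModel,
          mode: str = "semiglobal") -> AlignmentResult:
    """Optimal affine-gap alignment of P and Q under the given model."""
    _check_mode(mode)
    n, m = len(p), len(q)
    if model.p_len != n or model.q_len != m:
        raise ValueError(
            f"model covers {model.p_len}x{model.q_len} positions but the "
            f"sequences have lengths {n} and {m}"
        )
    M, X, Y = _fill(n, m, model, mode)
    tied = False

    if mode == "global":
        end_i, end_j = n, m
        state, score, t = _best_state(M, X, Y, n, m)
        tied |= t
    else:
        # free trailing gaps: best cell on the last row or last column,
        # preferring the corner, then fewer appended trailing gaps
        candidates = [(n, m)]
        candidates += [(i, m) for i in range(n - 1, -1, -1)]
        candidates += [(n, j) for j in range(m - 1, -1, -1)]
        score = NEG_INF
        end_i = end_j = 0
        state = _M
        for (i, j) in candidates:
            st, v, t = _best_state(M, X, Y, i, j)
            if v > score:
                score, end_i, end_j, state, cell_tied = v, i, j, st, t
        tied |= cell_tied

    go, ge = model.gap_open, model.gap_extend
    pa = []
    qa = []
    # trailing free gaps (semiglobal end cell off the corner)
    if end_i < n:
        pa.append(p.residues[end_i:])
        qa.append(GAP * (n - end_i))
    if end_j < m:
        pa.append(GAP * (m - end_j))
        qa.append(q.residues[end_j:])

    i, j = end_i, end_j
    core_p = []
    core_q = []
    while i > 0 or j > 0:
        if j == 0:
            core_p.append(p.residues[i - 1::-1])
            core_q.append(GAP * i)
            break
        if i == 0:
            core_p.append(GAP * j)
            core_q.append(q.residues[j - 1::-1])
            break
        if state == _M:
            prev = (M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            order = (_M, _X, _Y)
            target = max(prev)
            choices = [st for st in order if prev[st] == target]
            tied |= len(choices) > 1
            core_p.append(p.residues[i - 1])
            core_q.append(q.residues[j - 1])
            state = choices[0]
            i, j = i - 1, j - 1
        elif state == _X:
            prev = {_X: X[i - 1, j] + ge, _M: M[i - 1, j] + go + ge,
                    _Y: Y[i - 1, j] + go + ge}
            order = (_X, _M, _Y)  # prefer extension over opening
            target = max(prev.values())
            choices = [st for st in order if prev[st] == target]
            tied |= len(choices) > 1
            core_p.append(p.residues[i - 1])
            core_q.append(GAP)
            state = choices[0]
            i -= 1
        else:
            prev = {_Y: Y[i, j - 1] + ge, _M: M[i, j - 1] + go + ge,
                    _X: X[i, j - 1] + go + ge}
            order = (_Y, _M, _X)
            target = max(prev.values())
            choices = [st for st in order if prev[st] == target]
            tied |= len(choices) > 1
            core_p.append(GAP)
            core_q.append(q.residues[j - 1])
            state = choices[0]
            j -= 1

    p_aligned = "".join(core_p)[::-1] + "".join(pa)
    q_aligned = "".join(core_q)[::-1] + "".join(qa)
    alignment = PairwiseAlignment(p_aligned, q_aligned)
    return AlignmentResult(alignment, float(score), mode, model.label, tied)


def score_alignment(alignment: PairwiseAlignment, model: ScoringModel,
                    mode: str = "semiglobal") -> float:
    """Score an existing alignment under a model: substitution scores over
    residue-residue columns plus affine costs per gap run (terminal runs are
    free in semiglobal mode)."""
    _check_mode(mode)
    if len(alignment.p) != model.p_len or len(alignment.q) != model.q_len:
        raise ValueError(
            "alignment de-gaps to lengths "
            f"({len(alignment.p)}, {len(alignment.q)}) but the model covers "
            f"({model.p_len}, {model.q_len})"
        )
    total = 0.0
    i = j = 0
    for a, b in zip(alignment.p_aligned, alignment.q_aligned):
        if a != GAP:
            i += 1
        if b != GAP:
            j += 1
        if a != GAP and b != GAP:
            total += model.score_at(i, j)
    L = len(alignment)
    for row in (alignment.p_aligned, alignment.q_aligned):
        k = 0
        while k < L:
            if row[k] == GAP:
                start = k
                while k < L and row[k] == GAP:
                    k += 1
                terminal = start == 0 or k == L
                if not (mode == "semiglobal" and terminal):
                    total += model.gap_open + (k - start) * model.gap_extend
            else:
                k += 1
    return total


def enumerate_alignments(p: str, q: str):
    """Yield every alignment of the two strings (pairs of gapped rows with no
    double-gap column), by enumerating monotone move sequences."""
    n, m = len(p), len(q)
    stack = [(0, 0, "", "")]
    while stack:
        i, j, pa, qa = stack.pop()
        if i == n and j == m:
            yield PairwiseAlignment(pa, qa)
            continue
        if i < n and j < m:
            stack.append((i + 1, j + 1, pa + p[i], qa + q[j]))
        if i < n:
            stack.append((i + 1, j, pa + p[i], qa + GAP))
        if j < m:
            stack.append((i, j + 1, pa + GAP, qa + q[j]))


def brute_force_align(p: ProteinSequence, q: ProteinSequence,
                      model: ScoringModel,
                      mode: str = "semiglobal") -> AlignmentResult:
    """Exhaustive-enumeration optimum; the test oracle for :func:`align`.
    Only feasible for |P| + |Q| <= 12."""
    _check_mode(mode)
    if len(p) + len(q) > 12:
        raise ValueError("brute force limited to |P| + |Q| <= 12")
    best = None
    best_score = NEG_INF
    for aln in enumerate_alignments(p.residues, q.residues):
        s = score_alignment(aln, model, mode)
        if s > best_score:
            best, best_score = aln, s
    return AlignmentResult(best, best_score, mode, model.label)
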