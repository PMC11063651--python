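"""Distances between two alignments of the same sequence pair.

Five metrics are provided, all valued in [0, 1] with 0 for identical
alignments.  Three are homology-set distances (Jaccard-style ``d_ssp`` which
ignores gaps, ``d_seq`` which treats all gaps in a sequence as one symbol,
and ``d_pos`` which labels each gap with the number of residues of its own
sequence preceding it).  The other two are position-based:

* the relative displacement distance ``d_d`` compares, for every residue
  pair (i of P, j of Q), the column offset p_i - q_j between the two
  alignments, normalized by 1 / (m * n * (m + n));

* the closest context distance ``d_cc`` measures, for every residue, how far
  (counted in letters, gaps free) the other alignment places it from a
  position with the same opposite symbol, normalized by 1 / (4 * m * n).

Throughout, P has length n and Q has length m, and positions are 1-based.
"""

from __future__ import annotations

from .io_formats import GAP, MSA, PairwiseAlignment


def position_index_map(alignment: PairwiseAlignment):
    """1-based columns of each residue in the gapped rows: ``p[i-1]`` is the
    column of P[i] in the P row, ``q[j-1]`` the column of Q[j] in the Q row.
    Both lists are strictly increasing."""
    p = [k + 1 for k, c in enumerate(alignment.p_aligned) if c != GAP]
    q = [k + 1 for k, c in enumerate(alignment.q_aligned) if c != GAP]
    return p, q


def _check_same_sequences(a1: PairwiseAlignment, a2: PairwiseAlignment):
    if a1.p != a2.p or a1.q != a2.q:
        raise ValueError(
            "the two alignments do not align the same sequences: "
            f"({a1.p!r}, {a1.q!r}) vs ({a2.p!r}, {a2.q!r})"
        )


# ---------------------------------------------------------------------------
# Relative displacement distance

def displacement_profile(alignment: PairwiseAlignment):
    """d_A(i, j) = p_i - q_j for all residue pairs, as a nested list."""
    p, q = position_index_map(alignment)
    return [[pi - qj for qj in q] for pi in p]


def relative_displacement_distance(a1: PairwiseAlignment,
                                   a2: PairwiseAlignment) -> float:
    """Mean absolute change of the column offset p_i - q_j between the two
    alignments, scaled by 1 / (m * n * (m + n)) into [0, 1]."""
    _check_same_sequences(a1, a2)
    n, m = len(a1.p), len(a1.q)
    d1 = displacement_profile(a1)
    d2 = displacement_profile(a2)
    total = sum(
        abs(d1[i][j] - d2[i][j]) for i in range(n) for j in range(m)
    )
    return total / (m * n * (m + n))


# ---------------------------------------------------------------------------
# Closest context distance

def _letters_in_range(w: str, i: int, j: int) -> int:
    """Number of letters in the range w[i..j]: positions i+1..j when i <= j,
    positions j..i-1 when i > j (1-based, both interpretations inclusive of
    their stated endpoints).  w[i..i] is empty."""
    if i <= j:
        segment = w[i:j]  # 1-based positions i+1 .. j
    else:
        segment = w[j - 1:i - 1]  # 1-based positions j .. i-1
    return sum(1 for c in segment if c != GAP)


def _letters_before(w: str, pos: int) -> int:
    """Letters among the first pos-1 characters of w (1-based)."""
    return sum(1 for c in w[: pos - 1] if c != GAP)


def _cc_contribution(row_l: str, row_other: str,
                     pos_l: int, pos_other: int) -> int:
    """Closest-context contribution of one residue from alignment l.

    ``row_l``/``row_other`` are the OPPOSITE rows of alignments l and the
    other alignment; ``pos_l``/``pos_other`` are the residue's columns in
    the two alignments.  Case (a): the symbol opposite in alignment l is a
    letter; count the fewest letters from the residue's column in the other
    alignment to an occurrence of that letter there.  Case (b): the opposite
    symbol is a gap; take the difference of letter counts before the
    residue's position in the two opposite rows.
    """
    opposite = row_l[pos_l - 1]
    if opposite != GAP:
        dists = [
            _letters_in_range(row_other, pos_other, k + 1)
            for k, c in enumerate(row_other)
            if c == opposite
        ]
        if not dists:  # impossible when both alignments align the same pair
            raise AssertionError(
                f"letter {opposite!r} missing from the other alignment's row"
            )
        return min(dists)
    return abs(_letters_before(row_l, pos_l) - _letters_before(row_other,
                                                               pos_other))


def closest_context_contributions(a1: PairwiseAlignment,
                                  a2: PairwiseAlignment):
    """Per-residue contributions (d_P[l][i-1], d_Q[l][j-1] for l = 0, 1
    meaning alignments 1 and 2) that sum to 4*m*n*d_cc."""
    _check_same_sequences(a1, a2)
    p1, q1 = position_index_map(a1)
    p2, q2 = position_index_map(a2)
    rows_q = (a1.q_aligned, a2.q_aligned)
    rows_p = (a1.p_aligned, a2.p_aligned)
    pos_p = (p1, p2)
    pos_q = (q1, q2)
    d_p = [[], []]
    d_q = [[], []]
    for l in (0, 1):
        o = 1 - l
        for i in range(len(p1)):
            d_p[l].append(_cc_contribution(rows_q[l], rows_q[o],
                                           pos_p[l][i], pos_p[o][i]))
        for j in range(len(q1)):
            d_q[l].append(_cc_contribution(rows_p[l], rows_p[o],
                                           pos_q[l][j], pos_q[o][j]))
    return d_p, d_q


def closest_context_distance(a1: PairwiseAlignment,
                             a2: PairwiseAlignment) -> float:
    """Sum of all closest-context contributions, scaled by 1 / (4 * m * n)."""
    d_p, d_q = closest_context_contributions(a1, a2)
    n = len(a1.p)
    m = len(a1.q)
    total = sum(d_p[0]) + sum(d_p[1]) + sum(d_q[0]) + sum(d_q[1])
    return total / (4 * m * n)


# ---------------------------------------------------------------------------
# Homology-set distances

_VARIANTS = ("ssp", "seq", "pos")


def homology_sets(alignment: PairwiseAlignment, variant: str):
    """Homology sets H(A)^s_k: for each sequence s (1 = P, 2 = Q) and residue
    position k, the set of symbols opposite that residue.

    Gap treatment by variant: ``ssp`` drops gaps (empty set); ``seq`` labels
    every gap of sequence s as the one symbol ``g^s``; ``pos`` labels a gap
    of sequence s by the number of residues of s preceding it (``g^s_c``).
    Returned as ``{1: [...], 2: [...]}`` of frozensets in residue order.
    """
    if variant not in _VARIANTS:
        raise ValueError(f"variant must be one of {_VARIANTS}, got {variant!r}")
    p, q = position_index_map(alignment)
    out = {1: [], 2: []}
    for s, (positions, other_row, other_tag) in enumerate(
        [(p, alignment.q_aligned, 2),
         (q, alignment.p_aligned, 1)], start=1
    ):
        for col in positions:
            opposite = other_row[col - 1]
            if opposite != GAP:
                out[s].append(frozenset({opposite}))
            elif variant == "ssp":
                out[s].append(frozenset())
            elif variant == "seq":
                out[s].append(frozenset({f"g{other_tag}"}))
            else:  # pos: count residues of the gapped sequence before the gap
                c = _letters_before(other_row, col)
                out[s].append(frozenset({f"g{other_tag}_{c}"}))
    return out


def d_ssp(a1: PairwiseAlignment, a2: PairwiseAlignment) -> float:
    """Jaccard-style distance on gap-free homology sets: one minus the ratio
    of summed intersections to summed unions over all residue positions of
    both sequences.  All-empty sets (no residue pairings at all) give 0."""
    _check_same_sequences(a1, a2)
    h1 = homology_sets(a1, "ssp")
    h2 = homology_sets(a2, "ssp")
    inter = union = 0
    for s in (1, 2):
        for x, y in zip(h1[s], h2[s]):
            inter += len(x & y)
            union += len(x | y)
    if union == 0:
        return 0.0
    return 1.0 - inter / union


def _symmetric_difference_distance(a1, a2, variant):
    _check_same_sequences(a1, a2)
    h1 = homology_sets(a1, variant)
    h2 = homology_sets(a2, variant)
    terms = []
    for s in (1, 2):
        for x, y in zip(h1[s], h2[s]):
            denom = len(x) + len(y)
            terms.append(len(x ^ y) / denom if denom else 0.0)
    return sum(terms) / len(terms)


def d_seq(a1: PairwiseAlignment, a2: PairwiseAlignment) -> float:
    """Mean per-residue normalized symmetric difference of homology sets,
    with all gaps of a sequence treated as one symbol."""
    return _symmetric_difference_distance(a1, a2, "seq")


def d_pos(a1: PairwiseAlignment, a2: PairwiseAlignment) -> float:
    """Mean per-residue normalized symmetric difference of homology sets,
    with gaps labeled by the count of preceding residues of their sequence."""
    return _symmetric_difference_distance(a1, a2, "pos")


METRICS = {
    "cc": closest_context_distance,
    "d": relative_displacement_distance,
    "pos": d_pos,
    "seq": d_seq,
    "ssp": d_ssp,
}


def distance_report(a1: PairwiseAlignment, a2: PairwiseAlignment,
                    metrics=("cc", "d", "pos", "seq", "ssp")) -> dict:
    """All requested distances between two alignments, as a dict."""
    return {name: METRICS[name](a1, a2) for name in metrics}


# ---------------------------------------------------------------------------
# Reference alignments induced by an MSA

def induced_pairwise(msa: MSA, row_i: int, row_j: int) -> PairwiseAlignment:
    """The pairwise alignment of two MSA rows (0-based indices): their gapped
    strings with columns gapped in both rows removed."""
    if row_i == row_j:
        raise ValueError("row indices must differ")
    a = msa.rows[row_i][1]
    b = msa.rows[row_j][1]
    kept = [(x, y) for x, y in zip(a, b) if not (x == GAP and y == GAP)]
    if not kept:
        raise ValueError("both rows are all gaps")
    pa = "".join(x for x, _ in kept)
    qa = "".join(y for _, y in kept)
    if pa.count(GAP) == len(pa) or qa.count(GAP) == len(qa):
        raise ValueError("a row is all gaps after projection")
    return PairwiseAlignment(pa, qa)
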