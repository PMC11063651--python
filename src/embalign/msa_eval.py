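"""Benchmarking scorers against reference multiple sequence alignments.

The pipeline mirrors how alignment scoring functions are evaluated against
curated reference MSAs (e.g. conserved-domain alignments): sample sequence
pairs from the MSA, align each pair under every scorer, measure the distance
of each alignment to the reference alignment induced by the MSA, then
compare scorers by mean distance, paired Wilcoxon signed-rank tests, and
better/equal/worse tallies.

The module also computes 20 x 20 average-score matrices from residue pairs
sampled in the same MSA column ("aligned") versus different columns
("unaligned"), their Pearson correlation with substitution matrices, and a
synthetic conserved-motif MSA generator used as a self-contained benchmark.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .align_distances import METRICS, induced_pairwise
from .io_formats import (GAP, MSA, STANDARD_AA, ProteinSequence,
                         SubstitutionMatrix)
from .pairwise_align import align
from .scoring import (BLOSUM_GAP_EXTEND, BLOSUM_GAP_OPEN, ESCORE_GAP_EXTEND,
                      ESCORE_GAP_OPEN, make_blosum_model, make_escore_model)

DEFAULT_METRICS = ("cc", "d", "pos", "seq", "ssp")


# ---------------------------------------------------------------------------
# Scorer factories

class MatrixScorer:
    """Fixed substitution-matrix scorer factory (default NCBI BLAST gap
    penalties: open -11, extend -1)."""

    def __init__(self, matrix: SubstitutionMatrix,
                 gap_open: float = BLOSUM_GAP_OPEN,
                 gap_extend: float = BLOSUM_GAP_EXTEND,
                 label: str | None = None):
        self.matrix = matrix
        self.gap_open = gap_open
        self.gap_extend = gap_extend
        self.label = label or matrix.name

    def build(self, p: ProteinSequence, q: ProteinSequence):
        return make_blosum_model(self.matrix, p, q, self.gap_open,
                                 self.gap_extend)


class EscoreScorer:
    """Embedding-based scorer factory (default gap penalties matched to the
    [-1, 1] cosine scale: open -0.25, extend -0.01).  Embeddings are memoized
    per residue string."""

    def __init__(self, provider, gap_open: float = ESCORE_GAP_OPEN,
                 gap_extend: float = ESCORE_GAP_EXTEND):
        self.provider = provider
        self.gap_open = gap_open
        self.gap_extend = gap_extend
        self.label = f"escore:{provider.name}"
        self._memo: dict = {}

    def _embed(self, seq: ProteinSequence):
        key = seq.residues
        if key not in self._memo:
            self._memo[key] = self.provider.embed(seq)
        return self._memo[key]

    def build(self, p: ProteinSequence, q: ProteinSequence):
        return make_escore_model(self._embed(p), self._embed(q),
                                 self.gap_open, self.gap_extend)


def identity_matrix(match: float = 1.0, mismatch: float = -1.0,
                    name: str = "identity") -> SubstitutionMatrix:
    """Context-free identity/mismatch matrix over the full residue alphabet,
    on the same [-1, 1] scale as cosine scores."""
    from .io_formats import RESIDUE_ALPHABET
    scores = {
        (a, b): (match if a == b else mismatch)
        for a in RESIDUE_ALPHABET for b in RESIDUE_ALPHABET
    }
    return SubstitutionMatrix(name, scores)


# ---------------------------------------------------------------------------
# Pair sampling and evaluation

@dataclass(frozen=True)
class EvaluationConfig:
    max_pairs: int = 1000
    seed: int = 0
    mode: str = "semiglobal"
    metrics: tuple = DEFAULT_METRICS
    p_threshold: float = 0.01
    equal_tolerance: float = 1e-12

    def __post_init__(self):
        if self.max_pairs < 1:
            raise ValueError("max_pairs must be >= 1")
        if not 0.0 < self.p_threshold < 1.0:
            raise ValueError("p_threshold must be in (0, 1)")


@dataclass
class EvaluationResult:
    pairs: list                 # list of (row_i, row_j) actually evaluated
    per_pair: dict              # scorer label -> list of {metric: distance}
    means: dict                 # scorer label -> {metric: mean distance}
    wilcoxon: dict              # (label_a, label_b) -> {metric: p-value}
    tallies: dict               # (label_a, label_b) -> {metric: (a_better, equal, b_better)}
    skipped: list = field(default_factory=list)


def sample_pairs(msa: MSA, max_pairs: int = 1000, seed: int = 0) -> list:
    """Uniform sample without replacement from all unordered row pairs; if
    there are at most ``max_pairs`` pairs, all of them in deterministic
    order."""
    if len(msa) < 2:
        raise ValueError("MSA needs at least 2 rows")
    all_pairs = list(itertools.combinations(range(len(msa)), 2))
    if len(all_pairs) <= max_pairs:
        return all_pairs
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(all_pairs), size=max_pairs, replace=False)
    return [all_pairs[k] for k in sorted(idx)]


def wilcoxon_p(x, y, n_exact: int = 25) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value; zero differences are
    dropped, exact enumeration is used for up to ``n_exact`` nonzero
    tie-free differences, and the continuity-corrected normal approximation
    otherwise.  All-zero differences give p = 1."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    d = x - y
    d = d[d != 0.0]
    if d.size == 0:
        return 1.0
    tie_free = np.unique(np.abs(d)).size == d.size
    method = "exact" if (d.size <= n_exact and tie_free) else "approx"
    if method == "exact":
        res = stats.wilcoxon(d, zero_method="wilcox", method="exact")
    else:
        res = stats.wilcoxon(d, zero_method="wilcox", correction=True,
                             method="approx")
    return float(res.pvalue)


def evaluate_msa(msa: MSA, scorers: list, cfg: EvaluationConfig
                 ) -> EvaluationResult:
    """Align sampled MSA row pairs under every scorer and measure distances
    to the MSA-induced reference alignments.

    The design is strictly paired: if any scorer fails on a pair, that pair
    is dropped for all scorers (with a warning)."""
    labels = [s.label for s in scorers]
    if len(set(labels)) != len(labels):
        labels = [f"{lab}#{k}" for k, lab in enumerate(labels)]
    pairs = sample_pairs(msa, cfg.max_pairs, cfg.seed)
    per_pair = {lab: [] for lab in labels}
    kept_pairs = []
    skipped = []
    for (ri, rj) in pairs:
        ref = induced_pairwise(msa, ri, rj)
        p = ProteinSequence(msa.rows[ri][0], ref.p)
        q = ProteinSequence(msa.rows[rj][0], ref.q)
        records = []
        try:
            for scorer in scorers:
                model = scorer.build(p, q)
                res = align(p, q, model, cfg.mode)
                records.append({m: METRICS[m](res.alignment, ref)
                                for m in cfg.metrics})
        except Exception as exc:  # paired design: drop the pair everywhere
            warnings.warn(f"pair ({ri}, {rj}) skipped: {exc}")
            skipped.append((ri, rj))
            continue
        kept_pairs.append((ri, rj))
        for lab, rec in zip(labels, records):
            per_pair[lab].append(rec)

    means = {
        lab: {m: float(np.mean([r[m] for r in recs])) if recs else float("nan")
              for m in cfg.metrics}
        for lab, recs in per_pair.items()
    }
    wil = {}
    tal = {}
    for (la, lb) in itertools.combinations(labels, 2):
        wil[(la, lb)] = {}
        tal[(la, lb)] = {}
        for m in cfg.metrics:
            xs = np.array([r[m] for r in per_pair[la]])
            ys = np.array([r[m] for r in per_pair[lb]])
            wil[(la, lb)][m] = wilcoxon_p(xs, ys)
            diff = xs - ys
            better = int(np.sum(diff < -cfg.equal_tolerance))
            worse = int(np.sum(diff > cfg.equal_tolerance))
            equal = len(diff) - better - worse
            tal[(la, lb)][m] = (better, equal, worse)
    return EvaluationResult(kept_pairs, per_pair, means, wil, tal, skipped)


# ---------------------------------------------------------------------------
# Average E-score matrices and correlations

@dataclass(frozen=True)
class AverageScoreMatrix:
    """20 x 20 mean E-scores per amino-acid pair, sampled from an MSA.
    Rows/columns follow ``STANDARD_AA`` order; entries with no samples are
    NaN.  ``counts`` holds the per-entry sample counts."""

    category: str               # "aligned" or "unaligned"
    values: np.ndarray
    counts: np.ndarray
    n_samples: int
    same_row_draws: int = 0


def _aa_index() -> dict:
    return {aa: k for k, aa in enumerate(STANDARD_AA)}


def average_score_matrices(msa: MSA, provider, n_samples: int = 100_000,
                           seed: int = 0):
    """Average E-score matrices for residue pairs drawn from the same MSA
    column (aligned) and from different columns (unaligned).

    Samples for (a, b) and (b, a) are pooled, so both matrices are symmetric
    by construction.  Only the 20 standard amino acids enter the matrices.
    Returns ``(aligned, unaligned)`` :class:`AverageScoreMatrix` objects.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    aa_idx = _aa_index()
    embeddings = [provider.embed(msa.sequence(r)) for r in range(len(msa))]
    # residue cells: (row, column, letter index, residue position within row)
    cells = []
    col_cells: dict = {}
    for r, (_, gapped) in enumerate(msa.rows):
        pos = 0
        for c, ch in enumerate(gapped):
            if ch == GAP:
                continue
            pos += 1
            if ch not in aa_idx:
                continue
            cell = (r, c, aa_idx[ch], pos)
            cells.append(cell)
            col_cells.setdefault(c, []).append(cell)
    cols = [c for c, lst in col_cells.items() if len(lst) >= 2]
    if not cols or len(cells) < 2:
        raise ValueError("MSA has too few standard-residue cells to sample")
    col_weights = np.array(
        [len(col_cells[c]) * (len(col_cells[c]) - 1) / 2 for c in cols],
        dtype=np.float64)
    col_weights /= col_weights.sum()

    def score(cell_a, cell_b) -> float:
        ra, _, _, pa = cell_a
        rb, _, _, pb = cell_b
        va = embeddings[ra].row(pa)
        vb = embeddings[rb].row(pb)
        return float(np.dot(va, vb) /
                     (np.linalg.norm(va) * np.linalg.norm(vb)))

    out = {}
    same_row = 0
    for category in ("aligned", "unaligned"):
        sums = np.zeros((20, 20))
        counts = np.zeros((20, 20), dtype=np.int64)
        drawn = 0
        while drawn < n_samples:
            if category == "aligned":
                c = cols[rng.choice(len(cols), p=col_weights)]
                k1, k2 = rng.choice(len(col_cells[c]), size=2, replace=False)
                a, b = col_cells[c][k1], col_cells[c][k2]
            else:
                k1, k2 = rng.choice(len(cells), size=2, replace=False)
                a, b = cells[k1], cells[k2]
                if a[1] == b[1]:
                    continue  # same column: not an unaligned draw
                if a[0] == b[0]:
                    same_row += 1
            s = score(a, b)
            ia, ib = a[2], b[2]
            sums[ia, ib] += s
            counts[ia, ib] += 1
            if ia != ib:
                sums[ib, ia] += s
                counts[ib, ia] += 1
            drawn += 1
        with np.errstate(invalid="ignore"):
            values = np.where(counts > 0, sums / np.maximum(counts, 1),
                              np.nan)
        out[category] = AverageScoreMatrix(
            category, values, counts, n_samples,
            same_row if category == "unaligned" else 0)
    return out["aligned"], out["unaligned"]


def substitution_matrix_array(matrix: SubstitutionMatrix,
                              scale: bool = True) -> np.ndarray:
    """The 20 x 20 standard-residue block of a substitution matrix, optionally
    scaled to [-1, 1] by its maximum absolute entry (for comparability with
    cosine-score matrices)."""
    arr = np.array([[matrix.score(a, b) for b in STANDARD_AA]
                    for a in STANDARD_AA])
    if scale:
        arr = arr / np.max(np.abs(arr))
    return arr


def matrix_correlation(m1: np.ndarray, m2: np.ndarray) -> float:
    """Pearson correlation over the 210 upper-triangle-with-diagonal cells of
    two 20 x 20 matrices.  Missing (NaN) cells are an error."""
    m1 = np.asarray(m1, dtype=np.float64)
    m2 = np.asarray(m2, dtype=np.float64)
    if m1.shape != m2.shape:
        raise ValueError(f"shapes differ: {m1.shape} vs {m2.shape}")
    iu = np.triu_indices(m1.shape[0])
    x = m1[iu]
    y = m2[iu]
    bad = np.where(np.isnan(x) | np.isnan(y))[0]
    if bad.size:
        cells = [(int(iu[0][k]), int(iu[1][k])) for k in bad[:10]]
        raise ValueError(f"missing entries at cells {cells}")
    return float(stats.pearsonr(x, y).statistic)


# ---------------------------------------------------------------------------
# Synthetic conserved-motif benchmark MSA

def conserved_motif_msa(n_rows: int = 8, n_motifs: int = 3,
                        motif_len: int = 10, linker_len: int = 12,
                        motif_sub_rate: float = 0.05,
                        linker_sub_rate: float = 0.5,
                        linker_del_rate: float = 0.15,
                        seed: int = 0) -> MSA:
    """Generate a reference MSA emulating a conserved protein domain:
    strongly conserved motif blocks separated by noisy linkers.

    An ancestor sequence of alternating linkers and motifs is sampled, then
    each row independently substitutes residues (rarely inside motifs, often
    inside linkers) and deletes linker residues.  Columns are ancestor
    positions, so the alignment is true by construction.  The high linker
    substitution rate creates coincidental letter matches at non-homologous
    positions — the trap a context-free identity scorer falls into and a
    context-aware scorer is expected to avoid.
    """
    rng = np.random.default_rng(seed)
    aa = np.array(list(STANDARD_AA))
    segments = []  # (is_motif, length)
    segments.append((False, linker_len))
    for _ in range(n_motifs):
        segments.append((True, motif_len))
        segments.append((False, linker_len))
    ancestor = []
    is_motif = []
    for motif, length in segments:
        for _ in range(length):
            ancestor.append(str(rng.choice(aa)))
            is_motif.append(motif)
    rows = []
    for r in range(n_rows):
        chars = []
        for ch, motif in zip(ancestor, is_motif):
            if motif:
                if rng.random() < motif_sub_rate:
                    ch = str(rng.choice(aa))
                chars.append(ch)
            else:
                if rng.random() < linker_del_rate:
                    chars.append(GAP)
                elif rng.random() < linker_sub_rate:
                    chars.append(str(rng.choice(aa)))
                else:
                    chars.append(ch)
        rows.append((f"seq{r}", "".join(chars)))
    return MSA(tuple(rows))
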