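import itertools
import math

import numpy as np
import pytest

from embalign import (MSA, EscoreScorer, EvaluationConfig, MatrixScorer,
                      SyntheticEmbedder, average_score_matrices,
                      conserved_motif_msa, evaluate_msa, identity_matrix,
                      load_blosum, matrix_correlation, sample_pairs,
                      substitution_matrix_array, wilcoxon_p)
from embalign.io_formats import STANDARD_AA


class TestSamplePairs:
    def test_small_msa_returns_all_pairs(self):
        msa = MSA(tuple((f"s{i}", "ARND") for i in range(5)))
        pairs = sample_pairs(msa, max_pairs=1000, seed=0)
        assert pairs == list(itertools.combinations(range(5), 2))

    def test_reproducible_under_seed(self):
        msa = MSA(tuple((f"s{i}", "ARND") for i in range(30)))
        a = sample_pairs(msa, max_pairs=50, seed=7)
        b = sample_pairs(msa, max_pairs=50, seed=7)
        assert a == b

    def test_subsample_distinct(self):
        msa = MSA(tuple((f"s{i}", "ARND") for i in range(100)))
        pairs = sample_pairs(msa, max_pairs=50, seed=3)
        assert len(pairs) == 50
        assert len(set(pairs)) == 50


class TestWilcoxon:
    @staticmethod
    def exact_wilcoxon_oracle(d):
        """Exact two-sided signed-rank p-value by enumerating all sign
        assignments of the ranked absolute differences."""
        d = [x for x in d if x != 0]
        n = len(d)
        ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
        w_plus = sum(r for x, r in zip(d, ranks) if x > 0)
        total = n * (n + 1) / 2
        stat = min(w_plus, total - w_plus)
        count = 0
        for signs in itertools.product([0, 1], repeat=n):
            w = sum(r for s, r in zip(signs, ranks) if s)
            if min(w, total - w) <= stat:
                count += 1
        return count / 2 ** n

    def test_matches_exact_enumeration_small_samples(self, rng):
        for _ in range(10):
            n = int(rng.integers(5, 13))
            # tie-free differences so the exact null is unambiguous
            d = rng.permutation(np.arange(1, n + 1)).astype(float)
            d *= rng.choice([-1.0, 1.0], size=n)
            x = rng.normal(size=n)
            y = x - d
            assert wilcoxon_p(x, y) == pytest.approx(
                self.exact_wilcoxon_oracle(d), abs=1e-12)

    def test_all_zero_differences(self):
        x = np.arange(5.0)
        assert wilcoxon_p(x, x) == 1.0


class ReferenceScorer:
    """Scorer whose alignment trivially reproduces the induced reference:
    scores +1 exactly for the residue pairs the reference aligns."""

    def __init__(self, msa, pairs):
        from embalign import induced_pairwise
        from embalign.align_distances import position_index_map
        self.label = "oracle"
        self._maps = {}
        for (i, j) in pairs:
            ref = induced_pairwise(msa, i, j)
            p_cols, q_cols = position_index_map(ref)
            cols = {c: k + 1 for k, c in enumerate(q_cols)}
            matched = {
                (pi + 1, cols[c])
                for pi, c in enumerate(p_cols) if c in cols
            }
            self._maps[(ref.p, ref.q)] = matched

    def build(self, p, q):
        from embalign import make_matrix_model
        matched = self._maps[(p.residues, q.residues)]
        mat = np.full((len(p), len(q)), -1.0)
        for (i, j) in matched:
            mat[i - 1, j - 1] = 1.0
        return make_matrix_model(mat, "oracle", -0.6, -0.1)


class TestEvaluateMsa:
    MSA_TOY = MSA((
        ("a", "ARND-KWQ"),
        ("b", "-RNDQKW-"),
        ("c", "ARND-KW-"),
    ))

    def test_reference_reproducing_scorer_scores_zero(self):
        pairs = [(0, 1), (0, 2), (1, 2)]
        scorer = ReferenceScorer(self.MSA_TOY, pairs)
        cfg = EvaluationConfig(max_pairs=10, seed=0)
        res = evaluate_msa(self.MSA_TOY, [scorer], cfg)
        for m, v in res.means["oracle"].items():
            assert v == pytest.approx(0.0, abs=1e-12)

    def test_identical_scorer_twice_all_equal(self):
        m45 = load_blosum("BLOSUM45")
        scorers = [MatrixScorer(m45, label="x"), MatrixScorer(m45, label="y")]
        cfg = EvaluationConfig(max_pairs=10, seed=0)
        res = evaluate_msa(self.MSA_TOY, scorers, cfg)
        for m, p in res.wilcoxon[("x", "y")].items():
            assert p == 1.0
        for m, (better, equal, worse) in res.tallies[("x", "y")].items():
            assert (better, worse) == (0, 0)
            assert equal == len(res.pairs)

    def test_paired_design_counts_match(self):
        emb = SyntheticEmbedder(dimension=8, context_window=1, seed=0)
        scorers = [MatrixScorer(load_blosum("BLOSUM45")), EscoreScorer(emb)]
        cfg = EvaluationConfig(max_pairs=10, seed=0)
        res = evaluate_msa(self.MSA_TOY, scorers, cfg)
        counts = {len(v) for v in res.per_pair.values()}
        assert counts == {len(res.pairs)}

    def test_determinism_under_seed(self):
        msa = conserved_motif_msa(n_rows=5, seed=4)
        cfg = EvaluationConfig(max_pairs=6, seed=9)
        results = [
            evaluate_msa(msa, [MatrixScorer(load_blosum("BLOSUM45")),
                               EscoreScorer(SyntheticEmbedder(8, 1, 0))], cfg)
            for _ in range(2)
        ]
        assert results[0].means == results[1].means
        assert results[0].pairs == results[1].pairs

    def test_mean_invariant_to_pair_order(self):
        cfg = EvaluationConfig(max_pairs=10, seed=0)
        m45 = load_blosum("BLOSUM45")
        res = evaluate_msa(self.MSA_TOY, [MatrixScorer(m45)], cfg)
        recs = res.per_pair["BLOSUM45"]
        for m in cfg.metrics:
            assert np.mean([r[m] for r in reversed(recs)]) == pytest.approx(
                res.means["BLOSUM45"][m])


class TestAverageScoreMatrices:
    MSA_CONS = conserved_motif_msa(n_rows=6, n_motifs=2, motif_len=8,
                                   linker_len=8, seed=2)

    def test_context_free_provider_aligned_equals_unaligned(self):
        """With a context-free embedder the score of a letter pair does not
        depend on column, so the two matrices agree up to sampling noise."""
        emb = SyntheticEmbedder(dimension=16, context_window=0, seed=1)
        aligned, unaligned = average_score_matrices(
            self.MSA_CONS, emb, n_samples=4000, seed=5)
        both = ~np.isnan(aligned.values) & ~np.isnan(unaligned.values)
        # context-free scores are exact per letter pair: no noise at all
        np.testing.assert_allclose(aligned.values[both],
                                   unaligned.values[both], atol=1e-9)

    def test_symmetric_by_construction(self):
        emb = SyntheticEmbedder(dimension=16, context_window=2, seed=1)
        aligned, unaligned = average_score_matrices(
            self.MSA_CONS, emb, n_samples=2000, seed=5)
        for mat in (aligned, unaligned):
            np.testing.assert_allclose(mat.values, mat.values.T, atol=1e-12)

    def test_aligned_mean_exceeds_unaligned_with_context(self):
        """Residues from the same column share context on a conserved MSA,
        so a context-aware embedder scores them higher on average."""
        emb = SyntheticEmbedder(dimension=16, context_window=2, seed=1)
        aligned, unaligned = average_score_matrices(
            self.MSA_CONS, emb, n_samples=3000, seed=5)
        a = np.nanmean(aligned.values)
        u = np.nanmean(unaligned.values)
        assert a > u

    def test_diagonal_identical_contexts_approach_one(self):
        # an MSA of identical rows: aligned same-letter pairs share exact
        # context, so diagonal entries are exactly 1
        msa = MSA((("a", "ARNDKWARNDKW"), ("b", "ARNDKWARNDKW"),
                   ("c", "ARNDKWARNDKW")))
        emb = SyntheticEmbedder(dimension=16, context_window=2, seed=1)
        aligned, _ = average_score_matrices(msa, emb, n_samples=500, seed=5)
        diag = np.diag(aligned.values)
        sampled = ~np.isnan(diag)
        np.testing.assert_allclose(diag[sampled], 1.0, atol=1e-9)

    def test_unsampled_entries_are_nan_not_zero(self):
        msa = MSA((("a", "AAAA"), ("b", "AAAA")))
        emb = SyntheticEmbedder(dimension=8, context_window=0, seed=1)
        aligned, _ = average_score_matrices(msa, emb, n_samples=50, seed=5)
        idx = STANDARD_AA.index("A")
        assert not math.isnan(aligned.values[idx, idx])
        assert np.isnan(aligned.values[0, 1])  # (A, R) never sampled
        assert aligned.counts[0, 1] == 0


class TestMatrixCorrelation:
    def test_self_and_negated(self, rng):
        m = rng.normal(size=(20, 20))
        assert matrix_correlation(m, m) == pytest.approx(1.0)
        assert matrix_correlation(m, -m) == pytest.approx(-1.0)

    def test_hand_computed_toy(self):
        m1 = np.array([[1.0, 2.0, 3.0], [2.0, 4.0, 5.0], [3.0, 5.0, 6.0]])
        m2 = np.array([[2.0, 1.0, 4.0], [1.0, 3.0, 2.0], [4.0, 2.0, 5.0]])
        x = m1[np.triu_indices(3)]
        y = m2[np.triu_indices(3)]
        expected = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
        assert matrix_correlation(m1, m2) == pytest.approx(expected, abs=1e-12)

    def test_missing_cells_error(self):
        m = np.ones((20, 20))
        m2 = m.copy()
        m2[0, 3] = np.nan
        with pytest.raises(ValueError, match="missing"):
            matrix_correlation(m, m2)

    def test_blosum_scaling_bounds(self):
        arr = substitution_matrix_array(load_blosum("BLOSUM45"), scale=True)
        assert np.max(np.abs(arr)) == 1.0
        assert arr.shape == (20, 20)


class TestConservedMotifBenchmark:
    def test_generator_shape_and_determinism(self):
        m1 = conserved_motif_msa(seed=3)
        m2 = conserved_motif_msa(seed=3)
        assert m1.rows == m2.rows
        assert len(m1) == 8
        # motifs are never deleted, so rows keep all motif columns
        assert m1.alignment_length == 12 + 3 * (10 + 12)

    def test_context_aware_scorer_beats_identity(self):
        """The comparison design end to end on a small scale: on conserved-
        motif MSAs the context-aware embedding scorer produces alignments
        closer to the reference than a context-free identity matrix."""
        metrics = ("cc", "d", "pos")
        wins = {m: 0 for m in metrics}
        n_seeds = 5
        for seed in range(n_seeds):
            msa = conserved_motif_msa(seed=seed)
            scorers = [
                EscoreScorer(SyntheticEmbedder(32, 2, seed=seed)),
                MatrixScorer(identity_matrix(), gap_open=-0.25,
                             gap_extend=-0.01, label="identity"),
            ]
            cfg = EvaluationConfig(max_pairs=12, seed=seed, metrics=metrics)
            res = evaluate_msa(msa, scorers, cfg)
            for m in metrics:
                if res.means[scorers[0].label][m] < res.means["identity"][m]:
                    wins[m] += 1
        for m in metrics:
            assert wins[m] == n_seeds
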