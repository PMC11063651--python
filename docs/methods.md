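# Methods

## Scoring model

For proteins P (length n) and Q (length m), an embedding method E maps each
sequence to a matrix of per-residue vectors; the E-score of positions (i, j)
is the cosine similarity of row i of E(P) and row j of E(Q). Cosine values
are clamped to [−1, 1] after the dot/norm quotient so floating-point
overshoot cannot break downstream range invariants, and bit-identical (or
exactly opposite) vectors return the endpoints ±1 exactly. A zero embedding
row is a hard error rather than a zero score: it indicates a broken
provider, and silently scoring it 0 would bias alignments.

BLOSUM scoring looks the letter pair up in a fixed matrix. The bundled
BLOSUM45/50/62/80/90 tables are the canonical NCBI half-bit matrices, parsed
from NCBI-format text by the package's own reader, which validates symmetry
and coverage of the 20 standard residues on load. Ambiguity codes (B, Z, X,
U, O) are retained in sequences; under BLOSUM scoring they use the matrix's
own rows when present and are a named error otherwise — no substitution
values are invented. The transformer adapter maps U→C, O→K, B/Z→X before
tokenization (the usual convention for ProtT5-family vocabularies;
configurable).

## Aligner

The aligner is the Gotoh three-state affine-gap dynamic program. A gap run
of length k costs `gap_open + k·gap_extend` (opening charged once per run,
every gap symbol pays the extension), matching the NCBI BLAST convention in
which "−11 open / −1 extend" makes a length-1 gap cost −12. Default gap
parameters are (−11, −1) for BLOSUM models and (−0.25, −0.01) for E-score
models — the latter matched to the [−1, 1] score scale — both overridable.

Semi-global mode zero-initializes the first row/column of the gap states and
takes the optimum over the last row/column, so leading and trailing gap runs
in either row are free; it is the default because domain sequences are
expected to align end to end while end-gap penalties would distort the
alignment. Traceback is deterministic: at equal score the residue-pair state
is preferred over a gap in the Q row over a gap in the P row, and extending
an open gap is preferred over opening a new one; encountering any
equal-score choice sets a `tied` flag on the result. Scores are real-valued
throughout (cosine scores are non-integer; no integer fast path).
Correctness is checked against `brute_force_align`, which enumerates every
alignment of short sequences (|P|+|Q| ≤ 12) and scores each with the
independent `score_alignment` routine.

## Alignment distances

All five distances take two alignments of the same P, Q and are in [0, 1],
symmetric, and 0 for identical alignments. Positions are 1-based throughout.

* **d_d** compares the column offsets `d_A(i,j) = p_i − q_j` (p_i the column
  of P[i] in the gapped row) between the alignments and averages the
  absolute differences with normalization `1/(mn(m+n))`; the per-term bound
  `|d_{A1}(i,j) − d_{A2}(i,j)| ≤ m+n` makes the normalization valid and is
  asserted in the property sweep.
* **d_cc** sums, over both alignments and all residues, a per-residue
  contribution: if the symbol opposite the residue is a letter, the fewest
  letters (gaps free) from the residue's column in the other alignment to an
  occurrence of that letter there, using a range convention in which the
  range from i to j excludes position i when i ≤ j and runs from j to i−1
  when i > j; if the opposite symbol is a gap, the absolute difference in
  the number of letters before the residue's position in the two opposite
  rows. Normalization is `1/(4mn)` (contributions are bounded by m and n
  respectively). The letter case can never fail to find an occurrence when
  both alignments align the same pair, so that situation is asserted, not
  handled.
* **d_ssp / d_seq / d_pos** are built on homology sets: for each residue,
  the symbol opposite it. d_ssp ignores gaps (empty set) and is one minus
  the ratio of summed intersections to summed unions (an all-empty
  denominator, possible only when neither alignment pairs any residues,
  yields 0). d_seq labels every gap of sequence k with the single symbol
  g^k; d_pos labels it g^k_c where c is the count of residues of k
  preceding the gap in its own row — the labeling that actually carries
  positional information (labeling a gap by the index of the residue
  opposite it would make d_pos collapse onto d_seq). For d_seq/d_pos the
  scalar distance is the mean over the n+m residue positions of the
  normalized symmetric difference |H1 △ H2| / (|H1| + |H2|), with 0/0
  defined as 0. Homology entries are stored as sets although they are
  singletons for pairwise alignments, so the definitions generalize.

Reference alignments are induced from an MSA by taking two rows and deleting
columns gapped in both.

## Evaluation pipeline

`evaluate_msa` samples up to `max_pairs` (default 1000) unordered row pairs
uniformly without replacement (all pairs when fewer exist), aligns each
de-gapped pair under every scorer in the configured mode (default
semi-global), and measures the requested distances to the induced reference
alignment. The design is strictly paired: a scorer failure drops the pair
for all scorers. Scorers are compared by per-metric means, paired Wilcoxon
signed-rank p-values (two-sided, zero differences dropped, exact enumeration
for ≤ 25 tie-free differences, continuity-corrected normal approximation
otherwise; the default significance threshold is 0.01), and
better/equal/worse tallies with equality at 1e-12 — exact ties do occur,
e.g. when two scorers produce the identical alignment.

`average_score_matrices` draws residue pairs from the same MSA column
(aligned) or different columns (unaligned; same-row draws are permitted and
counted) and averages E-scores per amino-acid letter pair, pooling (a, b)
with (b, a) so the 20×20 matrices are symmetric by construction; an
unsampled entry is NaN, never 0. `matrix_correlation` is the Pearson
correlation over the 210 upper-triangle-with-diagonal cells. For
comparability with cosine matrices a substitution matrix is scaled to
[−1, 1] by its maximum absolute entry (max-abs rather than affine min-max;
configurable in principle by scaling beforehand).

## Synthetic embedder and benchmark

The synthetic embedder gives every residue letter (ambiguity codes included,
keeping the shape contract total) a fixed pseudo-random standard-normal base
vector drawn from the seed, and embeds a residue as its base vector plus its
neighbours' base vectors weighted by `decay^|offset|` within
`context_window` positions (defaults: dimension 32, window 2, decay 0.5 — a
simple, monotone model of local context influence). It is deterministic and
bit-reproducible given (sequence, dimension, window, seed), stored as
64-bit reals. With window 0 it is context-free: the E-score then depends
only on the letter pair, and the E-score aligner provably reduces to a
fixed-matrix aligner — a property used to validate the DP engine under
positional scoring.

The benchmark generator `conserved_motif_msa` emulates a conserved protein
domain family: an ancestor of alternating linkers and motifs (defaults:
3 motifs of 10 residues, linkers of 12, 8 rows), per-row substitutions at
rate 0.05 inside motifs and 0.5 inside linkers, and linker deletions at rate
0.15. Columns are ancestor positions, so the reference alignment is true by
construction. The high linker noise plants coincidental letter matches at
non-homologous offsets — the trap a context-free identity scorer falls
into, paying cheap gap penalties to chase spurious matches, while the
context-aware scorer discounts them because their neighbourhoods disagree.
The benchmark runs 20 generator seeds with up to 12 pairs per seed (sizes
chosen to exercise the full pipeline at small scale while keeping the suite
fast) and compares per-seed mean d_cc, d_d and d_pos between the embedding
scorer and an identity/mismatch matrix scorer given the same gap penalties,
with a paired Wilcoxon test across seeds.

What the generator does not emulate: insertions (only deletions, so columns
never have to be merged across rows), rate heterogeneity beyond the
motif/linker dichotomy, biochemically structured substitution preferences,
and phylogenetic correlation between rows (all rows are independent draws
from the ancestor). Passing the benchmark therefore shows that the pipeline
detects context sensitivity under controlled conditions, not that any
particular language model aligns real proteins better; with real model
embeddings the same machinery applies unchanged through the transformer
adapter.

## Numerical and interface choices

* 1-based positions in every public API touching sequence positions.
* Duplicate sequence ids are deduplicated by suffixing (conserved-domain
  exports can repeat accessions); '.' gaps are normalized to '-'.
* The embedding cache stores one HDF5 dataset per (model, sequence id) with
  a SHA-256 of the residue string; a reused id with a changed sequence is
  rejected rather than silently served.
* The CLI seeds all randomness from a single `--seed`; outputs carry a
  provenance header (version, scorer label, gap parameters, seed).

## Known limitations

* No local (Smith–Waterman) alignment, banding, or linear-memory variant;
  the DP is quadratic in time and memory.
* The transformer adapter is a thin, single-sequence interface; it refuses
  sequences beyond a configurable length rather than truncating.
* d_seq/d_pos aggregation follows the mean-over-positions form; other
  normalizations of the same per-position quotient exist in the literature,
  so cross-tool numeric comparisons of these two metrics should confirm the
  aggregation first.
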