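# Methods

This note records the scientific and numerical choices behind `acpsmo`:
what the pipeline assumes, which knobs matter, and what its tests do and
do not demonstrate.

## Problem setting

The task is binary classification of short peptides (≤ 50 standard
residues): anticancer peptides (ACPs) against either antimicrobial
peptides (AMPs, the hard negative) or generic non-functional peptides.
All features are sequence-derived; no structural or physicochemical
descriptors are used.  Labels are +1 (positive/ACP) and −1 throughout.

## Dataset hygiene

Pipelines in this field prepare data with CD-HIT: exact deduplication
within each class and removal of negatives similar to positives above an
identity threshold.  `acpsmo` re-implements the *semantics* exactly and
skips CD-HIT's speed machinery, which is unnecessary at peptide scale:

- **Identity measure.**  Matched positions of an optimal global alignment
  scoring match = 1 and charging nothing for mismatches or gaps, divided
  by the shorter sequence's length (CD-HIT's denominator; the alignment
  length is available as an alternative).  With free gaps the optimal
  match count equals the longest common subsequence, computed with
  Biopython's `PairwiseAligner`.  This is deliberately the most permissive
  alignment, so it *over*-estimates identity relative to gap-penalized
  aligners: two unrelated random 20-letter peptides typically score
  0.2–0.35, and occasionally above 0.4.  A 40% threshold (the
  conventional cross-set value, and the default) is therefore very
  stringent when the reference set is large; the threshold is an explicit
  parameter everywhere, and the worked examples use higher values on
  small synthetic sets.
- **Deduplication** is exact string matching, first occurrence kept —
  the standard "100% identity cut-off".
- **Splitting** samples uniformly without replacement under a caller
  seed; negative train/test counts may differ from positive ones to
  build imbalanced test sets (e.g. 100 positives vs 500 negatives).
  Every stage appends a provenance line with before/after counts.

## Encoders

- **AAC** and **N5C5** are residue compositions (each sums to 1).  The
  N5C5 frame is the first five plus last five residues; for peptides
  shorter than ten the two windows overlap (a 7-mer contributes positions
  1–5 and 3–7), and peptides shorter than five contribute their sequence
  twice.  Overlap preserves a fixed 10-position frame for the positional
  frequency analysis; the alternative (truncating the frame) would make
  position 6 mean different things for different lengths.
- **k-space** counts ordered pairs `(s[i], s[i+k+1])`; a length-L peptide
  has exactly `L−k−1` of them, and the block is normalized by that count
  (all-zero when `L ≤ k+1`, rather than undefined).  Set-level
  differential ranking pools counts per class and per k, ranks
  `|f_pos − f_neg|` across all `400·(k_max+1)` pairs, and breaks ties
  lexicographically on the spacer name.
- **PSSM.**  Column frequencies are smoothed as
  `q_ij = (c_ij + α·b_j) / (n + α)` with pseudocount α (default 1) and
  background `b` (default uniform 1/20); scores are `log2(q_ij / b_j)`,
  with exact zeros (possible only at α = 0) floored at −10 instead of −∞.
  A variable-length peptide becomes a fixed 400-dim vector by the
  standard PSSM-composition transform: entry (r, j) is the mean score
  `P_ij` over the positions where the peptide carries residue r.  The
  profile source is configurable; the default is the N5C5 frames of the
  training positives, which gives an equal-length gapless alignment
  without requiring any database search.

## The SMO-trained SVM

The dual soft-margin SVM is solved by sequential minimal optimization:

- **Working-set selection** follows the canonical two-loop scheme: an
  outer loop alternating passes over all points and over non-bound points
  (0 < λ < C), a second-choice heuristic maximizing |E₁ − E₂|, then
  randomized fallback scans (seeded from the problem, so training is
  reproducible).
- **The two-variable step** solves the subproblem analytically along
  λ₁y₁ + λ₂y₂ = const and clips to the box; the endpoint geometry differs
  between equal and opposite labels.  Non-positive curvature
  (η = K₁₁ + K₂₂ − 2K₁₂ ≤ 0) is handled by evaluating the objective at
  both box endpoints and keeping the larger; ties leave the multiplier
  unchanged.
- **Tolerances.**  KKT tolerance 1e−3; minimum accepted multiplier change
  1e−12 (relative).  In debug mode the trainer asserts after every
  accepted step that the dual objective did not decrease and that
  0 ≤ λ ≤ C and Σyλ = 0 hold — the pairwise update preserves the equality
  constraint exactly.
- **Final bias.**  The running b1/b2 updates (midpoint when both
  multipliers end at bounds) track the optimization, but when *every*
  multiplier finishes at a bound the last pairwise value can be stale
  even though λ is optimal.  At convergence the bias is therefore
  recomputed from λ: the mean of `y_i − Σ_j λ_j y_j K_ij` over free
  support vectors when any exist, else the midpoint of the KKT-feasible
  interval.  This matches what QP-based solvers report and is covered by
  the oracle-agreement tests.
- **Linear kernel** maintains the explicit weight vector incrementally
  (`w ← w + y₁Δλ₁x₁ + y₂Δλ₂x₂`); tests assert it equals Σλyx recomputed
  from scratch at 1e−9.
- **Probability calibration** is Platt's sigmoid
  `P⁺ = 1/(1 + exp(A·f + B))` fit by Newton iterations with backtracking
  on the regularized likelihood, using Platt's target smoothing
  ((N⁺+1)/(N⁺+2) and 1/(N⁻+2)).  By default calibration uses the training
  decision values — the behavior of the classical SMO toolchain — which
  overstates confidence slightly relative to held-out calibration; both
  are available.

## Posterior weight tuning

After calibration, classification is redone as *positive iff
w·P⁺ ≥ P⁻* with w swept over 0.1–10 in steps of 0.1 (100 candidates); the
training-accuracy maximizer is kept, smallest w on ties (the most
conservative shift toward the negative class).  A multiplier applied to
*both* probabilities would cancel, so the weight acts on P⁺ only; this is
algebraically identical to sweeping a decision threshold of 1/(1+w) on
P⁺ (asserted exactly in the tests), which is also how the ROC curve
relates to the sweep.  Symmetric alternatives (weighting P⁻) can be
expressed by passing 1/w.

## Model selection and evaluation

- Grid search maximizes pooled stratified-CV accuracy over a C (and, for
  RBF, gamma) grid; ties prefer smaller C, then smaller gamma.  The
  canonical coarse grids (C = 2⁻⁵…2¹⁵, γ = 2⁻¹⁵…2³) are exported as
  defaults of the library function; the CLI ships a reduced default grid
  (C ∈ {0.1, 1, 10}, linear) so a desk-scale run finishes in seconds, and
  takes full grids via flags.
- Cross-validation folds are stratified, dealt round-robin after a seeded
  within-class shuffle, so membership depends only on (labels, seed) —
  never on feature values.  Metrics are reported per fold and pooled.
- SN, SP, ACC, MCC follow the standard confusion-matrix formulas; an
  undefined metric (zero denominator or empty MCC marginal) raises
  instead of silently returning 0, since published comparison tables
  print a dash in exactly that situation.  ROC sweeps descending scores
  with tied scores grouped into single steps; AUC is the trapezoid area
  and equals the Mann–Whitney statistic (tested by brute force and
  against scikit-learn).

## Synthetic benchmarks

The generators emulate the compositional signal of real ACP benchmarks:
positives enriched in K/L/A (cationic amphipathic chemistry), negatives
in N/Y/Q (AMP-like flavor) or M/R/Q (generic flavor), remaining mass
uniform, lengths uniform on [5, 50].  The strong profiles put 50% of the
mass on the three enriched residues, the moderate profiles 26%, and the
null profile is uniform for both classes.  Residues are drawn i.i.d. per
position, so the benchmarks contain *no* motif, positional, or
correlational structure: a high score here shows the pipeline recovers
compositional class signal and is honest at the null — it does not certify
performance on curated ACP/AMP data, whose signal is partly positional
and motif-like.  Generated sets always pass validation unchanged and are
reproducible from their seeds; the two classes never share a sequence.

## Problem sizes and runtime

The test suite and the acceptance script run on one CPU in well under a
minute combined: oracle comparisons use 100 random problems of ≤ 8 points
(where an SLSQP solve of the full QP is an exact independent reference),
and end-to-end runs use 200 peptides per class with AAC features — the
scale at which stratified ten-fold CV with an inner grid search is
near-instant while still tightly constraining correctness.

## Known limitations

- The exact all-pairs cross-set filter is quadratic; it is meant for
  peptide benchmarks (hundreds to thousands of sequences), not
  proteome-scale redundancy removal.
- SMO here has no shrinking or kernel-cache eviction; the full Gram
  matrix is held in memory, capping comfortable training sizes at a few
  thousand points.
- Platt calibration on training decision values inherits that method's
  optimism; use held-out calibration for probability-sensitive work.
- The free-gap identity measure overestimates similarity relative to
  gap-penalized aligners (see above); thresholds are not numerically
  interchangeable with CD-HIT's.
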