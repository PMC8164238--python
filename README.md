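# acpsmo

Anticancer peptides (ACPs) are short (≤ 50 residue) cationic peptides that
selectively disrupt cancer-cell membranes.  Screening candidates by
experiment is slow, so sequence-based classifiers are used to triage
peptide libraries — including the harder task of separating ACPs from
antimicrobial peptides (AMPs), which share much of their chemistry.
`acpsmo` is a complete, self-contained implementation of this kind of
classification pipeline for bioinformaticians who want every stage — data
hygiene, encoders, optimizer, calibration, tuning, evaluation — inspectable
and testable rather than hidden inside a toolkit.

## What it implements

**Dataset preparation.** FASTA in/out, removal of peptides longer than 50
residues or containing non-standard amino acids, exact deduplication,
CD-HIT-2D-style cross-set removal of negatives with sequence identity ≥ a
threshold (default 40%) to any positive, and seeded balanced train/test
splitting.  Every set carries a provenance log with per-stage counts.

**Sequence encoders.**

- *AAC*: amino-acid composition, 20 per-residue fractions.
- *N5C5*: composition of the first five plus last five residues
  concatenated into a 10-position frame, plus 10×20 positional frequency
  maps and class-difference heatmapping.
- *k-space* (CKSAAP): frequencies of ordered residue pairs with exactly
  *k* residues between them; a length-*N* peptide yields *N−k−1* pairs per
  *k*, one 400-dim block each.  Class-differential pairs are ranked with
  `X` spacers (`KXXXK` is K…K at k = 3).
- *PSSM composition*: 400 residue-grouped mean scores of a peptide against
  an N×20 log-odds position-specific scoring matrix,
  `P_ij = log2(q_ij / b_j)` with pseudocount-smoothed column frequencies
  `q_ij`, built from any gapless alignment (by default the N5C5 frames of
  the training positives).

Encoders hybridize by concatenation in any order.

**The classifier.**  A soft-margin SVM solved in the dual,

```
max_λ  Σ_j λ_j − ½ Σ_j Σ_k λ_j λ_k y_j y_k K(x_j, x_k)
s.t.   0 ≤ λ_j ≤ C,   Σ_j y_j λ_j = 0,
```

trained from scratch by sequential minimal optimization: repeated analytic
solution of two-multiplier subproblems along the constraint line
λ₁y₁ + λ₂y₂ = const, with Platt's working-set heuristics, an error cache,
incremental maintenance of the linear weight vector
`w ← w + y₁Δλ₁x₁ + y₂Δλ₂x₂`, and a final KKT-consistent bias.  Linear and
RBF kernels.  Decision values are calibrated to probabilities
`P⁺ = 1/(1 + exp(A·f + B))` by Platt's regularized sigmoid fit.

**Tuning and evaluation.**  C/gamma grid search under stratified
cross-validation; a posterior class-weight sweep (0.1–10, step 0.1) that
re-classifies as positive iff `w·P⁺ ≥ P⁻` and keeps the training-accuracy
maximizer; stratified ten-fold CV; SN, SP, ACC, MCC (undefined metrics
raise rather than report 0) and ROC/AUC with proper tie handling.

**Synthetic benchmarks.**  Generators for two-class peptide sets with the
compositional structure of real ACP benchmarks — positives enriched in
K/L/A, negatives in N/Y/Q (AMP-like) or M/R/Q (generic) — at strong,
moderate, or null contrast, so the whole pipeline is testable without any
external dataset.

## Worked example

`python examples/03_train_and_evaluate.py` trains on 200 synthetic
peptides per class with AAC + N5C5 + k-space(0) features (440 dimensions)
and evaluates on a fresh draw:

```
grid search selected C = 0.1
10-fold CV (pooled): SN=0.985 SP=0.990 ACC=0.988 MCC=0.975
tuned posterior weight = 0.7 (positive iff weight * P+ >= P-, i.e. P+ threshold 0.588)
held-out test: SN=0.980 SP=1.000 ACC=0.990 MCC=0.980
held-out ROC AUC = 1.000
```

The CV block is the pooled out-of-fold confusion matrix of ten stratified
folds; the weight 0.7 means the tuned rule calls a peptide positive once
its calibrated P⁺ clears 0.588.  On the null benchmark (identical class
compositions) the same pipeline sits at chance, ACC ≈ 0.5.  The other
examples walk through dataset preparation (`01`), compositional and
k-space contrast analysis (`02`), and the optimizer's internals on an
analytically solvable problem (`04`).

A command-line interface mirrors the same workflow for shell use:

```
acpsmo prepare pos.fasta neg.fasta --outdir prepared
acpsmo train prepared/train.fasta --model-out model.txt
acpsmo predict model.txt prepared/test.fasta --out predictions.tsv
acpsmo evaluate predictions.tsv prepared/test.fasta
```

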