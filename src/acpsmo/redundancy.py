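"""Dataset hygiene: deduplication, cross-set similarity removal, splitting.

This module emulates, exactly and at desk scale, the redundancy-reduction
steps commonly performed with CD-HIT / CD-HIT-2D when preparing peptide
benchmark datasets:

* within-set removal of 100%-identical sequences,
* removal from one set of every peptide whose sequence identity to *any*
  member of a reference set reaches a threshold (default 40%),
* seeded balanced splitting into training and testing subsets.

Identity between two peptides is the number of matched positions under an
optimal global alignment divided by (by default) the length of the shorter
sequence — CD-HIT's convention.  The alignment scores matches 1 and charges
nothing for mismatches or gaps, so the optimum match count equals the
longest common subsequence; gapped columns never count as identities.
Unlike CD-HIT, no word-filter heuristics are used: every pair is aligned,
which is exact and entirely adequate for peptides of at most ~50 residues.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from Bio import Align

from .errors import DataSizeError
from .sequence_io import Peptide, PeptideSet


@dataclass(frozen=True)
class IdentityParams:
    """How pairwise sequence identity is computed.

    threshold
        Identity fraction at or above which a peptide is considered
        redundant, in (0, 1].
    denominator_rule
        ``"shorter_sequence"`` (CD-HIT convention, default) or
        ``"alignment_length"``.
    match / mismatch / open_gap / extend_gap
        Scores of the global alignment used to count identical positions.
        The defaults (1 / 0 / 0 / 0) maximize the raw match count.
    """

    threshold: float = 0.4
    denominator_rule: str = "shorter_sequence"
    match: float = 1.0
    mismatch: float = 0.0
    open_gap: float = 0.0
    extend_gap: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold <= 1.0:
            raise ValueError(f"threshold must be in (0, 1], got {self.threshold}")
        if self.denominator_rule not in ("shorter_sequence", "alignment_length"):
            raise ValueError(f"unknown denominator_rule {self.denominator_rule!r}")

    def aligner(self) -> Align.PairwiseAligner:
        a = Align.PairwiseAligner()
        a.mode = "global"
        a.match_score = self.match
        a.mismatch_score = self.mismatch
        a.open_gap_score = self.open_gap
        a.extend_gap_score = self.extend_gap
        return a


def pairwise_identity(a: Peptide, b: Peptide, params: Optional[IdentityParams] = None) -> float:
    """Fraction of identical aligned positions between two peptides.

    Symmetric in its arguments.  With the default scoring the matched-
    position count is the longest common subsequence of the two sequences.
    """
    params = params or IdentityParams()
    if not a.sequence or not b.sequence:
        raise ValueError("pairwise_identity requires non-empty sequences")
    aligner = params.aligner()
    matches = _match_count(aligner, a.sequence, b.sequence, params)
    if params.denominator_rule == "shorter_sequence":
        denom = min(len(a), len(b))
    else:
        denom = next(iter(aligner.align(a.sequence, b.sequence))).length
    return matches / denom


def _match_count(aligner: Align.PairwiseAligner, sa: str, sb: str, params: IdentityParams) -> float:
    score = aligner.score(sa, sb)
    if params.mismatch == 0.0 and params.open_gap == 0.0 and params.extend_gap == 0.0:
        # score is match * (number of matched columns)
        return score / params.match
    # General scoring: count identities in one optimal alignment.
    aln = next(iter(aligner.align(sa, sb)))
    counts = aln.counts()
    return counts.identities


def dedup_identical(pset: PeptideSet) -> PeptideSet:
    """Remove peptides whose sequence string already occurred (first wins)."""
    seen: set[str] = set()
    kept = []
    for p in pset:
        if p.sequence not in seen:
            seen.add(p.sequence)
            kept.append(p)
    out = PeptideSet(kept, name=pset.name, provenance=list(pset.provenance))
    return out.logged(
        f"dedup_identical: {len(pset)} -> {len(kept)} ({len(pset) - len(kept)} removed)"
    )


def cross_set_filter(
    keep: PeptideSet, prune: PeptideSet, params: Optional[IdentityParams] = None
) -> PeptideSet:
    """Drop from `prune` every peptide similar to any member of `keep`.

    A peptide survives only if its pairwise identity to *every* member of
    `keep` is strictly below ``params.threshold``.  `keep` is never
    modified.  All pairs are aligned (no clustering heuristics), so the
    result does not depend on the order of either set.
    """
    params = params or IdentityParams()
    aligner = params.aligner()
    kept = []
    for cand in prune:
        redundant = False
        for ref in keep:
            matches = _match_count(aligner, cand.sequence, ref.sequence, params)
            if params.denominator_rule == "shorter_sequence":
                denom = min(len(cand), len(ref))
            else:
                denom = next(iter(aligner.align(cand.sequence, ref.sequence))).length
            if matches / denom >= params.threshold:
                redundant = True
                break
        if not redundant:
            kept.append(cand)
    out = PeptideSet(kept, name=prune.name, provenance=list(prune.provenance))
    return out.logged(
        f"cross_set_filter(threshold={params.threshold}, vs {keep.name or 'keep'}): "
        f"{len(prune)} -> {len(kept)} ({len(prune) - len(kept)} removed)"
    )


def balance_and_split(
    pos: PeptideSet,
    neg: PeptideSet,
    n_train: int,
    n_test: int,
    seed: int,
    neg_n_train: Optional[int] = None,
    neg_n_test: Optional[int] = None,
) -> tuple[PeptideSet, PeptideSet]:
    """Sample disjoint labeled train/test sets from a positive and a negative pool.

    `n_train` / `n_test` give the positive counts; the negative counts
    default to the same (a balanced design) but may be set independently
    for imbalanced test sets.  Sampling is uniform without replacement and
    reproducible under `seed`.

    Returns ``(train, test)`` with labels attached and counts logged.
    """
    neg_n_train = n_train if neg_n_train is None else neg_n_train
    neg_n_test = n_test if neg_n_test is None else neg_n_test
    for pool, need, who in ((pos, n_train + n_test, "positive"), (neg, neg_n_train + neg_n_test, "negative")):
        if len(pool) < need:
            raise DataSizeError(
                f"{who} pool has {len(pool)} peptides but {need} are required "
                f"(short by {need - len(pool)})"
            )
    rng = np.random.default_rng(seed)
    pos_idx = rng.permutation(len(pos))
    neg_idx = rng.permutation(len(neg))
    pos_l = pos.with_label("positive")
    neg_l = neg.with_label("negative")
    train = PeptideSet(
        [pos_l[i] for i in pos_idx[:n_train]] + [neg_l[i] for i in neg_idx[:neg_n_train]],
        name="train",
    )
    test = PeptideSet(
        [pos_l[i] for i in pos_idx[n_train : n_train + n_test]]
        + [neg_l[i] for i in neg_idx[neg_n_train : neg_n_train + neg_n_test]],
        name="test",
    )
    stamp = (
        f"balance_and_split(seed={seed}): train {n_train}+{neg_n_train}, "
        f"test {n_test}+{neg_n_test} (pos pool {len(pos)}, neg pool {len(neg)})"
    )
    train.logged(stamp)
    test.logged(stamp)
    return train, test
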