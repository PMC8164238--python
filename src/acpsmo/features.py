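"""Peptide sequence encoders and compositional analysis utilities.

Four encoders turn a variable-length peptide into a fixed-length numeric
vector:

AAC
    Amino-acid composition — the fraction of each of the 20 residues in the
    sequence (20 dimensions, sums to 1).
N5C5
    The first five and last five residues are cut off and concatenated into
    a 10-residue frame; the composition of that frame is the feature
    (20 dimensions).  For peptides shorter than 10 the two ends overlap.
k-space (CKSAAP)
    Frequencies of ordered residue pairs separated by exactly *k*
    intervening positions.  A sequence of length N yields N−k−1 pairs;
    each k contributes a 400-dimensional block.
PSSM composition
    Residue-grouped mean scores of the peptide against an N×20
    position-specific scoring matrix (400 dimensions).

The module also carries the set-level analyses used to characterise a
two-class peptide collection: per-position residue frequencies of the
N5C5 frame, and the ranking of the most class-differential k-space pairs
(written with ``X`` spacers, e.g. ``KXXXK`` for a K..K pair at k = 3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import FeatureMismatchError
from .sequence_io import ALPHABET, RESIDUE_INDEX, Peptide, PeptideSet

#: Ordered residue pairs backing every 400-dimensional block.
PAIRS = [a + b for a in ALPHABET for b in ALPHABET]

_N_AA = len(ALPHABET)


# ---------------------------------------------------------------------------
# containers

@dataclass(frozen=True)
class Pssm:
    """An N×20 position-specific scoring matrix.

    ``matrix[i, j]`` scores residue ``ALPHABET[j]`` at position ``i`` as the
    log2 odds of its (pseudocount-smoothed) frequency in the source
    alignment against a background probability.  Large values mark
    conserved positions.
    """

    matrix: np.ndarray
    background: np.ndarray
    pseudocount: float
    source_n: int

    def __post_init__(self) -> None:
        if self.matrix.ndim != 2 or self.matrix.shape[1] != _N_AA:
            raise ValueError(f"PSSM must be N x {_N_AA}, got {self.matrix.shape}")
        if not math.isclose(float(self.background.sum()), 1.0, abs_tol=1e-9):
            raise ValueError("background probabilities must sum to 1")

    @property
    def n_positions(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class FeatureSpec:
    """The recipe producing a feature vector: which encoders, in what order.

    `encoders` is an ordered subset of {"AAC", "N5C5", "KSPACE", "PSSM"};
    hybrids are expressed by listing several.  `k_values` applies to
    KSPACE (one 400-dim block per k); `pssm` must be supplied when PSSM is
    listed; `n5c5_mode` selects the 20-dim composition (default) or the
    10×20 positional one-hot frame.
    """

    encoders: tuple[str, ...] = ("AAC",)
    k_values: tuple[int, ...] = ()
    pssm: Optional[Pssm] = None
    n5c5_mode: str = "composition"

    def __post_init__(self) -> None:
        known = {"AAC", "N5C5", "KSPACE", "PSSM"}
        bad = set(self.encoders) - known
        if bad:
            raise ValueError(f"unknown encoders {sorted(bad)}")
        if ("KSPACE" in self.encoders) != bool(self.k_values):
            raise ValueError("k_values must be given iff KSPACE is an encoder")
        if ("PSSM" in self.encoders) and self.pssm is None:
            raise ValueError("a Pssm must be supplied when PSSM is an encoder")
        if any(k < 0 for k in self.k_values):
            raise ValueError("k values must be non-negative")
        if self.n5c5_mode not in ("composition", "positional"):
            raise ValueError(f"unknown n5c5_mode {self.n5c5_mode!r}")

    @property
    def n_dims(self) -> int:
        return len(self.feature_names)

    @property
    def feature_names(self) -> list[str]:
        names: list[str] = []
        for enc in self.encoders:
            if enc == "AAC":
                names += [f"AAC_{aa}" for aa in ALPHABET]
            elif enc == "N5C5":
                if self.n5c5_mode == "composition":
                    names += [f"N5C5_{aa}" for aa in ALPHABET]
                else:
                    names += [f"N5C5_P{i + 1}_{aa}" for i in range(10) for aa in ALPHABET]
            elif enc == "KSPACE":
                for k in self.k_values:
                    names += [f"K{k}_{p}" for p in PAIRS]
            elif enc == "PSSM":
                names += [f"PSSM_{a}_{b}" for a in ALPHABET for b in ALPHABET]
        return names

    def fingerprint(self) -> str:
        """A short string identifying the recipe (stored with models)."""
        parts = []
        for enc in self.encoders:
            if enc == "KSPACE":
                parts.append("KSPACE:k=" + ",".join(str(k) for k in self.k_values))
            elif enc == "N5C5":
                parts.append(f"N5C5:{self.n5c5_mode}")
            elif enc == "PSSM":
                parts.append(f"PSSM:n={self.pssm.n_positions if self.pssm else 0}")
            else:
                parts.append(enc)
        return "+".join(parts)


@dataclass(frozen=True)
class FeatureVector:
    """A fixed-length encoding of one peptide plus the spec that made it."""

    values: np.ndarray
    spec: FeatureSpec
    peptide_id: str


@dataclass(frozen=True)
class KSpaceTable:
    """Aggregate ordered-pair counts of a peptide set at one spacing k."""

    k: int
    counts: np.ndarray          # 400 ints, PAIRS order
    total_pairs: int

    @property
    def frequencies(self) -> np.ndarray:
        if self.total_pairs == 0:
            return np.zeros_like(self.counts, dtype=float)
        return self.counts / self.total_pairs


# ---------------------------------------------------------------------------
# single-peptide encoders

def _composition(seq: str) -> np.ndarray:
    v = np.zeros(_N_AA)
    for ch in seq:
        v[RESIDUE_INDEX[ch]] += 1.0
    return v / len(seq)


def aac(p: Peptide) -> FeatureVector:
    """Amino-acid composition: 20 per-residue fractions, summing to 1."""
    if not p.sequence:
        raise ValueError("cannot compute composition of an empty sequence")
    return FeatureVector(_composition(p.sequence), FeatureSpec(("AAC",)), p.id)


def extract_n5c5(p: Peptide) -> Peptide:
    """The N5C5 frame: first five plus last five residues, concatenated.

    Short peptides overlap: a 7-mer contributes positions 1–5 and 3–7,
    and a peptide shorter than 5 contributes its full sequence twice.
    The frame length is min(5, L) + min(5, L) <= 10.
    """
    s = p.sequence
    frame = s[:5] + s[-5:]
    return Peptide(p.id, frame, label=p.label, description="N5C5")


def n5c5_features(p: Peptide) -> FeatureVector:
    """Composition of the N5C5 frame (20 dimensions, sums to 1)."""
    frame = extract_n5c5(p)
    return FeatureVector(_composition(frame.sequence), FeatureSpec(("N5C5",)), p.id)


def _n5c5_positional(p: Peptide) -> np.ndarray:
    v = np.zeros(10 * _N_AA)
    frame = extract_n5c5(p).sequence
    for i, ch in enumerate(frame[:10]):
        v[i * _N_AA + RESIDUE_INDEX[ch]] = 1.0
    return v


def kspace_features(p: Peptide, k: int) -> FeatureVector:
    """Frequencies of ordered residue pairs at spacing k (400 dimensions).

    A length-L peptide yields exactly L−k−1 pairs ``(s[i], s[i+k+1])``;
    counts are normalized by that number.  Peptides with L <= k+1 yield
    the all-zero vector.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    v = _kspace_counts(p.sequence, k)
    n_pairs = max(len(p) - k - 1, 0)
    if n_pairs > 0:
        v = v / n_pairs
    return FeatureVector(v, FeatureSpec(("KSPACE",), k_values=(k,)), p.id)


def _kspace_counts(seq: str, k: int) -> np.ndarray:
    v = np.zeros(_N_AA * _N_AA)
    for i in range(len(seq) - k - 1):
        v[RESIDUE_INDEX[seq[i]] * _N_AA + RESIDUE_INDEX[seq[i + k + 1]]] += 1.0
    return v


def pssm_features(p: Peptide, pssm: Pssm) -> FeatureVector:
    """PSSM composition: 400 residue-grouped mean scores.

    Entry (r, j) is the mean of ``pssm.matrix[i, j]`` over the scored
    positions i at which the peptide carries residue r; rows for residue
    classes absent from the peptide are zero.  Scoring covers positions
    1..min(L, N); peptides longer than the matrix are scored on its N
    positions only.
    """
    n = min(len(p), pssm.n_positions)
    if n == 0:
        raise ValueError("no overlap between peptide and PSSM positions")
    v = np.zeros((_N_AA, _N_AA))
    counts = np.zeros(_N_AA)
    for i in range(n):
        r = RESIDUE_INDEX[p.sequence[i]]
        v[r] += pssm.matrix[i]
        counts[r] += 1.0
    present = counts > 0
    v[present] /= counts[present, None]
    spec = FeatureSpec(("PSSM",), pssm=pssm)
    return FeatureVector(v.ravel(), spec, p.id)


def hybridize(vectors: Sequence[FeatureVector]) -> FeatureVector:
    """Concatenate feature vectors of the same peptide, in the given order."""
    if not vectors:
        raise ValueError("nothing to hybridize")
    ids = {v.peptide_id for v in vectors}
    if len(ids) != 1:
        raise FeatureMismatchError(f"vectors come from different peptides: {sorted(ids)}")
    encoders: tuple[str, ...] = ()
    k_values: tuple[int, ...] = ()
    pssm = None
    mode = "composition"
    for v in vectors:
        encoders += v.spec.encoders
        k_values += v.spec.k_values
        if v.spec.pssm is not None:
            pssm = v.spec.pssm
        if "N5C5" in v.spec.encoders:
            mode = v.spec.n5c5_mode
    spec = FeatureSpec(encoders, k_values=k_values, pssm=pssm, n5c5_mode=mode)
    return FeatureVector(np.concatenate([v.values for v in vectors]), spec, vectors[0].peptide_id)


def encode(p: Peptide, spec: FeatureSpec) -> FeatureVector:
    """Encode one peptide under a full recipe (hybrids included)."""
    blocks: list[np.ndarray] = []
    for enc in spec.encoders:
        if enc == "AAC":
            blocks.append(aac(p).values)
        elif enc == "N5C5":
            if spec.n5c5_mode == "composition":
                blocks.append(n5c5_features(p).values)
            else:
                blocks.append(_n5c5_positional(p))
        elif enc == "KSPACE":
            for k in spec.k_values:
                blocks.append(kspace_features(p, k).values)
        elif enc == "PSSM":
            blocks.append(pssm_features(p, spec.pssm).values)
    return FeatureVector(np.concatenate(blocks), spec, p.id)


def encode_set(pset: PeptideSet, spec: FeatureSpec) -> tuple[np.ndarray, list[str]]:
    """Encode every peptide; returns (matrix of shape (n, d), ids)."""
    X = np.vstack([encode(p, spec).values for p in pset])
    return X, pset.ids


# ---------------------------------------------------------------------------
# set-level analyses

def positional_frequency(pset: PeptideSet) -> np.ndarray:
    """10×20 per-position residue frequencies of the N5C5 frames.

    Entry (i, j) is the fraction of peptides whose N5C5 frame carries
    residue j at position i, among peptides whose frame reaches position i;
    rows with no contributors are zero.
    """
    if len(pset) == 0:
        raise ValueError("positional_frequency of an empty set")
    counts = np.zeros((10, _N_AA))
    contributors = np.zeros(10)
    for p in pset:
        frame = extract_n5c5(p).sequence
        for i, ch in enumerate(frame[:10]):
            counts[i, RESIDUE_INDEX[ch]] += 1.0
            contributors[i] += 1.0
    nz = contributors > 0
    counts[nz] /= contributors[nz, None]
    return counts


def positional_difference(pos: PeptideSet, neg: PeptideSet) -> np.ndarray:
    """Positive-set minus negative-set positional frequency matrices."""
    return positional_frequency(pos) - positional_frequency(neg)


def kspace_table(pset: PeptideSet, k: int) -> KSpaceTable:
    """Pooled ordered-pair counts of a whole set at spacing k."""
    counts = np.zeros(_N_AA * _N_AA)
    total = 0
    for p in pset:
        counts += _kspace_counts(p.sequence, k)
        total += max(len(p) - k - 1, 0)
    return KSpaceTable(k=k, counts=counts, total_pairs=total)


def pair_name(k: int, pair: str) -> str:
    """Field-style name of a k-spaced pair: k X's between the residues."""
    return pair[0] + "X" * k + pair[1]


def top_differential_pairs(
    pos: PeptideSet, neg: PeptideSet, k_max: int, n: int = 10
) -> list[tuple[str, float]]:
    """The n pairs with the largest |pos − neg| pooled frequency difference.

    Frequencies are pooled per set and per spacing (each k's 400 pair
    frequencies sum to 1 over that set), spacings 0..k_max are ranked
    together, and pairs are named with X spacers (``KXL`` is K–L at k=1).
    Ties are broken lexicographically on the pair name.  Differences are
    signed: positive means enriched in the positive set.
    """
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both sets must be non-empty")
    rows: list[tuple[str, float]] = []
    for k in range(k_max + 1):
        fp = kspace_table(pos, k).frequencies
        fn = kspace_table(neg, k).frequencies
        diff = fp - fn
        rows += [(pair_name(k, PAIRS[j]), float(diff[j])) for j in range(len(PAIRS))]
    rows.sort(key=lambda r: (-abs(r[1]), r[0]))
    return rows[:n]


# ---------------------------------------------------------------------------
# PSSM construction

def uniform_background() -> np.ndarray:
    """The default flat background: every residue at probability 1/20."""
    return np.full(_N_AA, 1.0 / _N_AA)


def build_pssm(
    alignment: PeptideSet,
    background: Optional[np.ndarray] = None,
    pseudocount: float = 1.0,
    floor: float = -10.0,
) -> Pssm:
    """Build an N×20 log-odds PSSM from a gapless equal-length alignment.

    With column counts c_ij over n sequences, the smoothed frequency is
    ``q_ij = (c_ij + pseudocount * background_j) / (n + pseudocount)`` and
    the score ``P_ij = log2(q_ij / background_j)``.  Cells with q = 0
    (possible only at pseudocount 0) are floored at `floor` instead of −∞.
    """
    if len(alignment) == 0:
        raise ValueError("alignment must contain at least one sequence")
    lengths = {len(p) for p in alignment}
    if len(lengths) != 1:
        raise ValueError(f"aligned sequences must share one length, got {sorted(lengths)}")
    bg = uniform_background() if background is None else np.asarray(background, dtype=float)
    if bg.shape != (_N_AA,) or not math.isclose(float(bg.sum()), 1.0, abs_tol=1e-9):
        raise ValueError("background must be 20 probabilities summing to 1")
    if np.any(bg <= 0):
        raise ValueError("background probabilities must all be positive")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    n_pos = lengths.pop()
    n_seq = len(alignment)
    counts = np.zeros((n_pos, _N_AA))
    for p in alignment:
        for i, ch in enumerate(p.sequence):
            counts[i, RESIDUE_INDEX[ch]] += 1.0
    q = (counts + pseudocount * bg[None, :]) / (n_seq + pseudocount)
    with np.errstate(divide="ignore"):
        scores = np.log2(q / bg[None, :])
    scores = np.maximum(scores, floor)
    return Pssm(matrix=scores, background=bg, pseudocount=pseudocount, source_n=n_seq)


def pssm_from_training_positives(pos: PeptideSet, **kwargs) -> Pssm:
    """Default profile source: the N5C5 frames of the training positives.

    Frames shorter than 10 (peptides shorter than 5 residues) are skipped
    so the alignment is gapless and equal-length.
    """
    frames = [extract_n5c5(p) for p in pos]
    full = [f for f in frames if len(f) == 10]
    if not full:
        raise ValueError("no peptide yields a full 10-residue N5C5 frame")
    return build_pssm(PeptideSet(_dedup_ids(full), name=f"{pos.name}-n5c5"), **kwargs)


def _dedup_ids(peps: list[Peptide]) -> list[Peptide]:
    from dataclasses import replace

    seen: dict[str, int] = {}
    out = []
    for p in peps:
        if p.id in seen:
            seen[p.id] += 1
            out.append(replace(p, id=f"{p.id}.{seen[p.id]}"))
        else:
            seen[p.id] = 1
            out.append(p)
    return out
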