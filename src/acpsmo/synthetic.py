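"""Synthetic two-class peptide generators.

Real anticancer-peptide (ACP) benchmarks show strong compositional
contrasts: ACPs are enriched in lysine (K), leucine (L) and alanine (A) —
cationic, amphipathic membrane-active chemistry — while the hard-negative
antimicrobial peptides are relatively enriched in N, Y, Q and plain
non-functional peptides in M, R, Q.  The generators here emulate exactly
that structure: per-position i.i.d. residue draws from class-specific
composition profiles, with lengths uniform on [5, 50].  What they do *not*
emulate is motif or positional structure, secondary-structure constraints,
or the length distributions of curated databases; see the methods note.

Every generated set passes dataset validation unchanged (standard alphabet,
length ≤ 50) and is reproducible from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .sequence_io import ALPHABET, Peptide, PeptideSet

_N_AA = len(ALPHABET)


@dataclass(frozen=True)
class CompositionProfile:
    """Residue-draw probabilities for one peptide class.

    `residue_probs` is a length-20 vector over :data:`~acpsmo.sequence_io.ALPHABET`
    summing to 1; `length_range` bounds the uniform length draw;
    `terminal_bias`, when set, replaces the draw distribution at the first
    five and last five positions.
    """

    residue_probs: np.ndarray
    length_range: tuple[int, int] = (5, 50)
    terminal_bias: Optional[np.ndarray] = None
    name: str = ""

    def __post_init__(self) -> None:
        p = np.asarray(self.residue_probs, dtype=float)
        object.__setattr__(self, "residue_probs", p)
        if p.shape != (_N_AA,) or abs(float(p.sum()) - 1.0) > 1e-12 or (p < 0).any():
            raise ValueError("residue_probs must be 20 non-negative values summing to 1")
        lo, hi = self.length_range
        if lo < 2 or hi > 50 or lo > hi:
            raise ValueError("length_range must satisfy 2 <= min <= max <= 50")
        if self.terminal_bias is not None:
            t = np.asarray(self.terminal_bias, dtype=float)
            object.__setattr__(self, "terminal_bias", t)
            if t.shape != (_N_AA,) or abs(float(t.sum()) - 1.0) > 1e-12 or (t < 0).any():
                raise ValueError("terminal_bias must be 20 non-negative values summing to 1")


def profile(boost: dict[str, float], name: str = "", **kwargs) -> CompositionProfile:
    """A profile giving `boost` residues their stated probabilities and
    spreading the remainder uniformly over the other residues."""
    p = np.zeros(_N_AA)
    total = sum(boost.values())
    if not 0 <= total < 1:
        raise ValueError("boost probabilities must sum to less than 1")
    rest = (1.0 - total) / (_N_AA - len(boost))
    for i, aa in enumerate(ALPHABET):
        p[i] = boost.get(aa, rest)
    return CompositionProfile(p, name=name, **kwargs)


#: Class profiles used by :func:`make_benchmark`.  The positive class
#: carries the K/L/A enrichment characteristic of ACPs; negatives come in
#: an AMP-like flavor (N/Y/Q enriched) and a generic-peptide flavor
#: (M/R/Q enriched).  "strong" profiles produce a clearly separable
#: problem, "moderate" a harder one, "null" no class signal at all.
PROFILES = {
    ("strong", "positive"): {"K": 0.22, "L": 0.16, "A": 0.12},
    ("strong", "amp"): {"N": 0.22, "Y": 0.16, "Q": 0.12},
    ("strong", "generic"): {"M": 0.22, "R": 0.16, "Q": 0.12},
    ("moderate", "positive"): {"K": 0.11, "L": 0.08, "A": 0.07},
    ("moderate", "amp"): {"N": 0.11, "Y": 0.08, "Q": 0.07},
    ("moderate", "generic"): {"M": 0.11, "R": 0.08, "Q": 0.07},
}


def sample_peptides(
    prof: CompositionProfile, n: int, seed: int, id_prefix: str = "pep"
) -> PeptideSet:
    """Draw n peptides from a composition profile, reproducibly under seed."""
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    residues = np.array(list(ALPHABET))
    lo, hi = prof.length_range
    peptides = []
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        draws = rng.choice(residues, size=length, p=prof.residue_probs)
        if prof.terminal_bias is not None:
            n_term = min(5, length)
            draws[:n_term] = rng.choice(residues, size=n_term, p=prof.terminal_bias)
            draws[length - n_term :] = rng.choice(residues, size=n_term, p=prof.terminal_bias)
        peptides.append(Peptide(f"{id_prefix}_{i + 1:05d}", "".join(draws)))
    out = PeptideSet(peptides, name=prof.name or id_prefix)
    return out.logged(f"sample_peptides(n={n}, seed={seed}, profile={prof.name or 'custom'})")


def make_benchmark(
    effect: str,
    n_per_class: int,
    seed: int,
    negative_flavor: str = "amp",
) -> tuple[PeptideSet, PeptideSet]:
    """Two disjoint labeled peptide sets with a controlled class contrast.

    `effect` is ``"strong"`` (clearly separable compositions),
    ``"moderate"``, or ``"null"`` (identical uniform compositions — any
    classifier should sit at chance).  `negative_flavor` picks the
    AMP-like or generic-peptide negative profile.  The two sets never
    share a sequence string (collisions are resampled).
    """
    if effect not in ("strong", "moderate", "null"):
        raise ValueError(f"unknown effect {effect!r}")
    if negative_flavor not in ("amp", "generic"):
        raise ValueError(f"unknown negative_flavor {negative_flavor!r}")
    if effect == "null":
        pos_prof = profile({}, name="null-positive")
        neg_prof = profile({}, name="null-negative")
    else:
        pos_prof = profile(PROFILES[(effect, "positive")], name=f"{effect}-positive")
        neg_prof = profile(PROFILES[(effect, negative_flavor)], name=f"{effect}-{negative_flavor}")
    pos = sample_peptides(pos_prof, n_per_class, seed, id_prefix="pos")
    neg = sample_peptides(neg_prof, n_per_class, seed + 1, id_prefix="neg")
    # enforce disjoint sequence strings between (and within) the two sets
    rng = np.random.default_rng(seed + 2)
    seen = set()
    for pset, prof_ in ((pos, pos_prof), (neg, neg_prof)):
        for i, p in enumerate(pset.peptides):
            attempt = 0
            while p.sequence in seen:
                attempt += 1
                p = sample_peptides(prof_, 1, int(rng.integers(2**31)), id_prefix="re")[0]
                p = Peptide(pset.peptides[i].id, p.sequence)
                if attempt > 100:
                    raise RuntimeError("could not generate disjoint peptide sets")
            seen.add(p.sequence)
            pset.peptides[i] = Peptide(pset.peptides[i].id, p.sequence)
    pos = pos.with_label("positive")
    neg = neg.with_label("negative")
    stamp = f"make_benchmark(effect={effect}, n={n_per_class}, seed={seed}, flavor={negative_flavor})"
    pos.logged(stamp)
    neg.logged(stamp)
    return pos, neg
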