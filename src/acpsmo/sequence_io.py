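"""Reading, validating and writing short peptide sequences.

The unit of data is the :class:`Peptide` — a sequence over the 20 standard
amino acids, at most ~50 residues once filtered, optionally carrying a
binary class label (``"positive"`` / ``"negative"``).  Collections are
:class:`PeptideSet` objects that keep an audit trail (*provenance*) of every
filter applied to them, with before/after counts, so a prepared dataset can
always explain itself.

FASTA is the only on-disk format.  Labels survive round-trips by being
encoded in the header as ``id|label``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Optional, Sequence

from Bio import SeqIO

from .errors import FastaParseError

#: The 20 standard amino acids, alphabetical by one-letter code.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_ALPHABET_SET = frozenset(ALPHABET)

#: Index of each residue in :data:`ALPHABET`.
RESIDUE_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

_LABELS = ("positive", "negative")


@dataclass(frozen=True)
class Peptide:
    """One peptide sequence with an identifier and optional class label."""

    id: str
    sequence: str
    label: Optional[str] = None
    description: str = ""

    def __post_init__(self) -> None:
        if self.label is not None and self.label not in _LABELS:
            raise ValueError(f"label must be one of {_LABELS}, got {self.label!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def is_valid(self) -> bool:
        """True when non-empty and made only of standard residues."""
        return bool(self.sequence) and set(self.sequence) <= _ALPHABET_SET


@dataclass
class PeptideSet:
    """An ordered collection of peptides with a filter audit trail."""

    peptides: list[Peptide] = field(default_factory=list)
    name: str = ""
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [p.id for p in self.peptides]
        if len(ids) != len(set(ids)):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValueError(f"duplicate peptide id {dup!r} in set {self.name!r}")

    def __len__(self) -> int:
        return len(self.peptides)

    def __iter__(self) -> Iterator[Peptide]:
        return iter(self.peptides)

    def __getitem__(self, i: int) -> Peptide:
        return self.peptides[i]

    @property
    def ids(self) -> list[str]:
        return [p.id for p in self.peptides]

    @property
    def sequences(self) -> list[str]:
        return [p.sequence for p in self.peptides]

    def logged(self, message: str) -> "PeptideSet":
        """Return self with an extra provenance line (mutates in place)."""
        self.provenance.append(message)
        return self

    def with_label(self, label: str) -> "PeptideSet":
        """A copy of the set in which every peptide carries `label`."""
        out = PeptideSet(
            [replace(p, label=label) for p in self.peptides],
            name=self.name,
            provenance=list(self.provenance),
        )
        return out.logged(f"labeled all {len(out)} peptides as {label!r}")


def _split_header(header: str, parse_labels: bool) -> tuple[str, Optional[str], str]:
    """Break a FASTA header into (id, label, description)."""
    parts = header.split(None, 1)
    ident, desc = parts[0], parts[1] if len(parts) > 1 else ""
    label = None
    if parse_labels and "|" in ident:
        stem, _, tail = ident.rpartition("|")
        if tail in _LABELS:
            ident, label = stem, tail
    return ident, label, desc


def read_fasta(path, name: str = "", parse_labels: bool = False) -> PeptideSet:
    """Read a multi-record FASTA file into a :class:`PeptideSet`.

    Sequences are uppercased; record order is preserved; no validation or
    filtering is applied (see :func:`filter_valid`).  Duplicate header ids
    get a numeric ``.2``, ``.3``... suffix, logged in provenance.  With
    ``parse_labels=True``, headers of the form ``id|positive`` /
    ``id|negative`` yield labeled peptides.
    """
    path = Path(path)
    peptides: list[Peptide] = []
    seen: dict[str, int] = {}
    renamed = 0
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:  # e.g. text before the first '>' header
        raise FastaParseError(f"{path}: {exc}") from exc
    for i, rec in enumerate(records, start=1):
        seq = str(rec.seq).upper()
        if not seq:
            raise FastaParseError(
                f"{path}: record {i} ({rec.id!r}) has a header but no sequence"
            )
        if not rec.id:
            raise FastaParseError(f"{path}: record {i} has an empty header")
        ident, label, desc = _split_header(rec.description, parse_labels)
        if ident in seen:
            seen[ident] += 1
            ident = f"{ident}.{seen[ident]}"
            renamed += 1
        else:
            seen[ident] = 1
        peptides.append(Peptide(ident, seq, label=label, description=desc))
    pset = PeptideSet(peptides, name=name or path.stem)
    pset.logged(f"read_fasta({path.name}): {len(pset)} records")
    if renamed:
        pset.logged(f"read_fasta: {renamed} duplicate ids renamed with numeric suffix")
    return pset


def filter_valid(pset: PeptideSet, max_len: int = 50) -> PeptideSet:
    """Keep peptides of length <= `max_len` made only of standard residues.

    Peptides containing any non-standard character (B, J, O, U, X, Z,
    lowercase, digits...) are removed whole — non-standard residues are
    never masked.  Idempotent; provenance records the removed count.
    """
    kept = [p for p in pset if p.is_valid and len(p) <= max_len]
    out = PeptideSet(kept, name=pset.name, provenance=list(pset.provenance))
    removed = len(pset) - len(kept)
    return out.logged(
        f"filter_valid(max_len={max_len}): {len(pset)} -> {len(kept)} ({removed} removed)"
    )


def write_fasta(pset: PeptideSet, path, width: int = 60) -> Path:
    """Write a peptide set as 60-column-wrapped FASTA.

    Labels, when present, are encoded into the header as ``id|label`` so
    that ``read_fasta(..., parse_labels=True)`` round-trips them.
    """
    path = Path(path)
    with open(path, "w") as fh:
        for p in pset:
            header = p.id if p.label is None else f"{p.id}|{p.label}"
            if p.description:
                header = f"{header} {p.description}"
            fh.write(f">{header}\n")
            for start in range(0, len(p.sequence), width):
                fh.write(p.sequence[start : start + width] + "\n")
    return path
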