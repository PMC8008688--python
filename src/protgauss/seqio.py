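"""Protein sequence input, deduplication and k-mer tokenization.

Sequences are read from FASTA, normalized to uppercase, deduplicated on
(id, residues) pairs, and decomposed into overlapping subsequences of a
fixed length ``k`` (the "biological words" fed to the embedding model).
A sequence of length ``l`` yields ``l - (k - 1)`` tokens.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio import SeqIO

from .errors import ValidationError

logger = logging.getLogger(__name__)

#: The 20 standard amino acids.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: Ambiguity / non-standard letters tolerated on input (Swiss-Prot style).
AMBIGUITY_LETTERS = "BJOUXZ"

_ALLOWED = frozenset(AMINO_ACIDS + AMBIGUITY_LETTERS)


@dataclass(frozen=True)
class ProteinSequence:
    """A named amino-acid sequence.

    Residues are uppercased on construction; the standard alphabet plus
    the ambiguity letters B, J, O, U, X, Z are accepted.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())
        if not self.residues:
            raise ValidationError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - _ALLOWED
        if bad:
            raise ValidationError(
                f"sequence {self.id!r} contains invalid residue(s) {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class SubsequenceList:
    """Overlapping length-``k`` windows of a parent sequence, in order."""

    parent_id: str
    k: int
    tokens: tuple[str, ...] = field(default_factory=tuple)

    def __len__(self) -> int:
        return len(self.tokens)


def read_fasta(path) -> list[ProteinSequence]:
    """Read a FASTA file into a list of :class:`ProteinSequence`.

    The header token before the first whitespace becomes the id; bodies
    may span multiple lines and are uppercased. An entry with an empty
    body raises :class:`ValidationError` naming the offending id.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        body = str(rec.seq)
        if not body:
            raise ValidationError(f"FASTA record {rec.id!r} has an empty sequence")
        records.append(ProteinSequence(id=rec.id, residues=body))
    return records


def dedupe_sequences(records: list[ProteinSequence]) -> list[ProteinSequence]:
    """Collapse repeated entries, keeping one record per (id, residues) pair.

    Records that share an id but differ in residues are all retained and
    renamed ``id.1``, ``id.2``, ... in first-seen order, so that ids are
    unique in the result. Exact duplicates beyond the first are dropped
    and the removed count is logged.
    """
    seen: dict[tuple[str, str], None] = {}
    for rec in records:
        seen.setdefault((rec.id, rec.residues), None)
    n_removed = len(records) - len(seen)
    if n_removed:
        logger.info("dedupe_sequences: removed %d duplicate record(s)", n_removed)

    # ids that still collide after exact-duplicate removal get suffixes
    by_id: dict[str, int] = {}
    for rec_id, _ in seen:
        by_id[rec_id] = by_id.get(rec_id, 0) + 1

    counters: dict[str, int] = {}
    out = []
    for rec_id, residues in seen:
        if by_id[rec_id] > 1:
            counters[rec_id] = counters.get(rec_id, 0) + 1
            out.append(ProteinSequence(id=f"{rec_id}.{counters[rec_id]}", residues=residues))
        else:
            out.append(ProteinSequence(id=rec_id, residues=residues))
    return out


def split_subsequences(seq: ProteinSequence, k: int) -> SubsequenceList:
    """Decompose ``seq`` into its ``l - (k - 1)`` overlapping k-mers.

    Token ``i`` spans residues ``[i, i + k)`` (0-based, half-open).
    Sequences shorter than ``k`` are rejected.
    """
    if k < 1:
        raise ValidationError(f"subsequence length must be >= 1, got {k}")
    l = len(seq)
    if l < k:
        raise ValidationError(
            f"sequence {seq.id!r} (length {l}) is too short for subsequence length {k}"
        )
    tokens = tuple(seq.residues[i : i + k] for i in range(l - k + 1))
    return SubsequenceList(parent_id=seq.id, k=k, tokens=tokens)


def write_fasta(records: list[ProteinSequence], path) -> None:
    """Write records as plain two-line-per-entry FASTA."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.residues}\n")
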