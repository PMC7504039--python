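"""Charge-complementary motif patterns and sequence scanning.

A short charged peptide segment (e.g. the amyloid-β site ``EVHH``, residues
11–14) can pair with an oppositely charged segment on a partner protein.
This module derives the PROSITE-style pattern of residues complementary to a
query segment — positive residues (H/R/K) pair with negative ones (D/E),
small hydrophobics (V/A/L/I) pair with themselves — and scans protein
sequences for matches, reporting 1-based coordinates.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence, Union

from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "AmbiguousResidueError",
    "MotifPattern",
    "MotifHit",
    "CLASS_MEMBERS",
    "classify_residue",
    "complement_class",
    "complement_pattern",
    "scan_sequences",
    "read_fasta",
    "hits_to_tsv",
]

#: one-letter members of each charge class, in the fixed rendering order
CLASS_MEMBERS = {
    "positive": "HRK",
    "negative": "DE",
    "hydrophobic_small": "VALI",
}

_STANDARD = set("ACDEFGHIKLMNPQRSTVWY")

_CLASS_OF = {}
for _cls, _members in CLASS_MEMBERS.items():
    for _aa in _members:
        _CLASS_OF[_aa] = _cls
for _aa in _STANDARD - set(_CLASS_OF):
    _CLASS_OF[_aa] = "other"

_COMPLEMENT = {
    "positive": "negative",
    "negative": "positive",
    "hydrophobic_small": "hydrophobic_small",
}


class AmbiguousResidueError(ValueError):
    """Raised for non-standard or ambiguous one-letter codes (B, Z, X, U, O, *)."""


def classify_residue(aa: str) -> str:
    """Return the charge class of a standard one-letter residue code.

    Classes are ``positive`` (H, R, K), ``negative`` (D, E),
    ``hydrophobic_small`` (V, A, L, I) and ``other`` (everything else).
    Case-insensitive.  Non-standard codes raise :class:`AmbiguousResidueError`
    rather than being silently classed.
    """
    if not isinstance(aa, str) or len(aa) != 1:
        raise AmbiguousResidueError(f"expected a single one-letter code, got {aa!r}")
    up = aa.upper()
    if up not in _STANDARD:
        raise AmbiguousResidueError(
            f"ambiguous/non-standard residue code {aa!r}; "
            "only the 20 standard one-letter codes are classifiable"
        )
    return _CLASS_OF[up]


def complement_class(cls: str) -> str:
    """Complement of a charge class: positive↔negative, hydrophobic_small↔itself.

    ``other`` has no chemical complement; callers decide the policy (see
    :func:`complement_pattern`).
    """
    try:
        return _COMPLEMENT[cls]
    except KeyError:
        raise ValueError(f"class {cls!r} has no defined complement") from None


def _render_position(members: frozenset) -> str:
    # fixed spellings so renderings are byte-comparable: [HRK], [VALI], [DE]
    for cls, spelled in CLASS_MEMBERS.items():
        if members == frozenset(spelled):
            return f"[{spelled}]"
    if len(members) == 1:
        return next(iter(members))
    return "[" + "".join(sorted(members)) + "]"


@dataclass(frozen=True)
class MotifPattern:
    """A positional residue-class pattern, e.g. ``[HRK]-[VALI]-[DE]-[DE]``.

    ``positions`` is an ordered tuple of allowed-residue sets; a sequence
    window matches when every window residue is in the corresponding set.
    """

    positions: tuple
    orientation: str
    source_query: str

    def __post_init__(self):
        if len(self.positions) != len(self.source_query):
            raise ValueError("pattern length must equal query length")
        if self.orientation not in ("parallel", "antiparallel"):
            raise ValueError(f"unknown orientation {self.orientation!r}")
        for pos in self.positions:
            if not pos:
                raise ValueError("empty position set in pattern")
            if not set(pos) <= _STANDARD:
                raise ValueError(f"non-standard residues in position set {set(pos)!r}")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def rendering(self) -> str:
        """PROSITE-style text, positions joined by ``-``."""
        return "-".join(_render_position(p) for p in self.positions)

    def matches_at(self, sequence: str, start0: int) -> bool:
        """True if the pattern matches ``sequence`` at 0-based offset ``start0``."""
        if start0 < 0 or start0 + len(self) > len(sequence):
            return False
        for pos, aa in zip(self.positions, sequence[start0 : start0 + len(self)]):
            if aa.upper() not in pos:
                return False
        return True


@dataclass(frozen=True)
class MotifHit:
    """One pattern match; ``start``/``end`` are 1-based inclusive."""

    sequence_id: str
    start: int
    end: int
    matched: str
    pattern_rendering: str


def complement_pattern(
    query: str,
    orientation: str = "parallel",
    other_policy: str = "identity",
) -> MotifPattern:
    """Build the charge-complementary pattern of a query peptide.

    Parallel: position *i* of the pattern is the complement class of
    ``query[i]`` (``EVHH`` → ``[HRK]-[VALI]-[DE]-[DE]``).  Antiparallel: the
    query is reversed first, then complemented position-wise
    (``EVHH`` → ``[DE]-[DE]-[VALI]-[HRK]``).

    Residues of class ``other`` have no chemical complement.
    ``other_policy="identity"`` keeps the residue itself (with a warning);
    ``"strict"`` refuses.
    """
    if not query:
        raise ValueError("query must be non-empty")
    if other_policy not in ("identity", "strict"):
        raise ValueError(f"unknown other_policy {other_policy!r}")
    residues = query.upper()
    if orientation == "antiparallel":
        residues = residues[::-1]
    elif orientation != "parallel":
        raise ValueError(f"unknown orientation {orientation!r}")

    positions = []
    for aa in residues:
        cls = classify_residue(aa)  # raises on non-standard
        if cls == "other":
            if other_policy == "strict":
                raise ValueError(
                    f"residue {aa!r} in query {query!r} has class 'other' and "
                    "no complement (strict policy)"
                )
            warnings.warn(
                f"residue {aa!r} has no charge complement; keeping it verbatim "
                "in the pattern (other_policy='identity')",
                stacklevel=2,
            )
            positions.append(frozenset(aa))
        else:
            positions.append(frozenset(CLASS_MEMBERS[complement_class(cls)]))
    return MotifPattern(tuple(positions), orientation, query.upper())


SequenceInput = Union[str, Path, Iterable]


def read_fasta(source: Union[str, Path]) -> list:
    """Read a (possibly line-wrapped) multi-record FASTA file."""
    return list(SeqIO.parse(str(source), "fasta"))


def _iter_records(sequences: SequenceInput) -> Iterator[tuple]:
    """Yield (id, sequence string) from FASTA path, SeqRecords, or (id, seq) pairs."""
    if isinstance(sequences, (str, Path)):
        for rec in SeqIO.parse(str(sequences), "fasta"):
            yield rec.id, str(rec.seq)
        return
    for item in sequences:
        if hasattr(item, "seq"):  # Bio.SeqRecord
            yield item.id, str(item.seq)
        else:
            sid, seq = item
            yield sid, str(seq)


def scan_sequences(
    pattern: MotifPattern,
    sequences: SequenceInput,
    allow_overlaps: bool = True,
) -> list:
    """Scan protein sequences for pattern matches.

    Returns :class:`MotifHit` objects with 1-based inclusive coordinates, in
    deterministic order (input sequence order, then start position).  Windows
    overlapping non-standard residues never match; one warning is logged per
    such sequence.  With ``allow_overlaps=False`` matches are taken greedily
    left to right.
    """
    hits = []
    m = len(pattern)
    for sid, seq in _iter_records(sequences):
        seq_u = seq.upper()
        if set(seq_u) - _STANDARD:
            logger.warning(
                "sequence %s contains non-standard residues; windows covering "
                "them will not match",
                sid,
            )
        i = 0
        n = len(seq_u)
        while i + m <= n:
            if pattern.matches_at(seq_u, i):
                hits.append(
                    MotifHit(
                        sequence_id=sid,
                        start=i + 1,
                        end=i + m,
                        matched=seq_u[i : i + m],
                        pattern_rendering=pattern.rendering,
                    )
                )
                i += m if not allow_overlaps else 1
            else:
                i += 1
    return hits


def hits_to_tsv(hits: Sequence, path: Union[str, Path]) -> None:
    """Write hits as TSV: sequence_id, start, end, matched, pattern."""
    with open(path, "w") as fh:
        fh.write("sequence_id\tstart\tend\tmatched\tpattern\n")
        for h in hits:
            fh.write(f"{h.sequence_id}\t{h.start}\t{h.end}\t{h.matched}\t{h.pattern_rendering}\n")
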