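"""Sequence and alignment I/O.

Readers emit :class:`ProteinSequence` records (uppercase one-letter residues,
``X`` for unknown) and :class:`Alignment` objects whose members may carry
``-`` gap characters.  A redundancy filter removes records with byte-identical
residue strings, keeping the first occurrence.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, TextIO

from .errors import AlignmentShapeError, NoRecordsError, ParseError

log = logging.getLogger(__name__)

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
#: residues a reader accepts: the 20 standard amino acids, X (unknown), - (gap)
VALID_RESIDUES = frozenset(STANDARD_AA + "X-")
GAP = "-"
FASTA_WIDTH = 60  # wrap column of the writer, fixed so output is bit-stable


@dataclass(frozen=True)
class ProteinSequence:
    """One protein record: identifier, residue string, free-text description."""

    identifier: str
    residues: str
    description: str = ""

    def __post_init__(self):
        if not self.identifier or any(c.isspace() for c in self.identifier):
            raise ValueError(f"invalid identifier {self.identifier!r}")
        if not self.residues:
            raise ValueError(f"empty residue string for {self.identifier!r}")

    def __len__(self) -> int:
        return len(self.residues)

    def ungapped(self) -> "ProteinSequence":
        """Copy of this record with gap characters removed."""
        if GAP not in self.residues:
            return self
        return ProteinSequence(
            self.identifier, self.residues.replace(GAP, ""), self.description
        )


@dataclass(frozen=True)
class Alignment:
    """A fixed-width multiple alignment (members may contain ``-``)."""

    members: tuple[ProteinSequence, ...]
    column_count: int

    def __post_init__(self):
        if len(self.members) < 2:
            raise AlignmentShapeError("an alignment needs at least 2 members")
        bad = [m.identifier for m in self.members if len(m) != self.column_count]
        if bad:
            raise AlignmentShapeError(
                f"members not matching column count {self.column_count}: "
                + ", ".join(bad)
            )


def _as_stream(source) -> TextIO:
    if isinstance(source, str) and (
        not source or "\n" in source or source.lstrip().startswith(">")
    ):
        return io.StringIO(source)
    if hasattr(source, "read"):
        return source
    return open(source, "r", encoding="utf-8")


def read_fasta(source) -> list[ProteinSequence]:
    """Parse FASTA text into records.

    ``source`` may be a path, an open text stream, or FASTA text itself.
    Residues are uppercased, one terminal ``*`` is stripped, and duplicate
    identifiers get a numeric suffix (``_2``, ``_3`` ...) with a warning.
    Characters outside the 20 amino acids, ``X`` and ``-`` are a
    :class:`ParseError` naming the line.
    """
    stream = _as_stream(source)
    records: list[tuple[str, str, list[str], int]] = []  # id, desc, chunks, line
    header_line = 0
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            head = line[1:].strip()
            if not head:
                raise ParseError(f"empty FASTA header at line {lineno}")
            ident, _, desc = head.partition(" ")
            records.append((ident, desc.strip(), [], lineno))
            header_line = lineno
        else:
            if not records:
                raise ParseError(
                    f"sequence data before any '>' header at line {lineno}"
                )
            chunk = line.upper().replace(" ", "")
            bad = set(chunk) - VALID_RESIDUES - {"*"}
            if bad:
                raise ParseError(
                    f"invalid residue character(s) {''.join(sorted(bad))!r} "
                    f"at line {lineno}"
                )
            records[-1][2].append(chunk)
    if not records:
        raise NoRecordsError("no records in FASTA input")

    seen: dict[str, int] = {}
    out: list[ProteinSequence] = []
    for ident, desc, chunks, lineno in records:
        residues = "".join(chunks)
        if residues.endswith("*"):
            residues = residues[:-1]
        if "*" in residues:
            raise ParseError(
                f"internal stop character '*' in record {ident!r} "
                f"(header at line {lineno})"
            )
        if not residues:
            raise ParseError(f"record {ident!r} (line {lineno}) has no residues")
        final = ident
        if ident in seen:
            n = seen[ident] + 1
            while f"{ident}_{n}" in seen:
                n += 1
            final = f"{ident}_{n}"
            seen[ident] = n
            log.warning("duplicate identifier %r renamed to %r", ident, final)
        seen.setdefault(ident, 1)
        seen.setdefault(final, 1)
        out.append(ProteinSequence(final, residues, desc))
    return out


def write_fasta(seqs: Iterable[ProteinSequence], dest) -> None:
    """Write records as FASTA wrapped at 60 columns."""
    own = False
    if not hasattr(dest, "write"):
        dest = open(dest, "w", encoding="utf-8")
        own = True
    try:
        for s in seqs:
            head = f">{s.identifier}"
            if s.description:
                head += f" {s.description}"
            dest.write(head + "\n")
            for i in range(0, len(s.residues), FASTA_WIDTH):
                dest.write(s.residues[i : i + FASTA_WIDTH] + "\n")
    finally:
        if own:
            dest.close()


def read_alignment(source, dialect: str = "fasta") -> Alignment:
    """Read a multiple alignment in aligned-FASTA or Clustal format.

    Clustal conservation lines are ignored.  Ragged member lengths raise
    :class:`AlignmentShapeError` listing the offending identifiers.
    """
    if dialect == "fasta":
        members = tuple(read_fasta(source))
    elif dialect == "clustal":
        from Bio import AlignIO

        stream = _as_stream(source)
        aln = AlignIO.read(stream, "clustal")
        members = tuple(
            ProteinSequence(rec.id, str(rec.seq).upper()) for rec in aln
        )
    else:
        raise ValueError(f"unknown alignment dialect {dialect!r}")
    if not members:
        raise NoRecordsError("no records in alignment input")
    width = len(members[0])
    bad = [m.identifier for m in members if len(m) != width]
    if bad:
        raise AlignmentShapeError(
            "alignment members with deviating lengths: " + ", ".join(bad)
        )
    return Alignment(members, width)


def dedupe_identical(
    seqs: list[ProteinSequence],
) -> tuple[list[ProteinSequence], dict[str, str]]:
    """Drop records whose residue strings are byte-identical to an earlier one.

    Returns ``(kept, removed)`` where ``removed`` maps each dropped
    identifier to the identifier of its retained representative.  Order of
    ``kept`` is first-occurrence order; descriptions are ignored.
    """
    kept: list[ProteinSequence] = []
    removed: dict[str, str] = {}
    first_by_residues: dict[str, str] = {}
    for s in seqs:
        rep = first_by_residues.get(s.residues)
        if rep is None:
            first_by_residues[s.residues] = s.identifier
            kept.append(s)
        else:
            removed[s.identifier] = rep
    return kept, removed


def write_removed_tsv(removed: Mapping[str, str], dest) -> None:
    """Write the redundancy map as TSV with columns removed_id, kept_id."""
    own = False
    if not hasattr(dest, "write"):
        dest = open(dest, "w", encoding="utf-8")
        own = True
    try:
        dest.write("removed_id\tkept_id\n")
        for rem, kept in removed.items():
            dest.write(f"{rem}\t{kept}\n")
    finally:
        if own:
            dest.close()
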