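"""Prosite-syntax pattern parsing, rendering and matching.

A pattern is a dash-separated list of elements: residue literals (``C``),
classes (``[VLI]``), negated classes (``{DE}``), and the wildcard ``x``;
every element may carry a repeat ``(n)`` or ``(n,m)``.  ``<`` anchors the
match to the N-terminus, ``>`` to the C-terminus, and a terminal ``.`` is
tolerated.

Matching enumerates every wildcard/repeat length assignment exhaustively, so
greedy-versus-lazy distinctions familiar from regular expressions do not
arise: :func:`scan` reports *all* distinct (start, end) spans.  An ``X``
(unknown residue) in the sequence matches only wildcards, never a literal,
class or negated class.

The built-ins are the two published nsLTP signatures (``typeI``, ``typeII``)
and the classic plant-LTP entry ``PS00597``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional

from .core_io import STANDARD_AA, ProteinSequence
from .errors import PatternSyntaxError

KIND_LITERAL = "literal"
KIND_CLASS = "class"
KIND_NEGATED = "negated_class"
KIND_WILDCARD = "wildcard"


@dataclass(frozen=True)
class PatternElement:
    kind: str
    residues: tuple  # ordered, empty for wildcard
    repeat_min: int = 1
    repeat_max: int = 1

    def __post_init__(self):
        if not (0 <= self.repeat_min <= self.repeat_max):
            raise ValueError(f"bad repeat range ({self.repeat_min},{self.repeat_max})")
        if self.kind == KIND_LITERAL and len(self.residues) != 1:
            raise ValueError("literal needs exactly one residue")
        if self.kind in (KIND_CLASS, KIND_NEGATED) and not self.residues:
            raise ValueError("class needs at least one residue")

    def accepts(self, ch: str) -> bool:
        """Whether one sequence character satisfies this element."""
        if self.kind == KIND_WILDCARD:
            return ch != "-"
        if self.kind == KIND_NEGATED:
            return ch in STANDARD_AA and ch not in self.residues
        return ch in self.residues  # literal / class; 'X' is never listed


@dataclass(frozen=True)
class PrositePattern:
    elements: tuple
    anchored_start: bool = False
    anchored_end: bool = False
    name: str = ""

    def __post_init__(self):
        if not self.elements:
            raise ValueError("pattern needs at least one element")

    @property
    def min_length(self) -> int:
        return sum(e.repeat_min for e in self.elements)

    @property
    def max_length(self) -> int:
        return sum(e.repeat_max for e in self.elements)


class MatchSpan(NamedTuple):
    start: int  # 0-based inclusive
    end: int  # exclusive


def parse_pattern(text: str, name: str = "") -> PrositePattern:
    """Parse Prosite syntax; errors carry the character offset."""
    s = text
    n = len(s)
    i = 0

    def err(msg: str, pos: int):
        raise PatternSyntaxError(f"{msg} at offset {pos} in pattern {text!r}")

    def skip_ws():
        nonlocal i
        while i < n and s[i].isspace():
            i += 1

    skip_ws()
    anchored_start = False
    if i < n and s[i] == "<":
        anchored_start = True
        i += 1
    elements: list[PatternElement] = []
    while True:
        skip_ws()
        if i >= n:
            err("unexpected end of pattern", i)
        ch = s[i]
        if ch in "xX":
            kind, residues = KIND_WILDCARD, ()
            i += 1
        elif ch in "[{":
            closer = "]" if ch == "[" else "}"
            kind = KIND_CLASS if ch == "[" else KIND_NEGATED
            j = s.find(closer, i)
            if j < 0:
                err(f"unbalanced {ch!r}", i)
            body = s[i + 1 : j]
            residues_l: list[str] = []
            for k, c in enumerate(body):
                if c.isspace() or c == ",":
                    continue
                cu = c.upper()
                if cu not in STANDARD_AA:
                    err(f"unknown residue letter {c!r}", i + 1 + k)
                if cu not in residues_l:
                    residues_l.append(cu)
            if not residues_l:
                err("empty residue class", i)
            residues = tuple(residues_l)
            i = j + 1
        elif ch.upper() in STANDARD_AA:
            kind, residues = KIND_LITERAL, (ch.upper(),)
            i += 1
        else:
            err(f"unexpected character {ch!r}", i)
        skip_ws()
        rmin = rmax = 1
        if i < n and s[i] == "(":
            j = s.find(")", i)
            if j < 0:
                err("unclosed repeat", i)
            body = s[i + 1 : j].strip()
            parts = [p.strip() for p in body.split(",")]
            try:
                if len(parts) == 1:
                    rmin = rmax = int(parts[0])
                elif len(parts) == 2:
                    rmin, rmax = int(parts[0]), int(parts[1])
                else:
                    raise ValueError
            except ValueError:
                err(f"invalid repeat {body!r}", i)
            if rmin < 0 or rmin > rmax:
                err(f"inverted or negative repeat {body!r}", i)
            i = j + 1
        elements.append(PatternElement(kind, residues, rmin, rmax))
        skip_ws()
        if i < n and s[i] == "-":
            i += 1
            continue
        break
    anchored_end = False
    skip_ws()
    if i < n and s[i] == ">":
        anchored_end = True
        i += 1
        skip_ws()
    if i < n and s[i] == ".":
        i += 1
        skip_ws()
    if i < n:
        err(f"trailing text {s[i:]!r}", i)
    return PrositePattern(tuple(elements), anchored_start, anchored_end, name)


def render_pattern(p: PrositePattern) -> str:
    """Canonical text form; ``parse_pattern(render_pattern(p))`` is stable."""
    parts = []
    for e in p.elements:
        if e.kind == KIND_WILDCARD:
            core = "x"
        elif e.kind == KIND_LITERAL:
            core = e.residues[0]
        elif e.kind == KIND_CLASS:
            core = "[" + "".join(e.residues) + "]"
        else:
            core = "{" + "".join(e.residues) + "}"
        if (e.repeat_min, e.repeat_max) == (1, 1):
            parts.append(core)
        elif e.repeat_min == e.repeat_max:
            parts.append(f"{core}({e.repeat_min})")
        else:
            parts.append(f"{core}({e.repeat_min},{e.repeat_max})")
    out = "-".join(parts)
    if p.anchored_start:
        out = "<" + out
    if p.anchored_end:
        out += ">"
    return out


_BUILTIN_TEXT = {
    "typeI": (
        "C-x(2)-V-x(5,7)-C-[VLI]-x-Y-[LAV]-x(8,13)-C-C-x-G-x(12)-D-x-[QKR]-"
        "x(2)-C-x-C-x(16,21)-P-x(2)-C-x(13,15)-C"
    ),
    "typeII": (
        "C-x(4)-L-x(2)-C-x(9,11)-P-[ST]-x(2)-C-C-x(5)-Q-x(2,4)-C-[LF]-C-"
        "x(2)-[ALI]-x-[DN]-P-x(10,12)-[KR]-x(4,5)-C-x(3,4)-P-x(0,2)-C"
    ),
    "PS00597": (
        "[LIVM]-[PA]-x(2)-C-x-[LIVM]-x-[LIVM]-x-[LIVMFY]-x-[LIVM]-[ST]-"
        "x(3)-[DN]-C-x(2)-[LIVM]"
    ),
}


def builtin_patterns() -> dict[str, PrositePattern]:
    """The published Type I / Type II nsLTP signatures plus PS00597."""
    return {name: parse_pattern(text, name) for name, text in _BUILTIN_TEXT.items()}


def _residue_string(seq) -> str:
    return seq.residues if isinstance(seq, ProteinSequence) else str(seq)


def scan(seq, pattern: PrositePattern) -> list[MatchSpan]:
    """All distinct (start, end) spans where the pattern matches contiguously.

    Wildcard/repeat variability is enumerated exhaustively; spans are sorted
    by (start, end).  Anchors restrict spans to the respective terminus.
    """
    res = _residue_string(seq)
    n = len(res)
    elems = pattern.elements
    k = len(elems)
    spans: set[tuple[int, int]] = set()

    def extend(ei: int, pos: int, ends: set):
        if ei == k:
            ends.add(pos)
            return
        e = elems[ei]
        p = pos
        for _ in range(e.repeat_min):
            if p >= n or not e.accepts(res[p]):
                return
            p += 1
        extend(ei + 1, p, ends)
        for _ in range(e.repeat_max - e.repeat_min):
            if p >= n or not e.accepts(res[p]):
                return
            p += 1
            extend(ei + 1, p, ends)

    starts = (0,) if pattern.anchored_start else range(n + 1)
    for start in starts:
        if start + pattern.min_length > n:
            break
        ends: set[int] = set()
        extend(0, start, ends)
        for end in ends:
            if end > start and (not pattern.anchored_end or end == n):
                spans.add((start, end))
    return [MatchSpan(a, b) for a, b in sorted(spans)]


def matches(seq, pattern: PrositePattern) -> bool:
    """Whether the pattern matches anywhere in the sequence."""
    return bool(scan(seq, pattern))


def first_segmentation(seq, pattern: PrositePattern) -> Optional[list]:
    """First element-wise segmentation of a match, or None.

    Returns ``[(element_index, seg_start, seg_end), ...]`` for the earliest
    start; among equal starts, shorter repeat counts are tried first.
    """
    res = _residue_string(seq)
    n = len(res)
    elems = pattern.elements
    k = len(elems)

    def walk(ei: int, pos: int, acc: list) -> Optional[list]:
        if ei == k:
            if pattern.anchored_end and pos != n:
                return None
            return list(acc)
        e = elems[ei]
        p = pos
        for _ in range(e.repeat_min):
            if p >= n or not e.accepts(res[p]):
                return None
            p += 1
        for extra in range(e.repeat_max - e.repeat_min + 1):
            acc.append((ei, pos, p))
            got = walk(ei + 1, p, acc)
            acc.pop()
            if got is not None:
                return got
            if p >= n or not e.accepts(res[p]):
                return None
            p += 1
        return None

    starts = (0,) if pattern.anchored_start else range(n + 1)
    for start in starts:
        got = walk(0, start, [])
        if got is not None and got and got[-1][2] > start:
            return got
    return None


def pattern_to_regex(p: PrositePattern) -> str:
    """Mechanical translation to an equivalent regular-expression body.

    Intended for cross-checking :func:`scan` with an independent engine via
    ``re.fullmatch`` on sequence slices (anchors are the caller's concern).
    ``X`` in sequences matches only the wildcard's ``[A-Z]``.
    """
    parts = []
    for e in p.elements:
        if e.kind == KIND_WILDCARD:
            cls = "[A-Z]"
        elif e.kind in (KIND_LITERAL, KIND_CLASS):
            cls = "[" + "".join(e.residues) + "]"
        else:
            allowed = [a for a in STANDARD_AA if a not in e.residues]
            cls = ("[" + "".join(allowed) + "]") if allowed else "(?!x)x"
        if (e.repeat_min, e.repeat_max) == (1, 1):
            rep = ""
        elif e.repeat_min == e.repeat_max:
            rep = f"{{{e.repeat_min}}}"
        else:
            rep = f"{{{e.repeat_min},{e.repeat_max}}}"
        parts.append(cls + rep)
    return "".join(parts)


def cysteine_gap_hulls(p: PrositePattern) -> dict[str, tuple[int, int]]:
    """Inter-cysteine gap ranges implied by a pattern with eight C literals.

    Returns min/max residue counts for the g1..g5 slots of the 8-Cys
    scaffold, computed by summing repeat ranges of the elements between
    consecutive cysteine literals.  Raises ``ValueError`` unless the pattern
    contains exactly eight single-repeat ``C`` literals.
    """
    cys_idx = [
        i
        for i, e in enumerate(p.elements)
        if e.kind == KIND_LITERAL
        and e.residues == ("C",)
        and (e.repeat_min, e.repeat_max) == (1, 1)
    ]
    if len(cys_idx) != 8:
        raise ValueError(f"pattern has {len(cys_idx)} cysteine literals, need 8")
    slot_pairs = {"g1": (0, 1), "g2": (1, 2), "g3": (3, 4), "g4": (5, 6), "g5": (6, 7)}
    out = {}
    for slot, (a, b) in slot_pairs.items():
        between = p.elements[cys_idx[a] + 1 : cys_idx[b]]
        out[slot] = (
            sum(e.repeat_min for e in between),
            sum(e.repeat_max for e in between),
        )
    return out


def read_pattern_file(source) -> dict[str, PrositePattern]:
    """Read one pattern per line, optionally ``NAME;PATTERN``."""
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        with open(source, "r", encoding="utf-8") as fh:
            lines = fh.read().splitlines()
    out: dict[str, PrositePattern] = {}
    auto = 0
    for line in lines:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if ";" in line:
            name, _, text = line.partition(";")
            name = name.strip()
        else:
            auto += 1
            name, text = f"pat{auto}", line
        out[name] = parse_pattern(text.strip(), name)
    return out


def write_scan_tsv(rows, dest) -> None:
    """TSV with columns sequence_id, pattern_name, start_1based, end_1based,
    matched_subsequence; ``rows`` yields (seq, pattern, span)."""
    own = False
    if not hasattr(dest, "write"):
        dest = open(dest, "w", encoding="utf-8")
        own = True
    try:
        dest.write(
            "sequence_id\tpattern_name\tstart_1based\tend_1based\tmatched_subsequence\n"
        )
        for seq, pattern, span in rows:
            dest.write(
                f"{seq.identifier}\t{pattern.name or '.'}\t{span.start + 1}\t"
                f"{span.end}\t{seq.residues[span.start:span.end]}\n"
            )
    finally:
        if own:
            dest.close()
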