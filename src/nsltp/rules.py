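"""Inter-cysteine spacing rules for the five nsLTP types and the
cysteine-deficient categories A-D.

Each table slot is a set of allowed residue counts written in the compact
``"7,13-15"`` notation: comma-separated exact values, dashes inclusive
integer ranges.  Type rows constrain the N-terminal offset before Cys1, the
five inter-cysteine gaps g1..g5 (Cys1-Cys2, Cys2-Cys3, Cys4-Cys5, Cys6-Cys7,
Cys7-Cys8), and the C-terminal tail after Cys8.  Deficient rows constrain the
gaps between the cysteine blocks that remain when one or two of the eight
cysteines are missing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

SpanSet = frozenset  # frozenset[int]

TYPE_ORDER = ("I", "II", "III", "IV", "V")


def parse_spans(text: str) -> frozenset:
    """Parse ``"0-12,16"`` into a frozenset of ints."""
    out: set[int] = set()
    for part in text.split(","):
        part = part.strip()
        if not part:
            continue
        if "-" in part:
            lo_s, hi_s = part.split("-", 1)
            lo, hi = int(lo_s), int(hi_s)
            if lo > hi:
                raise ValueError(f"inverted range {part!r}")
            out.update(range(lo, hi + 1))
        else:
            out.add(int(part))
    if not out:
        raise ValueError(f"empty span set {text!r}")
    return frozenset(out)


def format_spans(s: frozenset) -> str:
    """Render a span set back to compact ``"0-12,16"`` notation."""
    vals = sorted(s)
    parts: list[str] = []
    i = 0
    while i < len(vals):
        j = i
        while j + 1 < len(vals) and vals[j + 1] == vals[j] + 1:
            j += 1
        if j > i + 1:
            parts.append(f"{vals[i]}-{vals[j]}")
        elif j == i + 1:
            parts.append(f"{vals[i]},{vals[j]}")
        else:
            parts.append(str(vals[i]))
        i = j + 1
    return ",".join(parts)


def hull(s: frozenset) -> tuple[int, int]:
    """Interval hull (min, max) of a span set."""
    return (min(s), max(s))


@dataclass(frozen=True)
class TypeRule:
    """Spacing constraints for one nsLTP type."""

    n_offset: frozenset
    gaps: tuple  # 5 frozensets for g1..g5
    c_tail: frozenset


def _tr(n: str, g1: str, g2: str, g3: str, g4: str, g5: str, tail: str) -> TypeRule:
    return TypeRule(
        parse_spans(n),
        tuple(parse_spans(g) for g in (g1, g2, g3, g4, g5)),
        parse_spans(tail),
    )


#: Spacing table for Types I-V.  The Type III g4 entry "21-24,2" is carried
#: literally; the isolated value 2 looks like a typographic artifact and can
#: be dropped via :func:`type_rules`.
TYPE_RULES: Mapping[str, TypeRule] = {
    "I": _tr("0-12,16", "8-10", "12-17", "18-20,29", "19-24", "7,13-15", "26,37,48"),
    "II": _tr("0-20", "7", "13,15", "8-10", "16,21,24", "4-7", "0-2"),
    "III": _tr("0-7", "9,10", "12,15,17", "9", "21-24,2", "6-10,13", "0-5,10"),
    "IV": _tr("2-5,10", "14", "14", "11-13", "24", "10", "6,10,12"),
    "V": _tr("2-17", "10", "16,17", "9", "22,23", "7,9", "5-12"),
}


def type_rules(iii_g4_drop_outlier: bool = False) -> dict[str, TypeRule]:
    """Return a copy of the type table.

    With ``iii_g4_drop_outlier`` the isolated value 2 in the Type III g4 set
    (likely a typographic slip for a 21-24 range) is removed.
    """
    rules = dict(TYPE_RULES)
    if iii_g4_drop_outlier:
        r = rules["III"]
        gaps = list(r.gaps)
        gaps[3] = frozenset(v for v in gaps[3] if v != 2)
        rules["III"] = TypeRule(r.n_offset, tuple(gaps), r.c_tail)
    return rules


@dataclass(frozen=True)
class DeficientRule:
    """Block skeleton and gap constraints for one deficient category."""

    category: str
    skeleton: tuple  # block names drawn from {"C", "CC", "CXC"}
    gaps: tuple  # frozensets, one per inter-block gap
    n_offset: Optional[frozenset]  # None = unconstrained
    c_tail: Optional[frozenset]


def _dr(cat, skeleton, gaps, n, tail) -> DeficientRule:
    return DeficientRule(
        cat,
        tuple(skeleton),
        tuple(parse_spans(g) for g in gaps),
        parse_spans(n) if n else None,
        parse_spans(tail) if tail else None,
    )


#: Categories for sequences missing one or two of the eight cysteines.
#: A and B retain seven cysteines, C and D six; C and D share the same block
#: skeleton and are distinguished only by their gap sets, so a sequence is
#: reported under every category it satisfies.
DEFICIENT_RULES: Mapping[str, DeficientRule] = {
    "A": _dr(
        "A",
        ("C", "CC", "CXC", "C", "C"),
        ("8,13-16", "8,9,16-19", "22,23", "6-14"),
        "1-13,18,29",
        "1-6",
    ),
    "B": _dr(
        "B",
        ("C", "C", "CC", "CXC", "C"),
        ("7,9", "13-16", "8,12,19", "21-24,36"),
        "1-3,11",
        "4,10,13,33,64",
    ),
    "C": _dr(
        "C",
        ("C", "CC", "CXC", "C"),
        ("13", "15,19", "22,45"),
        "4,9",
        "1,11,12",
    ),
    "D": _dr(
        "D",
        ("C", "CC", "CXC", "C"),
        ("1-11", "19", "21-23"),
        None,
        "4,5,10,12",
    ),
}
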