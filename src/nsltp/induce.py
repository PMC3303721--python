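"""Pattern induction from a multiple alignment.

Per-column amino-acid occurrence drives the decision: a column dominated by
one residue becomes a literal, a column covered by a small set of frequent
residues becomes a class (residues ordered by descending frequency, ties
alphabetical), and anything else -- including sparsely occupied columns --
becomes a wildcard.  Maximal runs of wildcard columns collapse into a single
``x(m,M)`` whose bounds are the observed per-member non-gap counts over the
run, so variable-length loop regions turn into the familiar gap ranges of
published patterns.  Columns that are pure cysteine are pinned as ``C``
literals regardless of occupancy, since the eight-cysteine scaffold is the
one invariant of the family.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .core_io import GAP, Alignment
from .errors import InsufficientDataError
from .prosite import (
    KIND_CLASS,
    KIND_LITERAL,
    KIND_WILDCARD,
    PatternElement,
    PrositePattern,
)


@dataclass(frozen=True)
class ColumnProfile:
    column_index: int
    counts: dict  # residue -> count over non-gap members
    occupancy: float  # fraction of members that are non-gap


@dataclass(frozen=True)
class InductionConfig:
    literal_threshold: float = 0.90
    class_cum_threshold: float = 0.90
    class_max_size: int = 4
    min_occupancy: float = 0.50
    anchor_cys: bool = True

    def __post_init__(self):
        for name in ("literal_threshold", "class_cum_threshold", "min_occupancy"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name}={v} outside (0, 1]")
        if self.class_max_size < 2:
            raise ValueError("class_max_size must be >= 2")


def column_profiles(aln: Alignment) -> list[ColumnProfile]:
    """One occurrence profile per column, counting non-gap residues only."""
    n = len(aln.members)
    out = []
    for j in range(aln.column_count):
        col = [m.residues[j] for m in aln.members]
        nongap = [c for c in col if c != GAP]
        out.append(
            ColumnProfile(j, dict(Counter(nongap)), len(nongap) / n)
        )
    return out


def _decide_columns(aln: Alignment, config: InductionConfig):
    """Per-column decision: ('literal', res) | ('class', residues) |
    ('wildcard', None), plus the profile."""
    decisions = []
    for prof in column_profiles(aln):
        total = sum(prof.counts.values())
        if (
            config.anchor_cys
            and total > 0
            and set(prof.counts) == {"C"}
        ):
            decisions.append((("literal", ("C",)), prof))
            continue
        if total == 0 or prof.occupancy < config.min_occupancy:
            decisions.append((("wildcard", None), prof))
            continue
        ranked = sorted(prof.counts.items(), key=lambda kv: (-kv[1], kv[0]))
        top_freq = ranked[0][1] / total
        if top_freq >= config.literal_threshold:
            decisions.append((("literal", (ranked[0][0],)), prof))
            continue
        cum = 0.0
        chosen = []
        for res, cnt in ranked:
            chosen.append(res)
            cum += cnt / total
            if cum >= config.class_cum_threshold:
                break
        if cum >= config.class_cum_threshold and len(chosen) <= config.class_max_size:
            decisions.append((("class", tuple(chosen)), prof))
        else:
            decisions.append((("wildcard", None), prof))
    return decisions


def induce_pattern(
    aln: Alignment, config: InductionConfig = InductionConfig()
) -> PrositePattern:
    """Derive a Prosite-styled pattern from an alignment (>= 2 members)."""
    if len(aln.members) < 2:
        raise InsufficientDataError("pattern induction needs at least 2 members")
    decisions = _decide_columns(aln, config)
    elements: list[PatternElement] = []
    j = 0
    ncol = len(decisions)
    while j < ncol:
        (kind, residues), _ = decisions[j]
        if kind == "literal":
            elements.append(PatternElement(KIND_LITERAL, residues))
            j += 1
        elif kind == "class":
            elements.append(PatternElement(KIND_CLASS, residues))
            j += 1
        else:
            j2 = j
            while j2 < ncol and decisions[j2][0][0] == "wildcard":
                j2 += 1
            run_lengths = [
                sum(
                    1
                    for c in range(j, j2)
                    if m.residues[c] != GAP
                )
                for m in aln.members
            ]
            lo, hi = min(run_lengths), max(run_lengths)
            if hi > 0:
                elements.append(PatternElement(KIND_WILDCARD, (), lo, hi))
            j = j2
    if not elements:
        raise InsufficientDataError("alignment has no informative columns")
    return PrositePattern(tuple(elements), name="induced")


def write_column_report(aln: Alignment, config: InductionConfig, dest) -> None:
    """TSV: column (1-based), decision, top residues, frequencies."""
    own = False
    if not hasattr(dest, "write"):
        dest = open(dest, "w", encoding="utf-8")
        own = True
    try:
        dest.write("column\tdecision\toccupancy\ttop_residues\tfrequencies\n")
        for (kind, residues), prof in _decide_columns(aln, config):
            total = sum(prof.counts.values())
            ranked = sorted(prof.counts.items(), key=lambda kv: (-kv[1], kv[0]))
            tops = ",".join(r for r, _ in ranked[:5]) or "."
            freqs = (
                ",".join(f"{cnt / total:.2f}" for _, cnt in ranked[:5])
                if total
                else "."
            )
            label = kind if kind != "class" else "class:" + "".join(residues or ())
            if kind == "literal":
                label = "literal:" + residues[0]
            dest.write(
                f"{prof.column_index + 1}\t{label}\t{prof.occupancy:.2f}\t"
                f"{tops}\t{freqs}\n"
            )
    finally:
        if own:
            dest.close()
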