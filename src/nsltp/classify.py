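"""Five-type spacing classification of nsLTP sequences.

A sequence's 8-Cys scaffold is typed by testing its inter-cysteine gap
vector (g1..g5) against the per-type spacing table; ``strict`` mode also
tests the N-terminal offset and C-terminal tail.  The default is ``core``
mode because the terminal lengths depend on where the signal peptide was
cleaved, which is upstream of this toolkit.  Ambiguity (several compatible
types, notably the III/V overlap) is reported as such and never silently
broken; callers may impose a priority order via ``prefer``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .core_io import ProteinSequence
from .motif import CysMotif, DeficientMotif, find_cys_motifs, find_deficient_motifs
from .physchem import (
    PhyschemReport,
    compute_report,
    polarity_of,
)
from .prosite import PrositePattern, builtin_patterns, matches
from .rules import TYPE_ORDER, TYPE_RULES, TypeRule, format_spans

SLOT_NAMES = ("g1", "g2", "g3", "g4", "g5")


@dataclass(frozen=True)
class TypeAssignment:
    """Result of testing one motif against the spacing table."""

    compatible: tuple  # subset of TYPE_ORDER, in table order
    resolved: str  # one of TYPE_ORDER, "ambiguous", "unclassified"
    evidence: dict  # type -> slot -> (observed, matched set string or "miss")


def classify_spacing(
    motif: CysMotif,
    mode: str = "core",
    rules: Mapping[str, TypeRule] = TYPE_RULES,
    prefer: Optional[Sequence[str]] = None,
) -> TypeAssignment:
    """Test a motif's gap vector against every type row.

    ``core`` mode tests g1..g5 only; ``strict`` additionally tests the
    N-offset and C-tail.  Evidence records, for every tested type and slot,
    the observed count and the matched set (or ``"miss"``).
    """
    if mode not in ("core", "strict"):
        raise ValueError(f"unknown mode {mode!r}")
    evidence: dict[str, dict[str, tuple]] = {}
    compatible: list[str] = []
    for t in TYPE_ORDER:
        if t not in rules:
            continue
        rule = rules[t]
        ev: dict[str, tuple] = {}
        ok = True
        slots = list(zip(SLOT_NAMES, motif.gaps, rule.gaps))
        if mode == "strict":
            slots.append(("n_offset", motif.n_offset, rule.n_offset))
            slots.append(("c_tail", motif.c_tail, rule.c_tail))
        for name, obs, allowed in slots:
            if obs in allowed:
                ev[name] = (obs, format_spans(allowed))
            else:
                ev[name] = (obs, "miss")
                ok = False
        evidence[t] = ev
        if ok:
            compatible.append(t)
    if not compatible:
        resolved = "unclassified"
    elif len(compatible) == 1:
        resolved = compatible[0]
    else:
        resolved = "ambiguous"
        if prefer:
            for t in prefer:
                if t in compatible:
                    resolved = t
                    break
    return TypeAssignment(tuple(compatible), resolved, evidence)


@dataclass(frozen=True)
class ClassificationReport:
    """Everything the classifier knows about one sequence."""

    sequence: ProteinSequence
    motif: Optional[CysMotif]
    assignment: Optional[TypeAssignment]
    deficient: tuple  # DeficientMotif placements (only when no full motif)
    pattern_matches: Optional[dict]  # {"typeI": bool, "typeII": bool}
    agreement: Optional[bool]  # spacing call vs pattern call, when both apply
    physchem: PhyschemReport

    @property
    def resolved(self) -> str:
        return self.assignment.resolved if self.assignment else "unclassified"

    @property
    def deficient_categories(self) -> tuple:
        seen: list[str] = []
        for d in self.deficient:
            if d.category not in seen:
                seen.append(d.category)
        return tuple(seen)


def classify_sequence(
    seq: ProteinSequence,
    mode: str = "core",
    use_patterns: bool = False,
    rules: Mapping[str, TypeRule] = TYPE_RULES,
    prefer: Optional[Sequence[str]] = None,
    patterns: Optional[dict[str, PrositePattern]] = None,
) -> ClassificationReport:
    """Full per-sequence classification.

    Runs the motif search; among multiple scaffold placements the first (in
    motif sort order) yielding a non-unclassified assignment wins, falling
    back to the first placement.  Without a full scaffold the deficient
    categories are reported.  With ``use_patterns`` the built-in Type I /
    Type II signatures are matched against the sequence and an agreement
    flag records whether the two evidence sources coincide.
    """
    motifs = find_cys_motifs(seq)
    motif: Optional[CysMotif] = None
    assignment: Optional[TypeAssignment] = None
    for m in motifs:
        a = classify_spacing(m, mode=mode, rules=rules, prefer=prefer)
        if a.resolved != "unclassified":
            motif, assignment = m, a
            break
    if motifs and motif is None:
        motif = motifs[0]
        assignment = classify_spacing(motif, mode=mode, rules=rules, prefer=prefer)
    deficient: tuple = ()
    if not motifs:
        deficient = tuple(find_deficient_motifs(seq))

    pattern_matches: Optional[dict] = None
    agreement: Optional[bool] = None
    if use_patterns:
        pats = patterns or builtin_patterns()
        pattern_matches = {
            name: matches(seq, pats[name])
            for name in ("typeI", "typeII")
            if name in pats
        }
        resolved = assignment.resolved if assignment else "unclassified"
        if resolved in ("I", "II"):
            agreement = pattern_matches.get(f"type{resolved}", False)

    return ClassificationReport(
        sequence=seq,
        motif=motif,
        assignment=assignment,
        deficient=deficient,
        pattern_matches=pattern_matches,
        agreement=agreement,
        physchem=compute_report(seq, motif),
    )


def write_classification_tsv(reports, dest) -> None:
    """TSV report, one row per sequence; '.' marks missing values."""
    own = False
    if not hasattr(dest, "write"):
        dest = open(dest, "w", encoding="utf-8")
        own = True

    def cell(v):
        if v is None or v == ():
            return "."
        if isinstance(v, bool):
            return str(int(v))
        if isinstance(v, float):
            return f"{v:.3f}"
        return str(v)

    try:
        header = (
            ["sequence_id", "resolved", "compatible"]
            + list(SLOT_NAMES)
            + [
                "n_offset",
                "c_tail",
                "patternI_match",
                "patternII_match",
                "deficient_category",
                "cxc_x",
                "cxc_polarity",
                "mw_da",
                "pi",
            ]
        )
        dest.write("\t".join(header) + "\n")
        for r in reports:
            m = r.motif
            pm = r.pattern_matches or {}
            cells = [
                r.sequence.identifier,
                r.resolved,
                ",".join(r.assignment.compatible) if r.assignment and r.assignment.compatible else ".",
            ]
            cells += [cell(g) for g in (m.gaps if m else (None,) * 5)]
            cells += [
                cell(m.n_offset if m else None),
                cell(m.c_tail if m else None),
                cell(pm.get("typeI")),
                cell(pm.get("typeII")),
                ",".join(r.deficient_categories) if r.deficient_categories else ".",
                cell(m.cxc_x if m else None),
                cell(polarity_of(m.cxc_x) if m else None),
                cell(r.physchem.mw_da),
                cell(r.physchem.pi),
            ]
            dest.write("\t".join(cells) + "\n")
    finally:
        if own:
            dest.close()
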