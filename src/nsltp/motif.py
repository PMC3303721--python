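"""Detection of the conserved eight-cysteine scaffold.

The scaffold is the consensus C-Xn-C-Xn-CC-Xn-CXC-Xn-C-Xn-C: eight cysteines
of which Cys3/Cys4 are adjacent and Cys5/Cys6 flank a single residue (the
CXC block).  All other inter-cysteine gaps must hold at least one residue.
Sequences with only six or seven cysteines may still fit one of the deficient
block skeletons (categories A-D).

Coordinates are 0-based internally; user-facing reports are 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

from .core_io import ProteinSequence
from .errors import MotifExplosionError
from .rules import DEFICIENT_RULES, DeficientRule

#: gap slot -> (left cysteine index, right cysteine index) in the 8-tuple
GAP_FLANKS = ((0, 1), (1, 2), (3, 4), (5, 6), (6, 7))

_BLOCK_WIDTH = {"C": 1, "CC": 2, "CXC": 3}


@dataclass(frozen=True)
class CysMotif:
    """One placement of the full 8-Cys scaffold on a sequence."""

    cys_positions: tuple  # 8 strictly increasing 0-based indices
    gaps: tuple  # g1..g5 intervening residue counts
    n_offset: int  # residues before Cys1
    c_tail: int  # residues after Cys8
    cxc_x: str  # residue between Cys5 and Cys6

    @property
    def span(self) -> int:
        return self.cys_positions[-1] - self.cys_positions[0]


@dataclass(frozen=True)
class DeficientMotif:
    """One placement of a deficient (6- or 7-cysteine) block skeleton."""

    category: str
    block_skeleton: tuple
    positions: tuple  # cysteine indices, increasing
    gaps: tuple  # inter-block intervening counts
    n_offset: int
    c_tail: int


def find_cys_motifs(seq: ProteinSequence, max_candidates: int = 10_000) -> list[CysMotif]:
    """Enumerate every placement of the full 8-Cys scaffold.

    Candidates are increasing 8-tuples of cysteine indices with Cys3/Cys4
    adjacent, Cys5/Cys6 two apart, and every other gap >= 1.  The result is
    sorted by (Cys1 position, total span).  More than ``max_candidates``
    placements raise :class:`MotifExplosionError`.
    """
    if max_candidates < 1:
        raise ValueError("max_candidates must be >= 1")
    res = seq.residues
    cys = [i for i, c in enumerate(res) if c == "C"]
    cset = set(cys)
    out: list[CysMotif] = []
    for a1, p1 in enumerate(cys):
        for a2 in range(a1 + 1, len(cys)):
            p2 = cys[a2]
            if p2 - p1 < 2:
                continue
            for a3 in range(a2 + 1, len(cys)):
                p3 = cys[a3]
                if p3 - p2 < 2:
                    continue
                p4 = p3 + 1
                if p4 not in cset:
                    continue
                for p5 in cys:
                    if p5 < p4 + 2:
                        continue
                    p6 = p5 + 2
                    if p6 not in cset:
                        continue
                    for p7 in cys:
                        if p7 < p6 + 2:
                            continue
                        for p8 in cys:
                            if p8 < p7 + 2:
                                continue
                            pos = (p1, p2, p3, p4, p5, p6, p7, p8)
                            out.append(
                                CysMotif(
                                    cys_positions=pos,
                                    gaps=(
                                        p2 - p1 - 1,
                                        p3 - p2 - 1,
                                        p5 - p4 - 1,
                                        p7 - p6 - 1,
                                        p8 - p7 - 1,
                                    ),
                                    n_offset=p1,
                                    c_tail=len(res) - 1 - p8,
                                    cxc_x=res[p5 + 1],
                                )
                            )
                            if len(out) > max_candidates:
                                raise MotifExplosionError(len(cys), max_candidates)
    out.sort(key=lambda m: (m.cys_positions[0], m.span, m.cys_positions))
    return out


def _block_positions(block: str, start: int, cset: set) -> Optional[tuple]:
    if block == "C":
        return (start,)
    if block == "CC":
        return (start, start + 1) if start + 1 in cset else None
    if block == "CXC":
        return (start, start + 2) if start + 2 in cset else None
    raise ValueError(block)


def find_deficient_motifs(
    seq: ProteinSequence,
    rules: Mapping[str, DeficientRule] = DEFICIENT_RULES,
) -> list[DeficientMotif]:
    """Match the deficient block skeletons (categories A-D).

    The full scaffold takes precedence: if :func:`find_cys_motifs` finds any
    placement the result is empty.  A placement matches a category when its
    block skeleton equals the category's and every inter-block gap lies in
    the category's printed set; skeletons satisfying several categories are
    reported once per category.
    """
    if find_cys_motifs(seq):
        return []
    res = seq.residues
    cys = [i for i, c in enumerate(res) if c == "C"]
    cset = set(cys)
    out: list[DeficientMotif] = []

    for cat in sorted(rules):
        rule = rules[cat]

        def extend(block_idx: int, prev_end: int, acc: list):
            if block_idx == len(rule.skeleton):
                out.append(
                    DeficientMotif(
                        category=cat,
                        block_skeleton=rule.skeleton,
                        positions=tuple(acc),
                        gaps=tuple(
                            # recompute inter-block gaps from stored boundaries
                            gaps_acc
                        ),
                        n_offset=acc[0],
                        c_tail=len(res) - 1 - acc[-1],
                    )
                )
                return
            block = rule.skeleton[block_idx]
            for start in cys:
                if block_idx > 0:
                    gap = start - prev_end - 1
                    if gap < 1 or gap not in rule.gaps[block_idx - 1]:
                        continue
                elif start <= prev_end:
                    continue
                pos = _block_positions(block, start, cset)
                if pos is None:
                    continue
                if block_idx > 0:
                    gaps_acc.append(start - prev_end - 1)
                acc.extend(pos)
                extend(block_idx + 1, pos[-1], acc)
                del acc[-len(pos):]
                if block_idx > 0:
                    gaps_acc.pop()

        gaps_acc: list[int] = []
        extend(0, -1, [])

    out.sort(key=lambda m: (m.category, m.positions))
    return out


def write_motif_tsv(rows: Iterable[tuple[str, CysMotif]], dest) -> None:
    """Write a motif report: sequence_id, cys1..cys8 (1-based), g1..g5,
    n_offset, c_tail, cxc_x."""
    own = False
    if not hasattr(dest, "write"):
        dest = open(dest, "w", encoding="utf-8")
        own = True
    try:
        header = (
            ["sequence_id"]
            + [f"cys{i}" for i in range(1, 9)]
            + [f"g{i}" for i in range(1, 6)]
            + ["n_offset", "c_tail", "cxc_x"]
        )
        dest.write("\t".join(header) + "\n")
        for seq_id, m in rows:
            cells = (
                [seq_id]
                + [str(p + 1) for p in m.cys_positions]
                + [str(g) for g in m.gaps]
                + [str(m.n_offset), str(m.c_tail), m.cxc_x]
            )
            dest.write("\t".join(cells) + "\n")
    finally:
        if own:
            dest.close()
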