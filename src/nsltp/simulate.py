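"""Synthetic sequence generation for exercising every stage of the toolkit.

The generators produce three kinds of fixtures: sequences realizing a
Prosite pattern, sequences with the 8-Cys scaffold spaced according to one
of the five type rows (with the CXC X residue hydrophilic for Type I and
hydrophobic otherwise, matching the observed trend), and single-violation
decoys derived from either.  Spacer residues are drawn from a background
alphabet that excludes cysteine by default, so scaffold detection on
generated sequences is unambiguous; include ``C`` in the background to
stress the multi-candidate path.

All sampling uses Python's integer-based ``random.Random`` under an explicit
seed, so output is byte-identical across platforms and runs.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Mapping, Optional

from .classify import classify_spacing
from .core_io import STANDARD_AA, Alignment, ProteinSequence
from .errors import SimulationError
from .motif import GAP_FLANKS, find_cys_motifs
from .physchem import HYDROPHILIC, HYDROPHOBIC
from .prosite import (
    KIND_CLASS,
    KIND_LITERAL,
    KIND_NEGATED,
    KIND_WILDCARD,
    PrositePattern,
    first_segmentation,
    matches,
)
from .rules import TYPE_RULES, TypeRule

DEFAULT_BACKGROUND = "".join(c for c in STANDARD_AA if c != "C")


@dataclass(frozen=True)
class SimSpec:
    seed: int = 0
    n: int = 1
    background_alphabet: str = DEFAULT_BACKGROUND
    conservation: float = 1.0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not self.background_alphabet:
            raise ValueError("background alphabet must be non-empty")
        if not (0.0 <= self.conservation <= 1.0):
            raise ValueError("conservation must be in [0, 1]")


def _bg(rng: random.Random, alphabet: str, k: int) -> str:
    return "".join(rng.choice(alphabet) for _ in range(k))


def _realize_element(rng: random.Random, e, background: str) -> str:
    count = (
        e.repeat_min
        if e.repeat_min == e.repeat_max
        else rng.randint(e.repeat_min, e.repeat_max)
    )
    if e.kind == KIND_LITERAL:
        return e.residues[0] * count
    if e.kind == KIND_CLASS:
        return "".join(rng.choice(e.residues) for _ in range(count))
    if e.kind == KIND_NEGATED:
        allowed = [a for a in STANDARD_AA if a not in e.residues]
        if not allowed:
            raise SimulationError("negated class excludes every residue")
        return "".join(rng.choice(allowed) for _ in range(count))
    return _bg(rng, background, count)  # wildcard


def sample_from_pattern(
    p: PrositePattern, spec: SimSpec, flank_range: tuple = (0, 0)
) -> list[ProteinSequence]:
    """Sequences realizing the pattern: literals copied, classes sampled
    uniformly, wildcards filled from the background alphabet.  Optional
    random N/C flanks with lengths drawn from ``flank_range``."""
    rng = random.Random(spec.seed)
    name = p.name or "pattern"
    out = []
    for i in range(spec.n):
        body = "".join(_realize_element(rng, e, spec.background_alphabet) for e in p.elements)
        nf = rng.randint(*flank_range)
        cf = rng.randint(*flank_range)
        seq = _bg(rng, spec.background_alphabet, nf) + body + _bg(
            rng, spec.background_alphabet, cf
        )
        out.append(
            ProteinSequence(f"{name}_{i + 1}", seq, f"generator=pattern source={name}")
        )
    return out


def sample_type_sequences(
    t: str, spec: SimSpec, rules: Mapping[str, TypeRule] = TYPE_RULES
) -> list[ProteinSequence]:
    """Sequences with the 8-Cys scaffold spaced per the type's table row.

    N-offset, g1..g5 and C-tail are drawn uniformly from the transcribed
    sets; the CXC X residue is hydrophilic for Type I and hydrophobic for
    Types II-V; spacers come from the (cysteine-free) background alphabet.
    """
    if t not in rules:
        raise ValueError(f"unknown type {t!r}")
    rule = rules[t]
    rng = random.Random(spec.seed)
    xpool = sorted(HYDROPHILIC if t == "I" else HYDROPHOBIC)
    out = []
    for i in range(spec.n):
        noff = rng.choice(sorted(rule.n_offset))
        gaps = [rng.choice(sorted(g)) for g in rule.gaps]
        tail = rng.choice(sorted(rule.c_tail))
        x = rng.choice(xpool)
        seq = (
            _bg(rng, spec.background_alphabet, noff)
            + "C" + _bg(rng, spec.background_alphabet, gaps[0])
            + "C" + _bg(rng, spec.background_alphabet, gaps[1])
            + "CC" + _bg(rng, spec.background_alphabet, gaps[2])
            + "C" + x + "C" + _bg(rng, spec.background_alphabet, gaps[3])
            + "C" + _bg(rng, spec.background_alphabet, gaps[4])
            + "C" + _bg(rng, spec.background_alphabet, tail)
        )
        out.append(
            ProteinSequence(
                f"type{t}_{i + 1}",
                seq,
                f"generator=type source={t} gaps={','.join(map(str, gaps))}",
            )
        )
    return out


def make_decoys(
    seqs: list[ProteinSequence],
    mode: str,
    seed: int,
    pattern: Optional[PrositePattern] = None,
    rules: Mapping[str, TypeRule] = TYPE_RULES,
) -> list[ProteinSequence]:
    """Single-violation decoys; the violation is recorded in the description.

    ``drop_cys`` replaces one scaffold cysteine with alanine.  ``shift_gap``
    inserts or deletes one spacer residue so that one gap leaves the sets of
    the sequence's (first) compatible type.  ``shuffle_conserved`` corrupts
    one non-cysteine conserved position of the supplied generating pattern,
    replacing the residue with one outside the element's residue set, and
    verifies the pattern no longer matches anywhere.
    """
    rng = random.Random(seed)
    out = []
    for s in seqs:
        m = None
        if mode in ("drop_cys", "shift_gap"):
            motifs = find_cys_motifs(s)
            if not motifs:
                raise SimulationError(f"no 8-Cys motif in {s.identifier}")
            m = motifs[0]
        res = s.residues
        if mode == "drop_cys":
            k = rng.randrange(8)
            pos = m.cys_positions[k]
            new = res[:pos] + "A" + res[pos + 1:]
            desc = f"violation=drop_cys cys={k + 1} pos={pos + 1}"
        elif mode == "shift_gap":
            assignment = classify_spacing(m, rules=rules)
            if not assignment.compatible:
                raise SimulationError(
                    f"{s.identifier}: no compatible type, cannot pick a gap set"
                )
            t = assignment.compatible[0]
            slots = list(range(5))
            rng.shuffle(slots)
            new = None
            for slot in slots:
                g = m.gaps[slot]
                allowed = rules[t].gaps[slot]
                left = m.cys_positions[GAP_FLANKS[slot][0]]
                right = m.cys_positions[GAP_FLANKS[slot][1]]
                if g + 1 not in allowed:
                    ins = rng.choice(DEFAULT_BACKGROUND)
                    new = res[:right] + ins + res[right:]
                    desc = f"violation=shift_gap type={t} slot=g{slot + 1} {g}->{g + 1}"
                    break
                if g - 1 >= 1 and g - 1 not in allowed:
                    # delete a non-cysteine spacer residue
                    for pos in range(right - 1, left, -1):
                        if res[pos] != "C":
                            new = res[:pos] + res[pos + 1:]
                            break
                    else:
                        continue
                    desc = f"violation=shift_gap type={t} slot=g{slot + 1} {g}->{g - 1}"
                    break
            if new is None:
                raise SimulationError(
                    f"{s.identifier}: no gap can leave the type {t} sets"
                )
        elif mode == "shuffle_conserved":
            if pattern is None:
                raise ValueError("shuffle_conserved needs the generating pattern")
            segs = first_segmentation(s, pattern)
            if segs is None:
                raise SimulationError(
                    f"{s.identifier} does not match pattern {pattern.name!r}"
                )
            targets = []
            for ei, seg_start, seg_end in segs:
                e = pattern.elements[ei]
                if e.kind not in (KIND_LITERAL, KIND_CLASS):
                    continue
                for pos in range(seg_start, seg_end):
                    if res[pos] != "C":
                        targets.append((pos, e))
            if not targets:
                raise SimulationError(
                    f"{s.identifier}: no non-cysteine conserved position to corrupt"
                )
            new = None
            for _ in range(50):
                pos, e = rng.choice(targets)
                pool = [
                    a
                    for a in STANDARD_AA
                    if a not in e.residues and a != "C" and a != res[pos]
                ]
                if not pool:
                    continue
                repl = rng.choice(pool)
                cand = res[:pos] + repl + res[pos + 1:]
                if not matches(cand, pattern):
                    new = cand
                    desc = (
                        f"violation=shuffle_conserved pos={pos + 1} "
                        f"{res[pos]}->{repl}"
                    )
                    break
            if new is None:
                raise SimulationError(
                    f"{s.identifier}: could not break the pattern in 50 attempts"
                )
        else:
            raise ValueError(f"unknown decoy mode {mode!r}")
        out.append(
            ProteinSequence(f"{s.identifier}_decoy", new, f"{s.description} {desc}".strip())
        )
    return out


def synthetic_alignment(p: PrositePattern, spec: SimSpec) -> Alignment:
    """Alignment of pattern realizations with controlled conservation.

    Fixed-length elements align column-for-column; variable wildcard runs are
    right-padded with gaps to the longest realization.  At conserved
    (literal/class) columns each residue is replaced by a background residue
    with probability ``1 - conservation``.
    """
    rng = random.Random(spec.seed)
    realizations = []
    for _ in range(spec.n):
        realizations.append(
            [_realize_element(rng, e, spec.background_alphabet) for e in p.elements]
        )
    widths = [
        max(len(row[k]) for row in realizations) for k in range(len(p.elements))
    ]
    members = []
    for i, row in enumerate(realizations):
        parts = []
        for k, e in enumerate(p.elements):
            seg = row[k]
            if e.kind in (KIND_LITERAL, KIND_CLASS, KIND_NEGATED) and spec.conservation < 1.0:
                chars = list(seg)
                for c in range(len(chars)):
                    if rng.random() < 1.0 - spec.conservation:
                        repl = rng.choice(spec.background_alphabet)
                        while repl == chars[c] and len(spec.background_alphabet) > 1:
                            repl = rng.choice(spec.background_alphabet)
                        chars[c] = repl
                seg = "".join(chars)
            parts.append(seg + "-" * (widths[k] - len(seg)))
        members.append(
            ProteinSequence(
                f"{p.name or 'pattern'}_aln_{i + 1}",
                "".join(parts),
                f"generator=alignment source={p.name}",
            )
        )
    return Alignment(tuple(members), sum(widths))


def random_pattern(
    rng: random.Random, max_elements: int = 10, alphabet: str = "ACDEG"
) -> PrositePattern:
    """Random small Prosite pattern for stress-testing the match engine."""
    k = rng.randint(1, max_elements)
    elements = []
    from .prosite import PatternElement  # local to avoid cycle at import time

    for _ in range(k):
        kind = rng.choice(
            [KIND_LITERAL, KIND_CLASS, KIND_NEGATED, KIND_WILDCARD, KIND_WILDCARD]
        )
        if kind == KIND_LITERAL:
            residues = (rng.choice(alphabet),)
        elif kind == KIND_CLASS:
            residues = tuple(rng.sample(alphabet, rng.randint(1, min(3, len(alphabet)))))
        elif kind == KIND_NEGATED:
            residues = tuple(rng.sample(alphabet, rng.randint(1, min(2, len(alphabet)))))
        else:
            residues = ()
        roll = rng.random()
        if roll < 0.5:
            rmin = rmax = 1
        elif roll < 0.75:
            rmin = rmax = rng.randint(0, 3)
        else:
            rmin = rng.randint(0, 2)
            rmax = rng.randint(rmin, rmin + 3)
        elements.append(PatternElement(kind, residues, rmin, rmax))
    return PrositePattern(
        tuple(elements),
        anchored_start=rng.random() < 0.1,
        anchored_end=rng.random() < 0.1,
        name="random",
    )


def random_sequence(
    rng: random.Random, max_len: int = 60, alphabet: str = "ACDEG", x_rate: float = 0.05
) -> str:
    """Random residue string over a small alphabet with occasional X."""
    n = rng.randint(1, max_len)
    return "".join(
        "X" if rng.random() < x_rate else rng.choice(alphabet) for _ in range(n)
    )


def write_manifest_tsv(seqs, dest, generator: str, seed: int) -> None:
    """TSV: sequence_id, generator, seed, source, violation."""
    own = False
    if not hasattr(dest, "write"):
        dest = open(dest, "w", encoding="utf-8")
        own = True
    try:
        dest.write("sequence_id\tgenerator\tseed\tsource\tviolation\n")
        for s in seqs:
            fields = dict(
                kv.split("=", 1) for kv in s.description.split() if "=" in kv
            )
            dest.write(
                f"{s.identifier}\t{generator}\t{seed}\t"
                f"{fields.get('source', '.')}\t{fields.get('violation', '.')}\n"
            )
    finally:
        if own:
            dest.close()
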