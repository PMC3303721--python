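import random
import re

import pytest

from nsltp import ProteinSequence, parse_pattern, render_pattern, scan
from nsltp.errors import PatternSyntaxError
from nsltp.prosite import (
    KIND_CLASS,
    KIND_LITERAL,
    KIND_NEGATED,
    KIND_WILDCARD,
    cysteine_gap_hulls,
    first_segmentation,
    matches,
    read_pattern_file,
)
from nsltp.simulate import random_pattern, random_sequence


def regex_oracle_spans(residues, pattern):
    """Independent oracle: mechanical per-element regex, evaluated with
    re.fullmatch over every candidate slice."""
    aa20 = "ACDEFGHIKLMNPQRSTVWY"
    parts = []
    for e in pattern.elements:
        if e.kind == KIND_WILDCARD:
            cls = "[A-Z]"
        elif e.kind == KIND_NEGATED:
            allowed = "".join(a for a in aa20 if a not in e.residues)
            cls = f"[{allowed}]" if allowed else "(?!a)a"
        else:
            cls = "[" + "".join(e.residues) + "]"
        if (e.repeat_min, e.repeat_max) == (1, 1):
            parts.append(cls)
        else:
            parts.append(cls + f"{{{e.repeat_min},{e.repeat_max}}}")
    rx = re.compile("".join(parts))
    n = len(residues)
    out = set()
    starts = (0,) if pattern.anchored_start else range(n + 1)
    for i in starts:
        for j in range(i + 1, n + 1):
            if pattern.anchored_end and j != n:
                continue
            if rx.fullmatch(residues[i:j]):
                out.add((i, j))
    return out


def test_parse_simple():
    p = parse_pattern("C-x(2)-V")
    kinds = [(e.kind, e.repeat_min, e.repeat_max) for e in p.elements]
    assert kinds == [(KIND_LITERAL, 1, 1), (KIND_WILDCARD, 2, 2), (KIND_LITERAL, 1, 1)]


def test_parse_ps00597_structure(builtins):
    p = builtins["PS00597"]
    assert len(p.elements) == 18
    assert not p.anchored_start and not p.anchored_end
    assert p.elements[0].residues == ("L", "I", "V", "M")


def test_builtin_type_i_transcription(builtins):
    p = builtins["typeI"]
    assert len(p.elements) == 28
    cys = [e for e in p.elements if e.kind == KIND_LITERAL and e.residues == ("C",)]
    assert len(cys) == 8


def test_builtin_type_ii_has_cxc_block(builtins):
    elems = builtins["typeII"].elements
    triples = [
        (a.residues, b.residues, c.residues)
        for a, b, c in zip(elems, elems[1:], elems[2:])
        if a.kind == KIND_LITERAL and c.kind == KIND_LITERAL and b.kind == KIND_CLASS
    ]
    assert (("C",), ("L", "F"), ("C",)) in triples


def test_builtins_round_trip(builtins):
    for p in builtins.values():
        text = render_pattern(p)
        assert render_pattern(parse_pattern(text, p.name)) == text


@pytest.mark.parametrize(
    "text,fragment",
    [
        ("A-x(3,2)", "inverted"),
        ("[AC", "unbalanced"),
        ("[]-C", "empty residue class"),
        ("A-J", "unexpected character"),
        ("[AB2]", "unknown residue"),
        ("A-x(z)", "invalid repeat"),
        ("", "unexpected end"),
    ],
)
def test_parse_errors_carry_offset(text, fragment):
    with pytest.raises(PatternSyntaxError, match=fragment) as exc:
        parse_pattern(text)
    assert "offset" in str(exc.value)


@pytest.mark.parametrize(
    "pattern,seq,expected",
    [
        ("A-x(2,3)-C", "AGGC", [(0, 4)]),
        ("A-x(2,3)-C", "AGGGC", [(0, 5)]),
        ("A-x(2,3)-C", "AGC", []),
        ("C", "C", [(0, 1)]),
        ("C", "ACA", [(1, 2)]),
        ("{C}", "ACD", [(0, 1), (2, 3)]),
    ],
)
def test_scan_examples(pattern, seq, expected):
    assert [(s.start, s.end) for s in scan(seq, parse_pattern(pattern))] == expected


def test_ps00597_conforming_peptide(builtins):
    spans = scan("LPAACALAVAFAISAAADCAAL", builtins["PS00597"])
    assert spans == [(0, 22)]


def test_anchored_patterns_touch_termini():
    assert [(s.start, s.end) for s in scan("ACA", parse_pattern("<A"))] == [(0, 1)]
    assert [(s.start, s.end) for s in scan("ACA", parse_pattern("A>"))] == [(2, 3)]
    assert scan("CA", parse_pattern("<A")) == []


def test_x_matches_only_wildcards():
    # unknown residue X satisfies the wildcard but no literal/class/negation
    assert matches("AXA", parse_pattern("A-x-A"))
    assert matches("X", parse_pattern("x"))
    assert not matches("X", parse_pattern("A"))
    assert not matches("X", parse_pattern("[AC]"))
    assert not matches("X", parse_pattern("{A}"))
    assert matches(ProteinSequence("q", "AXA"), parse_pattern("A-x-A"))


def test_scan_agrees_with_regex_oracle():
    rng = random.Random(123)
    for _ in range(400):
        p = random_pattern(rng)
        s = random_sequence(rng)
        mine = {(sp.start, sp.end) for sp in scan(s, p)}
        assert mine == regex_oracle_spans(s, p), (render_pattern(p), s)


def test_first_segmentation_covers_match(builtins):
    from nsltp import SimSpec, sample_from_pattern

    p = builtins["typeII"]
    for s in sample_from_pattern(p, SimSpec(seed=3, n=5)):
        segs = first_segmentation(s, p)
        assert segs is not None
        assert len(segs) == len(p.elements)
        assert segs[0][1] == 0
        # segments tile the match contiguously
        for (_, a1, b1), (_, a2, b2) in zip(segs, segs[1:]):
            assert b1 == a2


def test_pattern_file_named_and_anonymous(tmp_path):
    f = tmp_path / "pats.txt"
    f.write_text("mypat;C-x(2)-V\nA-C\n# comment\n")
    pats = read_pattern_file(str(f))
    assert set(pats) == {"mypat", "pat1"}
    assert len(pats["mypat"].elements) == 3


def test_cysteine_gap_hulls_type_i(builtins):
    hulls = cysteine_gap_hulls(builtins["typeI"])
    assert hulls["g1"] == (8, 10)
    assert hulls["g3"] == (19, 19)
    with pytest.raises(ValueError, match="cysteine literals"):
        cysteine_gap_hulls(parse_pattern("A-C"))
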