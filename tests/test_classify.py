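import dataclasses
import random

import pytest

from nsltp import (
    ProteinSequence,
    SimSpec,
    classify_sequence,
    classify_spacing,
    sample_type_sequences,
)
from nsltp.rules import TYPE_ORDER, TYPE_RULES, type_rules
from conftest import make_scaffold


def motif_with_gaps(gaps, n_offset=2, c_tail=5):
    from nsltp import find_cys_motifs

    return find_cys_motifs(make_scaffold(gaps, n_offset=n_offset, c_tail=c_tail))[0]


@pytest.mark.parametrize(
    "gaps,resolved,compatible",
    [
        ((7, 13, 9, 16, 5), "II", ("II",)),
        ((9, 14, 19, 21, 14), "I", ("I",)),
        ((10, 17, 9, 22, 7), "ambiguous", ("III", "V")),
        ((1, 1, 1, 1, 1), "unclassified", ()),
    ],
)
def test_spacing_examples(gaps, resolved, compatible):
    a = classify_spacing(motif_with_gaps(gaps))
    assert a.resolved == resolved
    assert a.compatible == compatible


def test_evidence_filled_for_every_slot_of_every_type():
    a = classify_spacing(motif_with_gaps((9, 14, 19, 21, 14)), mode="strict")
    assert set(a.evidence) == set(TYPE_ORDER)
    for ev in a.evidence.values():
        assert set(ev) == {"g1", "g2", "g3", "g4", "g5", "n_offset", "c_tail"}
    assert a.evidence["II"]["g1"] == (9, "miss")


def test_strict_mode_tests_terminals():
    # Type II gaps but a long C-tail: fine in core mode, miss in strict mode
    m = motif_with_gaps((7, 13, 9, 16, 5), n_offset=3, c_tail=30)
    assert classify_spacing(m, mode="core").resolved == "II"
    strict = classify_spacing(m, mode="strict")
    assert "II" not in strict.compatible
    m2 = motif_with_gaps((7, 13, 9, 16, 5), n_offset=3, c_tail=1)
    assert classify_spacing(m2, mode="strict").resolved == "II"


def test_prefer_breaks_ambiguity():
    m = motif_with_gaps((10, 17, 9, 22, 7))
    assert classify_spacing(m).resolved == "ambiguous"
    assert classify_spacing(m, prefer=["V", "III"]).resolved == "V"
    assert classify_spacing(m, prefer=["III"]).resolved == "III"


def test_types_i_and_ii_never_jointly_compatible():
    assert not (TYPE_RULES["I"].gaps[0] & TYPE_RULES["II"].gaps[0])
    rng = random.Random(11)
    for _ in range(2000):
        gaps = tuple(rng.randint(1, 30) for _ in range(5))
        a = classify_spacing(motif_with_gaps(gaps))
        assert not ({"I", "II"} <= set(a.compatible))


@pytest.mark.parametrize("t", TYPE_ORDER)
def test_generated_sequences_contain_generating_type(t):
    for s in sample_type_sequences(t, SimSpec(seed=5, n=200)):
        rep = classify_sequence(s)
        assert t in rep.assignment.compatible


def test_iii_g4_outlier_opt_out():
    gaps = (9, 12, 9, 2, 6)  # g4=2 only allowed via the literal "21-24,2" entry
    assert "III" in classify_spacing(motif_with_gaps(gaps)).compatible
    fixed = type_rules(iii_g4_drop_outlier=True)
    assert "III" not in classify_spacing(motif_with_gaps(gaps), rules=fixed).compatible


def test_classify_sequence_type_ii_with_patterns():
    # Pattern realizations always match their pattern; the subset whose
    # wildcard draws also land in the exact Table spacing sets resolves II,
    # and there the two evidence sources agree.
    from nsltp import builtin_patterns, sample_from_pattern

    seqs = sample_from_pattern(builtin_patterns()["typeII"], SimSpec(seed=6, n=30))
    resolved_ii = 0
    for s in seqs:
        rep = classify_sequence(s, use_patterns=True)
        assert rep.pattern_matches["typeII"] is True
        if rep.resolved == "II":
            resolved_ii += 1
            assert rep.agreement is True
    assert resolved_ii > 0


def test_type_spaced_type_i_sequences_resolve_i_with_patterns():
    for s in sample_type_sequences("I", SimSpec(seed=61, n=20)):
        rep = classify_sequence(s, use_patterns=True)
        assert "I" in rep.assignment.compatible
        assert rep.pattern_matches is not None


def test_classify_sequence_no_motif():
    rep = classify_sequence(ProteinSequence("p", "AAAA"))
    assert rep.resolved == "unclassified"
    assert rep.motif is None
    assert rep.deficient == ()


def test_scrambled_conserved_positions_spacing_vs_pattern_disagree():
    from nsltp import builtin_patterns
    from nsltp.simulate import make_decoys, sample_from_pattern

    typeI = builtin_patterns()["typeI"]
    seqs = sample_from_pattern(typeI, SimSpec(seed=7, n=10))
    decoys = make_decoys(seqs, "shuffle_conserved", seed=8, pattern=typeI)
    for d in decoys:
        rep = classify_sequence(d, use_patterns=True)
        assert "I" in rep.assignment.compatible  # spacing untouched
        assert rep.pattern_matches["typeI"] is False
        if rep.resolved == "I":
            assert rep.agreement is False


def test_pattern_matches_imply_gap_vector_in_rule_hull(builtins):
    from nsltp import SimSpec, classify_sequence, sample_from_pattern
    from nsltp.rules import hull

    for name, t in (("typeI", "I"), ("typeII", "II")):
        for s in sample_from_pattern(builtins[name], SimSpec(seed=9, n=30)):
            rep = classify_sequence(s)
            for g, allowed in zip(rep.motif.gaps, TYPE_RULES[t].gaps):
                lo, hi = hull(allowed)
                assert lo <= g <= hi
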