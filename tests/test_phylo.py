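import itertools
import random

import numpy as np
import pytest

from nsltp import (
    DistanceMatrix,
    ProteinSequence,
    SimSpec,
    candidate_filter,
    distance_matrix,
    leaf_path_lengths,
    neighbor_joining,
    pairwise_identity,
    root_to_leaf_depths,
    sample_from_pattern,
    upgma,
    write_newick,
)
from nsltp.errors import NsltpError


def dm_from_pairs(labels, pairs):
    n = len(labels)
    m = np.zeros((n, n))
    for (a, b), d in pairs.items():
        i, j = labels.index(a), labels.index(b)
        m[i, j] = m[j, i] = d
    return DistanceMatrix(tuple(labels), m)


def brute_force_identity(a, b, blosum, gap_open=10.0, gap_ext=0.5):
    """Enumerate every global alignment of two tiny sequences."""
    best = (-1e9, 0.0)

    def rec(i, j, score, matchc, cols, prev_gap):
        nonlocal best
        if i == len(a) and j == len(b):
            if score > best[0] + 1e-12:
                best = (score, matchc / cols)
            elif abs(score - best[0]) <= 1e-12:
                best = (best[0], max(best[1], matchc / cols))
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + blosum[a[i]][b[j]],
                matchc + (a[i] == b[j]), cols + 1, 0)
        if i < len(a):
            pen = gap_ext if prev_gap == 1 else gap_open
            rec(i + 1, j, score - pen, matchc, cols + 1, 1)
        if j < len(b):
            pen = gap_ext if prev_gap == 2 else gap_open
            rec(i, j + 1, score - pen, matchc, cols + 1, 2)

    rec(0, 0, 0.0, 0, 0, 0)
    return best


def test_identity_identical_sequences():
    assert pairwise_identity("ACDE", "ACDE") == 1.0


def test_identity_single_substitution_matches_brute_force():
    from Bio.Align import substitution_matrices

    bl = substitution_matrices.load("BLOSUM62")
    table = {x: {y: bl[x, y] for y in "ACDEF"} for x in "ACDEF"}
    score, ident = brute_force_identity("ACDE", "ACDF", table)
    assert ident == 0.75
    assert pairwise_identity("ACDE", "ACDF") == 0.75


@pytest.mark.parametrize("seed", range(3))
def test_identity_symmetric(seed):
    rng = random.Random(seed)
    for _ in range(30):
        a = "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(rng.randint(3, 40)))
        b = "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(rng.randint(3, 40)))
        assert pairwise_identity(a, b) == pytest.approx(pairwise_identity(b, a), abs=1e-12)


def test_identity_empty_errors():
    with pytest.raises(NsltpError):
        pairwise_identity("", "ACD")


def test_distance_matrix_properties(builtins):
    same = [ProteinSequence(f"s{i}", "MKWVAC") for i in range(3)]
    dm = distance_matrix(same)
    assert np.allclose(dm.values, 0.0)
    ti = sample_from_pattern(builtins["typeI"], SimSpec(seed=1, n=5))
    tii = sample_from_pattern(builtins["typeII"], SimSpec(seed=2, n=5))
    dm = distance_matrix(ti + tii)
    assert (dm.values >= 0.0).all() and (dm.values <= 1.0).all()
    v = dm.values
    within = [v[i, j] for i in range(5) for j in range(i + 1, 5)]
    within += [v[i, j] for i in range(5, 10) for j in range(i + 1, 10)]
    between = [v[i, j] for i in range(5) for j in range(5, 10)]
    assert np.mean(within) < np.mean(between)


def test_distance_matrix_duplicate_labels_error():
    seqs = [ProteinSequence("a", "MK"), ProteinSequence("a", "MW"),
            ProteinSequence("b", "MV")]
    with pytest.raises(NsltpError, match="duplicate"):
        distance_matrix(seqs)


def test_upgma_two_leaves():
    t = upgma(dm_from_pairs(["a", "b"], {("a", "b"): 2.0}))
    assert write_newick(t) == "(a:1.000000,b:1.000000):0.000000;"


def test_upgma_recovers_ultrametric_tree():
    # heights: ((a,b) at 1.0, (c,d) at 2.0, root at 3.0)
    pairs = {("a", "b"): 2.0, ("c", "d"): 4.0,
             ("a", "c"): 6.0, ("a", "d"): 6.0, ("b", "c"): 6.0, ("b", "d"): 6.0}
    t = upgma(dm_from_pairs(["a", "b", "c", "d"], pairs))
    pl = leaf_path_lengths(t)
    for k, v in pairs.items():
        assert pl[k] == pytest.approx(v, abs=1e-9)
    depths = root_to_leaf_depths(t)
    assert max(depths.values()) - min(depths.values()) < 1e-9


def test_upgma_ultrametric_and_matches_scipy_on_random_matrix():
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import squareform

    rng = np.random.default_rng(5)
    n = 7
    m = rng.random((n, n))
    m = (m + m.T) / 2.0
    np.fill_diagonal(m, 0.0)
    labels = [f"l{i}" for i in range(n)]
    t = upgma(DistanceMatrix(tuple(labels), m))
    depths = root_to_leaf_depths(t)
    assert max(depths.values()) - min(depths.values()) < 1e-9
    ours = sorted(2.0 * h for h in _merge_heights(t))
    scipys = sorted(linkage(squareform(m), method="average")[:, 2])
    assert np.allclose(ours, scipys, atol=1e-9)


def _merge_heights(tree):
    """Heights of the internal nodes of an ultrametric tree."""
    out = []

    def walk(node):
        if node.is_leaf:
            return 0.0
        hs = [walk(c) + c.length for c in node.children]
        assert max(hs) - min(hs) < 1e-9
        out.append(hs[0])
        return hs[0]

    walk(tree.root)
    return out


def test_nj_three_taxa_closed_form():
    pairs = {("a", "b"): 3.0, ("a", "c"): 4.0, ("b", "c"): 5.0}
    t = neighbor_joining(dm_from_pairs(["a", "b", "c"], pairs))
    lengths = {c.label: c.length for c in t.root.children}
    assert lengths["a"] == pytest.approx(1.0, abs=1e-12)
    assert lengths["b"] == pytest.approx(2.0, abs=1e-12)
    assert lengths["c"] == pytest.approx(3.0, abs=1e-12)


@pytest.mark.parametrize("n_taxa", [4, 5])
def test_nj_exact_on_additive_matrices(n_taxa):
    rng = random.Random(n_taxa)
    labels = [f"t{i}" for i in range(n_taxa)]
    # caterpillar tree: leaves hang off a backbone line, which gives an
    # additive metric d(a,b) = |x_a - x_b| + stem_a + stem_b
    xs = {lab: i * 1.0 + rng.uniform(0.0, 0.4) for i, lab in enumerate(labels)}
    stem = {lab: rng.uniform(0.2, 1.5) for lab in labels}
    pairs = {
        (a, b): abs(xs[a] - xs[b]) + stem[a] + stem[b]
        for a, b in itertools.combinations(labels, 2)
    }
    t = neighbor_joining(dm_from_pairs(labels, pairs))
    got = leaf_path_lengths(t)
    for k, v in pairs.items():
        assert got[k] == pytest.approx(v, abs=1e-9)


def test_tree_builders_input_order_invariant():
    rng = np.random.default_rng(8)
    n = 6
    m = rng.random((n, n))
    m = (m + m.T) / 2.0
    np.fill_diagonal(m, 0.0)
    labels = [f"x{i}" for i in range(n)]
    perm = list(range(n))
    random.Random(0).shuffle(perm)
    m2 = m[np.ix_(perm, perm)]
    labels2 = [labels[i] for i in perm]
    for builder in (upgma, neighbor_joining):
        t1 = builder(DistanceMatrix(tuple(labels), m))
        t2 = builder(DistanceMatrix(tuple(labels2), m2))
        p1, p2 = leaf_path_lengths(t1), leaf_path_lengths(t2)
        assert set(p1) == set(p2)
        for k in p1:
            assert p1[k] == pytest.approx(p2[k], abs=1e-9)


def test_newick_round_trip_with_independent_reader():
    import dendropy

    pairs = {("a b", "c"): 2.0, ("a b", "d"): 3.0, ("c", "d"): 3.0}
    t = neighbor_joining(dm_from_pairs(["a b", "c", "d"], pairs))
    text = write_newick(t)
    assert "'a b'" in text  # labels with spaces are quoted
    parsed = dendropy.Tree.get(data=text, schema="newick")
    taxa = {lf.taxon.label for lf in parsed.leaf_node_iter()}
    assert taxa == {"a b", "c", "d"}
    pdm = parsed.phylogenetic_distance_matrix()
    tax = {tx.label: tx for tx in parsed.taxon_namespace}
    for (la, lb), d in leaf_path_lengths(t).items():
        assert pdm.distance(tax[la], tax[lb]) == pytest.approx(d, abs=1e-6)


def test_distance_matrix_tsv_round_trip(tmp_path):
    labels = ("a", "b", "c")
    m = np.array([[0.0, 0.25, 0.5], [0.25, 0.0, 0.75], [0.5, 0.75, 0.0]])
    dm = DistanceMatrix(labels, m)
    f = tmp_path / "d.tsv"
    dm.to_tsv(str(f))
    back = DistanceMatrix.from_tsv(str(f))
    assert back.labels == labels
    assert np.allclose(back.values, m, atol=1e-6)


def test_candidate_filter_threshold():
    refs = [ProteinSequence("ref", "MKWVTFISLLFLFSSAYSRGVFRR")]
    close = ProteinSequence("close", "MKWVTFISLLFLFSSAYSRGVFRA")
    far = ProteinSequence("far", "GGGGGGGGGG")
    kept = candidate_filter([close, far], refs, min_identity=0.15)
    assert [s.identifier for s in kept] == ["close"]
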