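"""Pairwise identity, distance matrices, and UPGMA / neighbor-joining trees.

Identity comes from a global (end-to-end) Needleman-Wunsch/Gotoh alignment
with BLOSUM62 scores and affine gaps (open 10, extend 0.5): identical
aligned pairs divided by aligned columns.  Tie-breaks during traceback
prefer the diagonal move, then the vertical (gap in the second sequence),
then the horizontal, so results are deterministic.  The dynamic program is
compiled with numba since distance matrices need thousands of alignments.

Both tree builders use lexicographic label tie-breaks, so identical inputs
give identical trees regardless of row order.  UPGMA produces a rooted
ultrametric tree (heights are half the merge distance, linkage averaged
with cluster-size weights); neighbor joining produces an unrooted tree via
the standard Q criterion, with negative branch lengths clamped to zero and
logged.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
from numba import njit

from .core_io import GAP, ProteinSequence
from .errors import NsltpError

log = logging.getLogger(__name__)

GAP_OPEN = 10.0
GAP_EXTEND = 0.5

_SCORE_MATRIX = None
_ALPHA_INDEX = None


def _blosum62():
    global _SCORE_MATRIX, _ALPHA_INDEX
    if _SCORE_MATRIX is None:
        from Bio.Align import substitution_matrices

        m = substitution_matrices.load("BLOSUM62")
        _SCORE_MATRIX = np.array(m, dtype=np.float64)
        _ALPHA_INDEX = {ch: i for i, ch in enumerate(m.alphabet)}
    return _SCORE_MATRIX, _ALPHA_INDEX


@njit(cache=False)
def _gotoh(a, b, S, gap_open, gap_ext):  # pragma: no cover - exercised via wrapper
    n = a.shape[0]
    m = b.shape[0]
    NEG = -1e30
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b (vertical / "up")
    Y = np.full((n + 1, m + 1), NEG)  # gap in a (horizontal / "left")
    pM = np.zeros((n + 1, m + 1), dtype=np.int8)
    pX = np.zeros((n + 1, m + 1), dtype=np.int8)
    pY = np.zeros((n + 1, m + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -(gap_open + (i - 1) * gap_ext)
        pX[i, 0] = 0 if i == 1 else 1
    for j in range(1, m + 1):
        Y[0, j] = -(gap_open + (j - 1) * gap_ext)
        pY[0, j] = 0 if j == 1 else 2
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = S[a[i - 1], b[j - 1]]
            best = M[i - 1, j - 1]
            p = 0
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                p = 1
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                p = 2
            M[i, j] = best + s
            pM[i, j] = p

            best = M[i - 1, j] - gap_open
            p = 0
            if X[i - 1, j] - gap_ext > best:
                best = X[i - 1, j] - gap_ext
                p = 1
            if Y[i - 1, j] - gap_open > best:
                best = Y[i - 1, j] - gap_open
                p = 2
            X[i, j] = best
            pX[i, j] = p

            best = M[i, j - 1] - gap_open
            p = 0
            if X[i, j - 1] - gap_open > best:
                best = X[i, j - 1] - gap_open
                p = 1
            if Y[i, j - 1] - gap_ext > best:
                best = Y[i, j - 1] - gap_ext
                p = 2
            Y[i, j] = best
            pY[i, j] = p

    state = 0
    best = M[n, m]
    if X[n, m] > best:
        best = X[n, m]
        state = 1
    if Y[n, m] > best:
        best = Y[n, m]
        state = 2
    i, j = n, m
    matched = 0
    columns = 0
    while i > 0 or j > 0:
        columns += 1
        if state == 0:
            nxt = pM[i, j]
            if a[i - 1] == b[j - 1]:
                matched += 1
            i -= 1
            j -= 1
        elif state == 1:
            nxt = pX[i, j]
            i -= 1
        else:
            nxt = pY[i, j]
            j -= 1
        state = nxt
    return matched, columns


def _encode(res: str) -> np.ndarray:
    _, idx = _blosum62()
    x = idx["X"]
    return np.array([idx.get(c, x) for c in res], dtype=np.int64)


def pairwise_identity(a, b) -> float:
    """Fraction of identical aligned pairs over aligned columns (gaps count
    as columns; there are no gap-gap columns in a pairwise alignment)."""
    ra = (a.residues if isinstance(a, ProteinSequence) else str(a)).replace(GAP, "")
    rb = (b.residues if isinstance(b, ProteinSequence) else str(b)).replace(GAP, "")
    if not ra or not rb:
        raise NsltpError("cannot align an empty sequence")
    S, _ = _blosum62()
    matched, columns = _gotoh(_encode(ra), _encode(rb), S, GAP_OPEN, GAP_EXTEND)
    return matched / columns


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple
    values: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self):
        v = self.values
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if len(set(self.labels)) != len(self.labels):
            raise NsltpError("duplicate labels in distance matrix")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("matrix not symmetric")
        if np.abs(np.diag(v)).max(initial=0.0) != 0.0:
            raise ValueError("nonzero diagonal")

    def get(self, la: str, lb: str) -> float:
        i, j = self.labels.index(la), self.labels.index(lb)
        return float(self.values[i, j])

    def to_tsv(self, dest) -> None:
        own = False
        if not hasattr(dest, "write"):
            dest = open(dest, "w", encoding="utf-8")
            own = True
        try:
            dest.write("\t" + "\t".join(self.labels) + "\n")
            for i, lab in enumerate(self.labels):
                row = "\t".join(f"{self.values[i, j]:.6f}" for j in range(len(self.labels)))
                dest.write(f"{lab}\t{row}\n")
        finally:
            if own:
                dest.close()

    @classmethod
    def from_tsv(cls, source) -> "DistanceMatrix":
        if hasattr(source, "read"):
            lines = source.read().splitlines()
        else:
            with open(source, "r", encoding="utf-8") as fh:
                lines = fh.read().splitlines()
        lines = [ln for ln in lines if ln.strip()]
        labels = tuple(lines[0].lstrip("\t").split("\t"))
        vals = []
        for ln in lines[1:]:
            cells = ln.split("\t")
            vals.append([float(c) for c in cells[1:]])
        return cls(labels, np.array(vals, dtype=float))


def distance_matrix(seqs: list[ProteinSequence]) -> DistanceMatrix:
    """d = 1 - identity for every pair of input sequences."""
    if len(seqs) < 2:
        raise NsltpError("need at least 2 sequences for a distance matrix")
    labels = tuple(s.identifier for s in seqs)
    if len(set(labels)) != len(labels):
        raise NsltpError("duplicate sequence identifiers")
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = 1.0 - pairwise_identity(seqs[i], seqs[j])
    return DistanceMatrix(labels, d)


@dataclass
class Node:
    label: Optional[str] = None
    length: float = 0.0  # branch to parent
    children: list = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class Tree:
    root: Node
    rooted: bool

    def leaves(self) -> list[Node]:
        out = []

        def walk(n: Node):
            if n.is_leaf:
                out.append(n)
            for c in n.children:
                walk(c)

        walk(self.root)
        return out


def _min_pair(active, dist, key_of):
    """Smallest-distance active pair; ties broken by sorted label pair."""
    best = None
    best_pair = None
    best_key = None
    for a, b in itertools.combinations(sorted(active), 2):
        d = dist[(a, b) if a < b else (b, a)]
        k = tuple(sorted((key_of[a], key_of[b])))
        if best is None or d < best or (d == best and k < best_key):
            best, best_pair, best_key = d, (a, b), k
    return best_pair, best


def upgma(dm: DistanceMatrix) -> Tree:
    """Average-linkage agglomeration; heights are half the merge distance."""
    n = len(dm.labels)
    nodes = {i: Node(label=dm.labels[i]) for i in range(n)}
    size = {i: 1 for i in range(n)}
    height = {i: 0.0 for i in range(n)}
    key_of = {i: dm.labels[i] for i in range(n)}
    dist = {
        (i, j): float(dm.values[i, j])
        for i in range(n)
        for j in range(i + 1, n)
    }
    active = set(range(n))
    nxt = n
    while len(active) > 1:
        (a, b), d = _min_pair(active, dist, key_of)
        h = d / 2.0
        na, nb = nodes[a], nodes[b]
        na.length = h - height[a]
        nb.length = h - height[b]
        children = sorted((na, nb), key=lambda c: key_of[a] if c is na else key_of[b])
        parent = Node(children=children)
        nodes[nxt] = parent
        size[nxt] = size[a] + size[b]
        height[nxt] = h
        key_of[nxt] = min(key_of[a], key_of[b])
        for k in active:
            if k in (a, b):
                continue
            dak = dist[(a, k) if a < k else (k, a)]
            dbk = dist[(b, k) if b < k else (k, b)]
            dist[(k, nxt)] = (size[a] * dak + size[b] * dbk) / (size[a] + size[b])
        active -= {a, b}
        active.add(nxt)
        nxt += 1
    root = nodes[nxt - 1] if n > 1 else nodes[0]
    return Tree(root=root, rooted=True)


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Standard Q-criterion neighbor joining; unrooted (trifurcating root)."""
    n = len(dm.labels)
    if n < 3:
        raise NsltpError("neighbor joining needs at least 3 labels")
    nodes = {i: Node(label=dm.labels[i]) for i in range(n)}
    key_of = {i: dm.labels[i] for i in range(n)}
    dist = {
        (i, j): float(dm.values[i, j])
        for i in range(n)
        for j in range(i + 1, n)
    }
    active = set(range(n))
    nxt = n

    def d_of(a, b):
        return dist[(a, b) if a < b else (b, a)]

    def clamp(x, what):
        if x < 0.0:
            log.info("negative branch length %.6g clamped to 0 (%s)", x, what)
            return 0.0
        return x

    while len(active) > 3:
        r = len(active)
        R = {i: sum(d_of(i, k) for k in active if k != i) for i in active}
        best = None
        best_pair = None
        best_key = None
        for a, b in itertools.combinations(sorted(active), 2):
            q = (r - 2) * d_of(a, b) - R[a] - R[b]
            k = tuple(sorted((key_of[a], key_of[b])))
            if best is None or q < best or (q == best and k < best_key):
                best, best_pair, best_key = q, (a, b), k
        a, b = best_pair
        if key_of[b] < key_of[a]:  # canonical order so la/lb follow labels
            a, b = b, a
        d = d_of(a, b)
        la = 0.5 * d + (R[a] - R[b]) / (2.0 * (r - 2))
        la = clamp(la, f"{key_of[a]} join")
        lb = clamp(d - la, f"{key_of[b]} join")
        nodes[a].length = la
        nodes[b].length = lb
        children = sorted(
            ((key_of[a], nodes[a]), (key_of[b], nodes[b])), key=lambda t: t[0]
        )
        parent = Node(children=[c for _, c in children])
        nodes[nxt] = parent
        key_of[nxt] = min(key_of[a], key_of[b])
        for k in active:
            if k in (a, b):
                continue
            dist[(k, nxt)] = 0.5 * (d_of(a, k) + d_of(b, k) - d)
        active -= {a, b}
        active.add(nxt)
        nxt += 1

    a, b, c = sorted(active, key=lambda i: key_of[i])
    dab, dac, dbc = d_of(a, b), d_of(a, c), d_of(b, c)
    nodes[a].length = clamp(0.5 * (dab + dac - dbc), f"{key_of[a]} terminal")
    nodes[b].length = clamp(0.5 * (dab + dbc - dac), f"{key_of[b]} terminal")
    nodes[c].length = clamp(0.5 * (dac + dbc - dab), f"{key_of[c]} terminal")
    children = sorted(
        ((key_of[i], nodes[i]) for i in (a, b, c)), key=lambda t: t[0]
    )
    root = Node(children=[nd for _, nd in children])
    return Tree(root=root, rooted=False)


_SAFE_LABEL = frozenset(
    "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789_.|+-"
)


def _quote(label: str) -> str:
    if label and all(c in _SAFE_LABEL for c in label):
        return label
    return "'" + label.replace("'", "''") + "'"


def write_newick(tree: Tree) -> str:
    """Newick text with 6-decimal branch lengths and a terminating ';'."""

    def render(node: Node) -> str:
        if node.is_leaf:
            return _quote(node.label or "")
        inner = ",".join(
            f"{render(c)}:{c.length:.6f}" for c in node.children
        )
        return f"({inner})"

    return f"{render(tree.root)}:{tree.root.length:.6f};"


def leaf_path_lengths(tree: Tree) -> dict:
    """Pairwise leaf-to-leaf path lengths, keyed by sorted label pairs."""
    out: dict[tuple, float] = {}

    def walk(node: Node) -> list:
        if node.is_leaf:
            return [(node.label, 0.0)]
        below: list = []
        groups = []
        for c in node.children:
            sub = [(lab, d + c.length) for lab, d in walk(c)]
            groups.append(sub)
            below.extend(sub)
        for ga, gb in itertools.combinations(groups, 2):
            for la, da in ga:
                for lb, db in gb:
                    out[tuple(sorted((la, lb)))] = da + db
        return below

    walk(tree.root)
    return out


def root_to_leaf_depths(tree: Tree) -> dict:
    out: dict[str, float] = {}

    def walk(node: Node, depth: float):
        if node.is_leaf:
            out[node.label] = depth
        for c in node.children:
            walk(c, depth + c.length)

    walk(tree.root, 0.0)
    return out


def candidate_filter(
    seqs: Iterable[ProteinSequence],
    references: list[ProteinSequence],
    min_identity: float = 0.15,
) -> list[ProteinSequence]:
    """Keep sequences whose best identity to any reference exceeds the
    threshold (strictly greater).  Note this uses the global-alignment
    identity of this module, which is not numerically interchangeable with
    local-alignment (e.g. BLAST-derived) identities."""
    if not references:
        raise NsltpError("candidate_filter needs at least one reference")
    return [
        s
        for s in seqs
        if max(pairwise_identity(s, r) for r in references) > min_identity
    ]
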