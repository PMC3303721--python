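# Methods

This note documents the models, conventions and numerical choices behind
the toolkit, in the order the pipeline uses them.

## The 8-Cys scaffold and its detection

Plant nsLTPs carry eight conserved cysteines arranged as
`C-Xn-C-Xn-CC-Xn-CXC-Xn-C-Xn-C`.  The motif finder enumerates *every*
increasing 8-tuple of cysteine indices satisfying the structural
constraints — Cys3/Cys4 strictly adjacent, Cys5 and Cys6 exactly two
apart (the CXC block), and at least one intervening residue in each of the
five remaining gaps (g1..g5).  Requiring g ≥ 1 between single cysteines
prevents ambiguous re-segmentation of a `CC` run as part of a CXC block.
Candidates are sorted by (Cys1 position, total span) and no placement is
discarded here: choosing among candidates is classification policy, not
detection mechanism.  Coordinates are 0-based internally and 1-based in
every report, following protein-residue convention.  A guard aborts with a
diagnostic when a cysteine-rich input would enumerate more than
`max_candidates` (default 10,000) placements.

Sequences with six or seven cysteines are matched against four deficient
block skeletons (categories A–D).  Categories C and D share the same
skeleton (`C, CC, CXC, C`) and differ only in their gap sets; since the
sequence alone cannot reveal *which* cysteines are missing, a placement is
reported under every category whose gap sets it satisfies.  As transcribed,
the C and D rows have disjoint first-gap sets ({13} versus {1–11}), so with
the shipped tables no single placement satisfies both; the multi-category
reporting path is still exercised in tests with an injected overlapping
table.

## Spacing tables and the five-type classification

The per-type constraints are unions of exact values and inclusive ranges
(`"7,13-15"` = {7, 13, 14, 15}), covering the N-terminal offset before
Cys1, g1..g5, and the C-terminal tail after Cys8.  The default
classification mode (`core`) tests only g1..g5: the terminal lengths depend
on where the signal peptide was cleaved, which is upstream of this toolkit
(mature sequences are the expected input), so anchoring decisions to them
is fragile.  `strict` mode adds the two terminal constraints for users whose
inputs are reliably mature.

Type I and Type II can never be jointly compatible (g1 sets {8–10} and {7}
are disjoint).  Types III and V overlap substantially; an overlapping gap
vector is reported as `ambiguous` with the full compatible set, and a
user-supplied priority order (`prefer`) may impose a call.  The Type III g4
entry is transcribed literally as {2, 21–24}; the isolated 2 reads like a
typographic slip for the 21–24 range, so `rules.type_rules(iii_g4_drop_outlier=True)`
provides an opt-out without silently editing the shipped table.

Evidence is retained for every slot of every tested type (observed count
and matched set, or `miss`), so a report can always explain *why* a type
was excluded.

## Prosite engine

Patterns are dash-separated elements — literals, classes `[..]`, negated
classes `{..}`, wildcards `x` — each with an optional repeat `(n)` or
`(n,m)`, plus `<` / `>` terminal anchors.  Matching is exhaustive
enumeration of repeat-length assignments, collecting **all** distinct
(start, end) spans; greedy-versus-lazy semantics from regex practice are
therefore irrelevant by construction.  The unknown residue `X` satisfies
only wildcards — never a literal, class, or negated class — a conservative
choice that avoids false signature hits on low-quality sequence.

A mechanical translation of any pattern into a regular-expression body is
provided solely as an independent cross-check: tests and the acceptance
script compare the engine's span set with `re.fullmatch` over every
candidate slice on thousands of random pattern/sequence pairs.

The built-ins transcribe the published Type I and Type II nsLTP signatures
and the PLANT_LTP entry PS00597.  In the printed Type I pattern the `×`
glyph is read as the single-position wildcard and subscripted ranges as
`x(n,m)`.  One analytic property links the two classification routes: the
inter-cysteine gap ranges implied by each built-in (summing element repeat
ranges between consecutive `C` literals) lie inside the interval hulls of
the corresponding spacing-table rows.  The containment is hull-level, not
set-level: e.g. the Type II pattern admits g4 ∈ 21..24 while the exact
table set is {16, 21, 24}, so a pattern-conforming sequence occasionally
falls between table values.  This discrepancy is surfaced, not reconciled.

## Pattern induction

Per column of an alignment, occurrence counts over non-gap residues drive a
three-way decision:

* top residue frequency ≥ `literal_threshold` (default 0.90) → literal;
* else, smallest frequency-descending residue set reaching
  `class_cum_threshold` (default 0.90) with ≤ `class_max_size` (default 4)
  members → class, residues in descending-frequency order (ties
  alphabetical), mirroring printed classes like `[V,L,I]`;
* else — or when occupancy < `min_occupancy` (default 0.50) — wildcard.

Columns that are 100 % cysteine among non-gap residues are pinned as `C`
literals regardless of occupancy (`anchor_cys`), since the scaffold is the
family's one invariant.  Maximal wildcard runs collapse to `x(m,M)` with
bounds taken from the observed per-member non-gap counts, which turns
variable loop regions into the gap ranges seen in published signatures.

The numeric thresholds are deliberate choices, not measurements: they are
set so that positions conserved at the levels reported for this family
(high-80s to 90s percent) emerge as literals or small classes, and all are
configurable.  On alignments produced by the generator at conservation 1.0,
every ungapped training sequence matches the induced pattern by
construction (wildcard bounds are observed bounds and every observed class
member is included).  On arbitrary noisy alignments this guarantee does not
hold — a literal column at 95 % conservation excludes the 5 % minority —
which is the expected behaviour of a consensus signature.

## Physicochemical profiling

Molecular weight sums residue masses plus one water; average isotopic
masses are the default (whole-protein, dalton-scale reporting), with a
monoisotopic table available.  Unknown residues have no mass and are a
hard error naming their positions.

Net charge is the Henderson–Hasselbalch sum over the N-terminus, H, K, R
(positive) and the C-terminus, D, E, C, Y (negative), with a
Bjellqvist-style pKa set (N-term 7.5, C-term 3.55, D 4.05, E 4.45, C 9.0,
Y 10.0, H 5.98, K 10.0, R 12.0) chosen to match the behaviour of the
common web calculators; the table is injectable via a key=value config and
serialized with results.  Each term is strictly decreasing in pH, so the
pI is found by bisection on [0, 14] to |charge| < 1e-4 (≤ 200 iterations);
the two termini guarantee a sign change exists.

The CXC X-residue polarity partition is a declared convention anchored at
the family's observed extremes (asparagine hydrophilic; leucine and
phenylalanine hydrophobic): hydrophilic {S,T,N,Q,D,E,K,R,H}, hydrophobic
{A,V,L,I,M,F,W,Y}, and `other` for {G,P,C,X} to avoid over-claiming for
glycine, proline, cysteine and unknowns.

## Identity, distances and trees

Pairwise identity uses a global Needleman–Wunsch/Gotoh alignment with
BLOSUM62 scores and affine gaps (open 10, extend 0.5; a gap of length L
costs open + (L−1)·extend).  Identity is identical aligned pairs divided by
aligned columns (gap columns count; gap–gap columns cannot occur pairwise).
Traceback tie-breaks prefer diagonal, then vertical, then horizontal moves,
making results deterministic.  The DP kernel is numba-compiled because a
distance matrix over n sequences needs n(n−1)/2 alignments.  Note this
global identity is not numerically interchangeable with local-alignment
(e.g. BLAST) identities; the >15 % candidate filter is exposed as a utility
with that caveat.

Distances are d = 1 − identity.  UPGMA merges the closest pair (ties by
lexicographically smallest label pair), placing the parent at half the
merge distance with size-weighted average linkage — the output is exactly
ultrametric.  Neighbor joining follows the standard Q criterion with the
same lexicographic tie-break; the asymmetric branch-length formula is
applied to the label-ordered pair so results are independent of input row
order, and negative branch lengths (possible on non-additive inputs) are
clamped to zero with a log note.  On additive matrices NJ reconstructs
path lengths exactly (≤ 1e-9 in tests).  Newick output carries 6-decimal
branch lengths and quotes labels containing unsafe characters.

## Synthetic data

The generators define the conditions under which the toolkit is verified:

* `sample_from_pattern` realizes a pattern (literals copied, classes and
  wildcard lengths uniform) with spacers from a background alphabet that
  excludes cysteine by default, so the scaffold of a generated sequence is
  unambiguous; include `C` in the background to stress multi-candidate
  handling.
* `sample_type_sequences` draws N-offset, g1..g5 and C-tail uniformly from
  the type's table sets and couples the CXC X residue to the type
  (hydrophilic for Type I, hydrophobic for II–V), matching the family's
  described trend.
* `make_decoys` introduces exactly one violation per output — a scaffold
  cysteine → alanine, a single-residue gap shift out of the source type's
  sets, or a conserved-position corruption outside the pattern element's
  residue set (verified against the matcher so no alternate segmentation
  still matches) — and records it in the description line.
* `synthetic_alignment` aligns realizations column-for-column (variable
  wildcard runs gap-padded) and perturbs conserved columns with probability
  1 − conservation.

All randomness flows through seeded integer-based `random.Random`, so
output is byte-identical across platforms.  The generators emulate the
family's scaffold, spacing and conserved positions; they do **not** emulate
realistic amino-acid composition, signal peptides, indel processes or
phylogenetic correlation, so passing tests demonstrate correctness of the
algorithms under the stated model, not recall on natural sequence
databases.

## Problem sizes used in verification

The acceptance script exercises: 1,000 random pattern/sequence pairs for
the engine cross-check; 500 realizations per built-in pattern plus 100
decoys per mode; 1,000 spacing draws per type; a 50-sequence induction
round trip; 100 random sequences for pI/charge properties; 4- and 5-taxon
additive matrices and a 7-taxon random matrix for the tree checks; and a
60-sequence end-to-end pipeline.  These sizes make every stochastic check
overwhelming at the shipped seeds while keeping the whole run within a few
seconds.

## Known limitations

* Deficient-category calls test inter-block gaps only; terminal lengths of
  the deficient rows are transcribed but not enforced.
* Whether published per-type mass/pI ranges were computed on mature or
  precursor sequences is unknown; this toolkit profiles exactly the
  residues it is given.
* HMM-based identification and disulfide connectivity assignment are out
  of scope, as are database retrieval and signal-peptide prediction.
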