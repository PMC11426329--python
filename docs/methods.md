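# Methods

## Data model

A *motif* is one loop instance: ordered strand segments (residue-label
ranges kept as metadata), a sequence over {A,C,G,U}, and a list of base
interactions between 1-based positions that run 5′→3′ contiguously across
segments (no index gap between segments).  Base pairs carry a
Leontis–Westhof class — glycosidic orientation (cis/trans) plus the
interacting edge of each partner (Watson-Crick, Hoogsteen, sugar), 18
classes in all — and stackings carry one of four categories (upward,
downward, inward, outward; upward/downward exchange under strand-order
reversal).  Break points mark the last position of each segment, so
hairpins have one, internal loops two, multi-loops three or more.

A *profile* of MC instances stores, per column, a count map over
nucleotides plus the explicit gap symbol `-` (counts always sum to MC; the
explicit gap key is what makes that conservation checkable), and per
position pair a count map of base pairs keyed by (LW class, nucleotide
pair) — frequencies are counted separately per nucleotide pair — and one
of stackings.  A single motif converts to a profile with MC = 1 and every
count 1.

## Alignment scoring

Matching a cell of X against a cell of Y scores
(1/m) Σ_a (1/n) Σ_b Count(e_b^Y)·M(e_b^Y, e_a^X) over the m and n distinct
entries of the two cells.  As printed, this weights only the Y-side counts
and scales with MC^Y; by default Count is therefore divided by MC^Y
(relative frequency) so that profiles of different sizes compare on one
scale, and `AlignConfig(normalize_counts=False)` restores the literal
raw-count form.  Both behaviours are exercised by the tests.

The packaged matrices are authored, isostericity-patterned defaults:
identical LW class 5, edge-swapped class (e.g. trans-H/S vs trans-S/H) 2.5,
shared edge at same orientation 1, same orientation otherwise −1,
orientation mismatch −2; stacking diagonal 3, reversal partners 0.5,
otherwise −1; nucleotide match 2, mismatch −1, nucleotide–gap −2, gap–gap
0.  Any TSV in the same dialect can be supplied instead; asymmetric
matrices are supported (lookups always take the Y-side entry first), and a
file may give only one triangle, which is mirrored.  An optional
nucleotide-pair refinement table overrides the class-level base-pair score
when present.  Every correctness property in the test suite is
matrix-agnostic.

## Compatibility graph and clique search

Interaction cells are ordered 5′→3′ ((i,j) before (k,l) iff i<k, or i=k and
j<l).  A vertex pairs an X cell with a same-kind Y cell whose endpoints lie
in the same segment indices (strand correspondence is positional after the
orientation choice; cross-segment matches are structurally meaningless).
An edge joins two vertices iff the relation group of the X cells equals
that of the Y cells *with the same direction*: if the X cells are in
increasing cell order but the Y cells in decreasing order, the joint
matching would force a non-monotone alignment and gets no edge.  The six
groups are: juxtaposing (j<k), juxtaposing with shared nucleotide (j=k),
crossing (i<k<j<l), enclosing (i<k<l<j), enclosing shared-left (i=k) and
shared-right (j=l).  Identical cells on *both* sides are consistent only
across kinds (a base pair and a stacking may occupy the same position
pair).

Every clique is a consistent anchor set.  `find_best_clique` is a
branch-and-bound maximum-weight clique search: candidates are pruned when
the current weight plus an optimistic potential — the top positive weights
capped by the largest t with t(t−1)/2 edges available among the remaining
candidates — cannot beat the incumbent; the result provably equals subset
enumeration (tested on random graphs).  Ties prefer the larger clique,
then the lexicographically smallest vertex-index list.

## Extension, total score and optimality

Anchors fix matched columns; each unanchored stretch between consecutive
anchors of one segment is aligned by global dynamic programming over the
sequence-profile columns with a linear gap penalty (default −2.0 per
gapped column; traceback ties prefer the diagonal, then consuming X).
Gaps can never bridge break points because regions are confined to
segments.  The total score sums the clique's cell scores, the stacking
cells recoverable between clique-anchored endpoints, the nucleotide-column
scores of *all* aligned columns (global-alignment reading), and the gap
penalties.  Stacking cells outside the anchor set deliberately do not
contribute: that keeps the total a function of (clique, mapping) that the
DP optimizes exactly.  With `include_stackings=True` stacking cells become
graph vertices and can anchor alignments themselves (expensive for large
loops; off by default).

`align_profiles` does not merely extend the heaviest clique: it enumerates
cliques (branch-and-bound pruned by the positive-weight potential, the
edge bound, the unconstrained sequence-DP optimum and the maximum stacking
bonus — all sound upper bounds) and evaluates each candidate's full
extension, over every cyclic strand orientation of Y (2 for internal
loops, s for s-way junctions; reflections are not generated).
Re-orienting rotates the strand order, re-indexes all cells and reverses
interaction types whose endpoint order flips.  The reported alignment is
therefore exactly optimal for the total score, a property the test suite
verifies against brute-force enumeration over all consistent matchings ×
all monotone gapped mappings on small instances.  Cross-orientation ties
keep the earlier orientation.

## Merging and the guide tree

Merging sums aligned column maps; a column aligned to a gap gains a gap
count equal to the other profile's MC, so conservation (column sums = MC)
is preserved.  Interaction cells are re-keyed through the mapping and
summed entry-wise; unaligned interactions are carried over, so the total
interaction count is additive.  Profile building repeatedly merges the
best-scoring pair (exhaustive pair scan; ties keep the lowest index pair)
until one profile remains; inputs beyond `chunk_size` (default 5) are
first reduced chunk-wise in input order, recursively.  The merge order is
part of the result, so the merge tree is emitted as a newick-like string
alongside the profile.  Mixed junction types (different segment counts)
are rejected with the offending ids listed.

## Loop extraction and annotation merging

Loop boundaries use the stem criterion: a stacked run of cis-W/W pairs
qualifies as a bounding stem if it contains at least one canonical pair
(A–U or G–C) or at least two G–U wobbles.  The wobbles are necessarily
consecutive within a helix run; whether the criterion intends to admit two
non-stacked wobbles is unverified, and this implementation requires the
stacked run.  Extracted motifs include the closing pair positions of their
bounding stems and every annotated interaction with both endpoints inside.
Pseudoknotted (crossing) helices are dropped in favour of the
earlier-starting one.

Annotation lists from two sources (FR3D-style and DSSR-style) are merged
by union; when the sources disagree on a residue pair, the (nucleotide
pair, type) combination with the higher count in the interaction-frequency
table wins.  The packaged table is synthetic — plausible relative
magnitudes, not survey counts — and is clearly labelled as such; ties or
missing combinations fall back to the first-listed source with a warning.

## Search and z-scores

Candidates whose segment count differs from the profile's are skipped
(logged): they cannot align in any orientation.  Calibration aligns the
profile against each member's single-motif profile and uses the population
standard deviation (divide by N); z = (s − μ)/σ, with a degenerate family
(σ = 0) mapping its own mean to 0 and anything else to ±inf.  Hits are
reported for all candidate loops sorted by score (ties by id); a `min_z`
filter is optional.

## Visualization

Rendering filters the profile first: base-pair entries and nucleotides
below 10% of MC are dropped, columns whose gap fraction exceeds 75% are
dropped unless they participate in a surviving interaction, and stackings
are never drawn (they remain in the `.pfl` text).  Exactly 75% gap is
kept — the rule is "more than".  Both thresholds are exposed
(`RenderSpec`).  Circle radius and edge width are affine in count/MC
between documented clamps; nucleotides participating in a drawn pair get a
circular outline; profiles with three or more strands are laid out on a
circle, others on strand rows.  The SVG output is deterministic
(fixed-precision coordinates, frequency-then-lexicographic entry order),
which makes golden-file comparison meaningful.

## Synthetic data

The generator emulates what profile building needs to see: a conserved
interaction core with per-position nucleotide substitution (rate 0.08–0.10
per position), base-pair dropout (0.10–0.15 per pair) and occasional
single-nucleotide indels (0.10–0.15 per motif) — magnitudes chosen to
mimic the moderate within-family variation of curated internal-loop
families, where most instances share the characteristic pairs but few are
identical.  Decoy loops have random sequences with one to three random
base pairs.  It does not emulate modified nucleotides, annotation noise
(conflicting or spurious annotations), pseudoknots, coordinate geometry,
or the long-tailed length variation of real multi-loops; passing tests
therefore demonstrate algorithmic correctness and recoverability under
calibrated noise, not detection performance on real chains.  The packaged
kink-turn-like and sarcin-ricin-like templates carry the families'
textbook interaction signatures (tandem trans-H/S with crossing trans-S/S;
trans-H/S, trans-W/H, cis-H/S, trans-H/H, trans-S/H) as fixtures.

## Problem sizes and numerics

The test suite and the acceptance script run everything at desk scale:
families of 2–17 instances, loops of 6–13 nucleotides, compatibility
graphs up to ~25 vertices, 100-trial search experiments — sizes at which
the exhaustive oracles (subset enumeration, full matching × mapping
enumeration) remain tractable, which is what makes exact-agreement checks
possible at all.  Score comparisons in the oracles use exact floating
arithmetic on identical operation orders where possible and 1e-9
tolerances otherwise.  Degenerate inputs are defined explicitly: empty
graphs yield the empty clique at score 0; all-negative graphs prefer the
empty clique; empty profile cells are a caller contract violation rather
than a silent 0.

## Known limitations

Mixed-junction multi-loop groups are rejected by design.  The greedy
guide tree is order-dependent (hence the logged merge tree); chunking uses
input order.  The clique enumeration in `align_profiles` is exponential in
the worst case and is intended for the sparse interaction sets of real
loops (a handful of base pairs); `include_stackings=True` on large
internal or multi-loops can be slow.  Scoring matrices are stand-in
defaults, so absolute score values are not comparable to other tools —
only rankings and z-scores within one matrix set are meaningful.
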