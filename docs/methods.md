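# Methods

This note records the models, numerical procedures and design choices
behind `ssdraw`, at the level a maintainer or careful user needs.

## Sequence weighting and consensus annotation

Weighted frequencies, not raw counts, drive all annotation, so that a
clade of near-identical sequences cannot dominate the consensus.  Weights
follow the Gerstein–Sonnhammer–Chothia scheme: a rooted guide tree is
built by UPGMA on fractional-identity distances (d = 1 − matches/shared
non-gap columns; 1 when no columns are shared), each tree edge's length
is divided evenly among the leaves below it, and a leaf's weight is the
sum of its shares along the path to the root, normalized to total 1.
UPGMA ties are broken by merging the lexicographically smallest pair of
cluster indices (creation order), making weights deterministic; a
degenerate all-zero tree (identical sequences) falls back to uniform
weights.  The unit test suite cross-checks the tree heights against
scipy's average-linkage clustering and the weights against an independent
brute-force path-sum on trees of up to five leaves.

Conservation calls use a strict-inequality cascade with thresholds
(t50, t75, t90, t97) = (0.50, 0.75, 0.90, 0.97), all adjustable:

1. a specific nucleotide if its weighted frequency among non-gap rows
   exceeds t75 (tier = highest of 75/90/97 strictly exceeded);
2. else R (purine) or Y (pyrimidine) by the same rule on class
   frequencies — ambiguity codes R/Y in the input count toward their
   class, N toward none;
3. else presence tiers on the weighted non-gap fraction over **all**
   rows; at or below t50 the position is not drawn.

Identity frequencies are computed among non-gap rows while presence is a
separate fraction over all rows; this keeps R/Y calls meaningful in gappy
columns.  Covariation classes treat {AU, UA, GC, CG, GU, UG} as
canonical; a gap at either position of a pair counts as non-canonical
evidence, and a weighted non-canonical frequency strictly above 0.10
suppresses shading entirely.  Among canonical rows, any two observed pair
types differing at both positions make the pair covarying (this dominates
over compatible single-position differences).  Modular-structure
frequencies and the 10% rule both use GSC weights by default; callers can
pass uniform weights to obtain raw fractions.

## Geometry

Internal coordinates are y-up with two length parameters: d_nt = 1.0
between consecutive backbone positions (held exactly constant everywhere
except across variable-length arcs) and d_bp = 1.6·d_nt across a pair.
Any fixed ratio > 1 satisfies the geometry; 1.6 gives readable ladders.
Stems are parallel ladders (rung d_bp, rise d_nt); the 3' partner sits
90° clockwise of the 5' strand when looking along the stem, which makes
every loop walk run clockwise.

Loops are circles.  For radius r a chord d subtends 2·arcsin(d/(2r)); the
angle sum over a loop's chords decreases monotonically in r, so the
radius at which it equals 360° (closed loop) or 180° (one side of a
bulge/internal loop) is found by bisection: lower bracket max(d)/2, upper
bracket doubled until the sum drops below target, tolerance 1e-9 on the
angle sum, at most 200 iterations.  A chord set that cannot reach the
target even at the minimum radius (e.g. a single chord asked to close a
full circle) raises an infeasible-radius error.

In the layout path, terminal loops, bulges, internal loops and
uncommanded multistem junctions all use one uniform construction: every
loop participant (unpaired nucleotides plus the flanking nucleotides of
each pair, with pair chords d_bp and backbone chords d_nt) is placed on a
single full circle.  Drawing each side of an internal loop on its own
half circle was considered and kept only as a solver mode (the 180°
total), because with unequal side lengths the two half circles imply
different stem separations and the stems could no longer both remain
rigid ladders at constant spacing; the full-circle form preserves the
spacing invariant exactly and reduces to the symmetric picture when the
sides match.  The root level is a straight baseline from which stems rise
perpendicular; `turn` commands set a new absolute baseline direction at a
labeled column.

Variable-length regions outside junctions are drawn as dashed arcs
spanning a fixed 3·d_nt of backbone, labelled "m–M nt" from the per-row
non-gap count range; their columns get no coordinates and the flanking
bonds are marked as breaks exempt from the spacing invariant.

An overlap detector reports any two glyph centers closer than 0.8·d_nt;
all shipped fixtures must lay out with zero violations.  No automatic
overlap removal is attempted — layout selection remains the user's
responsibility, as in the surrounding tool tradition.

## Multistem junctions as constrained NLPs

When the user fixes stem directions, a junction is laid out by minimizing
deviation from a circle subject to those directions.  Three formulations
are provided; all are solved by scipy's SLSQP with finite-difference
gradients (an SQP method; any gradient-based constrained optimizer
satisfies the contract), warm-started from the plain circular layout that
ignores stem directions.

**Formulation 1** (on-circle).  Variables: radius r, the start angle of
the enclosing pair's 5' nucleotide as seen from the center, one
intersection parameter t ∈ [0,1] per base pair (0 at the 5' nucleotide,
1 at the 3'), and one length per variable-length region.  Positions are
derived from these by a clockwise walk: unpaired nucleotides go on the
circle (the next position is the closed-form intersection of the main
circle with a d_nt-radius circle about the previous point, taking the
clockwise-advancing root); each pair is placed so that the point at
parameter t along its rung lies on the circle while the rung stays
perpendicular to the user's stem direction; the center itself is derived
from (r, start angle, t₀) via a quadratic.  Two equality constraints
close the walk: the final bond back to the enclosing 3' nucleotide has
length d_nt, and the swept center angles total 360°.  The objective sums
(d_n − d_a)² over base-paired nucleotides n with backbone neighbor a,
d's measured to the center — penalizing sudden radius changes.  The
paper-level description fixes the variable set but not the derivation;
the clockwise walk with closed-form circle intersections is this
package's parametrization, chosen so the variable count stays at
2 + (number of pairs) + (number of variable regions).

**Formulations 2 and 3** (free circle).  Variables: main-circle center
and radius, the (x, y) of each emanating stem's 5' nucleotide — replaced
by a single bond angle when a stem follows its predecessor with no
unpaired nucleotides between them — plus variable-region lengths; the
enclosing pair is fixed in the plane.  Each run of unpaired nucleotides
lies on its own segment circle, fully determined by its flanking paired
positions and the constant spacing: with m backbone-unit chord
equivalents between flanks a distance L apart, the wrap angle θ solves
d_nt·sin(θ/2)/sin(θ/(2m)) = L, which is monotone decreasing in θ and is
bisected to machine precision; the center then sits at signed distance
r_s·cos(θ/2) from the chord midpoint on the side consistent with
clockwise traversal (so deep bulges bow outward).  An empty closing run
adds one equality constraint (bond length d_nt).  Formulation 2's
objective sums (d_pc − r)² over N + 2 + 3V sample points per run (its N
nucleotides, the 2 flanks, 3 per variable region); formulation 3 sums
(cos θ − 1)² between each sample point's directions to the main and
segment centers — runs with no segment circle (consecutive pairs)
contribute no slope term.  Formulation 2 is the default.

Alignment constraints apply to all formulations via scalar projections:
for axis angle φ the anchor points (base-pair midpoints of the named
stems) must share their projection onto the axis normal — φ = 0° aligns
horizontally (equal y), 90° vertically (equal x) — and centroid variants
equate a group centroid's projection with a target stem's.

Solving: the warm start is tried first, together with two deterministic
corner starts for formulation 1 (all intersection parameters at 0 and at
1, where the exact-circle optimum lies); if nothing feasible emerges,
up to 8 Gaussian-perturbed restarts (σ = 0.1·r₀, fixed seed list) are
attempted and the search stops at the first feasible solution, keeping
everything deterministic.  A solution is accepted only if every equality
constraint is met to 1e-6 and no two stem midpoints have collapsed onto
each other (closer than d_bp/2) — the latter rejects degenerate
"solutions" to contradictory alignment constraints, which then surface
as an infeasibility error suggesting another formulation.  Variable
region lengths are bounded to [0.5, 10] backbone units; the bound is a
declared choice, not derived.

## Pseudoknots, modular structures, rendering

Pseudoknot pairings live on separate, independently nested
`#=GC SS_cons_pk<NAME>` bracket lines.  The in-line style draws rungs
between partners where the main layout already put them and is judged
infeasible — with an error suggesting the callout — when any partner
pair spans more than 2.5·d_bp (a proxy for "rungs would cross the
drawing"; the overlap check is the other guard).  The callout style
builds a separate duplex ladder panel, shaded by the same covariation
classes, joined to the main drawing by a dashed connector labelled
"pseudoknot".

Modular structures are declared by predicates over rows (sequence-name
regular expressions and per-column content tests combined with
and/or/not); their weighted frequency is shown as a whole percent next to
a sub-panel.  The modular element currently also remains part of the main
drawing rather than being excised from it — a known simplification.

Rendering composes ordered primitives (shades below rungs below glyphs
below text) and serializes to SVG 1.1 with the y-axis flipped, a single
root group, text anchored at glyph centers, coordinates written at three
decimals, and a viewBox fitted with a 2-unit margin.  Identical inputs
produce byte-identical files.  The skeleton style reuses the same
coordinates and emits only backbone paths and arcs.  The default palette
(red/black/gray identity tiers, green-to-gray pair shades, ring-styled
presence glyphs) is conventional rather than canonical and is fully
overridable from a JSON style file.

## Synthetic data

The fixture generator produces tiny families in the style of a contrived
worked example: templates for a hairpin, an internal loop, 3- and 4-way
junctions (stems of 3–4 pairs, loops of 4, runs of 2 unpaired — small
motifs typical of published consensus diagrams) and an H-type pseudoknot.
One seed fixes everything.  Covariation is injected by swapping a pair's
canonical type for the canonical type differing at both positions, per
row and pair at the requested rate, with row 0 always keeping the
reference type — so expected pair classes are known by construction (rate
0 → invariant, any rate in (0,1] → covarying).  A modular hairpin is
carried by exactly round(fraction·n) rows.  What the generator does *not*
emulate: realistic substitution processes (single-position compatible
mutations arise only at rate 0 boundaries), alignment error, length
variation within stems, or phylogenetic correlation between columns —
passing tests therefore demonstrate the algorithmic contracts, not
robustness to messy natural alignments.

## Problem sizes and tolerances used in validation

The validation suite and the acceptance script run junction NLPs with 3–5
stems and 2–4 unpaired nucleotides per segment, alignments of up to 100
rows, and bisections to 1e-6 in frequency; loop closures are checked to
1e-6 degrees, NLP feasibility to 1e-6, oracle equivalence of the three
formulations to 1e-4 in position and 1e-8 in objective, and GSC weights
to 1e-9 against brute force.  These sizes exercise every code path while
keeping the whole suite in tens of seconds.

## Known limitations

No PDF backend (convert the SVG externally), no GUI, no automatic choice
of stem directions or global overlap removal, no tertiary-interaction
projection styles, no entropy-based conservation measure (tier thresholds
were preferred as directly interpretable), and no covariation confidence
scores — the shading reports presence of mutational evidence, not its
strength.
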