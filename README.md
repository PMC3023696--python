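# ssdraw

Publication-quality consensus RNA secondary-structure diagrams from
annotated multiple-sequence alignments, written for bioinformaticians who
infer structured RNA motifs and need readable, editable figures rather
than raw automatic layouts.

Given a Stockholm alignment whose `#=GC SS_cons` line marks base pairs
with matched angle brackets, `ssdraw` computes

* **GSC sequence weights** (Gerstein–Sonnhammer–Chothia, on a UPGMA guide
  tree) so redundant sequences do not bias the consensus;
* **conservation tiers** per column: a specific nucleotide when its
  weighted frequency exceeds 75% (sub-tiers at 90% and 97%), else a
  purine/pyrimidine symbol (R/Y) at the same thresholds, else
  "nucleotide present" tiers at 50/75/90/97% — positions below 50%
  presence are not drawn;
* **covariation classes** per predicted pair: *covarying* (two canonical
  pairs differing at both positions), *compatible* (differing at one),
  *invariant*, or no shading when non-canonical pairs exceed 10%;
* a **constant-spacing layout**: consecutive backbone positions are
  always exactly d_nt apart and pairs span d_bp (the two need not be
  equal).  Loop nucleotides sit on a common circle whose radius r* solves

      Σᵢ 2·arcsin(dᵢ / 2r) = 360°   (180° for one side of a bulge),

  found by binary search on r, each chord dᵢ subtending the apex angle of
  the isosceles triangle (r, r, dᵢ);
* **multistem junctions** laid out on an approximate circle under
  user-fixed stem directions, via a constrained non-linear program solved
  by SQP, in three formulations (on-circle with per-pair intersection
  parameters; free circle with per-run segment circles and a radial
  least-squares objective; the same with a slope-deviation objective),
  with scalar-projection alignment constraints at arbitrary axes;
* **SVG output** built from renderer-neutral primitives — deterministic,
  editable in Inkscape or Illustrator.

Pseudoknots arrive on extra `#=GC SS_cons_pk*` lines and are drawn
in-line or as a labelled "pseudoknot" callout panel; modular
sub-structures (optional hairpins, alternative terminal loops) are
declared by regular-expression/Boolean predicates and annotated with
their weighted occurrence frequency; variable-length regions become
dashed arcs labelled "m–M nt".  Single sequences are the one-row special
case.

## Worked example

Generate a small synthetic family (8 sequences, hairpin, 40% covariation
injection) and draw it:

```sh
ssdraw fixtures make --template hairpin --n 8 --covariation 0.4 --seed 4 -o demo.sto
ssdraw draw demo.sto demo.svg --dump-layout demo.tsv
```

The same pipeline from Python, showing what the numbers mean:

```python
from ssdraw import *
from ssdraw.consensus import alignment_weights, annotate_alignment

aln = generate_fixture(FixtureSpec(template="hairpin", n_seqs=8,
                                   seed=4, covariation_rate=0.4))
w = alignment_weights(aln)       # GSC weights, sum to 1
ann = annotate_alignment(aln, w)
print(ann.to_tsv())
```

```
col  symbol  identity_tier  presence_tier  partner  pair_class
0    U       97             97
2    present                97             13       covarying
5    Y       97             97             10       covarying
7    A       97             97
10   R       97             97             5        covarying
...
```

Column 7 is an invariant A (weighted frequency > 97%, drawn as a colored
letter); column 5 conserves only pyrimidine identity (Y); columns 2–4
vary too much for any identity call but always contain a nucleotide
(presence tier 97).  Every stem pair is classified *covarying* — the
injected substitutions swap whole canonical pairs, which is exactly the
mutational evidence the shading reports.  The 4-nt terminal loop plus
closing pair fit a circle of radius 1.110 internal units with step angles
summing to 360.000000°.

Junction layout with the NLP solver is driven by alignment commands, e.g.

```
#=GF R2R multistem_junction j dirs 180,90,0 formulation 2
```

with `j` a column label from the `#=GC R2R_LABEL` line; `align` /
`align_centroid` clauses constrain stems to a common axis.

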