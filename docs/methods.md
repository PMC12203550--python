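# Methods

## Pedigree model and normalization

A pedigree is represented by individual records (id, parent links, sex,
affections, vital status, proband and availability flags), a relationship
table for structure that parent links cannot express (monozygotic,
dizygotic and unknown-zygosity twins; spouse pairs without children),
fill scales for plotting, and layout hints. The `(famid, id)` pair is the
global key: the same id string may recur in different families.

Raw tables are cleaned by `normalize` before a `Pedigree` can be built.
The normalization rules, and their rationale:

* **Sex coercion** — "m"/"male"/"1" and "f"/"female"/"2"
  (case-insensitive) map to male/female; anything else maps to *unknown*
  rather than erroring, because sex-unknown individuals are legitimate in
  autosomal analyses and are only rejected where sex matters (X-linked
  kinship).
* **Parental-role repair** — an id used in a dad column is forced male
  (mom column → female). When this contradicts a declared sex the repair
  is recorded as a "mis-sexed parent" correction; when the declared sex
  was unknown the assignment is silent inference. An id used in *both*
  parent columns is unrepairable and reported as an error.
* **Both-or-neither parents** — an individual with exactly one known
  parent receives a placeholder founder of the required sex, named
  `<child>_father` / `<child>_mother` (numeric suffix on collision) so
  placeholder generation is deterministic and test-reproducible. Repairing
  rather than erroring keeps real-world tables (where one parent is often
  unrecorded) usable; the kinship recursion then never sees
  half-specified parentage. Parents referenced but absent from the table
  are likewise created as founders.
* **Missing codes** — parent ids in {"0", "", "NA"} (configurable) are
  missing. Affection values use a separate missing set {"", "NA", "-9"}
  because 0 is a meaningful affection value; the LINKAGE writer emits -9
  for missing phenotypes.

`normalize` is idempotent — a second pass adds no corrections — and its
output either fails validation only for defects normalization cannot
repair (self-parenting, ancestor loops) or passes cleanly.

Validation checks every structural invariant and returns all violations
at once: parent links resolve within the family, fathers are male and
mothers female, nobody is their own ancestor (cycle search on the
directed parent→child graph), relationship members exist, twins share
both parents, and MZ twins share sex. A `Pedigree` constructor succeeds
iff the report is error-free.

`make_famid` labels connected components (child–parent edges plus
relationship pairs) as families; `subset` restricts to a kept set,
clearing *both* parent links whenever either parent is dropped so the
both-or-neither invariant survives trimming.

## Kinship

Within each family the classical recursion is evaluated in generation
order (longest path from a founder), giving exact rational values in
double precision; the per-family dense blocks are assembled into one
sparse CSR matrix with exact structural zeros between families. The
X-linked recursion treats males as hemizygous (self-kinship 1; kinship
with anyone else equal to the mother's). Unknown-sex individuals are
rejected in X mode with the individual named.

MZ twin groups are handled by collapsing each group to its first-listed
member, re-running the recursion on the collapsed pedigree, and
expanding rows/columns back. Copying rows of the uncollapsed matrix
would be wrong whenever a third party descends from two different group
members (e.g. a child of twin a married to a child of twin b), which is
why `apply_mz_twins` recomputes on the collapsed pedigree rather than
editing the input matrix in place. DZ/UZ twins are genetically ordinary
siblings and get no adjustment.

The distance transform D = log₂(1/K) maps K = 0 to +∞ and rejects
values outside [0, 1].

Y-chromosomal and mitochondrial modes, condensed (Jacquard) identity
coefficients and genotype-based realized kinship are out of scope.

## Trimming

`min_distance_to_probands` gives each individual its minimum distance to
any proband (a non-inbred proband is at distance 1 from itself;
unrelated individuals, including all other families, are at +∞).
`useful_inds` keeps the core set {D ≤ max_dist} ∪ probands (ties at the
threshold kept; an inbred proband's self-distance is simply below 1, no
special-casing), with optional availability/affection filters that never
remove probands.

"Parents needed to keep the structure" is read as minimal connectivity:
whenever two core individuals were connected in the original family but
are separated in the kept set, the individuals on a deterministic
shortest connecting path are added, and parent couples are completed
(both parents or neither, matching `subset`'s clearing rule), iterated to
a fixed point. Additions beyond the threshold are reported separately as
`structural_ids`. This reading is the weakest closure that guarantees
every originally-connected pair of core individuals stays connected
after trimming.

## Layout and rendering

Drawing is a two-step pipeline so the intermediate tables can be
inspected and edited.

**Generations.** Longest-path layering from the founders, then
married-in founders are pulled down to the lowest of their mates'
levels, and children are re-levelled to max(parent levels) + 1 until a
fixed point. Couples left on different levels — both members have
parents, so neither can move — are flagged; `align` refuses such a
pedigree unless `bypass_spouse_alignment` is set, in which case the
mating line is routed between levels instead of the spouses being placed
adjacent.

**Ordering.** A deterministic depth-first traversal over mating unions
builds each level left to right: spouses adjacent to their anchor,
sibships hanging under their parent couple in hint order.
`auto_hints` keeps record order except that within-sibship mates are
moved adjacent (keeping consanguineous connecting paths short);
user-supplied hints pass through untouched. A union whose partner will
later hang as a child elsewhere is deferred until both partners are
placed; when a loop then closes on one level, the spouse (or child) that
is already drawn elsewhere is duplicated, and both copies share a
`dup_group` and are joined by a dotted connector. Sib matings need no
duplication (the mates are already adjacent in their sibship); a
first-cousin mating duplicates exactly one individual. Crossing
minimization is heuristic and best-effort, not optimal.

**Coordinates.** Iterative smoothing (12 passes by default): children
are centred under their parent couple's midpoint, then couples over
their children's mean, each pass solved as an order-constrained least
squares with a minimum gap of one symbol width by pool-adjacent-
violators. This preserves the drawing order exactly, guarantees ≥1 unit
between neighbours on a level (symbols are 0.7 units wide, so boxes
never overlap), and is deterministic. Families are placed side by side
with a 3-unit gap.

**Symbols and connectors.** Sex determines the shape (square/circle/
diamond); each displayed affection fills one equal angular sector,
clockwise from the top; deceased individuals get a slash, probands an
arrow with "P"; border colour encodes the availability flag. Connectors:
horizontal mating lines (routed polylines for bypassed cross-generation
unions), an offspring drop from the couple midpoint, a sibship bar,
per-child drops, twin forks with a joining bar for MZ pairs, and dotted
links within duplicate groups. SVG output is built by a small string
writer with fixed float formatting, making it byte-deterministic;
per-individual annotation lines are embedded as SVG `<title>` tooltips.
Output is static SVG only.

## Colour scales

Binary affections use white/dark fills. Continuous affections get linear
RGB gradients over the observed range: with a threshold, two
sub-gradients of `n_breaks` steps each (unaffected white→light blue
below, affected light→dark red from the threshold up; the threshold
value itself is affected); without, a single white→dark-red gradient.
Intervals are half-open on the right with the closing interval of each
gradient closed, the interval edges are forced onto the exact observed
extremes so boundary values are always covered, and missing values get a
dedicated grey. Default palettes have strictly decreasing lightness with
value; no perceptual-uniformity claim is made. Scales serialize to a
small dict for YAML/JSON configs.

## Synthetic data

`fixtures()` provides seven canonical pedigrees (trio, nuclear family,
first cousins, sib-mating loop, cross-generational mating, MZ+DZ twins,
two disjoint families) used throughout the tests; the cousin and sibling
fixtures realize the textbook values K = 0.0625 and K = 0.25.

`generate_random_pedigree` is a forward-in-time simulator: founders,
random matings per generation, Poisson sibship sizes, optional
consanguineous matings (mate chosen among relatives with the loop
probability; otherwise an unrelated same-generation female or a new
married-in founder, which is what guarantees a completely outbred
pedigree when the loop probability is 0) and twin birth events. Defaults
— 8 founders, 3 generations, mean sibship 2.5, mating probability 0.8,
loop probability 0.05, twinning 2% of birth events with one third MZ —
describe a modest breeding-colony-like pedigree with human-like twinning
rates. The simulator emulates pedigree *structure* only: no overlapping
generations, migration, assortative mating or realistic demography, and
affection values are not simulated — so passing tests speak to the
graph/kinship machinery, not to any demographic realism.

`gene_drop_kinship` is the independent oracle for the kinship recursion:
per replicate, founders receive unique allele labels (two autosomal
copies; one X in males), alleles are transmitted Mendelianly (sons
receive their mother's X only; MZ twins copy their representative's
genotype), and the kinship of a pair is estimated as the fraction of
replicates in which one randomly sampled allele from each is identical
by descent, with binomial standard error √(p(1−p)/n). Self-pairs draw
twice independently, estimating (1+F)/2. All randomness flows from one
explicitly seeded generator; there is no global random state.

A caveat that matters when reading the oracle-equivalence test: a 3-SE
band is a per-comparison criterion. Checked simultaneously over the
~400 non-degenerate pairs of all fixtures × modes × MZ settings at
200 000 replicates, about one excursion beyond 3 SE is *expected* per
run from sampling noise alone, so an isolated 3-SE violation among many
passing pairs reflects the multiplicity of the check, not a defect in
either the recursion or the simulator (the estimator is unbiased; at
10⁶ replicates the worst observed |z| across fixtures is ≈2.1).

## Problem sizes and numerical choices

The test-suite runs everything at desk scale: fixtures of 3–11
individuals, 50 simulated pedigrees (tens of individuals each) for the
matrix-property sweep, and 200 000 gene-dropping replicates per
fixture/mode for oracle comparisons — all chosen as the smallest sizes
at which the properties being asserted are non-trivial. Positive
semidefiniteness is asserted via the smallest eigenvalue with a 1e-10
floor for floating-point round-off; all worked-example kinship values
are exact in double precision (dyadic rationals). Determinism is treated
as a feature throughout: layout, rendering, simulation and the oracle
are reproducible bit-for-bit given the same inputs, options and seeds.
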