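# Methods

This note documents the models and procedures implemented in `modq`, the
design choices made where conventions leave room, and what the synthetic
test data does and does not establish.

## Definition grammar and its semantics

Module definitions follow the public KEGG DEFINITION conventions. The
grammar implemented is, loosest to tightest binding:

* **space** — at the top level, separates blocks (conjunctive reaction
  steps); inside parentheses, a conjunction of sub-steps within one
  block;
* **comma** — interchangeable alternatives (OR);
* **plus / minus** — complex subunits (AND), with `-X` marking subunit
  `X` optional; all operators left-associative; parentheses group;
* `--` — a gap step with no gene requirement.

Identifiers are K numbers (`K` + 5 digits) or EC numbers (1–4
dot-separated components, `-` as a wildcard component); one definition
uses one namespace throughout. Tokenization is lossless (concatenating
lexemes reproduces the input), and rendering is normalizing: redundant
parentheses and repeated whitespace are dropped, and
`parse(render(parse(t)))` is structurally identical to `parse(t)`.

A deliberate choice, flagged because the conventions are ambiguous on
it: **only top-level spaces create blocks**. A space inside parentheses
(`(A B) C`) is a conjunction within a single block, so that definition
has two blocks, not three. This keeps the mcf denominator equal to the
number of visually separated steps.

## Completeness

For gene set *G* and module with countable blocks *b₁…bₙ*:
mcf = |{i : G ⊨ bᵢ}| / n. Satisfaction is Boolean per block — there is
no partial credit within a block, which keeps every mcf an exact k/n
rational. The engine computes and stores the integer pair (satisfied,
total) and derives the float; equality-sensitive operations
(zero-variance detection, ground-truth comparison) use the pairs.

Numerical / degenerate-input choices:

* **Gap steps** demand no gene. Counting them as satisfied would inflate
  mcf, so they are excluded from numerator and denominator by default;
  `count_gaps="as-satisfied"` restores the inflating behaviour for
  users who want the raw block count.
* **All-gap or empty definitions** have no countable requirement; mcf is
  defined as 1 with a `DegenerateDefinitionWarning` rather than raising
  on a 0/0.
* **Optional subunits** never affect satisfaction and are never reported
  as missing genes.
* **EC wildcards**: a *requirement* `1.1.1.-` denotes a family and is
  satisfied by any annotated `1.1.1.x`; an *annotation* `1.1.1.-`
  expresses uncertainty and does not satisfy the specific requirement
  `1.1.1.1`. Matching is per component, requirement-side dashes (and
  absent trailing components) acting as wildcards. The behaviour can be
  disabled (`ec_wildcards=False`) for strict identity matching.

Monotonicity (A ⊆ B ⇒ mcf(A) ≤ mcf(B)) holds because the grammar has no
negation; the test suite asserts it over ten thousand nested draws.

## K→EC translation

Translation operates leaf by leaf on the parsed tree (never on the text,
which preserves parenthesization): a K leaf with m ≥ 2 enzyme images
becomes their OR, m = 1 becomes the single EC leaf. Unmapped K numbers
follow a policy:

* `KEEP_UNSATISFIABLE` (default) — the leaf becomes an always-false
  sentinel node. Conservative: enzyme-based completeness is never
  overstated. The sentinel renders back to the original K identifier, so
  a rendered translated definition containing sentinels is intentionally
  not re-parseable in the EC namespace.
* `DROP_OPTIONALIZE` — the leaf is wrapped optional, so the missing
  mapping does not penalize the module.

Block count and tree shape are preserved; any K-set satisfying a node
has an EC image satisfying the translated node, and under a bijective
mapping the K- and EC-based mcf matrices are identical (both are tested).

## Missing genes

For each unsatisfied block, all inclusion-minimal token sets whose
addition satisfies the block are enumerated by exhaustive subset search
over the block's absent required leaves. The overall completion is a
minimum-cardinality union of one choice per block, found by exact
enumeration while the module has ≤ 20 leaves (and the per-block choice
product stays below 10⁵), greedily beyond that — greedy results carry an
`approximate` flag and a warning. Ties break lexicographically on sorted
identifiers everywhere, so outputs are deterministic and diff-stable.

## Analysis statistics

* **Mean Euclidean distance** of p points: Σᵢ<ⱼ ‖xᵢ−xⱼ‖ / (p(p−1)/2),
  computed with SciPy's pairwise-distance routine. Fewer than two points
  is an error; in *grouped* computations a singleton group is reported
  as NaN with a warning — zero would falsely signal perfect tightness.
* **Per-module SD** uses the sample (n−1) denominator, matching the
  statistical environments this kind of matrix is usually analysed in.
* **Principal components** are delegated to scikit-learn's PCA on
  centered columns, unscaled by default since mcf columns share the
  [0, 1] unit; `scale=True` standardizes (zero-variance columns are left
  at zero rather than dividing by zero). All components are retained
  before distance computation by default (`n_components` caps it).
* **The automated report** always produces the genome/module counts,
  global heatmap, per-module boxplot, SD scatter and zero-variance
  table; when grouping factors are supplied it adds per-factor
  group-mean heatmaps, the cumulative-variance plot, component plots
  overlaid by group, and within-group mean distances. A failed section
  is recorded in `summary.json` (`sections`/`errors`) and the rest of
  the report is still produced.

## Plots

All figure functions return the matplotlib `Figure` alongside writing
the file, and the tests assert structural metadata (axis tick counts,
wedge counts and angles, legend entries, colour-scale limits) rather
than pixels, so they are backend-stable. Completeness shares one fixed
viridis [0, 1] scale across the heatmap and the sunburst. The sunburst
is drawn as concentric rings of matplotlib wedges: each leaf path gets
an equal angular span, inner rings aggregate consecutive leaves sharing
a prefix, and the outer ring is coloured by leaf values (mcf scale) or
by count share.

## Synthetic fixtures: what they emulate and what they don't

The generator emits module, genome and mapping files in the flat-file
and `.list` dialects with *exactly known* completeness: for each
(genome, module) pair a target k of the module's n countable blocks is
chosen (uniformly 0…n by default, or from an explicit profile), the
genome receives one full satisfying gene selection per satisfied block,
and unsatisfied blocks get at most a strict, verified-non-satisfying
subset as a distractor. Defaults: 10 modules of 2–5 blocks (alternative
probability 0.30, complex 0.25, nested parenthesization 0.10, optional
subunit 0.15, gap 0.05), 20 genomes across four genera; all randomness
derives from a single seed and outputs are byte-identical across runs.

Every leaf of every generated definition is a fresh K number, so token
pools are disjoint across blocks and modules and withholding genes from
one block cannot accidentally satisfy another; the generator still
re-verifies every realized genome against the engine and resamples on
collision (bounded retries). EC numbers in generated mappings are
globally unique.

What this does **not** emulate: real KEGG modules share orthologs across
modules and blocks, definitions can be deeper and larger (some real
modules have > 20 orthologs), gene frequencies are phylogenetically
correlated, and annotations carry errors. Passing tests therefore
establish the correctness of the parsing/evaluation/query machinery on
the full grammar, not distributional claims about real genomes; analyses
of real annotations inherit whatever biases the annotation pipeline has.

## Problem sizes

The test suite and the acceptance script run at desk scale: the
exhaustive oracle comparison covers all 1- and 2-block combinations of
ten grammar shapes (2,450 definition-subset evaluations), monotonicity
uses 10,000 nested draws, missing-gene soundness 1,000 pairs, and the
central ground-truth integration check 20 genomes × 10 modules. These
sizes exercise every code path while keeping a full run in seconds; all
of them are parameters, not limits.

## Known limitations

* Signature-module semantics beyond the grammar (e.g. KEGG's reaction
  or amino-acid level constructs) are out of scope.
* Gene presence is binary; abundance-weighted completeness for
  metagenome read counts is not implemented.
* The flat-file parser targets the module/genome record shapes (ENTRY,
  NAME, DEFINITION, CLASS, TAXONOMY, 12-column continuation, `///`);
  KGML/XML pathway maps and sequence collections are not parsed.
* `module_to_genomes` reports raw mcf against a threshold; categorical
  labels like "one block missing" are left to consumers.
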