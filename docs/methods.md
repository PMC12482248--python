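# Methods

This note documents the model implemented by `svmfp`, the choices made
where the design was genuinely open, and what the synthetic benchmarks
do and do not demonstrate.

## Model

A molecule is represented by the set of vocabulary substructures it
contains and by how those occurrences are arranged.  The pipeline has
four stages:

1. **Matching.**  Every vocabulary SMARTS is matched against the
   molecular graph.  One instance is one distinct (substructure, atom
   set) pair: automorphic repeats of the same atom set (e.g. the twelve
   symmetry mappings of benzene onto itself) count once.  R-group
   placeholder atoms never participate in matches, and atoms in
   single-atom fragments (counter-ions, solvents) yield no instances.
   A carbon-backbone instance is then kept only if at least one of its
   atoms is not covered by any functional-group instance — backbones
   exist to cover the regions functional groups do not claim, while the
   overlap that remains is what links the graph together.

2. **Substructure graph.**  Nodes are instances; edges are overlaps.
   The *topological* route links instances whose atom sets intersect or
   that contain a bonded atom pair.  The *geometric* route — the route
   an image detector would feed — derives an axis-aligned bounding box
   per instance from 2D depiction coordinates (padded by 0.25 × median
   bond length so single-atom instances have area), grows every box by
   a margin of 10% of the diagonal of the *smallest* box in that
   depiction, and links instances whose expanded closed boxes intersect
   (touching counts, so substructures sharing one atom are linked).
   The margin is recomputed per depiction, which makes the construction
   invariant under translation and uniform scaling of the layout.

3. **Fingerprint.**  The distance d between two instances is the
   minimum number of *intermediate* instances on a path between them:
   directly linked instances have d = 0, disconnected pairs are
   infinitely far.  The upper-triangular matrix holds
   f_ii = h1·n_i + g_ii on the diagonal and
   g_ij = Σ w·h2(d) over unordered instance pairs off it.
   Only non-zero values are stored (sparse vector over the flattened
   n² index space).

4. **Retrieval.**  Collections are ranked by
   s = ‖f1 − f2‖/‖f1 + f2‖ ascending.  s is 0 exactly at identity, 1
   for disjoint non-empty supports, and lies in [0, 1] because all
   coefficients are non-negative.

## Parameters

| parameter         | default                              | meaning |
|-------------------|--------------------------------------|---------|
| `h1`              | 10                                   | weight per instance count on the diagonal |
| `h2(d)`           | 2, 2, 2/4, 2/16, 2/256 for d = 0…4   | intersection weight by instance distance; 0 beyond `d_max` |
| `d_max`           | 4                                    | distance cut-off; controls sparsity |
| `backbone_factor` | 0.5                                  | halving applied once per pair when either instance is a carbon backbone |
| `n_slots`         | vocabulary size (1561 reserved)      | matrix side length; fix at 1561 for interchange compatibility |
| box pad           | 0.25 × median bond length            | detector-box stand-in for atom extent |
| box expansion     | 0.10 × smallest box diagonal         | overlap margin of the geometric route |

All h2 values and the halving factor are dyadic rationals, so
coefficient sums are exact in double precision regardless of
accumulation order; the dense-oracle tests can therefore require exact
equality.

### Ambiguities resolved

The defining sums leave three conventions open; the package fixes them
as follows and the choices are visible in the dense-oracle test:

* **Pair counting.**  Instance pairs are unordered and self-pairs are
  excluded; for i = j each pair α < β counts once.  Double-counting
  would make g_ii inconsistent with g_ij.  Ranking is invariant to a
  global factor on g, so retrieval is unaffected by this convention.
* **Backbone halving.**  Mixed functional-group/backbone pairs are
  halved once, as are backbone–backbone pairs — the halving names the
  instances, not the pair arity.  The diagonal count term h1·n_i is
  never halved.
* **Distance convention.**  d counts intermediate instances
  (shortest-path edges − 1), so directly overlapping instances get
  d = 0, matching the h2 table's domain starting at 0.

## Vocabulary

The vocabulary is file-driven (TSV: index, name, smarts, smiles, kind).
The repo ships a curated starter set of 101 common functional groups
and a generated default of 27 carbon backbones: linear chains of 3–6
carbons with all single bonds (4), with exactly one double bond at
positions unique under chain reversal (8), the same with one triple
bond (8), saturated rings of 3–6 members (4), benzene, cyclopentene and
cyclohexene.  The fingerprint dimension follows the loaded file;
`n_slots` can reserve the full 1561-slot space.

**Maximal-run chain semantics.**  The default chain SMARTS constrain
their terminal atoms to carbons that cannot extend into a further
non-ring aliphatic carbon (`[C;!R;!$([C;!R](~[C;!R])~[C;!R])]`).  A
chain pattern of length L therefore matches exactly the maximal carbon
runs of length L, which makes the 27 defaults mutually non-contained —
`prune_contained`, which removes any backbone whose query matches into
another entry's structure (without the reverse holding), leaves the set
unchanged and is idempotent.  Uncapped, generic chain patterns supplied
by a user are pruned as expected (a generic propane chain disappears
next to a generic butane chain).  The price of capping is that carbon
runs longer than six match no chain pattern at all; such runs are rare
in drug-like chemistry but do occur (fatty chains), and molecules
dominated by them will be under-covered.

Functional-group candidate enumeration builds connected chains of 2–5
atoms over {C, O, S, N, B, P} with at least one heteroatom and expands
each heteroatom with a fixed substitution table
(S → S, SO, SO₂; N → N, NO₂; P → P, PO), deduplicating by canonical
form.  The shipped curated list is preferred for actual fingerprinting;
the enumerator exists to generate candidate pools for manual curation.

Validation of the heteroatom/all-carbon rules reads the definite atomic
numbers of the query atoms; patterns whose elements are expressed only
through wildcards or OR-lists fail the functional-group check and
should be written with explicit elements.

## Synthetic data

No external datasets are used; three generators stand in for the data a
production system would take from compound databases and rendered
depictions:

* **Drug-like molecules** — one or two ring scaffolds (benzene,
  pyridine, piperazine, indole, …) joined by common linkers (amide,
  ester, sulfonamide, short chains) and decorated with 2–6 typical
  substituents, constrained to 15–40 heavy atoms.  This emulates the
  size and functional-group density of drug-size organic molecules.
  It does not emulate stereochemistry, charged species, organometallics
  or exotic ring systems.
* **Analog sets** — near-duplicate distractors built by ≤ 2 random
  graph edits of a reference (substituent add/remove, N/O/S swap, chain
  homologation, halogen decoration on carbon), accepted only when a
  path-based binary fingerprint (RDKit, maxPath = 5) gives Tanimoto
  ≥ 0.90 to the reference.  The path length was chosen when the
  generator was designed: at the default maxPath = 7 almost no
  single-atom edit of a drug-sized reference stays above 0.90, which
  would starve the generator; maxPath = 5 admits the gentle edits while
  still rejecting scaffold changes.  The generators play the same
  statistical role as sampling high-similarity neighbours from a large
  compound database, but their edit distribution is narrower than real
  database neighbourhoods.
* **Markush structures** — 1–3 operations on a molecule: replace a
  terminal atom with an R-group placeholder, or attach a new R group to
  a ring atom; emitted as CXSMILES with the R-group label block.
  Bracket repeat/frequency notation is not generated.
* **Layout perturbation** — random rotation, uniform scale in
  [1 − m, 1 + m], and per-atom jitter bounded by m × the median
  nearest-neighbour distance (a bond-length proxy computable from
  coordinates alone).  This emulates depiction variability at the
  coordinate level; it does not emulate raster artefacts, fonts, or
  drawing-style changes, so geometric-route results here say nothing
  about raster-image robustness.

### Retrieval benchmark protocol

The self-query benchmark asks at which rank a molecule's own
fingerprint retrieves it from an analog set.  The fingerprint is not
injective: positional isomers can have identical class counts and
identical instance distances, hence identical fingerprints, and under
deterministic tie-breaking only one member of such a pair can rank
first.  `generate_analog_benchmark` therefore additionally rejects
candidates whose ground-truth fingerprint duplicates one already in the
set — the self-query question is only well-posed over entries the
representation can distinguish.  `generate_analog_set` applies no such
filter.  With a 100-analog benchmark the topological route gives
self-query mean rank exactly 1.0, and the geometric route under layout
perturbation of magnitude 0.1 keeps the correct molecule's median rank
within 5 (both checked in the test suite at exactly these sizes; the
suite and the acceptance script use 100 molecules / 100 analogs as
their standard problem size).

## Numerical and degenerate-input choices

* Ranking uses a stable sort; ties keep dataset insertion order.
* The similarity measure accumulates over sorted coefficient indices so
  that s(a, b) and s(b, a) are bit-identical; two empty fingerprints
  compare at distance 0.
* Exact-match percentage compares F1 against 1.0 exactly; F1 equals 1.0
  in floating point iff TP = |truth| = |pred|, so no tolerance is
  needed.
* Self-distance between instances is undefined (an error), matching the
  exclusion of self-pairs from the sums; disconnected instance pairs
  contribute nothing.
* An empty instance list produces an empty graph and an empty
  fingerprint; an empty vocabulary is rejected at load time.
* Single-atom instances get nonzero-area boxes via the pad; a
  bond-free depiction falls back to pad = 0.25 × 1.0.

## Known limitations

* The detection backend is a contract plus a fixture-replay test
  double; no trained image segmenter ships here, so absolute benchmark
  figures from patent-image datasets are out of reach of this package.
* Abbreviation/superatom expansion is not implemented; depictions using
  shorthand labels would be under-matched.
* The curated functional-group list covers common organic chemistry
  only (no organometallics); coverage-sensitive applications should
  load their own vocabulary file.
* Carbon runs longer than six atoms match no default chain pattern
  (see maximal-run semantics above).
* Fingerprint collisions between positional isomers are inherent to a
  count-and-distance representation; applications needing exact
  structure identity should verify top-ranked hits with a graph match.
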