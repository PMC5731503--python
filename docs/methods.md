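# Methods

## Model

An assembly of a scaffold set S is a set of *assembly points*: adjacencies
`(o1·s1, o2·s2)` between distinct scaffolds, each side oriented forward,
reverse, or unknown. A point and its reversal (both orientations flipped,
scaffolds swapped) denote the same adjacency; the canonical representative
has the lexicographically smaller scaffold first. Self-adjacencies are
rejected: a scaffold adjacent to itself has no consistent extremity pair
under the matching model, and repeated scaffolds (repetitive DNA) are
outside the model — they surface as conflicts instead.

A *realization* of a point fixes every unknown orientation; oriented,
semi-oriented and unoriented points have exactly 1, 2 and 4 realizations.
An oriented point joins two scaffold *extremities* under the convention
that `(+x, +y)` joins x.head to y.tail; reversing a scaffold swaps the end
it contributes. This map is injective across the four realizations of a
scaffold pair and invariant under canonicalization.

The scaffold assembly graph (SAG) has one directed scaffold edge per
scaffold (tail→head) and one undirected assembly edge per realization per
point, colored by origin assembly: *actual* for oriented points,
*candidate* for realizations of non-oriented ones. Two oriented points
conflict iff their extremity pairs share exactly one extremity; identical
pairs are agreement, disjoint pairs are unrelated. For general points the
classifier evaluates all |R(p)|×|R(c)| realization pairs: every pair
conflicting ⇒ conflicting, some ⇒ semiconflicting, prefixed in-/out- for
same/different origin. The flags are non-exclusive labels (a point can be
out-conflicting with one partner and out-semiconflicting with another),
and only point pairs sharing a scaffold are ever compared — pairs on
disjoint scaffold sets cannot share an extremity, which keeps
classification near-linear on realistic inputs. Point identity for
uniqueness counting is the exact canonical form including orientation
status: a semi-oriented point and its oriented restriction are different
points that merely share realizations.

## Merging

Each assembly edge carries a confidence weight: the point's `cw ∈ [0,1]`
(default 1 when unset) for actual edges, discounted by a factor (default
0.75) for candidate edges. The discount is multiplicative in `cw` so
user-supplied confidences propagate to realizations. Collapsing parallel
edges of the SAG gives the merged graph (MSAG) whose edge weight is the
sum of its contributors' weights; contributors are retained for
traceability. Edges lighter than the weight threshold (default 0, strict
`<`) are removed *before* solving so that discarded edges cannot bias the
selection.

A merged assembly M must be (i) a matching on extremities, (ii) free of
alternating cycles — with `allow_circular`, a single cycle is admitted
only if it traverses *all* scaffold edges (unichromosomal circular
genomes) — and (iii) contain at most one realization of any input point.
Maximizing total weight under these constraints generalizes a known
NP-complete path/cycle-cover problem, hence:

* **Greedy**: edges in descending weight (ties by lexicographic endpoint
  key) are added when both endpoints are unmatched, no forbidden cycle
  closes, and no sibling realization of a contributing input point was
  already taken. Cycle detection contracts each scaffold to one
  union-find node; an edge closes an alternating cycle iff it joins two
  extremities already in one component.
* **Matching**: a maximum-weight matching over the assembly edges
  (networkx blossom implementation), then the lowest-weight edge of every
  alternating cycle is removed (cycles of a matching are vertex-disjoint;
  deterministic tie-break by endpoint key), then condition (iii) is
  enforced by iteratively dropping all but the heaviest selected
  realization of any over-represented input point until a fixpoint;
  removed edges are never revisited.
* **Exact**: branch-and-bound over edges ordered by descending weight
  (include-branch first, remaining-weight pruning, rollbackable
  union-find), keeping the first optimum found along this fixed order —
  deterministic, intended as an oracle; it refuses instances above a
  configurable edge bound (default 20) since the search is exponential.

The consistency score of an input assembly A against M sums, over points
p of M, the weight of the best point of A realizing p (its actual weight
for an exact match, the discounted candidate weight otherwise; 0 when
none). With these semantics the summed consistency scores of all inputs
equal the MSAG weight of M's edges, so the matching formulation optimizes
exactly the summed scores. The equivalence presumes each scaffold pair
occurs at most once per assembly — guaranteed for assemblies that are
chains without repeated scaffolds; a hand-built assembly containing both
an oriented point and its unoriented twin double-counts on the MSAG side.

`validate_solution` re-checks all feasibility conditions independently of
the solvers and is asserted (and fuzz-tested) on every solver output.
Merged chains are reconstructed by walking the alternating paths; each
chain is emitted in its lexicographically smaller direction, circular
chains start at their smallest scaffold, and scaffolds in no merged point
come out as orientation-less singletons.

## Synthetic data

The generator emulates several error-prone scaffolders observing one
genome. A reference is a uniform random signed order of `n_scaffolds`
split into `n_chromosomes` linear chains (uniform cut positions). Each
derived assembly processes the true adjacencies in canonical order and,
per adjacency, draws: drop with `p_missing`; else rewire with
`p_adjacency_error` to a uniformly random free extremity of another
scaffold (never recreating an existing scaffold pair); then each side of
an emitted point loses its orientation with `p_orientation_loss`.
Extremities are never reused and scaffold pairs never repeat, so every
derived assembly respects the matching discipline of a genuine scaffold
order; an adjacency whose extremity was consumed by an earlier rewiring
is dropped. All randomness comes from one `random.Random` stream seeded
with the string `"{seed}:{assembly_index}"` (string seeding is stable
across platforms and releases) with the draw order fixed as above.

Defaults (20 scaffolds, 2 chromosomes, 3 assemblies, 5% adjacency error,
20% orientation loss, 10% missing) reflect a modest draft-genome
comparison: a handful of chromosome-scale chains, scaffolders that agree
on most adjacencies, and a substantial minority of placements without
strand information. What the generator does not emulate: repetitive
scaffolds (excluded by the model), assemblies over partial scaffold
subsets, correlated errors between assemblies produced by similar
methods, and gap-size information. Passing recovery tests therefore show
that merging resolves independent random noise and orientation loss, not
that it survives systematically correlated misjoins.

## Numerical and design choices

* All tie-breaks are lexicographic on (scaffold name, extremity end);
  every output (tables, exports, merged orders) is byte-stable across
  runs and interpreter hash seeds.
* Duplicate canonical points within one assembly collapse to one with a
  warning, keeping the highest confidence weight (unset counts as the
  default, i.e. the maximum) — assemblies are sets of points.
* Floats are serialized with `repr` (exact round-trip); weight
  comparisons in solvers use a 1e-9 tolerance.
* The report's section 4 writes the joined sources set in the `origin`
  column (duplicated in `sources`) so the file re-reads as a points
  table while listing each distinct point exactly once.
* Test problem sizes: solver cross-checks run 500+ random instances of 6
  scaffolds × 2 assemblies against the exhaustive oracle (instances kept
  below ~26 merged edges so the oracle stays instant); recovery suites
  use 8–20 scaffolds. These sizes already exercise every structural case
  (cycles, orientation resolution, realization exclusivity) — the
  algorithms themselves scale to thousands of scaffolds since only the
  exhaustive oracle is exponential.

## Known limitations

* Repetitive scaffolds are unsupported; duplicates within one input
  chain are an error, and cross-assembly duplications appear as
  conflicts.
* The exact solver is exponential and guarded by an edge bound; the two
  heuristics carry no approximation guarantee (objective equality with
  the oracle is frequent but not asserted).
* Points files carry no sequence, length or gap semantics; gap sizes are
  preserved opaquely. Merging operates on scaffold orders, not FASTA
  sequences.
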