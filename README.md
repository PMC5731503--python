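# scafmerge

Comparative analysis and merging of scaffold assemblies of the same
scaffold set.

Draft genomes come as collections of scaffolds whose order and orientation
along chromosomes are unknown, and the many scaffolding techniques
(jumping libraries, long reads, homology, FISH, Hi-C, genome maps)
produce partial, error-prone and mutually disagreeing orderings — some,
like FISH or Hi-C placement, without even resolving scaffold strand.
`scafmerge` takes two or more such assemblies, expressed as *assembly
points* (adjacencies between oriented, semi-oriented or unoriented
scaffolds), and

1. builds the **scaffold assembly graph** (SAG): a breakpoint graph whose
   vertices are scaffold extremities (head/tail), with one directed
   scaffold edge per scaffold and colored undirected assembly edges per
   adjacency — *actual* edges for oriented points, *candidate* edges for
   every realization of a semi-/un-oriented point (2 or 4 of them);
2. classifies every point as unique / in- or out-conflicting / in- or
   out-semiconflicting / non-conflicting, where two points conflict when
   their extremity pairs share exactly one extremity, extended to
   non-oriented points over all pairs of realizations (all conflict ⇒
   conflicting, some ⇒ semiconflicting);
3. computes a **merged assembly**: collapse parallel edges into the
   weighted merged graph (MSAG; default weights 1 for actual, 0.75 for
   candidate edges, summed per multiedge) and pick a maximum-weight set of
   assembly edges *M* that is a matching, creates no alternating cycle
   (linear chromosomes; optionally one circular chromosome through all
   scaffolds), and contains at most one realization of every input point.
   Two solvers are provided — a greedy path-joining heuristic and a
   blossom maximum-weight matching with cycle repair — plus an exhaustive
   branch-and-bound oracle for small instances;
4. reports four machine-readable tables (per-assembly aggregates, subset
   consistency, per-instance and per-point records) plus DOT and
   Cytoscape-style JSON graph exports.

A synthetic-fixture module generates reference scaffold orders and
corrupted derived assemblies with controlled adjacency-error,
orientation-loss and missingness rates, so the merger's recovery behaviour
is testable without any external data.

## Worked example

The classic three-assembly example over scaffolds `s1..s4`:
`A1 = (+s1 +s3 -s4), (s2)`, `A2 = (+s1 +s2 +s3 s4)`,
`A3 = (+s1 +s2 s3), (s4)` — `s4` in A2 and `s3` in A3 are unoriented.

```python
import io
from scafmerge import build_msag, merge_greedy, scaffold_orders, validate_solution
from scafmerge.io import read_orders

A1 = read_orders(io.StringIO("+s1 +s3 -s4 $\ns2 $\n"), "A1")
A2 = read_orders(io.StringIO("+s1 +s2 +s3 s4 $\n"), "A2")
A3 = read_orders(io.StringIO("+s1 +s2 s3 $\ns4 $\n"), "A3")

msag = build_msag([A1, A2, A3])
for e in msag.edges:
    print([str(v) for v in e.key], e.weight)
M = merge_greedy(msag)
print(M.objective, [str(p) for p in M.points])
print(scaffold_orders(M, msag.scaffolds))
print(validate_solution(M, [A1, A2, A3]))
```

prints

```
['s1.h', 's2.t'] 2.0
['s1.h', 's3.t'] 1.0
['s2.h', 's3.h'] 0.75
['s2.h', 's3.t'] 1.75
['s3.h', 's4.h'] 1.75
['s3.h', 's4.t'] 0.75
5.5 ['(+s1, +s2)', '(+s2, +s3)', '(+s3, -s4)']
[([('s1', '+'), ('s2', '+'), ('s3', '+'), ('s4', '-')], False)]
[]
```

The adjacency `s1–s2` is supported by two assemblies (weight 2), so the
greedy pass takes it first; the two weight-1.75 edges combine an actual
edge with a supporting candidate realization, which both orients `s4`
(as `-s4`, the realization consistent with A1) and rejects A1's
conflicting `(+s1, +s3)`. The objective 5.5 is the summed weight of the
three chosen edges, the empty list means the solution passes all
feasibility checks, and the reconstructed chromosome is
`+s1 +s2 +s3 -s4`.

The same workflows are available from the shell:

```bash
scafmerge simulate -o sim --n-scaffolds 20 --n-assemblies 3 --seed 7
scafmerge analyze sim/A1.tsv sim/A2.tsv sim/A3.tsv -o report
scafmerge merge sim/A*.tsv -o merged --heuristic matching
```

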