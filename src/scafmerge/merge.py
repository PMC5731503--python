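"""Assembly merging: weights, merged graph, and restricted matching solvers.

Merging several input assemblies into a single most-confident one is posed
as an optimization problem on the merged scaffold assembly graph (MSAG):
collapse parallel assembly edges of the combined SAG into simple weighted
edges (weight = sum of the contributors' confidence weights), then pick a
subset M of assembly edges such that

  (i)   M is a matching on scaffold extremities (no scaffold end is claimed
        by two adjacencies — the merged assembly is not self-conflicting),
  (ii)  the total weight of M is maximal,
  (iii) the union of M with the scaffold edges contains no alternating
        cycle (chromosomes are linear; optionally one circular chromosome
        spanning *all* scaffolds is allowed), and
  (iv)  for every input point, at most one of its realizations is in M —
        an unoriented scaffold gets at most one resolved orientation.

The unrestricted variant with fixed path/cycle counts is NP-complete, so
two heuristics are provided — a greedy path-joining pass and a
maximum-weight matching (networkx blossom) followed by cycle repair — plus
an exhaustive branch-and-bound solver usable as an exact oracle on small
instances.

Weight defaults: an oriented (actual) edge weighs the point's confidence
weight, 1 when unset; a candidate edge (one realization of a non-oriented
point) is discounted by a factor of 0.75.  Edges below a user threshold are
removed *before* solving, so that discarded low-confidence adjacencies
cannot bias the selection among the remaining ones.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import networkx as nx

from .points import (
    Assembly,
    AssemblyPoint,
    Extremity,
    PointKey,
    point_from_extremities,
    realization_keys,
)
from .sag import (
    DEFAULT_ACTUAL_WEIGHT,
    DEFAULT_CANDIDATE_FACTOR,
    AssemblyEdge,
    build_sag,
)

__all__ = [
    "WeightPolicy",
    "MsagEdge",
    "MergedSAG",
    "MergedAssembly",
    "InstanceTooLargeError",
    "InfeasibleSolutionError",
    "assign_weights",
    "build_msag",
    "consistency_score",
    "merge_greedy",
    "merge_matching",
    "merge_exact",
    "validate_solution",
    "scaffold_orders",
]

_EPS = 1e-9

# identifier for a source point instance: (origin assembly, canonical key)
SourceKey = Tuple[str, PointKey]


class InstanceTooLargeError(RuntimeError):
    """The exhaustive solver was given more edges than its configured bound."""


class InfeasibleSolutionError(RuntimeError):
    """A proposed merged assembly violates the feasibility conditions."""


@dataclass
class WeightPolicy:
    """Confidence-weight defaults and the pre-solve weight threshold."""

    default_actual: float = DEFAULT_ACTUAL_WEIGHT
    default_candidate_factor: float = DEFAULT_CANDIDATE_FACTOR
    threshold: float = 0.0

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ValueError("weight threshold must be >= 0")


@dataclass(frozen=True)
class MsagEdge:
    """A simple weighted assembly edge of the merged graph.

    ``contributors`` traces the edge back to the input: one entry per
    parallel SAG edge collapsed into it, ``(origin, source point,
    per-origin weight)``.
    """

    endpoints: FrozenSet[Extremity]
    weight: float
    contributors: Tuple[Tuple[str, AssemblyPoint, float], ...]

    @property
    def key(self) -> Tuple[Extremity, Extremity]:
        a, b = sorted(self.endpoints)
        return (a, b)

    @property
    def source_keys(self) -> FrozenSet[SourceKey]:
        return frozenset((origin, p.key) for origin, p, _ in self.contributors)


@dataclass
class MergedSAG:
    """SAG with parallel assembly edges collapsed to single weighted edges."""

    scaffolds: Set[str]
    edges: List[MsagEdge]
    colors: List[str]

    def edge_by_key(self, key: Tuple[Extremity, Extremity]) -> MsagEdge:
        for e in self.edges:
            if e.key == key:
                return e
        raise KeyError(key)


@dataclass
class MergedAssembly:
    """A feasible merged assembly: oriented canonical points + objective."""

    points: Tuple[AssemblyPoint, ...]
    objective: float
    edges: Tuple[MsagEdge, ...] = ()

    def point_keys(self) -> Set[PointKey]:
        return {p.key for p in self.points}


def assign_weights(
    assemblies: Sequence[Assembly], policy: Optional[WeightPolicy] = None
) -> List[AssemblyEdge]:
    """Weighted SAG assembly-edge list under ``policy`` defaults.

    Actual edges weigh the point's cw (``default_actual`` when unset);
    candidate edges are discounted multiplicatively by
    ``default_candidate_factor``, so user-supplied confidences propagate to
    realizations.
    """
    policy = policy or WeightPolicy()
    graph = build_sag(
        assemblies,
        default_actual=policy.default_actual,
        candidate_factor=policy.default_candidate_factor,
    )
    return graph.assembly_edges


def build_msag(
    assemblies: Sequence[Assembly], policy: Optional[WeightPolicy] = None
) -> MergedSAG:
    """Collapse parallel SAG edges into weighted MSAG edges, then threshold.

    Edges whose combined weight is strictly below ``policy.threshold`` are
    removed before any solving.
    """
    policy = policy or WeightPolicy()
    edges = assign_weights(assemblies, policy)
    grouped: Dict[Tuple[Extremity, Extremity], List[AssemblyEdge]] = defaultdict(list)
    for e in edges:
        grouped[e.pair_key].append(e)
    msag_edges = []
    for key in sorted(grouped):
        members = grouped[key]
        total = sum(e.weight for e in members)
        if total < policy.threshold:
            continue
        msag_edges.append(
            MsagEdge(
                endpoints=frozenset(key),
                weight=total,
                contributors=tuple(
                    (e.origin, e.source, e.weight) for e in members
                ),
            )
        )
    scaffolds: Set[str] = set()
    for a in assemblies:
        scaffolds.update(a.scaffolds)
    return MergedSAG(
        scaffolds=scaffolds, edges=msag_edges, colors=[a.id for a in assemblies]
    )


def consistency_score(
    M: object, assembly: Assembly, policy: Optional[WeightPolicy] = None
) -> float:
    """Weighted agreement of one input assembly with a merged assembly.

    Each oriented point p of M contributes the weight of the best point of
    ``assembly`` realizing p: its cw for an exact (actual) match, the
    discounted candidate weight when p only realizes a non-oriented point;
    0 when nothing in the assembly realizes p.
    """
    policy = policy or WeightPolicy()
    points = getattr(M, "points", M)
    score = 0.0
    for p in points:
        best = 0.0
        for x in assembly.points:
            if p.key in realization_keys(x):
                base = x.cw if x.cw is not None else policy.default_actual
                w = base if x.is_oriented else policy.default_candidate_factor * base
                best = max(best, w)
        score += best
    return score


class _UnionFind:
    """Union-by-size without path compression, supporting rollback."""

    def __init__(self, items: Iterable[str]):
        self.parent = {x: x for x in items}
        self.size = {x: 1 for x in self.parent}
        self._trail: List[Tuple[str, str]] = []

    def find(self, x: str) -> str:
        while self.parent[x] != x:
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return
        if self.size[ra] < self.size[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        self.size[ra] += self.size[rb]
        self._trail.append((rb, ra))

    def mark(self) -> int:
        return len(self._trail)

    def rollback(self, mark: int) -> None:
        while len(self._trail) > mark:
            rb, ra = self._trail.pop()
            self.parent[rb] = rb
            self.size[ra] -= self.size[rb]

    def component_size(self, x: str) -> int:
        return self.size[self.find(x)]


def _edge_order(edges: Iterable[MsagEdge]) -> List[MsagEdge]:
    """Descending weight, ties broken by lexicographic endpoint key."""
    return sorted(edges, key=lambda e: (-e.weight, e.key))


def _finalize(chosen: Iterable[MsagEdge]) -> MergedAssembly:
    edges = tuple(sorted(chosen, key=lambda e: e.key))
    points = tuple(
        sorted(
            (point_from_extremities(e.endpoints, origin="merged") for e in edges),
            key=lambda p: p.key,
        )
    )
    return MergedAssembly(
        points=points, objective=sum(e.weight for e in edges), edges=edges
    )


def merge_greedy(msag: MergedSAG, allow_circular: bool = False) -> MergedAssembly:
    """Greedy path-joining heuristic.

    Starting from the bare scaffold edges, assembly edges are considered in
    descending weight order; an edge is added when both endpoints are still
    unmatched, it closes no alternating cycle (except, with
    ``allow_circular``, a single cycle through *all* scaffolds), and no
    sibling realization of any of its contributing input points was added
    before.
    """
    matched: Set[Extremity] = set()
    used_sources: Set[SourceKey] = set()
    uf = _UnionFind(msag.scaffolds)
    cycle_used = False
    chosen: List[MsagEdge] = []
    n = len(msag.scaffolds)
    for e in _edge_order(msag.edges):
        a, b = e.key
        if a in matched or b in matched:
            continue
        if e.source_keys & used_sources:
            continue
        if uf.find(a.scaffold) == uf.find(b.scaffold):
            if not (
                allow_circular
                and not cycle_used
                and uf.component_size(a.scaffold) == n
            ):
                continue
            cycle_used = True
        else:
            uf.union(a.scaffold, b.scaffold)
        matched.update((a, b))
        used_sources |= e.source_keys
        chosen.append(e)
    return _finalize(chosen)


def _find_cycles(
    chosen: Sequence[MsagEdge], n_scaffolds: int, allow_circular: bool
) -> List[List[MsagEdge]]:
    """Alternating cycles among chosen edges (scaffold-contracted view).

    Because the chosen edges form a matching and scaffold edges a perfect
    matching, every component of the contraction is a path or a cycle; a
    component is a cycle iff it has as many edges as nodes.  A cycle
    through all scaffolds is exempt when ``allow_circular``.
    """
    g: nx.MultiGraph = nx.MultiGraph()
    for i, e in enumerate(chosen):
        a, b = e.key
        g.add_node(a.scaffold)
        g.add_node(b.scaffold)
        g.add_edge(a.scaffold, b.scaffold, index=i)
    cycles = []
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        if sub.number_of_edges() != len(comp):
            continue
        if allow_circular and len(comp) == n_scaffolds:
            continue
        cycles.append(
            sorted(
                (chosen[d["index"]] for _, _, d in sub.edges(data=True)),
                key=lambda e: e.key,
            )
        )
    return cycles


def merge_matching(msag: MergedSAG, allow_circular: bool = False) -> MergedAssembly:
    """Maximum-weight matching heuristic with cycle repair.

    Computes a maximum weighted matching over the assembly edges (networkx
    blossom algorithm), removes the lowest-weight edge from every
    alternating cycle (cycles of a matching are vertex-disjoint), then
    enforces the one-realization-per-input-point condition by dropping all
    but the heaviest selected realization of any input point.
    """
    g: nx.Graph = nx.Graph()
    by_key: Dict[Tuple[Extremity, Extremity], MsagEdge] = {}
    for e in _edge_order(msag.edges):
        a, b = e.key
        g.add_edge(a, b, weight=e.weight)
        by_key[(a, b)] = e
    mate = nx.max_weight_matching(g, maxcardinality=False)
    chosen = [by_key[tuple(sorted(pair))] for pair in mate]
    chosen.sort(key=lambda e: e.key)

    for cycle in _find_cycles(chosen, len(msag.scaffolds), allow_circular):
        drop = min(cycle, key=lambda e: (e.weight, e.key))
        chosen.remove(drop)

    # one realization per input point: iterate to a fixpoint since an edge
    # may realize several input points at once
    while True:
        by_source: Dict[SourceKey, List[MsagEdge]] = defaultdict(list)
        for e in chosen:
            for sk in e.source_keys:
                by_source[sk].append(e)
        offending = sorted(
            (sk for sk, es in by_source.items() if len(es) > 1)
        )
        if not offending:
            break
        edges = by_source[offending[0]]
        keep = min(edges, key=lambda e: (-e.weight, e.key))
        for e in edges:
            if e is not keep:
                chosen.remove(e)
    return _finalize(chosen)


def merge_exact(
    msag: MergedSAG, allow_circular: bool = False, max_edges: int = 20
) -> MergedAssembly:
    """Exhaustive branch-and-bound solver (oracle for small instances).

    Enumerates feasible subsets (matching, acyclic modulo the circular
    exception, one realization per input point) and returns a maximum-weight
    one; deterministic (first optimum found along the fixed search order is
    kept).  Raises :class:`InstanceTooLargeError` above ``max_edges``.
    """
    edges = _edge_order(msag.edges)
    if len(edges) > max_edges:
        raise InstanceTooLargeError(
            f"{len(edges)} assembly edges exceed the exhaustive bound {max_edges}"
        )
    n = len(msag.scaffolds)
    suffix = [0.0] * (len(edges) + 1)
    for i in range(len(edges) - 1, -1, -1):
        suffix[i] = suffix[i + 1] + edges[i].weight

    best_obj = -1.0
    best_chosen: List[MsagEdge] = []
    matched: Set[Extremity] = set()
    used_sources: Dict[SourceKey, int] = defaultdict(int)
    uf = _UnionFind(msag.scaffolds)
    chosen: List[MsagEdge] = []
    state = {"cycle_used": False}

    def dfs(i: int, total: float) -> None:
        nonlocal best_obj, best_chosen
        if total + suffix[i] <= best_obj + _EPS:
            return
        if i == len(edges):
            best_obj = total
            best_chosen = list(chosen)
            return
        e = edges[i]
        a, b = e.key
        feasible = a not in matched and b not in matched and not any(
            used_sources[sk] for sk in e.source_keys
        )
        closes = feasible and uf.find(a.scaffold) == uf.find(b.scaffold)
        closed_here = False
        if feasible and closes:
            if allow_circular and not state["cycle_used"] and uf.component_size(
                a.scaffold
            ) == n:
                closed_here = True
            else:
                feasible = False
        if feasible:
            mark = uf.mark()
            if closed_here:
                state["cycle_used"] = True
            else:
                uf.union(a.scaffold, b.scaffold)
            matched.update((a, b))
            for sk in e.source_keys:
                used_sources[sk] += 1
            chosen.append(e)
            dfs(i + 1, total + e.weight)
            chosen.pop()
            for sk in e.source_keys:
                used_sources[sk] -= 1
            matched.difference_update((a, b))
            if closed_here:
                state["cycle_used"] = False
            else:
                uf.rollback(mark)
        dfs(i + 1, total)

    dfs(0, 0.0)
    return _finalize(best_chosen)


def validate_solution(
    M: object,
    assemblies: Sequence[Assembly],
    allow_circular: bool = False,
) -> List[str]:
    """Feasibility check of a merged assembly; returns violation messages.

    Verifies (a) all points oriented, (b) the extremity matching, (c) the
    absence of alternating cycles (a single all-scaffold cycle is exempt
    when ``allow_circular``), and (d) at most one realization per input
    point.
    """
    points = list(getattr(M, "points", M))
    violations: List[str] = []

    for p in points:
        if not p.is_oriented:
            violations.append(f"non-oriented point in merged assembly: {p}")
    points = [p for p in points if p.is_oriented]

    seen: Dict[Extremity, AssemblyPoint] = {}
    from .points import extremities as _ext

    for p in sorted(points, key=lambda q: q.key):
        for v in sorted(_ext(p)):
            if v in seen:
                violations.append(
                    f"matching violation: extremity {v} used by {seen[v]} and {p}"
                )
            else:
                seen[v] = p

    scaffolds: Set[str] = set()
    for a in assemblies:
        scaffolds.update(a.scaffolds)
    for p in points:
        scaffolds.update((p.scaffold1, p.scaffold2))
    uf = _UnionFind(scaffolds)
    cycle_used = False
    for p in sorted(points, key=lambda q: q.key):
        if uf.find(p.scaffold1) == uf.find(p.scaffold2):
            if (
                allow_circular
                and not cycle_used
                and uf.component_size(p.scaffold1) == len(scaffolds)
            ):
                cycle_used = True
            else:
                violations.append(f"alternating cycle closed by {p}")
        else:
            uf.union(p.scaffold1, p.scaffold2)

    merged_keys = {p.key for p in points}
    for a in assemblies:
        for x in a.points:
            hits = sorted(k for k in realization_keys(x) if k in merged_keys)
            if len(hits) > 1:
                violations.append(
                    f"{len(hits)} realizations of {x} (assembly {a.id}) selected"
                )
    return violations


def scaffold_orders(
    M: object, scaffolds: Iterable[str]
) -> List[Tuple[List[Tuple[str, str]], bool]]:
    """Reconstruct signed scaffold chains from a merged assembly.

    Walks the alternating paths/cycles of the merged graph and returns, per
    chromosome, a list of ``(scaffold, sign)`` entries plus a circularity
    flag.  Scaffolds absent from every merged point come out as singletons
    with sign ``"?"`` (their orientation is undetermined).  Each chain is
    emitted in its lexicographically smaller direction; output is sorted by
    first scaffold name.
    """
    points = list(getattr(M, "points", M))
    from .points import extremities as _ext

    link: Dict[Extremity, Extremity] = {}
    all_scaffolds = set(scaffolds)
    for p in points:
        a, b = sorted(_ext(p))
        link[a] = b
        link[b] = a
        all_scaffolds.update((p.scaffold1, p.scaffold2))

    def other_end(e: Extremity) -> Extremity:
        return Extremity(e.scaffold, "head" if e.end == "tail" else "tail")

    def walk(entry: Extremity, stop_scaffold: Optional[str]) -> List[Tuple[str, str]]:
        seq = []
        cur = entry
        while True:
            seq.append((cur.scaffold, "+" if cur.end == "tail" else "-"))
            exit_ = other_end(cur)
            nxt = link.get(exit_)
            if nxt is None or nxt.scaffold == stop_scaffold:
                return seq
            cur = nxt

    chains: List[Tuple[List[Tuple[str, str]], bool]] = []
    visited: Set[str] = set()
    for s in sorted(all_scaffolds):
        if s in visited:
            continue
        head, tail = Extremity(s, "head"), Extremity(s, "tail")
        if head not in link and tail not in link:
            visited.add(s)
            chains.append(([(s, "?")], False))
            continue
        # find a free end of the component, if any (path); else circular
        ends: List[Extremity] = []
        for entry in (tail, head):  # entering at the tail = forward traversal
            cur = entry
            while True:
                exit_ = other_end(cur)
                nxt = link.get(exit_)
                if nxt is None or nxt.scaffold == s:
                    break
                cur = nxt
            if nxt is None:
                ends.append(other_end(cur))
        if ends:
            candidates = [walk(e, None) for e in ends]
            circular = False
        else:
            candidates = [walk(tail, s), walk(head, s)]
            circular = True
        seq = min(candidates)
        visited.update(name for name, _ in seq)
        chains.append((seq, circular))
    chains.sort(key=lambda c: c[0][0][0])
    return chains
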