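"""Scaffold assembly graphs and conflict classification.

The scaffold assembly graph (SAG) is the breakpoint graph of a set of
scaffold assemblies: each scaffold contributes one directed *scaffold edge*
from its tail extremity to its head extremity, and every assembly point
contributes undirected *assembly edges* joining the extremities it
adjoins, colored by the assembly it came from.  An oriented point yields a
single *actual* edge; a semi-oriented or unoriented point yields one
*candidate* edge per realization (2 or 4 of them).  The graph of several
assemblies is the superposition of their individual graphs, glued on the
identically labeled scaffold edges.

Parallel assembly edges between the same two extremities form a multiedge;
its *multicolor* is the set of contributing assemblies.  ``odeg`` counts the
assembly edges incident to a vertex, ``mdeg`` the distinct neighbours —
when all k assemblies agree on an adjacency, both endpoints have
``odeg == k`` and ``mdeg == 1``, and any deviation signals disagreement.

Two oriented points conflict when their extremity pairs share exactly one
extremity (a scaffold end claimed by two different partners).  The extended
classification for non-oriented points compares all pairs of realizations:
conflicting when every pair conflicts, *semiconflicting* when some but not
all do, with an ``in-``/``out-`` prefix for same/different origin assembly.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

from .points import (
    Assembly,
    AssemblyPoint,
    Extremity,
    PointKey,
    extremities,
    realizations,
)

__all__ = [
    "AssemblyEdge",
    "ScaffoldAssemblyGraph",
    "PointClassification",
    "build_sag",
    "realization_pair_conflicts",
    "classify_points",
    "DEFAULT_ACTUAL_WEIGHT",
    "DEFAULT_CANDIDATE_FACTOR",
]

# Default confidence weights: actual edges carry full weight, candidate
# edges (realizations of un-/semi-oriented points) are discounted.
DEFAULT_ACTUAL_WEIGHT = 1.0
DEFAULT_CANDIDATE_FACTOR = 0.75


@dataclass(frozen=True)
class AssemblyEdge:
    """One colored assembly edge of the SAG.

    ``kind`` is ``"actual"`` for edges encoding oriented points and
    ``"candidate"`` for edges encoding realizations of semi-/un-oriented
    points; all edges derived from one input point share ``source``.
    """

    endpoints: FrozenSet[Extremity]
    origin: str
    kind: str  # "actual" | "candidate"
    source: AssemblyPoint
    weight: float = DEFAULT_ACTUAL_WEIGHT

    @property
    def pair_key(self) -> Tuple[Extremity, Extremity]:
        a, b = sorted(self.endpoints)
        return (a, b)

    @property
    def sort_key(self):
        return (self.pair_key, self.origin, self.kind, self.source.key)


def point_edges(
    point: AssemblyPoint,
    *,
    default_actual: float = DEFAULT_ACTUAL_WEIGHT,
    candidate_factor: float = DEFAULT_CANDIDATE_FACTOR,
) -> List[AssemblyEdge]:
    """Assembly edges encoded by one point (1 actual or 2/4 candidates)."""
    base = point.cw if point.cw is not None else default_actual
    if point.is_oriented:
        return [
            AssemblyEdge(
                endpoints=extremities(point),
                origin=point.origin,
                kind="actual",
                source=point,
                weight=base,
            )
        ]
    return [
        AssemblyEdge(
            endpoints=extremities(r),
            origin=point.origin,
            kind="candidate",
            source=point,
            weight=candidate_factor * base,
        )
        for r in sorted(realizations(point), key=lambda p: p.key)
    ]


@dataclass
class ScaffoldAssemblyGraph:
    """Superposition breakpoint graph of one or more assemblies."""

    scaffolds: Set[str] = field(default_factory=set)
    assembly_edges: List[AssemblyEdge] = field(default_factory=list)
    colors: List[str] = field(default_factory=list)

    @property
    def vertices(self) -> List[Extremity]:
        """All extremities, two per scaffold, in deterministic order."""
        return sorted(
            Extremity(s, end) for s in self.scaffolds for end in ("head", "tail")
        )

    def _check_vertex(self, vertex: Extremity) -> None:
        if vertex.scaffold not in self.scaffolds:
            raise KeyError(f"unknown vertex {vertex}")

    def odeg(self, vertex: Extremity) -> int:
        """Number of assembly edges incident to ``vertex`` (parallel counted)."""
        self._check_vertex(vertex)
        return sum(1 for e in self.assembly_edges if vertex in e.endpoints)

    def mdeg(self, vertex: Extremity) -> int:
        """Number of distinct assembly-edge neighbours of ``vertex``."""
        self._check_vertex(vertex)
        neighbours = {
            next(iter(e.endpoints - {vertex}))
            for e in self.assembly_edges
            if vertex in e.endpoints
        }
        return len(neighbours)

    def multicolor(self, endpoints: Iterable[Extremity]) -> Set[str]:
        pair = frozenset(endpoints)
        return {e.origin for e in self.assembly_edges if e.endpoints == pair}


def build_sag(
    assemblies: Sequence[Assembly],
    *,
    default_actual: float = DEFAULT_ACTUAL_WEIGHT,
    candidate_factor: float = DEFAULT_CANDIDATE_FACTOR,
) -> ScaffoldAssemblyGraph:
    """Build the combined SAG of ``assemblies`` (superposition of colors)."""
    ids = [a.id for a in assemblies]
    if len(set(ids)) != len(ids):
        raise ValueError(f"assembly ids are not distinct: {ids}")
    graph = ScaffoldAssemblyGraph(colors=list(ids))
    for asm in assemblies:
        graph.scaffolds.update(asm.scaffolds)
        for p in asm.points:
            graph.assembly_edges.extend(
                point_edges(
                    p,
                    default_actual=default_actual,
                    candidate_factor=candidate_factor,
                )
            )
    graph.assembly_edges.sort(key=lambda e: e.sort_key)
    return graph


def realization_pair_conflicts(p_r: AssemblyPoint, c_r: AssemblyPoint) -> bool:
    """Do two oriented points claim the same scaffold end for different partners?

    True iff their extremity pairs share exactly one extremity.  Identical
    pairs are *not* conflicting (the same adjacency twice), and disjoint
    pairs touch no common scaffold end.
    """
    return len(extremities(p_r) & extremities(c_r)) == 1


@dataclass
class PointClassification:
    """Non-exclusive conflict labels of one assembly point instance.

    A point may be, say, out-conflicting with one partner and
    out-semiconflicting with another; each flag records "with at least one
    other point".  ``non_conflicting`` holds iff all four flags are clear.
    """

    unique: bool = False
    in_conflicting: bool = False
    out_conflicting: bool = False
    in_semiconflicting: bool = False
    out_semiconflicting: bool = False
    in_merged: bool = False

    @property
    def non_conflicting(self) -> bool:
        return not (
            self.in_conflicting
            or self.out_conflicting
            or self.in_semiconflicting
            or self.out_semiconflicting
        )


def classify_points(
    assemblies: Sequence[Assembly],
    merged: Optional[object] = None,
) -> Dict[Tuple[str, PointKey], PointClassification]:
    """Classify every (assembly, point) instance against all other points.

    ``merged`` may be a merged assembly (anything with a ``points``
    attribute) or an iterable of oriented points; an instance gets
    ``in_merged`` when exactly one of its realizations appears there.
    """
    instances: List[Tuple[str, AssemblyPoint, List[FrozenSet[Extremity]]]] = []
    for asm in assemblies:
        for p in asm.points:
            exts = [
                extremities(r)
                for r in sorted(realizations(p), key=lambda q: q.key)
            ]
            instances.append((asm.id, p, exts))

    flags = {
        (origin, p.key): PointClassification() for origin, p, _ in instances
    }

    # uniqueness: canonical form (incl. orientation status) in exactly one assembly
    sources: Dict[PointKey, Set[str]] = defaultdict(set)
    for origin, p, _ in instances:
        sources[p.key].add(origin)
    for origin, p, _ in instances:
        flags[(origin, p.key)].unique = len(sources[p.key]) == 1

    # only pairs sharing a scaffold can share an extremity
    by_scaffold: Dict[str, List[int]] = defaultdict(list)
    for idx, (_, p, _) in enumerate(instances):
        by_scaffold[p.scaffold1].append(idx)
        by_scaffold[p.scaffold2].append(idx)
    pairs: Set[Tuple[int, int]] = set()
    for idxs in by_scaffold.values():
        for i_pos in range(len(idxs)):
            for j_pos in range(i_pos + 1, len(idxs)):
                i, j = idxs[i_pos], idxs[j_pos]
                pairs.add((i, j) if i < j else (j, i))

    for i, j in pairs:
        origin_p, p, exts_p = instances[i]
        origin_c, c, exts_c = instances[j]
        if origin_p == origin_c and p.key == c.key:
            continue  # the same instance is never compared with itself
        n_conf = sum(
            1 for ep in exts_p for ec in exts_c if len(ep & ec) == 1
        )
        total = len(exts_p) * len(exts_c)
        if n_conf == 0:
            continue
        fp = flags[(origin_p, p.key)]
        fc = flags[(origin_c, c.key)]
        same = origin_p == origin_c
        if n_conf == total:
            if same:
                fp.in_conflicting = fc.in_conflicting = True
            else:
                fp.out_conflicting = fc.out_conflicting = True
        else:
            if same:
                fp.in_semiconflicting = fc.in_semiconflicting = True
            else:
                fp.out_semiconflicting = fc.out_semiconflicting = True

    if merged is not None:
        merged_points = getattr(merged, "points", merged)
        merged_keys = {p.key for p in merged_points}
        for origin, p, _ in instances:
            hits = sum(1 for r in realizations(p) if r.key in merged_keys)
            flags[(origin, p.key)].in_merged = hits == 1

    return flags
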