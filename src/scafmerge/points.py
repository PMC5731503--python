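"""Assembly-point data model.

A draft genome assembly orders a set of *scaffolds* (atomic, possibly
oriented sequence fragments) into chains.  The elementary observation an
assembly makes is an *assembly point*: an adjacency between two scaffolds,
each carrying an orientation that is either known (forward/reverse relative
to the scaffold's own sequence) or unknown.  Techniques such as FISH mapping
or Hi-C scaffolding routinely place scaffolds without resolving their
strand, which is where semi-oriented and unoriented points come from.

This module fixes the combinatorial semantics everything else builds on:

* the three-state :class:`Orientation` and its reversal,
* the canonical representative of the two-element reversal orbit of a point
  (``(+s1, -s2)`` and ``(+s2, -s1)`` describe the same adjacency),
* enumeration of *realizations* — the oriented points obtainable by fixing
  unknown orientations (1, 2 or 4 of them),
* the mapping from an oriented point to the pair of scaffold *extremities*
  (head/tail ends) it joins, which turns assemblies into graphs.

Scaffold names are compared exactly (byte-wise); self-adjacencies are
rejected because a scaffold adjacent to itself has no valid extremity pair
under the matching model used downstream.
"""

from __future__ import annotations

import enum
import itertools
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, Iterable, Iterator, List, NamedTuple, Optional, Set, Tuple

__all__ = [
    "Orientation",
    "AssemblyPoint",
    "Extremity",
    "Assembly",
    "InvalidPointError",
    "canonicalize",
    "orientation_class",
    "realizations",
    "extremities",
    "point_from_extremities",
]


class InvalidPointError(ValueError):
    """Raised for malformed assembly points (e.g. self-adjacencies)."""


class Orientation(enum.Enum):
    """Orientation of one scaffold within an assembly point."""

    FORWARD = "+"
    REVERSE = "-"
    UNKNOWN = "?"

    def reversed(self) -> "Orientation":
        """Reversal: forward <-> reverse; unknown is a fixed point."""
        if self is Orientation.FORWARD:
            return Orientation.REVERSE
        if self is Orientation.REVERSE:
            return Orientation.FORWARD
        return self

    @property
    def is_known(self) -> bool:
        return self is not Orientation.UNKNOWN

    @classmethod
    def from_token(cls, token: str) -> "Orientation":
        try:
            return cls(token)
        except ValueError:
            raise InvalidPointError(f"unknown orientation token {token!r}") from None


class Extremity(NamedTuple):
    """One end (head or tail) of a scaffold; a vertex of the assembly graph."""

    scaffold: str
    end: str  # "head" | "tail"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.scaffold}.{'h' if self.end == 'head' else 't'}"


# Structural identity of a point, used as a dict/set key throughout.
PointKey = Tuple[str, str, str, str]


@dataclass(frozen=True)
class AssemblyPoint:
    """An adjacency between two scaffolds in one assembly.

    ``cw`` is an optional confidence weight in [0, 1] reflecting how much
    the producing method trusts this adjacency; ``None`` means unset (the
    merge step substitutes its defaults).  ``gap_size`` is opaque metadata
    carried through I/O, never used by the algorithms.
    """

    scaffold1: str
    orientation1: Orientation
    scaffold2: str
    orientation2: Orientation
    origin: str = ""
    cw: Optional[float] = None
    gap_size: Optional[float] = None

    def __post_init__(self) -> None:
        if self.scaffold1 == self.scaffold2:
            raise InvalidPointError(
                f"self-adjacency on scaffold {self.scaffold1!r} is not allowed"
            )
        if self.cw is not None and not (0.0 <= self.cw <= 1.0):
            raise InvalidPointError(f"confidence weight {self.cw} outside [0, 1]")

    @property
    def key(self) -> PointKey:
        """Structural identity of the canonical form (ignores origin/cw)."""
        c = canonicalize(self)
        return (c.scaffold1, c.orientation1.value, c.scaffold2, c.orientation2.value)

    def reversed(self) -> "AssemblyPoint":
        """The other member of the reversal orbit (same adjacency)."""
        return replace(
            self,
            scaffold1=self.scaffold2,
            orientation1=self.orientation2.reversed(),
            scaffold2=self.scaffold1,
            orientation2=self.orientation1.reversed(),
        )

    @property
    def is_oriented(self) -> bool:
        return self.orientation1.is_known and self.orientation2.is_known

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"({self.orientation1.value}{self.scaffold1}, "
            f"{self.orientation2.value}{self.scaffold2})"
        )


def canonicalize(point: AssemblyPoint) -> AssemblyPoint:
    """Return the canonical representative of the point's reversal orbit.

    The representative has ``scaffold1 <= scaffold2`` lexicographically.
    Idempotent; self-adjacencies are rejected at construction time, so the
    orientation tie-break for equal names never fires.
    """
    if point.scaffold1 <= point.scaffold2:
        return point
    return point.reversed()


def orientation_class(point: AssemblyPoint) -> str:
    """Classify a point as ``oriented``, ``semi-oriented`` or ``unoriented``."""
    known = point.orientation1.is_known + point.orientation2.is_known
    return ("unoriented", "semi-oriented", "oriented")[known]


_KNOWN = (Orientation.FORWARD, Orientation.REVERSE)


def realizations(point: AssemblyPoint) -> FrozenSet[AssemblyPoint]:
    """All oriented canonical points obtainable by fixing unknown orientations.

    An oriented point has exactly one realization (itself); a semi-oriented
    point two; an unoriented point four.
    """
    choices1 = (point.orientation1,) if point.orientation1.is_known else _KNOWN
    choices2 = (point.orientation2,) if point.orientation2.is_known else _KNOWN
    return frozenset(
        canonicalize(replace(point, orientation1=o1, orientation2=o2))
        for o1, o2 in itertools.product(choices1, choices2)
    )


def realization_keys(point: AssemblyPoint) -> FrozenSet[PointKey]:
    """Structural keys of all realizations of ``point``."""
    return frozenset(r.key for r in realizations(point))


def extremities(point: AssemblyPoint) -> FrozenSet[Extremity]:
    """The two scaffold extremities an oriented point joins.

    Convention: in ``(+x, +y)`` the head of ``x`` meets the tail of ``y``;
    reversing a scaffold swaps which of its ends participates.  The map is
    invariant under canonicalization (reversal flips both contributions).
    """
    if not point.is_oriented:
        raise InvalidPointError(f"extremities undefined for non-oriented point {point}")
    e1 = Extremity(
        point.scaffold1,
        "head" if point.orientation1 is Orientation.FORWARD else "tail",
    )
    e2 = Extremity(
        point.scaffold2,
        "tail" if point.orientation2 is Orientation.FORWARD else "head",
    )
    return frozenset((e1, e2))


def point_from_extremities(
    ends: Iterable[Extremity], origin: str = "", cw: Optional[float] = None
) -> AssemblyPoint:
    """Inverse of :func:`extremities`: rebuild the canonical oriented point."""
    a, b = sorted(ends)
    if a.scaffold == b.scaffold:
        raise InvalidPointError(f"extremity pair within one scaffold: {a}, {b}")
    return AssemblyPoint(
        scaffold1=a.scaffold,
        orientation1=Orientation.FORWARD if a.end == "head" else Orientation.REVERSE,
        scaffold2=b.scaffold,
        orientation2=Orientation.FORWARD if b.end == "tail" else Orientation.REVERSE,
        origin=origin,
        cw=cw,
    )


@dataclass
class Assembly:
    """A named set of assembly points plus the scaffolds it mentions.

    An assembly is completely defined by its set of assembly points; the
    scaffold registry additionally records isolated scaffolds (singleton
    chains) so they can surface in graphs and merged output.  Duplicate
    canonical points are collapsed keeping the maximum confidence weight
    (an unset weight counts as the default, i.e. the maximum), with a
    warning.
    """

    id: str
    _points: Dict[PointKey, AssemblyPoint] = field(default_factory=dict)
    scaffolds: Set[str] = field(default_factory=set)

    def add_point(self, point: AssemblyPoint) -> AssemblyPoint:
        p = canonicalize(replace(point, origin=self.id))
        self.scaffolds.update((p.scaffold1, p.scaffold2))
        old = self._points.get(p.key)
        if old is not None:
            warnings.warn(
                f"duplicate assembly point {p} in assembly {self.id!r}; "
                "keeping the highest confidence weight",
                stacklevel=2,
            )
            # keep the max cw; unset (None) counts as the default, the maximum
            if old.cw is None or (p.cw is not None and p.cw < old.cw):
                p = old
        self._points[p.key] = p
        return p

    def register_scaffold(self, name: str) -> None:
        self.scaffolds.add(name)

    @property
    def points(self) -> List[AssemblyPoint]:
        """Points in deterministic (canonical-key) order."""
        return [self._points[k] for k in sorted(self._points)]

    def point_keys(self) -> Set[PointKey]:
        return set(self._points)

    def __len__(self) -> int:
        return len(self._points)

    def __contains__(self, point: AssemblyPoint) -> bool:
        return point.key in self._points

    @classmethod
    def from_points(
        cls, id: str, points: Iterable[AssemblyPoint], scaffolds: Iterable[str] = ()
    ) -> "Assembly":
        asm = cls(id=id)
        for p in points:
            asm.add_point(p)
        for s in scaffolds:
            asm.register_scaffold(s)
        return asm


def parse_signed(token: str) -> Tuple[str, Orientation]:
    """Parse a signed scaffold token: ``+s1``/``-s1`` or bare ``s1`` (unknown)."""
    if token.startswith("+"):
        return token[1:], Orientation.FORWARD
    if token.startswith("-"):
        return token[1:], Orientation.REVERSE
    return token, Orientation.UNKNOWN
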