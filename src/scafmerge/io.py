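"""Readers and writers: points tables, order files, AGP, DOT and JSON graphs.

The native interchange format is a tab-separated *assembly points* table
with a header line and the fixed column order::

    origin  seq1  seq1_or  seq2  seq2_or  gap_size  cw

Orientation tokens are ``+`` / ``-`` / ``?`` (unknown); ``gap_size`` and
``cw`` accept ``?`` for "unset".  Lines starting with ``#`` are comments.
Extra columns after ``cw`` are ignored on input, which lets annotated
report exports round-trip through :func:`read_points`.

Order-based input (GRIMM-style signed sequences, one chromosome per line,
optional terminal ``$``/``@``) and AGP v2 component lines are converted to
points via :func:`points_from_orders`.  Graphs are exported as DOT text and
as Cytoscape-style JSON (nodes/edges arrays).
"""

from __future__ import annotations

import json
from typing import Dict, IO, Iterable, List, Optional, Sequence, Tuple

from .points import (
    Assembly,
    AssemblyPoint,
    Extremity,
    InvalidPointError,
    Orientation,
    parse_signed,
)
from .sag import ScaffoldAssemblyGraph

__all__ = [
    "PointsParseError",
    "POINTS_COLUMNS",
    "read_points",
    "write_points",
    "read_orders",
    "write_orders",
    "points_from_orders",
    "read_agp",
    "export_dot",
    "export_graph_json",
]

POINTS_COLUMNS = ("origin", "seq1", "seq1_or", "seq2", "seq2_or", "gap_size", "cw")

UNSET = "?"


class PointsParseError(ValueError):
    """Malformed input; the message names the offending line number."""


def _parse_cw(token: str, line_no: int) -> Optional[float]:
    if token in (UNSET, ""):
        return None
    try:
        cw = float(token)
    except ValueError:
        raise PointsParseError(f"line {line_no}: bad confidence weight {token!r}")
    if not (0.0 <= cw <= 1.0):
        raise PointsParseError(f"line {line_no}: confidence weight {cw} outside [0, 1]")
    return cw


def _parse_gap(token: str, line_no: int) -> Optional[float]:
    if token in (UNSET, ""):
        return None
    try:
        gap = float(token)
    except ValueError:
        raise PointsParseError(f"line {line_no}: bad gap size {token!r}")
    if gap < 0:
        raise PointsParseError(f"line {line_no}: negative gap size {gap}")
    return gap


def read_points(stream: IO[str]) -> List[Assembly]:
    """Parse an assembly-points table into assemblies grouped by origin.

    Points are canonicalized on the way in; assemblies come out in
    first-seen origin order.  Raises :class:`PointsParseError` (with the
    line number) on unknown orientation tokens, out-of-range weights or
    short rows.
    """
    assemblies: Dict[str, Assembly] = {}
    header: Optional[Dict[str, int]] = None
    for line_no, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if header is None:
            header = {name: i for i, name in enumerate(fields)}
            missing = [c for c in POINTS_COLUMNS[:5] if c not in header]
            if missing:
                raise PointsParseError(
                    f"line {line_no}: header lacks required columns {missing}"
                )
            continue
        if len(fields) < 5:
            raise PointsParseError(
                f"line {line_no}: expected at least 5 fields, got {len(fields)}"
            )

        def get(col: str) -> str:
            i = header[col] if col in header else -1
            return fields[i] if 0 <= i < len(fields) else UNSET

        origin = get("origin")
        try:
            point = AssemblyPoint(
                scaffold1=get("seq1"),
                orientation1=Orientation.from_token(get("seq1_or")),
                scaffold2=get("seq2"),
                orientation2=Orientation.from_token(get("seq2_or")),
                origin=origin,
                gap_size=_parse_gap(get("gap_size"), line_no),
                cw=_parse_cw(get("cw"), line_no),
            )
        except InvalidPointError as exc:
            raise PointsParseError(f"line {line_no}: {exc}") from None
        asm = assemblies.setdefault(origin, Assembly(id=origin))
        asm.add_point(point)
    return list(assemblies.values())


def _format_opt(value: Optional[float]) -> str:
    # repr round-trips floats exactly; "?" marks unset
    return UNSET if value is None else repr(value)


def write_points(assemblies: Sequence[Assembly], stream: IO[str]) -> None:
    """Serialize assemblies as a points table (deterministic row order)."""
    stream.write("\t".join(POINTS_COLUMNS) + "\n")
    for asm in sorted(assemblies, key=lambda a: a.id):
        for p in asm.points:
            stream.write(
                "\t".join(
                    (
                        asm.id,
                        p.scaffold1,
                        p.orientation1.value,
                        p.scaffold2,
                        p.orientation2.value,
                        _format_opt(p.gap_size),
                        _format_opt(p.cw),
                    )
                )
                + "\n"
            )


SignedSequence = List[Tuple[str, Orientation]]


def points_from_orders(
    sequences: Iterable[SignedSequence], origin: str
) -> Assembly:
    """Convert signed scaffold chains to an assembly of points.

    Every pair of consecutive scaffolds yields one point (a chain of n
    scaffolds yields n-1 points); singleton chains register their scaffold
    without contributing points.  A scaffold may occur only once across all
    chains of one assembly (repeats are outside the model).
    """
    asm = Assembly(id=origin)
    seen: set = set()
    for seq in sequences:
        for name, _ in seq:
            if name in seen:
                raise InvalidPointError(
                    f"scaffold {name!r} occurs more than once in assembly {origin!r}"
                )
            seen.add(name)
            asm.register_scaffold(name)
        for (n1, o1), (n2, o2) in zip(seq, seq[1:]):
            asm.add_point(
                AssemblyPoint(
                    scaffold1=n1, orientation1=o1, scaffold2=n2, orientation2=o2
                )
            )
    return asm


def read_orders(stream: IO[str], origin: str) -> Assembly:
    """Read GRIMM-style order lines (one chromosome per line) as an assembly.

    Tokens are ``+name`` / ``-name`` / bare ``name`` (unknown orientation),
    whitespace-separated; a terminal ``$`` (linear) or ``@`` (circular
    marker, accepted but adjacency-wise treated as linear input) is
    dropped; ``#`` lines are comments.
    """
    sequences: List[SignedSequence] = []
    for raw in stream:
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split()
        if tokens and tokens[-1] in ("$", "@"):
            tokens = tokens[:-1]
        if tokens:
            sequences.append([parse_signed(t) for t in tokens])
    return points_from_orders(sequences, origin)


def write_orders(
    chains: Sequence[Tuple[Sequence[Tuple[str, str]], bool]], stream: IO[str]
) -> None:
    """Write signed chains (as produced by ``merge.scaffold_orders``).

    Linear chromosomes end with ``$``, circular ones with ``@``; a sign of
    ``"?"`` (undetermined singleton orientation) writes the bare name.
    """
    for seq, circular in chains:
        tokens = [
            name if sign == "?" else f"{sign}{name}" for name, sign in seq
        ]
        tokens.append("@" if circular else "$")
        stream.write(" ".join(tokens) + "\n")


def read_agp(stream: IO[str], origin: str) -> Assembly:
    """Thin AGP v2 reader: component lines become signed chains per object.

    Gap lines (component types N/U) are skipped; component orientations
    ``+``/``-`` map directly, anything else (``?``, ``0``, ``na``) maps to
    unknown.  The chains are then delegated to :func:`points_from_orders`.
    """
    chains: Dict[str, SignedSequence] = {}
    order: List[str] = []
    for line_no, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 9:
            raise PointsParseError(
                f"line {line_no}: AGP line has {len(fields)} fields, expected 9"
            )
        obj, _, _, _, comp_type = fields[:5]
        if comp_type in ("N", "U"):
            continue
        name, orientation_token = fields[5], fields[8]
        if obj not in chains:
            chains[obj] = []
            order.append(obj)
        orientation = {
            "+": Orientation.FORWARD,
            "-": Orientation.REVERSE,
        }.get(orientation_token, Orientation.UNKNOWN)
        chains[obj].append((name, orientation))
    return points_from_orders([chains[o] for o in order], origin)


_DOT_PALETTE = (
    "red",
    "blue",
    "green",
    "orange",
    "purple",
    "brown",
    "cyan",
    "magenta",
)


def _color_map(colors: Sequence[str]) -> Dict[str, str]:
    return {
        origin: _DOT_PALETTE[i % len(_DOT_PALETTE)]
        for i, origin in enumerate(colors)
    }


def _vertex_id(v: Extremity) -> str:
    return f"{v.scaffold}.{'h' if v.end == 'head' else 't'}"


def export_dot(graph: ScaffoldAssemblyGraph) -> str:
    """Render a SAG as DOT text.

    Scaffold edges are directed tail->head and labeled by scaffold name;
    assembly edges are undirected (``dir=none``), colored per origin
    assembly, solid for actual and dashed for candidate edges.
    """
    colors = _color_map(graph.colors)
    lines = ["digraph SAG {", "  node [shape=circle];"]
    for s in sorted(graph.scaffolds):
        lines.append(
            f'  "{s}.t" -> "{s}.h" [label="{s}", color=black];'
        )
    for e in graph.assembly_edges:
        a, b = e.pair_key
        style = "solid" if e.kind == "actual" else "dashed"
        color = colors.get(e.origin, "gray")
        lines.append(
            f'  "{_vertex_id(a)}" -> "{_vertex_id(b)}" '
            f'[dir=none, color={color}, style={style}, '
            f'label="{format(e.weight, "g")}"];'
        )
    lines.append("}")
    return "\n".join(lines) + "\n"


def export_graph_json(graph: ScaffoldAssemblyGraph) -> str:
    """Export a SAG as Cytoscape-style JSON (nodes and edges arrays)."""
    nodes = [
        {"data": {"id": _vertex_id(v), "scaffold": v.scaffold, "end": v.end}}
        for v in graph.vertices
    ]
    edges = []
    for s in sorted(graph.scaffolds):
        edges.append(
            {
                "data": {
                    "source": f"{s}.t",
                    "target": f"{s}.h",
                    "type": "scaffold",
                    "label": s,
                }
            }
        )
    for e in graph.assembly_edges:
        a, b = e.pair_key
        edges.append(
            {
                "data": {
                    "source": _vertex_id(a),
                    "target": _vertex_id(b),
                    "type": "assembly",
                    "origin": e.origin,
                    "kind": e.kind,
                    "weight": e.weight,
                }
            }
        )
    return json.dumps({"nodes": nodes, "edges": edges}, indent=1, sort_keys=True)
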