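"""Comparative report tables.

Four machine-readable sections summarize how the input assemblies relate
to each other and to the merged assembly:

1. per-assembly aggregates (orientation status and conflict counts),
2. consistency across subsets of assemblies — each distinct point counted
   once, for the exact set of assemblies containing it,
3. one record per (assembly, point) instance with its classification,
4. one record per distinct point with the set of source assemblies.

Sections are plain :class:`pandas.DataFrame` values; :func:`render` writes
them as TSV files plus one JSON bundle, byte-identical across runs on
identical input.  Section 4 keeps the native points-table columns (with the
joined sources set as the origin), so its TSV re-reads through
``io.read_points``.
"""

from __future__ import annotations

import json
import os
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd

from .points import Assembly, AssemblyPoint, PointKey, orientation_class
from .sag import PointClassification

__all__ = [
    "section1",
    "section2",
    "section3",
    "section4",
    "filter_records",
    "render",
]

Classifications = Mapping[Tuple[str, PointKey], PointClassification]

_FLAGS = (
    "unique",
    "in_conflicting",
    "out_conflicting",
    "in_semiconflicting",
    "out_semiconflicting",
    "non_conflicting",
    "in_merged",
)

SOURCES_SEP = ";"


def _flag(c: PointClassification, name: str) -> bool:
    return getattr(c, name)


def section1(
    assemblies: Sequence[Assembly],
    classifications: Classifications,
    merged: Optional[object] = None,
) -> pd.DataFrame:
    """Per-assembly aggregates: orientation statuses and conflict counts."""
    rows = []
    for asm in assemblies:
        counts = {f"n_{name}": 0 for name in _FLAGS}
        status = {"n_oriented": 0, "n_semi_oriented": 0, "n_unoriented": 0}
        for p in asm.points:
            status["n_" + orientation_class(p).replace("-", "_")] += 1
            c = classifications[(asm.id, p.key)]
            for name in _FLAGS:
                counts[f"n_{name}"] += bool(_flag(c, name))
        rows.append(
            {"assembly": asm.id, "n_points": len(asm), **status, **counts}
        )
    return pd.DataFrame(
        rows,
        columns=[
            "assembly",
            "n_points",
            "n_oriented",
            "n_semi_oriented",
            "n_unoriented",
            "n_in_conflicting",
            "n_out_conflicting",
            "n_in_semiconflicting",
            "n_out_semiconflicting",
            "n_non_conflicting",
            "n_unique",
            "n_in_merged",
        ],
    )


def _point_sources(
    assemblies: Sequence[Assembly],
) -> Dict[PointKey, List[str]]:
    sources: Dict[PointKey, List[str]] = {}
    for asm in assemblies:
        for p in asm.points:
            sources.setdefault(p.key, []).append(asm.id)
    return sources


def section2(
    assemblies: Sequence[Assembly],
    classifications: Classifications,
    merged: Optional[object] = None,
    top_n: Optional[int] = None,
) -> pd.DataFrame:
    """Consistency across subsets of assemblies.

    Each distinct point is counted exactly once, for the exact subset of
    assemblies containing it; subsets with no points are omitted.  Rows are
    sorted by descending unique-point count and truncated to ``top_n``.
    """
    sources = _point_sources(assemblies)
    groups: Dict[Tuple[str, ...], List[PointKey]] = {}
    for key, origins in sources.items():
        subset = tuple(sorted(origins))
        groups.setdefault(subset, []).append(key)
    rows = []
    for subset, keys in groups.items():
        n_in_merged = n_in_conf = n_in_semi = 0
        for key in keys:
            cs = [classifications[(origin, key)] for origin in subset]
            n_in_merged += any(c.in_merged for c in cs)
            n_in_conf += any(c.in_conflicting for c in cs)
            n_in_semi += any(c.in_semiconflicting for c in cs)
        rows.append(
            {
                "subset": ",".join(subset),
                "n_unique_points": len(keys),
                "n_in_merged": n_in_merged,
                "n_in_conflicting": n_in_conf,
                "n_in_semiconflicting": n_in_semi,
            }
        )
    rows.sort(key=lambda r: (-r["n_unique_points"], r["subset"]))
    if top_n is not None:
        rows = rows[:top_n]
    return pd.DataFrame(
        rows,
        columns=[
            "subset",
            "n_unique_points",
            "n_in_merged",
            "n_in_conflicting",
            "n_in_semiconflicting",
        ],
    )


def _point_fields(p: AssemblyPoint) -> Dict[str, str]:
    return {
        "seq1": p.scaffold1,
        "seq1_or": p.orientation1.value,
        "seq2": p.scaffold2,
        "seq2_or": p.orientation2.value,
        "gap_size": "?" if p.gap_size is None else format(p.gap_size, "g"),
        "cw": "?" if p.cw is None else format(p.cw, "g"),
    }


_S3_COLUMNS = [
    "origin",
    "seq1",
    "seq1_or",
    "seq2",
    "seq2_or",
    "gap_size",
    "cw",
    "orientation_class",
    *_FLAGS,
]


def section3(
    assemblies: Sequence[Assembly], classifications: Classifications
) -> pd.DataFrame:
    """One record per (assembly, point) instance, with all flags."""
    rows = []
    for asm in assemblies:
        for p in asm.points:
            c = classifications[(asm.id, p.key)]
            rows.append(
                {
                    "origin": asm.id,
                    **_point_fields(p),
                    "orientation_class": orientation_class(p),
                    **{name: _flag(c, name) for name in _FLAGS},
                }
            )
    rows.sort(key=lambda r: (r["origin"], r["seq1"], r["seq2"], r["seq1_or"], r["seq2_or"]))
    return pd.DataFrame(rows, columns=_S3_COLUMNS)


def section4(
    assemblies: Sequence[Assembly],
    classifications: Classifications,
    merged: Optional[object] = None,
) -> pd.DataFrame:
    """One record per distinct point, with its sources set.

    The ``origin`` column repeats the joined sources set so the TSV stays
    readable as a points table; flags are aggregated over instances (a
    point carries a flag when any of its instances does).
    """
    sources = _point_sources(assemblies)
    by_key: Dict[PointKey, AssemblyPoint] = {}
    cw_by_key: Dict[PointKey, Optional[float]] = {}
    for asm in assemblies:
        for p in asm.points:
            by_key.setdefault(p.key, p)
            prev = cw_by_key.get(p.key)
            if p.key not in cw_by_key or (
                p.cw is not None and (prev is None or p.cw > prev)
            ):
                cw_by_key[p.key] = p.cw
    rows = []
    for key in sorted(by_key):
        p = by_key[key]
        origins = sorted(sources[key])
        cs = [classifications[(o, key)] for o in origins]
        joined = SOURCES_SEP.join(origins)
        fields = _point_fields(p)
        fields["cw"] = (
            "?" if cw_by_key[key] is None else format(cw_by_key[key], "g")
        )
        rows.append(
            {
                "origin": joined,
                **fields,
                "sources": joined,
                "orientation_class": orientation_class(p),
                **{name: any(_flag(c, name) for c in cs) for name in _FLAGS},
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "origin",
            "seq1",
            "seq1_or",
            "seq2",
            "seq2_or",
            "gap_size",
            "cw",
            "sources",
            "orientation_class",
            *_FLAGS,
        ],
    )


def filter_records(
    records: pd.DataFrame,
    scaffold: Optional[str] = None,
    origin: Optional[str] = None,
    flag: Optional[str] = None,
) -> pd.DataFrame:
    """Predicate filtering of section 3/4 records.

    ``scaffold`` matches a substring of either scaffold name, ``origin``
    an exact origin/source id, ``flag`` keeps rows where the named flag is
    set.
    """
    out = records
    if scaffold is not None:
        out = out[
            out["seq1"].str.contains(scaffold, regex=False)
            | out["seq2"].str.contains(scaffold, regex=False)
        ]
    if origin is not None:
        col = "sources" if "sources" in out.columns else "origin"
        out = out[
            out[col].map(lambda v: origin in str(v).split(SOURCES_SEP))
            | (out[col] == origin)
        ]
    if flag is not None:
        if flag not in _FLAGS:
            raise ValueError(f"unknown flag {flag!r}; choose from {_FLAGS}")
        out = out[out[flag]]
    return out.reset_index(drop=True)


def render(sections: Mapping[str, pd.DataFrame], destination: str) -> List[str]:
    """Write each section as TSV plus one JSON bundle; deterministic bytes."""
    os.makedirs(destination, exist_ok=True)
    paths = []
    bundle = {}
    for name in sorted(sections):
        df = sections[name]
        path = os.path.join(destination, f"{name}.tsv")
        df.to_csv(path, sep="\t", index=False, lineterminator="\n")
        bundle[name] = df.to_dict(orient="records")
        paths.append(path)
    json_path = os.path.join(destination, "report.json")
    with open(json_path, "w") as fh:
        json.dump(bundle, fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")
    paths.append(json_path)
    return paths
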