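"""Synthetic fixtures: a ground-truth scaffold order and corrupted copies.

Real inputs to assembly comparison are several draft assemblies of the
same scaffold set, each incomplete and partly wrong in its own way.  The
generator emulates that setting: a reference genome is a random signed
order of scaffolds over one or more linear chromosomes, and each derived
assembly independently

* drops a true adjacency with probability ``p_missing`` (fragmentation),
* replaces it with probability ``p_adjacency_error`` by an adjacency to a
  uniformly random free scaffold extremity (a join error),
* erases each remaining orientation with probability ``p_orientation_loss``
  (as FISH/Hi-C-style placement without strand information would).

Each derived assembly keeps the matching discipline of a genuine scaffold
order — no scaffold extremity is used twice — and never repeats a
scaffold, per the model.  All randomness flows through one
``random.Random`` stream per (seed, assembly index) with a fixed draw
order, so fixtures are stable across runs and releases.

Recovery of the reference by the merger is scored with precision/recall
over canonical oriented points.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from typing import List, Optional, Set, Tuple

from .points import (
    Assembly,
    AssemblyPoint,
    Extremity,
    Orientation,
    point_from_extremities,
    extremities,
)

__all__ = [
    "SimulationConfig",
    "RecoveryMetrics",
    "generate_reference",
    "reference_orders",
    "corrupt",
    "recovery",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated comparison."""

    n_scaffolds: int = 20
    n_chromosomes: int = 2
    n_assemblies: int = 3
    p_adjacency_error: float = 0.05
    p_orientation_loss: float = 0.2
    p_missing: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_scaffolds < 1 or self.n_chromosomes < 1 or self.n_assemblies < 1:
            raise ValueError("counts must be positive")
        if self.n_chromosomes > self.n_scaffolds:
            raise ValueError("n_chromosomes cannot exceed n_scaffolds")
        for name in ("p_adjacency_error", "p_orientation_loss", "p_missing"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name}={p} outside [0, 1]")


@dataclass(frozen=True)
class RecoveryMetrics:
    """Precision/recall of a merged assembly against the reference points."""

    precision: float
    recall: float


def _scaffold_names(n: int) -> List[str]:
    width = len(str(n))
    return [f"s{str(i).zfill(width)}" for i in range(1, n + 1)]


def reference_orders(
    config: SimulationConfig,
) -> List[List[Tuple[str, Orientation]]]:
    """The reference signed chains (deterministic in ``config.seed``).

    Scaffolds are shuffled, signed uniformly, and split into
    ``n_chromosomes`` non-empty chains at uniformly sampled cut points.
    Draw order: shuffle, then one sign draw per scaffold, then the cuts.
    """
    rng = random.Random(f"{config.seed}:reference")
    names = _scaffold_names(config.n_scaffolds)
    rng.shuffle(names)
    signed = [
        (name, rng.choice((Orientation.FORWARD, Orientation.REVERSE)))
        for name in names
    ]
    cuts = sorted(
        rng.sample(range(1, config.n_scaffolds), config.n_chromosomes - 1)
    )
    bounds = [0, *cuts, config.n_scaffolds]
    return [signed[a:b] for a, b in zip(bounds, bounds[1:])]


def generate_reference(config: SimulationConfig) -> Assembly:
    """Fully oriented reference assembly derived from the reference chains."""
    from .io import points_from_orders

    asm = points_from_orders(reference_orders(config), origin="reference")
    return asm


def corrupt(
    reference: Assembly, config: SimulationConfig, assembly_index: int
) -> Assembly:
    """Derive one corrupted assembly from the reference.

    True adjacencies are processed in canonical order; per adjacency the
    draws are: drop?, error?, (error target choice), then one orientation-
    loss draw per side of the emitted point.  An errored adjacency keeps
    its first extremity and is rewired to a random free extremity of a
    different scaffold; an adjacency whose extremities were consumed by an
    earlier rewiring is dropped.
    """
    rng = random.Random(f"{config.seed}:{assembly_index}")
    asm = Assembly(id=f"A{assembly_index + 1}")
    for s in sorted(reference.scaffolds):
        asm.register_scaffold(s)
    free: Set[Extremity] = {
        Extremity(s, end)
        for s in reference.scaffolds
        for end in ("head", "tail")
    }
    used_pairs: Set[frozenset] = set()
    for p in reference.points:
        drop = rng.random() < config.p_missing
        err = rng.random() < config.p_adjacency_error
        if drop:
            continue
        a, b = sorted(extremities(p))
        emitted: Optional[AssemblyPoint] = None
        if err:
            if a not in free:
                continue
            candidates = sorted(
                z
                for z in free
                if z.scaffold != a.scaffold
                and z != b
                and frozenset((a.scaffold, z.scaffold)) not in used_pairs
            )
            if not candidates:
                continue
            z = rng.choice(candidates)
            free.discard(a)
            free.discard(z)
            emitted = point_from_extremities((a, z))
        else:
            if a not in free or b not in free:
                continue
            if frozenset((a.scaffold, b.scaffold)) in used_pairs:
                continue
            free.discard(a)
            free.discard(b)
            emitted = point_from_extremities((a, b))
        used_pairs.add(frozenset((emitted.scaffold1, emitted.scaffold2)))
        o1 = (
            Orientation.UNKNOWN
            if rng.random() < config.p_orientation_loss
            else emitted.orientation1
        )
        o2 = (
            Orientation.UNKNOWN
            if rng.random() < config.p_orientation_loss
            else emitted.orientation2
        )
        asm.add_point(replace(emitted, orientation1=o1, orientation2=o2))
    return asm


def recovery(M: object, reference: Assembly) -> RecoveryMetrics:
    """Precision/recall of merged points against the reference points.

    Both sides are compared as canonical oriented points, so a point and
    its reversal count once.  An empty merged assembly has precision 1 by
    convention.
    """
    merged_keys = {p.key for p in getattr(M, "points", M)}
    ref_keys = reference.point_keys()
    hit = len(merged_keys & ref_keys)
    precision = 1.0 if not merged_keys else hit / len(merged_keys)
    recall = 0.0 if not ref_keys else hit / len(ref_keys)
    if not ref_keys and not merged_keys:
        recall = 0.0
    return RecoveryMetrics(precision=precision, recall=recall)
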