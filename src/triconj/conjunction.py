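"""Minimal-t-statistic conjunction maps over the three task t-maps.

A voxel belongs to a conjunction category when every included task passes
the one-sided voxel threshold and every excluded task fails it; the category
statistic is the minimum (sign-adjusted) t over the included tasks.  The
seven categories partition the set of voxels suprathreshold in at least one
task.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
from scipy import stats

from .cluster import extent_filter, label_clusters
from .glm import StatMap
from .volume_io import Mask, Volume

__all__ = [
    "TASKS",
    "TASK_LETTERS",
    "CATEGORIES",
    "ConjunctionSpec",
    "ConjunctionMap",
    "category_label",
    "category_from_label",
    "t_threshold",
    "conjoin",
    "partition",
]

TASKS = ("Value", "Mathematical", "Emotion")
TASK_LETTERS = {"Value": "V", "Mathematical": "M", "Emotion": "E"}

# The seven include-sets in the conventional reporting order.
CATEGORIES: tuple[frozenset, ...] = (
    frozenset({"Value", "Mathematical", "Emotion"}),
    frozenset({"Value", "Mathematical"}),
    frozenset({"Value", "Emotion"}),
    frozenset({"Mathematical", "Emotion"}),
    frozenset({"Value"}),
    frozenset({"Mathematical"}),
    frozenset({"Emotion"}),
)


def category_label(include: frozenset) -> str:
    """Human-readable category label, e.g. ``V&M&~E``."""
    parts = []
    for task in TASKS:
        letter = TASK_LETTERS[task]
        parts.append(letter if task in include else f"~{letter}")
    return "&".join(parts)


def category_from_label(label: str) -> frozenset:
    include = set()
    letters = {v: k for k, v in TASK_LETTERS.items()}
    for part in label.split("&"):
        part = part.strip()
        if not part.startswith("~"):
            include.add(letters[part])
    return frozenset(include)


@dataclasses.dataclass(frozen=True)
class ConjunctionSpec:
    """Which tasks must pass / fail threshold, at what level, and which sign."""

    include: frozenset
    sign: str = "positive"
    voxel_p: float = 0.001
    extent_k: int = 50

    def __post_init__(self) -> None:
        include = frozenset(self.include)
        if not include:
            raise ValueError("include must be nonempty")
        unknown = include - set(TASKS)
        if unknown:
            raise ValueError(f"unknown tasks {sorted(unknown)}")
        if self.sign not in ("positive", "negative"):
            raise ValueError("sign must be 'positive' or 'negative'")
        if not 0 < self.voxel_p < 1:
            raise ValueError("voxel_p must lie in (0, 1)")
        if self.extent_k < 1:
            raise ValueError("extent_k must be >= 1")
        object.__setattr__(self, "include", include)

    @property
    def exclude(self) -> frozenset:
        return frozenset(TASKS) - self.include

    @property
    def label(self) -> str:
        return category_label(self.include)


@dataclasses.dataclass
class ConjunctionMap:
    """Membership mask plus the minimal (sign-adjusted) t of one category."""

    min_t: Volume
    membership: Mask
    spec: ConjunctionSpec


def t_threshold(df: int, p: float, sign: str = "positive") -> float:
    """One-sided critical t value; the negative sign mirrors the threshold."""
    if df < 1:
        raise ValueError("df must be >= 1")
    if not 0 < p < 1:
        raise ValueError("p must lie in (0, 1)")
    crit = float(stats.t.isf(p, df))
    if sign == "positive":
        return crit
    if sign == "negative":
        return -crit
    raise ValueError("sign must be 'positive' or 'negative'")


def _signed_t(stat: StatMap, sign: str) -> np.ndarray:
    t = stat.values.values
    return t if sign == "positive" else -t


def conjoin(
    maps: Mapping[str, StatMap],
    spec: ConjunctionSpec,
    connectivity: int = 26,
    apply_extent: bool = True,
) -> ConjunctionMap:
    """Minimal-t conjunction of the task maps under one include/exclude spec."""
    missing = (spec.include | spec.exclude) & (set(TASKS) - set(maps))
    if missing:
        raise ValueError(f"no StatMap supplied for tasks {sorted(missing)}")
    grid = next(iter(maps.values())).values.grid
    member = np.ones(grid.dims, bool)
    min_signed = np.full(grid.dims, np.inf)
    for task in sorted(spec.include):
        stat = maps[task]
        crit = abs(t_threshold(stat.df, spec.voxel_p, "positive"))
        signed = _signed_t(stat, spec.sign)
        passes = np.isfinite(signed) & (signed >= crit)
        member &= passes
        min_signed = np.minimum(min_signed, signed)
    for task in sorted(spec.exclude):
        stat = maps[task]
        crit = abs(t_threshold(stat.df, spec.voxel_p, "positive"))
        signed = _signed_t(stat, spec.sign)
        fails = ~(np.isfinite(signed) & (signed >= crit))
        member &= fails

    membership = Mask(membership=member, grid=grid)
    if apply_extent and member.any():
        clusters = label_clusters(membership, connectivity=connectivity)
        membership = extent_filter(clusters, spec.extent_k)

    # report on the original t scale: negative conjunctions carry negative t
    min_t = min_signed if spec.sign == "positive" else -min_signed
    min_t = np.where(np.isfinite(min_t), min_t, 0.0)
    return ConjunctionMap(
        min_t=Volume(values=min_t, grid=grid), membership=membership, spec=spec
    )


def partition(
    maps: Mapping[str, StatMap],
    sign: str = "positive",
    voxel_p: float = 0.001,
    extent_k: int = 50,
    connectivity: int = 26,
    apply_extent: bool = True,
) -> dict[frozenset, ConjunctionMap]:
    """All seven conjunction categories for one sign.

    Before extent filtering the seven membership masks are pairwise disjoint
    and their union is the set of voxels suprathreshold in >= 1 task.
    """
    out: dict[frozenset, ConjunctionMap] = {}
    for include in CATEGORIES:
        spec = ConjunctionSpec(
            include=include, sign=sign, voxel_p=voxel_p, extent_k=extent_k
        )
        out[include] = conjoin(
            maps, spec, connectivity=connectivity, apply_extent=apply_extent
        )
    return out
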