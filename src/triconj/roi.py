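"""ROI construction (conjunction clusters and a-priori spheres) and response
extraction.

Conjunction ROIs are the surviving suprathreshold clusters of each category,
minus clusters overlapping supplied excluded structures and minus voxels of
more-exclusive categories lying in the immediate periphery (a configurable
dilation) of more-inclusive categories' clusters.
"""

from __future__ import annotations

import dataclasses
import json
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .cluster import connectivity_structure, label_clusters
from .conjunction import ConjunctionMap, category_label
from .volume_io import AcquisitionGrid, Mask, Volume

__all__ = [
    "ROI",
    "PairedTestResult",
    "sphere_roi",
    "rois_from_conjunctions",
    "a_priori_catalog",
    "a_priori_rois",
    "extract_responses",
    "roi_compare",
]


@dataclasses.dataclass
class ROI:
    """Named voxel set, either a conjunction cluster or an a-priori sphere."""

    name: str
    source: str  # "conjunction" | "a_priori"
    category: str
    membership: Mask
    center_mm: tuple[float, float, float] | None = None
    radius_mm: float | None = None

    def __post_init__(self) -> None:
        if self.source not in ("conjunction", "a_priori"):
            raise ValueError("source must be 'conjunction' or 'a_priori'")
        if not self.membership.membership.any():
            raise ValueError(f"ROI {self.name} is empty")


def sphere_roi(
    center_mm: Sequence[float],
    radius_mm: float,
    grid: AcquisitionGrid,
    name: str | None = None,
    category: str = "a_priori",
) -> ROI:
    """Sphere ROI by voxel-centre distance from an MNI coordinate."""
    center = np.asarray(center_mm, dtype=float)
    coords = grid.world_coordinates()
    member = ((coords - center) ** 2).sum(axis=-1) <= radius_mm**2
    if not member.any():
        raise ValueError(
            f"sphere at {tuple(center)} r={radius_mm} mm covers no voxel centre"
        )
    return ROI(
        name=name or f"sphere_{center[0]:g}_{center[1]:g}_{center[2]:g}",
        source="a_priori",
        category=category,
        membership=Mask(membership=member, grid=grid),
        center_mm=tuple(center),
        radius_mm=float(radius_mm),
    )


def _dilate(
    member: np.ndarray, grid: AcquisitionGrid, dilation_mm: float | None
) -> np.ndarray:
    """Dilate by ceil(dilation_mm / voxel) steps; None means one voxel step."""
    if dilation_mm is not None and dilation_mm <= 0:
        return member
    iters = (
        1
        if dilation_mm is None
        else max(int(np.ceil(dilation_mm / min(grid.voxel_size))), 1)
    )
    struct = connectivity_structure(26)
    return ndimage.binary_dilation(member, structure=struct, iterations=iters)


def rois_from_conjunctions(
    categories: Mapping[frozenset, ConjunctionMap],
    excluded_structures: Mask | None = None,
    dilation_mm: float | None = None,
    connectivity: int = 26,
) -> list[ROI]:
    """One ROI per surviving cluster of each conjunction category.

    Clusters overlapping ``excluded_structures`` are dropped.  Voxels of a
    category lying within ``dilation_mm`` of a cluster of a strictly
    more-inclusive category (its include-set a proper superset) are removed
    as residual-smoothing periphery; ROIs emptied by exclusion are dropped.
    """
    grid = next(iter(categories.values())).membership.grid
    # dilated footprint of every category's clusters, for the periphery rule
    halo: dict[frozenset, np.ndarray] = {
        inc: _dilate(cmap.membership.membership, grid, dilation_mm)
        for inc, cmap in categories.items()
    }
    rois: list[ROI] = []
    for include, cmap in categories.items():
        member = cmap.membership.membership
        if not member.any():
            continue
        periphery = np.zeros(grid.dims, bool)
        for other, other_halo in halo.items():
            if other > include:  # strictly more inclusive
                periphery |= other_halo
        clusters = label_clusters(
            Mask(membership=member, grid=grid),
            connectivity=connectivity,
            stat=cmap.min_t,
        )
        for k in range(1, clusters.n_clusters + 1):
            cluster_member = clusters.labels == k
            if excluded_structures is not None and np.any(
                cluster_member & excluded_structures.membership
            ):
                continue
            kept = cluster_member & ~periphery
            if not kept.any():
                continue
            rois.append(
                ROI(
                    name=f"{category_label(include)}_c{k}",
                    source="conjunction",
                    category=category_label(include),
                    membership=Mask(membership=kept, grid=grid),
                )
            )
    return rois


def a_priori_catalog() -> list[dict]:
    """Versioned catalog of meta-analysis coordinates (MNI mm, 5 mm spheres)."""
    payload = resources.files("triconj").joinpath("data/a_priori_rois.json")
    return json.loads(payload.read_text())["rois"]


def a_priori_rois(grid: AcquisitionGrid, radius_mm: float = 5.0) -> list[ROI]:
    """Sphere ROIs for every catalog entry on the given grid."""
    return [
        sphere_roi(
            entry["center_mm"],
            radius_mm,
            grid,
            name=entry["name"],
            category=entry["domain"],
        )
        for entry in a_priori_catalog()
    ]


def extract_responses(
    contrasts: Mapping[str, Mapping[str, Mapping[str, Volume]]],
    rois: Sequence[ROI],
) -> pd.DataFrame:
    """Mean response over ROI voxels per subject x task x phase x ROI.

    ``contrasts[subject][task][phase]`` is a contrast Volume.
    """
    rows = []
    for roi in rois:
        member = roi.membership.membership
        if not member.any():
            raise ValueError(f"ROI {roi.name} is empty")
        for subject, by_task in contrasts.items():
            for task, by_phase in by_task.items():
                for phase, vol in by_phase.items():
                    rows.append(
                        (
                            subject,
                            task,
                            phase,
                            roi.name,
                            float(vol.values[member].mean()),
                        )
                    )
    return pd.DataFrame(
        rows, columns=["subject", "task", "phase", "roi", "mean_response"]
    )


@dataclasses.dataclass(frozen=True)
class PairedTestResult:
    """Two-sided paired t-test with the 95% CI of the mean difference."""

    t: float
    df: int
    p: float
    ci_low: float
    ci_high: float
    mean_diff: float


def paired_ttest(a: np.ndarray, b: np.ndarray, ci: float = 0.95) -> PairedTestResult:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("need two equal-length 1-D samples")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    diff = a - b
    mean = diff.mean()
    se = diff.std(ddof=1) / np.sqrt(n)
    df = n - 1
    if se == 0:
        t = 0.0 if mean == 0 else np.inf * np.sign(mean)
        p = 1.0 if mean == 0 else 0.0
    else:
        t = mean / se
        p = float(2 * stats.t.sf(abs(t), df))
    half = stats.t.ppf(0.5 + ci / 2, df) * se
    return PairedTestResult(
        t=float(t),
        df=df,
        p=p,
        ci_low=float(mean - half),
        ci_high=float(mean + half),
        mean_diff=float(mean),
    )


def roi_compare(
    table: pd.DataFrame,
    roi: str,
    phase: str,
    task_a: str,
    task_b: str,
) -> PairedTestResult:
    """Paired t-test of two tasks' mean ROI responses across subjects."""
    sel = table[(table["roi"] == roi) & (table["phase"] == phase)]
    a = sel[sel["task"] == task_a].set_index("subject")["mean_response"]
    b = sel[sel["task"] == task_b].set_index("subject")["mean_response"]
    if not a.index.sort_values().equals(b.index.sort_values()):
        raise ValueError("both tasks must be present for the same subjects")
    b = b.loc[a.index]
    return paired_ttest(a.to_numpy(), b.to_numpy())
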