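"""Whole-brain spatial-pattern similarity between task response maps.

Per subject, the two tasks' contrast values are correlated over the voxels
that respond significantly in either task (within gray matter); correlations
are Fisher-Z transformed and task pairs compared with a paired t-test.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .roi import PairedTestResult, paired_ttest
from .volume_io import Mask, Volume

__all__ = [
    "SimilarityResult",
    "similarity_mask",
    "spatial_correlation",
    "fisher_z",
    "subject_similarity",
    "compare_pairs",
]


@dataclasses.dataclass(frozen=True)
class SimilarityResult:
    subject: str
    pair: tuple[str, str]
    phase: str
    n_voxels: int
    r: float
    z: float

    def __post_init__(self) -> None:
        if self.n_voxels < 3:
            raise ValueError("similarity needs >= 3 voxels")
        if not np.isclose(self.z, np.arctanh(self.r)):
            raise ValueError("z must equal atanh(r)")


def similarity_mask(
    sig_a: Mask,
    sig_b: Mask,
    gray: Mask,
    combine: str = "union",
) -> Mask:
    """Gray-matter-restricted combination of two significance masks."""
    if combine not in ("union", "intersection"):
        raise ValueError("combine must be 'union' or 'intersection'")
    if combine == "union":
        member = sig_a.membership | sig_b.membership
    else:
        member = sig_a.membership & sig_b.membership
    member = member & gray.membership
    if member.sum() < 3:
        raise ValueError("similarity mask has fewer than 3 voxels")
    return Mask(membership=member, grid=gray.grid)


def spatial_correlation(map_a: Volume, map_b: Volume, mask: Mask) -> float:
    """Pearson correlation of the two maps over the masked voxels."""
    member = mask.membership
    if member.sum() < 3:
        raise ValueError("need >= 3 masked voxels")
    a = map_a.values[member]
    b = map_b.values[member]
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a**2).sum() * (b**2).sum())
    if denom == 0:
        raise ValueError("zero variance within mask")
    return float((a * b).sum() / denom)


def fisher_z(r: float) -> float:
    """Variance-stabilizing transform z = atanh(r) = 0.5 ln((1+r)/(1-r))."""
    if abs(r) >= 1:
        raise ValueError("|r| must be < 1")
    return float(np.arctanh(r))


def subject_similarity(
    contrasts: Mapping[str, Mapping[str, Mapping[str, Volume]]],
    mask_for_pair: Mapping[tuple[str, str], Mask],
    phase: str,
) -> pd.DataFrame:
    """Per-subject r and Fisher Z for each requested task pair."""
    rows = []
    for subject, by_task in contrasts.items():
        for (task_a, task_b), mask in mask_for_pair.items():
            r = spatial_correlation(
                by_task[task_a][phase], by_task[task_b][phase], mask
            )
            rows.append(
                (
                    subject,
                    f"{task_a}-{task_b}",
                    phase,
                    int(mask.membership.sum()),
                    r,
                    fisher_z(r),
                )
            )
    return pd.DataFrame(
        rows, columns=["subject", "pair", "phase", "n_voxels", "r", "z"]
    )


def compare_pairs(
    table: pd.DataFrame, pair_a: str, pair_b: str, phase: str | None = None
) -> PairedTestResult:
    """Paired t-test on Fisher Z between two task pairings across subjects."""
    sel = table if phase is None else table[table["phase"] == phase]
    a = sel[sel["pair"] == pair_a].set_index("subject")["z"]
    b = sel[sel["pair"] == pair_b].set_index("subject")["z"]
    if not a.index.sort_values().equals(b.index.sort_values()):
        raise ValueError("both pairs must be present for every subject")
    b = b.loc[a.index]
    return paired_ttest(a.to_numpy(), b.to_numpy())
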